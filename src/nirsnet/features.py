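"""Group-difference scan over (metric, sparsity) and feature-vector selection.

For every combination of nodal attribute (4) and sparsity level (50 by
default) the per-channel values of patients and controls are compared with a
Welch two-sample t-test.  The selection score of a combination is the number
of channels significant at ``alpha``; the combination with the highest score
becomes the per-subject feature vector (subjects x channels).  Ties are
broken deterministically: lower sparsity first, then metric order
degree < clustering < local_efficiency < global_efficiency.

No multiple-testing correction is applied: the score is a ranking device
across combinations, not an inferential claim (pass a smaller ``alpha``
for a Bonferroni-style criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import GROUP_CONTROL, GROUP_PATIENT
from .graph_metrics import METRIC_NAMES, NodalMetricSet

__all__ = [
    "FeatureTensor",
    "SelectionReport",
    "FeatureMatrix",
    "build_feature_tensor",
    "group_difference_scan",
    "select_feature_vector",
]

logger = logging.getLogger("nirsnet.features")


@dataclass
class FeatureTensor:
    """Subjects x metrics x sparsity-levels x channels array of nodal metrics."""

    values: np.ndarray  # (n_subjects, 4, n_levels, n_channels)
    labels: np.ndarray  # (n_subjects,) in {+1, -1}
    sparsities: np.ndarray  # (n_levels,)
    channel_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)
    metric_names: tuple[str, ...] = METRIC_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("feature tensor must be 4-D (subjects, metrics, levels, channels)")
        n, m, s, c = self.values.shape
        if m != len(self.metric_names):
            raise ValueError(f"expected {len(self.metric_names)} metric slices, got {m}")
        if s != self.sparsities.size:
            raise ValueError("sparsity axis length mismatch")
        if n != self.labels.size:
            raise ValueError("label length must equal subject count")
        if not np.isfinite(self.values).all():
            raise ValueError("feature tensor contains missing/non-finite entries")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(c)]
        if not self.subject_ids:
            self.subject_ids = [f"s{i + 1:03d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[3]

    def level_index(self, sparsity: float) -> int:
        hits = np.flatnonzero(np.isclose(self.sparsities, sparsity, atol=1e-9))
        if hits.size == 0:
            raise KeyError(
                f"sparsity {sparsity} not in tensor grid "
                f"[{self.sparsities.min():.2f}..{self.sparsities.max():.2f}]"
            )
        return int(hits[0])

    def metric_index(self, metric: str) -> int:
        if metric not in self.metric_names:
            raise KeyError(f"unknown metric {metric!r}; valid: {self.metric_names}")
        return self.metric_names.index(metric)

    def subset(self, rows: np.ndarray) -> "FeatureTensor":
        """Tensor restricted to a subject subset (used for per-fold selection)."""
        rows = np.asarray(rows)
        return FeatureTensor(
            values=self.values[rows],
            labels=self.labels[rows],
            sparsities=self.sparsities,
            channel_labels=list(self.channel_labels),
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(rows)],
            metric_names=self.metric_names,
        )


@dataclass
class SelectionReport:
    """Outcome of the (metric, sparsity) group-difference scan."""

    chosen_metric: str
    chosen_sparsity: float
    per_channel_p: np.ndarray  # p-values at the chosen combination
    n_significant: int
    score_table: np.ndarray  # (4, n_levels) counts of significant channels
    alpha: float
    sparsities: np.ndarray
    metric_names: tuple[str, ...] = METRIC_NAMES

    def to_dict(self) -> dict:
        return {
            "chosen_metric": self.chosen_metric,
            "chosen_sparsity": float(self.chosen_sparsity),
            "n_significant": int(self.n_significant),
            "alpha": float(self.alpha),
            "per_channel_p": [float(p) for p in self.per_channel_p],
            "score_table": self.score_table.astype(int).tolist(),
            "sparsities": [float(s) for s in self.sparsities],
            "metric_names": list(self.metric_names),
        }


@dataclass
class FeatureMatrix:
    """Subjects x channels slice of the tensor at one (metric, sparsity)."""

    values: np.ndarray
    labels: np.ndarray
    metric: str
    sparsity: float
    channel_labels: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != self.labels.size:
            raise ValueError("row count must equal subject count")


def build_feature_tensor(
    profiles: list[list[NodalMetricSet]],
    labels: np.ndarray,
    *,
    channel_labels: list[str] | None = None,
    subject_ids: list[str] | None = None,
) -> FeatureTensor:
    """Assemble per-subject metric profiles (one per sparsity level) into a tensor."""
    if not profiles:
        raise ValueError("no subjects")
    sparsities = np.array([p.sparsity for p in profiles[0]])
    values = np.stack(
        [np.stack([ms.as_array() for ms in subj], axis=1) for subj in profiles]
    )  # (n, 4, levels, C)
    return FeatureTensor(
        values=values,
        labels=np.asarray(labels),
        sparsities=sparsities,
        channel_labels=channel_labels or [],
        subject_ids=subject_ids or [],
    )


def _welch_pvalues(patients: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Vectorised Welch t-test p-values; constant-everywhere entries get p=1."""
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # nodal metrics are legitimately constant at extreme sparsity levels
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(patients, controls, axis=0, equal_var=False)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning(
            "%d (metric, sparsity, channel) entries constant across subjects; "
            "p set to 1",
            int(bad.sum()),
        )
        p[bad] = 1.0
    return p


def group_difference_scan(tensor: FeatureTensor, alpha: float = 0.05) -> SelectionReport:
    """Score every (metric, sparsity) by its count of significant channels.

    Patients (+1) and controls (-1) are compared channel-wise with Welch's
    t-test; the winning combination maximises the number of channels with
    p < alpha, ties resolved toward lower sparsity then canonical metric
    order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pat = tensor.values[tensor.labels == GROUP_PATIENT]
    ctl = tensor.values[tensor.labels == GROUP_CONTROL]
    if pat.shape[0] < 2 or ctl.shape[0] < 2:
        raise ValueError(
            f"need at least 2 subjects per group, got {pat.shape[0]} patients "
            f"and {ctl.shape[0]} controls"
        )
    pvals = _welch_pvalues(pat, ctl)  # (4, levels, C)
    score = (pvals < alpha).sum(axis=2)  # (4, levels)

    best_metric, best_level = 0, 0
    best_score = -1
    n_levels = tensor.sparsities.size
    for li in range(n_levels):  # lower sparsity wins ties
        for mi in range(len(tensor.metric_names)):  # then metric order
            if score[mi, li] > best_score:
                best_score = int(score[mi, li])
                best_metric, best_level = mi, li
    return SelectionReport(
        chosen_metric=tensor.metric_names[best_metric],
        chosen_sparsity=float(tensor.sparsities[best_level]),
        per_channel_p=pvals[best_metric, best_level],
        n_significant=best_score,
        score_table=score,
        alpha=alpha,
        sparsities=tensor.sparsities.copy(),
    )


def select_feature_vector(
    tensor: FeatureTensor, metric: str, sparsity: float
) -> FeatureMatrix:
    """Slice the tensor at one (metric, sparsity) into a subjects x C matrix."""
    mi = tensor.metric_index(metric)
    li = tensor.level_index(sparsity)
    return FeatureMatrix(
        values=tensor.values[:, mi, li, :].copy(),
        labels=tensor.labels.copy(),
        metric=metric,
        sparsity=float(tensor.sparsities[li]),
        channel_labels=list(tensor.channel_labels),
        subject_ids=list(tensor.subject_ids),
    )
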