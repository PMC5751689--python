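"""Synthetic two-group multichannel fNIRS-like cohorts with known ground truth.

The generator emulates the study geometry the pipeline targets: 42 patients
and 34 controls, 52 channels sampled at 10 Hz for 150 s (5 s pre-scan, 25 s
wait, 70 s task, 50 s post-task), giving 1500 samples per channel.  Each
recording is the sum of four components:

* a spatially correlated Gaussian baseline whose channel-by-channel
  correlation follows a block structure (4 blocks of 13 channels; high
  within-block, low between-block correlation).  Patients get within-block
  correlations attenuated by a fixed factor — the planted connectivity
  deficit.  The baseline is temporally band-limited (Butterworth smoother)
  so it survives the 0.5 Hz preprocessing filter;
* a task-locked response: the task boxcar convolved with a canonical
  double-gamma hemodynamic response (peak 6 s, undershoot 16 s), with a
  lower amplitude in the patient group — the planted activation deficit;
* a slow sinusoidal drift with random frequency and phase per channel;
* white high-frequency noise, most of whose power lies above 0.5 Hz and is
  removed by preprocessing.

Everything is reproducible from (cohort seed, subject index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as _signal
from scipy.special import gamma as _gamma_fn

from .connectivity import CorrelationMatrix, default_sparsity_grid
from .dataio import (
    GROUP_CONTROL,
    GROUP_PATIENT,
    CohortManifest,
    ManifestEntry,
    Recording,
    write_manifest,
    write_recording,
)
from .features import FeatureTensor
from .preprocess import TaskWindow

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "build_group_correlation",
    "double_gamma_hrf",
    "simulate_recording",
    "simulate_cohort",
    "planted_feature_tensor",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study-geometry and effect-size parameters of a synthetic cohort.

    Defaults reproduce the target regime: a detectable but non-trivial group
    difference carried jointly by reduced within-block connectivity
    (attenuation 0.3: within-block r drops 0.6 -> 0.42 in patients) and a
    reduced task response amplitude (1.0 -> 0.6).
    """

    n_patients: int = 42
    n_controls: int = 34
    n_channels: int = 52
    sampling_rate_hz: float = 10.0
    task: TaskWindow = field(default_factory=TaskWindow)
    n_blocks: int = 4
    within_block_r: float = 0.6
    between_block_r: float = 0.1
    patient_connectivity_attenuation: float = 0.3
    hrf_amplitude_control: float = 1.0
    hrf_amplitude_patient: float = 0.6
    noise_sd: float = 1.0  # baseline (correlated, band-limited) amplitude
    drift_amplitude: float = 0.3
    hf_noise_sd: float = 0.4  # white noise, mostly above 0.5 Hz
    baseline_cutoff_hz: float | None = 0.2  # temporal band limit of the baseline; None = white
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_channels % self.n_blocks:
            raise ValueError("n_channels must divide evenly into n_blocks")
        if not 0 <= self.patient_connectivity_attenuation <= 1:
            raise ValueError("patient_connectivity_attenuation must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.task.total_s * self.sampling_rate_hz))

    @property
    def block_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_blocks), self.n_channels // self.n_blocks)

    def hrf_amplitude(self, group: int) -> float:
        return self.hrf_amplitude_patient if group == GROUP_PATIENT else self.hrf_amplitude_control


@dataclass
class GroundTruth:
    """What was planted: per-group target correlations and amplitudes."""

    control_correlation: CorrelationMatrix
    patient_correlation: CorrelationMatrix
    hrf_amplitude_control: float
    hrf_amplitude_patient: float
    discriminative_channels: list[int]

    def to_dict(self) -> dict:
        return {
            "control_correlation": self.control_correlation.values.tolist(),
            "patient_correlation": self.patient_correlation.values.tolist(),
            "hrf_amplitude_control": self.hrf_amplitude_control,
            "hrf_amplitude_patient": self.hrf_amplitude_patient,
            "discriminative_channels": self.discriminative_channels,
        }


def build_group_correlation(spec: CohortSpec, group: int) -> CorrelationMatrix:
    """Block-structured target correlation matrix for one group.

    Within-block entries are ``within_block_r`` (times 1-attenuation for
    patients); between-block entries are ``between_block_r``.  The matrix
    must be positive definite, otherwise the offending eigenvalue is
    reported.
    """
    within = spec.within_block_r
    if group == GROUP_PATIENT:
        within *= 1.0 - spec.patient_connectivity_attenuation
    blocks = spec.block_assignment
    same_block = blocks[:, None] == blocks[None, :]
    r = np.where(same_block, within, spec.between_block_r)
    np.fill_diagonal(r, 1.0)
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"requested block correlation is not positive definite "
            f"(minimum eigenvalue {eigmin:.3e})"
        )
    return CorrelationMatrix(r, [f"ch{i + 1:02d}" for i in range(spec.n_channels)])


def double_gamma_hrf(t_s: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalised to 1.

    Positive lobe peaking at 6 s, undershoot at 16 s with 1/6 relative
    amplitude (shape parameters 6 and 16, unit time scale).
    """
    t = np.asarray(t_s, dtype=float)
    h = np.where(
        t >= 0,
        t ** 5 * np.exp(-t) / _gamma_fn(6) - (t ** 15 * np.exp(-t) / _gamma_fn(16)) / 6.0,
        0.0,
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def _task_regressor(spec: CohortSpec) -> np.ndarray:
    """Task boxcar convolved with the HRF, peak normalised to 1."""
    n = spec.n_samples
    boxcar = np.zeros(n)
    boxcar[spec.task.task_slice(spec.sampling_rate_hz)] = 1.0
    t = np.arange(0, 32.0, 1.0 / spec.sampling_rate_hz)
    kernel = double_gamma_hrf(t)
    reg = np.convolve(boxcar, kernel)[:n]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def _band_limit(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    sos = _signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x, axis=-1)


def simulate_recording(
    target: CorrelationMatrix,
    spec: CohortSpec,
    group: int,
    subject_seed: int,
    *,
    subject_id: str | None = None,
    signal_kind: str = "oxy",
) -> Recording:
    """One synthetic recording (channels x samples) for a given group.

    The spatial correlation is imposed by a Cholesky factor of the target
    matrix; per-channel re-standardisation after temporal smoothing leaves
    the correlation structure untouched (correlation is scale-invariant).
    """
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, int(subject_seed)])
    c, n = spec.n_channels, spec.n_samples

    chol = np.linalg.cholesky(target.values)
    base = chol @ rng.standard_normal((c, n))
    if spec.baseline_cutoff_hz:
        # same filter on every channel + per-channel rescale: correlation
        # structure is untouched (Pearson r is scale-invariant)
        base = _band_limit(base, spec.baseline_cutoff_hz, spec.sampling_rate_hz)
        base /= base.std(axis=1, keepdims=True)
    base *= spec.noise_sd

    task = spec.hrf_amplitude(group) * _task_regressor(spec)

    t = np.arange(n) / spec.sampling_rate_hz
    drift_f = rng.uniform(0.005, 0.02, size=c)
    drift_phase = rng.uniform(0, 2 * np.pi, size=c)
    drift = spec.drift_amplitude * np.sin(
        2 * np.pi * drift_f[:, None] * t[None, :] + drift_phase[:, None]
    )

    hf = spec.hf_noise_sd * rng.standard_normal((c, n))

    data = base + task[None, :] + drift + hf
    return Recording(
        subject_id=subject_id or f"subj{subject_seed:03d}",
        data=data,
        sampling_rate_hz=spec.sampling_rate_hz,
        channel_labels=list(target.channel_labels),
        group=group,
        signal_kind=signal_kind,
    )


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    out_dir: str | Path | None = None,
) -> tuple[list[Recording], CohortManifest, GroundTruth]:
    """Generate a full two-group cohort (patients first, then controls).

    Per-subject seeds are the subject's index, combined with the cohort
    master seed inside :func:`simulate_recording`, so the same spec always
    regenerates identical data.  When ``out_dir`` is given, recordings,
    manifest and ground truth are written there via the dataio conventions.
    """
    targets = {
        GROUP_PATIENT: build_group_correlation(spec, GROUP_PATIENT),
        GROUP_CONTROL: build_group_correlation(spec, GROUP_CONTROL),
    }
    recordings: list[Recording] = []
    entries: list[ManifestEntry] = []
    idx = 0
    for group, count, prefix in (
        (GROUP_PATIENT, spec.n_patients, "P"),
        (GROUP_CONTROL, spec.n_controls, "C"),
    ):
        for j in range(count):
            sid = f"{prefix}{j + 1:02d}"
            rec = simulate_recording(
                targets[group], spec, group, subject_seed=idx, subject_id=sid
            )
            recordings.append(rec)
            entries.append(
                ManifestEntry(
                    subject_id=sid,
                    group=group,
                    signal_kind="oxy",
                    path=f"recordings/{sid}.csv",
                )
            )
            idx += 1
    manifest = CohortManifest(entries)
    attenuated = spec.patient_connectivity_attenuation > 0
    truth = GroundTruth(
        control_correlation=targets[GROUP_CONTROL],
        patient_correlation=targets[GROUP_PATIENT],
        hrf_amplitude_control=spec.hrf_amplitude_control,
        hrf_amplitude_patient=spec.hrf_amplitude_patient,
        discriminative_channels=list(range(spec.n_channels)) if attenuated else [],
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "recordings").mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_recording(rec, out / "recordings" / f"{rec.subject_id}.csv")
        write_manifest(manifest, out / "manifest.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh)
            fh.write("\n")
    return recordings, manifest, truth


def planted_feature_tensor(
    *,
    n_patients: int = 20,
    n_controls: int = 20,
    n_channels: int = 52,
    sparsities: np.ndarray | None = None,
    metric: str = "degree",
    sparsity: float = 0.21,
    effect_size: float = 1.5,
    n_affected_channels: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTensor, np.ndarray]:
    """Noise feature tensor with a group shift planted at one (metric, sparsity).

    All entries are N(0, 1); patients additionally receive a mean shift of
    ``effect_size`` pooled standard deviations on ``n_affected_channels``
    randomly chosen channels, only in the planted slice.  Returns the tensor
    and the affected channel indices — scaffolding for selection-recovery
    tests.
    """
    rng = rng or np.random.default_rng(0)
    if sparsities is None:
        sparsities = default_sparsity_grid()
    sparsities = np.asarray(sparsities, dtype=float)
    n = n_patients + n_controls
    values = rng.standard_normal((n, 4, sparsities.size, n_channels))
    labels = np.r_[
        np.full(n_patients, GROUP_PATIENT), np.full(n_controls, GROUP_CONTROL)
    ]
    tensor = FeatureTensor(values=values, labels=labels, sparsities=sparsities)
    mi = tensor.metric_index(metric)
    li = tensor.level_index(sparsity)
    affected = rng.choice(n_channels, size=n_affected_channels, replace=False)
    planted_slice = tensor.values[:n_patients, mi, li]  # view into the tensor
    planted_slice[:, affected] += effect_size
    return tensor, np.sort(affected)
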