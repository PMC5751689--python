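# Methods

## Pipeline model

`nirsnet` treats each subject's recording as a C × N matrix of hemoglobin
concentration changes (C channels, N samples at rate f_s; the reference
geometry is C = 52, f_s = 10 Hz, N = 1500 over a 5/25/70/50 s block
paradigm). The discrimination pipeline is a fixed chain of deterministic
stages; every stage is a pure function of its inputs and configuration, so
identical config + seed reproduces byte-identical outputs.

### Preprocessing

A zero-phase Butterworth low-pass (order 4, cutoff 0.5 Hz, applied
forward–backward with `scipy.signal.sosfiltfilt`) removes high-frequency
noise while preserving DC and hemodynamic timing. The forward–backward pass
squares the single-pass magnitude response: the closed form
|H(f)|² = 1/(1 + (f/f_c)^(2·order)) gives ≈ 1.5·10⁻⁵ residual amplitude at
2 Hz and ≥ 0.999 retention at 0.1 Hz, which the tests verify against the
filtered output directly. Edge transients are handled by `sosfiltfilt`'s
odd-reflection padding over the filter warm-up length; recordings shorter
than the warm-up are rejected with the minimum usable length. Only the
cutoff frequency is externally fixed by the problem; the Butterworth family
and order 4 are this package's choices — zero phase avoids distorting
response latencies, and an FFT brick-wall alternative was rejected because
of ringing.

Correlations are computed on the full filtered recording by default; a
`task_only` window mode restricts them to the 70 s task block (samples
[(pre+wait)·f_s, (pre+wait+task)·f_s)). Which segment is scientifically
preferable is genuinely open; both are provided and the default is the
longer, statistically more stable one.

### Network construction

Pearson correlation with the diagonal pinned to exactly 1. Binarization
uses |r| ≥ T (so strong negative couplings also form edges). The 0.01–0.50
grid is interpreted as *sparsity* levels, not raw correlation cuts: each
level S maps to the k-th largest |r| with k = round(S·M), M = C(C−1)/2.
At S = 0.5 this makes T the upper median of the correlation magnitudes.
A `raw` threshold mode applies grid values directly to |r| for users who
want the literal-threshold reading. Tie handling is deterministic: every
pair with |r| exactly equal to T is kept, so the achieved sparsity can
exceed the requested level by at most the tie-group size divided by M
(ties have measure zero for continuous data). k is clamped to ≥ 1 so tiny
matrices never produce an undefined threshold; rounding is configurable to
`floor`.

### Nodal metrics

Standard complex-network indices, computed on the binary network with
unweighted hop distances:

* degree k_i;
* Watts–Strogatz clustering C_i = 2t_i/(k_i(k_i−1)), zero for k_i < 2;
* nodal global efficiency E_glob(i) = mean over j≠i of 1/d(i,j), with
  1/∞ = 0 — the nodal (per-channel) form is used so each attribute yields a
  C-dimensional per-subject vector; the network-level scalar (the mean) is
  also exposed;
* nodal local efficiency: the efficiency of the subgraph induced by i's
  neighbours, averaged over ordered neighbour pairs, zero for k_i < 2.

Disconnected pairs contribute zero efficiency rather than restricting to
the largest component, keeping all vectors defined at the sparsest levels.
Distances come from a level-synchronous BFS implemented with boolean matrix
products (fast for these small dense graphs); tests verify equality with an
independent Floyd–Warshall oracle, exhaustive triangle counts, and
networkx on hundreds of random graphs.

### Feature selection

For every (metric, sparsity) combination, a channel-wise Welch two-sample
t-test compares patients and controls; the selection score is the number of
channels with p < α (α = 0.05 default). Welch's test was chosen because
the groups differ in size and need not share a variance; the score applies
no multiple-testing correction — it is a ranking device across
combinations, not an inferential claim (a Bonferroni-style correction can
be emulated by passing a smaller α). Ties are broken toward lower sparsity,
then metric order degree < clustering < local < global efficiency, making
selection order-independent. Channels constant across all subjects (common
at extreme sparsity, e.g. degree ≡ C−1 at S = 1) get p = 1 with a logged
warning.

Selection can run once on the whole sample before cross-validation
(`paper` mode) or be re-run inside every training fold (`fold` mode, the
default): in fold mode the held-out subject never influences which feature
is chosen, which is the statistically sound protocol. Both are reported by
the same machinery.

### Classification

RBF-kernel SVM (scikit-learn's libsvm backend) at libsvm defaults: C = 1,
γ = 1/n_features. Features are z-scored with training-fold statistics by
default because RBF kernels on raw degree counts (0…51) are scale
sensitive; `standardize=False` gives the literal unscaled variant. A zero
decision value predicts the patient class (+1), deterministically.
Leave-one-out cross-validation runs one fold per subject; the confusion
matrix is assembled across folds and summarised as ACC, sensitivity
(patient recall) and specificity (control recall), reported as percentages
rounded to one decimal.

## Synthetic cohort generator

The generator exists so every downstream stage is testable with known
ground truth. Defaults: 42 patients + 34 controls, 52 channels in 4 blocks
of 13, 10 Hz, 150 s block paradigm (N = 1500). Each recording sums:

* **Correlated baseline** — Cholesky factor of a block-structured target
  correlation (within-block r = 0.6, between-block r = 0.1) applied to
  i.i.d. Gaussians, giving the target spatial structure exactly in
  expectation. Patients' within-block correlations are attenuated by 0.3
  (0.6 → 0.42) — the planted connectivity deficit. The baseline is
  temporally band-limited (order-2 Butterworth smoother at 0.2 Hz, then
  re-standardised per channel, which cannot change Pearson correlations)
  so that it survives the 0.5 Hz preprocessing filter the way real
  hemodynamics do; setting `baseline_cutoff_hz=None` gives the plain white
  construction, used by the Monte-Carlo convergence test because smoothing
  inflates the variance of correlation estimates at fixed N.
* **Task response** — the 70 s task boxcar convolved with a canonical
  double-gamma hemodynamic response (positive lobe peaking ~5–6 s,
  undershoot at ~16 s with 1/6 relative amplitude), peak-normalised, scaled
  1.0 for controls and 0.6 for patients — the planted activation deficit.
  The response is applied uniformly across channels (a diffuse prefrontal
  activation); the HRF is test scaffolding, not a physiological claim.
* **Drift** — a sinusoid per channel with random frequency in
  0.005–0.02 Hz and random phase, amplitude 0.3.
* **High-frequency noise** — white Gaussian noise, σ = 0.4, most of whose
  power lies above 0.5 Hz and is removed by preprocessing (verified with a
  Hann-tapered spectrum; the plain FFT leaks energy from the strong slow
  components into the high band and would mask the comparison).

Baseline σ = 1 sets the amplitude scale. With these defaults the full
pipeline reaches ~88–93% LOOCV accuracy across master seeds — a detectable
but non-trivial planted effect — and falls to chance when both effects are
switched off (attenuation 0, equal amplitudes). Effect sizes were fixed
from this target regime before being frozen; they are study conditions, not
tuning knobs.

What the generator does **not** emulate: optical physics (Beer–Lambert),
motion artifacts, physiological oscillations (cardiac ~1 Hz, respiratory
~0.3 Hz) as structured rhythms, spatially varying activation topographies,
deoxy-Hb anticorrelation, or between-subject variability in connectivity
structure (all subjects of a group share one target matrix; only the noise
realisations differ). Passing tests therefore demonstrate that the
pipeline recovers connectivity/activation group differences of the planted
kind — not that it reproduces any particular clinical dataset's numbers.

## Statistical calibration checks

* **Null scan calibration** — with labels permuted (500 reps), the fraction
  of channel-level Welch tests rejecting at α = 0.05 stays within
  [0.03, 0.07].
* **Planted-signal recovery** — a 1.5 pooled-SD shift on 10 channels at
  (degree, 0.21), n = 20+20, is recovered by the scan in ≥ 90% of 50 reps.
* **Null-cohort LOOCV** — on 20 zero-effect cohorts (20+20) the *mean*
  LOOCV accuracy lies within the 95% binomial band around chance and no
  cohort exceeds the band's upper limit. Individual cohorts may fall below
  the band: leave-one-out on balanced null data is pessimistically biased,
  because removing the test subject always leaves its class as the training
  minority, and per-fold outcomes are mutually dependent. The upper-limit
  check is the direction that would expose leakage or selection optimism;
  the downward bias is an expected property of the protocol, not a defect.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 76-subject, 52-channel,
50-level pipeline (~15 s per cohort); statistical properties use 50
selection replicates, 500 permutations, and 20 null cohorts of 20+20
subjects with the single-feature (degree @ 0.21) route, which is
statistically equivalent for the null calibration and far cheaper than the
full sweep per cohort. Matrix round-trips are exact to 12 significant
digits (`%.12g`). Correlations are clipped to [−1, 1] and symmetrised
against floating-point asymmetry before validation.

## Known limitations

* The sparsity interpretation of the 0.01–0.50 grid and the nodal form of
  global efficiency are documented choices among defensible readings; the
  `raw` threshold mode and the network-level efficiency scalar cover the
  alternatives.
* Welch-t selection scores ignore correlation between channels; the score
  is a count, so two combinations with very different spatial patterns can
  tie.
* The generator's group difference is spatially uniform within blocks;
  channel-level localisation claims cannot be validated against it.
* No motion/physiology artifact correction is implemented; recordings are
  assumed already converted to concentration changes.
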