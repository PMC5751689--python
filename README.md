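# nirsnet

Functional brain-network analysis and SVM classification for multichannel
fNIRS (functional near-infrared spectroscopy) recordings.

## The problem

Prefrontal hemodynamic recordings from a working-memory task can separate
schizophrenia patients from healthy controls, but only after the raw
multichannel time series are distilled into stable discriminative features.
`nirsnet` implements that whole chain as a tested, reusable pipeline for
researchers working with ETG-style 52-channel cohorts (or any channels ×
samples layout):

1. **Preprocessing** — FFT spectrum inspection and a zero-phase order-4
   Butterworth low-pass at 0.5 Hz (hemodynamic signal lives in 0–0.5 Hz);
   optional extraction of the task block from the 5 s pre-scan / 25 s wait /
   70 s task / 50 s post-task paradigm.
2. **Network construction** — the Pearson correlation between channels i, j,

   $$r_{ij} = \frac{\mathrm{cov}(X_i, X_j)}{\sigma_{X_i}\,\sigma_{X_j}},$$

   binarized by $e_{ij} = 1 \iff |r_{ij}| \ge T$. The threshold $T$ is set
   through the network **sparsity** $S$ (fraction of realised edges over
   $M = C(C-1)/2$): $T$ is the $k$-th largest $|r|$ with $k =
   \mathrm{round}(S \cdot M)$. The default sweep covers $S = 0.01 \ldots
   0.50$ in steps of 0.01 (50 networks per subject).
3. **Nodal graph metrics** — degree $k_i$, Watts–Strogatz clustering
   $C_i = 2t_i / (k_i(k_i-1))$, and Latora–Marchiori nodal global/local
   efficiency $E_{glob}(i) = \frac{1}{C-1}\sum_{j\ne i} 1/d_{ij}$,
   $E_{loc}(i)$ = efficiency of the neighbour-induced subgraph.
4. **Feature selection** — channel-wise Welch t-tests for every
   (metric, sparsity) combination; the combination with the most channels
   significant at $\alpha = 0.05$ becomes the per-subject feature vector.
5. **Classification** — RBF-kernel SVM at libsvm defaults ($C=1$,
   $\gamma = 1/\text{n features}$), leave-one-out cross-validation, and

   $$ACC = \frac{TP+TN}{TP+FP+TN+FN},\quad SS = \frac{TP}{TP+FN},\quad
   TNR = \frac{TN}{TN+FP}$$

   with patients encoded +1 and controls −1.

Because clinical fNIRS datasets are rarely shareable, the package ships a
**synthetic cohort generator** that emulates the study geometry (42 patients
+ 34 controls, 52 channels, 10 Hz, 150 s block design) with two planted
group differences — attenuated within-block connectivity and reduced
task-response amplitude in patients — plus slow drift and high-frequency
noise, all reproducible from a single seed.

## Worked example

```python
import nirsnet as nn
from nirsnet.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(cohort=nn.CohortSpec(seed=42)))
print(f"ACC {report.accuracy_pct}%  SS {report.sensitivity_pct}%  "
      f"TNR {report.specificity_pct}%  ({len(report.folds)} folds)")
```

prints

```
ACC 92.1%  SS 85.7%  TNR 100.0%  (76 folds)
```

i.e. on the default synthetic cohort the pipeline classifies 92.1% of the
76 subjects correctly in leave-one-out cross-validation, recovering 85.7%
of patients (sensitivity) and all controls (specificity). Setting the
planted effects to zero (`patient_connectivity_attenuation=0,
hrf_amplitude_patient=1`) drops accuracy to chance — the pipeline detects
exactly the kind of group difference it is built for, and nothing when
there is none.

The same run is available from the shell:

```bash
nirsnet run --seed 42 --out runs/demo     # writes all intermediates + report.json
nirsnet simulate --out data/ --seed 7     # just generate a cohort
```

Stage-by-stage subcommands (`preprocess`, `network`, `metrics`, `features`,
`classify`) operate on the materialised intermediates of a run directory.

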