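# lcdyn — EEG source estimation and anatomically constrained connectome dynamics

`lcdyn` implements a two-stage analysis of dynamic information flow in the
brain from somatosensory-evoked EEG and diffusion-MRI tractography, for
researchers studying effective connectivity (for example, cortical network
reorganization after stroke):

1. **Source localization.** Preprocessed event-related potentials (ERPs) are
   inverted to cortical current sources with a hierarchical-variance Bayesian
   estimator: a Wiener-filter-form regularized inverse whose per-source
   current variances are updated iteratively by automatic relevance
   determination (ARD), pruning inactive cortex.
2. **Linear connectome dynamics (LCD).** Source vertices are clustered into
   regions of interest (ROIs); each ROI's mean current becomes one variable
   of a lagged multivariate autoregressive model in which inter-regional
   terms exist *only* along anatomical fiber connections, each at a delay
   `τ = length / v` set by its mean fiber length at an axonal conduction
   velocity of 6 m/s. Coefficients are estimated per target ROI by
   L2-regularized least squares (`λ = 0.01`):

   ```
   S_i(t) = a1_i S_i(t−1) + a2_i S_i(t−2) + Σ_j w_ij S_j(t − τ_ij) + e_i(t)
   ```

Model quality is scored by variance accounted for (VAF):
`VAF = (1 − var(x − x̂)/var(x))·100 %`, per channel for the sensor-level
reconstruction `M̂ = L Ŝ` (median across channels) and across ROIs per time
point for one-step (≈2 ms) dynamics prediction (mean over the 0–200 ms
window, two-fold cross-validated). Sensor quality is reported as an RMS
signal-to-noise ratio, `SNR(dB) = 10·log10(A_signal/A_noise)` with the
signal percentage `100·A_s/(A_s+A_n)`. A white-noise null — the recording
replaced by noise and pushed through the identical estimation chain —
establishes the chance level of the dynamic VAF, and an unconstrained
correlation comparator shows the false-discovery cost of dropping the
anatomical mask.

Because the analysis needs inputs that rarely ship with a repository (EEG
epochs, a leadfield, a tractography edge table), the package includes a
first-class synthetic study generator (`lcdyn.synthetic`) producing all of
them with known ground truth: SEP-like ERPs with P50/N100 deflections, a
stimulus artifact around t = 0, band-limited sensor noise at a target SNR,
a sparse two-hemisphere fiber network, and stable lagged linear dynamics
restricted to that network.

## Worked example

```python
from lcdyn.pipeline import RunConfig, run
from lcdyn.synthetic import SyntheticConfig

cfg = RunConfig(synthetic=SyntheticConfig(seed=1), baseline_realizations=100)
rep = run(cfg)  # simulate -> preprocess -> localize -> connectome -> LCD -> compare
```

Printed at the desk scale (32 channels, 500 sources, 50 ROIs, 100 trials,
10 dB target SNR):

```
sensor SNR:          10.02 dB (90.94 % signal)
P50 / N100 latency:  43.0 ms / 134.8 ms
median channel VAF:  99.98 %
dynamic VAF (CV):    95.17 % (sd 12.77)
white-noise baseline: 0.000 % over 100 realizations
intra/inter-hemispheric terms: 164 (85.42 %) / 28 (14.58 %)
correlation comparator: FP 765, FDR 91.40 %
```

Reading the numbers: the realized sensor SNR matches the 10 dB target under
the residual-based estimator; the ERP shows the expected positive deflection
near 50 ms and negative deflection near 100 ms; the ARD inverse re-explains
almost all sensor variance; one-step LCD prediction of held-out-fold source
activity accounts for ~95 % of cross-ROI variance while the same pipeline
fed pure noise accounts for none; and unconstrained correlation "detects"
hundreds of ROI pairs with no anatomical pathway (FDR > 90 %), which the
anatomically masked model excludes by construction.

The two model stages are also usable directly, statsmodels-style:

```python
from lcdyn import HierarchicalVBSource, LinearConnectomeDynamics

src = HierarchicalVBSource(erp, leadfield).fit()     # SourceEstimateResults
print(src.summary())
lcd = LinearConnectomeDynamics(roi_ts, network).fit()  # LCDResults
print(lcd.summary())
```

A `lcdyn` console script exposes the stages for shell use
(`simulate`, `preprocess`, `localize`, `connectome`, `lcd`, `compare`,
`run`); see `lcdyn --help`.

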