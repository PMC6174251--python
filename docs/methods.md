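# Methods

This note documents the models, the synthetic study generator, the numerical
choices, and the limitations of `lcdyn`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Continuous EEG is band-pass filtered 1–30 Hz with a 4th-order zero-phase
(forward–backward) Butterworth filter — zero-phase so component latencies
(P50 near 50 ms, N100 near 100 ms) are preserved — then resampled to 512 Hz
by polyphase anti-aliased decimation, with event indices rescaled. Epochs
span −50..+200 ms around the stimulus (26 + 102 = 128 samples at 512 Hz;
the 0–200 ms analysis window is 102 samples). The stimulus artifact is
removed by blanking −10..+10 ms and filling the gap with the forward
prediction of an order-3 autoregressive model fitted by least squares to up
to 100 ms of pre-gap signal, per trial and channel. Baseline correction
subtracts the per-trial mean over −50..−10 ms; trials are then averaged
into the ERP.

**AR-fill stabilization.** A least-squares AR(3) fitted to ~21 noisy samples
is explosive in a substantial fraction of trials, and an explosive 11-step
extrapolation injects artifacts larger than the one being removed (in early
experiments it biased the measured SNR by >3 dB). Poles outside the unit
circle are therefore reflected to its interior (`z → 1/conj(z)`) before
prediction. Exact-fit cases — constant signals, noiseless autoregressive
continuations — are unaffected (verified to 1e−9 in the tests).

**SNR.** `A_signal` is the RMS of the ERP over 0–200 ms (pooled over
channels, no mean removal); `A_noise` is the RMS of per-trial residuals
(trial − ERP) rescaled by `sqrt(N/(N−1))` to the single-epoch level. The
decibel convention is `10·log10(A_signal/A_noise)`: it is the power-style
formula applied to an amplitude ratio, adopted deliberately because it is
the only convention under which the standard printed (dB, signal-%) pairs of
evoked-SNR tables are mutually consistent (85.30 % ↔ 7.64 dB); the signal
percentage is `100·r/(1+r)` with `r` the amplitude ratio. Whether such
tables used pre-stimulus or residual noise is generally unstated; the
residual estimator is self-contained and testable against the generator.
RMS is always taken without mean removal; variances are sample variances
(ddof = 1) throughout.

**Peaks.** P50 is the maximum in a 30–80 ms search window, N100 the minimum
in 70–140 ms; a peak is "absent" when the extremum lies on the window
boundary (monotone trace) or the trace is flat there.

## Hierarchical-variance (ARD) source estimation

Model per time sample: `m = L s + e`, `s ~ N(0, V)` with `V = diag(v)`,
`e ~ N(0, Σ)` diagonal. Iteration alternates the posterior (Wiener) estimate
`Ŝ = V Lᵀ (L V Lᵀ + Σ)⁻¹ M` with the EM update of the per-source variances
`v_i ← (Σ_t ŝ_i(t)² + T·Σpost_ii + 2β) / (T + 2α)`, where `Σpost` is the
posterior covariance and `(α, β)` an optional inverse-gamma hyperprior
(defaults 0, 0 → plain EM, whose marginal likelihood is non-decreasing — a
tested property). An optional Gaussian kernel over source positions
(default radius 6 mm) smooths the variance map between updates, encoding
the assumption that neighboring cortex activates together; with smoothing
the EM monotonicity guarantee no longer holds formally. Convergence is
declared at relative variance change < 1e−6, cap 100 iterations.

Choices:

* **Noise covariance** — diagonal, estimated per channel from the −50..−10 ms
  ERP baseline (configurable to a fixed value).
* **Initial prior variance** — data-adaptive, `tr(M Mᵀ)/T / tr(L Lᵀ)`: the
  uniform current variance that reproduces the observed sensor power through
  the leadfield. A fixed O(1) initialization can sit orders of magnitude
  above the true current scale and under-regularize badly.
* **Fixed-variance mode** (`method="wiener"`) — a single pass at the initial
  variances; the classical MNE/Wiener baseline, equal to the closed-form
  expression (tested against direct matrix algebra).
* **Source orientation** — fixed scalar moment per vertex.
* **Channel VAF** — `(1 − var(M_i − M̂_i)/var(M_i))·100` over 0–200 ms;
  summary is the **median** across channels (channels over inactive cortex
  are uninformative and drag a mean); zero-variance channels are excluded
  with a warning; even channel counts take the mean of the two central
  values. VAF is invariant to jointly rescaling measured and reconstructed
  data and may be negative for predictors worse than the channel mean.

Exact hierarchical-Bayes update conventions differ between published
implementations; the scheme above is the standard ARD-EM form, with the
fixed-variance pass as the independently verifiable anchor.

## Connectome stage

* **Parcellation** — k-means centroids over vertex positions followed by a
  capacity-constrained nearest-first assignment (cap `ceil(n/k)`), so ROI
  sizes differ by at most one vertex ("equally distributed"); centroids are
  recomputed from final membership; deterministic under seed. Hemisphere =
  sign of the medio-lateral centroid coordinate, exact midline broken toward
  left.
* **ROI time courses** — mean of member dipole moments.
* **Conduction lags** — `lag = round_half_up(length_mm / 1000 / v · fs)`,
  clamped to ≥ 1 sample so no instantaneous inter-regional term exists (the
  inter-ROI interaction order is one, strictly lagged); default
  `v = 6 m/s`, `fs = 512 Hz`. Whether reference implementations round or
  floor, and whether they use mean or minimum streamline length, is
  unstated; half-up rounding on fiber-count-weighted mean length is this
  package's convention, property-tested against exact rational arithmetic.
* **Fiber tables** — TSV (`roi_a, roi_b, n_fibers, mean_length_mm`);
  duplicate/reversed rows merge by fiber-count-weighted mean length;
  self-loops and non-positive lengths are rejected with row numbers.

## Linear connectome dynamics

Per target ROI `i`, predictors are `S_i(t−1)`, `S_i(t−2)` and `S_j(t−τ_ij)`
for each anatomical neighbor `j`; rows are restricted to `t` with all lags
available (burn-in = the target's maximum lag). The fit is ridge,
`w = (XᵀX + λI)⁻¹ Xᵀ y`, `λ = 0.01`, no intercept, unstandardized
predictors (signals are baseline-corrected, treated as zero-mean). The
anatomical mask is asserted after every fit: no coefficient exists outside
the directed expansion of the fiber edges (each undirected edge yields two
directed coefficients sharing one lag — the convention consistent with
published interaction-count magnitudes, recorded as an assumption).

One-step prediction (≈2 ms at 512 Hz, 1000/512 = 1.953 ms, conventionally
reported as 2 ms) uses observed history only — no recursive feedback.
`VAF_S(t)` takes variances **across the ROI dimension** at fixed `t`
(sample variance); the summary is the mean ± sd over the window, excluding
time points with zero cross-ROI variance.

**Cross-validation.** Published evaluations of this model family cite a
cross-validation test without stating the protocol. Here: two-fold split of
trials — sources estimated from the odd-trial ERP, the LCD fitted on them,
and one-step prediction scored on the even-trial ERP's sources (for
trial-less series, the window is split into halves). The choice matters: an
in-sample ridge with tens of predictors per target on a 102-sample window
could not produce the near-zero white-noise baseline below.

**The absolute penalty and data scale.** `λ = 0.01` is an absolute default
applied to unstandardized predictors, so its effect depends on the data's
unit scale — a property inherited from the method being reproduced, not a
bug, but one worth understanding:

* On a single noiseless homogeneous transient (the exact-recovery
  experiments), the design's weakest direction can carry arbitrarily little
  energy; a fixed penalty then biases that direction by an amount set purely
  by the unit scale. Exact-recovery experiments therefore fit in the
  unpenalized limit (`λ = 0`), where a 102-sample window obeying the true
  recursion is recovered to ~1e−8 RMSE.
* With stochastic innovations at exactly 20 dB below the signal, the
  per-coefficient error along weakly excited directions has a statistical
  floor of roughly `1/√n` for `n ≈ 89` usable rows (~0.1), independent of
  scale. The parameter-recovery property is demonstrated at 50 dB, where
  the floor is far below the 0.05 criterion.

**White-noise baseline.** The null replaces the recorded trials by Gaussian
white noise at the measured single-epoch noise floor and repeats the entire
chain: each CV fold's "ERP" is an average of n/2 noise epochs (RMS
`A_noise/√(n/2)`), sources are estimated per fold, and the two-fold LCD CV
is scored; 100 realizations by default. Two mechanisms put the result near
zero: the hierarchical inverse sees data indistinguishable from its own
noise model (the baseline-window variance equals the whole-window variance)
and shrinks the source estimate, and what survives is small against the
absolute ridge penalty, so pure-noise coefficients collapse and
`VAF_S ≈ 0`. A ROI-level variant (`lcdyn.lcd.noise_baseline`) with an
explicit noise RMS is also provided; at an RMS matched to the data's ROI
series it yields a markedly negative VAF (≈ −100·p/n from out-of-sample
coefficient noise), which is why the sensor-level procedure — the one that
repeats the estimation chain — is the package's baseline.

**Interaction accounting.** Every directed inter-ROI coefficient permitted
by the mask is classified by whether its endpoints share a hemisphere;
percentages are of the directed total; intra-ROI (self) terms are excluded.

## Correlation comparator

Pairwise Pearson correlation of ROI time courses over the analysis window;
the detection criterion (the reference analyses leave theirs unstated) is a
two-sided test at `p < 0.05` with Bonferroni correction over pairs, exposed
in the configuration and echoed in reports. Scoring treats the anatomical
edge set as the operative truth: `FDR = FP/(FP+TP)·100 %`. On fixed data,
loosening the threshold nests the detected sets and cannot decrease the FP
count; the FDR *ratio* itself is not monotone, because added detections may
be anatomical.

## Synthetic study generator

The generator emulates a somatosensory-stimulation EEG study at a desk
scale chosen to preserve every structural feature at test speed: 32
channels, 500 source vertices, 50 ROIs, 100 trials (configurable up to the
full 64 / 10,000 / 250 / 500), 512 Hz, −50..+200 ms epochs, target sensor
SNR default 10 dB inside the study range 8–15 dB.

* **Geometry** — vertices on a superior hemispheric shell (radius ~70 mm,
  RAS mm); electrodes on a 95 mm scalp sphere.
* **Leadfield** — each channel's gain is a random radial-basis field
  (15 mm correlation length) evaluated at the vertex positions, scaled so
  evoked currents project to physiological tens of µV. Spatial smoothness
  is the property of physical leadfields that makes within-region current
  redistribution nearly invisible at the scalp; without it, region-mean
  currents are not identifiable by any inverse. Full row rank is enforced
  (regenerate up to 5 times, then error).
* **Network** — undirected ROI pairs kept with probability `edge_density`
  (default 0.10, mirroring able-bodied anatomical connection counts);
  inter-hemispheric pairs at 0.25 of that rate (callosal sparsity); lengths
  uniform 20–150 mm; lags from the conduction-velocity rule.
* **Dynamics** — per-ROI damped resonators (`a1 = 2ρcosθ, a2 = −ρ²`,
  `ρ ~ U(0.75, 0.95)`, `θ ~ U(0.05, 0.6)`) plus Gaussian directed edge
  weights (sd 0.08); all lag matrices rescaled `A_k ← c^k A_k` (which
  scales every companion eigenvalue by `c`) until the companion spectral
  radius is below 0.95.
* **Stimulus drive** — two Gamma-density kernels (positive peaking near
  50 ms, negative near 100 ms) injected into 5 contralateral-hemisphere
  ROIs with random weights and 0–15 ms per-ROI onset jitter. The jitter
  reflects cascaded activation across somatosensory areas and keeps the
  driven ROIs from crossing zero simultaneously between the P50 and N100
  (which would collapse the cross-ROI variance denominator of `VAF_S(t)` at
  single time points). Default amplitude 0.05 current-units — the package's
  unit convention, giving evoked ROI currents of ~3e−2 RMS over the window.
* **Artifact** — the 512 Hz area-preserving rendition of a 400 µs
  monophasic stimulation pulse (single-sample equivalent) plus a 2 ms
  exponential recovery tail, peak 20× the ERP's RMS amplitude, entirely
  inside ±10 ms. A long 20 ms boxcar at 20× the ERP *peak* would, after the
  zero-phase band-pass that precedes blanking, leak far outside the ±10 ms
  blanking window and corrupt the SNR accounting; the pulse rendition keeps
  the filtered leakage below the noise floor while still exercising the
  blank/fill stage hard (raw artifact ~100× the noise).
* **Noise** — Gaussian, spatially white, band-limited to the analysis band
  (1–30 Hz) since the SNR targets refer to the preprocessed signal; scaled
  so the realized single-epoch SNR under the residual estimator matches the
  target, pre-compensating two measurable effects: the epoch-in-context
  band-pass response of the clean signal, and the noise inflation caused by
  baseline correction with temporally correlated noise (the subtracted
  baseline mean is itself noisy). Round trip verified to within 1 dB.
* **Record layout** — trials concatenated with noise-only gaps of one epoch
  length; one marker per trial; written as BrainVision triplet + .sfp
  positions + HDF5 leadfield/ground truth + TSV fiber/parcellation tables.

What the generator does **not** emulate: realistic cortical geometry and
BEM volume conduction, ocular/muscle artifacts (the ICA stage is therefore
delegated and off by default), 1/f background spectra, inter-trial evoked
variability (trials share the deterministic response unless innovations are
enabled), lesions, and volume-conduction leakage structure beyond what the
smooth random leadfield induces. Passing tests therefore demonstrate the
pipeline's correctness and its behavior under the stated noise model — not
performance on recorded patient data.

## Degenerate inputs and tie-breaks

Zero-variance channels and zero-variance time points are excluded from VAF
summaries with warnings; empty detections leave FDR undefined (flagged);
empty epoch sets refuse to average; an all-zero signal cannot take an SNR
target; `edge_density = 0` yields a valid intra-only model; midline ROIs
go to the left hemisphere; BrainVision markers are 1-based on disk.

## Problem sizes used

Unit tests run miniature configurations (8–16 channels, 40–120 vertices,
4–12 ROIs); the study-level checks and the acceptance script run the desk
scale above (50 ROIs, 102-sample window, 100 trials, 100 baseline
realizations) — sizes chosen as the smallest that preserve the structural
features of the full-scale analysis.
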