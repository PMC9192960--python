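# Methods

This note documents the models implemented in `decpipe`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Signal model

Observed BOLD in region *i* is modeled as latent neural activity
convolved with a region-specific hemodynamic response function (HRF)
plus noise:

    b_i(t) = (x_i ⊛ h_i)(t) + ε_i(t).

The HRF is the canonical double-gamma difference

    h(t) ∝ Γpdf(t; a₁, d₁) − ρ · Γpdf(t; a₂, d₂),

with shape `a = delay / dispersion` and scale `d = dispersion`, so the
positive lobe peaks at `peak_delay − peak_dispersion` (5 s with the
defaults: peak delay 6 s, undershoot delay 16 s, dispersions 1 s,
undershoot ratio 1/6). Curves are peak-normalized to 1; only the shape
matters downstream because connectivity is estimated on standardized
series.

## Blind deconvolution

Resting-state data carry no task timing, so the HRF is estimated
blindly per region:

1. **Pseudo-events**: local maxima of the standardized series exceeding
   `threshold_k` SDs above the mean (default 1 SD). Detection is
   invariant to positive affine rescaling; a constant series has no
   events.
2. **HRF fit**: detected maxima lag the underlying neural onsets by
   roughly the HRF peak delay, so event indices are shifted back by
   `round(peak_delay / TR)` before fitting. The series is regressed on
   the shifted impulse train convolved with a canonical + temporal-
   derivative basis over a 0–24 s lag window (both configurable); the
   fitted basis combination is the region's HRF. With fewer events
   than basis functions the canonical shape is used instead (recorded
   in the result).
3. **Wiener inversion**: `X(f) = Y(f) H*(f) / (|H(f)|² + λ)`. The
   default λ is data-driven: the mean power of the observed series in
   the top 20% of the spectrum (a band the HRF essentially blocks, so
   it is read as noise) scaled by the peak of `|H|²`. λ = 0 is refused
   whenever `|H|` has a zero.

**Numerical choice — padding.** The FFT length is the series length
plus two kernel lengths of zero padding. Reflect padding was rejected:
its seam injects high-frequency content which the near-singular inverse
amplifies catastrophically at short TR (round-trip correlation fell
from >0.98 to 0.83 at TR 0.72 s). The first and last kernel-length
samples remain edge-contaminated and are trimmed in all quantitative
checks.

**Physical limit.** At TR 0.72 s the HRF transfer function is ~10⁻⁴ at
high frequencies; white, spike-like latent signals are unrecoverable
there in any noise. Round-trip validation at short TR therefore uses
burst-like (≈2 s) latent activity, which is also the physiologically
relevant regime. Passing round-trip tests show the inverse filter is
correct, not that arbitrary broadband signals can be recovered.

## Kalman dMVAR

The dynamic multivariate autoregression lets coefficients drift:

    y_t = Σ_k A_k(t) y_{t−k} + e_t,     θ_t = θ_{t−1} + w_t,

with `θ` the stacked vectorized `A_k` and `cov(w) = c·I`. Because every
target region shares the same lagged-regressor vector and the state
noise is isotropic, the joint filter factorizes *exactly* into one
scalar-observation Kalman filter per target region; that form is
implemented (identical estimates, O(n) cheaper). DEC of connection
j→i at time t is `Σ_k A_k(t)[i, j]`; with the default order p = 1 this
is the single lag-1 coefficient, consistent with one DEC value per
directed pair per time point. Filtering is forward-only by default (the
time-varying Granger framework is filter-based); a fixed-interval RTS
smoother is available behind `DmvarConfig(smooth=True)`.

Defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| order p | 1 | one DEC value per directed pair; p>1 sums over lags |
| adaptation c | 1e−3 | on standardized data, tracks slow drift without excess variance |
| initial state | 0, variance 10 | diffuse start; forgotten within the burn-in |
| observation noise R | recursive, exp. window α = 0.02 | estimated from innovations; avoids a second free parameter |
| burn-in | max(50, 5% of T) | discards the filter transient |
| connections | the 7 analyzed pairs (3 arbitration, 2 habitual, 2 goal-directed) when labels allow, else all ordered pairs | the full ordered-pair set is available because no fixed published subset beyond the analyzed 7 is enumerable |

Validated properties: under channel independence time-averaged DEC is
centered on 0; as c → 0 on constant-coefficient data the time-averaged
estimate converges to the full-sample least-squares VAR solution
(checked against `statsmodels` VAR within 0.05 at T = 5000); a
sinusoidal coefficient (amplitude 0.4, period 200 samples) is tracked
with correlation > 0.7 after a small grid search over c; estimates are
deterministic and permutation-equivariant.

`resample_series` provides anti-aliased polyphase resampling between
acquisition rates (e.g. 0.72 s ↔ 2.0 s); upsampling beyond 10× is
refused. Subject-level DEC means computed at native vs resampled rates
correlate strongly across subjects (> 0.8 at n = 20 in the suite),
mirroring the robustness check used when comparing cohorts acquired at
different TRs.

## Summaries and motion QC

Each connection's trajectory reduces to its arithmetic mean
(direction/magnitude) and sample SD with denominator n−1 (variability).
DVARS is the spatial SD of each successive difference image (for ROI
matrices, the SD across regions of the temporal difference); the
subject scalar is the mean over transitions. Exclusion uses a strict
`dvars > mean + 2·SD` rule computed **once** per dataset (no iterative
re-thresholding), reading "two standard deviations of the mean" as the
distribution SD rather than the standard error, which matches common
practice. Under this rule a value of 10 among {1,1,1,1,10} is *not*
excluded (threshold ≈ 10.85).

## Inference layer

* **MANCOVA**: outcomes = connection means (or SDs), group + age +
  gender + DVARS design. Implemented via hypothesis/error SSCP
  matrices: `E = Yᵀ(I − P_full)Y`, `H = Yᵀ(P_full − P_reduced)Y`,
  Pillai's trace `V = tr(H(H+E)⁻¹)`, with the standard F approximation
  — for a two-level factor `F(q, n − rank(X) − q + 1)`, giving
  F(3, 60) at n = 67 with three covariates. Cross-checked against
  `statsmodels` MANOVA to 1e−8 in the suite. Gender enters as a binary
  numeric covariate; the patient level always codes as 1 so group
  coefficients are patient-minus-control.
* **Post-hoc regressions**: per-connection OLS (group + covariates),
  Bonferroni over the connection family; residual df = n − 5.
* **Effect sizes**: `d = |t|·√(1/n₁ + 1/n₂)` with 95% CI from the
  variance approximation `(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`, z = 1.96 —
  this specific approximation reproduces published intervals to two
  decimals. Pearson tests use `t = r√((n−2)/(1−r²))` and Fisher-z CIs
  `tanh(atanh r ± 1.96/√(n−3))`.
* **Summary arithmetic**: pooled-variance (not Welch) two-sample t —
  the convention implied by df = n₁+n₂−2 in published tables — and
  Yates-continuity-corrected χ² for 2×2 gender tables (the uncorrected
  variant is a flag away).
* **Sample size**: smallest total n whose two-sample t test reaches the
  target power, computed from the noncentral t distribution. For
  d = 0.74, 85% power, one-sided α = 0.05, equal allocation this gives
  n = 54, agreeing with the normal-approximation closed form; smaller
  published figures for this configuration are not reproducible under
  standard equal-allocation assumptions.

Type-I error of the MANCOVA and post-hoc layers is calibrated by
Monte-Carlo (200 null cohorts; rejection rates required within
[0.02, 0.08] at α = 0.05).

## Synthetic cohorts: what they emulate, and what they do not

`CohortDesign` defaults emulate a two-group clinical resting-state
study: 43 patients vs 24 controls, TR 2.0 s, 300 volumes (10 min), a
patient offset of −0.109 on the L vlPFC → L putamen (A) connection
over a control mean of +0.05, between-subject coefficient SD 0.15
(so the standardized group difference is ≈ 0.73), symptom slope
+12.157 with noise SD 4.3 (YBOCS-scale scores, clipped to 0–40, SD ≈
4.7 and a DEC–symptom correlation ≈ 0.3–0.4), age ~ N(30, 10²)
truncated at 18, gender ~ Bernoulli(0.5), DVARS log-normal, about a
third of patients medicated. The coupling graph is feed-forward
(self-coupling 0.3 plus the configured directed connections), so the
companion spectral radius is bounded well below 1 for all subject
draws; the generator additionally verifies stationarity at every time
index and refuses violating specifications with the first bad index.

Not emulated: full-brain physiology, spatially structured or
physiological noise spectra, scanner drift and artifacts, HRF
undershoot variability beyond peak-delay jitter, non-Gaussian
innovations, or missing data. Passing tests therefore demonstrate the
correctness of the estimation chain under its own assumptions — not
that real acquisitions meet those assumptions.

## Problem sizes

The suite and the acceptance script run everything at desk scale:
static-limit checks at T = 5000, tracking at T = 4000 (averaged over
three realizations in the acceptance script), null calibration over
200 table-level cohorts, and one full end-to-end cohort of 67 subjects
at 300 volumes. These sizes give Monte-Carlo standard errors comfortably
inside the stated tolerances.

## Known limitations

* The blind HRF fit assumes the canonical family; pathological or
  strongly delayed hemodynamics outside the basis span degrade the
  deconvolution (the canonical fallback is recorded per region).
* DEC magnitudes after deconvolution are attenuated relative to the
  generating coefficients (≈ 0.6× in the default regime); group and
  symptom analyses rely on between-subject contrasts, which survive.
* The Kalman filter's adaptation constant trades tracking speed against
  variance; no automatic selection is performed beyond the documented
  grid search in validation.
* `extract_roi_timeseries` assumes images are already in MNI space;
  no registration is performed.
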