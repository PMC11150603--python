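# Methods

This note documents the statistical model, the estimators, the numerical
choices, the synthetic-data designs behind the validation experiments, and
the limitations a user should know about.

## Signal decomposition

Phase and amplitude series come from zero-phase Butterworth band-filtering
(second-order sections, forward-backward via `sosfiltfilt`) followed by the
frequency-domain analytic signal; `bandpass(order=4)` therefore realizes
the "8th-order zero-phase filter implemented as two passes of a 4th-order
filter" convention. The phase convention is the half-open interval
[−π, π).

**Edge padding.** Forward-backward filtering uses odd-reflection padding.
The default length is regime-dependent: records shorter than twice the
filter's 3× impulse-response scale (3·fs/bandwidth) are padded maximally
(length−1), because the odd reflection then synthesizes a coherent
continuation of the passband component — essential when one passband period
is comparable to the whole record, e.g. a 0.03–0.07 Hz band on a 20 s
signal, where short padding leaves the filtered slow wave at ~15 % of its
true RMS and badly distorts its phase. Longer records use short standard
padding (3·(2·order+1) samples), since their edge transients are a
negligible fraction of the data and long reflections measurably inject
spurious low-frequency energy from the splice (we observed stop-band
leakage at −22 dB with long padding versus −46 dB with short padding on a
400 s test tone). Amplitudes are floored at 1e−12 before model fitting
because log y enters the likelihood.

**Edge margins.** Filter and Hilbert transients occupy the first and last
~1/bandwidth seconds. For one-shot records these edge samples carry a
deterministic phase-amplitude association (the envelope dips at fixed
phases), which surrogate shifts destroy; surrogate-based inference on short
records should therefore discard an edge margin (`extract_pair(trim=...)`).
Without it we measured mildly anti-conservative empirical p-values on
uncoupled signals (P(p ≤ 0.05) ≈ 0.11 pooled over 180 runs); with a 1 s
trim the rate returns to its nominal bound.

## The gamma GLM

Amplitude given phase is gamma with constant shape α and log-linked mean
exp(L(w;θ)), L = R(θ)ᵀw with the Fourier regressors
R(θ) = (1, cos θ, sin θ, …, cos Kθ, sin Kθ). This basis is orthogonal on
the circle, so harmonics are individually interpretable and nested fits are
well-behaved. The implied rate is β(θ) = α·e^{−L}.

**Two-step fit.** The weight subproblem min_w Σ y_t e^{−L_t} + L_t is
convex and independent of α; it is solved by damped Newton iterations with
the analytic gradient Rᵀ(1 − y e^{−L}) and Hessian Rᵀdiag(y e^{−L})R,
backtracking line search, initialization w = (log ȳ, 0, …, 0), gradient
tolerance 1e−8 with an iteration cap of 500 and an L-BFGS polish as
fallback. Because gradient entries are sums of T order-one terms, the
attainable gradient norm in double precision scales with the objective;
once progress stalls the iterate is accepted at a scale-aware floor of
1e−6·max(1, |f|) (in parameter terms this is ~1e−9-level accuracy since the
Hessian has the same scale). The shape subproblem is also convex; its
stationarity condition ψ(α) − log α = mean(log y − L − y e^{−L}) + 1 has a
strictly increasing left side mapping (0, ∞) onto (−∞, 0), so the solution
is found by bracketed root-finding on log α (positivity by
reparameterization). A constant-amplitude degenerate fit (right side 0) is
reported as a warning with a large shape. Fits warn below 10 samples per
parameter.

**Model order.** K is selected from a candidate set (default {0, …, 5}) by
the minimum-description-length criterion
PNNLL(K) = NLL/T + (2K+1)/(2T)·log T, ties broken toward smaller K. The
consistency of this criterion presumes conditionally independent samples:
on i.i.d. model-class data it selects the true order essentially always
(100/100 at T = 10 000 in both the K=2 and the unmodulated arm of the
validation suite). On *filtered* envelopes of short narrowband signals the
samples are strongly autocorrelated and the criterion systematically
over-selects (see Limitations).

## Mutual information and information density

PAC is I(Y;Θ) = E_Y[D(P(Θ|Y=y) ‖ P(Θ))] in nats, with the uniform phase
prior 1/2π. The posterior over phase follows from Bayes' rule with the
fitted conditional gamma density; the relative entropy is integrated by a
midpoint Riemann sum on a uniform M-node grid (default M = 256; MI changes
by < 1e−4 nats between M = 256 and 1024 on fitted models). The expectation
over Y is the empirical average along the observed sample path; a
model-only variant integrates the fitted joint by dense 2-D quadrature
(512 phase nodes × 4000 amplitude nodes out to the 1−1e−8 conditional
quantile) and serves as the independent cross-check — the two agree within
3e−4 nats at T = 50 000 in the validation suite. All densities are handled
in log space; terms of log f(y|θ) that are constant in θ cancel between the
posterior numerator and its normalizer and are never computed, which keeps
the estimator O(T·M) with small constants. Floating-point negatives above
−1e−9 are clipped to zero; an intercept-only model returns exactly 0.

The information density i(y, θ) = log f(y|θ) − log f_Y(y) (marginal by
Riemann-sum marginalization over the same grid) may be negative; its time
average equals the sample-path MI identically.

## Goodness of fit

U_t = F(y_t | θ_t) (regularized lower incomplete gamma at shape α̂ and rate
α̂e^{−L̂}) must be i.i.d. uniform when the model is adequate. The package
reports the empirical CDF of U with pointwise 95 % KS bands
(±1.3581/√T around the diagonal) and the one-sample two-sided KS test.
When data are simulated from a model and transformed through that same
model the PIT is exactly uniform, and the 5 % KS test rejects at its
nominal rate (5.5 % of 200 replicates at T = 2000 in the validation run);
transforming through a *refitted* model is conservative because parameters
are estimated from the same data. Against lognormal amplitudes with heavy
modulation the misspecification is detected essentially always at
T = 5000. Long recordings are assessed per non-overlapping window
(`segment_pit`, default 1 s).

## Baseline measures

PLV (phase-phase; the designated negative control), MVL, ndPAC (MVL of the
standardized amplitude, implemented exactly as the printed formula, without
the original publication's significance-thresholding step), and the Tort
Modulation Index with N = 18 phase bins by default (the convention of the
original Modulation Index literature; configurable). Empty bins contribute
0·log 0 := 0 with a warning.

## Synthetic data

The generator produces x(t) = A_f(t)·sin(2πf_high t) + A_s·sin(2πf_low t)
+ η(t) with envelope A_f(t) = χ·sin(2πf_low t) + √(2−χ²), χ ∈ [0, 1], and
white Gaussian noise whose variance is set from the target SNR in dB
against the mean square of the noiseless sum (the SNR definition is a
package choice; the convention is recorded with outputs). Defaults are the
gut-brain reference conditions: 10 / 0.05 Hz, 50 Hz sampling, 20 s (one
slow cycle), A_s = 1, 0 dB SNR. Time-varying coupling replaces χ by a
per-sample χ(t) (square wave or ramp) in both the envelope and its offset.
Trial sets are independent noise realizations, each circularly shifted by
a uniform random jitter (default 1–100 samples; onset-delay jitter
available); per-trial streams are spawned from one master seed.

**Drifting oscillator.** A strictly periodic signal makes circular-shift
surrogates vacuous: shifting a perfect sinusoid's phase is a constant
phase rotation, to which every PAC measure here is invariant, so the
surrogate null coincides with the observed value. Real oscillators have a
finite phase-coherence time, which is exactly the premise of shift
surrogates. `generate_drifting` therefore concatenates independent
realizations with random time origins (the segment length acts as the
coherence time, and surrogate shifts should exceed it); it is used for the
comodulogram validation.

What the generator does **not** emulate: 1/f background spectra,
non-sinusoidal oscillation shapes (a known source of spurious PAC),
nonstationary amplitudes of the slow component, and recording artifacts.
Passing the validation suite therefore demonstrates correctness of the
estimators under the stated generative model, not robustness to these
real-data complications.

## Time-resolved PAC

idPAC evaluates the information density along the sample path of a single
fit. The raw trace leaks at the phase frequency, so it is post-processed
by a zero-phase 4th-order Butterworth lowpass and truncation of negatives
at zero. The default cutoff is 0.5·f_low: the leakage artifact sits *at*
f_low, and a 4th-order filter needs the cutoff well below it (~24 dB of
attenuation at twice the cutoff) for meaningful suppression — at a cutoff
of 0.8·f_low the artifact passes nearly unattenuated and ramp-coupling
tracking degrades from r ≈ 0.75–0.94 to r ≈ 0.65 in the 5/40 Hz
configuration. A Gaussian-kernel mode (σ in seconds, default 0.08 s) is
available for short epoched data where filter edge effects dominate.

ERPAC pools one full slow cycle (window round(fs/f_low), forced odd so the
evaluated column is the exact midpoint) across all trials at each time
point, fits one gamma GLM per window at fixed K = 2 (per-window MDL
available but slower and non-essential: the pooled window sees the full
phase range by construction), evaluates the information density at the
center column per trial, post-processes each per-trial trace as above, and
averages over trials. Edges are mirror-padded by half a window by default.
A `step` parameter evaluates every step-th column; the validation
experiment uses 100 trials × 60 s at 50 Hz with step 10 (300 window fits
on 100 × 1001-sample pools), which resolves the square-wave coupling at
the trace sampling rate of 5 Hz.

## Surrogates, p-values, FDR, comodulograms

Surrogate nulls circularly time-shift the slow signal (or its phase
series) by a uniform offset of at least a minimum shift, preserving both
marginals exactly. Empirical p-values use the (1 + #{surrogates ≥
observed}) / (1 + N) convention so p is never zero; when only ~100
surrogates are affordable a gamma distribution is fitted to the surrogate
values (moment-matched start, MLE, location fixed at 0) and used for tail
p-values, guarded by a KS check at the 0.05 level with automatic fallback
to the empirical p-value on rejection.

Benjamini-Hochberg control follows the critical-index formulation
(c = largest rank i with p(i) < q·i/N; all ranks ≤ c rejected, including
any above the line below c), with adjusted values p(i)·N/i reported
without monotonicity enforcement; Benjamini-Yekutieli divides the level by
the harmonic number. Both match brute-force step-up oracles on 1000 random
instances in the validation suite, and simulated FDR is controlled at
q = 0.05 (empirical 0.044).

Comodulograms scan 4 Hz-wide low bands stepped by 2 Hz from 0.5 Hz (starts
strictly below the stop frequency; (0.5, 20.5, 4, 2) gives the ten bands
[0.5, 4.5] … [18.5, 22.5]) against 10 Hz-wide high bands stepped by 5 Hz
up to a user-supplied upper frequency (spectral-peak-driven selection of
that bound is out of scope, so it is an explicit parameter). Cells are
computed independently with counter-derived seeds, so results are
identical under any evaluation order; non-significant cells are zeroed for
display.

## Validation experiment sizes

The reference experiments (in `gammapac.experiments`, re-run by
`scripts/acceptance.py`) use: parameter recovery at T = 20 000 over 20
seeds; MDL selection over 100 replicates at T = 10 000; ROC with 30
coupled vs 30 uncoupled 20 s signals over 20 repetitions at χ ∈ {0.1,
0.3}; GOF calibration over 200 replicates at T = 2000 and power over 50
replicates at T = 5000; tracking over 20 seeds per configuration (12 s at
200 Hz for 5/40 Hz, 120 s at 50 Hz for 0.05/10 Hz); ERPAC with 100 trials
of 60 s; comodulogram localization on an 80 s drifting signal (16 × 5 s
segments) at 125 Hz with 50 surrogates per cell and gamma-fitted nulls.
These sizes were chosen to make each experiment's Monte-Carlo error small
relative to the effect it demonstrates.

## Known limitations

- **MDL on autocorrelated envelopes.** On single-slow-cycle records the
  envelope noise of the filtered fast band is smooth on the timescale of
  the phase sweep, so the i.i.d. likelihood overstates the evidence for
  high Fourier orders and the MDL criterion often selects K = 4–5 on
  uncoupled signals. The MI from such over-parameterized fits is inflated
  and more variable, which costs discrimination power at low coupling. A
  fixed small K (1–2) is markedly more powerful in that regime (AUC ≈ 0.99
  versus ≈ 0.88–0.92 at χ = 0.3 under the reference conditions). Users
  analyzing short records should prefer a fixed small order or select K on
  an independent record.
- **Band-edge leakage of binned measures.** With sinusoidal AM, the
  spectral sidebands sit at f_high ± f_low; scan bands whose edge falls
  between carrier and sideband pass the sideband at full gain while
  attenuating the carrier, inflating the *relative* modulation depth. The
  Tort MI, being scale-invariant, systematically peaks in such off-target
  bands in the 5→40 Hz localization experiment; the gamma-MI peak stays in
  the band pair containing the true frequencies.
- **Surrogates require phase drift.** On strictly periodic signals,
  shift surrogates cannot destroy coupling (see above); minimum shifts
  must exceed the oscillator's coherence time.
- **Uniform phase prior.** The MI calculation assumes a uniform phase
  marginal, appropriate for narrowband oscillations; an empirical prior
  hook would be needed for strongly non-uniform phase distributions and is
  not implemented.
- Gamma mixture conditionals and IRLS acceleration of the fit are out of
  scope.
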