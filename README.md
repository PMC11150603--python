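# gammapac

Phase-amplitude coupling (PAC) estimation for electrophysiology, built on a
gamma generalized linear model of the joint amplitude-phase distribution.

## The problem

Cross-frequency coupling — in particular the modulation of a fast
oscillation's amplitude envelope by a slow oscillation's phase — is a
widespread motif in neural and gut-brain electrophysiology (theta-gamma
coupling in hippocampus, the ~0.05 Hz gastric slow wave modulating cortical
alpha). The workhorse PAC measures (Tort's Modulation Index, mean vector
length, ndPAC) summarize the binned or first-moment relation between phase
and amplitude but do not model their joint statistics, which limits
statistical interpretation and power at low coupling strengths.

`gammapac` instead fits the full conditional distribution of amplitude given
phase and reports PAC as the **mutual information** of the fitted joint — a
canonical dependence measure that is non-negative and zero exactly under
independence.

## The model

Let Y ≥ 0 be the instantaneous amplitude of the fast band (Hilbert envelope)
and Θ ∈ [−π, π) the instantaneous phase of the slow band, with a uniform
phase prior f(θ) = 1/2π. The conditional model is gamma with constant shape
α and a log-linked, Fourier-parameterized mean:

    Y | Θ=θ  ~  Gamma(α, rate β(θ) = α e^{−L(w;θ)}),
    L(w;θ) = w₀ + Σ_{k=1..K} [w_{2k−1} cos(kθ) + w_{2k} sin(kθ)]

Fitting is two-step and convex: ŵ minimizes Σ_t (y_t e^{−L_t} + L_t)
(independent of α), then α̂ solves a 1-D convex problem. The Fourier order K
is chosen by minimum description length (penalized normalized negative
log-likelihood, penalty (2K+1)/(2T)·log T). PAC is then

    I(Y;Θ) = E_Y[ D_KL( P(Θ|Y=y) ‖ P(Θ) ) ]   (nats),

computed via Bayes' rule and a Riemann sum on the circle, averaged along the
observed sample path. The same machinery yields a time-resolved measure: the
information density i(y_t, θ_t) = log f(y_t|θ_t)/f(y_t) ("idPAC"), whose time
average is exactly the MI, and an event-related variant (ERPAC) that pools a
full slow-oscillation cycle across trials at every time point. Model
adequacy is checked by the probability integral transform: U_t = F(y_t|θ_t)
must be uniform, assessed with Kolmogorov-Smirnov statistics and probability
plots. Significance uses circular time-shift surrogates with
Benjamini-Hochberg FDR control across comodulogram band grids.

The classical comparators (PLV, MVL, ndPAC, Tort MI) and a synthetic
coupled-signal generator (sinusoidal carrier, amplitude-modulated by a slow
sinusoid, Gaussian noise at a target SNR; optional time-varying coupling and
jittered trials) are included.

## Worked example

```python
from gammapac import (SyntheticSpec, generate, extract_pair, clip_amplitude,
                      select_order, mutual_information, tort_mi,
                      pit, ks_statistic)

# gut-brain-like signal: 10 Hz carrier modulated by a 0.05 Hz slow wave,
# coupling strength 0.3, 0 dB SNR, 100 s at 50 Hz
spec = SyntheticSpec(f_high=10.0, f_low=0.05, fs=50.0, duration=100.0,
                     chi=0.3, snr_db=0.0, seed=7)
x = generate(spec)
phase, amp = extract_pair(x, (0.03, 0.07), (8.0, 12.0))
y = clip_amplitude(amp)

report = select_order(y, phase, candidates=(1, 2, 3, 4, 5))
model = report.model
mi = mutual_information(y, phase, model)
print(f"chosen Fourier order K = {model.K}")
print(f"gamma shape alpha      = {model.alpha:.2f}")
print(f"gamma-MI PAC           = {mi.value:.4f} nats")
print(f"Tort MI                = {tort_mi(y, phase):.4f}")
D, p = ks_statistic(pit(y, phase, model))
print(f"PIT KS statistic D     = {D:.3f}")
```

prints

```
chosen Fourier order K = 4
gamma shape alpha      = 10.68
gamma-MI PAC           = 0.0852 nats
Tort MI                = 0.0035
PIT KS statistic D     = 0.050
```

The gamma-MI of 0.085 nats quantifies how much observing the slow-wave phase
reduces uncertainty about the alpha-band amplitude. The same pipeline on an
uncoupled signal (`chi=0`) gives 0.0135 nats — a six-fold separation at a
coupling strength where binned measures barely move (Tort MI 0.0035). The KS
statistic near 0.05 on 5000 points indicates an adequate conditional fit.

A command-line interface mirrors the library:

```bash
gammapac simulate --chi 0.3 --seed 7 sig.csv
gammapac pac --method gamma-mi --phase phase.csv --amp amp.csv
gammapac comodulogram --in sig.csv --fs 125 --low 0.5:20.5:4:2 \
    --high 0.5:45.5:10:5 --measure gamma-mi --surrogates 100 \
    --min-shift 5 --fdr bh:0.05 --out comod
```

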