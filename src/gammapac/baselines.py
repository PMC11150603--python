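"""Reference cross-frequency-coupling measures used as comparators.

All four are time-order-blind statistics of the (phase, amplitude) sample
cloud:

* ``plv``  — phase-locking value, |mean unit phasor of the phase difference|
  (a phase-phase measure; serves as the negative control for PAC).
* ``mvl``  — mean vector length, |mean amplitude-weighted phasor|.
* ``ndpac`` — MVL computed on the standardized (zero-mean, unit-variance)
  amplitude.
* ``tort_mi`` — Modulation Index: KL divergence of the phase-binned,
  normalized mean-amplitude profile from uniform, divided by log(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BinnedPhaseProfile", "plv", "mvl", "ndpac", "tort_mi"]

DEFAULT_TORT_BINS = 18


@dataclass
class BinnedPhaseProfile:
    """Phase-binned mean-amplitude profile normalized to a distribution."""

    n_bins: int
    edges: np.ndarray          # N+1 edges spanning [-pi, pi)
    mean_amp: np.ndarray       # N mean amplitudes (0 for empty bins)
    pmf: np.ndarray            # N probabilities summing to 1


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if a.size != b.size:
        raise ValueError("sequences must have equal length")
    return a, b


def plv(phi1, phi2) -> float:
    """Phase-locking value in [0, 1]."""
    phi1, phi2 = _check_pair(phi1, phi2)
    return float(np.abs(np.mean(np.exp(1j * (phi1 - phi2)))))


def mvl(a1, phi2) -> float:
    """Mean vector length (amplitude-weighted mean phasor modulus)."""
    a1, phi2 = _check_pair(a1, phi2)
    if np.any(a1 < 0):
        raise ValueError("amplitudes must be non-negative")
    return float(np.abs(np.mean(a1 * np.exp(1j * phi2))))


def ndpac(a1, phi2) -> float:
    """Normalized direct PAC: MVL of the standardized amplitude."""
    a1, phi2 = _check_pair(a1, phi2)
    sd = np.std(a1)
    if sd == 0:
        raise ValueError("amplitude has zero variance")
    a_norm = (a1 - np.mean(a1)) / sd
    return float(np.abs(np.mean(a_norm * np.exp(1j * phi2))))


def binned_profile(amplitude, phase, n_bins: int = DEFAULT_TORT_BINS
                   ) -> BinnedPhaseProfile:
    """Phase-binned conditional-mean amplitude profile, normalized to a PMF."""
    amplitude, phase = _check_pair(amplitude, phase)
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    if np.any(counts == 0):
        warnings.warn("empty phase bin(s); their KL contribution is 0",
                      stacklevel=2)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude profile")
    return BinnedPhaseProfile(n_bins=n_bins, edges=edges,
                              mean_amp=mean_amp, pmf=mean_amp / total)


def tort_mi(amplitude, phase, n_bins: int = DEFAULT_TORT_BINS) -> float:
    """Modulation Index: KL(P || Uniform) / log(N) in [0, 1].

    Empty bins contribute 0 (the 0*log 0 := 0 convention).
    """
    prof = binned_profile(amplitude, phase, n_bins)
    p = prof.pmf
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * prof.n_bins)))
    return kl / np.log(prof.n_bins)
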