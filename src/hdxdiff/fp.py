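"""Fluorescence-polarization receptivity analysis.

A fluorescent reporter peptide tumbles slowly when bound to a receptive
molecule (high polarization) and quickly when free (~50 mP here).
Polarization is computed from background-subtracted parallel (S) and
perpendicular (P) count rates with the grating factor G:

    mP = 1000 * (S - G * P) / (S + G * P)

Two receptivity read-outs are provided, because decay of binding sites
is commonly reported both ways:

* :func:`receptive_fraction` — baseline-subtracted fraction of initial
  binding sites, (mP_t - mP_unbound) / (mP_initial - mP_unbound);
  the default for "% loss of binding sites";
* :func:`polarization_ratio` — the raw ratio mP_t / mP_initial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MP_UNBOUND_DEFAULT",
    "FPSeries",
    "compute_mP",
    "receptive_fraction",
    "polarization_ratio",
    "simulate_fp_series",
]

MP_UNBOUND_DEFAULT = 50.0


def compute_mP(S: float, P: float, G: float) -> float:
    """Millipolarization from filter count rates."""
    S, P, G = float(S), float(P), float(G)
    if S < 0 or P < 0:
        raise ValueError("count rates must be >= 0")
    if G <= 0:
        raise ValueError("grating factor must be > 0")
    denom = S + G * P
    if denom <= 0:
        raise ValueError("zero total intensity: S + G*P must be > 0")
    return 1000.0 * (S - G * P) / denom


def receptive_fraction(mP_t: float, mP_initial: float,
                       mP_unbound: float = MP_UNBOUND_DEFAULT) -> float:
    """Fraction of initial binding sites still receptive at time t."""
    if mP_initial <= mP_unbound:
        raise ValueError("mP_initial must exceed the unbound baseline")
    return (mP_t - mP_unbound) / (mP_initial - mP_unbound)


def polarization_ratio(mP_t: float, mP_initial: float) -> float:
    """Raw polarization relative to the initial reading."""
    if mP_initial <= 0:
        raise ValueError("mP_initial must be > 0")
    return mP_t / mP_initial


@dataclass
class FPSeries:
    """Time course of polarization readings for one sample.

    ``time_h`` in hours; ``S``/``P`` background-subtracted count rates;
    scalar grating factor ``G``.
    """

    time_h: np.ndarray
    S: np.ndarray
    P: np.ndarray
    G: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (self.time_h.shape == self.S.shape == self.P.shape):
            raise ValueError("time, S and P must be equal-length arrays")
        if (self.S < 0).any() or (self.P < 0).any():
            raise ValueError("count rates must be >= 0")
        if self.G <= 0:
            raise ValueError("grating factor must be > 0")

    @property
    def mP(self) -> np.ndarray:
        return np.array([compute_mP(s, p, self.G) for s, p in zip(self.S, self.P)])

    def receptive_fractions(self, mP_unbound: float = MP_UNBOUND_DEFAULT) -> np.ndarray:
        mp = self.mP
        return np.array([receptive_fraction(v, mp[0], mP_unbound) for v in mp])

    def losses(self, mP_unbound: float = MP_UNBOUND_DEFAULT) -> np.ndarray:
        return 1.0 - self.receptive_fractions(mP_unbound)


def simulate_fp_series(
    times_h: Sequence[float],
    mP_initial: float = 250.0,
    mP_unbound: float = MP_UNBOUND_DEFAULT,
    phase_rates: Sequence[tuple[float, float]] = ((24.0, 0.0017), (46.0, 0.0040), (np.inf, 0.085)),
    G: float = 1.0,
    noise_mP: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> FPSeries:
    """Synthetic receptive-site decay: piecewise-exponential fraction.

    ``phase_rates`` is a list of (phase end in hours, decay rate 1/h);
    the default emulates a stable plateau (~few % loss over the first
    two days) followed by rapid loss of binding sites.  Count rates are
    back-calculated from mP assuming constant total intensity.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times_h, dtype=float)
    frac = np.empty_like(times)
    for i, t in enumerate(times):
        remaining, t0, f = t, 0.0, 1.0
        for t_end, k in phase_rates:
            dt = min(t_end, t0 + remaining) - t0
            if dt <= 0:
                break
            f *= np.exp(-k * dt)
            remaining -= dt
            t0 = t_end
            if remaining <= 0:
                break
        frac[i] = f
    mp = mP_unbound + (mP_initial - mP_unbound) * frac
    if noise_mP:
        mp = mp + rng.normal(0.0, noise_mP, size=mp.shape)
    # invert mP = 1000 (S - GP)/(S + GP) with S + GP == 2 (arbitrary units)
    x = np.clip(mp / 1000.0, -0.999, 0.999)
    S = 1.0 + x
    P = (1.0 - x) / G
    return FPSeries(time_h=times, S=S, P=P, G=G, label=label)
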