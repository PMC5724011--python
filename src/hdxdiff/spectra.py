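"""Isotopic envelopes of partially deuterated peptides.

The deuteration envelope of a peptide with ``n`` exchange-competent
sites, each independently deuterated with probability ``p``, is a
binomial mass function over the deuteron count k; an EX1-type mixed
population is a weighted mixture of such binomials.  Peaks sit at
``base_mz + k * DELTA_MASS / charge``.  Natural-isotope fine structure
(13C etc.) is omitted by default — it cancels in relative uptake — but a
convolution hook is provided.

Modality classification fits one- vs two-component binomial mixtures by
maximum likelihood (normalized intensities as an empirical distribution
over k) and selects by BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "DELTA_MASS",
    "Spectrum",
    "ModalityResult",
    "simulate_envelope",
    "centroid_mass",
    "classify_modality",
]

#: mass difference per incorporated deuteron (Da)
DELTA_MASS = 1.00628


@dataclass(frozen=True)
class Spectrum:
    """A centroided stick spectrum of one peptide charge state."""

    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    peptide: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be equal-length 1-D arrays")
        if (np.diff(mz) <= 0).any():
            raise ValueError("mz values must be strictly increasing")
        if (inten < 0).any():
            raise ValueError("intensities must be >= 0")
        if not inten.any():
            raise ValueError("intensities must not be all zero")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


def simulate_envelope(
    n_sites: int,
    incorporation: Sequence[Tuple[float, float]],
    base_mz: float,
    charge: int = 1,
    isotope_pattern: Optional[np.ndarray] = None,
) -> Spectrum:
    """Binomial-mixture deuteration envelope.

    ``incorporation`` lists (probability, weight) per population; the
    weights must sum to 1.  Intensity at k deuterons is
    sum_pop weight * Binomial(n_sites, p_pop).pmf(k).  If an
    ``isotope_pattern`` (intensities at +0, +1, ... Da) is given, the
    envelope is convolved with it on the same k-grid spacing.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    probs = np.array([p for p, _ in incorporation], dtype=float)
    weights = np.array([w for _, w in incorporation], dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("incorporation probabilities must be in [0, 1]")
    if (weights < 0).any() or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("population weights must be >= 0 and sum to 1")
    k = np.arange(n_sites + 1)
    pmf = np.zeros(n_sites + 1)
    for p, w in zip(probs, weights):
        pmf += w * sps.binom.pmf(k, n_sites, p)
    if isotope_pattern is not None:
        pat = np.asarray(isotope_pattern, dtype=float)
        pmf = np.convolve(pmf, pat / pat.sum())
        k = np.arange(pmf.size)
    mz = base_mz + k * DELTA_MASS / charge
    return Spectrum(mz=mz, intensity=pmf, charge=charge)


def centroid_mass(spectrum: Spectrum) -> float:
    """Intensity-weighted mean m/z of a spectrum."""
    total = spectrum.intensity.sum()
    if total <= 0:
        raise ValueError("cannot centroid an all-zero spectrum")
    return float((spectrum.mz * spectrum.intensity).sum() / total)


# ---------------------------------------------------------------------------
# modality classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModalityResult:
    label: str                           # "unimodal" | "bimodal"
    components: tuple[tuple[float, float], ...]  # (p, weight) per component
    bic_one: float
    bic_two: float
    n_sites: int
    degenerate: bool = False

    @property
    def delta_bic(self) -> float:
        return self.bic_one - self.bic_two


def _mixture_nll(f: np.ndarray, k: np.ndarray, n: int,
                 comps: Sequence[Tuple[float, float]]) -> float:
    q = np.zeros_like(f)
    for p, w in comps:
        q += w * sps.binom.pmf(k, n, min(max(p, 0.0), 1.0))
    return float(-(f * np.log(np.maximum(q, 1e-300))).sum())


def classify_modality(
    spectrum: Spectrum,
    n_sites: Optional[int] = None,
    n_eff: float = 1000.0,
    delta_bic_threshold: float = 2.0,
) -> ModalityResult:
    """Classify a deuteration envelope as unimodal or bimodal.

    The normalized intensities are treated as an empirical distribution
    over the deuteron count k (inferred from the m/z grid); one- and
    two-component binomial mixtures are fit by maximum likelihood and
    compared by BIC at an effective ion count ``n_eff``.  Two
    components win when BIC1 - BIC2 exceeds ``delta_bic_threshold``.
    Classification is invariant to uniform intensity scaling.
    """
    if spectrum.mz.size < 3:
        raise ValueError("need at least 3 peaks to assess modality")
    k = np.round((spectrum.mz - spectrum.mz[0]) * spectrum.charge / DELTA_MASS).astype(int)
    if n_sites is None:
        n_sites = int(k[-1])
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    f = spectrum.intensity / spectrum.intensity.sum()

    # one component: bounded scalar MLE
    res1 = optimize.minimize_scalar(
        lambda p: _mixture_nll(f, k, n_sites, [(p, 1.0)]),
        bounds=(1e-6, 1 - 1e-6), method="bounded",
    )
    p1_hat, nll1 = float(res1.x), float(res1.fun)

    # two components: coarse grid then Nelder-Mead polish
    grid_p = np.linspace(0.02, 0.98, 25)
    grid_w = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
    pmf = sps.binom.pmf(k[None, :], n_sites, grid_p[:, None])  # (25, K)
    best = (np.inf, 0.1, 0.9, 0.5)
    for wi in grid_w:
        mix = wi * pmf[:, None, :] + (1 - wi) * pmf[None, :, :]  # (25, 25, K)
        nll = -(f[None, None, :] * np.log(np.maximum(mix, 1e-300))).sum(axis=2)
        a, b = np.unravel_index(np.argmin(nll), nll.shape)
        if nll[a, b] < best[0]:
            best = (float(nll[a, b]), float(grid_p[a]), float(grid_p[b]), float(wi))
    def nll2_fn(x):
        pa, pb, w = x
        if not (0 <= pa <= 1 and 0 <= pb <= 1 and 1e-6 <= w <= 1 - 1e-6):
            return 1e9
        return _mixture_nll(f, k, n_sites, [(pa, w), (pb, 1 - w)])
    res2 = optimize.minimize(nll2_fn, x0=list(best[1:]), method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    pa, pb, w = res2.x
    nll2 = float(res2.fun)
    degenerate = not res2.success

    bic1 = 2.0 * n_eff * nll1 + 1.0 * math.log(n_eff)
    bic2 = 2.0 * n_eff * nll2 + 3.0 * math.log(n_eff)
    if bic1 - bic2 > delta_bic_threshold:
        comps = sorted([(float(pa), float(w)), (float(pb), float(1 - w))])
        return ModalityResult("bimodal", tuple(comps), bic1, bic2, n_sites, degenerate)
    return ModalityResult("unimodal", ((p1_hat, 1.0),), bic1, bic2, n_sites, degenerate)
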