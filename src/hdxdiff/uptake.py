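"""Per-peptide deuterium-uptake computations.

All uptake values are in daltons of deuterium above the undeuterated
centroid.  A peptide's *maximum theoretical uptake* is its number of
exchange-competent backbone amides: every residue except the first
``first_residue_exclusion`` residues (rapid back-exchange at the newly
formed N terminus) and prolines, which carry no backbone amide hydrogen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AMINO_ACIDS",
    "UptakeStat",
    "DifferentialUptake",
    "exchangeable_amides",
    "replicate_stats",
    "relative_fractional_uptake",
    "differential_uptake",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class UptakeStat:
    """Replicate summary for one (protein, state, peptide, time).

    ``sd`` is the sample standard deviation (n-1 denominator) when
    ``n >= 2``; with a single replicate it is 0 and ``single_replicate``
    is flagged.
    """

    mean: float
    sd: float
    n: int
    single_replicate: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass(frozen=True)
class DifferentialUptake:
    """Between-state uptake difference for one peptide at one time.

    ``delta`` is perturbed mean minus reference mean (Da);
    ``rel_frac_delta`` is ``delta / max_uptake``; ``pooled_sd`` is the
    standard error of the difference of means,
    sqrt(sd_ref^2/n_ref + sd_pert^2/n_pert).
    """

    delta: float
    rel_frac_delta: float
    pooled_sd: float
    time: float


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - AMINO_ACIDS
    if not seq:
        raise ValueError("empty peptide sequence")
    if bad:
        raise ValueError(f"invalid residue character(s): {sorted(bad)!r}")
    return seq


def exchangeable_amides(peptide_sequence: str, first_residue_exclusion: int = 1) -> int:
    """Number of backbone amides of a peptide that can retain deuterium.

    Counts residues beyond the first ``first_residue_exclusion``
    positions, minus prolines among them.

    >>> exchangeable_amides("KRLIGKRY")
    7
    >>> exchangeable_amides("APGP")
    1
    """
    seq = _check_sequence(peptide_sequence)
    if first_residue_exclusion < 0:
        raise ValueError("first_residue_exclusion must be >= 0")
    tail = seq[first_residue_exclusion:]
    return len(tail) - tail.count("P")


def replicate_stats(values) -> UptakeStat:
    """Mean and sample SD of replicate uptake measurements."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("need at least one replicate value")
    n = len(vals)
    mean = sum(vals) / n
    if n == 1:
        return UptakeStat(mean=mean, sd=0.0, n=1, single_replicate=True)
    if max(vals) == min(vals):  # exact zero, no rounding residue
        return UptakeStat(mean=vals[0], sd=0.0, n=n)
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return UptakeStat(mean=mean, sd=math.sqrt(var), n=n)


def relative_fractional_uptake(mean_uptake: float, max_uptake: float) -> float:
    """Uptake as a fraction of the maximum theoretical uptake.

    Values above 1 are possible only if the input exceeds ``max_uptake``
    (a convention mismatch); they are returned as-is, never clamped —
    callers should treat ``> 1`` as a QC warning.
    """
    if max_uptake <= 0:
        raise ValueError("max_uptake must be > 0")
    return mean_uptake / max_uptake


def differential_uptake(
    ref: UptakeStat, pert: UptakeStat, max_uptake: float, time: float = float("nan")
) -> DifferentialUptake:
    """Perturbed-minus-reference uptake difference for one peptide/time."""
    if max_uptake <= 0:
        raise ValueError("max_uptake must be > 0")
    delta = pert.mean - ref.mean
    pooled = math.sqrt(ref.sd**2 / ref.n + pert.sd**2 / pert.n)
    return DifferentialUptake(
        delta=delta,
        rel_frac_delta=delta / max_uptake,
        pooled_sd=pooled,
        time=time,
    )
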