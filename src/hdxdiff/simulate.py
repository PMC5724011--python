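"""Forward simulation of HDX-MS uptake tables.

Exchange follows independent-site first-order (EX2) kinetics in the
Linderstrom-Lang framework: residue i of a protein in state s exchanges
with observed rate ``k_int_i / P_{s,i}`` where P is the protection
factor (>= 1; +inf for non-exchanging sites).  The noiseless uptake of a
peptide after labeling time t (minutes) is

    D(t) = back_exchange * d2o_fraction
           * sum_i (1 - exp(-(k_int_i / P_i) * t))

summed over the peptide's exchange-competent residues: everything
except its first ``n_term_exclusion`` residues and prolines.  Replicate
measurements add Gaussian noise and are floored at zero.

The peptic digestion simulator emulates the overlapping peptide maps of
a typical experiment: it tiles covered segments with random-length
peptides and tops up until the requested mean redundancy is met.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consolidate import Interval
from .stats import coverage_redundancy
from .uptake import AMINO_ACIDS, exchangeable_amides

__all__ = [
    "ExchangeModel",
    "DigestionParams",
    "NoiseModel",
    "InfeasibleDigestionError",
    "simulate_digestion",
    "expected_uptake",
    "simulate_uptake",
    "random_protein",
    "child_seed",
]

#: approximate residue frequencies in globular proteins (Swiss-Prot order A..Y)
_AA_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}


class InfeasibleDigestionError(ValueError):
    """Raised when coverage/redundancy targets cannot be realized."""


def child_seed(master_seed: int, *tokens: str) -> int:
    """Deterministic child seed for a (protein, state, ...) context."""
    h = zlib.crc32(("/".join(tokens)).encode("utf-8"))
    return int(np.random.SeedSequence([int(master_seed), h]).generate_state(1)[0] % (2**31))


def random_protein(length: int, seed: int, min_proline_gap: int = 0) -> str:
    """Random amino-acid sequence with realistic residue frequencies."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    aas = np.array(sorted(_AA_FREQ))
    p = np.array([_AA_FREQ[a] for a in sorted(_AA_FREQ)], dtype=float)
    p /= p.sum()
    seq = list(rng.choice(aas, size=length, p=p))
    if min_proline_gap:
        last_p = -min_proline_gap
        for i, a in enumerate(seq):
            if a == "P":
                if i - last_p < min_proline_gap:
                    seq[i] = "G"
                else:
                    last_p = i
    return "".join(seq)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExchangeModel:
    """Per-residue kinetics and per-state protection for one protein.

    ``k_int`` is the intrinsic exchange rate (1/min) per residue (1-based
    mature-protein numbering, index 0 = residue 1).  ``protection`` maps
    state name -> per-residue protection factors (>= 1, +inf allowed).
    ``d2o_fraction`` is the deuterium fraction of the labeling buffer
    after dilution; ``back_exchange`` the multiplicative recovery factor
    on observable uptake.
    """

    protein_id: str
    sequence: str
    k_int: np.ndarray
    protection: dict[str, np.ndarray]
    d2o_fraction: float = 0.95
    back_exchange: float = 0.7

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue character(s) in sequence: {sorted(bad)!r}")
        self.k_int = np.asarray(self.k_int, dtype=float)
        if self.k_int.shape != (len(self.sequence),):
            raise ValueError("k_int length must equal sequence length")
        if (self.k_int < 0).any():
            raise ValueError("intrinsic rates must be >= 0")
        for state, prof in self.protection.items():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (len(self.sequence),):
                raise ValueError(f"protection profile for state {state!r} has wrong length")
            if (prof < 1).any():
                raise ValueError(f"protection factors must be >= 1 (state {state!r})")
            self.protection[state] = prof
        if not 0 <= self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must be in [0, 1]")
        if not 0 <= self.back_exchange <= 1:
            raise ValueError("back_exchange must be in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def observed_rates(self, state: str) -> np.ndarray:
        if state not in self.protection:
            raise KeyError(f"unknown state {state!r}")
        with np.errstate(divide="ignore"):
            return np.where(np.isinf(self.protection[state]), 0.0,
                            self.k_int / self.protection[state])


@dataclass(frozen=True)
class DigestionParams:
    mean_length: float = 12.0
    length_sd: float = 3.0
    target_redundancy: float = 5.0
    coverage_target: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_length < 3:
            raise ValueError("mean_length must be >= 3")
        if self.target_redundancy < 1:
            raise ValueError("target_redundancy must be >= 1")
        if not 0 < self.coverage_target <= 1:
            raise ValueError("coverage_target must be in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    uptake_sd: float = 0.08
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.uptake_sd < 0:
            raise ValueError("uptake_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def _covered_segments(length: int, coverage_target: float, rng: np.random.Generator) -> list[Interval]:
    """Split [1, length] into covered segments leaving random interior gaps."""
    gap_total = int(round((1.0 - coverage_target) * length))
    if gap_total == 0:
        return [(1, length)]
    n_gaps = int(rng.integers(1, min(3, gap_total) + 1))
    cuts = np.sort(rng.choice(np.arange(1, gap_total), size=n_gaps - 1, replace=False)) if n_gaps > 1 else np.array([], dtype=int)
    gap_sizes = np.diff(np.concatenate(([0], cuts, [gap_total])))
    # gap anchor positions, interior and non-adjacent
    anchors = np.sort(rng.choice(np.arange(10, max(11, length - 10)), size=n_gaps, replace=False))
    segments: list[Interval] = []
    pos = 1
    for anchor, g in zip(anchors, gap_sizes):
        start_gap = max(pos, int(anchor))
        end_gap = min(length, start_gap + int(g) - 1)
        if start_gap > pos:
            segments.append((pos, start_gap - 1))
        pos = end_gap + 1
    if pos <= length:
        segments.append((pos, length))
    return [s for s in segments if s[1] >= s[0]]


def _draw_length(rng: np.random.Generator, params: DigestionParams, cap: int) -> int:
    ln = int(round(rng.normal(params.mean_length, params.length_sd)))
    return int(np.clip(ln, 3, cap))


def simulate_digestion(sequence: str, params: DigestionParams) -> list[Interval]:
    """Random overlapping peptide map hitting coverage/redundancy targets.

    Deterministic for a fixed ``params.seed``.  Achieved coverage is
    within +/-5 percentage points of ``coverage_target`` and achieved
    redundancy within +/-20% of ``target_redundancy`` (verified against
    :func:`hdxdiff.stats.coverage_redundancy`); otherwise
    :class:`InfeasibleDigestionError` is raised.
    """
    length = len(sequence)
    if length < params.mean_length:
        raise InfeasibleDigestionError(
            f"sequence length {length} shorter than mean peptide length {params.mean_length}"
        )
    if params.target_redundancy > params.mean_length:
        raise InfeasibleDigestionError(
            "target redundancy cannot exceed mean peptide length with distinct intervals"
        )
    if params.coverage_target * length < 3:
        raise InfeasibleDigestionError("covered region too short for any peptide")

    for attempt in range(12):
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), attempt]))
        peptides = _attempt_digestion(length, params, rng)
        rep = coverage_redundancy(peptides, length)
        if (
            abs(rep.coverage_percent - 100 * params.coverage_target) <= 5.0
            and abs(rep.mean_redundancy - params.target_redundancy)
            <= 0.2 * params.target_redundancy
        ):
            return peptides
    raise InfeasibleDigestionError(
        f"could not reach coverage {params.coverage_target:.0%} at redundancy "
        f"{params.target_redundancy:g} for a length-{length} sequence"
    )


def _attempt_digestion(length: int, params: DigestionParams, rng: np.random.Generator) -> list[Interval]:
    segments = _covered_segments(length, params.coverage_target, rng)
    peptides: set[Interval] = set()
    step = max(1.0, params.mean_length / params.target_redundancy)
    for seg_s, seg_e in segments:
        seg_len = seg_e - seg_s + 1
        pos = seg_s
        while pos <= seg_e:
            ln = _draw_length(rng, params, min(seg_len, int(2 * params.mean_length)))
            end = min(seg_e, pos + ln - 1)
            start = max(seg_s, end - ln + 1)
            peptides.add((start, end))
            if end >= seg_e:
                break
            adv = int(round(rng.normal(step, 0.3 * step)))
            pos = pos + max(1, adv)
            if pos > end + 1:  # never open a gap inside a covered segment
                pos = end + 1
        # top up redundancy with random interior peptides
        counts = np.zeros(length + 2)
        for s, e in peptides:
            counts[s : e + 1] += 1
        target_n = params.target_redundancy * seg_len / params.mean_length
        guard = 0
        while len([p for p in peptides if seg_s <= p[0] and p[1] <= seg_e]) < target_n and guard < 10 * target_n:
            guard += 1
            ln = _draw_length(rng, params, seg_len)
            start = int(rng.integers(seg_s, seg_e - ln + 2))
            peptides.add((start, start + ln - 1))
    return sorted(peptides)


# ---------------------------------------------------------------------------
# uptake
# ---------------------------------------------------------------------------

def _competent_mask(sequence: str, start: int, end: int, n_term_exclusion: int) -> np.ndarray:
    """Boolean mask (0-based, over the whole protein) of a peptide's
    exchange-competent residues."""
    mask = np.zeros(len(sequence), dtype=bool)
    first = start - 1 + n_term_exclusion
    for i in range(first, end):
        if sequence[i] != "P":
            mask[i] = True
    return mask


def expected_uptake(
    model: ExchangeModel,
    peptide: Interval,
    time: float,
    state: str,
    n_term_exclusion: int = 1,
) -> float:
    """Noiseless peptide uptake D(t) in daltons."""
    if time < 0:
        raise ValueError("labeling time must be >= 0")
    s, e = peptide
    if s < 1 or e > model.length or e < s:
        raise ValueError(f"peptide {peptide} outside sequence")
    k = model.observed_rates(state)
    mask = _competent_mask(model.sequence, s, e, n_term_exclusion)
    frac = 1.0 - np.exp(-k[mask] * time)
    return float(model.back_exchange * model.d2o_fraction * frac.sum())


TABLE_COLUMNS = [
    "protein", "state", "sequence", "start", "end",
    "max_uptake", "time", "replicate", "uptake",
]


def simulate_uptake(
    model: ExchangeModel,
    peptides: Sequence[Interval],
    times: Sequence[float],
    noise: NoiseModel,
    state: str,
    seed: int,
    n_term_exclusion: int = 1,
) -> pd.DataFrame:
    """Replicate uptake measurements for one protein state.

    Returns a long-format table (one row per peptide x time x replicate)
    with the standard state-table columns.  Peptides with no
    exchange-competent amide (e.g. all-proline short fragments) carry no
    observable signal and are omitted, as in real data processing.
    """
    if any(t < 0 for t in times):
        raise ValueError("labeling times must be >= 0")
    model.observed_rates(state)  # raises on unknown state
    rng = np.random.default_rng(seed)
    rows = []
    for s, e in peptides:
        pep_seq = model.sequence[s - 1 : e]
        maxu = exchangeable_amides(pep_seq, n_term_exclusion)
        if maxu == 0:
            continue
        for t in times:
            mu = expected_uptake(model, (s, e), t, state, n_term_exclusion)
            eps = rng.normal(0.0, noise.uptake_sd, size=noise.n_replicates)
            for r in range(noise.n_replicates):
                rows.append(
                    (model.protein_id, state, pep_seq, s, e, maxu,
                     float(t), r + 1, max(0.0, mu + eps[r]))
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
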