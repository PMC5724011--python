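"""Dataset-level statistics for differential HDX-MS experiments.

Covers peptide-map quality metrics (coverage, redundancy), the
normalized uptake-increase statistic used for membrane-proximal domains,
paired two-tailed t tests across peptides of a domain, per-peptide
Welch comparisons between states with Benjamini-Hochberg control, and
region-recovery helpers for consolidated residue maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .consolidate import Interval, ResidueMap
from .uptake import UptakeStat

__all__ = [
    "CoverageReport",
    "NormalizedIncrease",
    "PairedTResult",
    "WelchResult",
    "ComparisonResult",
    "coverage_redundancy",
    "normalized_increase",
    "paired_t_test",
    "welch_t_test",
    "peptide_state_comparison",
    "compare_all_peptides",
    "top_fraction_residues",
    "jaccard_index",
]


# ---------------------------------------------------------------------------
# coverage / redundancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageReport:
    """Map statistics for one protein.

    ``coverage_percent`` is 100 x |union of intervals| / length;
    ``mean_redundancy`` is the mean number of peptides containing each
    *covered* residue (full interval membership — this is a map
    statistic, not the heat-map rendering rule, so no N-terminus
    exclusion applies).  With no peptides, redundancy is NaN and
    ``undefined_redundancy`` is flagged.
    """

    protein_id: str
    coverage_percent: float
    mean_redundancy: float
    n_peptides: int
    undefined_redundancy: bool = False


def coverage_redundancy(
    peptides: Sequence[Interval], protein_length: int, protein_id: str = ""
) -> CoverageReport:
    if protein_length <= 0:
        raise ValueError("protein_length must be > 0")
    counts = np.zeros(protein_length, dtype=np.int64)
    n = 0
    for s, e in peptides:
        s, e = int(s), int(e)
        if s < 1 or e < s or e > protein_length:
            raise ValueError(f"invalid peptide interval ({s}, {e})")
        counts[s - 1 : e] += 1
        n += 1
    covered = counts > 0
    coverage = 100.0 * covered.sum() / protein_length
    if covered.any():
        red = float(counts[covered].mean())
        return CoverageReport(protein_id, coverage, red, n)
    return CoverageReport(protein_id, 0.0, float("nan"), n, undefined_redundancy=True)


# ---------------------------------------------------------------------------
# normalized uptake increase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedIncrease:
    """Normalized uptake increase for one peptide.

    value = (mean_pert(T) - mean_ref(T)) / mean_ref(T), both states
    taken at the reference labeling time T (the longest labeling point).
    Per-replicate variants pair replicate indices in the numerator and
    keep the mean reference denominator.  A non-positive denominator
    excludes the peptide (flag set, values NaN).
    """

    peptide: Interval
    value: float
    per_replicate: tuple[float, ...]
    mean: float
    sd: float
    excluded: bool = False


def normalized_increase(
    ref_values: Sequence[float],
    pert_values: Sequence[float],
    peptide: Interval = (0, 0),
) -> NormalizedIncrease:
    """Normalized increase from paired replicate uptakes at the reference time."""
    ref = [float(v) for v in ref_values]
    pert = [float(v) for v in pert_values]
    if not ref or not pert:
        raise ValueError("need replicate values for both states")
    mean_ref = sum(ref) / len(ref)
    mean_pert = sum(pert) / len(pert)
    if mean_ref <= 0:
        nan = float("nan")
        return NormalizedIncrease(peptide, nan, (), nan, nan, excluded=True)
    value = (mean_pert - mean_ref) / mean_ref
    k = min(len(ref), len(pert))
    reps = tuple((pert[i] - ref[i]) / mean_ref for i in range(k))
    mean = sum(reps) / k
    sd = math.sqrt(sum((r - mean) ** 2 for r in reps) / (k - 1)) if k >= 2 else 0.0
    return NormalizedIncrease(peptide, value, reps, mean, sd)


# ---------------------------------------------------------------------------
# paired t test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> PairedTResult:
    """Paired two-tailed t test over peptide-matched value lists.

    Pairing is positional (one peptide per index).  A zero-variance
    difference vector is reported as degenerate: t = 0, p = 1 when the
    lists are identical; |t| = inf, p = 0 when the constant difference
    is non-zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired lists must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite value in paired t test input")
    d = a - b
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTResult(0.0, 1.0, df, degenerate=True)
        return PairedTResult(math.copysign(math.inf, mean_d), 0.0, df, degenerate=True)
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(float(t), float(p), df)


# ---------------------------------------------------------------------------
# per-peptide state comparison (Welch)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    p: float
    df: float
    degenerate: bool = False


def welch_t_test(ref: UptakeStat, pert: UptakeStat) -> WelchResult:
    """Welch two-sample t test from replicate summaries.

    Degrees of freedom by Welch-Satterthwaite.  Requires >= 2 replicates
    per state.  Zero variance in both states is degenerate: equal means
    give p = 1 (not significant), unequal means give p = 0.
    """
    if ref.n < 2 or pert.n < 2:
        raise ValueError("Welch comparison needs >= 2 replicates per state")
    v1, v2 = ref.sd**2 / ref.n, pert.sd**2 / pert.n
    diff = pert.mean - ref.mean
    if v1 + v2 == 0.0:
        if diff == 0.0:
            return WelchResult(0.0, 1.0, float(ref.n + pert.n - 2), degenerate=True)
        return WelchResult(math.copysign(math.inf, diff), 0.0, float(ref.n + pert.n - 2), degenerate=True)
    t = diff / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (ref.n - 1) + v2**2 / (pert.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(p), float(df), degenerate=False)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-time Welch results for one peptide plus an overall call."""

    per_time: Mapping[float, WelchResult]
    significant_times: tuple[float, ...]
    significant: bool
    alpha: float
    min_p: float


def peptide_state_comparison(
    ref: "UptakeStat | Mapping[float, UptakeStat]",
    pert: "UptakeStat | Mapping[float, UptakeStat]",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare one peptide's uptake between two states.

    Accepts either single-time replicate summaries or per-time mappings.
    Each timepoint gets an uncorrected Welch test; the overall call is
    significant if any timepoint rejects at ``alpha``.  Multiplicity
    control across the whole dataset belongs to
    :func:`compare_all_peptides`.
    """
    if isinstance(ref, UptakeStat):
        ref = {0.0: ref}
    if isinstance(pert, UptakeStat):
        pert = {0.0: pert}
    if set(ref) != set(pert):
        raise ValueError("states measured at different timepoints")
    per_time = {t: welch_t_test(ref[t], pert[t]) for t in sorted(ref)}
    sig = tuple(t for t, r in per_time.items() if r.p < alpha)
    min_p = min(r.p for r in per_time.values())
    return ComparisonResult(per_time, sig, bool(sig), alpha, min_p)


def compare_all_peptides(
    stats_by_peptide: Mapping[Interval, Mapping[float, tuple[UptakeStat, UptakeStat]]],
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> "list[dict]":
    """Welch tests for every (peptide, time) with multiplicity control.

    ``stats_by_peptide`` maps peptide -> time -> (ref_stat, pert_stat).
    Returns one record per (peptide, time) with raw and adjusted p;
    ``method`` is any statsmodels ``multipletests`` method, or None for
    uncorrected calls.
    """
    records = []
    for pep, per_time in stats_by_peptide.items():
        for t, (r, p) in sorted(per_time.items()):
            w = welch_t_test(r, p)
            records.append(
                {"peptide": pep, "time": t, "t": w.t, "p": w.p, "df": w.df,
                 "degenerate": w.degenerate}
            )
    if not records:
        return records
    pvals = [rec["p"] for rec in records]
    if method is None:
        adj = pvals
        reject = [p < alpha for p in pvals]
    else:
        reject, adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
    for rec, a, rj in zip(records, adj, reject):
        rec["p_adjusted"] = float(a)
        rec["significant"] = bool(rj)
    return records


# ---------------------------------------------------------------------------
# region recovery on residue maps
# ---------------------------------------------------------------------------

def top_fraction_residues(
    rmap: ResidueMap, times: Optional[Sequence[float]] = None, fraction: float = 0.1
) -> set[int]:
    """Residues in the top ``fraction`` of |value| among covered residues.

    |value| is aggregated as the mean of |rel_frac_delta| over ``times``
    (default: all intermediate timepoints, i.e. all but the first and
    last when there are >= 3).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    all_times = rmap.times
    if times is None:
        times = all_times[1:-1] if len(all_times) >= 3 else all_times
    cols = [all_times.index(t) for t in times]
    score = np.abs(rmap.values[:, cols]).mean(axis=1)
    covered = ~np.isnan(score)
    idx = np.flatnonzero(covered)
    if idx.size == 0:
        return set()
    k = max(1, int(round(fraction * idx.size)))
    order = idx[np.argsort(score[idx])[::-1]]
    return {int(i) + 1 for i in order[:k]}


def jaccard_index(a: Iterable[int], b: Iterable[int]) -> float:
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
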