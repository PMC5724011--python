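"""Brute-force reference implementations used only to check the package.

These deliberately re-derive each rule independently, step by step, and
share no code with hdxdiff.
"""

from __future__ import annotations

import numpy as np


def oracle_select(residue, peptides):
    """Representative peptide for a residue by direct rule application:
    eligibility s < r <= e, then shortest, then greatest end, then
    greatest start."""
    eligible = []
    for (s, e) in peptides:
        if s < residue <= e:
            eligible.append((s, e))
    if not eligible:
        return None
    best = eligible[0]
    for cand in eligible[1:]:
        len_c = cand[1] - cand[0] + 1
        len_b = best[1] - best[0] + 1
        if len_c < len_b:
            best = cand
        elif len_c == len_b:
            if cand[1] > best[1]:
                best = cand
            elif cand[1] == best[1] and cand[0] > best[0]:
                best = cand
    return best


def oracle_residue_map(diffs, peptides, length):
    """(values, source) arrays built residue by residue from scratch."""
    times = sorted({t for per_time in diffs.values() for t in per_time})
    values = np.full((length, len(times)), np.nan)
    source = [None] * length
    for r in range(1, length + 1):
        chosen = oracle_select(r, peptides)
        if chosen is None:
            continue
        source[r - 1] = chosen
        for j, t in enumerate(times):
            values[r - 1, j] = float(diffs[chosen][t])
    return values, source, times


def oracle_coverage_redundancy(peptides, length):
    """Coverage percent and mean redundancy by counting residue by residue."""
    counts = []
    for r in range(1, length + 1):
        c = 0
        for (s, e) in peptides:
            if s <= r <= e:
                c += 1
        counts.append(c)
    covered = [c for c in counts if c > 0]
    coverage = 100.0 * len(covered) / length
    redundancy = sum(covered) / len(covered) if covered else float("nan")
    return coverage, redundancy


def random_peptide_map(rng, max_length=300, max_peptides=100):
    """A random protein length and random (possibly empty) interval set."""
    length = int(rng.integers(1, max_length + 1))
    n = int(rng.integers(0, max_peptides + 1))
    peptides = set()
    for _ in range(n):
        s = int(rng.integers(1, length + 1))
        e = int(rng.integers(s, min(length, s + int(rng.integers(1, 40))) + 1))
        peptides.add((s, e))
    return length, sorted(peptides)


def random_diffs(rng, peptides, times):
    return {p: {t: float(rng.normal()) for t in times} for p in peptides}
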