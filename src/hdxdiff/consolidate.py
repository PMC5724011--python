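"""Residue-level consolidation of overlapping-peptide differentials.

Heat maps of differential uptake need one value per (residue, time), but
peptic digestion yields overlapping peptides (redundancy ~5-6 in typical
maps).  The consolidation rule implemented here:

* a peptide (s, e) is *eligible* for residue r iff ``s < r <= e`` — a
  peptide's own N-terminal residue never contributes (its amide deuterium
  is lost to back-exchange);
* among eligible peptides the **shortest** supplies the value;
* ties are broken by the peptide whose C-terminal residue is closest to
  the protein C terminus (greatest ``end``), then by greatest ``start``;
* residues with no eligible peptide are explicit gaps.

The chosen peptide depends only on the peptide map, never on time, so a
residue's source is constant across labeling times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .uptake import DifferentialUptake

__all__ = [
    "Interval",
    "ResidueMap",
    "eligible_peptides",
    "select_representative",
    "build_residue_map",
]

Interval = Tuple[int, int]


def _validate_peptides(peptides: Sequence[Interval]) -> list[Interval]:
    out = []
    for s, e in peptides:
        s, e = int(s), int(e)
        if s < 1 or e < s:
            raise ValueError(f"invalid peptide interval ({s}, {e})")
        out.append((s, e))
    return out


def eligible_peptides(residue: int, peptides: Sequence[Interval]) -> list[Interval]:
    """Peptides that can report on ``residue`` (N-terminal position excluded)."""
    return [(s, e) for s, e in _validate_peptides(peptides) if s < residue <= e]


def select_representative(residue: int, peptides: Sequence[Interval]) -> Optional[Interval]:
    """The peptide whose value represents ``residue``, or None (gap).

    Shortest eligible peptide; ties broken by greatest end, then
    greatest start.
    """
    cands = eligible_peptides(residue, peptides)
    if not cands:
        return None
    return min(cands, key=lambda p: (p[1] - p[0], -p[1], -p[0]))


@dataclass
class ResidueMap:
    """Residues x labeling-times matrix of consolidated differentials.

    ``values[r-1, j]`` holds the rel_frac_delta of residue ``r`` at
    ``times[j]``; gaps are NaN.  ``source[r-1]`` is the (start, end) of
    the peptide that supplied row ``r``, or None for gaps.
    """

    protein_id: str
    times: list[float]
    values: np.ndarray
    source: list[Optional[Interval]]
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def is_gap(self, residue: int) -> bool:
        return self.source[residue - 1] is None

    def __eq__(self, other) -> bool:  # value equality incl. NaN gaps
        if not isinstance(other, ResidueMap):
            return NotImplemented
        return (
            self.protein_id == other.protein_id
            and self.times == other.times
            and self.source == other.source
            and self.values.shape == other.values.shape
            and bool(np.array_equal(self.values, other.values, equal_nan=True))
        )


def build_residue_map(
    diffs: Mapping[Interval, Mapping[float, "DifferentialUptake | float"]],
    peptides: Sequence[Interval],
    protein_length: int,
    protein_id: str = "",
) -> ResidueMap:
    """Consolidate per-(peptide, time) differentials onto residues.

    ``diffs`` maps each peptide interval to a per-time mapping of either
    :class:`DifferentialUptake` objects or bare rel_frac_delta floats.
    Every peptide selected as a representative must carry a value at
    every time, otherwise a ``KeyError``-style ValueError is raised.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    peps = _validate_peptides(peptides)
    for s, e in peps:
        if e > protein_length:
            raise ValueError(f"peptide ({s}, {e}) exceeds protein length {protein_length}")

    times = sorted({t for per_time in diffs.values() for t in per_time})
    # one pass: peptides in selection-priority order, first eligible wins
    order = sorted(peps, key=lambda p: (p[1] - p[0], -p[1], -p[0]))
    values = np.full((protein_length, len(times)), np.nan)
    source: list[Optional[Interval]] = [None] * protein_length
    for r in range(1, protein_length + 1):
        for s, e in order:
            if s < r <= e:
                chosen = (s, e)
                if chosen not in diffs:
                    raise ValueError(f"no differential values for selected peptide {chosen}")
                per_time = diffs[chosen]
                for j, t in enumerate(times):
                    if t not in per_time:
                        raise ValueError(
                            f"missing differential for peptide {chosen} at time {t}"
                        )
                    v = per_time[t]
                    values[r - 1, j] = v.rel_frac_delta if isinstance(v, DifferentialUptake) else float(v)
                source[r - 1] = chosen
                break
    return ResidueMap(protein_id=protein_id, times=list(times), values=values, source=source)
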