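"""On-disk formats: uptake state tables, FASTA sequences, residue maps.

Conventions used throughout the package:

* residue coordinates are **1-based inclusive**, numbered from the first
  residue of the mature protein (residue 1 = first FASTA character);
* uptake is in daltons of deuterium above the undeuterated centroid;
* labeling times are minutes internally; the parsers accept ``"25s"``,
  ``"2.1min"``, ``"4.34h"`` forms and normalize.

State tables are comma-separated UTF-8 files with a mandatory header,
modeled on the "state data" exports of common HDX processing software;
a column-alias map accommodates that dialect's capitalized names.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .consolidate import Interval, ResidueMap
from .uptake import AMINO_ACIDS, exchangeable_amides

__all__ = [
    "UptakeTable",
    "RunConfig",
    "parse_time",
    "read_fasta",
    "read_state_table",
    "write_state_table",
    "read_residue_map",
    "write_residue_map",
]

TABLE_COLUMNS = [
    "protein", "state", "sequence", "start", "end",
    "max_uptake", "time", "replicate", "uptake",
]

#: DynamX-style export header names -> internal names
COLUMN_ALIASES = {
    "Protein": "protein",
    "State": "state",
    "Sequence": "sequence",
    "Start": "start",
    "End": "end",
    "MaxUptake": "max_uptake",
    "Exposure": "time",
    "Replicate": "replicate",
    "Uptake": "uptake",
}

_TIME_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*(s|sec|m|min|h|hr)?\s*$")
_TIME_FACTOR = {"s": 1 / 60, "sec": 1 / 60, "m": 1.0, "min": 1.0, "h": 60.0, "hr": 60.0, None: 1.0}


def parse_time(value) -> float:
    """Labeling time in minutes from a number or a '25s'/'4.34h' string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _TIME_RE.match(str(value))
    if not m:
        raise ValueError(f"unparseable labeling time {value!r}")
    return float(m.group(1)) * _TIME_FACTOR[m.group(2)]


# ---------------------------------------------------------------------------
# uptake tables
# ---------------------------------------------------------------------------

@dataclass
class UptakeTable:
    """Long-format uptake measurements for one experiment.

    One row per (protein, state, peptide, time, replicate); metadata
    (timepoints, states, replicate count) is derived from the rows.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        self.df = self.df[TABLE_COLUMNS].copy()
        for col, typ in (("start", int), ("end", int), ("replicate", int),
                         ("max_uptake", float), ("time", float), ("uptake", float)):
            self.df[col] = self.df[col].astype(typ)

    # -- metadata ----------------------------------------------------------
    @property
    def times(self) -> list[float]:
        return sorted(self.df["time"].unique().tolist())

    @property
    def states(self) -> list[str]:
        return sorted(self.df["state"].unique().tolist())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.df["protein"].unique().tolist())

    @property
    def n_replicates(self) -> int:
        return int(self.df.groupby(["protein", "state", "start", "end", "time"]).size().max())

    def peptides(self, protein: str) -> list[Interval]:
        sub = self.df[self.df["protein"] == protein]
        return sorted({(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])})

    def peptide_sequence(self, protein: str, peptide: Interval) -> str:
        sub = self.df[
            (self.df["protein"] == protein)
            & (self.df["start"] == peptide[0])
            & (self.df["end"] == peptide[1])
        ]
        return str(sub["sequence"].iloc[0])

    def replicate_values(self, protein: str, state: str, peptide: Interval, time: float) -> list[float]:
        sub = self.df[
            (self.df["protein"] == protein)
            & (self.df["state"] == state)
            & (self.df["start"] == peptide[0])
            & (self.df["end"] == peptide[1])
            & (np.isclose(self.df["time"], time))
        ].sort_values("replicate")
        return sub["uptake"].tolist()

    # -- validation --------------------------------------------------------
    def validate(self, sequences: Optional[Mapping[str, str]] = None,
                 first_residue_exclusion: int = 1) -> list[str]:
        """Enforce table invariants; returns QC warnings (never raises for
        soft issues such as uptake above max_uptake)."""
        warnings: list[str] = []
        df = self.df
        for i, row in df.iterrows():
            if row["end"] < row["start"] or row["start"] < 1:
                raise ValueError(f"row {i}: bad coordinates ({row['start']}, {row['end']})")
            if len(row["sequence"]) != row["end"] - row["start"] + 1:
                raise ValueError(
                    f"row {i}: sequence length {len(row['sequence'])} does not match "
                    f"interval ({row['start']}, {row['end']})"
                )
            if row["uptake"] < 0:
                raise ValueError(f"row {i}: negative uptake")
            if sequences is not None:
                prot = sequences.get(row["protein"])
                if prot is None:
                    raise ValueError(f"row {i}: unknown protein {row['protein']!r}")
                ref = prot[row["start"] - 1 : row["end"]]
                if ref != row["sequence"]:
                    raise ValueError(
                        f"row {i}: peptide sequence mismatch against protein "
                        f"{row['protein']!r} at ({row['start']}, {row['end']})"
                    )
            expected_max = exchangeable_amides(row["sequence"], first_residue_exclusion)
            if not math.isclose(row["max_uptake"], expected_max):
                raise ValueError(
                    f"row {i}: max_uptake {row['max_uptake']} inconsistent with "
                    f"exchangeable amide count {expected_max}"
                )
            if row["uptake"] > row["max_uptake"]:
                warnings.append(
                    f"row {i}: uptake {row['uptake']:.3f} exceeds max_uptake "
                    f"{row['max_uptake']:.0f} (convention mismatch?)"
                )
        keys = df[["protein", "state", "start", "end", "time", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate measurement key: {dup}")
        # every (peptide, state) must have >= 1 replicate at each listed time
        times = self.times
        grouped = df.groupby(["protein", "state", "start", "end"])["time"].apply(set)
        for key, seen in grouped.items():
            missing = [t for t in times if not any(math.isclose(t, u) for u in seen)]
            if missing:
                raise ValueError(f"peptide {key} missing timepoint(s) {missing}")
        return warnings

    def __eq__(self, other) -> bool:
        if not isinstance(other, UptakeTable):
            return NotImplemented
        a = self.df.sort_values(TABLE_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(TABLE_COLUMNS).reset_index(drop=True)
        if a.shape != b.shape:
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=0, atol=1e-12)
        except AssertionError:
            return False
        return True


def read_state_table(path, sequences: Optional[Mapping[str, str]] = None,
                     first_residue_exclusion: int = 1) -> UptakeTable:
    """Read and validate a state-table CSV.

    Accepts internal or DynamX-style column names; labeling times may be
    numeric minutes or '25s'/'4.34h' strings.  Raises with row context
    on any invariant violation; sequence/coordinate checks run when a
    FASTA-derived ``sequences`` mapping is given.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sequence": str, "Sequence": str},
                     float_precision="round_trip")
    df = df.rename(columns=COLUMN_ALIASES)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df["time"] = [parse_time(v) for v in df["time"]]
    table = UptakeTable(df)
    table.validate(sequences=sequences, first_residue_exclusion=first_residue_exclusion)
    return table


def write_state_table(table: UptakeTable, path) -> None:
    """Write a state table as CSV with stable column order."""
    df = table.df.sort_values(TABLE_COLUMNS).reset_index(drop=True)
    df.to_csv(path, index=False)  # default float repr round-trips exactly


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """protein_id -> uppercased sequence; residue 1 is the first character."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"record {rec.id!r}: non-amino-acid character(s) {sorted(bad)!r}")
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# residue maps
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["residue", "time", "value", "source_start", "source_end", "gap_flag"]


def write_residue_map(rmap: ResidueMap, path) -> None:
    """Serialize a residue map as long-format CSV.

    Gaps are explicit: one row per (gap residue, time) with ``gap_flag``
    1 and an empty value.
    """
    rows = []
    for r in range(1, rmap.length + 1):
        src = rmap.source[r - 1]
        for j, t in enumerate(rmap.times):
            if src is None:
                rows.append((r, t, "", "", "", 1))
            else:
                rows.append((r, t, repr(float(rmap.values[r - 1, j])), src[0], src[1], 0))
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, index=False)


def read_residue_map(path, protein_id: str = "") -> ResidueMap:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing residue-map column(s): {missing}")
    times = sorted(df["time"].unique().tolist())
    length = int(df["residue"].max())
    values = np.full((length, len(times)), np.nan)
    source: list[Optional[Interval]] = [None] * length
    for _, row in df.iterrows():
        r = int(row["residue"])
        j = times.index(row["time"])
        if int(row["gap_flag"]):
            continue
        values[r - 1, j] = float(row["value"])
        source[r - 1] = (int(row["source_start"]), int(row["source_end"]))
    return ResidueMap(protein_id=protein_id, times=[float(t) for t in times],
                      values=values, source=source)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``states`` is an ordered mapping state name -> role, with exactly
    one ``"reference"`` role; ``"perturbed"`` states are compared
    against it and an optional ``"rescue"`` state is expected to match
    the reference.  ``domains`` optionally names residue ranges per
    protein (e.g. the membrane-proximal domain) for domain-level tests.
    """

    proteins: dict[str, str]              # id -> FASTA path (or "" if given in-memory)
    states: dict[str, str]                # name -> role
    times: list[float]
    state_tables: list[str] = field(default_factory=list)
    replicate_count: int = 3
    first_residue_exclusion: int = 1
    alpha: float = 0.05
    ref_time: float = 260.4
    heatmap_limit: Optional[float] = None  # symmetric color limit; None = auto
    domains: dict[str, dict[str, Interval]] = field(default_factory=dict)
    allotype_pairs: list[tuple[str, str]] = field(default_factory=list)
    out_dir: str = "results"
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        roles = [r for r in self.states.values() if r == "reference"]
        if len(roles) != 1:
            raise ValueError("exactly one state must have the 'reference' role")
        times = [parse_time(t) for t in self.times]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing")
        self.times = times
        if self.first_residue_exclusion not in (1, 2):
            raise ValueError("first_residue_exclusion must be 1 or 2")

    @property
    def reference_state(self) -> str:
        return next(s for s, r in self.states.items() if r == "reference")

    @property
    def perturbed_states(self) -> list[str]:
        return [s for s, r in self.states.items() if r == "perturbed"]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "domains" in raw:
            raw["domains"] = {
                prot: {name: tuple(iv) for name, iv in doms.items()}
                for prot, doms in raw["domains"].items()
            }
        if "allotype_pairs" in raw:
            raw["allotype_pairs"] = [tuple(p) for p in raw["allotype_pairs"]]
        return cls(**raw)
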