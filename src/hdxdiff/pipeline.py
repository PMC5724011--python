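"""End-to-end orchestration of the differential HDX-MS analysis.

Stages: load/validate inputs -> coverage and redundancy -> per-peptide
replicate statistics -> per-peptide state comparisons (Welch + BH) ->
differential uptake and residue-map consolidation per perturbed state ->
normalized uptake increases and paired t tests per configured domain ->
common-peptide matching between allotype pairs -> tables (and plots)
under the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as hio
from .consolidate import Interval, ResidueMap, build_residue_map
from .stats import (
    CoverageReport,
    NormalizedIncrease,
    PairedTResult,
    compare_all_peptides,
    coverage_redundancy,
    normalized_increase,
    paired_t_test,
)
from .uptake import UptakeStat, differential_uptake, replicate_stats

logger = logging.getLogger("hdxdiff")

__all__ = ["AnalysisReport", "PipelineError", "run_pipeline", "common_peptides", "table_stats"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage


@dataclass
class AnalysisReport:
    coverage: dict[str, CoverageReport] = field(default_factory=dict)
    uptake_stats: Optional[pd.DataFrame] = None
    residue_maps: dict[tuple[str, str], ResidueMap] = field(default_factory=dict)
    normalized: dict[tuple[str, str], list[NormalizedIncrease]] = field(default_factory=dict)
    domain_tests: dict[tuple[str, str, str], PairedTResult] = field(default_factory=dict)
    comparisons: dict[str, list[dict]] = field(default_factory=dict)
    common: dict[tuple[str, str], list[dict]] = field(default_factory=dict)
    qc_warnings: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def table_stats(
    table: "hio.UptakeTable", protein: str
) -> dict[Interval, dict[str, dict[float, UptakeStat]]]:
    """peptide -> state -> time -> replicate summary, for one protein."""
    out: dict[Interval, dict[str, dict[float, UptakeStat]]] = {}
    sub = table.df[table.df["protein"] == protein]
    for (s, e, state, t), grp in sub.groupby(["start", "end", "state", "time"]):
        out.setdefault((int(s), int(e)), {}).setdefault(str(state), {})[float(t)] = (
            replicate_stats(grp["uptake"].tolist())
        )
    return out


def common_peptides(table_a: "hio.UptakeTable", table_b: "hio.UptakeTable",
                    protein_a: Optional[str] = None, protein_b: Optional[str] = None) -> list[dict]:
    """Peptides present in both tables, matched on (start, end).

    Coordinate identity defines the match; a sequence difference at
    matched coordinates is reported as a polymorphism note, not a
    mismatch (allotypes differ at polymorphic positions inside shared
    intervals).
    """
    pa = protein_a or table_a.proteins[0]
    pb = protein_b or table_b.proteins[0]
    set_a = set(table_a.peptides(pa))
    set_b = set(table_b.peptides(pb))
    out = []
    for s, e in sorted(set_a & set_b):
        seq_a = table_a.peptide_sequence(pa, (s, e))
        seq_b = table_b.peptide_sequence(pb, (s, e))
        out.append({
            "start": s, "end": e,
            "sequence_a": seq_a, "sequence_b": seq_b,
            "polymorphic": seq_a != seq_b,
        })
    return out


def _nearest_time(times: list[float], target: float) -> float:
    return min(times, key=lambda t: abs(t - target))


def run_pipeline(
    config: "hio.RunConfig",
    tables: Optional[Mapping[str, "hio.UptakeTable"]] = None,
    sequences: Optional[Mapping[str, str]] = None,
) -> AnalysisReport:
    """Run the full analysis; deterministic for fixed inputs.

    ``tables``/``sequences`` may be passed in-memory (e.g. from the
    scenario generator); otherwise they are read from the paths in the
    config.  Emits CSV tables (and plots when ``config.make_plots``)
    under ``config.out_dir`` and returns the in-memory report.
    """
    report = AnalysisReport()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.params = {
        "first_residue_exclusion": config.first_residue_exclusion,
        "alpha": config.alpha,
        "ref_time": config.ref_time,
        "reference_state": config.reference_state,
        "states": dict(config.states),
    }
    logger.info("run parameters: %s", report.params)

    # ---- load ------------------------------------------------------------
    try:
        if sequences is None:
            sequences = {}
            for pid, fasta in config.proteins.items():
                sequences = {**sequences, **hio.read_fasta(fasta)}
        if tables is None:
            loaded: dict[str, hio.UptakeTable] = {}
            for path in config.state_tables:
                t = hio.read_state_table(path, sequences=sequences,
                                         first_residue_exclusion=config.first_residue_exclusion)
                for pid in t.proteins:
                    part = hio.UptakeTable(t.df[t.df["protein"] == pid])
                    if pid in loaded:
                        part = hio.UptakeTable(pd.concat([loaded[pid].df, part.df], ignore_index=True))
                    loaded[pid] = part
            tables = loaded
        for pid, table in tables.items():
            report.qc_warnings += table.validate(
                sequences=sequences if sequences else None,
                first_residue_exclusion=config.first_residue_exclusion,
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc

    ref_state = config.reference_state
    pert_states = [s for s in config.perturbed_states]
    rescue_states = [s for s, r in config.states.items() if r == "rescue"]
    if not pert_states and not rescue_states:
        report.qc_warnings.append(
            "single-state configuration: differential stages skipped"
        )

    # ---- coverage --------------------------------------------------------
    try:
        cov_rows = []
        for pid, table in tables.items():
            peps = table.peptides(pid)
            length = len(sequences[pid]) if pid in (sequences or {}) else max(e for _, e in peps)
            rep = coverage_redundancy(peps, length, protein_id=pid)
            report.coverage[pid] = rep
            cov_rows.append({"protein": pid, "coverage_percent": rep.coverage_percent,
                             "mean_redundancy": rep.mean_redundancy, "n_peptides": rep.n_peptides})
        pd.DataFrame(cov_rows).to_csv(out / "coverage.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("coverage", exc) from exc

    # ---- replicate statistics -------------------------------------------
    try:
        rows = []
        per_protein_stats = {}
        for pid, table in tables.items():
            stats = table_stats(table, pid)
            per_protein_stats[pid] = stats
            for pep, by_state in sorted(stats.items()):
                maxu = float(table.df[(table.df["protein"] == pid)
                                      & (table.df["start"] == pep[0])
                                      & (table.df["end"] == pep[1])]["max_uptake"].iloc[0])
                if maxu <= 0:
                    report.qc_warnings.append(
                        f"{pid} peptide {pep}: no exchange-competent amide, excluded")
                    continue
                for state, by_time in sorted(by_state.items()):
                    for t, st in sorted(by_time.items()):
                        rows.append({"protein": pid, "start": pep[0], "end": pep[1],
                                     "state": state, "time": t, "mean": st.mean,
                                     "sd": st.sd, "n": st.n, "max_uptake": maxu,
                                     "rel_frac_uptake": st.mean / maxu})
        report.uptake_stats = pd.DataFrame(rows)
        report.uptake_stats.to_csv(out / "uptake_stats.csv", index=False, float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("replicate-stats", exc) from exc

    # ---- differential maps and comparisons ------------------------------
    for pid, table in tables.items():
        stats = per_protein_stats[pid]
        peps = table.peptides(pid)
        length = len(sequences[pid]) if pid in (sequences or {}) else max(e for _, e in peps)
        for state in pert_states + rescue_states:
            if state not in table.states:
                continue
            try:
                diffs = {}
                for pep, by_state in stats.items():
                    if ref_state not in by_state or state not in by_state:
                        continue
                    maxu = float(table.df[(table.df["protein"] == pid)
                                          & (table.df["start"] == pep[0])
                                          & (table.df["end"] == pep[1])]["max_uptake"].iloc[0])
                    if maxu <= 0:
                        continue
                    diffs[pep] = {
                        t: differential_uptake(by_state[ref_state][t], by_state[state][t], maxu, time=t)
                        for t in by_state[ref_state]
                    }
                rmap = build_residue_map(diffs, list(diffs), length, protein_id=pid)
                report.residue_maps[(pid, state)] = rmap
                hio.write_residue_map(rmap, out / f"residue_map_{pid}_{state}_vs_{ref_state}.csv")
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"residue-map:{pid}:{state}", exc) from exc

        if pert_states:
            try:
                pairs = {}
                for pep, by_state in stats.items():
                    for state in pert_states:
                        if ref_state in by_state and state in by_state:
                            pairs[pep] = {t: (by_state[ref_state][t], by_state[state][t])
                                          for t in by_state[ref_state]}
                recs = compare_all_peptides(pairs, alpha=config.alpha)
                report.comparisons[pid] = recs
                pd.DataFrame(recs).to_csv(out / f"comparisons_{pid}.csv", index=False)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"comparisons:{pid}", exc) from exc

    # ---- domain statistics ----------------------------------------------
    try:
        dom_rows = []
        for pid, domains in config.domains.items():
            if pid not in tables:
                continue
            table = tables[pid]
            stats = per_protein_stats[pid]
            ref_t = _nearest_time(table.times, config.ref_time)
            for dom_name, (ds, de) in domains.items():
                dom_peps = [p for p in table.peptides(pid) if p[0] >= ds and p[1] <= de]
                for state in pert_states:
                    norm = []
                    a, b = [], []
                    for pep in dom_peps:
                        by_state = stats[pep]
                        if ref_state not in by_state or state not in by_state:
                            continue
                        ref_vals = table.replicate_values(pid, ref_state, pep, ref_t)
                        pert_vals = table.replicate_values(pid, state, pep, ref_t)
                        norm.append(normalized_increase(ref_vals, pert_vals, peptide=pep))
                        a.append(by_state[state][ref_t].mean)
                        b.append(by_state[ref_state][ref_t].mean)
                    report.normalized[(pid, dom_name)] = norm
                    if len(a) >= 2:
                        res = paired_t_test(a, b)
                        report.domain_tests[(pid, dom_name, state)] = res
                        dom_rows.append({"protein": pid, "domain": dom_name, "state": state,
                                         "n_peptides": len(a), "t": res.t, "p": res.p,
                                         "df": res.df, "ref_time": ref_t})
        if dom_rows:
            pd.DataFrame(dom_rows).to_csv(out / "domain_tests.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("domain-stats", exc) from exc

    # ---- common peptides -------------------------------------------------
    try:
        for pid_a, pid_b in config.allotype_pairs:
            if pid_a in tables and pid_b in tables:
                common = common_peptides(tables[pid_a], tables[pid_b], pid_a, pid_b)
                report.common[(pid_a, pid_b)] = common
                pd.DataFrame(common).to_csv(out / f"common_{pid_a}_{pid_b}.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("common-peptides", exc) from exc

    # ---- plots -----------------------------------------------------------
    if config.make_plots:
        try:
            from . import plotting

            for (pid, state), rmap in report.residue_maps.items():
                plotting.heatmap(rmap, out / f"heatmap_{pid}_{state}.png",
                                 vlim=config.heatmap_limit)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("plots", exc) from exc

    # ---- summary ---------------------------------------------------------
    summary = {
        "params": report.params,
        "coverage": {pid: {"coverage_percent": c.coverage_percent,
                           "mean_redundancy": c.mean_redundancy,
                           "n_peptides": c.n_peptides}
                     for pid, c in report.coverage.items()},
        "domain_tests": {f"{pid}/{dom}/{state}": {"t": r.t, "p": r.p, "df": r.df}
                         for (pid, dom, state), r in report.domain_tests.items()},
        "common_counts": {f"{a}~{b}": len(v) for (a, b), v in report.common.items()},
        "qc_warnings": report.qc_warnings,
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return report
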