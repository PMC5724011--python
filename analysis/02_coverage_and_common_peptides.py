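#!/usr/bin/env python
"""Peptide-map quality: coverage, redundancy and allotype overlap.

Reads the simulated state tables, reports per-protein coverage percent
and mean redundancy, and counts the peptides common to both heavy
chains (matched on sequence location, polymorphisms annotated).
"""

import argparse
from pathlib import Path

import pandas as pd

from hdxdiff.io import read_fasta, read_state_table
from hdxdiff.pipeline import common_peptides
from hdxdiff.stats import coverage_redundancy


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simulated"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sequences = read_fasta(args.data / "proteins.fasta")
    tables = {pid: read_state_table(args.data / f"state_table_{pid}.csv", sequences=sequences)
              for pid in sequences}

    rows = []
    for pid, table in tables.items():
        rep = coverage_redundancy(table.peptides(pid), len(sequences[pid]), protein_id=pid)
        rows.append({"protein": pid, "coverage_percent": rep.coverage_percent,
                     "mean_redundancy": rep.mean_redundancy, "n_peptides": rep.n_peptides})
        print(f"{pid}: {rep.n_peptides} peptides, {rep.coverage_percent:.1f}% coverage, "
              f"redundancy {rep.mean_redundancy:.2f}")
    pd.DataFrame(rows).to_csv(args.out / "coverage_report.csv", index=False)

    common = common_peptides(tables["HC_A"], tables["HC_B"], "HC_A", "HC_B")
    n_poly = sum(rec["polymorphic"] for rec in common)
    print(f"heavy chains share {len(common)} peptides "
          f"({n_poly} spanning a polymorphic residue)")
    pd.DataFrame(common).to_csv(args.out / "common_peptides_HC.csv", index=False)


if __name__ == "__main__":
    main()
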