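# hdxdiff

Differential hydrogen–deuterium exchange mass spectrometry (HDX-MS)
analysis for comparing the conformational dynamics of a protein across
ligand states and allotypes — built around the study design in which a
photocleavable ("conditional") ligand is hydrolyzed by UV light to
synchronously generate peptide-receptive MHC class I molecules, which
are then compared with their ligand-loaded and peptide-rescued
counterparts.

The package is organized as an analysis project: the library under
`src/hdxdiff/` holds every computation; the numbered scripts under
`analysis/` are thin drivers that run the study end to end on simulated
data and write their tables under `results/`.

## What it computes

**Per-peptide uptake.** For each peptic peptide (1-based inclusive
residue coordinates on the mature protein), deuterium uptake in Da
above the undeuterated centroid, summarized per (state, labeling time)
as mean ± sample SD over replicates. The maximum theoretical uptake of
a peptide is its number of exchange-competent amides:

    N_amides = (length − n_term_exclusion) − #prolines beyond the exclusion

with `n_term_exclusion = 1` by default (the N-terminal amide
back-exchanges during workup; 2 is available as the common field
alternative). Relative fractional uptake is `D / N_amides`.

**Differential maps.** For a perturbed state vs the reference,
`Δ = D̄_pert − D̄_ref` and the relative fractional difference
`Δ / N_amides` per peptide and time, consolidated to residue level by
the overlapping-peptide rule: for each residue, among peptides covering
it non-terminally (`start < r ≤ end`), the **shortest** peptide supplies
the value; ties go to the peptide whose C terminus is closest to the
protein C terminus; residues with no eligible peptide are explicit
gaps. The result is a residues × times matrix rendered as a red–blue
heat map.

**Dataset statistics.** Peptide-map coverage and mean redundancy;
per-peptide Welch tests between states with Benjamini–Hochberg control
across (peptides × times); the normalized uptake increase of a domain's
peptides, `(D̄_pert − D̄_ref) / D̄_ref` at the longest labeling time
(4.34 h); and a paired two-tailed t test across a domain's peptides for
a state effect.

**Forward simulation.** Linderstrøm-Lang EX2 kinetics: residue *i* in
state *s* exchanges at `k_int,i / P_s,i` (protection factor `P ≥ 1`,
`+∞` for non-exchanging), so a peptide's noiseless uptake is

    D(t) = β · f_D2O · Σ_i (1 − exp(−(k_int,i / P_i) · t))

over its exchange-competent residues, with back-exchange recovery
`β = 0.7` and `f_D2O = 0.95` (20-fold dilution into D2O buffer) by
default. A digestion simulator emulates overlapping peptic maps at a
requested coverage and redundancy, and a scenario builder produces the
full two-allotype × {loaded, receptive, rescued} design with known
ground-truth perturbed regions. Isotopic envelopes are binomial (EX2)
or binomial mixtures (EX1-like), classified unimodal/bimodal by
BIC-selected maximum-likelihood mixture fits. Fluorescence-polarization
receptivity uses `mP = 1000(S − G·P)/(S + G·P)` with an unbound
baseline of 50 mP.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_coverage_and_common_peptides.py
python analysis/03_differential_heatmaps.py
python analysis/04_domain_statistics.py
```

which prints (seed 1):

```
HC_A: 99 peptides, 98.5% coverage, redundancy 5.15
...
heavy chains share 85 peptides (30 spanning a polymorphic residue)
HC_A: top-decile residues vs strong ground truth, Jaccard = 0.60
HC_A: rescued-state max |rel frac diff| = 0.0185 (reversal control)
HC_A alpha3: 29 peptides, receptive vs loaded paired t = 3.242, p = 3.06e-03
```

Reading: the simulated heavy chain map has 99 overlapping peptides at
~5× redundancy covering 98.5% of the chain. The residues flagged by the
top decile of |relative fractional difference| at intermediate labeling
times overlap the ground-truth strongly destabilized sub-regions
(Jaccard 0.60); the rescued state shows only noise-level differences
(max 0.018), i.e. re-adding peptide reverses the receptive-state
signature. The small long-range uptake increase simulated in the
membrane-proximal domain is detected by the paired t test (p ≈ 0.003
across its 29 peptides).

The same pipeline runs from the shell on any state-table CSV + FASTA
input via the `hdxdiff` CLI (`simulate`, `analyze`, `heatmap`, `fp`
subcommands); see `hdxdiff --help`.

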