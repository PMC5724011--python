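# Methods

## Exchange model

Backbone amide hydrogens exchange with solvent deuterium; with the
exception of proline (no backbone amide H) every residue can exchange.
We model the EX2 limit of the Linderstrøm-Lang framework: each residue
exchanges independently and first-order at an observed rate
`k_obs,i = k_int,i / P_s,i`, where `k_int,i` is the intrinsic rate and
`P_s,i ≥ 1` the protection factor of residue *i* in state *s*
(`+∞` marks sites that never exchange). The noiseless uptake of a
peptide after labeling time *t* (minutes) is

    D(t) = β · f_D2O · Σ_i (1 − exp(−k_obs,i · t))

summed over the peptide's exchange-competent residues. Replicate
measurements add Gaussian noise (SD `uptake_sd`) and are floored at 0.

Assumptions and consequences:

* **EX2 only.** Each hydrogen-bond opening rarely leads to exchange, so
  envelopes shift gradually and stay unimodal; centroid uptake is the
  right summary. EX1-like mixed populations appear only in the spectra
  module's mixture generator, used for the dissociation control.
* **Exchange-competent residues** of a peptide are all residues except
  its first `n_term_exclusion` (default 1) and prolines. The first
  residue's amide deuterium is lost to back-exchange at the nascent
  N terminus during quench/digestion; excluding the first two residues
  is the common field alternative and is a configuration switch read by
  every module. The protein's residue 1 can only ever be a peptide's
  first residue, so it never contributes.
* **Intrinsic rates** default to a uniform base rate (60 min⁻¹,
  representative of amide exchange near neutral pH) with optional
  per-residue multipliers. Sequence-dependent intrinsic-rate tables
  would only re-parameterize the product `k_int/P`, which is already
  free via the protection profile; recovery tests need known ground
  truth, not chemical realism per residue.
* **Back-exchange** (β = 0.7) and **labeling-buffer deuterium fraction**
  (f_D2O = 0.95, a 20-fold dilution into D2O buffer) scale observable
  uptake multiplicatively. No back-exchange correction is applied to
  *measured* uptake anywhere in the analysis — the analysis reports
  relative uptake, and β cancels in all comparisons; β lives only in
  the simulator. Maximum theoretical uptake is the amide count, so
  fully exchanged peptides plateau near β·f_D2O ≈ 66% of theoretical
  maximum, matching the behavior of real peptides.

## Units and conventions

Residue coordinates are 1-based inclusive, numbered from the first
residue of the mature protein (= first FASTA character). Uptake is in
daltons above the undeuterated centroid. Times are minutes internally;
parsers accept `25s` / `2.1min` / `4.34h`. State tables are UTF-8 CSV
with a mandatory header; DynamX-style capitalized column names are
accepted via an alias map. CSV floats are written with full round-trip
precision and parsed with pandas' `round_trip` option so write→read is
the exact identity.

## Residue-level consolidation

A peptide (s, e) is *eligible* for residue r iff `s < r ≤ e`; among
eligible peptides the shortest supplies the value; ties break to the
peptide whose C-terminal residue index is greatest, then to the
greatest start. Residues with no eligible peptide are explicit gaps.
Because selection depends only on the peptide map, a residue's source
peptide is constant across labeling times.

The tie-break phrase "residue closest to the protein C terminus" is
interpreted as the greatest *end* index of the tied peptides — the only
parameter-free reading for interval data; "closest start" is a
conceivable alternative but would make a longer reach toward the
C terminus lose to a shorter one, which contradicts the phrase's
intent. Equal-length peptides with equal ends are identical intervals,
so the third tie-break matters only if charge variants are kept as
duplicates. Heat-map rendering is a plotting concern (red–blue,
symmetric limits about 0); the map itself stores numbers.

## Statistics

* **Coverage / redundancy**: coverage = 100·|∪intervals|/length;
  redundancy = mean number of peptides containing each *covered*
  residue (full membership, no N-terminus exclusion — a map statistic,
  not a rendering rule).
* **Replicate summaries**: mean and sample SD (n−1); single replicates
  carry SD 0 with a flag.
* **Differential uptake**: Δ = perturbed − reference mean;
  `pooled_sd = sqrt(sd_r²/n_r + sd_p²/n_p)` (the SE of the difference
  of means). Values above the theoretical maximum are flagged as QC
  warnings, never clamped — they are evidence of a convention mismatch.
* **Per-peptide comparisons**: Welch two-sample t per timepoint from
  replicate summaries, Welch–Satterthwaite df; dataset-level calls
  apply Benjamini–Hochberg across (peptides × times) at α = 0.05 by
  default (configurable; the criterion itself is a design choice, as
  significance procedures are rarely stated in published HDX work).
  Zero-variance cases are reported as degenerate, not silently decided.
* **Normalized increase** (membrane-proximal domains): per peptide,
  `(D̄_pert(T) − D̄_ref(T)) / D̄_ref(T)` with T the longest labeling
  time (4.34 h); per-replicate variants pair replicate indices over the
  mean reference denominator. Non-positive denominators exclude the
  peptide with a flag. Both numerator and denominator at T is the
  default reading; the numerator time is a parameter.
* **Domain test**: paired two-tailed t across a domain's peptides
  (receptive vs loaded mean uptake at T), df = n − 1; p from the t
  distribution. Degenerate zero-variance difference vectors are
  flagged (t = 0, p = 1 if identical; |t| = ∞, p = 0 otherwise).

**Small-sample behavior of Welch's test.** With triplicates the
Welch–Satterthwaite approximation is conservative: the true size at
nominal α = 0.05 is ≈ 0.036 (the same holds for reference
implementations). The empirical-level check is therefore run at 10
replicates per state, where the approximation is accurate (size
≈ 0.048); a companion check verifies the triplicate test never exceeds
the nominal level — it errs only on the safe side for significance
calls.

## Synthetic study design

The default scenario emulates the design the analysis was built for:
two closely related class I heavy chains (275 residues, differing at 8
positions), each non-covalently paired with a shared 98-residue light
chain; three states (loaded = reference, receptive = perturbed,
rescued = identical protection to loaded); labeling times 25 s, 2.1,
10.4, 52.1 min, 4.34 h; triplicate measurements with replicate SD
0.08 Da.

* **Digestion**: random overlapping tiling that meets requested
  coverage (±5 points) and redundancy (±20%), validated against the
  map-statistics module; infeasible targets raise an explicit error.
  Heavy chains use mean length 14, redundancy 5.95, coverage 98.5%;
  the light chain mean length 12, redundancy 5.46, coverage 100% —
  giving ~99 heavy-chain and 40 light-chain peptides. Because pepsin
  cleavage is sequence-determined, both allotype maps derive from one
  parent digest by randomly dropping ~15% of peptides per allotype
  (never uncovering a residue), leaving ~85 peptides common to both
  heavy chains.
* **Protection**: a two-population lognormal profile — ~25% of residues
  "solvent-exposed" (median P = 300, saturating within minutes in every
  state) and the rest "structured" (median P = 2·10⁴), σ_lnP = 0.6.
* **Perturbed regions** (receptive state only): two strongly
  destabilized peptide-binding-domain sub-regions per heavy chain
  (residues 110–119 and 130–148; protection ÷ 20–30), sized together to
  ≈10% of the chain so decile-based localization is well-posed; weaker
  long-range increases (fold 2–6) in helix analogs (57–80, 149–155) and
  membrane-proximal analogs (196–213, 231–240), and one weak light-chain
  region (54–62, fold 4). Ground truth (with fold changes, and the
  strong subset separately) rides in scenario metadata for recovery
  scoring.
* **Seeding**: one master seed; per-(protein, state, purpose) child
  seeds derived via CRC-hashed `SeedSequence` spawning, so any
  sub-simulation is reproducible in isolation.

What the generator does *not* emulate: chromatographic losses and
carry-over, peptide misassignment, correlated replicate drift,
sequence-dependent intrinsic rates, temperature/pD corrections, and
EX1 behavior in the uptake tables. Passing recovery tests therefore
shows the analysis logic is correct under the stated noise model, not
that real instruments behave this simply.

## Spectra

Envelopes are binomial: with n exchange-competent sites each deuterated
with probability p, intensity at k deuterons is Binom(n, p) at k, peaks
at `base_mz + k·1.00628/charge` Da. Mixed populations are weighted
binomial mixtures. Natural isotope structure (¹³C…) is omitted by
default — it cancels in relative (centroid-difference) uptake — with a
convolution hook for callers who want it. Modality: normalized
intensities are treated as an empirical distribution over k; one- and
two-component binomial mixtures are fit by maximum likelihood (bounded
scalar search; coarse grid + Nelder–Mead polish) and compared by BIC at
an effective ion count of 1000, two components winning when
ΔBIC > 2. Classification is invariant to intensity scaling by
construction.

## Fluorescence polarization

`mP = 1000(S − G·P)/(S + G·P)` from background-subtracted parallel/
perpendicular count rates and grating factor G. Receptivity is
reported both ways found in practice: the baseline-subtracted fraction
of binding sites `(mP_t − 50)/(mP_0 − 50)` (default for "% loss of
binding sites"; unbound reporter ≈ 50 mP) and the raw ratio
`mP_t/mP_0`. The simulated decay is piecewise-exponential in the
receptive fraction — a two-day plateau (fractional loss rates of order
10⁻³ h⁻¹) followed by rapid collapse (~0.1 h⁻¹), the shape observed
for conditionally loaded class I molecules.

## Numerical choices and degenerate inputs

* Empty replicate lists, non-positive maximum uptake, unknown states,
  negative times, invalid residues, duplicate measurement keys and
  coordinate/sequence mismatches all raise with context; QC-grade
  issues (uptake above theoretical maximum, excluded zero-amide
  peptides) are warnings.
* Peptides with no exchange-competent amide (short all-proline
  fragments) are omitted by the simulator and excluded by the pipeline
  with a warning — they carry no observable signal.
* The "rescue reverses the signature" check compares the rescued map's
  maximum |relative fractional difference| with the 99th percentile of
  the *distribution of map-wide maxima* under replicate null
  simulations (not the percentile of cell values within one null map,
  which the maximum of any same-distribution map would almost surely
  exceed).
* Analysis problem sizes used by the validation suite: 1000 random maps
  for oracle equivalence, 4000 null tests for the empirical level, 60
  null replicates for the reversal threshold, 500 spectra for the
  modality benchmark, 10⁴ replicates for the law-of-large-numbers
  check.

## Known limitations

* Residue-level values are peptide-consolidated, not deconvolved;
  boundaries of perturbed regions blur by roughly the length of the
  shortest covering peptides (this bounds localization Jaccard well
  below 1 even with noiseless data).
* The BH-corrected Welch procedure treats (peptide × time) tests as
  exchangeable and ignores the correlation between overlapping
  peptides.
* The digestion simulator matches map *statistics*, not pepsin
  specificity; common-peptide realism between allotypes is imposed by
  construction.
* No raw-spectrum ingestion: centroided stick spectra and uptake tables
  are the entry points.
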