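"""Multi-state, multi-allotype study scenarios.

A scenario emulates the design of a conditional-ligand HDX-MS study:
each protein is measured in three states sharing one peptide map —

* ``loaded``    — reference, intact ligand, baseline protection;
* ``receptive`` — ligand hydrolyzed; protection is reduced *only*
  inside configured sub-regions, each by its own fold-change;
* ``rescued``   — ligand hydrolyzed then re-supplied with excess
  peptide; its protection profile is identical to ``loaded``, so any
  apparent differential is pure noise (the reversal control).

The default demo scenario models two closely related class I allotypes
(heavy chains of 275 residues differing at eight positions, plus a
shared 98-residue light chain), with strongly elevated receptive-state
exchange in two peptide-binding-domain sub-regions and weaker long-range
increases in membrane-proximal regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consolidate import Interval
from .io import UptakeTable
from .simulate import (
    DigestionParams,
    ExchangeModel,
    NoiseModel,
    child_seed,
    random_protein,
    simulate_digestion,
    simulate_uptake,
)
from .stats import coverage_redundancy

__all__ = [
    "Region",
    "ProteinSpec",
    "ScenarioConfig",
    "Scenario",
    "make_two_state_scenario",
    "demo_scenario_config",
    "thin_peptide_map",
    "STATE_LOADED",
    "STATE_RECEPTIVE",
    "STATE_RESCUED",
]

STATE_LOADED = "loaded"
STATE_RECEPTIVE = "receptive"
STATE_RESCUED = "rescued"


@dataclass(frozen=True)
class Region:
    """A sub-region whose protection drops in the receptive state."""

    start: int
    end: int
    fold: float  # protection divided by this factor; 1 = no change

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region ({self.start}, {self.end})")
        if self.fold < 1:
            raise ValueError("fold-change must be >= 1")


@dataclass
class ProteinSpec:
    protein_id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)
    peptides: Optional[list[Interval]] = None   # explicit map, else digested
    digestion: Optional[DigestionParams] = None

    def __post_init__(self) -> None:
        regs = sorted(self.regions, key=lambda r: (r.start, r.end))
        for a, b in zip(regs, regs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.protein_id}: overlapping region specifications "
                    f"({a.start},{a.end}) and ({b.start},{b.end})"
                )
        for r in regs:
            if r.end > len(self.sequence):
                raise ValueError(f"{self.protein_id}: region {r} outside sequence")


@dataclass
class ScenarioConfig:
    proteins: list[ProteinSpec]
    times: list[float] = field(default_factory=lambda: [25 / 60, 2.1, 10.4, 52.1, 260.4])
    noise: NoiseModel = field(default_factory=NoiseModel)
    k_int_base: float = 60.0                  # 1/min, uniform intrinsic rate
    protection_structured: float = 2.0e4      # median P of hydrogen-bonded core
    protection_exposed: float = 300.0         # median P of solvent-exposed turns
    exposed_fraction: float = 0.25
    protection_sigma: float = 0.6             # sigma of ln P
    d2o_fraction: float = 0.95
    back_exchange: float = 0.7
    n_term_exclusion: int = 1
    seed: int = 0


@dataclass
class Scenario:
    """Simulated experiment: tables, models, maps and ground truth."""

    config: ScenarioConfig
    tables: dict[str, UptakeTable]
    models: dict[str, ExchangeModel]
    peptide_maps: dict[str, list[Interval]]
    metadata: dict

    def table(self, protein_id: str) -> UptakeTable:
        return self.tables[protein_id]


def _protection_profile(length: int, cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    exposed = rng.random(length) < cfg.exposed_fraction
    median = np.where(exposed, cfg.protection_exposed, cfg.protection_structured)
    prof = np.exp(rng.normal(np.log(median), cfg.protection_sigma))
    return np.maximum(prof, 1.0)


def make_two_state_scenario(config: ScenarioConfig) -> Scenario:
    """Build the paired loaded/receptive/rescued tables for every protein.

    The rescued-state protection profile is *identical* to the loaded
    one; the receptive profile differs from it only inside each
    protein's configured regions.  All three states share one peptide
    map per protein.  Ground-truth regions are recorded in
    ``scenario.metadata["ground_truth_regions"]``.
    """
    tables: dict[str, UptakeTable] = {}
    models: dict[str, ExchangeModel] = {}
    maps: dict[str, list[Interval]] = {}
    truth: dict[str, list[tuple[int, int, float]]] = {}

    for spec in config.proteins:
        length = len(spec.sequence)
        rng = np.random.default_rng(child_seed(config.seed, spec.protein_id, "protection"))
        base = _protection_profile(length, config, rng)
        receptive = base.copy()
        for reg in spec.regions:
            receptive[reg.start - 1 : reg.end] = np.maximum(
                1.0, receptive[reg.start - 1 : reg.end] / reg.fold
            )
        model = ExchangeModel(
            protein_id=spec.protein_id,
            sequence=spec.sequence,
            k_int=np.full(length, config.k_int_base),
            protection={
                STATE_LOADED: base,
                STATE_RECEPTIVE: receptive,
                STATE_RESCUED: base.copy(),
            },
            d2o_fraction=config.d2o_fraction,
            back_exchange=config.back_exchange,
        )
        if spec.peptides is not None:
            peptides = list(spec.peptides)
        else:
            dig = spec.digestion or DigestionParams(
                seed=child_seed(config.seed, spec.protein_id, "digestion")
            )
            peptides = simulate_digestion(spec.sequence, dig)

        frames = [
            simulate_uptake(
                model, peptides, config.times, config.noise, state,
                seed=child_seed(config.seed, spec.protein_id, state),
                n_term_exclusion=config.n_term_exclusion,
            )
            for state in (STATE_LOADED, STATE_RECEPTIVE, STATE_RESCUED)
        ]
        tables[spec.protein_id] = UptakeTable(pd.concat(frames, ignore_index=True))
        models[spec.protein_id] = model
        maps[spec.protein_id] = peptides
        truth[spec.protein_id] = [(r.start, r.end, r.fold) for r in spec.regions]

    metadata = {
        "seed": config.seed,
        "states": {
            STATE_LOADED: "reference",
            STATE_RECEPTIVE: "perturbed",
            STATE_RESCUED: "rescue",
        },
        "times": list(config.times),
        "ground_truth_regions": truth,
        "strong_regions": {
            pid: [(s, e, f) for s, e, f in regs if f >= 10.0]
            for pid, regs in truth.items()
        },
    }
    return Scenario(config=config, tables=tables, models=models,
                    peptide_maps=maps, metadata=metadata)


# ---------------------------------------------------------------------------
# peptide-map thinning (allotype realism)
# ---------------------------------------------------------------------------

def thin_peptide_map(
    peptides: Sequence[Interval],
    drop_fraction: float,
    seed: int,
    protein_length: int,
) -> list[Interval]:
    """Drop a random subset of peptides without ever uncovering a residue.

    Pepsin cleavage is sequence-determined, so near-identical allotypes
    share most peptides; deriving each allotype's map from one parent
    digest by safe random drops reproduces that partial overlap.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    counts = np.zeros(protein_length, dtype=int)
    for s, e in peptides:
        counts[s - 1 : e] += 1
    order = list(peptides)
    rng.shuffle(order)
    target = int(round(drop_fraction * len(order)))
    kept = set(peptides)
    dropped = 0
    for s, e in order:
        if dropped >= target:
            break
        if counts[s - 1 : e].min() >= 2:
            kept.discard((s, e))
            counts[s - 1 : e] -= 1
            dropped += 1
    return sorted(kept)


# ---------------------------------------------------------------------------
# default demo scenario
# ---------------------------------------------------------------------------

#: heavy-chain positions that differ between the two demo allotypes
#: (eight substitutions, as in closely related class I allotype pairs)
POLYMORPHIC_POSITIONS = (22, 69, 79, 95, 111, 113, 126, 220)

HC_LENGTH = 275
B2M_LENGTH = 98

#: receptive-state fold-changes: two strong peptide-binding-domain
#: sub-regions (beta-6/alpha-2-1-sub-helix analogs, together ~10% of the
#: chain) plus weak long-range increases in helix/membrane-proximal
#: analogs.  The light chain gets one weak region.
HC_REGIONS_A = [
    Region(57, 80, 3.0),
    Region(110, 119, 25.0),
    Region(130, 148, 30.0),
    Region(149, 155, 4.0),
    Region(196, 213, 2.5),
    Region(231, 240, 2.5),
]
HC_REGIONS_B = [
    Region(57, 80, 2.5),
    Region(110, 119, 20.0),
    Region(130, 148, 24.0),
    Region(149, 155, 6.0),
    Region(196, 213, 2.0),
    Region(231, 240, 2.0),
]
B2M_REGIONS = [Region(54, 62, 4.0)]

_SUBSTITUTE = {"A": "S", "C": "S", "D": "G", "E": "D", "F": "Y", "G": "A",
               "H": "Q", "I": "V", "K": "R", "L": "W", "M": "L", "N": "S",
               "P": "A", "Q": "R", "R": "K", "S": "T", "T": "S", "V": "I",
               "W": "F", "Y": "F"}


def _mutate(sequence: str, positions: Sequence[int]) -> str:
    seq = list(sequence)
    for pos in positions:
        seq[pos - 1] = _SUBSTITUTE[seq[pos - 1]]
    return "".join(seq)


def demo_scenario_config(seed: int = 0, noise: Optional[NoiseModel] = None) -> ScenarioConfig:
    """Two-allotype, three-state demo scenario with known ground truth.

    Heavy chains HC_A / HC_B (275 residues, eight substitutions) carry
    ~110 overlapping peptides each (~5-6x redundancy, ~98% coverage),
    the shared light chain B2M ~40 peptides; both allotype maps derive
    from one parent digest so ~70% of peptides are common.
    """
    hc_a = random_protein(HC_LENGTH, child_seed(seed, "hc", "sequence"))
    hc_b = _mutate(hc_a, POLYMORPHIC_POSITIONS)
    b2m = random_protein(B2M_LENGTH, child_seed(seed, "b2m", "sequence"))

    hc_dig = DigestionParams(mean_length=14, length_sd=3, target_redundancy=5.95,
                             coverage_target=0.985, seed=child_seed(seed, "hc", "digestion"))
    b2m_dig = DigestionParams(mean_length=12, length_sd=3, target_redundancy=5.46,
                              coverage_target=1.0, seed=child_seed(seed, "b2m", "digestion"))
    hc_parent = simulate_digestion(hc_a, hc_dig)
    b2m_parent = simulate_digestion(b2m, b2m_dig)

    proteins = [
        ProteinSpec("HC_A", hc_a, list(HC_REGIONS_A),
                    peptides=thin_peptide_map(hc_parent, 0.15, child_seed(seed, "HC_A", "thin"), HC_LENGTH)),
        ProteinSpec("HC_B", hc_b, list(HC_REGIONS_B),
                    peptides=thin_peptide_map(hc_parent, 0.15, child_seed(seed, "HC_B", "thin"), HC_LENGTH)),
        ProteinSpec("B2M_A", b2m, list(B2M_REGIONS),
                    peptides=thin_peptide_map(b2m_parent, 0.12, child_seed(seed, "B2M_A", "thin"), B2M_LENGTH)),
        ProteinSpec("B2M_B", b2m, list(B2M_REGIONS),
                    peptides=thin_peptide_map(b2m_parent, 0.12, child_seed(seed, "B2M_B", "thin"), B2M_LENGTH)),
    ]
    return ScenarioConfig(proteins=proteins, noise=noise or NoiseModel(), seed=seed)


def null_scenario_config(seed: int = 0, protein_id: str = "HC_NULL",
                         length: int = HC_LENGTH,
                         noise: Optional[NoiseModel] = None) -> ScenarioConfig:
    """Single-protein scenario with *no* perturbed regions (pure noise)."""
    seq = random_protein(length, child_seed(seed, protein_id, "sequence"))
    dig = DigestionParams(mean_length=14, length_sd=3, target_redundancy=5.95,
                          coverage_target=0.985, seed=child_seed(seed, protein_id, "digestion"))
    spec = ProteinSpec(protein_id, seq, regions=[], digestion=dig)
    return ScenarioConfig(proteins=[spec], noise=noise or NoiseModel(), seed=seed)
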