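"""Exchange-kinetics simulator: digestion maps, EX2 uptake, noise."""

import numpy as np
import pytest

from hdxdiff.simulate import (
    DigestionParams,
    ExchangeModel,
    InfeasibleDigestionError,
    NoiseModel,
    expected_uptake,
    random_protein,
    simulate_digestion,
    simulate_uptake,
)
from hdxdiff.stats import coverage_redundancy
from oracles import oracle_coverage_redundancy


def make_model(sequence, protection, **kw):
    return ExchangeModel(
        protein_id="P",
        sequence=sequence,
        k_int=np.full(len(sequence), kw.pop("k_int", 60.0)),
        protection={"s": np.asarray(protection, dtype=float)},
        **kw,
    )


class TestDigestion:
    def test_only_feasible_map_is_whole_protein(self):
        params = DigestionParams(mean_length=20, length_sd=0, target_redundancy=1,
                                 coverage_target=1.0, seed=5)
        assert simulate_digestion("A" * 20, params) == [(1, 20)]

    def test_deterministic_for_fixed_seed(self):
        seq = random_protein(150, seed=4)
        params = DigestionParams(seed=9)
        assert simulate_digestion(seq, params) == simulate_digestion(seq, params)

    def test_targets_achieved_on_long_sequence(self):
        seq = random_protein(275, seed=2)
        params = DigestionParams(mean_length=12, length_sd=3, target_redundancy=5.5,
                                 coverage_target=0.985, seed=3)
        peps = simulate_digestion(seq, params)
        cov, red = oracle_coverage_redundancy(peps, 275)
        assert 93.5 <= cov <= 100.0
        assert 4.4 <= red <= 6.6

    def test_infeasible_targets_raise(self):
        with pytest.raises(InfeasibleDigestionError):
            simulate_digestion("A" * 10, DigestionParams(mean_length=20))
        with pytest.raises(InfeasibleDigestionError):
            simulate_digestion("A" * 50, DigestionParams(mean_length=5, target_redundancy=6.0))

    def test_intervals_within_bounds(self):
        seq = random_protein(120, seed=6)
        peps = simulate_digestion(seq, DigestionParams(seed=1))
        assert all(1 <= s <= e <= 120 for s, e in peps)


class TestExpectedUptake:
    def test_zero_time_gives_zero(self):
        m = make_model("KRLIGKRY", [100.0] * 8)
        assert expected_uptake(m, (1, 8), 0.0, "s") == 0.0

    def test_infinite_protection_gives_zero(self):
        m = make_model("KRLIGKRY", [np.inf] * 8)
        for t in (0.5, 10.0, 1e6):
            assert expected_uptake(m, (1, 8), t, "s") == 0.0

    def test_saturation_limit(self):
        # 8 residues, no prolines, N-terminus excluded -> 7 competent sites
        m = make_model("KRLIGKRY", [100.0] * 8, d2o_fraction=0.95, back_exchange=0.7)
        assert expected_uptake(m, (1, 8), 1e9, "s") == pytest.approx(7 * 0.7 * 0.95, abs=1e-9)
        assert expected_uptake(m, (1, 8), 1e9, "s") == pytest.approx(4.655, abs=1e-9)

    def test_monotone_in_time(self):
        seq = random_protein(60, seed=8)
        rng = np.random.default_rng(0)
        m = make_model(seq, np.exp(rng.normal(np.log(1e3), 1.0, 60)))
        times = np.logspace(-2, 4, 25)
        ups = [expected_uptake(m, (5, 40), t, "s") for t in times]
        assert all(b >= a for a, b in zip(ups, ups[1:]))

    def test_additive_over_single_residue_peptide_decomposition(self):
        # peptide uptake equals the sum of per-residue contributions,
        # computed independently from the closed-form rate expression
        seq = "KRLPIGKARY"
        prot = np.exp(np.random.default_rng(1).normal(np.log(500), 0.8, len(seq)))
        m = make_model(seq, prot)
        t = 7.3
        total = expected_uptake(m, (2, 9), t, "s")
        manual = 0.0
        for r in range(3, 10):  # residues 3..9; residue 2 is the peptide N-terminus
            if seq[r - 1] == "P":
                continue
            k = 60.0 / prot[r - 1]
            manual += 0.7 * 0.95 * (1.0 - np.exp(-k * t))
        assert total == pytest.approx(manual, abs=1e-12)

    def test_monotone_in_protection_scaling(self):
        seq = random_protein(40, seed=9)
        prot = np.exp(np.random.default_rng(2).normal(np.log(200), 1.0, 40))
        for c in (1.5, 3.0, 10.0):
            m1 = make_model(seq, prot)
            m2 = make_model(seq, prot * c)
            for t in (0.5, 10.0, 300.0):
                assert expected_uptake(m2, (3, 30), t, "s") <= expected_uptake(m1, (3, 30), t, "s") + 1e-12

    def test_errors(self):
        m = make_model("KRLIGKRY", [100.0] * 8)
        with pytest.raises(KeyError):
            expected_uptake(m, (1, 8), 1.0, "nope")
        with pytest.raises(ValueError):
            expected_uptake(m, (1, 8), -1.0, "s")


class TestSimulateUptake:
    def test_replicate_mean_converges_to_expectation(self):
        m = make_model("KRLIGKRYAACDEF", [300.0] * 14)
        noise = NoiseModel(uptake_sd=0.3, n_replicates=10_000)
        df = simulate_uptake(m, [(1, 14)], [5.0], noise, "s", seed=12)
        mu = expected_uptake(m, (1, 14), 5.0, "s")
        se = 0.3 / np.sqrt(10_000)
        assert abs(df["uptake"].mean() - mu) < 3 * se

    def test_noise_floor_at_zero(self):
        m = make_model("KRLIGKRY", [np.inf] * 8)
        df = simulate_uptake(m, [(1, 8)], [1.0], NoiseModel(0.5, 200), "s", seed=3)
        assert (df["uptake"] >= 0).all()

    def test_table_shape_and_max_uptake(self):
        m = make_model("KRLPIGKARY", [100.0] * 10)
        df = simulate_uptake(m, [(1, 10), (3, 8)], [1.0, 10.0], NoiseModel(0.05, 3), "s", seed=0)
        assert len(df) == 2 * 2 * 3
        row = df[(df["start"] == 1)].iloc[0]
        assert row["max_uptake"] == 8  # 10 residues - N-term - prolines at 4 (pos>1)
        assert row["sequence"] == "KRLPIGKARY"

    def test_seed_determinism(self):
        m = make_model("KRLIGKRY", [100.0] * 8)
        a = simulate_uptake(m, [(1, 8)], [1.0], NoiseModel(0.1, 3), "s", seed=42)
        b = simulate_uptake(m, [(1, 8)], [1.0], NoiseModel(0.1, 3), "s", seed=42)
        assert a.equals(b)
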