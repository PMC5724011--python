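import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hdxdiff.scenario import demo_scenario_config, make_two_state_scenario


@pytest.fixture(scope="session")
def demo_scenario():
    """One shared demo dataset (two allotypes x three states, seed 1)."""
    return make_two_state_scenario(demo_scenario_config(seed=1))


@pytest.fixture(scope="session")
def demo_diff_maps(demo_scenario):
    """Consolidated receptive-vs-loaded residue maps for every protein."""
    from hdxdiff.consolidate import build_residue_map
    from hdxdiff.pipeline import table_stats
    from hdxdiff.uptake import differential_uptake

    maps = {}
    for pid, table in demo_scenario.tables.items():
        stats = table_stats(table, pid)
        for pert in ("receptive", "rescued"):
            diffs = {}
            for pep, by_state in stats.items():
                sub = table.df[(table.df["protein"] == pid)
                               & (table.df["start"] == pep[0])
                               & (table.df["end"] == pep[1])]
                maxu = float(sub["max_uptake"].iloc[0])
                diffs[pep] = {
                    t: differential_uptake(by_state["loaded"][t], by_state[pert][t], maxu, time=t)
                    for t in by_state["loaded"]
                }
            length = len(demo_scenario.models[pid].sequence)
            maps[(pid, pert)] = build_residue_map(diffs, list(diffs), length, pid)
    return maps
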