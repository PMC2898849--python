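import numpy as np
import pytest

from plumeepi import synthcape, tracker


@pytest.fixture(scope="session")
def aquifer_cfg():
    return synthcape.AquiferScenarioConfig()


@pytest.fixture(scope="session")
def aquifer_model(aquifer_cfg):
    return synthcape.generate_aquifer(aquifer_cfg)


@pytest.fixture(scope="session")
def scenario_runs(aquifer_model, aquifer_cfg):
    """Flow + tracking for the low and high pumping scenarios (shared)."""
    out = {}
    for scen in ("low", "high"):
        periods, fields, tracks, sched = synthcape.run_scenario(
            aquifer_model, aquifer_cfg, scen, n_particles_per_cell=9, seed=1
        )
        out[scen] = {
            "periods": periods,
            "fields": fields,
            "tracks": tracks,
            "schedule": sched,
            "planar_map": tracker.planar_impact_map(tracks, aquifer_model.grid),
        }
    return out


@pytest.fixture(scope="session")
def synthetic_cohort(scenario_runs, aquifer_model):
    """One synthetic cohort generated under the high-scenario schedule."""
    sched = scenario_runs["high"]["schedule"]
    pmap = scenario_runs["high"]["planar_map"]
    cfg = synthcape.CohortConfig(seed=11, n_cases=300, n_controls=400)
    subjects, residences, systems, truth = synthcape.generate_cohort(
        cfg, sched, aquifer_model.grid, pmap
    )
    return {
        "cfg": cfg, "subjects": subjects, "residences": residences,
        "systems": systems, "truth": truth, "schedule": sched, "planar_map": pmap,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
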