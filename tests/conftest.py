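import pytest
from hypothesis import settings

import islandrad as ir

settings.register_profile("deterministic", derandomize=True,
                          database=None, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def two_region_scene():
    geo, strata = ir.build_geography(["T", "G"])
    return geo, strata


@pytest.fixture(scope="session")
def three_region_scene():
    geo, strata = ir.build_geography(["T", "G", "C"])
    return geo, strata


@pytest.fixture(scope="session")
def recovery_scene():
    """Scaled-down study scene: five regions, two with emergence ages."""
    geo, strata = ir.build_geography(
        ["T", "G", "C", "P", "H"], {"P": 1.7, "H": 1.1}
    )
    return geo, strata


@pytest.fixture(scope="session")
def three_tip_tree():
    return ir.DatedTree.from_newick("((a:0.6,b:0.6):0.9,c:1.5);")


@pytest.fixture(scope="session")
def four_tip_tree():
    return ir.DatedTree.from_newick("((a:0.6,b:0.6):0.9,(c:1.0,d:1.0):0.5);")


@pytest.fixture(scope="session")
def fifty_tip_radiation():
    """One canonical study-scale simulation reused across tests."""
    return ir.simulate_radiation(ir.study_sim_config(seed=20230223))
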