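import numpy as np
import pytest

import topocoil as tc


@pytest.fixture
def closed_drift_config():
    """3-segment closed lattice, drift only (the CTMC-oracle system)."""
    lat = tc.LatticeConfig(
        n_segments=3,
        initial_turn_units=0,
        boundary_left="barrier",
        boundary_right="barrier",
        k_drift=2.0,
    )
    return tc.SimulationConfig(lattice=lat)


@pytest.fixture
def loop_only_config():
    """Isolated barrier pair (two-state loop/unloop CTMC)."""
    lat = tc.LatticeConfig(
        n_segments=5,
        initial_turn_units=54,
        boundary_left="barrier",
        boundary_right="barrier",
        k_drift=0.0,
    )
    return tc.SimulationConfig(
        lattice=lat,
        barriers=[tc.BarrierSpec(site_a=0, site_b=4, initially_looped=False)],
    )


@pytest.fixture
def mini_gene_config():
    """12-segment lattice with a 6-segment gene and both topoisomerases:
    the smallest system exercising every reaction channel."""
    lat = tc.LatticeConfig(
        n_segments=12, diffusion_coefficient=0.02, boundary_target_units=53
    )
    gene = tc.GeneSpec(
        name="mini", strand="forward", tss_segment=3, end_segment=8, k_max=0.1
    )
    topos = [
        tc.TopoSpec(enzyme="topo_i"),
        tc.TopoSpec(enzyme="gyrase", k_unbind=0.5),
    ]
    return tc.SimulationConfig(lattice=lat, genes=[gene], topos=topos)


@pytest.fixture
def default_mech():
    return tc.MechanicsParams()


def make_state(config):
    return tc.build_state(config)
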