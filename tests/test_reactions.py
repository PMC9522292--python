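"""Channel-level contracts: firing conditions, effects and conservation."""

import numpy as np
import pytest

import topocoil as tc
from topocoil import reactions
from topocoil.state import BARRIER, FREE, GYRASE, RNAP, TOPO_I


def channels_by_kind(state, kind):
    chans = reactions.build_static_channels(state) + reactions.build_rnap_channels(state)
    return [c for c in chans if c.kind == kind]


def active(chans, state):
    return [c for c in chans if c.propensity(state) > 0]


class TestDrift:
    def test_gradient_rule_enumeration(self, closed_drift_config):
        st = tc.build_state(closed_drift_config)
        st.turn[:] = [54, 56, 54]
        act = active(channels_by_kind(st, "DRIFT"), st)
        assert len(act) == 2
        assert {c.key for c in act} == {("drift", 1, -1), ("drift", 1, +1)}
        for c in act:
            assert c.propensity(st) == closed_drift_config.lattice.k_drift

    def test_single_unit_move(self, closed_drift_config):
        st = tc.build_state(closed_drift_config)
        st.turn[:] = [54, 56, 54]
        chan = next(
            c for c in channels_by_kind(st, "DRIFT") if c.key == ("drift", 1, -1)
        )
        chan.apply(st, 0.0)
        assert list(st.turn) == [55, 55, 54]

    def test_flat_profile_is_absorbing(self, closed_drift_config):
        st = tc.build_state(closed_drift_config)
        st.turn[:] = [54, 54, 54]
        assert active(channels_by_kind(st, "DRIFT"), st) == []

    def test_occupied_destination_blocks(self, closed_drift_config):
        st = tc.build_state(closed_drift_config)
        st.turn[:] = [54, 56, 54]
        st.occupancy[0] = TOPO_I
        act = active(channels_by_kind(st, "DRIFT"), st)
        assert {c.key for c in act} == {("drift", 1, +1)}


class TestRandomWalk:
    def test_flat_profile_still_hops(self):
        lat = tc.LatticeConfig(
            n_segments=3,
            initial_turn_units=54,
            boundary_left="barrier",
            boundary_right="barrier",
            k_drift=2.0,
            diffusion_mode="explicit_random_walk",
        )
        st = tc.build_state(tc.SimulationConfig(lattice=lat))
        act = active(channels_by_kind(st, "RANDOM_WALK"), st)
        assert len(act) == 4  # both directions of both pairs

    def test_boundary_segment_hops_inward_only(self):
        lat = tc.LatticeConfig(
            n_segments=3,
            initial_turn_units=0,
            boundary_left="barrier",
            boundary_right="barrier",
            k_drift=2.0,
            diffusion_mode="explicit_random_walk",
        )
        st = tc.build_state(tc.SimulationConfig(lattice=lat))
        st.turn[0] = 1
        act = active(channels_by_kind(st, "RANDOM_WALK"), st)
        assert {c.key for c in act} == {("rw", 0, +1)}


class TestTopoChannels:
    def test_bind_rate_on_free_segment(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        bind = [
            c
            for c in channels_by_kind(st, "TOPO_BIND")
            if c.key[1] == "gyrase" and c.key[2] == 0
        ][0]
        assert bind.propensity(st) == pytest.approx(0.0018)

    def test_topo_i_step_adds_one_unit(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.occupancy[5] = TOPO_I
        st.turn[5] = 54
        cat = [
            c for c in channels_by_kind(st, "TOPO_CAT") if c.key == ("cat", "topo_i", 5)
        ][0]
        assert cat.propensity(st) > 0
        cat.apply(st, 0.0)
        assert st.turn[5] == 55

    def test_gyrase_step_removes_two_units(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.occupancy[5] = GYRASE
        st.turn[5] = 60
        cat = [
            c for c in channels_by_kind(st, "TOPO_CAT") if c.key == ("cat", "gyrase", 5)
        ][0]
        assert cat.propensity(st) > 0
        cat.apply(st, 0.0)
        assert st.turn[5] == 58

    def test_overshoot_past_relaxation_suppressed(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.occupancy[5] = GYRASE
        st.turn[5] = 58  # -2 would cross lk0 = 57
        cat = [
            c for c in channels_by_kind(st, "TOPO_CAT") if c.key == ("cat", "gyrase", 5)
        ][0]
        assert cat.propensity(st) == 0.0


class TestInitiation:
    def test_plateau_propensity_at_critical_sigma(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.turn[3] = 53  # sigma ~ -0.07 < sigma*
        chan = [c for c in channels_by_kind(st, "INIT")][0]
        assert chan.propensity(st) == pytest.approx(0.1)  # k_max

    def test_promoter_occlusion(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.occupancy[3] = RNAP
        chan = [c for c in channels_by_kind(st, "INIT")][0]
        assert chan.propensity(st) == 0.0

    def test_initiation_pushes_tss_units_downstream(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.turn[3], st.turn[4] = 54, 54
        chan = [c for c in channels_by_kind(st, "INIT")][0]
        chan.apply(st, 1.0)
        assert st.turn[3] == 0
        assert st.turn[4] == 108
        assert st.occupancy[3] == RNAP
        assert len(st.rnaps) == 1
        assert st.counters["initiations"][0] == 1


class TestTranslocation:
    def _with_rnap(self, cfg, seg=5):
        st = tc.build_state(cfg)
        init = [c for c in reactions.build_static_channels(st) if c.kind == "INIT"][0]
        init.apply(st, 0.0)
        rid = next(iter(st.rnaps))
        r = st.rnaps[rid]
        return st, rid

    def test_push_rule_conserves_total(self, mini_gene_config):
        st, rid = self._with_rnap(mini_gene_config)
        total = st.total_turn()
        chan = reactions.translocation_channel(st, rid)
        assert chan.propensity(st) == pytest.approx(1.0)  # 60 bp/s over 60-bp segments
        chan.apply(st, 1.0)
        assert st.total_turn() == total
        assert st.rnaps[rid].segment == 4
        assert st.turn[4] == 0  # melted under the RNAP

    def test_exclusion_needs_two_free_segments(self, mini_gene_config):
        st, rid = self._with_rnap(mini_gene_config)
        st.occupancy[5] = RNAP  # two segments ahead of the RNAP at 3
        chan = reactions.translocation_channel(st, rid)
        assert chan.propensity(st) == 0.0
        st.occupancy[5] = FREE
        st.occupancy[4] = TOPO_I
        assert chan.propensity(st) == 0.0

    def test_stalled_rnap_does_not_move(self, mini_gene_config):
        st, rid = self._with_rnap(mini_gene_config)
        st.rnaps[rid].mode = "stalled"
        chan = reactions.translocation_channel(st, rid)
        assert chan.propensity(st) == 0.0

    def test_termination_credits_mrna(self, mini_gene_config):
        st, rid = self._with_rnap(mini_gene_config)
        gene = mini_gene_config.genes[0]
        # walk the RNAP to the final segment
        for _ in range(gene.n_segments - 1):
            reactions.translocation_channel(st, rid).apply(st, 1.0)
        assert st.rnaps[rid].segment == gene.end_segment
        reactions.translocation_channel(st, rid).apply(st, 2.0)
        assert rid not in st.rnaps
        assert st.mrna_count[0] == 1
        assert st.occupancy[gene.end_segment] == FREE


class TestCounterrotation:
    def test_transfer_down_gradient_across_rnap(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        init = [c for c in reactions.build_static_channels(st) if c.kind == "INIT"][0]
        init.apply(st, 0.0)
        rid = next(iter(st.rnaps))
        st.turn[2], st.turn[4] = 50, 60
        chan = reactions.counterrotation_channel(st, rid)
        assert chan.propensity(st) == pytest.approx(0.2)  # k_rot
        chan.apply(st, 0.0)
        assert st.turn[2] == 51 and st.turn[4] == 59

    def test_equal_flanks_inactive(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        init = [c for c in reactions.build_static_channels(st) if c.kind == "INIT"][0]
        init.apply(st, 0.0)
        rid = next(iter(st.rnaps))
        st.turn[2] = st.turn[4]
        chan = reactions.counterrotation_channel(st, rid)
        assert chan.propensity(st) == 0.0


class TestDecayAndLoops:
    def test_first_order_decay_propensity(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.mrna_count[0] = 10
        chan = [c for c in channels_by_kind(st, "MRNA_DECAY")][0]
        assert chan.propensity(st) == pytest.approx(10 * 0.003)
        st.mrna_count[0] = 0
        assert chan.propensity(st) == 0.0

    def test_loop_channels_toggle_sites_atomically(self, loop_only_config):
        st = tc.build_state(loop_only_config)
        loop = [c for c in channels_by_kind(st, "LOOP")][0]
        unloop = [c for c in channels_by_kind(st, "UNLOOP")][0]
        assert loop.propensity(st) == pytest.approx(0.017)
        assert unloop.propensity(st) == 0.0
        loop.apply(st, 0.0)
        assert st.occupancy[0] == BARRIER and st.occupancy[4] == BARRIER
        assert unloop.propensity(st) == pytest.approx(0.003)
        unloop.apply(st, 1.0)
        assert st.occupancy[0] == FREE and st.occupancy[4] == FREE

    def test_occupied_site_defers_looping(self, loop_only_config):
        st = tc.build_state(loop_only_config)
        st.occupancy[0] = TOPO_I
        loop = [c for c in channels_by_kind(st, "LOOP")][0]
        assert loop.propensity(st) == 0.0

    def test_permanent_barrier_emits_no_channels(self):
        lat = tc.LatticeConfig(
            n_segments=5,
            boundary_left="barrier",
            boundary_right="barrier",
            k_drift=0.0,
        )
        cfg = tc.SimulationConfig(
            lattice=lat, barriers=[tc.BarrierSpec(site_a=0, site_b=4, permanent=True)]
        )
        st = tc.build_state(cfg)
        assert channels_by_kind(st, "LOOP") == []
        assert channels_by_kind(st, "UNLOOP") == []


class TestBoundary:
    def test_reset_semantics(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.turn[0] = 70
        chan = [
            c for c in channels_by_kind(st, "BOUNDARY_RELAX") if c.key == ("boundary", 0)
        ][0]
        assert chan.propensity(st) == pytest.approx(50.0)
        chan.apply(st, 0.0)
        assert st.turn[0] == 53

    def test_reset_is_idempotent(self, mini_gene_config):
        st = tc.build_state(mini_gene_config)
        st.turn[0] = 53
        chan = [
            c for c in channels_by_kind(st, "BOUNDARY_RELAX") if c.key == ("boundary", 0)
        ][0]
        chan.apply(st, 0.0)
        assert st.turn[0] == 53

    def test_barrier_mode_end_has_no_channel(self, closed_drift_config):
        st = tc.build_state(closed_drift_config)
        assert channels_by_kind(st, "BOUNDARY_RELAX") == []
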