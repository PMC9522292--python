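import numpy as np
import pytest

import topocoil as tc
from topocoil import scenarios
from topocoil.config_io import config_hash, config_to_dict


class TestSingleGene:
    def test_geometry(self):
        sc = scenarios.single_gene_scenario(0.1)
        lat = sc.config.lattice
        assert lat.n_segments == 150  # 9 kb at 60 bp
        g = sc.config.genes[0]
        assert g.n_segments == 85  # 5.1-kb unit
        assert g.report_window_bp == 3075
        # centred: equal margins up to rounding
        left = min(g.span)
        right = lat.n_segments - 1 - max(g.span)
        assert abs(left - right) <= 1

    def test_baseline_parameters(self):
        sc = scenarios.single_gene_scenario(0.1)
        assert sc.config.lattice.diffusion_coefficient == pytest.approx(0.02)
        topoI = [t for t in sc.config.topos if t.enzyme == "topo_i"][0]
        gy = [t for t in sc.config.topos if t.enzyme == "gyrase"][0]
        assert topoI.k_unbind == 1.0
        assert topoI.k_bind == gy.k_bind == pytest.approx(0.0018)
        assert sc.config.lattice.boundary_target_units == 53  # sigma_eq = -0.067
        assert sc.window == (750.0, 1000.0)

    def test_k_max_grid_one_config_per_value(self):
        cfgs = [scenarios.single_gene_scenario(km) for km in scenarios.K_MAX_GRID]
        assert len({c.config.genes[0].k_max for c in cfgs}) == len(scenarios.K_MAX_GRID)

    def test_out_of_range_k_max_rejected(self):
        with pytest.raises(tc.ConfigurationError):
            scenarios.single_gene_scenario(0.5)

    def test_geometry_not_fitting_rejected(self):
        with pytest.raises(tc.ConfigurationError):
            scenarios.single_gene_scenario(0.1, unit_bp=9000, domain_bp=9000)


class TestPromoterOff:
    def test_presets(self):
        strong = scenarios.promoter_off_scenario("strong")
        weak = scenarios.promoter_off_scenario("weak")
        assert strong.config.genes[0].k_max == pytest.approx(0.1)
        assert weak.config.genes[0].k_max == pytest.approx(0.001)
        assert strong.config.genes[0].promoter_block_after_bp == 2700

    def test_block_trigger_converts_promoter_to_barrier(self):
        from topocoil.fastsim import run_fast
        from topocoil.state import BARRIER

        sc = scenarios.promoter_off_scenario("strong", t_end=600.0)
        tr = run_fast(sc.config, tc.RunControl(t_end=600.0, seed=0), seed=4)
        blocks = tr.events_of("promoter_block")
        total_bp = 60 * len(tr.events_of("window")) if False else None
        if len(blocks):
            t_block = blocks["t"][0]
            ini = tr.events_of("initiation")
            assert (ini["t"] > t_block).sum() == 0  # promoter silent afterwards


class TestLoopingDomain:
    def test_barrier_positions_from_bp(self):
        sc = scenarios.looping_domain_scenario(0.1, "dynamic")
        assert sc.config.lattice.n_segments == 70  # 4.2 kb
        b = sc.config.barriers[0]
        assert (b.site_a, b.site_b) == (1, 69)  # 0.06 kb and 4.14 kb
        assert b.k_loop == pytest.approx(0.017)
        assert b.k_unloop == pytest.approx(0.003)

    def test_gene_centred_40_segments(self):
        sc = scenarios.looping_domain_scenario(0.005, "open")
        g = sc.config.genes[0]
        assert g.n_segments == 40
        assert sc.config.barriers == ()

    def test_permanent_mode(self):
        sc = scenarios.looping_domain_scenario(0.1, "permanent")
        assert sc.config.barriers[0].permanent

    def test_fast_mode_shortens_looped_dwell(self):
        dyn = scenarios.looping_domain_scenario(0.1, "dynamic")
        fast = scenarios.looping_domain_scenario(0.1, "dynamic_fast")
        assert 1 / fast.config.barriers[0].k_unloop < 1 / dyn.config.barriers[0].k_unloop


class TestTwoGene:
    def test_layout_and_gap(self):
        sc = scenarios.two_gene_scenario("convergent")
        a, b = sc.config.genes
        assert sc.config.lattice.n_segments == 160  # 9.6 kb
        assert a.n_segments == b.n_segments == 20  # 1.2-kb genes
        gap_lo, gap_hi = sc.meta["intergenic_segments"]
        assert gap_hi - gap_lo + 1 == 20  # 1.2-kb gap

    def test_divergent_promoters_face_the_gap(self):
        sc = scenarios.two_gene_scenario("divergent")
        a, b = sc.config.genes
        gap_lo, gap_hi = sc.meta["intergenic_segments"]
        assert a.tss_segment == gap_lo - 1
        assert b.tss_segment == gap_hi + 1
        assert a.direction == -1 and b.direction == +1

    def test_convergent_ends_face_the_gap(self):
        sc = scenarios.two_gene_scenario("convergent")
        a, b = sc.config.genes
        gap_lo, gap_hi = sc.meta["intergenic_segments"]
        assert a.end_segment == gap_lo - 1
        assert b.end_segment == gap_hi + 1

    def test_topo_boost_multipliers(self):
        base = scenarios.two_gene_scenario("convergent")
        boost = scenarios.two_gene_scenario("convergent", topo_boost=True)
        for tb, t0 in zip(boost.config.topos, base.config.topos):
            assert tb.k_bind == pytest.approx(50 * t0.k_bind)
            assert tb.kcat_max == pytest.approx(1000 * t0.kcat_max)

    def test_sweep_grid_values(self):
        assert scenarios.TWO_GENE_K_MAX_GRID == (0.001, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)

    def test_orientation_symmetry_of_marginals(self):
        """Convergent/divergent constructs are mirror-symmetric: with equal
        parameters the two genes' realized activities agree statistically."""
        from topocoil.fastsim import run_fast

        sc = scenarios.two_gene_scenario("convergent", t_end=800.0)
        counts = np.zeros(2)
        for i in range(12):
            tr = run_fast(sc.config, tc.RunControl(t_end=800.0, seed=0, regions=sc.run.regions), seed=600 + i)
            counts += tr.final_counters["initiations"]
        # equal promoters, mirrored geometry: initiation totals within noise
        assert abs(counts[0] - counts[1]) < 4 * np.sqrt(counts.sum())


class TestPhaseSweep:
    def test_manifest_is_cross_product(self):
        cells = scenarios.phase_sweep(
            d_grid=(0.02, 0.2), unbind_grid=(0.1, 1.0, 10.0), k_max_grid=(0.01, 0.1)
        )
        assert len(cells) == 2 * 3 * 2
        assert len({c["id"] for c in cells}) == len(cells)

    def test_default_grids(self):
        assert scenarios.D_GRID == (0.002, 0.006, 0.02, 0.06, 0.2, 0.6, 2.0)
        assert scenarios.TOPOI_UNBIND_GRID[0] == 0.001
        assert scenarios.TOPOI_UNBIND_GRID[-1] == 100.0

    def test_replicate_allocation_favours_weak_promoters(self):
        assert scenarios.replicates_for_k_max(0.001) > scenarios.replicates_for_k_max(0.1)

    def test_cell_hash_changes_with_parameters(self):
        a = scenarios.phase_sweep(d_grid=(0.02,), unbind_grid=(1.0,), k_max_grid=(0.1,))
        b = scenarios.phase_sweep(d_grid=(0.06,), unbind_grid=(1.0,), k_max_grid=(0.1,))
        assert a[0]["id"] != b[0]["id"]

    def test_empty_grid_rejected(self):
        with pytest.raises(tc.ConfigurationError):
            scenarios.phase_sweep(d_grid=())


class TestParameterDerivation:
    def test_gyrase_kinetics_from_tracking_numbers(self):
        out = scenarios.derive_topo_binding_kinetics()
        assert out["k_unbind"] == pytest.approx(0.5)
        assert out["k_bind"] == pytest.approx(0.00225)
        assert out["k_bind_corrected"] == pytest.approx(0.0018)


class TestRoundTrip:
    @pytest.mark.parametrize(
        "sc",
        [
            scenarios.single_gene_scenario(0.1),
            scenarios.looping_domain_scenario(0.005, "dynamic"),
            scenarios.two_gene_scenario("codirectional", topo_boost=True),
        ],
        ids=["single", "loop", "two-gene"],
    )
    def test_builder_configs_serialize_and_validate(self, sc, tmp_path):
        from topocoil.config_io import dump_config, load_config

        p = tmp_path / "cfg.yaml"
        dump_config(sc.config, p, run=sc.run)
        cfg2, run2 = load_config(p)
        assert config_hash(cfg2) == config_hash(sc.config)
        tc.build_state(cfg2)  # passes build validation
        assert run2.t_end == sc.run.t_end
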