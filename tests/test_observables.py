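import numpy as np
import pytest

import topocoil as tc
from topocoil import observables as obs
from topocoil.fastsim import run_fast


class TestFano:
    def test_no_variance(self):
        assert obs.fano_factor([4, 4, 4, 4]) == 0.0

    def test_hand_computed(self):
        assert obs.fano_factor([0, 2, 4]) == pytest.approx(2.0)

    def test_poisson_law_is_unity(self):
        rng = np.random.default_rng(5)
        draws = rng.poisson(6.0, size=1000)
        assert obs.fano_factor(draws) == pytest.approx(1.0, abs=0.15)

    def test_zero_mean_flagged(self):
        assert obs.fano_factor([0, 0, 0]) is None


class TestPiecewiseFit:
    def test_noiseless_hinge_recovered_exactly(self):
        x = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.08, 0.12, 0.2])
        y = np.where(x < 0.05, 100 * x + 10, 15.0)
        fit = obs.piecewise_linear_fit(x, y)
        assert fit.slope == pytest.approx(100, rel=1e-6)
        assert fit.intercept == pytest.approx(10, rel=1e-6)
        assert fit.breakpoint == pytest.approx(0.05, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.fitted

    def test_any_interior_breakpoint(self):
        for xstar in (0.03, 0.07, 0.11):
            x = np.linspace(0.005, 0.2, 25)
            y = 50 * np.minimum(x, xstar) + 3
            fit = obs.piecewise_linear_fit(x, y)
            assert fit.slope == pytest.approx(50, rel=1e-6)
            assert fit.breakpoint == pytest.approx(xstar, abs=2e-3)

    def test_flat_data_gives_zero_slope(self):
        x = np.linspace(0.01, 0.2, 10)
        y = np.full_like(x, 7.0)
        fit = obs.piecewise_linear_fit(x, y)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)

    def test_low_rate_condition_not_fitted(self):
        x = np.array([0.01, 0.02, 0.03, 0.04])
        fit = obs.piecewise_linear_fit(x, x * 10)
        assert not fit.fitted

    def test_noisy_recovery_within_2se(self):
        """Monte-Carlo parameter recovery on noisy hinge data."""
        rng = np.random.default_rng(11)
        true_k, xstar, b, noise = 120.0, 0.06, 8.0, 1.0
        slopes = []
        x = np.linspace(0.01, 0.2, 30)
        for _ in range(100):
            y = true_k * np.minimum(x, xstar) + b + rng.normal(0, noise, x.size)
            slopes.append(obs.piecewise_linear_fit(x, y).slope)
        se = np.std(slopes, ddof=1) / 10
        assert abs(np.mean(slopes) - true_k) < 2 * se + 1e-9

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            obs.piecewise_linear_fit([0.1] * 6, [1, 2, 3, 4, 5, 6])


class TestMSE:
    def test_identical_vectors(self):
        assert obs.mse_vs_reference([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        assert obs.mse_vs_reference([1, 2], [2, 4]) == pytest.approx(2.5)

    def test_pair_permutation_invariance(self):
        p, r = [1.0, 5.0, 9.0], [2.0, 4.0, 10.0]
        assert obs.mse_vs_reference(p, r) == obs.mse_vs_reference(p[::-1], r[::-1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            obs.mse_vs_reference([1], [1, 2])


class TestRatesFromTrajectories:
    @pytest.fixture(scope="class")
    def ensemble(self, request):
        lat = tc.LatticeConfig(
            n_segments=30, diffusion_coefficient=0.02, boundary_target_units=53
        )
        gene = tc.GeneSpec(
            name="g", strand="forward", tss_segment=8, end_segment=21, k_max=0.1
        )
        cfg = tc.SimulationConfig(
            lattice=lat,
            genes=[gene],
            topos=[tc.TopoSpec(enzyme="topo_i", kcat_max=100.0), tc.TopoSpec(enzyme="gyrase", k_unbind=0.5, kcat_max=100.0)],
        )
        run = tc.RunControl(t_end=400.0, seed=0, record_stall_episodes=True)
        return [run_fast(cfg, run, seed=700 + i) for i in range(6)]

    def test_initiation_rate_is_event_count_over_time(self, ensemble):
        r = obs.empirical_initiation_rate(ensemble, (100, 400))
        n = sum(
            int(((tr.events_of("initiation")["t"] >= 100) & (tr.events_of("initiation")["t"] <= 400)).sum())
            for tr in ensemble
        )
        assert r == pytest.approx(n / (300 * len(ensemble)))
        assert r <= 0.1  # occlusion can only reduce the realized rate

    def test_elongation_bounded_by_k_elong(self, ensemble):
        rates = obs.transcript_rates(ensemble, (0, 400))
        assert rates.size > 0
        assert (rates <= 60.0 + 1e-9).all()

    def test_no_transcripts_is_flagged_not_zero(self, ensemble):
        assert obs.empirical_elongation_rate(ensemble, (0.0, 1.0)) is None

    def test_spacing_and_load_rules(self, ensemble):
        spacing, load = obs.adjacent_spacing_and_load(ensemble, (100, 400))
        assert load is None or load >= 1.0  # frames without RNAPs excluded
        if spacing is not None:
            assert spacing >= 60.0  # exclusion: adjacent RNAPs at least one segment apart

    def test_stall_durations_are_positive(self, ensemble):
        d = obs.stall_durations(ensemble)
        assert (d > 0).all()

    def test_empty_window_rejected(self, ensemble):
        with pytest.raises(ValueError):
            obs.empirical_initiation_rate(ensemble, (200, 200))


class TestCorrelation:
    def _toy_traj(self, positions_a, positions_b, gene=0):
        """Two RNAPs walking with prescribed positions."""
        frames = []
        for pa, pb in zip(positions_a, positions_b):
            frames.append(np.array([[0, gene, pa, 0], [1, gene, pb, 0]], dtype=np.int64))
        n = len(frames)
        lat = tc.LatticeConfig(n_segments=50, diffusion_coefficient=0.02)
        cfg = tc.SimulationConfig(
            lattice=lat,
            genes=[tc.GeneSpec(name="g", strand="forward", tss_segment=1, end_segment=48, k_max=0.1)],
        )
        return tc.Trajectory(
            times=np.arange(n, dtype=float),
            mrna=np.zeros((n, 1), dtype=int),
            rnap_frames=frames,
            loop_state=np.zeros((n, 0), dtype=bool),
            events=np.empty(0, dtype=tc.Trajectory.EVENT_DTYPE),
            metadata={"config": cfg, "seed": 0, "record_dt": 1.0, "t_end": float(n - 1)},
        )

    def test_identical_trajectories_give_unity(self):
        rng = np.random.default_rng(3)
        steps = rng.integers(0, 2, 40)
        pa = 5 + np.cumsum(steps)
        pb = pa + 3
        tr = self._toy_traj(pa, pb)
        r = obs.adjacent_rnap_correlation([tr], (0, 40))
        assert r == pytest.approx(1.0)

    def test_independent_increments_give_near_zero(self):
        rng = np.random.default_rng(4)
        pa = 5 + np.cumsum(rng.integers(0, 2, 400))
        pb = 25 + np.cumsum(rng.integers(0, 2, 400))
        tr = self._toy_traj(pa, pb)
        r = obs.adjacent_rnap_correlation([tr], (0, 400))
        assert abs(r) < 0.15

    def test_too_few_pairs_flagged(self):
        tr = self._toy_traj([5, 6], [10, 10])
        assert obs.adjacent_rnap_correlation([tr], (0, 2)) is None

    def test_normalization_anchors(self):
        assert obs.normalize_correlation(0.5, 0.1, 0.9) == pytest.approx(0.5)
        assert obs.normalize_correlation(0.9, 0.1, 0.9) == pytest.approx(1.0)


class TestLoopConditioned:
    def test_permanent_loop_assigns_all_exposure_closed(self):
        sc = __import__("topocoil.scenarios", fromlist=["looping_domain_scenario"])
        scen = sc.looping_domain_scenario(0.1, "permanent", t_end=100.0)
        tr = run_fast(scen.config, tc.RunControl(t_end=100.0, seed=0), seed=3)
        out = obs.loop_state_conditioned_rates([tr])
        assert out["open_exposure_s"] == 0.0
        assert out["closed_exposure_s"] == pytest.approx(100.0)

    def test_exposure_partition_sums_to_window(self):
        sc = __import__("topocoil.scenarios", fromlist=["looping_domain_scenario"])
        scen = sc.looping_domain_scenario(0.1, "dynamic", t_end=300.0)
        tr = run_fast(scen.config, tc.RunControl(t_end=300.0, seed=0), seed=9)
        out = obs.loop_state_conditioned_rates([tr])
        assert out["open_exposure_s"] + out["closed_exposure_s"] == pytest.approx(300.0)


class TestKymograph:
    def test_shape_and_gene_columns(self, mini_gene_config):
        run = tc.RunControl(t_end=50.0, seed=2, record_turn=True)
        tr = run_fast(mini_gene_config, run, seed=21)
        sigma, overlay = obs.kymograph(tr)
        assert sigma.shape == (51, 12)
        assert len(overlay) == 51
        for arr in overlay:
            for row in arr:
                assert 3 <= row[1] <= 8  # within the configured gene span

    def test_requires_turn_recording(self, mini_gene_config):
        tr = run_fast(mini_gene_config, tc.RunControl(t_end=5.0, seed=2), seed=21)
        with pytest.raises(ValueError):
            obs.kymograph(tr)


class TestHistograms:
    def test_stalled_partition_obeys_stall_rules(self, mini_gene_config):
        run = tc.RunControl(t_end=150.0, seed=4, record_turn=True)
        trajs = [run_fast(mini_gene_config, run, seed=900 + i) for i in range(3)]
        out = obs.state_conditioned_histograms(trajs, (0, 150))
        df = out["samples"]
        mech = mini_gene_config.mechanics
        stalled = df[df["stalled"]]
        if len(stalled):
            ok = (
                (stalled["torque"] >= mech.stall_torque - 1e-9)
                | (stalled["sigma_up"] <= -mech.sigma_stall + 1e-9)
                | (stalled["sigma_down"] >= mech.sigma_stall - 1e-9)
            )
            # flank reconstruction from frames ignores bound topoisomerases,
            # so allow a small fraction of borderline misclassifications
            assert ok.mean() > 0.9

    def test_no_rnaps_is_empty_not_error(self):
        lat = tc.LatticeConfig(n_segments=12, diffusion_coefficient=0.02)
        gene = tc.GeneSpec(
            name="silent", strand="forward", tss_segment=3, end_segment=8,
            k_max=0.0, k_min=0.0,
        )
        cfg = tc.SimulationConfig(lattice=lat, genes=[gene])
        tr = run_fast(cfg, tc.RunControl(t_end=5.0, seed=1, record_turn=True), seed=31)
        out = obs.state_conditioned_histograms([tr], (0, 5))
        assert len(out["samples"]) == 0


class TestSweepTable:
    def _cells(self, with_bad_cell=True):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(2)
        x_grid = [0.002, 0.01, 0.03, 0.06, 0.1]
        for D, ku, k, b, xstar in [(0.02, 1.0, 150.0, 8.0, 0.04), (0.2, 10.0, 60.0, 12.0, 0.05)]:
            for x in x_grid:
                rows.append(
                    {
                        "D": D,
                        "topoI_unbind": ku,
                        "k_max": x * 2,
                        "empirical_initiation_rate_per_s": x,
                        "mean_elongation_rate_bp_per_s": k * min(x, xstar) + b,
                    }
                )
        if with_bad_cell:  # a capped cell: max initiation below 0.05 -> not fitted
            for x in (0.001, 0.004, 0.01, 0.02):
                rows.append(
                    {
                        "D": 0.02,
                        "topoI_unbind": 0.01,
                        "k_max": x * 2,
                        "empirical_initiation_rate_per_s": x,
                        "mean_elongation_rate_bp_per_s": 10.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_fits_recovered_per_cell(self):
        st = obs.build_sweep_table(self._cells())
        t = st.table.set_index(["D", "topoI_unbind"])
        assert t.loc[(0.02, 1.0), "slope"] == pytest.approx(150.0, rel=1e-6)
        assert t.loc[(0.2, 10.0), "slope"] == pytest.approx(60.0, rel=1e-6)
        assert not t.loc[(0.02, 1.0), "mask"]

    def test_low_initiation_cell_masked_not_fitted(self):
        st = obs.build_sweep_table(self._cells())
        t = st.table.set_index(["D", "topoI_unbind"])
        assert t.loc[(0.02, 0.01), "mask"]
        assert not t.loc[(0.02, 0.01), "fitted"]

    def test_mse_against_reference(self, tmp_path):
        ref = tmp_path / "ref.csv"
        ref.write_text("initiation_rate,elongation_rate\n0.01,9.5\n0.03,12.0\n0.06,14.0\n")
        x, y = obs.load_reference_elongation(ref)
        assert list(x) == [0.01, 0.03, 0.06]
        st = obs.build_sweep_table(self._cells(with_bad_cell=False), reference=(x, y))
        assert np.isfinite(st.table["mse"]).all()
        # the hinge through (150, 8, 0.04) predicts exactly; check one value
        pred = 150 * min(0.01, 0.04) + 8
        assert st.table["mse"].iloc[0] == pytest.approx(
            np.mean([(9.5 - pred) ** 2, (12.0 - (150 * 0.03 + 8)) ** 2, (14.0 - (150 * 0.04 + 8)) ** 2]),
            rel=1e-6,
        )
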