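"""Implausibility, NROY bookkeeping, waves, reuse, sensitivity, persistence."""

import numpy as np
import pandas as pd
import pytest

import hismatch as hm
from hismatch.design import EmptyNROYError


def exact_bank(space, u, biomarkers):
    """A bank whose emulators return the given values with ~zero variance at u."""
    emulators = []
    names = list(biomarkers.keys())
    for nm in names:
        emulators.append(hm.GPEmulator.from_hyperparameters(
            np.atleast_2d(u), [biomarkers[nm]], beta0=0.0,
            beta=np.zeros(len(u)), lengthscales=np.ones(len(u)),
            outputscale=1.0, noise_var=0.0, name=nm,
        ))
    return hm.EmulatorBank(names, emulators)


class TestTargets:
    def test_fractional_sigma_rule(self):
        t = hm.make_targets_from_values(["TAT", "TAT_LV_endo"], [76.4, 31.3], 0.1)
        np.testing.assert_allclose(t.sigma, [7.64, 3.13])

    def test_halving_c_halves_sigma(self):
        hi = hm.make_targets_from_values(["a"], [10.0], 0.10)
        lo = hm.make_targets_from_values(["a"], [10.0], 0.05)
        assert lo.sigma[0] == 0.5 * hi.sigma[0]

    def test_negative_mean_gives_positive_sigma(self):
        t = hm.make_targets_from_values(["a"], [-4.0], 0.1)
        assert t.sigma[0] == pytest.approx(0.4)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hm.make_targets_from_values(["a"], [0.0], 0.1)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            hm.TargetSpec(("a",), [1.0], [0.0])

    def test_literature_targets(self):
        t = hm.LITERATURE_TARGETS
        assert t.mu.tolist() == [76.4, 31.3]
        assert t.sigma.tolist() == [8.2, 11.21]


class TestImplausibility:
    def test_zero_when_prediction_hits_target(self):
        u = np.full(3, 0.5)
        bank = exact_bank(None, u, {"a": 5.0})
        t = hm.TargetSpec(("a",), [5.0], [1.0])
        assert hm.implausibility(bank, t, u[None, :])[0] == pytest.approx(0.0, abs=1e-6)

    def test_literature_example(self):
        """Exact predictions (84.04, 31.3) against 76.4/31.3 with sigma = 10% mu."""
        u = np.full(2, 0.5)
        bank = exact_bank(None, u, {"TAT": 84.04, "TAT_LV_endo": 31.3})
        t = hm.make_targets_from_values(["TAT", "TAT_LV_endo"], [76.4, 31.3], 0.1)
        assert hm.implausibility(bank, t, u[None, :])[0] == pytest.approx(1.0, abs=1e-4)

    def test_vectorized_matches_scalar_loop(self, small_run):
        """The batch implausibility equals a per-point, per-biomarker loop."""
        res = small_run["results"]
        bank, targets = res.waves[-1].bank, res.targets
        X = res.reference_set[:40]
        vec = hm.implausibility(bank, targets, X)
        for i in range(X.shape[0]):
            per_bio = []
            for nm, mu, sg in zip(targets.biomarker_names, targets.mu, targets.sigma):
                m, v = bank[nm].predict(X[i:i + 1])
                per_bio.append(abs(m[0] - mu) / np.sqrt(v[0] + sg**2))
            assert vec[i] == pytest.approx(max(per_bio), abs=1e-10)

    def test_monotone_decreasing_in_sigma(self, small_run):
        res = small_run["results"]
        bank = res.waves[-1].bank
        X = res.reference_set[:25]
        t1 = res.targets
        t2 = hm.TargetSpec(t1.biomarker_names, t1.mu, 2 * t1.sigma)
        i1 = hm.implausibility(bank, t1, X)
        i2 = hm.implausibility(bank, t2, X)
        pos = i1 > 0
        assert np.all(i2[pos] < i1[pos])

    def test_name_mismatch_raises(self):
        bank = exact_bank(None, np.zeros(2), {"a": 1.0})
        t = hm.TargetSpec(("b",), [1.0], [1.0])
        with pytest.raises(KeyError, match="b"):
            hm.implausibility(bank, t, np.zeros((1, 2)))


class TestVQ:
    def test_equal_variances_give_unity(self):
        u = np.linspace(0, 1, 5)[:, None]
        gp = hm.GPEmulator.from_hyperparameters(
            u, np.zeros(5), 0.0, [0.0], [1.0], 1.0, noise_var=0.25)
        bank = hm.EmulatorBank(["a"], [gp])
        # far from data the predictive variance -> sigma_f^2 + sigma_n = 1.25;
        # with sigma^2 set equal to it, VQ = 1 and (max, median) = (1, 1)
        t = hm.TargetSpec(("a",), [0.0], [np.sqrt(1.25)])
        far = np.full((3, 1), 60.0)
        vmax, vmed = hm.vq_stats(bank, t, far)
        assert vmax == pytest.approx(1.0, rel=1e-6)
        assert vmed == pytest.approx(1.0, rel=1e-6)

    def test_hand_max(self):
        u = np.full(2, 0.5)
        bank = exact_bank(None, u, {"a": 0.0, "b": 0.0})
        # far point: var_a = var_b = sigma_f^2 = 1; sigma = (0.5, 1)
        t = hm.TargetSpec(("a", "b"), [0.0, 0.0], [0.5, 1.0])
        far = np.zeros((1, 2)) + 40.0  # far in kernel distance -> var ~ 1
        vq = hm.variance_quotient(bank, t, far)
        assert vq[0] == pytest.approx(4.0, rel=1e-3)  # max(1/0.25, 1/1)

    def test_halving_sigma_quadruples_vq(self, small_run):
        res = small_run["results"]
        t1 = res.targets
        t2 = hm.TargetSpec(t1.biomarker_names, t1.mu, 0.5 * t1.sigma)
        X = res.reference_set[:20]
        v1 = hm.variance_quotient(res.final_bank, t1, X)
        v2 = hm.variance_quotient(res.final_bank, t2, X)
        np.testing.assert_allclose(v2, 4 * v1, rtol=1e-9)

    def test_empty_nroy_gives_nan(self, small_run):
        res = small_run["results"]
        vmax, vmed = hm.vq_stats(res.final_bank, res.targets, np.empty((0, 14)))
        assert np.isnan(vmax) and np.isnan(vmed)


class TestAgreement:
    def test_identical_masks(self):
        m = np.array([True, False, True])
        a = hm.nroy_agreement(m, m)
        assert a.whole_space_pct == 100.0 and a.nroy_pct == 100.0

    def test_hand_example(self):
        a = hm.nroy_agreement([1, 1, 0, 0], [1, 0, 1, 0])
        assert a.whole_space_pct == 50.0 and a.nroy_pct == 50.0

    def test_empty_a_flagged_not_applicable(self):
        a = hm.nroy_agreement([False, False], [True, False])
        assert a.nroy_pct is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hm.nroy_agreement([True], [True, False])


class TestFrequencyMap:
    def test_uniform_points_fill_bins_evenly(self, space):
        pts = hm.sobol_points(14, 4096)
        fm = hm.frequency_map(pts, space, n_bins=8)
        assert np.allclose(fm.proportion, 1 / 8, atol=0.01)

    def test_concentrated_points_fill_one_bin(self, space):
        pts = np.full((50, 14), 0.51)
        fm = hm.frequency_map(pts, space, n_bins=10)
        for name in space.names:
            sub = fm[fm.parameter == name]
            assert sub.proportion.max() == 1.0

    def test_rows_sum_to_one(self, small_run):
        res = small_run["results"]
        fm = res.frequency_map(n_bins=20)
        sums = fm.groupby("parameter").proportion.sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_empty_nroy_warns(self, space):
        with pytest.warns(RuntimeWarning, match="empty"):
            fm = hm.frequency_map(np.empty((0, 14)), space)
        assert fm.empty

    def test_natural_frame_bin_edges(self, space):
        fm = hm.frequency_map(np.full((5, 14), 0.5), space, n_bins=4)
        cv = fm[fm.parameter == "cv"]
        assert cv.bin_left.min() == pytest.approx(0.64)
        assert cv.bin_right.max() == pytest.approx(0.92)


class TestWaveConfig:
    def test_defaults_are_full_study_conditions(self):
        cfg = hm.WaveConfig()
        assert (cfg.n_initial_train, cfg.n_initial_val, cfg.n_initial_test) == (280, 70, 88)
        assert cfg.n_per_wave == 140 and cfg.n_candidates == 10_000
        assert cfg.thresholds == (3.2, 3.2, 3.0)

    def test_rejects_increasing_thresholds(self):
        with pytest.raises(ValueError, match="non-increasing"):
            hm.WaveConfig(thresholds=(3.0, 3.2))

    def test_rejects_zero_counts(self):
        with pytest.raises(ValueError):
            hm.WaveConfig(n_per_wave=0)

    def test_round_trip(self):
        cfg = hm.WaveConfig(seed=7, thresholds=(3.0,))
        assert hm.WaveConfig.from_dict(cfg.to_dict()) == cfg


class TestRun:
    def test_wave1_runs_no_extra_simulations(self, small_run):
        res = small_run["results"]
        assert res.waves[0].n_new_simulations == 0
        assert all(w.n_new_simulations == 25 for w in res.waves[1:])
        assert res.n_simulations == 60 + 12 + 6 + 2 * 25

    def test_nroy_monotone_and_membership_nested(self, small_run):
        res = small_run["results"]
        sizes = [res.nroy_size(w) for w in range(res.n_waves + 1)]
        assert sizes[0] == 100.0
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))
        m2 = res.reference_mask(2)
        m3 = res.reference_mask(3)
        assert np.all(m3 <= m2)

    def test_truth_stays_non_implausible(self, small_run):
        res = small_run["results"]
        truth = small_run["patient"].u_star
        for w in range(1, res.n_waves + 1):
            assert res.implausibility_at(truth, w) < 3.0
        assert res.nroy_membership(truth[None, :])[0]

    def test_candidate_counts_and_masks(self, small_run):
        res = small_run["results"]
        for ws in res.waves:
            assert ws.candidates.shape[0] <= 600
            assert ws.nroy_mask.shape[0] == ws.candidates.shape[0]
            assert ws.implausibility.shape[0] == ws.candidates.shape[0]

    def test_wave_report_and_summary(self, small_run):
        res = small_run["results"]
        rep = res.wave_report()
        assert list(rep.wave) == [1, 2, 3]
        assert {"nroy_pct", "vq_max", "vq_median", "implausibility_truth"} <= set(rep.columns)
        text = res.summary()
        assert "NROY" in text or "nroy" in text
        assert "TAT" in text

    def test_impossible_targets_empty_the_space(self, space):
        """Targets far beyond the simulator range rule out everything."""
        sim = hm.make_simulator(space)
        targets = hm.TargetSpec(("TAT",), [1000.0], [1.0])
        cfg = hm.WaveConfig(n_initial_train=40, n_initial_val=8, n_initial_test=2,
                            n_per_wave=10, n_candidates=200, n_reference=200,
                            thresholds=(3.0, 3.0), seed=0, restarts=2)
        model = hm.HistoryMatching(space, sim, targets, cfg)
        with pytest.raises(EmptyNROYError, match="wave 2"):
            model.fit()

    def test_lower_final_threshold_keeps_subset(self, small_run):
        res = small_run["results"]
        impl_final = hm.implausibility(res.final_bank, res.targets, res.reference_set)
        base = res.reference_mask(2)
        keep30 = base & (impl_final < 3.0)
        keep32 = base & (impl_final < 3.2)
        assert np.all(keep30 <= keep32)

    def test_plot_frequency_maps_returns_figure(self, small_run):
        fig = small_run["results"].plot_frequency_maps(n_bins=10)
        assert len(fig.axes) >= 14


class TestOneDimensionalToy:
    def test_identity_simulator_recovers_analytic_nroy(self):
        """f(x) = x, mu = 0.5, sigma = 0.1, T = 3 -> NROY is (0.2, 0.8)."""
        sp = hm.ParameterSpace(names=["x"], lower=[0.0], upper=[1.0])
        sim = lambda X: pd.DataFrame({"y": np.atleast_2d(X)[:, 0]})
        targets = hm.TargetSpec(("y",), [0.5], [0.1])
        cfg = hm.WaveConfig(n_initial_train=15, n_initial_val=4, n_initial_test=2,
                            n_per_wave=5, n_candidates=500, n_reference=4000,
                            thresholds=(3.0,), seed=0, restarts=2, noise_free=True)
        res = hm.HistoryMatching(sp, sim, targets, cfg).fit()
        assert res.nroy_size() == pytest.approx(60.0, abs=2.0)
        # brute-force grid oracle using the emulator directly
        grid = np.linspace(0, 1, 4001)[:, None]
        frac = 100 * np.mean(
            hm.implausibility(res.final_bank, targets, grid) < 3.0)
        assert frac == pytest.approx(res.nroy_size(), abs=1.0)


class TestReuse:
    def test_donor_targets_reproduce_single_cut(self, small_run):
        res = small_run["results"]
        out = hm.reuse_calibrate(res.final_bank, res.targets, res.reference_set,
                                 threshold=3.0)
        impl = hm.implausibility(res.final_bank, res.targets, res.reference_set)
        np.testing.assert_array_equal(out.mask, impl < 3.0)
        assert out.nroy_pct == pytest.approx(100 * out.mask.mean())

    def test_zero_simulator_calls(self, space, small_run):
        res = small_run["results"]
        recipient = hm.make_patient(space, seed=77, c=0.10)
        sim = hm.make_simulator(space)
        out = hm.reuse_calibrate(res.final_bank, recipient.targets,
                                 res.reference_set, truth=recipient.u_star)
        assert sim.n_calls == 0
        assert out.implausibility_truth is not None

    def test_missing_biomarker_raises(self, small_run):
        res = small_run["results"]
        t = hm.TargetSpec(("unknown",), [1.0], [1.0])
        with pytest.raises(KeyError):
            hm.reuse_calibrate(res.final_bank, t, res.reference_set)


class TestSensitivity:
    def test_same_bank_low_c_is_subset(self, small_run):
        """Scored by one fixed bank, shrinking sigma never adds NROY points."""
        res = small_run["results"]
        hi = res.reference_mask()
        lo = res.rescored(
            hm.make_targets_from_values(res.targets.biomarker_names,
                                        res.targets.mu, 0.05)
        ).reference_mask()
        assert np.all(lo <= hi)

    def test_duplicated_c_gives_full_overlap(self, small_run):
        res = small_run["results"]
        table = hm.uncertainty_sensitivity(lambda c: res, c_values=(0.10, 0.10))
        assert table.space_overlap_pct.iloc[0] == 100.0
        assert table.luc_in_huc_pct.iloc[0] == 100.0

    def test_rescore_table_schema(self, small_run):
        res = small_run["results"]

        def factory(c):
            return res.rescored(hm.make_targets_from_values(
                res.targets.biomarker_names, res.targets.mu, c))

        table = hm.uncertainty_sensitivity(factory, c_values=(0.10, 0.05))
        row = table.iloc[0]
        assert row.nroy_pct_luc <= row.nroy_pct_huc
        assert {"space_overlap_pct", "luc_in_huc_pct", "huc_in_luc_pct"} <= set(table.columns)


class TestPersistence:
    def test_save_load_reproduces_statistics(self, small_run, tmp_path):
        res = small_run["results"]
        res.save(tmp_path / "run")
        again = hm.load_run(tmp_path / "run")
        assert again.n_simulations == res.n_simulations
        np.testing.assert_allclose(again.reference_set, res.reference_set, atol=1e-12)
        for w in range(1, 4):
            assert again.nroy_size(w) == pytest.approx(res.nroy_size(w), abs=0.5)
        np.testing.assert_allclose(
            again.implausibility_at(res.truth), res.implausibility_at(res.truth),
            rtol=1e-5)

    def test_missing_bank_is_explicit(self, small_run, tmp_path):
        res = small_run["results"]
        res.save(tmp_path / "run")
        (tmp_path / "run" / "wave3_bank.json").unlink()
        with pytest.raises(FileNotFoundError, match="wave 3"):
            hm.load_run(tmp_path / "run")
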