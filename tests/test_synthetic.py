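"""Generator ground truth: determinism, linearity, round trips."""

import numpy as np
import pandas as pd
import pytest

from hoverstab import respirometry, stats
from hoverstab.reference import MO2NET_COEFFS, PREDICTORS, RATIO_COEFFS
from hoverstab.synthetic import (
    MotionParams,
    SyntheticPlan,
    TraceParams,
    TreeParams,
    gen_individuals,
    gen_landmark_series,
    gen_o2_trace,
    gen_species_table,
    gen_tree_with_trait,
)


class TestSpeciesTable:
    def test_noiseless_response_is_exact_linear_combination(self, noiseless_plan):
        t = gen_species_table(noiseless_plan)
        X = t[list(PREDICTORS)].to_numpy()
        beta = np.array([MO2NET_COEFFS[p] for p in PREDICTORS])
        expected = MO2NET_COEFFS["intercept"] + X @ beta
        np.testing.assert_allclose(t["mo2net"].to_numpy(), expected, rtol=1e-12)
        np.testing.assert_array_equal(t["mo2net"], t["mo2net_true"])

    def test_same_seed_reproduces_table_exactly(self):
        a = gen_species_table(SyntheticPlan(seed=9))
        b = gen_species_table(SyntheticPlan(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_coefficient_length_mismatch_raises(self):
        bad = dict(MO2NET_COEFFS)
        bad.pop("mass")
        with pytest.raises(ValueError, match="intercept"):
            gen_species_table(SyntheticPlan(seed=0, coeffs=bad))

    def test_degenerate_ranges_warn_of_collinearity(self):
        ranges = dict(SyntheticPlan().predictor_ranges)
        ranges["mass"] = (0.01, 0.01)
        ranges["comcob_ap"] = (0.0, 0.0)
        with pytest.warns(UserWarning, match="collinear"):
            gen_species_table(SyntheticPlan(seed=0, predictor_ranges=ranges))

    def test_coefficient_rmse_shrinks_with_sample_size(self):
        """OLS is consistent: error decreases monotonically over 100
        replicates as the species count grows 20 -> 80 -> 320."""
        truth = np.array([MO2NET_COEFFS[p] for p in PREDICTORS])
        rmse = []
        for n in (20, 80, 320):
            errs = []
            for rep in range(100):
                plan = SyntheticPlan(seed=rep * 7 + n, n_species=n)
                t = gen_species_table(plan)
                fit = stats.ols(t[list(PREDICTORS)], t["mo2net"])
                errs.append(
                    np.mean((fit.coeffs[list(PREDICTORS)].to_numpy() - truth) ** 2)
                )
            rmse.append(float(np.sqrt(np.mean(errs))))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_individuals_cover_every_species_in_both_conditions(self):
        plan = SyntheticPlan(seed=3)
        table = gen_species_table(plan)
        ind = gen_individuals(table, plan)
        per = ind.groupby(["species", "condition"]).size().unstack()
        assert set(per.index) == set(table["species"])
        assert (per >= 4).all().all() and (per <= 8).all().all()


class TestO2Trace:
    def test_slope_inverts_mo2_formula(self, noiseless_plan):
        # 113.57 mgO2/kg/h at 10 g in a 0.6 L net volume -> 0.05 mg/L/min
        tr = gen_o2_trace(113.57, 0.01, 0.61, 0.01, noiseless_plan)
        slope, r2 = respirometry.o2_slope(tr)
        assert slope == pytest.approx(0.05, rel=1e-4)
        assert r2 == pytest.approx(1.0)
        tr2 = gen_o2_trace(200.0, 0.005, 0.605, 0.005, noiseless_plan)
        slope2, _ = respirometry.o2_slope(tr2)
        assert slope2 == pytest.approx(200 * 0.005**0.9 / (0.6 * 60), rel=1e-6)
        assert slope2 == pytest.approx(0.0472, abs=5e-5)

    def test_noiseless_round_trip_recovers_target(self, noiseless_plan):
        tr = gen_o2_trace(200.0, 0.005, 0.605, 0.005, noiseless_plan)
        assert respirometry.mo2_from_trace(tr) == pytest.approx(200.0, rel=1e-10)

    def test_unphysical_trace_rejected(self, noiseless_plan):
        with pytest.raises(ValueError, match="unphysical"):
            gen_o2_trace(5000.0, 0.05, 0.615, 0.05, noiseless_plan)

    def test_noisy_slope_within_monte_carlo_tolerance(self):
        """Estimated slope stays within 3 SE of the generating slope."""
        slopes = []
        for rep in range(50):
            plan = SyntheticPlan(seed=rep, trace_params=TraceParams(noise_sd=0.01))
            tr = gen_o2_trace(150.0, 0.01, 0.61, 0.01, plan)
            slopes.append(respirometry.o2_slope(tr)[0])
        true_slope = 150.0 * 0.01**0.9 / (60 * 0.6)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - true_slope) < 3 * se


class TestLandmarkSeries:
    def test_roll_pitch_amplitudes_recovered(self):
        from hoverstab import kinematics as kin

        plan = SyntheticPlan(
            seed=2, motion_params=MotionParams(roll_amp_deg=4.0, pitch_amp_deg=0.0)
        )
        series, _ = gen_landmark_series(plan)
        _, _, summ = kin.roll_pitch(series)
        assert summ["roll_max_excursion"] == pytest.approx(4.0, abs=0.05)
        assert summ["pitch_max_excursion"] == pytest.approx(0.0, abs=1e-9)

    def test_phase_lag_parameter_recovered(self):
        from hoverstab import kinematics as kin

        plan = SyntheticPlan(
            seed=2, motion_params=MotionParams(phase_lag_deg=180.0)
        )
        series, _ = gen_landmark_series(plan)
        lag = kin.phase_lag(
            kin.abduction_signal(series, "left"),
            kin.abduction_signal(series, "right"),
            series.fps,
        )
        assert lag == pytest.approx(180.0, abs=1.0)

    def test_circular_stroke_fin_distance(self, still_series):
        from hoverstab import kinematics as kin

        series, truth = still_series
        fd = kin.fin_distance(
            series.points["pectoral_tip_left"], series.fps, series.bl
        )
        assert fd == pytest.approx(truth["pect_speed_bl_per_s"], rel=5e-3)
        assert truth["pect_speed_bl_per_s"] == pytest.approx(np.pi, rel=1e-9)

    def test_excessive_amplitude_rejected(self):
        plan = SyntheticPlan(seed=0, motion_params=MotionParams(roll_amp_deg=90.0))
        with pytest.raises(ValueError, match="gimbal"):
            gen_landmark_series(plan)

    def test_undersampling_rejected(self):
        plan = SyntheticPlan(
            seed=0, motion_params=MotionParams(fps=30.0, fin_freq_hz=3.0)
        )
        with pytest.raises(ValueError, match="fps"):
            gen_landmark_series(plan)

    def test_same_seed_reproduces_series(self):
        a, _ = gen_landmark_series(SyntheticPlan(seed=11))
        b, _ = gen_landmark_series(SyntheticPlan(seed=11))
        for name in a.points:
            np.testing.assert_array_equal(a.points[name], b.points[name])


class TestTreeWithTrait:
    def test_four_taxa_topology_counts(self):
        import dendropy

        nw, trait = gen_tree_with_trait(
            SyntheticPlan(seed=1, tree_params=TreeParams(n_taxa=4))
        )
        tree = dendropy.Tree.get(data=nw, schema="newick")
        leaves = list(tree.leaf_node_iter())
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 4
        assert len(internal) == 3
        assert len(trait) == 4

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            gen_tree_with_trait(SyntheticPlan(seed=0, tree_params=TreeParams(n_taxa=3)))

    def test_null_trait_gives_uniform_abouheif_pvalues(self):
        """With no signal, permutation p-values are ~Uniform(0, 1)."""
        from scipy.stats import kstest

        ps = []
        for i in range(200):
            nw, tr = gen_tree_with_trait(
                SyntheticPlan(seed=1000 + i, tree_params=TreeParams(n_taxa=13))
            )
            ps.append(stats.abouheif(nw, tr, n_perm=199, seed=i).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_brownian_trait_lowers_median_pvalue(self):
        pb, pn = [], []
        for i in range(60):
            nw, tr = gen_tree_with_trait(
                SyntheticPlan(
                    seed=2000 + i,
                    tree_params=TreeParams(n_taxa=13, signal="brownian"),
                )
            )
            pb.append(stats.abouheif(nw, tr, n_perm=199, seed=i).p)
            nw, tr = gen_tree_with_trait(
                SyntheticPlan(seed=3000 + i, tree_params=TreeParams(n_taxa=13))
            )
            pn.append(stats.abouheif(nw, tr, n_perm=199, seed=i).p)
        assert np.median(pb) < np.median(pn)

    def test_same_seed_reproduces_tree_and_trait(self):
        a = gen_tree_with_trait(SyntheticPlan(seed=21))
        b = gen_tree_with_trait(SyntheticPlan(seed=21))
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])
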