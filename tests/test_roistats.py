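"""ROI time-course machinery: HRF, preprocessing, per-timepoint GLM, AIC
selection, LOSO extraction, associations and PPI."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uvalley import design, roistats
from uvalley.roistats import CollinearRegressorsError, canonical_hrf


class TestHRF:
    def test_zero_at_onset_and_unit_peak(self):
        hrf = canonical_hrf(0.01)
        assert hrf.values[0] == 0.0
        assert hrf.values.max() == pytest.approx(1.0)
        # single positive peak followed by a smaller undershoot
        assert hrf.values.min() < 0
        assert abs(hrf.values.min()) < hrf.values.max()

    def test_peak_at_analytic_gamma_mode(self):
        """On the gamma-density parameterisation, the dominant component's
        mode is (peak_delay - dispersion); the undershoot only nudges it."""
        hrf = canonical_hrf(0.01)
        peak_t = hrf.grid[np.argmax(hrf.values)]
        mode = hrf.parameters["peak_delay"] - hrf.parameters["peak_dispersion"]
        assert peak_t == pytest.approx(mode, abs=0.1)

    def test_grid_refinement_consistency(self):
        coarse = canonical_hrf(0.2)
        fine = canonical_hrf(0.1)
        t_coarse = coarse.grid[np.argmax(coarse.values)]
        t_fine = fine.grid[np.argmax(fine.values)]
        assert abs(t_coarse - t_fine) <= 0.2

    def test_matches_nilearn_spm_reference(self):
        """Independent cross-check against the SPM-convention double gamma."""
        nilearn = pytest.importorskip("nilearn.glm.first_level")
        ours = canonical_hrf(0.1)
        ref = nilearn.spm_hrf(2.0, oversampling=20, time_length=32.0)
        ref = ref / ref.max()
        m = min(len(ref), len(ours.values))
        r = np.corrcoef(ours.values[:m], ref[:m])[0, 1]
        assert r > 0.999
        assert abs(0.1 * np.argmax(ref) - ours.grid[np.argmax(ours.values)]) <= 0.2


class TestSincOversample:
    def test_band_limited_sinusoid_oracle(self):
        """Interpolated values match the analytic sinusoid away from edges."""
        from uvalley.recovery import sinc_oracle_error
        for freq in (0.02, 0.1, 0.2):          # Nyquist is 0.25 at TR = 2 s
            assert sinc_oracle_error(freq=freq) < 1e-3

    def test_output_length_scales_with_factor(self):
        x = np.random.default_rng(0).standard_normal(128)
        assert roistats.sinc_oversample(x, 10).size == 1280
        assert np.array_equal(roistats.sinc_oversample(x, 1), x)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            roistats.sinc_oversample(np.zeros(64), 0)


class TestPreprocess:
    def _onsets(self, n=10):
        return np.arange(n) * 20.0 + 10.0

    def test_highpass_removes_slow_drift(self):
        tr = 2.0
        t = np.arange(256) * tr
        slow = np.sin(2 * np.pi * t / 400.0)        # period >> 128 s cutoff
        fast = np.sin(2 * np.pi * t / 20.0)
        filtered = roistats.dct_highpass(slow + fast, tr, cutoff=128.0)
        # drift suppressed by an order of magnitude (edges are imperfect),
        # the fast component passes essentially unchanged
        assert np.std(filtered - (fast - fast.mean())) < 0.1 * slow.std()
        assert np.std(roistats.dct_highpass(slow, tr)) < 0.05 * slow.std()
        assert np.corrcoef(filtered, fast)[0, 1] > 0.99

    def test_constant_input_flagged_zero(self):
        ep = roistats.preprocess_timecourse(np.full(200, 3.3), 2.0,
                                            self._onsets())
        assert ep.constant_input
        assert np.allclose(ep.matrix, 0.0)

    def test_oversampled_epoch_geometry(self):
        series = np.random.default_rng(1).standard_normal(200)
        ep = roistats.preprocess_timecourse(series, 2.0, self._onsets(),
                                            oversample=10,
                                            epoch_window=(0.0, 12.0))
        assert ep.matrix.shape == (10, 61)
        assert ep.tr_effective == pytest.approx(0.2)
        assert ep.times[0] == 0.0 and ep.times[-1] == pytest.approx(12.0)

    def test_z_normalisation_contract(self):
        series = np.random.default_rng(2).standard_normal(300) * 7 + 40
        filtered = roistats.dct_highpass(series, 2.0, 128.0)
        z = filtered / filtered.std()
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std() == pytest.approx(1.0)

    def test_bad_onsets_rejected(self):
        series = np.zeros(100)
        with pytest.raises(ValueError):
            roistats.preprocess_timecourse(series, 2.0, [500.0])
        with pytest.raises(ValueError):
            roistats.preprocess_timecourse(series, 2.0, [50.0, 10.0])


class TestTimepointGLM:
    def _epochs(self, Y):
        n_time = Y.shape[1]
        return roistats.ROITimecourse(matrix=Y, tr_effective=0.2,
                                      epoch_window=(0.0, 0.2 * (n_time - 1)),
                                      times=0.2 * np.arange(n_time),
                                      norm_sd=1.0)

    def test_orthogonal_regressors_match_simple_regressions(self):
        rng = np.random.default_rng(3)
        n = 40
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)      # orthogonal to a
        Y = np.outer(a, [0.5]) + np.outer(b, [-0.3]) + rng.normal(0, 0.1, (n, 1))
        regs = pd.DataFrame({"a": a, "b": b})
        eff = roistats.timepoint_glm(self._epochs(Y), regs, standardize=False)
        beta_a = a @ Y[:, 0] / (a @ a)
        beta_b = b @ Y[:, 0] / (b @ b)
        assert eff.coefficients[0, 0] == pytest.approx(beta_a, abs=1e-10)
        assert eff.coefficients[0, 1] == pytest.approx(beta_b, abs=1e-10)
        assert eff.vif["a"] == pytest.approx(1.0)
        assert eff.vif["b"] == pytest.approx(1.0)

    def test_normal_equations_oracle_on_toy_matrix(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 2))
        Y = rng.standard_normal((6, 3))
        regs = pd.DataFrame(X, columns=["u", "v"])
        eff = roistats.timepoint_glm(self._epochs(Y), regs, standardize=False)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        hand = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc).T
        assert np.allclose(eff.coefficients, hand, atol=1e-8)

    def test_exact_collinearity_refused_with_name(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(20)
        regs = pd.DataFrame({"a": a, "twice_a": 2 * a})
        Y = rng.standard_normal((20, 4))
        with pytest.raises(CollinearRegressorsError, match="twice_a"):
            roistats.timepoint_glm(self._epochs(Y), regs)

    def test_standardized_coefficients_scale_free(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 2))
        Y = X @ np.array([[0.7], [-0.2]]) + rng.normal(0, 0.3, (50, 1))
        regs = pd.DataFrame(X, columns=["a", "b"])
        eff1 = roistats.timepoint_glm(self._epochs(Y), regs)
        eff2 = roistats.timepoint_glm(self._epochs(Y * 10),
                                      regs.assign(a=X[:, 0] * 3))
        assert np.allclose(eff1.coefficients, eff2.coefficients, atol=1e-10)

    def test_group_stage_t_tests(self):
        rng = np.random.default_rng(7)
        effects = []
        for _ in range(15):
            coefs = np.array([[0.5], [0.0]]).T + rng.normal(0, 0.1, (1, 2))
            effects.append(roistats.EffectTimecourse(
                names=("a", "b"), coefficients=coefs, times=np.array([0.0]),
                tr_effective=0.2, vif={"a": 1.0, "b": 1.0}))
        g = roistats.group_effect_tests(effects)
        assert g.p[0, 0] < 0.001
        assert g.p[0, 1] > 0.05
        stack = np.stack([e.coefficients for e in effects])
        hand = stats.ttest_1samp(stack[:, 0, 0], 0.0)
        assert g.t[0, 0] == pytest.approx(hand.statistic)


class TestModelSelection:
    def test_aic_formula(self):
        assert roistats.aic(3.7, 24, 5) == pytest.approx(
            2 * 5 + 24 * np.log(3.7 / 24))

    def _simulate_group(self, step_weight, seed, n_subjects=8, n_trials=36):
        hrf = canonical_hrf(0.1)
        rng = np.random.default_rng(seed)
        onsets = design.build_onsets(n_trials, seed=seed)
        duration = onsets[-1] + 30.0
        epochs, designs = [], []
        human = np.tile([0, 0, 0, 0, 1, 1], n_trials // 6).astype(float)
        for _ in range(n_subjects):
            X = rng.standard_normal((n_trials, 3))
            amps = X @ [0.6, 0.3, 0.2] + step_weight * (human - human.mean())
            amps = amps + 0.2 * rng.standard_normal(n_trials)
            sess = design.simulate_bold(amps, onsets, 2.0, duration, hrf,
                                        noise_sd=0.8,
                                        seed=int(rng.integers(2 ** 31)))
            epochs.append(roistats.preprocess_timecourse(sess.series, 2.0,
                                                         onsets))
            designs.append(pd.DataFrame(
                {"likability": X[:, 0], "humanlikeness": X[:, 1],
                 "familiarity": X[:, 2], "human_detection": human}))
        return epochs, designs

    def test_base_model_selected_without_step_effect(self):
        rejected = 0
        for rep in range(5):
            epochs, designs = self._simulate_group(0.0, seed=100 + rep)
            sel = roistats.model_select_aic(epochs, designs)
            rejected += not sel.accepted
        assert rejected >= 4

    def test_extended_model_selected_with_strong_step(self):
        accepted = 0
        for rep in range(5):
            epochs, designs = self._simulate_group(1.5, seed=200 + rep)
            sel = roistats.model_select_aic(epochs, designs)
            accepted += sel.accepted
        assert accepted >= 4

    def test_missing_candidate_rejected(self):
        epochs, designs = self._simulate_group(0.0, seed=1, n_subjects=3)
        bare = [d.drop(columns=["human_detection"]) for d in designs]
        with pytest.raises(ValueError):
            roistats.model_select_aic(epochs, bare)


class TestLOSO:
    def test_identical_subjects_select_same_locus(self):
        maps = np.tile(np.array([0.1, 0.9, 0.3, 0.2]), (5, 1))
        vals, chosen = roistats.loso_extract(maps)
        assert (chosen == 1).all()
        assert np.allclose(vals, 0.9)

    def test_refit_count_equals_subjects(self):
        maps = np.random.default_rng(8).standard_normal((21, 12))
        vals, chosen = roistats.loso_extract(maps)
        assert vals.shape == (21,)
        assert chosen.shape == (21,)

    def test_selection_independent_of_own_data(self):
        """Perturbing subject s's own map cannot change s's chosen locus."""
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((8, 6))
        _, chosen = roistats.loso_extract(maps)
        bumped = maps.copy()
        bumped[3] += 100.0
        _, chosen_b = roistats.loso_extract(bumped)
        assert chosen[3] == chosen_b[3]

    def test_null_unbiased_but_naive_biased(self):
        from uvalley.recovery import loso_null_study
        out = loso_null_study(n_replicates=400, seed=10)
        assert abs(out["loso_bias_z"]) < 2.0
        assert out["naive_bias_z"] > 10.0
        assert out["naive_mean"] > 0.1

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            roistats.loso_extract(np.zeros((2, 4)))


class TestAssociation:
    def test_exact_linear_relation(self):
        b = np.array([0.1, 0.5, -0.2, 0.8, 0.3])
        out = roistats.across_subject_association(b, 2 * b)
        assert out.pearson_r == pytest.approx(1.0)
        assert out.robust_slope == pytest.approx(2.0, abs=1e-6)

    def test_pearson_matches_closed_form(self):
        a = np.array([1.0, 2.0, 4.0, 7.0])
        b = np.array([2.0, 1.0, 5.0, 9.0])
        out = roistats.across_subject_association(a, b)
        hand = (np.sum((a - a.mean()) * (b - b.mean()))
                / np.sqrt(np.sum((a - a.mean()) ** 2)
                          * np.sum((b - b.mean()) ** 2)))
        assert out.pearson_r == pytest.approx(hand, abs=1e-12)

    @pytest.mark.parametrize("context,alpha",
                             [("default", 0.05), ("rating_uv", 0.0125),
                              ("choice_uv", 0.0167)])
    def test_bonferroni_context_thresholds(self, context, alpha):
        rng = np.random.default_rng(11)
        out = roistats.across_subject_association(
            rng.standard_normal(10), rng.standard_normal(10), context=context)
        assert out.alpha_threshold == alpha

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError):
            roistats.across_subject_association([1, 2, 3], [1, 2, 3],
                                                context="whole_brain")

    def test_zero_variance_flagged(self):
        out = roistats.across_subject_association([1.0, 1.0, 1.0], [1, 2, 3])
        assert out.degenerate
        assert np.isnan(out.pearson_r)

    def test_type1_rate_at_bonferroni_alpha(self):
        from uvalley.recovery import association_type1_study
        out = association_type1_study(n_replicates=1000, seed=12,
                                      context="rating_uv")
        assert out["rejection_rate"] == pytest.approx(0.0125, abs=0.008)

    def test_robust_regression_resists_outlier(self):
        rng = np.random.default_rng(13)
        b = rng.standard_normal(20)
        n = 1.5 * b + 0.1 * rng.standard_normal(20)
        n[0] += 30.0                                 # gross outlier
        out = roistats.across_subject_association(b, n)
        assert out.robust_slope == pytest.approx(1.5, abs=0.3)


class TestPPI:
    def _series(self, seed, n_trials=30):
        hrf = canonical_hrf(0.1)
        rng = np.random.default_rng(seed)
        onsets = design.build_onsets(n_trials, seed=seed)
        duration = onsets[-1] + 30.0
        n = int(round(duration / 2.0))
        psych = np.tile([1.0, -1.0], n_trials // 2)
        amp = rng.uniform(0.5, 1.5, n_trials)
        seed_series = roistats.events_to_series(amp, onsets, 2.0, n, hrf) \
            + 0.3 * rng.standard_normal(n)
        return seed_series, psych, onsets, n, rng

    def test_positive_control_detected(self):
        hits = 0
        for rep in range(10):
            seed_series, psych, onsets, n, rng = self._series(300 + rep)
            hrf = canonical_hrf(0.1)
            psych_conv = roistats.events_to_series(psych - psych.mean(), onsets,
                                                   2.0, n, hrf)
            target = (0.3 * seed_series + 0.8 * psych_conv * seed_series
                      + 0.3 * rng.standard_normal(n))
            res = roistats.ppi_analysis(seed_series, target, psych, onsets, 2.0)
            hits += res.p < 0.05 and res.coefficient > 0
        assert hits >= 9

    def test_null_coupling_unbiased(self):
        coefs = []
        for rep in range(60):
            seed_series, psych, onsets, n, rng = self._series(600 + rep)
            target = rng.standard_normal(n)
            res = roistats.ppi_analysis(seed_series, target, psych, onsets, 2.0)
            coefs.append(res.coefficient)
        coefs = np.asarray(coefs)
        z = coefs.mean() / (coefs.std(ddof=1) / np.sqrt(len(coefs)))
        assert abs(z) < 2.0

    def test_constant_psych_refused(self):
        seed_series, psych, onsets, n, rng = self._series(900)
        with pytest.raises(CollinearRegressorsError):
            roistats.ppi_analysis(seed_series, rng.standard_normal(n),
                                  np.zeros(len(psych)), onsets, 2.0)

    def test_exact_neural_series_mode(self):
        seed_series, psych, onsets, n, rng = self._series(901)
        target = rng.standard_normal(n)
        res = roistats.ppi_analysis(seed_series, target, psych, onsets, 2.0,
                                    convolve_psych=False)
        assert np.isfinite(res.t)
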