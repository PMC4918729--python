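import numpy as np
import pandas as pd
import pytest

from rlcross.neuro import (
    DEFAULT_ITI,
    HrfSpec,
    RoiDataset,
    RoiError,
    RoiGlm,
    RoiWeights,
    build_regressor,
    compare_pe_vs_outcome,
    events_from_series,
    fit_glm,
    hrf_kernel,
    scan_length_for,
    session_design,
    simulate_roi,
    treatment_contrast,
)

SPEC = HrfSpec()


def _events(n=40, rng=None):
    rng = rng or np.random.default_rng(0)
    series = {
        "gain": (rng.normal(0, 0.3, n), rng.normal(0, 0.5, n),
                 rng.integers(0, 2, n).astype(float)),
        "loss": (rng.normal(0, 0.3, n), rng.normal(0, 0.5, n),
                 -rng.integers(0, 2, n).astype(float)),
    }
    return events_from_series(series)


class TestHrfKernel:
    def test_zero_at_origin_unit_peak(self):
        h = hrf_kernel(SPEC)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_peak_between_4_and_7_seconds(self):
        h = hrf_kernel(SPEC)
        t_peak = np.argmax(h) * SPEC.dt
        assert 4.0 <= t_peak <= 7.0

    def test_undershoot_negative_but_small(self):
        h = hrf_kernel(SPEC)
        assert h.min() < 0
        assert abs(h.min()) < h.max() / 3

    def test_matches_nilearn_spm_hrf_shape(self):
        from nilearn.glm.first_level import spm_hrf

        spec = HrfSpec(tr=3.3, microtime=16)
        mine = hrf_kernel(spec)
        ref = spm_hrf(spec.tr, oversampling=spec.microtime, time_length=spec.length + spec.dt)
        m = min(len(mine), len(ref))
        # allow a sub-bin grid offset between the two sampling conventions
        r = max(
            np.corrcoef(mine[: m - 3], ref[k : m - 3 + k])[0, 1] for k in range(3)
        )
        assert r > 0.999
        t_peak_ref = np.argmax(ref) * spec.dt
        assert abs(np.argmax(mine) * spec.dt - t_peak_ref) <= 1.0


class TestBuildRegressor:
    def test_zero_modulators_zero_regressor(self):
        reg = build_regressor(np.array([10.0, 30.0]), np.array([0.0, 0.0]), SPEC,
                              scan_length=100.0, mean_center=False)
        assert np.allclose(reg, 0.0)

    def test_single_onset_reproduces_kernel_samples(self):
        reg = build_regressor(np.array([0.0]), np.array([1.0]), SPEC,
                              scan_length=66.0, mean_center=False)
        h = hrf_kernel(SPEC)
        h = np.pad(h, (0, len(reg) * SPEC.microtime - len(h)))
        expected = h[np.arange(len(reg)) * SPEC.microtime]
        assert np.allclose(reg, expected)

    def test_superposition_and_scaling(self):
        on1, on2 = np.array([5.0, 40.0]), np.array([20.0, 60.0])
        m1, m2 = np.array([1.0, -0.5]), np.array([0.7, 0.2])
        both = build_regressor(np.sort(np.concatenate([on1, on2])),
                               np.concatenate([m1, m2])[np.argsort(np.concatenate([on1, on2]))],
                               SPEC, 120.0, mean_center=False)
        sep = (build_regressor(on1, m1, SPEC, 120.0, mean_center=False)
               + build_regressor(on2, m2, SPEC, 120.0, mean_center=False))
        assert np.allclose(both, sep, atol=1e-12)
        scaled = build_regressor(on1, 3.0 * m1, SPEC, 120.0, mean_center=False)
        assert np.allclose(scaled, 3.0 * build_regressor(on1, m1, SPEC, 120.0,
                                                         mean_center=False))

    def test_onset_outside_scan_rejected(self):
        with pytest.raises(RoiError):
            build_regressor(np.array([150.0]), np.array([1.0]), SPEC, 100.0)


class TestRoiGlm:
    def test_exact_recovery_of_noiseless_signal(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        y = 2.0 * X["a"] - 1.5 * X["c"]
        est = RoiGlm().fit(X, y)
        assert est.betas_["a"] == pytest.approx(2.0, abs=1e-10)
        assert est.betas_["b"] == pytest.approx(0.0, abs=1e-10)
        assert est.betas_["c"] == pytest.approx(-1.5, abs=1e-10)

    def test_orthogonal_design_betas_equal_projections(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        X = pd.DataFrame({"a": a, "b": b})
        y = rng.normal(size=200)
        est = RoiGlm().fit(X, y)
        assert est.betas_["a"] == pytest.approx((a @ y) / (a @ a), abs=1e-10)
        assert est.betas_["b"] == pytest.approx((b @ y) / (b @ b), abs=1e-10)

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
        with pytest.raises(RoiError, match="b"):
            RoiGlm().fit(X, rng.normal(size=50))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = rng.normal(size=80)
        perm = rng.permutation(80)
        est1 = RoiGlm().fit(X, y)
        est2 = RoiGlm().fit(X.iloc[perm].reset_index(drop=True), y[perm])
        assert np.allclose(est1.betas_, est2.betas_)

    def test_bic_definition(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = rng.normal(size=60)
        est = RoiGlm().fit(X, y)
        assert est.bic_ == pytest.approx(3 * np.log(60) - 2 * est.loglik_)


class TestSimulateRoi:
    def test_noiseless_recovery_of_planted_weights(self):
        events = _events()
        w = RoiWeights(w_outcome_onset=0.8, w_rpe=1.3, w_ppe=-0.9, w_cue=0.4)
        ds = simulate_roi("ventral_striatum", events, w, SPEC,
                          np.random.default_rng(0), noise_sd=0.0, drift_amplitude=0.0)
        X = session_design(events, SPEC, ds.scan_length)
        res = fit_glm(ds, X)
        assert res.betas["rpe"] == pytest.approx(1.3, abs=1e-6)
        assert res.betas["ppe"] == pytest.approx(-0.9, abs=1e-6)
        assert res.betas["outcome_onset"] == pytest.approx(0.8, abs=1e-6)
        assert res.betas["cue_q"] == pytest.approx(0.4, abs=1e-6)

    def test_same_seed_identical_dataset(self):
        events = _events()
        w = RoiWeights(w_rpe=1.0)
        a = simulate_roi("ventral_striatum", events, w, SPEC, np.random.default_rng(5))
        b = simulate_roi("ventral_striatum", events, w, SPEC, np.random.default_rng(5))
        assert np.array_equal(a.signal, b.signal)

    def test_unknown_roi_rejected(self):
        with pytest.raises(RoiError):
            simulate_roi("amygdala", _events(), RoiWeights(), SPEC,
                         np.random.default_rng(0))


class TestModelComparison:
    def test_identical_candidates_zero_bic_difference(self):
        # when delta equals the objective outcome, both designs coincide
        rng = np.random.default_rng(0)
        n = 30
        vals = rng.integers(0, 2, n).astype(float)
        series = {"gain": (rng.normal(0, 0.3, n), vals, vals)}
        events = events_from_series(series)
        w = RoiWeights(w_rpe=1.0)
        ds = simulate_roi("ventral_striatum", events, w, SPEC, rng, noise_sd=0.5)
        out = compare_pe_vs_outcome({"s1": ds}, SPEC)
        assert out["per_subject"]["delta_bic"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_pe_generated_data_favours_pe_and_reverses(self):
        rng = np.random.default_rng(1)
        events = _events(n=60, rng=rng)
        w = RoiWeights(w_rpe=1.0, w_ppe=-0.8)
        pe_ds = {f"s{i}": simulate_roi("ventral_striatum", events, w, SPEC,
                                       np.random.default_rng(i), noise_sd=1.0)
                 for i in range(6)}
        out_ds = {f"s{i}": simulate_roi("ventral_striatum", events, w, SPEC,
                                        np.random.default_rng(i), noise_sd=1.0,
                                        encode="outcome")
                  for i in range(6)}
        assert compare_pe_vs_outcome(pe_ds, SPEC)["group_log_bayes_factor"] > 0
        assert compare_pe_vs_outcome(out_ds, SPEC)["group_log_bayes_factor"] < 0


class TestTreatmentContrast:
    def _betas(self, diffs):
        rows = []
        for i, d in enumerate(diffs):
            rows.append({"subject_id": f"s{i}", "treatment": "placebo",
                         "roi": "ventral_striatum", "regressor": "rpe", "beta": 1.0})
            rows.append({"subject_id": f"s{i}", "treatment": "vaccine",
                         "roi": "ventral_striatum", "regressor": "rpe", "beta": 1.0 + d})
        return pd.DataFrame(rows)

    def test_direction_vaccine_minus_placebo(self):
        res = treatment_contrast(self._betas([-0.5, -0.4, -0.6, -0.45]),
                                 "ventral_striatum", "rpe")
        assert res.mean_diff < 0 and res.t < 0

    def test_unpaired_subjects_rejected(self):
        betas = self._betas([-0.5, -0.4, -0.6])
        betas = betas.drop(index=1)
        with pytest.raises(RoiError):
            treatment_contrast(betas, "ventral_striatum", "rpe")

    def test_larger_negative_ppe_weight_shows_as_negative_diff(self):
        # stronger punishment-PE encoding = more negative signed beta
        rows = []
        for i in range(5):
            rows.append({"subject_id": f"s{i}", "treatment": "placebo",
                         "roi": "anterior_insula", "regressor": "ppe",
                         "beta": -0.6 + 0.01 * i})
            rows.append({"subject_id": f"s{i}", "treatment": "vaccine",
                         "roi": "anterior_insula", "regressor": "ppe",
                         "beta": -1.1 + 0.02 * i})
        res = treatment_contrast(pd.DataFrame(rows), "anterior_insula", "ppe")
        assert res.mean_diff < 0
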