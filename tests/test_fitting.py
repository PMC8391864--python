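"""Fitting tests: objective arithmetic, simplex contracts, reproducibility,
bounds auditing and the observability degeneracy."""

import dataclasses

import numpy as np
import pytest

from ifflpulse import (
    FitConfig,
    InducerCondition,
    NOMINAL_HYBRID,
    NOMINAL_RNA_ONLY,
    TimeGrid,
    apply_analysis_window,
    fit_hybrid,
    fit_rna_only,
    observed_gfp,
    simulate,
    sse_objective,
    validate_fit,
)
from ifflpulse.errors import AnalysisError, ParameterError

TRAIN = (InducerCondition(iptg=500.0, arabinose=6600.0),
         InducerCondition(iptg=7.81, arabinose=1650.0))
GRID = TimeGrid(0.0, 300.0, 10.0)


def noiseless_courses(params, conditions=TRAIN, model_id="rna_only",
                      grid=GRID, windowed=True):
    courses = []
    for cond in conditions:
        traj = simulate(model_id, params, cond, grid)
        tc = observed_gfp(traj, params.S_G)
        if windowed:
            tc = apply_analysis_window(tc, model_id)
        courses.append(tc)
    return courses


class TestSseObjective:
    def test_self_consistency_zero(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        obj = sse_objective(NOMINAL_RNA_ONLY, courses, "rna_only")
        scale = sum(float(tc.signal[tc.mask] @ tc.signal[tc.mask])
                    for tc in courses)
        assert obj <= 1e-10 * scale

    def test_constant_offset_arithmetic(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        c = 7.5
        courses[0].signal = courses[0].signal + c
        k = int(courses[0].mask.sum())
        obj = sse_objective(NOMINAL_RNA_ONLY, courses, "rna_only", grid=GRID)
        assert obj == pytest.approx(k * c * c, rel=1e-6)

    def test_all_masked_rejected(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        courses[0].mask[:] = False
        with pytest.raises(AnalysisError):
            sse_objective(NOMINAL_RNA_ONLY, courses, "rna_only")

    def test_masked_values_do_not_matter(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        ref = sse_objective(NOMINAL_RNA_ONLY, courses, "rna_only")
        courses[0].signal[~courses[0].mask] = 1e9
        assert sse_objective(NOMINAL_RNA_ONLY, courses, "rna_only") == \
            pytest.approx(ref, abs=1e-12)

    def test_alpha_gfp_scale_factor_degeneracy(self):
        # alpha_GFP * c with S_G / c leaves the observable unchanged: the
        # known sloppiness of fitting a scale jointly with a linear rate
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        c = 3.7
        rescaled = dataclasses.replace(
            NOMINAL_RNA_ONLY,
            alpha_GFP=NOMINAL_RNA_ONLY.alpha_GFP * c,
            S_G=NOMINAL_RNA_ONLY.S_G / c)
        obj = sse_objective(rescaled, courses, "rna_only")
        scale = sum(float(tc.signal[tc.mask] @ tc.signal[tc.mask])
                    for tc in courses)
        assert obj <= 1e-2 * scale * 0.01  # < 1% of signal energy, easily


class TestFitRnaOnly:
    def test_fixed_point_from_truth(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        cfg = FitConfig(max_iterations=400, n_restarts=1, seed=0)
        res = fit_rna_only(courses, NOMINAL_RNA_ONLY, cfg, grid=GRID)
        assert res.objective <= 1e-8
        for name, value in res.params.items():
            assert value == pytest.approx(getattr(NOMINAL_RNA_ONLY, name),
                                          rel=1e-3)

    def test_trace_non_increasing_and_final_le_init(self):
        rng = np.random.default_rng(0)
        start = NOMINAL_RNA_ONLY.with_free_values(
            NOMINAL_RNA_ONLY.free_values() * rng.uniform(0.9, 1.1, 15))
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        cfg = FitConfig(max_iterations=300, n_restarts=1, seed=1)
        res = fit_rna_only(courses, start, cfg)
        trace = np.array(res.trace)
        assert np.all(np.diff(trace) <= 0)
        init_obj = sse_objective(start, courses, "rna_only")
        assert res.objective <= init_obj

    def test_seeded_restarts_reproducible(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        rng = np.random.default_rng(4)
        start = NOMINAL_RNA_ONLY.with_free_values(
            NOMINAL_RNA_ONLY.free_values() * rng.uniform(0.9, 1.1, 15))
        cfg = FitConfig(max_iterations=120, n_restarts=2, seed=99)
        a = fit_rna_only(courses, start, cfg)
        b = fit_rna_only(courses, start, cfg)
        assert a.params == b.params
        assert a.objective == b.objective
        assert a.trace == b.trace

    def test_log_transform_never_proposes_nonpositive(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        cfg = FitConfig(max_iterations=150, n_restarts=1, seed=2,
                        audit_evaluations=True)
        res = fit_rna_only(courses, NOMINAL_RNA_ONLY, cfg)
        audited = np.array(res.evaluation_log)
        assert np.all(audited > 0)

    def test_nonpositive_init_rejected(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        with pytest.raises(ParameterError):
            fit_rna_only(courses, NOMINAL_RNA_ONLY.with_free_values(
                np.zeros(15)), FitConfig())


class TestFitHybrid:
    HCONDS = (InducerCondition(iptg=1000.0, atc=40.0),)
    HGRID = TimeGrid(0.0, 480.0, 10.0)

    def _courses(self):
        return noiseless_courses(NOMINAL_HYBRID, self.HCONDS, "hybrid",
                                 self.HGRID)

    def test_objective_near_zero_from_truth(self):
        from ifflpulse import free_parameter_names
        bounds = {k: (getattr(NOMINAL_HYBRID, k) * 0.1,
                      getattr(NOMINAL_HYBRID, k) * 10.0)
                  for k in free_parameter_names("hybrid")}
        # k_off = 0 nominal: give it a positive window containing tiny values
        bounds["k_off"] = (1e-12, 1e-3)
        init = dataclasses.replace(NOMINAL_HYBRID, k_off=1e-12)
        cfg = FitConfig(bounds=bounds, max_iterations=150, n_restarts=1, seed=0)
        res = fit_hybrid(self._courses(), init, cfg)
        scale = sum(float(tc.signal[tc.mask] @ tc.signal[tc.mask])
                    for tc in self._courses())
        assert res.objective <= 1e-6 * scale

    def test_bounds_audited(self):
        from ifflpulse import free_parameter_names
        names = free_parameter_names("hybrid")
        bounds = {k: (getattr(NOMINAL_HYBRID, k) * 0.5,
                      getattr(NOMINAL_HYBRID, k) * 2.0) for k in names}
        bounds["k_off"] = (1e-12, 1e-3)
        init = dataclasses.replace(NOMINAL_HYBRID, k_off=1e-12)
        cfg = FitConfig(bounds=bounds, max_iterations=100, n_restarts=1,
                        seed=0, audit_evaluations=True)
        res = fit_hybrid(self._courses(), init, cfg)
        lo = np.array([bounds[k][0] for k in names])
        hi = np.array([bounds[k][1] for k in names])
        for x in res.evaluation_log:
            assert np.all(np.asarray(x) >= lo * (1 - 1e-12))
            assert np.all(np.asarray(x) <= hi * (1 + 1e-12))

    def test_nearly_collapsed_bounds_return_init(self):
        from ifflpulse import free_parameter_names
        names = free_parameter_names("hybrid")
        init = dataclasses.replace(NOMINAL_HYBRID, k_off=1e-12)
        bounds = {k: (getattr(init, k) * (1 - 1e-9),
                      getattr(init, k) * (1 + 1e-9)) for k in names}
        cfg = FitConfig(bounds=bounds, max_iterations=60, n_restarts=1, seed=0)
        res = fit_hybrid(self._courses(), init, cfg)
        for name in names:
            assert res.params[name] == pytest.approx(getattr(init, name),
                                                     rel=1e-8)

    def test_init_outside_bounds_rejected(self):
        from ifflpulse import free_parameter_names
        names = free_parameter_names("hybrid")
        bounds = {k: (getattr(NOMINAL_HYBRID, k) * 2.0,
                      getattr(NOMINAL_HYBRID, k) * 4.0) for k in names}
        bounds["k_off"] = (1e-12, 1e-3)
        init = dataclasses.replace(NOMINAL_HYBRID, k_off=1e-12)
        with pytest.raises(ParameterError):
            fit_hybrid(self._courses(), init,
                       FitConfig(bounds=bounds, n_restarts=1))

    def test_missing_bounds_rejected(self):
        with pytest.raises(ParameterError):
            fit_hybrid(self._courses(), NOMINAL_HYBRID,
                       FitConfig(bounds={"gamma": (0.1, 1.0)}))


class TestValidateFit:
    def _fit_at_truth(self):
        courses = noiseless_courses(NOMINAL_RNA_ONLY)
        cfg = FitConfig(max_iterations=50, n_restarts=1, seed=0)
        return fit_rna_only(courses, NOMINAL_RNA_ONLY, cfg), courses

    def test_heldout_equal_train_reproduces_training_residual(self):
        fit, courses = self._fit_at_truth()
        summary = validate_fit(fit, courses,
                               train_conditions=[tc.condition for tc in courses])
        sse = sum(v["rmse"] ** 2 * v["n_points"] for v in summary.values())
        assert sse == pytest.approx(fit.objective, abs=1e-9 + fit.objective)
        assert all(v["overlaps_train"] for v in summary.values())

    def test_noiseless_heldout_recovery(self):
        fit, _ = self._fit_at_truth()
        heldout = noiseless_courses(
            NOMINAL_RNA_ONLY,
            (InducerCondition(iptg=125.0, arabinose=412.5),))
        summary = validate_fit(fit, heldout)
        for v in summary.values():
            assert v["nrmse"] <= 0.01
            assert not v["overlaps_train"]

    def test_empty_heldout(self):
        fit, _ = self._fit_at_truth()
        assert validate_fit(fit, []) == {}
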