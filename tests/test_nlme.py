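"""Mixed-model likelihood, starting values, fitting and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import co2resp as cr
from co2resp.nlme import (
    FitConfig,
    FitResult,
    _combo_weights,
    _fd_gradient,
    _loglik_and_grad,
    build_design,
    curvewise_start,
    effects_from_theta,
    fit_model,
    marginal_estimates,
    theta_from_effects,
    validate_dataset,
)


def _small_levels(n_spec=2, n_int=3):
    base = cr.default_factor_levels()
    return cr.FactorLevels(
        intensities=base.intensities[:n_int] + (base.reference_intensity,),
        spectra=tuple(s for s in base.spectra
                      if s.label in list(base.spectrum_labels[:n_spec]) + ["37R36G27B"]),
        reference_intensity=base.reference_intensity,
        reference_spectrum=base.reference_spectrum,
    )


def _random_small_dataset(rng, n_plants=3, n_obs_per_plant=8):
    """A tiny random dataset plus random-but-valid generating parameters."""
    levels = _small_levels()
    spectra = levels.spectrum_labels
    rows = []
    for j in range(n_plants):
        spectrum = spectra[j % len(spectra)]
        for k in range(n_obs_per_plant):
            rows.append((
                f"P{j}", spectrum,
                float(rng.choice(levels.intensities)),
                float(rng.choice([200, 400, 600, 900])),
                k + 1,
                float(rng.normal(0, 5)),
            ))
    df = pd.DataFrame(rows, columns=["plant_id", "spectrum", "intensity",
                                     "co2", "replicate", "an"])
    effects = cr.EffectsTable(
        levels,
        intercepts={"c": float(rng.normal(-6, 1)),
                    "d": float(rng.normal(10, 1)),
                    "b": float(rng.uniform(200, 400))},
        intensity_offsets={
            p: {i: float(rng.normal(0, sc)) for i in levels.nonref_intensities}
            for p, sc in (("c", 1.0), ("d", 1.0), ("b", 30.0))
        },
        spectrum_offsets={
            p: {s: float(rng.normal(0, sc)) for s in levels.nonref_spectra}
            for p, sc in (("c", 1.0), ("d", 1.0), ("b", 30.0))
        },
        sigma_u=float(rng.uniform(0.1, 1.5)),
        residual_sds={i: float(rng.uniform(0.2, 1.0)) for i in levels.intensities},
    )
    return df, effects


def dense_loglik(effects, dataset):
    """Independent oracle: per-plant dense-covariance Gaussian log-density."""
    total = 0.0
    for _, grp in dataset.groupby("plant_id"):
        s = grp.spectrum.iloc[0]
        p = [cr.assemble_params(effects, s, i) for i in grp.intensity]
        g = np.array([1 - np.exp(-c / pp.b) for c, pp in zip(grp.co2, p)])
        mean = np.array([pp.c + (pp.d - pp.c) * gg for pp, gg in zip(p, g)])
        sd = np.array([effects.residual_sds[i] for i in grp.intensity])
        cov = np.diag(sd ** 2) + effects.sigma_u ** 2 * np.outer(g, g)
        total += stats.multivariate_normal.logpdf(grp.an.to_numpy(), mean, cov)
    return float(total)


class TestDesign:
    def test_fixed_effect_count_for_full_design(self, simulated_default, levels):
        design = build_design(simulated_default, levels)
        assert design.n_fixed == 48  # 3 x (1 + 6 + 9)
        assert design.n_theta == 56

    def test_reference_cell_selects_only_intercepts(self, levels, simulated_default):
        design = build_design(simulated_default, levels)
        w = _combo_weights(design, "d", levels.reference_spectrum,
                           levels.reference_intensity)
        assert w.sum() == 1.0 and w[design.n_fixed_per_param] == 1.0

    def test_level_mismatch_reported(self, levels):
        df = pd.DataFrame({
            "plant_id": ["P1"], "spectrum": ["UNKNOWN"], "intensity": [350.0],
            "co2": [400.0], "replicate": [1], "an": [1.0],
        })
        with pytest.raises(ValueError, match="UNKNOWN"):
            build_design(df, levels)

    def test_plants_nested_in_spectra(self):
        df = pd.DataFrame({
            "plant_id": ["P1", "P1"], "spectrum": ["100B", "100R"],
            "intensity": [350.0, 350.0], "co2": [400.0, 400.0],
            "replicate": [1, 1], "an": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="P1"):
            validate_dataset(df)


class TestLikelihood:
    def test_single_observation_closed_form(self):
        levels = _small_levels()
        rng = np.random.default_rng(0)
        df, effects = _random_small_dataset(rng, n_plants=1, n_obs_per_plant=1)
        effects.sigma_u = 0.0
        ll = cr.marginal_loglik(effects, df)
        row = df.iloc[0]
        p = cr.assemble_params(effects, row.spectrum, row.intensity)
        mu = cr.an_predict(p, row.co2)
        sd = effects.residual_sds[row.intensity]
        # sigma_u = 0 is carried as a 1e-6 floor inside theta, so agreement
        # is to ~1e-9 absolute rather than machine precision
        assert ll == pytest.approx(float(stats.norm.logpdf(row.an, mu, sd)), rel=1e-10)

    def test_rank1_equals_dense_on_random_datasets(self):
        """The rank-one computation matches a dense multivariate normal on
        many random small datasets (likelihood oracle)."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            df, effects = _random_small_dataset(
                rng, n_plants=int(rng.integers(1, 5)),
                n_obs_per_plant=int(rng.integers(2, 12)),
            )
            ll = cr.marginal_loglik(effects, df)
            oracle = dense_loglik(effects, df)
            worst = max(worst, abs(ll - oracle))
        assert worst < 1e-8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        df, effects = _random_small_dataset(rng, n_plants=2, n_obs_per_plant=10)
        ll = cr.marginal_loglik(effects, df)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert cr.marginal_loglik(effects, shuffled) == pytest.approx(ll, abs=1e-10)

    def test_invalid_variance_parameters_rejected(self):
        rng = np.random.default_rng(3)
        df, effects = _random_small_dataset(rng)
        with pytest.raises(ValueError):
            effects.sigma_u = -1.0
            effects.validate()

    def test_analytic_gradient_matches_finite_differences(self, simulated_default, levels):
        design = build_design(simulated_default, levels)
        truth = cr.SimulationTruth(seed=1)
        eff = truth.effects
        eff.sigma_u, eff.residual_sds = truth.sigma_u, truth.residual_sds
        theta = theta_from_effects(eff, design)
        ll, grad = _loglik_and_grad(theta, design)
        f_fd, g_fd = _fd_gradient(theta, design)
        assert ll == pytest.approx(-f_fd, rel=1e-12)
        rel = np.abs(grad + g_fd) / np.maximum(1.0, np.abs(g_fd))
        assert rel.max() < 1e-6


class TestCurvewiseStart:
    def test_noise_free_recovery(self, reference_effects):
        truth = cr.SimulationTruth(
            sigma_u=0.0,
            residual_sds={i: 0.0 for i in reference_effects.levels.intensities},
            plants_per_spectrum=1,
            seed=0,
        )
        df = cr.simulate_experiment(truth)
        start = curvewise_start(df, reference_effects.levels)
        for s in reference_effects.levels.spectrum_labels:
            for i in reference_effects.levels.intensities:
                for p in ("c", "d", "b"):
                    got = start.value(p, s, i)
                    want = reference_effects.value(p, s, i)
                    assert got == pytest.approx(want, rel=1e-3, abs=2e-3), (p, s, i)

    def test_single_cell_collapses_to_that_cell(self):
        co2 = np.array([200.0, 400.0, 600.0, 900.0] * 3)
        p_true = cr.CurveParams(-6.0, 9.0, 300.0)
        an = cr.an_predict(p_true, co2)
        base = cr.default_factor_levels()
        levels = cr.FactorLevels(
            intensities=(350.0,), spectra=(base.spectra[0],),
            reference_intensity=350.0, reference_spectrum=base.spectra[0].label,
        )
        df = pd.DataFrame({
            "plant_id": "P1", "spectrum": base.spectra[0].label,
            "intensity": 350.0, "co2": co2, "replicate": 1, "an": an,
        })
        start = curvewise_start(df, levels)
        assert start.intercepts["c"] == pytest.approx(-6.0, abs=1e-4)
        assert start.intercepts["d"] == pytest.approx(9.0, abs=1e-4)
        assert start.intercepts["b"] == pytest.approx(300.0, rel=1e-3)
        assert start.intensity_offsets["c"] == {}

    def test_largest_published_b_is_interior_to_the_grid(self):
        # the shallow 90-PPFD curve has b ~ 1265, well inside 50-5000
        co2 = np.tile(np.arange(200.0, 901.0, 100.0), 3)
        p_true = cr.CurveParams(-2.34, 7.73, 1264.96)
        rng = np.random.default_rng(2)
        an = cr.an_predict(p_true, co2) + rng.normal(0, 0.05, co2.size)
        base = cr.default_factor_levels()
        levels = cr.FactorLevels(
            intensities=(90.0,), spectra=(base.spectra[0],),
            reference_intensity=90.0, reference_spectrum=base.spectra[0].label,
        )
        df = pd.DataFrame({
            "plant_id": "P1", "spectrum": base.spectra[0].label,
            "intensity": 90.0, "co2": co2, "replicate": 1, "an": an,
        })
        start = curvewise_start(df, levels)
        assert 50.0 < start.intercepts["b"] < 5000.0
        assert start.intercepts["b"] == pytest.approx(1264.96, rel=0.25)

    def test_underdetermined_cell_is_named(self):
        df = pd.DataFrame({
            "plant_id": "P1", "spectrum": "100B", "intensity": 350.0,
            "co2": [200.0, 200.0, 400.0], "replicate": [1, 2, 3],
            "an": [1.0, 1.1, 2.0],
        })
        base = cr.default_factor_levels()
        levels = cr.FactorLevels(
            intensities=(350.0,),
            spectra=tuple(s for s in base.spectra if s.label == "100B"),
            reference_intensity=350.0, reference_spectrum="100B",
        )
        with pytest.raises(ValueError, match="100B"):
            curvewise_start(df, levels)


class TestFitModel:
    def test_near_noise_free_recovery(self, reference_effects):
        """With a tiny noise floor, ML recovers the generating fixed effects
        essentially exactly."""
        truth = cr.SimulationTruth(
            sigma_u=0.0,
            residual_sds={i: 0.001 for i in reference_effects.levels.intensities},
            plants_per_spectrum=1,
            seed=0,
        )
        df = cr.simulate_experiment(truth)
        fit = fit_model(df, FitConfig(maxiter=5000, compute_hessian=False))
        for s in reference_effects.levels.spectrum_labels:
            for i in reference_effects.levels.intensities:
                for p in ("c", "d"):
                    got = fit.effects.value(p, s, i)
                    want = reference_effects.value(p, s, i)
                    assert got == pytest.approx(want, rel=1e-3, abs=5e-3), (p, s, i)
                assert fit.effects.value("b", s, i) == pytest.approx(
                    reference_effects.value("b", s, i), rel=1e-3
                )

    def test_degenerate_equivalence_with_plain_nls(self):
        """sigma_u = 0 and one shared residual SD: the ML fixed effects agree
        with unweighted nonlinear least squares (independent scipy oracle)."""
        base = cr.default_factor_levels()
        levels = cr.FactorLevels(
            intensities=(350.0,),
            spectra=tuple(s for s in base.spectra
                          if s.label in ("37R36G27B", "100B", "20R80B")),
            reference_intensity=350.0,
            reference_spectrum="37R36G27B",
        )
        eff_true = cr.EffectsTable(
            levels,
            intercepts={"c": -6.0, "d": 10.0, "b": 300.0},
            intensity_offsets={p: {} for p in ("c", "d", "b")},
            spectrum_offsets={
                "c": {s: -0.3 for s in levels.nonref_spectra},
                "d": {s: 1.2 for s in levels.nonref_spectra},
                "b": {s: -10.0 for s in levels.nonref_spectra},
            },
        )
        truth = cr.SimulationTruth(
            effects=eff_true, sigma_u=0.0,
            residual_sds={350.0: 0.4},
            plants_per_spectrum=2, seed=13,
        )
        proto = cr.protocol_sequence(intensities=levels.intensities)
        df = cr.simulate_experiment(truth, proto)
        fit = fit_model(
            df,
            FitConfig(maxiter=5000, compute_hessian=False, fix_sigma_u=0.0),
            levels=levels,
        )

        design = build_design(df, levels)
        nf = design.n_fixed

        def nls_resid(beta):
            th = np.r_[beta, np.log(1e-8), np.zeros(len(levels.intensities))]
            eff = effects_from_theta(th, design)
            pred = np.array([
                cr.an_predict(
                    cr.assemble_params(eff, levels.spectrum_labels[s], levels.intensities[i]),
                    c,
                )
                for s, i, c in zip(design.spec_idx, design.int_idx, design.co2)
            ])
            return design.an - pred

        start = theta_from_effects(curvewise_start(df, levels), design)[:nf]
        sol = optimize.least_squares(nls_resid, start, method="lm", xtol=1e-12, ftol=1e-12)
        rel = np.abs(fit.theta[:nf] - sol.x) / np.maximum(1e-2, np.abs(sol.x))
        assert rel.max() < 1e-3

    def test_loglik_at_truth_not_above_optimum(self, fitted_default, simulated_default):
        truth = cr.SimulationTruth(seed=1)
        eff = truth.effects
        eff.sigma_u, eff.residual_sds = truth.sigma_u, truth.residual_sds
        ll_truth = cr.marginal_loglik(eff, simulated_default)
        assert ll_truth <= fitted_default.loglik + 1e-6

    def test_fit_reports_convergence_and_se(self, fitted_default):
        assert fitted_default.converged
        assert fitted_default.method == "ML"
        assert fitted_default.standard_errors is not None
        assert np.all(fitted_default.standard_errors[:48] > 0)
        # vcov symmetric PSD
        v = fitted_default.vcov
        assert np.allclose(v, v.T, atol=1e-10)
        assert np.linalg.eigvalsh(v).min() > -1e-8

    def test_estimate_near_truth_for_headline_cell(self, fitted_default):
        w = _combo_weights(fitted_default.design, "d", "37R36G27B", 700.0)
        est, se = fitted_default.linear_combo(w)
        assert abs(est - 12.01) <= 3 * se

    def test_iteration_cap_returns_partial_result(self, simulated_default):
        fit = fit_model(simulated_default, FitConfig(maxiter=3, compute_hessian=False))
        assert not fit.converged
        assert np.isfinite(fit.loglik)


class TestDiagnostics:
    @staticmethod
    def _manual_fit(effects):
        return FitResult(
            effects=effects, theta=np.empty(0), coef_names=[],
            standard_errors=None, vcov=None, loglik=0.0,
            converged=True, n_iter=0,
        )

    def test_zero_noise_residuals_vanish(self, reference_effects):
        truth = cr.SimulationTruth(
            sigma_u=0.0,
            residual_sds={i: 1e-6 for i in reference_effects.levels.intensities},
            plants_per_spectrum=1, seed=0,
        )
        df = cr.simulate_experiment(truth)
        eff = truth.effects
        eff.sigma_u, eff.residual_sds = 0.0, {
            i: 1.0 for i in reference_effects.levels.intensities
        }
        table, summary = cr.residual_diagnostics(self._manual_fit(eff), df)
        assert np.abs(table.residual).max() < 1e-4

    def test_correctly_specified_noise_passes_qq(self, fitted_default, simulated_default):
        table, summary = cr.residual_diagnostics(fitted_default, simulated_default)
        assert summary["n"] == 5040
        assert summary["qq_correlation"] > 0.99
        assert abs(summary["excess_kurtosis"]) < 0.5

    def test_heavy_tailed_noise_is_detected(self, reference_effects):
        """t3 noise injected in place of the Gaussian residuals shows up as
        excess kurtosis above 1."""
        rng = np.random.default_rng(17)
        truth = cr.SimulationTruth(
            sigma_u=0.0,
            residual_sds={i: 1e-9 for i in reference_effects.levels.intensities},
            plants_per_spectrum=3, seed=0,
        )
        df = cr.simulate_experiment(truth)
        df = df.assign(an=df.an + 0.5 * rng.standard_t(3, size=len(df)))
        eff = truth.effects
        eff.sigma_u, eff.residual_sds = 0.0, {
            i: 0.5 * np.sqrt(3.0) for i in reference_effects.levels.intensities
        }
        _, summary = cr.residual_diagnostics(self._manual_fit(eff), df)
        assert summary["excess_kurtosis"] > 1.0
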