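"""Tests of the comparative experiments and the response-surface regression."""

import numpy as np
import pandas as pd
import pytest

from neocolumn.column import build_column
from neocolumn.config import AEIF_FIELDS
from neocolumn.experiments import (
    SURFACE_PREDICTORS,
    fit_quadratic_response,
    morph_table,
    noise_robustness,
    normalized_to_table,
    run_assay,
    run_response_surface,
    sweep_background,
    sweep_std_recovery,
)
from neocolumn.stimulus import load_pattern


class TestMorph:
    def test_noop_morph_is_identity(self, config):
        base = config.aeif_tables["rodent"]
        morphed = morph_table(base, base, "V_th")
        assert morphed == base

    def test_scoped_morph_changes_exactly_three_entries(self, config):
        base = config.aeif_tables["rodent"]
        scope = [("L2/3", "LL-IN"), ("L5", "LL-IN"), ("L6", "LL-IN")]
        morphed = morph_table(base, config.aeif_tables["human"], "V_th", scope=scope)
        n_changed = sum(
            morphed[layer][cls] != base[layer][cls]
            for layer in base
            for cls in base[layer]
        )
        assert n_changed == 3

    def test_composition_of_all_morphs_equals_species_swap(self, config):
        """Morphing C, g_L, E_L, V_r and V_th in sequence from rodent to
        human reproduces the full human parameter table."""
        table = config.aeif_tables["rodent"]
        for param in ("C", "g_L", "E_L", "V_r", "V_th"):
            table = morph_table(table, config.aeif_tables["human"], param)
        net_morphed = build_column(config, seed=1, table=table)
        net_human = build_column(config, species="human", seed=1)
        assert np.array_equal(net_morphed.aeif, net_human.aeif)

    def test_factor_morph_scales_threshold_distance(self, config):
        base = config.aeif_tables["human"]
        morphed = morph_table(base, base, "V_th", factor=1.25)
        blk, mblk = base["L5"]["PC"], morphed["L5"]["PC"]
        assert mblk.V_th == pytest.approx(blk.E_L + 1.25 * (blk.V_th - blk.E_L))

    def test_unknown_parameter_rejected(self, config):
        with pytest.raises(ValueError, match="unknown parameter"):
            morph_table(config.aeif_tables["rodent"], config.aeif_tables["human"], "V_peak")


class TestAssayPlumbing:
    def test_reports_are_deterministic(self, config):
        pat = load_pattern("square")
        a = run_assay(config, "rodent", pat, n_repeats=1, seed=12)
        b = run_assay(config, "rodent", pat, n_repeats=1, seed=12)
        pd.testing.assert_frame_equal(a, b)

    def test_background_sweep_default_level_matches_baseline(self, config):
        df = sweep_background(
            config, levels=((250.0, 200.0),), patterns=("square",), n_repeats=1, seed=3
        )
        base = run_assay(config, "rodent", load_pattern("square"), n_repeats=1, seed=3)
        for metric in ("baseline_density", "pa_density", "accuracy"):
            assert df[metric].iloc[0] == base[metric].iloc[0]

    def test_background_sweep_row_count(self, config):
        df = sweep_background(
            config,
            levels=((250.0, 200.0), (300.0, 250.0), (200.0, 150.0)),
            patterns=("star",),
            n_repeats=1,
            seed=1,
        )
        assert len(df) == 3 and df["condition"].nunique() == 3

    def test_std_sweep_baseline_value_matches(self, config):
        df = sweep_std_recovery(
            config, (config.stp.tau_rec,), patterns=("square",), n_repeats=1, seed=4
        )
        base = run_assay(config, "human", load_pattern("square"), n_repeats=1, seed=4)
        assert df["accuracy"].iloc[0] == base["accuracy"].iloc[0]

    def test_noise_zero_equals_clean_assay(self, config):
        df = noise_robustness(
            config, proportions=(0.0,), species=("human",), n_repeats=1, seed=6
        )
        base = run_assay(config, "human", load_pattern("square"), n_repeats=1, seed=6)
        assert df["accuracy"].iloc[0] == base["accuracy"].iloc[0]


class TestQuadraticFit:
    def _synthetic(self, rng, n=60, noise=0.0):
        X = rng.random((n, 5))
        beta0 = 71.8
        lin = np.array([3.3, 0.1, 1.5, 1.4, 1.7])
        quad = np.array([-0.8, -1.9, 2.0, 1.7, 2.2])
        y = beta0 + X @ lin + (X**2) @ quad
        if noise:
            y = y + rng.normal(0, noise, n)
        return X, y, beta0, lin, quad

    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(8)
        X, y, beta0, lin, quad = self._synthetic(rng)
        fit = fit_quadratic_response(X, y)
        assert fit.intercept == pytest.approx(beta0, abs=1e-8)
        assert np.allclose(list(fit.linear.values()), lin, atol=1e-8)
        assert np.allclose(list(fit.quadratic.values()), quad, atol=1e-8)

    def test_iterative_initialized_at_one_matches_ols(self):
        rng = np.random.default_rng(9)
        X, y, *_ = self._synthetic(rng, noise=1.0)
        ols = fit_quadratic_response(X, y)
        it = fit_quadratic_response(X, y, method="iterative")
        # agreement to the iterative solver's stopping precision
        assert it.intercept == pytest.approx(ols.intercept, abs=1e-4)
        for k in ols.linear:
            assert it.linear[k] == pytest.approx(ols.linear[k], abs=1e-4)

    def test_constant_response_gives_flat_surface(self):
        rng = np.random.default_rng(10)
        X = rng.random((40, 5))
        fit = fit_quadratic_response(X, np.full(40, 83.0))
        assert fit.intercept == pytest.approx(83.0, abs=1e-8)
        assert np.allclose(list(fit.linear.values()), 0.0, atol=1e-8)
        assert np.allclose(list(fit.quadratic.values()), 0.0, atol=1e-8)

    def test_vertex_form_matches_completed_square(self):
        # single predictor: y = 4 + 2x + 3x^2 = 3 (x + 1/3)^2 + 4 - 1/3
        X = np.linspace(0, 1, 9).reshape(-1, 1)
        y = 4.0 + 2.0 * X[:, 0] + 3.0 * X[:, 0] ** 2
        fit = fit_quadratic_response(X, y, predictors=("x",))
        x_v, gamma = fit.vertex_form()["x"]
        assert x_v == pytest.approx(-1.0 / 3.0, abs=1e-8)
        assert gamma == pytest.approx(3.0, abs=1e-8)
        assert fit.vertex_intercept == pytest.approx(4.0 - 1.0 / 3.0, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.random((40, 5))
        X[:, 2] = 0.5  # constant predictor
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_quadratic_response(X, np.zeros(40))

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="at least 11"):
            fit_quadratic_response(rng.random((10, 5)), np.zeros(10))

    def test_predictions_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(13)
        X, y, *_ = self._synthetic(rng, noise=0.5)
        fit = fit_quadratic_response(X, y)
        scale, shift = 3.7, -1.2
        fit2 = fit_quadratic_response(scale * X + shift, y)
        assert np.allclose(fit2.predict(scale * X + shift), fit.predict(X), atol=1e-7)


class TestResponseSurfaceExperiment:
    def test_normalized_endpoints_reproduce_species_values(self, config):
        t0 = normalized_to_table(config, [0.0] * 5)
        t1 = normalized_to_table(config, [1.0] * 5)
        for name, layer, cls, fld in SURFACE_PREDICTORS:
            assert getattr(t0[layer][cls], fld) == getattr(
                config.aeif_tables["rodent"][layer][cls], fld
            )
            assert getattr(t1[layer][cls], fld) == getattr(
                config.aeif_tables["human"][layer][cls], fld
            )

    def test_surface_recovers_planted_quadratic(self, config, monkeypatch):
        """With the assay stubbed by a known quadratic in the normalized
        parameters, the sweep + fit pipeline recovers it."""
        lin = np.array([3.3, 0.1, 1.5, 1.4, 1.7])
        quad = np.array([-0.8, -1.9, 2.0, 1.7, 2.2])
        names = [p[0] for p in SURFACE_PREDICTORS]

        def fake_assay(cfg, species, pattern, n_repeats=None, seed=0, *, table=None, **kw):
            x = []
            for (name, layer, cls, fld) in SURFACE_PREDICTORS:
                v = getattr(table[layer][cls], fld)
                v0 = getattr(cfg.aeif_tables["rodent"][layer][cls], fld)
                v1 = getattr(cfg.aeif_tables["human"][layer][cls], fld)
                x.append((v - v0) / (v1 - v0))
            x = np.asarray(x)
            acc = 71.8 + x @ lin + (x**2) @ quad
            return pd.DataFrame([{"accuracy": acc}])

        import neocolumn.experiments as exps

        monkeypatch.setattr(exps, "run_assay", fake_assay)
        samples, fit = run_response_surface(config, n_samples=25, n_repeats=1, seed=2)
        assert list(samples.columns[:5]) == names
        assert fit.intercept == pytest.approx(71.8, abs=1e-6)
        assert np.allclose(list(fit.linear.values()), lin, atol=1e-6)
        assert np.allclose(list(fit.quadratic.values()), quad, atol=1e-6)
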