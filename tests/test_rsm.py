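"""Response-surface fitting, diagnostics (R2/Q2/reproducibility/lack of
fit) and backward refinement."""

import numpy as np
import pytest
from scipy import stats

import ionopt as io
from ionopt.design import generate_ccd, generate_ffd
from ionopt.errors import AliasedTermsError, NotComputableError
from ionopt.factors import ccd_factors, screening_factors
from ionopt.rsm import (
    QuadraticModel,
    build_model_matrix,
    fit_ols,
    lack_of_fit,
    predict,
    predict_natural,
    q2_press,
    refine_model,
    reproducibility,
)
from ionopt.terms import Term, linear_terms, quadratic_terms


def _replicated_y(design, f_of_coded, noise_sd=0.0, seed=0, n_rep=2):
    """Replicate-level responses exp(f + eps) aligned with the design."""
    rng = np.random.default_rng(seed)
    X = design.coded_array()
    f = f_of_coded(X)
    y = np.repeat(f, n_rep) + rng.normal(0, noise_sd, n_rep * len(f))
    return np.exp(y) * 1e4


class TestModelMatrix:
    def test_center_row_zeroes(self, ccd_design):
        terms = quadratic_terms(ccd_design.factor_names)
        X = build_model_matrix(ccd_design, terms)
        center = [i for i, r in enumerate(ccd_design.rows) if r.point_type == "center"]
        for i in center:
            assert X[i, 0] == 1.0
            assert np.all(X[i, 1:] == 0.0)

    def test_ffd_linear_columns_orthogonal(self, ffd_design):
        design, _ = ffd_design
        import dataclasses

        fact = dataclasses.replace(
            design, rows=[r for r in design.rows if r.point_type == "factorial"]
        )
        X = build_model_matrix(fact, linear_terms(design.factor_names))
        gram = X.T @ X
        assert np.allclose(gram, np.diag(np.diag(gram)))

    def test_interaction_sign_rule(self):
        from ionopt.terms import build_matrix

        X = np.array([[1.0, -1.0]])
        out = build_matrix(X, ["IntT", "CID"], [Term("interaction", ("IntT", "CID"))])
        assert out[0, 0] == -1.0


class TestFitOLS:
    def test_noise_free_recovery(self, ccd_design):
        truth = {
            "1": 9.2 + np.log(1e4),  # the helper scales responses by 1e4
            "CID": 0.2,
            "IntT": 0.15,
            "CID^2": -0.1,
            "CID*IntT": 0.05,
        }

        def f(X):
            c, t = X[:, 0], X[:, 1]
            return 9.2 + 0.2 * c + 0.15 * t - 0.1 * c**2 + 0.05 * c * t

        y = _replicated_y(ccd_design, f)
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        for name, b in truth.items():
            assert m.coefficient(name) == pytest.approx(b, abs=1e-8)
        assert m.r2 == pytest.approx(1.0, abs=1e-12)
        assert m.q2 == pytest.approx(1.0, abs=1e-10)

    def test_replicate_perturbation_shifts_intercept(self, ffd_design):
        """Perturbing one of two replicates by delta moves the grand-mean
        intercept by delta / (2 * n_runs) on an orthogonal design."""
        design, _ = ffd_design
        import dataclasses

        fact = dataclasses.replace(
            design, rows=[r for r in design.rows if r.point_type == "factorial"]
        )
        y = np.full(32, 100.0)
        m0 = fit_ols(fact, y, linear_terms(design.factor_names))
        delta = 8.0
        y2 = y.copy()
        y2[0] += delta
        m1 = fit_ols(fact, y2, linear_terms(design.factor_names))
        shift = m1.coefficient("1") - m0.coefficient("1")
        assert shift == pytest.approx(delta / 2 / 16)

    def test_aliased_terms_error_names_confounding(self, ffd_design):
        design, _ = ffd_design
        terms = linear_terms(design.factor_names) + [
            Term("interaction", ("IntV", "IntT")),
            Term("interaction", ("HG", "HB")),  # aliased with IntV*IntT
        ]
        y = np.full(38, 50.0)
        with pytest.raises(AliasedTermsError) as err:
            fit_ols(design, y, terms)
        named = set(err.value.terms)
        assert {"IntV*IntT", "HG*HB"} <= named
        assert "DL*CID" in named  # third member of the alias chain

    def test_significance_is_ci_excluding_zero(self, ccd_design):
        y = _replicated_y(
            ccd_design, lambda X: 9.0 + 0.3 * X[:, 0], noise_sd=0.04, seed=1
        )
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        sig = {t.name for t in m.significant_terms()}
        assert "CID" in sig


class TestLackOfFit:
    def test_pure_replicate_noise_gives_p_one(self, ccd_design):
        rng = np.random.default_rng(5)
        X = ccd_design.coded_array()
        f = 9.0 + 0.2 * X[:, 0] - 0.1 * X[:, 1] ** 2
        eps = rng.normal(0, 0.05, len(f))
        # same value for both replicates of a run: run means sit exactly on
        # a quadratic surface, so all residual SS is pure error... instead,
        # make replicates symmetric around the surface value
        y = np.exp(np.column_stack([f + eps, f - eps]).ravel()) * 1e4
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        F, p = lack_of_fit(m)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0)

    def test_detects_cubic_contamination(self, ccd_design):
        """Cubic contamination at 10x the noise SD is flagged (p < 0.05) in
        at least 95% of seeded simulations."""
        sd = 0.04
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            y = _replicated_y(
                ccd_design,
                lambda X: 0.2 * X[:, 0] - 0.1 * X[:, 0] ** 2 + 10 * sd * X[:, 1] ** 3,
                noise_sd=sd,
                seed=s,
            )
            m = fit_ols(
                ccd_design,
                y,
                quadratic_terms(ccd_design.factor_names),
                transform="log",
            )
            _, p = lack_of_fit(m)
            hits += p < 0.05
        assert hits >= 0.95 * n_sim

    def test_matches_hand_computed_anova(self):
        """Balanced two-level toy: F statistic equals the explicit
        SS decomposition done with independent arithmetic."""
        factors = [io.Factor("A", "", -1, 1, 0.01)]
        from ionopt.design import DesignRow, DesignMatrix

        rows = [
            DesignRow(1, "factorial", np.array([-1.0]), np.array([-1.0]), 2),
            DesignRow(2, "factorial", np.array([0.0]), np.array([0.0]), 2),
            DesignRow(3, "factorial", np.array([1.0]), np.array([1.0]), 2),
            DesignRow(4, "factorial", np.array([0.5]), np.array([0.5]), 2),
        ]
        design = DesignMatrix(factors=factors, rows=rows, design_kind="ofat")
        y = np.array([1.0, 1.2, 2.0, 2.2, 3.4, 3.0, 2.9, 2.7])
        m = fit_ols(design, y, linear_terms(["A"]))
        F, p = lack_of_fit(m)
        # independent decomposition
        x = np.array([-1, -1, 0, 0, 1, 1, 0.5, 0.5])
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        ss_res = np.sum(resid**2)
        means = {v: y[x == v].mean() for v in np.unique(x)}
        ss_pe = sum(np.sum((y[x == v] - means[v]) ** 2) for v in np.unique(x))
        df_pe, df_lof = 4, 4 - 2
        F_hand = ((ss_res - ss_pe) / df_lof) / (ss_pe / df_pe)
        assert F == pytest.approx(F_hand)
        assert p == pytest.approx(float(stats.f.sf(F_hand, df_lof, df_pe)))

    def test_single_replicates_not_computable(self):
        design = generate_ccd(ccd_factors(), alpha=1.35, n_center=1, n_replicates=1)
        y = np.exp(np.random.default_rng(0).normal(9, 0.1, design.n_runs()))
        m = fit_ols(design, y, quadratic_terms(design.factor_names), transform="log")
        with pytest.raises(NotComputableError):
            lack_of_fit(m)

    def test_anova_sum_of_squares_conservation(self, ccd_design):
        """SS_tot = SS_model + SS_lof + SS_pe."""
        y = _replicated_y(
            ccd_design,
            lambda X: 0.2 * X[:, 0] + 0.1 * X[:, 1],
            noise_sd=0.05,
            seed=11,
        )
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        ly = np.log(y)
        ss_tot = np.sum((ly - ly.mean()) ** 2)
        resid = ly - m._X @ m.coefficients
        ss_res = np.sum(resid**2)
        ss_model = ss_tot - ss_res
        keys = m._settings_key
        ss_pe = sum(
            np.sum((ly[keys == k] - ly[keys == k].mean()) ** 2)
            for k in np.unique(keys)
        )
        ss_lof = ss_res - ss_pe
        assert ss_tot == pytest.approx(ss_model + ss_lof + ss_pe)


class TestQ2:
    def test_q2_equals_explicit_loo(self):
        """PRESS shortcut equals brute-force leave-one-out refitting on a
        5-point line with an outlier."""
        factors = [io.Factor("A", "", -2, 2, 0.01)]
        from ionopt.design import DesignRow, DesignMatrix

        xs = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        rows = [
            DesignRow(i + 1, "factorial", np.array([x / 2]), np.array([x]), 1)
            for i, x in enumerate(xs)
        ]
        design = DesignMatrix(factors=factors, rows=rows, design_kind="ofat")
        y = np.array([1.0, 2.1, 2.9, 4.2, 9.0])  # last point is the outlier
        m = fit_ols(design, y, linear_terms(["A"]))
        press = 0.0
        X = m._X
        for i in range(5):
            mask = np.arange(5) != i
            beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
            press += (y[i] - X[i] @ beta) ** 2
        q2_loo = 1 - press / np.sum((y - y.mean()) ** 2)
        assert q2_press(m) == pytest.approx(q2_loo)

    def test_q2_never_exceeds_r2(self, ccd_design):
        for seed in range(25):
            y = _replicated_y(
                ccd_design,
                lambda X: 0.1 * X[:, 0] - 0.05 * X[:, 2],
                noise_sd=0.1,
                seed=seed,
            )
            m = fit_ols(
                ccd_design,
                y,
                quadratic_terms(ccd_design.factor_names),
                transform="log",
            )
            assert m.q2 <= m.r2 + 1e-12


class TestReproducibility:
    def test_identical_replicates_give_one(self, ccd_design):
        y = _replicated_y(ccd_design, lambda X: 0.3 * X[:, 0])
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        assert reproducibility(m) == pytest.approx(1.0)

    def test_replicate_scatter_equal_to_total(self):
        """All variation within replicates -> reproducibility near zero."""
        design = generate_ccd(ccd_factors(), alpha=1.35, n_center=3)
        rng = np.random.default_rng(2)
        y = np.exp(rng.normal(9.0, 0.2, 34))
        m = fit_ols(design, y, [Term("intercept")], transform="log")
        assert abs(reproducibility(m)) < 0.35

    def test_matches_direct_formula(self):
        design, resp = io.generate_regime("ccd", 7)
        m = fit_ols(
            design,
            resp,
            quadratic_terms(design.factor_names),
            transform="log",
            analyte="PGE2-d4",
        )
        # independent recomputation from sums of squares
        ly = m._y
        keys = m._settings_key
        ss_pe, df_pe = 0.0, 0
        for k in np.unique(keys):
            grp = ly[keys == k]
            ss_pe += np.sum((grp - grp.mean()) ** 2)
            df_pe += grp.size - 1
        ms_tot = np.sum((ly - ly.mean()) ** 2) / (ly.size - 1)
        assert reproducibility(m) == pytest.approx(1 - (ss_pe / df_pe) / ms_tot)


class TestRefinement:
    def test_recovers_active_structure(self, ccd_design):
        """Ground truth with only IntT and CID effects: refinement keeps
        exactly that main-effect structure in >= 90% of 200 seeded runs."""
        hits = 0
        for seed in range(200):
            y = _replicated_y(
                ccd_design,
                lambda X: 0.25 * X[:, 0] + 0.3 * X[:, 1] - 0.15 * X[:, 0] ** 2,
                noise_sd=0.04,
                seed=seed,
            )
            full = fit_ols(
                ccd_design,
                y,
                quadratic_terms(ccd_design.factor_names),
                transform="log",
            )
            refined = refine_model(full, ccd_design, y)
            mains = {t.factors[0] for t in refined.terms if t.kind == "linear"}
            hits += mains == {"CID", "IntT"}
        assert hits >= 180

    def test_all_noise_tends_to_intercept_only(self, ccd_design):
        rng_hits = 0
        for seed in range(20):
            y = _replicated_y(ccd_design, lambda X: 0.0 * X[:, 0], 0.04, seed)
            full = fit_ols(
                ccd_design,
                y,
                quadratic_terms(ccd_design.factor_names),
                transform="log",
            )
            refined = refine_model(full, ccd_design, y)
            rng_hits += len(refined.terms) == 1
        # family-adjusted retention: most runs collapse to the intercept
        assert rng_hits >= 13

    def test_heredity_protects_weak_main_effect(self, ccd_design):
        """A strong IntT*CID interaction keeps the weak IntT main effect."""
        y = _replicated_y(
            ccd_design,
            lambda X: 0.3 * X[:, 0] + 0.0 * X[:, 1] + 0.4 * X[:, 0] * X[:, 1],
            noise_sd=0.02,
            seed=3,
        )
        full = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        refined = refine_model(full, ccd_design, y)
        names = set(refined.term_names)
        assert "CID*IntT" in names
        assert "IntT" in names  # retained by heredity despite null coefficient

    def test_idempotent(self, ccd_design):
        y = _replicated_y(
            ccd_design, lambda X: 0.2 * X[:, 0] - 0.1 * X[:, 1] ** 2, 0.04, seed=9
        )
        full = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        once = refine_model(full, ccd_design, y)
        twice = refine_model(once, ccd_design, y)
        assert once.term_names == twice.term_names
        assert np.allclose(once.coefficients, twice.coefficients)


class TestPredict:
    def test_center_point_returns_intercept(self, ccd_design):
        y = _replicated_y(ccd_design, lambda X: 9.0 + 0.2 * X[:, 0])
        m = fit_ols(
            ccd_design, y, quadratic_terms(ccd_design.factor_names), transform="log"
        )
        mean, se = predict(m, [0, 0, 0])
        assert mean == pytest.approx(np.exp(m.coefficient("1")))
        assert se > 0

    def test_pure_quadratic_stationary_at_zero(self):
        factors = [io.Factor("A", "", -2, 2, 0.01)]
        from ionopt.design import DesignRow, DesignMatrix

        xs = np.linspace(-1.5, 1.5, 7)
        rows = [
            DesignRow(i + 1, "factorial", np.array([x]), np.array([2 * x]), 1)
            for i, x in enumerate(xs)
        ]
        design = DesignMatrix(factors=factors, rows=rows, design_kind="ofat")
        y = 1 - xs**2 + 2.0
        m = fit_ols(design, y, quadratic_terms(["A"]))
        grid = np.linspace(-1, 1, 201)
        preds = [predict(m, [g])[0] for g in grid]
        assert grid[int(np.argmax(preds))] == pytest.approx(0.0, abs=1e-9)

    def test_extrapolation_warning(self, refined_models_seed42):
        m = refined_models_seed42["PGE2-d4"]
        with pytest.warns(UserWarning, match="extrapolation"):
            predict(m, [2.0, 0, 0])

    def test_pge2_surface_optimum_window(self, noise_free_models):
        """The fitted PGE2-d4 surface peaks at a CID between 210 and 270 kPa
        at 2 kV interface voltage."""
        m = noise_free_models["PGE2-d4"]
        cids = np.arange(120, 271, 1.0)
        preds = [predict_natural(m, [c, 375.0, 2.0])[0] for c in cids]
        best = cids[int(np.argmax(preds))]
        assert 210 <= best <= 270
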