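"""Design construction: coded/natural mapping, fractional factorial alias
algebra, central composite geometry, D-optimal exchange."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ionopt as io
from ionopt.design import (
    design_from_csv,
    design_to_csv,
    generate_ccd,
    generate_d_optimal,
    generate_ffd,
)
from ionopt.errors import DesignInfeasibleError, InvalidValueError
from ionopt.factors import Factor, ccd_factors, ce_factors, screening_factors
from ionopt.terms import Term, build_matrix, linear_terms, quadratic_terms


def _factor(name):
    return {f.name: f for f in ccd_factors()}[name]


class TestCoding:
    @pytest.mark.parametrize(
        "name, coded, expected",
        [
            ("IntV", -1.35, 1.8),  # star point rounds onto the printed level
            ("IntV", 1.35, 3.2),
            ("CID", -1.35, 120.0),  # raw 120.75 -> 5 kPa step
            ("CID", 1.35, 270.0),
            ("IntT", -1.35, 282.0),  # raw 282.5, round-half-even
            ("IntT", 1.35, 400.0),  # hard ceiling clips the +alpha point
        ],
    )
    def test_decode_star_points(self, name, coded, expected):
        assert _factor(name).decode(coded) == expected

    def test_code_midpoint_is_zero(self):
        f = Factor("IntT", "degC", 300, 400)
        assert f.code(350.0) == 0.0

    def test_nonfinite_rejected(self):
        f = _factor("CID")
        with pytest.raises(InvalidValueError):
            f.code(float("nan"))
        with pytest.raises(InvalidValueError):
            f.decode(float("inf"))

    @given(st.sampled_from(ccd_factors()), st.integers(min_value=0, max_value=200))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_settable_values(self, factor, k):
        """decode(code(v)) = v for any settable natural value."""
        n_steps = int(round((factor.high - factor.low) / factor.rounding_step))
        v = factor.low + (k % (n_steps + 1)) * factor.rounding_step
        v = round(v, 10)
        assert factor.decode(factor.code(v)) == pytest.approx(v, abs=1e-9)


class TestFractionalFactorial:
    def test_shape_and_resolution(self, ffd_design):
        design, alias = ffd_design
        assert design.n_runs() == 19
        types = [r.point_type for r in design.rows]
        assert types.count("factorial") == 16 and types.count("center") == 3
        assert alias.resolution == 4
        assert design.generators == ("E=ABC", "F=BCD", "G=ACD")

    def test_balance_and_orthogonality(self, ffd_design):
        design, _ = ffd_design
        fact = np.array([r.coded for r in design.rows if r.point_type == "factorial"])
        assert fact.shape == (16, 7)
        assert np.all(np.sum(fact == 1, axis=0) == 8)
        assert np.all(np.sum(fact == -1, axis=0) == 8)
        gram = fact.T @ fact
        assert np.allclose(gram - np.diag(np.diag(gram)), 0)

    def test_center_rows_all_zero(self, ffd_design):
        design, _ = ffd_design
        for r in design.rows:
            if r.point_type == "center":
                assert np.all(r.coded == 0)

    def test_two_factor_full_factorial(self):
        factors = ccd_factors()[:2]
        design, alias = generate_ffd(factors, p=0, n_center=0)
        assert design.n_runs() == 4
        assert alias.resolution == "full"
        assert not alias.defining_words

    def test_defining_relation_matches_brute_force(self, ffd_design):
        """Expand I = ABCE = BCDF = ACDG by explicit mod-2 multiplication of
        every generator subset and compare with the design's relation."""
        _, alias = ffd_design
        gens = [frozenset("ABCE"), frozenset("BCDF"), frozenset("ACDG")]
        words = set()
        for r in range(1, 4):
            for combo in itertools.combinations(gens, r):
                w = frozenset()
                for g in combo:
                    w = frozenset(w ^ g)
                words.add(w)
        assert set(alias.defining_words) == words
        assert len(words) == 7
        assert min(len(w) for w in words) == 4

    def test_alias_map_two_factor_interactions(self, ffd_design):
        # with factors A..G = IntV,IntT,HG,DG,HB,DL,CID the AB interaction
        # is confounded with CE and FG
        _, alias = ffd_design
        assert alias.aliases_of(("IntV", "IntT")) == {("HG", "HB"), ("DL", "CID")}

    def test_alias_symmetry(self, ffd_design):
        _, alias = ffd_design
        amap = alias.alias_map()
        for eff, partners in amap.items():
            for p in partners:
                assert eff in amap[p]

    def test_main_effects_unaliased_through_order_two(self, ffd_design):
        design, alias = ffd_design
        for name in design.factor_names:
            assert alias.aliases_of((name,)) == set()

    def test_unattainable_resolution(self):
        with pytest.raises(DesignInfeasibleError):
            generate_ffd(screening_factors(), p=3, resolution_target=5)


class TestCentralComposite:
    def test_run_count_and_point_types(self, ccd_design):
        assert ccd_design.n_runs() == 17
        types = [r.point_type for r in ccd_design.rows]
        assert types.count("factorial") == 8
        assert types.count("axial") == 6
        assert types.count("center") == 3

    def test_axial_rows_vary_one_factor(self, ccd_design):
        for r in ccd_design.rows:
            if r.point_type == "axial":
                assert np.sum(r.coded != 0) == 1

    def test_axial_natural_levels_and_clip_annotation(self, ccd_design):
        names = ccd_design.factor_names
        axials = {}
        for r in ccd_design.rows:
            if r.point_type == "axial":
                j = int(np.nonzero(r.coded)[0][0])
                axials[(names[j], np.sign(r.coded[j]))] = r
        assert axials[("CID", -1)].natural[names.index("CID")] == 120.0
        assert axials[("CID", 1)].natural[names.index("CID")] == 270.0
        assert axials[("IntT", -1)].natural[names.index("IntT")] == 282.0
        hot = axials[("IntT", 1)]
        assert hot.natural[names.index("IntT")] == 400.0
        assert hot.clipped == ("IntT",)
        assert axials[("CID", -1)].clipped == ()
        assert axials[("IntV", -1)].natural[names.index("IntV")] == 1.8

    def test_face_centered_limit(self):
        design = generate_ccd(ccd_factors(), alpha=1.0, n_center=3)
        for f, col in zip(design.factors, design.natural_array().T):
            assert np.all(col >= f.low - 1e-9)
            assert np.all(col <= f.high + 1e-9)

    def test_invalid_alpha(self):
        with pytest.raises(InvalidValueError):
            generate_ccd(ccd_factors(), alpha=0.0)

    def test_unclipped_axial_symmetry(self):
        """Without hard bounds each axial pair is symmetric about center."""
        factors = [Factor("A", "", 0, 10), Factor("B", "", -5, 5)]
        design = generate_ccd(factors, alpha=1.35, n_center=1)
        coded = np.array([r.coded for r in design.rows if r.point_type == "axial"])
        assert np.allclose(sorted(coded.sum(axis=1)), [-1.35, -1.35, 1.35, 1.35])
        nat = np.array([r.natural for r in design.rows if r.point_type == "axial"])
        for j, f in enumerate(factors):
            vals = sorted(nat[np.nonzero(coded[:, j])[0], j])
            assert vals[0] + vals[1] == pytest.approx(2 * f.center)


def _exhaustive_logdet(candidates, terms, names, n_runs):
    X = build_matrix(candidates, names, terms)
    best, best_idx = -np.inf, None
    for idx in itertools.combinations(range(len(candidates)), n_runs):
        sign, ld = np.linalg.slogdet(X[list(idx)].T @ X[list(idx)])
        val = ld if sign > 0 else -np.inf
        if val > best:
            best, best_idx = val, idx
    return best, best_idx


class TestDOptimal:
    grid3 = np.array(list(itertools.product([-1.0, 0.0, 1.0], repeat=2)))
    factors2 = [Factor("x1", "", -1, 1, 0.01), Factor("x2", "", -1, 1, 0.01)]

    def test_four_runs_select_corners(self):
        terms = linear_terms(["x1", "x2"])
        design = generate_d_optimal(
            self.factors2, self.grid3, terms, n_runs=4, seed=1
        )
        picked = {tuple(r.coded) for r in design.rows}
        assert picked == {(-1, -1), (-1, 1), (1, -1), (1, 1)}
        best, _ = _exhaustive_logdet(self.grid3, terms, ["x1", "x2"], 4)
        assert design.log_det == pytest.approx(best)

    def test_all_candidates_returns_full_set(self):
        terms = linear_terms(["x1", "x2"])
        design = generate_d_optimal(
            self.factors2, self.grid3, terms, n_runs=9, seed=0
        )
        assert {tuple(r.coded) for r in design.rows} == {
            tuple(c) for c in self.grid3
        }

    def test_seed_reproducibility(self):
        terms = quadratic_terms(["x1", "x2"])
        a = generate_d_optimal(self.factors2, self.grid3, terms, n_runs=7, seed=3)
        b = generate_d_optimal(self.factors2, self.grid3, terms, n_runs=7, seed=3)
        assert np.array_equal(a.coded_array(), b.coded_array())

    @pytest.mark.parametrize("n_runs", [6, 7])
    def test_matches_exhaustive_on_small_grids(self, n_runs):
        terms = quadratic_terms(["x1", "x2"])
        best, _ = _exhaustive_logdet(self.grid3, terms, ["x1", "x2"], n_runs)
        design = generate_d_optimal(
            self.factors2, self.grid3, terms, n_runs=n_runs, seed=0
        )
        assert design.log_det == pytest.approx(best, abs=1e-9)

    def test_beats_random_subsets_on_ce_cid_grid(self):
        factors = ce_factors()
        cand = np.array(
            [
                [factors[0].code(ce), factors[1].code(cid)]
                for ce in np.arange(12, 28.1, 2)
                for cid in np.arange(190, 250.1, 10)
            ]
        )
        terms = quadratic_terms(["CE", "CID"])
        design = generate_d_optimal(factors, cand, terms, n_runs=14, seed=1)
        X = build_matrix(cand, ["CE", "CID"], terms)
        rng = np.random.default_rng(123)
        for _ in range(100):
            idx = rng.choice(len(cand), size=14, replace=False)
            sign, ld = np.linalg.slogdet(X[idx].T @ X[idx])
            assert design.log_det >= (ld if sign > 0 else -np.inf) - 1e-9

    def test_rank_deficiency_error(self):
        with pytest.raises(DesignInfeasibleError):
            generate_d_optimal(
                self.factors2,
                self.grid3,
                quadratic_terms(["x1", "x2"]),
                n_runs=3,
                seed=0,
            )


def test_design_csv_round_trip(tmp_path, ccd_design):
    path = tmp_path / "design.csv"
    design_to_csv(ccd_design, path)
    back = design_from_csv(path, ccd_design.factors, design_kind="ccd", alpha=1.35)
    assert back.n_runs() == ccd_design.n_runs()
    assert np.allclose(back.coded_array(), ccd_design.coded_array())
    assert np.allclose(back.natural_array(), ccd_design.natural_array())
    assert [r.point_type for r in back.rows] == [
        r.point_type for r in ccd_design.rows
    ]
    assert [r.n_replicates for r in back.rows] == [
        r.n_replicates for r in ccd_design.rows
    ]
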