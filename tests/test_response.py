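"""Selection-response engine and its closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimorph.gmatrix import MatrixModification, apply_modification, assemble
from dimorph.response import (
    SelectionGradient,
    SingleTraitParams,
    TwoTraitParams,
    both_selected_gradient,
    concordant_dominance_condition,
    conditional_response,
    d_statistic,
    d_threshold_to_variance_ratio,
    dimorphism_change_closed_form,
    modification_ratio_table,
    predict_response,
    single_trait_deltas,
    two_trait_both_selected,
    two_trait_indirect,
)

from .conftest import random_sexed_g


def one_trait_g(m, f, b):
    return assemble([[m]], [[f]], [[b]], ["T"], ["T"])


class TestPredictResponse:
    def test_identity_matrix_antagonistic(self):
        g = one_trait_g(1.0, 1.0, 0.0)
        grad = SelectionGradient.antagonistic(g, ["T"])
        resp = predict_response(g, grad)
        np.testing.assert_allclose(resp.dz.values, [0.35355339, -0.35355339])
        assert resp.delta_norm == pytest.approx(0.70710678)

    def test_half_factor_and_closed_form(self):
        # m = f = 1, b = 0.8, raw antagonistic beta (1, -1)
        g = one_trait_g(1.0, 1.0, 0.8)
        grad = SelectionGradient.custom([1.0, -1.0])
        resp = predict_response(g, grad)
        np.testing.assert_allclose(resp.dz.values, [0.1, -0.1])
        assert resp.dimorphism_change["T"] == pytest.approx(0.2)  # beta (gbar - b)

    def test_concordant_symmetric_no_dimorphism(self):
        g = one_trait_g(1.0, 1.0, 0.8)
        resp = predict_response(g, SelectionGradient.custom([1.0, 1.0]))
        assert resp.dimorphism_change["T"] == pytest.approx(0.0)

    def test_zero_gradient_rejected(self, rng):
        g = random_sexed_g(2, rng)
        with pytest.raises(ValueError, match="zero"):
            predict_response(g, SelectionGradient.custom(np.zeros(4)))

    def test_unit_total_norm_single_trait(self, rng):
        g = random_sexed_g(2, rng)
        grad = SelectionGradient.antagonistic(g, ["T1"])
        np.testing.assert_allclose(np.abs(grad.beta[grad.beta != 0]), 1 / np.sqrt(2))

    def test_linearity(self, rng):
        g = random_sexed_g(3, rng)
        b1 = rng.standard_normal(6)
        b2 = rng.standard_normal(6)
        r1 = predict_response(g, SelectionGradient.custom(b1))
        r2 = predict_response(g, SelectionGradient.custom(b2))
        r12 = predict_response(g, SelectionGradient.custom(b1 + b2))
        np.testing.assert_allclose(r12.dz.values, r1.dz.values + r2.dz.values,
                                   atol=1e-12)

    def test_vec_corr_one_under_concordant_sex_symmetry(self, rng):
        a = rng.standard_normal((3, 5))
        gm = a @ a.T
        b = (gm + gm.T) / 2 * 0.5
        g = assemble(gm, gm, b, ["a", "b", "c"], ["a", "b", "c"])
        resp = predict_response(g, SelectionGradient.concordant(g, ["a", "b"]))
        assert resp.vec_corr == pytest.approx(1.0)


class TestClosedFormEquivalence:
    @pytest.mark.parametrize("scheme", ["antagonistic", "concordant"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_engine(self, scheme, seed):
        rng = np.random.default_rng(seed)
        g = random_sexed_g(4, rng, n_male_only=1, n_female_only=2)
        builder = getattr(SelectionGradient, scheme)
        grad = builder(g, ["T1", "T3"])
        closed = dimorphism_change_closed_form(g, grad)
        engine = predict_response(g, grad).dimorphism_change
        np.testing.assert_allclose(closed.values, engine.values, atol=1e-12)

    def test_hand_values(self):
        g = one_trait_g(2.0, 1.0, 0.5)
        grad_a = SelectionGradient.custom([1.0, -1.0])
        grad_a = SelectionGradient(grad_a.beta, "antagonistic", ("T",), "raw")
        assert dimorphism_change_closed_form(g, grad_a)["T"] == pytest.approx(1.0)
        grad_c = SelectionGradient(np.array([1.0, 1.0]), "concordant", ("T",), "raw")
        assert dimorphism_change_closed_form(g, grad_c)["T"] == pytest.approx(0.5)

    def test_full_symmetry_concordant_zero(self, rng):
        a = rng.standard_normal((2, 4))
        gm = a @ a.T
        g = assemble(gm, gm, (gm * 0.3 + gm.T * 0.3) / 2, ["x", "y"], ["x", "y"])
        grad = SelectionGradient.concordant(g, ["x", "y"])
        np.testing.assert_allclose(
            dimorphism_change_closed_form(g, grad).values, 0.0, atol=1e-12
        )

    def test_custom_scheme_unsupported(self, rng):
        g = random_sexed_g(2, rng)
        with pytest.raises(ValueError, match="scheme"):
            dimorphism_change_closed_form(g, SelectionGradient.custom(np.ones(4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_antagonistic_depends_only_on_gbar_and_bs(self, seed):
        """Perturbing (G_M - G_F)/2 or B_A leaves every antagonistic
        dimorphism change unchanged."""
        rng = np.random.default_rng(seed)
        g = random_sexed_g(3, rng, scale=2.0)
        grad = SelectionGradient.antagonistic(g, ["T1", "T2", "T3"])
        base = predict_response(g, grad).dimorphism_change
        cov = g.cov.copy()
        k = 3
        # add a within-sex asymmetric perturbation and a B_A perturbation
        sym = rng.standard_normal((k, k))
        sym = (sym + sym.T) / 4
        cov[:k, :k] += sym
        cov[k:, k:] -= sym
        anti = rng.standard_normal((k, k)) / 4
        anti = anti - anti.T
        cov[:k, k:] += anti
        cov[k:, :k] += anti.T
        g2 = type(g)(g.variables, cov, validate=False)
        pert = predict_response(g2, grad).dimorphism_change
        np.testing.assert_allclose(pert.values, base.values, atol=1e-12)


class TestDStatistic:
    def test_equal_variances(self):
        assert d_statistic(1.0, 1.0) == 1.0

    def test_two_to_one(self):
        assert round(d_statistic(2.0, 1.0), 2) == 0.94
        assert d_statistic(2.0, 1.0) == pytest.approx(0.9428, abs=1e-4)

    def test_fourteen_to_one_halves(self):
        assert d_statistic(14.0, 1.0) == pytest.approx(0.4989, abs=1e-4)
        assert d_statistic(13.0, 1.0) > 0.5 > d_statistic(14.0, 1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            d_statistic(0.0, 1.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_range_and_symmetry(self, m, f):
        d = d_statistic(m, f)
        assert 0 < d <= 1 + 1e-12
        assert d == pytest.approx(d_statistic(f, m))


class TestSingleTrait:
    def test_perfect_correlation_blocks_antagonistic(self):
        p = SingleTraitParams(m=2.0, f=2.0, b=2.0)
        delta_a, _ = single_trait_deltas(p)
        assert delta_a == pytest.approx(0.0)

    def test_hand_values(self):
        p = SingleTraitParams(m=2.0, f=1.0, b=0.5, beta=1.0)
        delta_a, delta_c = single_trait_deltas(p)
        assert delta_a == pytest.approx(1.0)
        assert delta_c == pytest.approx(0.5)

    def test_rmf_form_equals_covariance_form(self):
        p = SingleTraitParams(m=3.0, f=1.5, b=1.2, beta=0.7)
        delta_a, _ = single_trait_deltas(p)
        assert delta_a == pytest.approx(p.beta * p.g_bar * (1 - p.d * p.r_mf))

    @given(st.floats(0.01, 50), st.floats(0.01, 50))
    @settings(max_examples=200, deadline=None)
    def test_concordant_magnitude_identity(self, m, f):
        """g_bar sqrt(1 - d^2) == |m - f| / 2, the algebraic identity
        linking the two printed forms of the concordant response."""
        g_bar = (m + f) / 2
        d = d_statistic(m, f)
        lhs = g_bar * np.sqrt(max(1 - d**2, 0.0))
        # when m ~ f to machine precision, 1 - d^2 cancels catastrophically
        # and the sqrt halves the remaining digits: tolerance ~ g_bar sqrt(eps)
        assert lhs == pytest.approx(abs(m - f) / 2, rel=1e-7, abs=2e-8 * g_bar)

    def test_rmf_undefined_at_zero_variance(self):
        with pytest.raises(ValueError):
            SingleTraitParams(m=0.0, f=1.0, b=0.0).r_mf


class TestCrossoverCondition:
    def test_threshold_at_perfect_correlation(self):
        assert concordant_dominance_condition(1.0) == pytest.approx(1.0)

    def test_threshold_at_075(self):
        assert concordant_dominance_condition(0.75) == pytest.approx(0.96)

    def test_d_to_variance_ratio(self):
        assert d_threshold_to_variance_ratio(0.5) == pytest.approx(13.9282, abs=1e-3)
        # the ratio solves 2 sqrt(rho)/(1+rho) = d
        rho = d_threshold_to_variance_ratio(0.7)
        assert 2 * np.sqrt(rho) / (1 + rho) == pytest.approx(0.7)

    def test_nonpositive_rmf_rejected(self):
        with pytest.raises(ValueError):
            concordant_dominance_condition(0.0)


class TestTwoTrait:
    def test_equal_cross_correlations_no_indirect_antagonistic(self):
        p = TwoTraitParams(0.4, 0.4, 0.6, 0.6, 0.4, 0.4)
        assert two_trait_indirect(p, "antagonistic") == pytest.approx(0.0)

    def test_indirect_hand_values(self):
        p = TwoTraitParams(r_m12=0.5, r_f12=0.5, r_mf1=0.3, r_mf2=0.3,
                           c12=0.3, c21=0.3)
        assert two_trait_indirect(p, "antagonistic") == pytest.approx(0.2)
        p2 = TwoTraitParams(r_m12=0.5, r_f12=0.3, r_mf1=0.4, r_mf2=0.4,
                            c12=0.2, c21=0.2)
        assert two_trait_indirect(p2, "concordant") == pytest.approx(0.1)

    @pytest.mark.parametrize("scheme", ["antagonistic", "concordant"])
    @pytest.mark.parametrize("seed", range(8))
    def test_indirect_matches_engine(self, scheme, seed):
        rng = np.random.default_rng(seed)
        p = _random_two_trait(rng)
        g = p.to_sexed_g()
        sign_f = -1.0 if scheme == "antagonistic" else 1.0
        grad = SelectionGradient.custom(np.array([p.beta, 0.0, sign_f * p.beta, 0.0]))
        engine = predict_response(g, grad, allow_correlation=True)
        assert two_trait_indirect(p, scheme) == pytest.approx(
            engine.dimorphism_change["z2"], abs=1e-12
        )

    def test_both_selected_symmetric_concordant_zero(self):
        p = TwoTraitParams(r_m12=0.5, r_f12=0.5, r_mf1=0.7, r_mf2=0.7,
                           c12=0.3, c21=0.3)
        np.testing.assert_allclose(two_trait_both_selected(p, "concordant"), 0.0)

    def test_both_selected_perfect_rmf_antagonistic_zero(self):
        p = TwoTraitParams(r_m12=0.0, r_f12=0.0, r_mf1=1.0, r_mf2=1.0,
                           c12=0.0, c21=0.0)
        np.testing.assert_allclose(two_trait_both_selected(p, "antagonistic"), 0.0)

    def test_both_selected_hand_values(self):
        p = TwoTraitParams(r_m12=0.4, r_f12=0.4, r_mf1=0.5, r_mf2=0.7,
                           c12=0.2, c21=0.2)
        np.testing.assert_allclose(
            two_trait_both_selected(p, "antagonistic"), [0.7, 0.5]
        )

    @pytest.mark.parametrize("scheme", ["antagonistic", "concordant"])
    @pytest.mark.parametrize("seed", range(8))
    def test_both_selected_matches_engine(self, scheme, seed):
        rng = np.random.default_rng(seed + 100)
        p = _random_two_trait(rng)
        g = p.to_sexed_g()
        grad = both_selected_gradient(p, scheme)
        engine = predict_response(g, grad, allow_correlation=True)
        np.testing.assert_allclose(
            two_trait_both_selected(p, scheme),
            engine.dimorphism_change.values,
            atol=1e-12,
        )

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValueError):
            TwoTraitParams(1.2, 0.0, 0.0, 0.0, 0.0, 0.0)


def _random_two_trait(rng) -> TwoTraitParams:
    """Rejection-sample a PSD unit-variance two-trait structure."""
    for _ in range(1000):
        vals = rng.uniform(-0.6, 0.6, 6)
        try:
            p = TwoTraitParams(*vals, beta=float(rng.uniform(0.2, 2.0)))
            p.to_sexed_g()
            return p
        except Exception:
            continue
    raise AssertionError("could not draw a valid two-trait structure")


class TestConditionalResponse:
    def test_diagonal_matrix_selects_own_variance(self):
        g = assemble(np.diag([2.0, 3.0]), np.diag([2.0, 3.0]), np.zeros((2, 2)),
                     ["a", "b"], ["a", "b"])
        beta = np.zeros(4)
        beta[0] = 1.0
        resp = conditional_response(g, SelectionGradient.custom(beta))
        assert resp.e == pytest.approx(2.0)

    def test_conditional_variance_formula(self):
        g = assemble([[1.0]], [[1.0]], [[0.9]], ["T"], ["T"])
        resp = conditional_response(g, SelectionGradient.custom([1.0, 0.0]))
        assert resp.e == pytest.approx(1 - 0.81)

    @pytest.mark.parametrize("seed", range(10))
    def test_conditional_never_exceeds_evolvability(self, seed):
        rng = np.random.default_rng(seed)
        g = random_sexed_g(3, rng)
        beta = rng.standard_normal(6)
        beta /= np.linalg.norm(beta)
        grad = SelectionGradient.custom(beta)
        c = conditional_response(g, grad).e
        e = predict_response(g, grad).e
        assert c <= e + 1e-10


class TestModificationRatios:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @pytest.mark.parametrize("seed", range(5))
    def test_structural_entries(self, seed):
        """Antagonistic ratios are exactly 1 under the averaging and
        B-symmetrizing substitutions; removing both asymmetries kills the
        concordant dimorphism response exactly."""
        rng = np.random.default_rng(seed)
        g = random_sexed_g(4, rng)
        grads = [
            SelectionGradient.antagonistic(g, ["T1"]),
            SelectionGradient.concordant(g, ["T1"]),
            SelectionGradient.antagonistic(g, g.shared_traits),
            SelectionGradient.concordant(g, g.shared_traits),
        ]
        table = modification_ratio_table(g, grads)
        ant = table[table.scheme == "antagonistic"]
        for mod in ("avg_G", "sym_B", "avg_G_sym_B"):
            np.testing.assert_allclose(
                ant[ant.modification == mod]["ratio"], 1.0, atol=1e-12
            )
        con = table[table.scheme == "concordant"]
        for mod in ("avg_G_sym_B", "avg_G_zero_B"):
            np.testing.assert_allclose(
                con[con.modification == mod]["ratio"], 0.0, atol=1e-12
            )
        np.testing.assert_allclose(
            table[table.modification == "none"]["ratio"], 1.0, atol=1e-12
        )

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_zero_baseline_reported_undefined(self):
        g = assemble([[1.0]], [[1.0]], [[1.0]], ["T"], ["T"])  # r_MF = 1
        grads = [SelectionGradient.antagonistic(g, ["T"])]
        table = modification_ratio_table(g, grads, ["avg_G"])
        assert np.isnan(table["ratio"]).all()
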