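"""Link functions, probability fields, likelihood, priors and the ICAR density."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.stats import truncnorm as scipy_truncnorm

import occudyn as od
from occudyn.model import (
    ModelParameters,
    truncated_normal_logpdf,
)
from conftest import random_params


class TestInvLogit:
    @pytest.mark.parametrize(
        "x, expected, dp",
        [
            (-3.25, 0.037, 3),  # overall occurrence on the probability scale
            (0.0, 0.5, 10),
            (-3.81 + 1.51, 0.091, 3),  # gap colonization
        ],
    )
    def test_reference_values(self, x, expected, dp):
        assert od.inv_logit(x) == pytest.approx(expected, abs=0.5 * 10**-dp)

    def test_saturates_without_warning(self):
        assert od.inv_logit(1e4) == 1.0
        assert od.inv_logit(-1e4) == 0.0

    @given(st.floats(-30, 30), st.floats(0.01, 5))
    def test_strictly_increasing(self, x, dx):
        assert od.inv_logit(x + dx) > od.inv_logit(x)

    def test_logit_inverts(self):
        p = np.array([0.037, 0.5, 0.921])
        np.testing.assert_allclose(od.inv_logit(od.logit(p)), p, rtol=1e-12)


class TestComputeFields:
    def test_all_zero_parameters_give_half_everywhere(self, small_lattice):
        p = ModelParameters.zeros(3, small_lattice.n_quadrats)
        y1 = np.zeros((3, small_lattice.n_quadrats), dtype=int)
        f = od.compute_fields(p, small_lattice, y1)
        for arr in (f.psi1, f.phi, f.gamma, f.psi2):
            np.testing.assert_allclose(arr, 0.5)

    def test_survival_in_non_gap_quadrat_matches_reference(self, small_lattice):
        # logit(phi) = -2.60 + 5.93 in a non-gap quadrat -> 96.5%
        J = small_lattice.n_quadrats
        p = ModelParameters.zeros(1, J, beta_s=-2.60)
        p.eps_s[:] = 5.93
        f = od.compute_fields(p, small_lattice, np.ones((1, J), dtype=int))
        non_gap = small_lattice.gap == 0
        np.testing.assert_allclose(f.phi[0, non_gap], 0.965, atol=5e-4)

    def test_gap_colonization_with_species_effects_matches_reference(self, small_lattice):
        # logit(gamma) = -3.81 + 1.51 - 1.07 + 2.32 in a gap quadrat -> 25.9%
        J = small_lattice.n_quadrats
        p = ModelParameters.zeros(1, J, beta_c=-3.81, beta_cg=1.51)
        p.eps_c[:] = -1.07
        p.eps_cg[:] = 2.32
        f = od.compute_fields(p, small_lattice, np.zeros((1, J), dtype=int))
        gap = small_lattice.gap == 1
        np.testing.assert_allclose(f.gamma[0, gap], 0.259, atol=5e-4)

    def test_psi2_is_survival_where_present_and_colonization_where_absent(
        self, small_lattice, rng
    ):
        p = random_params(4, small_lattice.n_quadrats, rng)
        y1 = rng.integers(0, 2, size=(4, small_lattice.n_quadrats))
        f = od.compute_fields(p, small_lattice, y1)
        np.testing.assert_array_equal(f.psi2[y1 == 1], f.phi[y1 == 1])
        np.testing.assert_array_equal(f.psi2[y1 == 0], f.gamma[y1 == 0])

    def test_monotone_in_each_coefficient(self, small_lattice, rng):
        p = random_params(3, small_lattice.n_quadrats, rng)
        y1 = np.zeros((3, small_lattice.n_quadrats), dtype=int)
        base = od.compute_fields(p, small_lattice, y1)
        p2 = p.copy()
        p2.beta_c += 0.5
        assert (od.compute_fields(p2, small_lattice, y1).gamma > base.gamma).all()
        p3 = p.copy()
        p3.eps_o[1] += 0.5
        bumped = od.compute_fields(p3, small_lattice, y1)
        assert (bumped.psi1[1] > base.psi1[1]).all()
        np.testing.assert_array_equal(bumped.psi1[0], base.psi1[0])

    def test_dimension_mismatch_raises(self, small_lattice):
        p = ModelParameters.zeros(2, 7)
        with pytest.raises(ValueError):
            od.compute_fields(p, small_lattice, np.zeros((2, 7), dtype=int))


class TestLogLikelihood:
    def test_closed_form_at_zero_parameters(self):
        lat = od.build_adjacency(1, 2)
        sv = od.PresenceAbsenceSurvey(["a"], list(lat.quadrat_ids), [[1, 1]], [[1, 1]])
        p = ModelParameters.zeros(1, 2)
        assert od.log_likelihood(p, sv, lat) == pytest.approx(4 * np.log(0.5))

    def test_probabilities_sum_to_one_over_all_outcomes(self, rng):
        # brute-force enumeration over the 16 (y1, y2) outcomes of a
        # 1-species x 2-quadrat survey
        lat = od.build_adjacency(1, 2)
        p = random_params(1, 2, rng)
        total = 0.0
        for code in range(16):
            bits = [(code >> k) & 1 for k in range(4)]
            sv = od.PresenceAbsenceSurvey(
                ["a"], list(lat.quadrat_ids), [bits[:2]], [bits[2:]]
            )
            total += np.exp(od.log_likelihood(p, sv, lat))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_naive_double_loop(self, small_lattice, rng):
        S, J = 3, small_lattice.n_quadrats
        p = random_params(S, J, rng)
        y1 = rng.integers(0, 2, size=(S, J))
        y2 = rng.integers(0, 2, size=(S, J))
        sv = od.PresenceAbsenceSurvey(
            [f"s{i}" for i in range(S)], list(small_lattice.quadrat_ids), y1, y2
        )
        g = small_lattice.gap
        ref = 0.0
        for i in range(S):
            for j in range(J):
                psi1 = 1 / (1 + np.exp(-(p.beta_o + p.eps_o[i] + p.r[j])))
                phi = 1 / (1 + np.exp(-(p.beta_s + p.eps_s[i] + (p.beta_sg + p.eps_sg[i]) * g[j])))
                gam = 1 / (1 + np.exp(-(p.beta_c + p.eps_c[i] + (p.beta_cg + p.eps_cg[i]) * g[j])))
                psi2 = phi if y1[i, j] else gam
                ref += np.log(psi1 if y1[i, j] else 1 - psi1)
                ref += np.log(psi2 if y2[i, j] else 1 - psi2)
        assert od.log_likelihood(p, sv, small_lattice) == pytest.approx(ref, rel=1e-12)


class TestTruncatedNormalPrior:
    def test_matches_scipy_truncnorm(self, rng):
        for sd in (0.5, 1.0, 2.27, 100.0):
            x = rng.uniform(-9.9, 9.9, 25)
            ref = scipy_truncnorm.logpdf(x, -10 / sd, 10 / sd, scale=sd)
            np.testing.assert_allclose(truncated_normal_logpdf(x, sd), ref, rtol=1e-10)

    def test_outside_truncation_is_minus_inf(self):
        assert truncated_normal_logpdf(10.5, 1.0) == -np.inf
        assert truncated_normal_logpdf(-10.5, 3.0) == -np.inf

    @pytest.mark.parametrize("sd", [0.5, 1.0, 3.0])
    def test_density_integrates_to_one(self, sd):
        val, err = integrate.quad(
            lambda x: np.exp(truncated_normal_logpdf(x, sd)), -10, 10
        )
        assert val == pytest.approx(1.0, abs=1e-8)


class TestLogPrior:
    def test_effect_outside_box_gives_minus_inf(self, small_lattice):
        p = ModelParameters.zeros(2, small_lattice.n_quadrats)
        p.eps_o[0] = 10.5
        assert od.log_prior(p, small_lattice) == -np.inf

    def test_nonpositive_sigma_gives_minus_inf_not_exception(self, small_lattice):
        p = ModelParameters.zeros(2, small_lattice.n_quadrats, sigma_c=0.0)
        assert od.log_prior(p, small_lattice) == -np.inf

    def test_finite_on_interior(self, small_lattice, rng):
        p = random_params(2, small_lattice.n_quadrats, rng)
        assert np.isfinite(od.log_prior(p, small_lattice))

    def test_target_is_well_defined(self, small_dataset, rng):
        survey, lattice, _ = small_dataset
        p = random_params(survey.n_species, lattice.n_quadrats, rng)
        t = od.log_prior(p, lattice) + od.log_likelihood(p, survey, lattice)
        assert np.isfinite(t)
        p.beta_o = 11.0
        assert od.log_prior(p, lattice) == -np.inf


class TestIcarDensity:
    def test_zero_field_maximizes_density(self, small_lattice, rng):
        base = od.icar_log_density(np.zeros(small_lattice.n_quadrats), 1.0, small_lattice)
        r = rng.normal(size=small_lattice.n_quadrats)
        r -= r.mean()
        assert od.icar_log_density(r, 1.0, small_lattice) < base

    def test_two_node_path_single_edge_form(self):
        lat = od.build_adjacency(1, 2)
        a, sigma = 0.7, 1.3
        d = od.icar_log_density(np.array([a, -a]), sigma, lat)
        d0 = od.icar_log_density(np.zeros(2), sigma, lat)
        assert d - d0 == pytest.approx(-((2 * a) ** 2) / (2 * sigma**2))

    def test_translation_invariance_of_pairwise_form(self, small_lattice, rng):
        r = rng.normal(size=small_lattice.n_quadrats)
        d1 = od.icar_log_density(r, 0.8, small_lattice)
        d2 = od.icar_log_density(r + 3.7, 0.8, small_lattice)
        assert d1 == pytest.approx(d2, rel=1e-10)

    def test_full_conditionals_on_four_cycle(self, rng):
        # on the 2x2 grid (a 4-cycle), the conditional of r_j given the rest
        # must be Normal(sum_k w_jk r_k / w_j+, sigma^2 / w_j+): check the
        # score and curvature of the joint by finite differences
        lat = od.build_adjacency(2, 2)
        sigma = 0.9
        r = rng.normal(size=4)
        W = lat.adjacency.toarray()
        h = 1e-5
        for j in range(4):
            def f(v):
                rr = r.copy()
                rr[j] = v
                return od.icar_log_density(rr, sigma, lat)
            score = (f(r[j] + h) - f(r[j] - h)) / (2 * h)
            curv = (f(r[j] + h) - 2 * f(r[j]) + f(r[j] - h)) / h**2
            wjp = W[j].sum()
            cond_mean = W[j] @ r / wjp
            assert curv == pytest.approx(-wjp / sigma**2, rel=1e-4)
            assert score == pytest.approx(-(wjp / sigma**2) * (r[j] - cond_mean), rel=1e-4)

    def test_disconnected_lattice_raises(self):
        import scipy.sparse as sp

        A = sp.block_diag(
            [np.array([[0, 1], [1, 0]]), np.array([[0, 1], [1, 0]])]
        ).tocsr()
        lat = od.QuadratLattice(["a", "b", "c", "d"], A, np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="connected"):
            od.icar_log_density(np.zeros(4), 1.0, lat)
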