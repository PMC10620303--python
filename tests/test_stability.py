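"""Steady states, Jacobians, dispersion relations and d_star."""
import math

import numpy as np
import pytest

from turingcross.efficacy import TransEfficacy, symmetric_f1_system
from turingcross.genetics import F1, PARENT_A, Genotype
from turingcross.params import AlleleRates
from turingcross.stability import (
    AdmissibilityError,
    SearchBounds,
    SearchExhausted,
    check_admissibility,
    critical_diffusion_ratio,
    dispersion,
    find_steady_state,
    jacobian,
    max_growth,
    search_admissible,
)
from turingcross.systems import (
    HillSpec,
    ReactionSystem,
    Species,
    build_diploid_system,
    eval_reaction_terms,
    genotype_system,
)

from conftest import random_reaction_system

#: A two-species system with three coexisting steady states (symmetric
#: parent construction; the nullcline oracle below confirms three crossings).
THREE_ROOT_RATES = {
    "u": AlleleRates(0.0012566781445347366, 0.18247628538741198, 3.867365926714674),
    "v": AlleleRates(0.025510824218092712, 1.5097601395226297, 15.30366928549334),
}
THREE_ROOT_KAPPA = {
    "uu": 0.6036525207570839,
    "uv": 0.10935407672221507,
    "vu": 0.2332164144935302,
    "vv": 19.625866411080768,
}


def _gamma_zero(system: ReactionSystem) -> ReactionSystem:
    return ReactionSystem(
        tuple(
            Species(s.name, s.role, s.alpha, s.beta, 0.0, s.hill)
            for s in system.species
        ),
        D_u=system.D_u,
        D_v=system.D_v,
    )


class TestSteadyState:
    def test_gamma_zero_closed_form(self):
        system = _gamma_zero(random_reaction_system(3))
        ss = find_steady_state(system)
        np.testing.assert_allclose(
            ss.concentrations, system.alpha / system.beta, rtol=1e-10
        )
        assert ss.unique
        assert ss.residual <= 1e-10

    def test_contracted_steady_state_is_sum_of_full(self, admissible):
        full = build_diploid_system(admissible.params, PARENT_A)
        con = genotype_system(admissible.params, PARENT_A)
        ss_full = find_steady_state(full)
        ss_con = find_steady_state(con)
        u, v, uh, vh = ss_full.concentrations
        np.testing.assert_allclose(
            ss_con.concentrations, [u + uh, v + vh], rtol=1e-8
        )

    def test_three_steady_states_flagged_not_unique(self):
        """Multi-start finds all three roots of a bistable-plus-saddle
        system; a dense nullcline scan is the independent count."""
        system = symmetric_f1_system(
            THREE_ROOT_RATES, THREE_ROOT_KAPPA, TransEfficacy()
        )
        ss = find_steady_state(system, n_starts=64)
        assert not ss.unique
        assert ss.n_roots_found == 3
        assert _count_nullcline_crossings(system) == 3


def _count_nullcline_crossings(system: ReactionSystem, n_grid: int = 4000) -> int:
    """Sign changes of g(u, v_f(u)) along the f-nullcline, by dense scan.

    For fixed u > 0 the activator reaction term f is strictly decreasing in
    v, so v_f(u) is found by bisection wherever f(u, 0) >= 0 >= f(u, inf).
    The u grid is log-spaced: roots can sit orders of magnitude apart.
    """
    a_u, b_u = system.species[0].alpha, system.species[0].beta
    u_hi = 2.0 * (a_u + system.species[0].gamma) / b_u

    def f(u, v):
        return eval_reaction_terms(system, np.array([u, v]))[0]

    def g(u, v):
        return eval_reaction_terms(system, np.array([u, v]))[1]

    signs = []
    for u in np.geomspace(1e-5 * a_u / b_u, u_hi, n_grid):
        if f(u, 0.0) < 0.0:
            continue
        lo, hi = 0.0, 1.0
        while f(u, hi) > 0.0:
            hi *= 2.0
            if hi > 1e12:
                break
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(u, mid) > 0.0:
                lo = mid
            else:
                hi = mid
        signs.append(math.copysign(1.0, g(u, 0.5 * (lo + hi))))
    return int(np.sum(np.abs(np.diff(signs)) > 0))


class TestJacobian:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        system = random_reaction_system(seed)
        rng = np.random.default_rng(seed + 1000)
        x = rng.uniform(0.05, 5.0, system.n_species)
        J = jacobian(system, x)
        Jfd = np.zeros_like(J)
        for j in range(system.n_species):
            h = 1e-6 * max(x[j], 1.0)
            dx = np.zeros(system.n_species)
            dx[j] = h
            Jfd[:, j] = (
                eval_reaction_terms(system, x + dx)
                - eval_reaction_terms(system, x - dx)
            ) / (2 * h)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(J)) <= 1e-6

    def test_gamma_zero_jacobian_is_negative_diagonal(self):
        system = _gamma_zero(random_reaction_system(4))
        J = jacobian(system, np.array([0.3, 0.7, 1.1, 0.2]))
        np.testing.assert_allclose(J, -np.diag(system.beta), atol=1e-14)

    def test_homozygous_jacobian_commutes_with_species_swap(self, admissible):
        """At a symmetric state of the doubly homozygous 4-species system,
        J commutes with the (u <-> u_hat, v <-> v_hat) permutation."""
        full = build_diploid_system(admissible.params, PARENT_A)
        ss = find_steady_state(full)
        J = jacobian(full, ss.concentrations)
        P = np.zeros((4, 4))
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            P[i, j] = 1.0
        np.testing.assert_allclose(P @ J @ P.T, J, rtol=1e-8, atol=1e-12)


class TestDispersion:
    def test_k_zero_equals_reaction_eigenvalue_and_tail_decays(self, admissible):
        system = genotype_system(admissible.params, PARENT_A)
        ss = find_steady_state(system)
        J = jacobian(system, ss.concentrations)
        sigma0 = float(np.max(np.linalg.eigvals(J).real))
        k_grid = np.linspace(0, 5.0, 200)
        curve = dispersion(system, ss, d=admissible.params.d, k_grid=k_grid)
        assert curve.growth_rates[0] == pytest.approx(sigma0, rel=1e-10)
        assert curve.growth_rates[0] < 0
        # asymptotically dominated by -k^2 D: strictly decreasing tail
        tail = curve.growth_rates[-20:]
        assert np.all(np.diff(tail) < 0)
        assert curve.growth_rates[-1] < -10 * abs(sigma0)

    def test_unstable_band_edges_match_determinant_roots(self, admissible):
        """For a 2-species system above d_star, the positive-growth band
        is exactly where det(J - k^2 D) < 0; edges from the closed-form
        quadratic in k^2 (standard two-species Turing analysis)."""
        system = genotype_system(admissible.params, PARENT_A)
        ss = find_steady_state(system)
        dstar = critical_diffusion_ratio(system, ss)
        d = 1.2 * dstar
        J = jacobian(system, ss.concentrations)
        Du = system.D_u
        Dv = d * Du
        a, b, c, e = J[0, 0], J[0, 1], J[1, 0], J[1, 1]
        # Du*Dv*(k^2)^2 - (a*Dv + e*Du)*k^2 + det(J) = 0
        coeffs = [Du * Dv, -(a * Dv + e * Du), a * e - b * c]
        roots = np.sort(np.roots(coeffs).real)
        assert np.all(roots > 0)
        k_edges = np.sqrt(roots)
        k_grid = np.linspace(0, 2.5 * k_edges[1], 4000)
        curve = dispersion(system, ss, d=d, k_grid=k_grid)
        positive = curve.growth_rates > 0
        assert positive.any()
        k_lo = k_grid[np.argmax(positive)]
        k_hi = k_grid[len(positive) - 1 - np.argmax(positive[::-1])]
        dk = k_grid[1] - k_grid[0]
        assert abs(k_lo - k_edges[0]) <= 2 * dk
        assert abs(k_hi - k_edges[1]) <= 2 * dk

    def test_reaction_unstable_state_is_rejected(self):
        """Turing analysis at an unstable uniform state (the middle root
        of the three-root system) is refused."""
        from scipy import optimize

        system = symmetric_f1_system(
            THREE_ROOT_RATES, THREE_ROOT_KAPPA, TransEfficacy()
        )
        sol = optimize.root(
            lambda x: eval_reaction_terms(system, np.abs(x)),
            np.array([0.0503, 0.0348]),
            tol=1e-14,
        )
        saddle = np.abs(sol.x)
        assert np.max(np.linalg.eigvals(jacobian(system, saddle)).real) > 0
        with pytest.raises(AdmissibilityError):
            dispersion(system, saddle, d=2.0)


class TestCriticalDiffusionRatio:
    def test_exceeds_one_for_admissible_sets(self, admissible):
        meta = admissible.meta
        assert meta["d_star_F1"] > 1.0
        assert meta["d_star_A"] > 1.0
        # recompute one of them from scratch
        system = genotype_system(admissible.params, F1)
        ss = find_steady_state(system)
        dstar = critical_diffusion_ratio(system, ss)
        assert dstar > 1.0
        assert dstar == pytest.approx(meta["d_star_F1"], rel=1e-4)

    def test_bifurcation_brackets_growth_sign(self, admissible):
        system = genotype_system(admissible.params, PARENT_A)
        ss = find_steady_state(system)
        dstar = critical_diffusion_ratio(system, ss, tol=1e-8)
        eps = 1e-4 * dstar
        assert max_growth(system, ss.concentrations, d=dstar + eps)[0] > 0
        assert max_growth(system, ss.concentrations, d=dstar - eps)[0] < 0

    def test_no_bifurcation_returns_inf_sentinel(self, admissible):
        system = genotype_system(admissible.params, PARENT_A)
        ss = find_steady_state(system)
        assert critical_diffusion_ratio(system, ss, d_bracket=(1.0, 10.0)) == math.inf

    def test_symmetric_f1_at_m1_equals_parent_dstar(self, symmetric_parent_spec):
        rates, kappa = symmetric_parent_spec
        parent = symmetric_f1_system(rates, kappa, TransEfficacy())
        hybrid = symmetric_f1_system(
            rates, kappa, TransEfficacy(1.0, 1.0, 1.0, 1.0)
        )
        ss_p = find_steady_state(parent)
        ss_h = find_steady_state(hybrid)
        assert critical_diffusion_ratio(parent, ss_p) == pytest.approx(
            critical_diffusion_ratio(hybrid, ss_h), rel=1e-9
        )


class TestAdmissibility:
    def test_fixture_verdict_true_with_ordered_dstars(self, admissible):
        report = check_admissibility(admissible.params)
        assert report.verdict
        assert report.d_star_F1 < report.d_used < min(
            report.d_star_A, report.d_star_B
        )

    def test_relabeling_swaps_parent_dstars(self, admissible):
        report = check_admissibility(admissible.params)
        swapped = check_admissibility(admissible.params.relabeled())
        assert swapped.verdict
        assert swapped.d_star_A == pytest.approx(report.d_star_B, rel=1e-6)
        assert swapped.d_star_B == pytest.approx(report.d_star_A, rel=1e-6)
        assert swapped.d_star_F1 == pytest.approx(report.d_star_F1, rel=1e-6)

    def test_allele_independent_params_are_inadmissible(self, symmetric_parent_spec):
        """With all-identical alleles the F1 IS the parents: no d separates
        them and the verdict is false."""
        from turingcross.efficacy import symmetric_param_set

        rates, kappa = symmetric_parent_spec
        params = symmetric_param_set(
            rates, kappa, TransEfficacy(1.0, 1.0, 1.0, 1.0), D_u=1.0, D_v=5.0
        )
        report = check_admissibility(params)
        assert not report.verdict
        assert report.reasons


class TestSearch:
    def test_deterministic_given_seed(self):
        r1 = search_admissible(rng_seed=6, max_tries=50)
        r2 = search_admissible(rng_seed=6, max_tries=50)
        assert r1.params.to_json() == r2.params.to_json()
        assert r1.try_index == r2.try_index
        assert r1.report.verdict

    def test_degenerate_bounds_never_accept(self, symmetric_parent_spec):
        """Point bounds with trans/cis ratio pinned at 1 make every
        candidate's F1 identical to its parents; the search must exhaust
        and report why."""
        rates, _ = symmetric_parent_spec
        ru, rv = rates["u"], rates["v"]
        bounds = SearchBounds(
            alpha=(ru.alpha, ru.alpha),
            beta=(ru.beta, ru.beta),
            gamma=(ru.gamma, ru.gamma),
            kappa=(0.5, 0.5),
            trans_ratio=(1.0, 1.0),
        )
        with pytest.raises(SearchExhausted) as exc:
            search_admissible(rng_seed=1, bounds=bounds, max_tries=5)
        assert exc.value.rejections
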