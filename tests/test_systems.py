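"""Reaction-term evaluation, diploid system construction and contraction."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from turingcross.genetics import F1, PARENT_A, PARENT_B, Genotype
from turingcross.params import BindingKey
from turingcross.systems import (
    HillSpec,
    ReactionSystem,
    Species,
    SystemError_,
    build_diploid_system,
    contract_system,
    eval_reaction_terms,
    genotype_system,
    hill_terms,
)

from conftest import draw_param_set, random_reaction_system as _random_system


class TestEvalReactionTerms:
    def test_zero_state_gives_baseline_production(self):
        sys4 = _random_system(0)
        np.testing.assert_array_equal(
            eval_reaction_terms(sys4, np.zeros(4)), sys4.alpha
        )

    def test_gamma_zero_is_linear(self):
        sys4 = _random_system(1)
        sys4 = ReactionSystem(
            tuple(
                Species(s.name, s.role, s.alpha, s.beta, 0.0, s.hill)
                for s in sys4.species
            ),
            D_u=1.0,
            D_v=2.0,
        )
        x = np.array([0.5, 1.0, 2.0, 0.1])
        np.testing.assert_allclose(
            eval_reaction_terms(sys4, x), sys4.alpha - sys4.beta * x, rtol=1e-15
        )

    def test_contract_violations(self):
        sys4 = _random_system(2)
        with pytest.raises(SystemError_):
            eval_reaction_terms(sys4, np.zeros(3))
        with pytest.raises(SystemError_):
            eval_reaction_terms(sys4, np.array([1.0, -0.1, 1.0, 1.0]))

    def test_matches_exact_rational_transcription(self):
        """Float evaluation agrees with an exact-arithmetic transcription
        of the four diploid equations, written independently with named
        binding constants (not the weight-matrix code path)."""
        params = draw_param_set(77)
        genotype = F1
        system = build_diploid_system(params, genotype)
        state = [Fraction(3, 7), Fraction(11, 5), Fraction(2, 9), Fraction(8, 3)]
        u, v, uh, vh = state

        def R(x: float) -> Fraction:
            return Fraction(x)

        def kap(label: str) -> Fraction:
            return R(params.kappa[BindingKey.from_label(label)])

        def hill(num: Fraction, act: Fraction, inh: Fraction) -> Fraction:
            return (num / (1 + act + inh)) ** 2

        exact = []
        # activator from haplotype 1 (allele A)
        rA = params.rates[("u", "A")]
        Uu = kap("uu_AA") * u + kap("uu_AB") * uh
        Vu = kap("uv_AA") * v + kap("uv_AB") * vh
        exact.append(R(rA.alpha) - R(rA.beta) * u + R(rA.gamma) * hill(Uu, Uu, Vu))
        # inhibitor from haplotype 1 (allele A)
        rvA = params.rates[("v", "A")]
        Uv = kap("vu_AA") * u + kap("vu_AB") * uh
        Vv = kap("vv_AA") * v + kap("vv_AB") * vh
        exact.append(R(rvA.alpha) - R(rvA.beta) * v + R(rvA.gamma) * hill(Uv, Uv, Vv))
        # activator from haplotype 2 (allele B)
        rB = params.rates[("u", "B")]
        Uuh = kap("uu_BA") * u + kap("uu_BB") * uh
        Vuh = kap("uv_BA") * v + kap("uv_BB") * vh
        exact.append(R(rB.alpha) - R(rB.beta) * uh + R(rB.gamma) * hill(Uuh, Uuh, Vuh))
        # inhibitor from haplotype 2 (allele B)
        rvB = params.rates[("v", "B")]
        Uvh = kap("vu_BA") * u + kap("vu_BB") * uh
        Vvh = kap("vv_BA") * v + kap("vv_BB") * vh
        exact.append(R(rvB.alpha) - R(rvB.beta) * vh + R(rvB.gamma) * hill(Uvh, Uvh, Vvh))

        got = eval_reaction_terms(system, np.array([float(s) for s in state]))
        np.testing.assert_allclose(got, [float(e) for e in exact], rtol=1e-12)


class TestBuildDiploidSystem:
    def test_f1_hill_weights_carry_expected_binding_keys(self, random_params):
        system = build_diploid_system(random_params, F1)
        k = random_params.kappa

        def K(label):
            return k[BindingKey.from_label(label)]

        u, v, uh, vh = system.species
        assert u.hill.numerator_weights == (K("uu_AA"), 0.0, K("uu_AB"), 0.0)
        assert u.hill.inhibitor_weights == (0.0, K("uv_AA"), 0.0, K("uv_AB"))
        assert uh.hill.numerator_weights == (K("uu_BA"), 0.0, K("uu_BB"), 0.0)
        assert v.hill.numerator_weights == (K("vu_AA"), 0.0, K("vu_AB"), 0.0)
        assert vh.hill.inhibitor_weights == (0.0, K("vv_BA"), 0.0, K("vv_BB"))

    def test_homozygous_parent_equations_pairwise_identical(self, random_params):
        system = build_diploid_system(random_params, PARENT_A)
        u, v, uh, vh = system.species
        assert (u.alpha, u.beta, u.gamma, u.hill) == (uh.alpha, uh.beta, uh.gamma, uh.hill)
        assert (v.alpha, v.beta, v.gamma, v.hill) == (vh.alpha, vh.beta, vh.gamma, vh.hill)

    def test_parent_b_is_parent_a_with_alleles_swapped(self, random_params):
        sysB = build_diploid_system(random_params, PARENT_B)
        sysA_swapped = build_diploid_system(random_params.relabeled(), PARENT_A)
        for sp1, sp2 in zip(sysB.species, sysA_swapped.species):
            assert (sp1.alpha, sp1.beta, sp1.gamma) == (sp2.alpha, sp2.beta, sp2.gamma)
            assert sp1.hill == sp2.hill


class TestContraction:
    def test_doubly_homozygous_contracts_to_two_species(self, random_params):
        con = genotype_system(random_params, PARENT_A)
        full = build_diploid_system(random_params, PARENT_A)
        assert con.n_species == 2
        assert con.names == ("u_bar", "v_bar")
        for merged, orig in zip(con.species, (full.species[0], full.species[1])):
            assert merged.alpha == pytest.approx(2 * orig.alpha)
            assert merged.gamma == pytest.approx(2 * orig.gamma)
            assert merged.beta == pytest.approx(orig.beta)
        # collapsed weights equal the per-allele weights (same kappa^AA)
        assert con.species[0].hill.numerator_weights == (
            full.species[0].hill.numerator_weights[0],
            0.0,
        )

    def test_single_heterozygous_contracts_to_three_species(self, random_params):
        g = Genotype("AB", "BB")
        con = genotype_system(random_params, g)
        assert con.n_species == 3
        assert con.names == ("u", "u_hat", "v_bar")
        rvB = random_params.rates[("v", "B")]
        vbar = con.species[2]
        assert vbar.alpha == pytest.approx(2 * rvB.alpha)
        assert vbar.gamma == pytest.approx(2 * rvB.gamma)
        assert vbar.beta == pytest.approx(rvB.beta)

    def test_f1_contraction_is_identity(self, random_params):
        full = build_diploid_system(random_params, F1)
        assert contract_system(full) is full

    @pytest.mark.parametrize("locus_u,locus_v", [("AA", "AA"), ("AB", "BB"), ("AA", "AB")])
    def test_contraction_preserves_ode_trajectories(
        self, random_params, locus_u, locus_v
    ):
        """Time integration of the full 4-species system from a split
        initial condition matches the contracted system's totals."""
        g = Genotype(locus_u, locus_v)
        full = build_diploid_system(random_params, g)
        con = contract_system(full)
        rng = np.random.default_rng(5)
        s0 = rng.uniform(0.1, 2.0, con.n_species)
        # distribute each contracted species' mass equally over its members
        x0 = np.empty(4)
        mapping = _contracted_to_full_indices(con, full)
        for ci, members in mapping.items():
            for m in members:
                x0[m] = s0[ci] / len(members)
        sol_full = solve_ivp(
            lambda t, x: eval_reaction_terms(full, np.maximum(x, 0)),
            (0, 20), x0, rtol=1e-10, atol=1e-12, dense_output=True,
        )
        sol_con = solve_ivp(
            lambda t, x: eval_reaction_terms(con, np.maximum(x, 0)),
            (0, 20), s0, rtol=1e-10, atol=1e-12, dense_output=True,
        )
        ts = np.linspace(0, 20, 7)
        for ci, members in mapping.items():
            total_full = sum(sol_full.sol(ts)[m] for m in members)
            np.testing.assert_allclose(
                total_full, sol_con.sol(ts)[ci], rtol=1e-8, atol=1e-10
            )


def _contracted_to_full_indices(con, full):
    """Map contracted species index -> list of full-system species indices."""
    full_idx = {name: i for i, name in enumerate(full.names)}
    out = {}
    for ci, name in enumerate(con.names):
        if name == "u_bar":
            out[ci] = [full_idx["u"], full_idx["u_hat"]]
        elif name == "v_bar":
            out[ci] = [full_idx["v"], full_idx["v_hat"]]
        else:
            out[ci] = [full_idx[name]]
    return out


class TestHillProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        n=st.integers(2, 4),
        scale=st.floats(1e-3, 1e3),
    )
    def test_hill_in_unit_interval_and_rate_floor(self, seed, n, scale):
        """The squared Hill term lies in [0, 1) for nonnegative state, so
        every reaction component is bounded below by -beta * x, across
        randomized systems, dimensions and concentration scales."""
        sysn = _random_system(seed, n=n)
        rng = np.random.default_rng(seed + 100)
        x = scale * rng.uniform(0, 10, n)
        h = hill_terms(sysn, x)
        assert np.all(h >= 0) and np.all(h < 1)
        rates = eval_reaction_terms(sysn, x)
        assert np.all(rates >= -sysn.beta * x - 1e-12)
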