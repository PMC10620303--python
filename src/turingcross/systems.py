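"""Concrete reaction-diffusion systems for one genotype.

Every species x in a system evolves by

    dx/dt = D nabla^2 x + alpha - beta * x + gamma * (U_x / (1 + U_x + V_x))^2

where U_x and V_x are nonnegative linear combinations of the activator-like
and inhibitor-like species concentrations (competitive binding of activator
and inhibitor to a pair of identical, independent regulatory sites gives
the squared Hill form).  A diploid genotype instantiates a four-species
system (u, v, u_hat, v_hat); homozygous loci can be contracted by summing
the allele pair, which doubles the zeroth-order rates (alpha, gamma) and
leaves the first-order rate (beta) unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genetics import Genotype, assign_parameters
from .params import MultigenParamSet


class SystemError_(ValueError):
    """Contract violation when building or evaluating a system."""


@dataclass(frozen=True)
class HillSpec:
    """Coefficients of one species' regulation term.

    ``numerator_weights`` (== the activator-side weights) form
    U_x = sum_j w_j x_j; ``inhibitor_weights`` form V_x.  The regulated
    production term is (U_x / (1 + U_x + V_x))^2.
    """

    numerator_weights: tuple[float, ...]
    inhibitor_weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.numerator_weights + self.inhibitor_weights):
            raise SystemError_("Hill weights must be nonnegative")


@dataclass(frozen=True)
class Species:
    """One gene product: its rates, diffusion role and regulation spec.

    ``role`` selects the diffusion coefficient: 'activator' -> D_u,
    'inhibitor' -> D_v.
    """

    name: str
    role: str
    alpha: float
    beta: float
    gamma: float
    hill: HillSpec

    def __post_init__(self) -> None:
        if self.role not in ("activator", "inhibitor"):
            raise SystemError_(f"invalid species role {self.role!r}")


@dataclass(frozen=True)
class ReactionSystem:
    """An n-species (n in {2, 3, 4}) reaction-diffusion system."""

    species: tuple[Species, ...]
    D_u: float
    D_v: float
    genotype: Genotype | None = None

    def __post_init__(self) -> None:
        n = len(self.species)
        if not 2 <= n <= 4:
            raise SystemError_(f"need 2-4 species, got {n}")
        for sp in self.species:
            if (
                len(sp.hill.numerator_weights) != n
                or len(sp.hill.inhibitor_weights) != n
            ):
                raise SystemError_(f"Hill weight dimension mismatch for {sp.name}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    # Cached coefficient arrays -------------------------------------------
    @property
    def alpha(self) -> np.ndarray:
        return np.array([sp.alpha for sp in self.species])

    @property
    def beta(self) -> np.ndarray:
        return np.array([sp.beta for sp in self.species])

    @property
    def gamma(self) -> np.ndarray:
        return np.array([sp.gamma for sp in self.species])

    @property
    def num_weights(self) -> np.ndarray:
        """(n, n) matrix: row i gives U_i coefficients."""
        return np.array([sp.hill.numerator_weights for sp in self.species])

    @property
    def inh_weights(self) -> np.ndarray:
        """(n, n) matrix: row i gives V_i coefficients."""
        return np.array([sp.hill.inhibitor_weights for sp in self.species])

    def diffusion_coeffs(self, d: float | None = None) -> np.ndarray:
        """Per-species diffusion coefficients; ``d`` overrides D_v = d * D_u."""
        D_v = self.D_v if d is None else d * self.D_u
        return np.array(
            [self.D_u if sp.role == "activator" else D_v for sp in self.species]
        )

    def with_diffusion(self, D_u: float, D_v: float) -> "ReactionSystem":
        return replace(self, D_u=D_u, D_v=D_v)


# --------------------------------------------------------------------------
# Reaction-term evaluation and analytic linearization
# --------------------------------------------------------------------------

def hill_terms(system: ReactionSystem, state: np.ndarray) -> np.ndarray:
    """The vector of (U_i / (1 + U_i + V_i))^2 terms; each lies in [0, 1)."""
    U = system.num_weights @ state
    V = system.inh_weights @ state
    return (U / (1.0 + U + V)) ** 2


def eval_reaction_terms(system: ReactionSystem, state: np.ndarray) -> np.ndarray:
    """Reaction part of d(state)/dt (no diffusion).

    Raises on dimension mismatch or negative concentrations.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (system.n_species,):
        raise SystemError_(
            f"state has shape {state.shape}, expected ({system.n_species},)"
        )
    if np.any(state < 0):
        raise SystemError_("negative concentration in state")
    return system.alpha - system.beta * state + system.gamma * hill_terms(system, state)


def _reaction_terms_field(system: ReactionSystem, field: np.ndarray) -> np.ndarray:
    """Vectorized reaction terms over a stacked (n, ...) concentration field."""
    U = np.tensordot(system.num_weights, field, axes=1)
    V = np.tensordot(system.inh_weights, field, axes=1)
    hill = (U / (1.0 + U + V)) ** 2
    shape = (system.n_species,) + (1,) * (field.ndim - 1)
    return (
        system.alpha.reshape(shape)
        - system.beta.reshape(shape) * field
        + system.gamma.reshape(shape) * hill
    )


def reaction_jacobian(system: ReactionSystem, state: np.ndarray) -> np.ndarray:
    """Closed-form Jacobian of the reaction terms at ``state``.

    d f_i / d x_j = -beta_i delta_ij
        + 2 gamma_i U_i (a_ij (1 + V_i) - b_ij U_i) / (1 + U_i + V_i)^3

    with a = numerator weights and b = inhibitor weights.  For the diploid
    species ordering (u, v, u_hat, v_hat) the result exposes the 2x2 block
    structure of the linearized system.
    """
    state = np.asarray(state, dtype=float)
    A = system.num_weights
    B = system.inh_weights
    U = A @ state
    V = B @ state
    denom = (1.0 + U + V) ** 3
    pref = 2.0 * system.gamma * U / denom
    J = pref[:, None] * (A * (1.0 + V)[:, None] - B * U[:, None])
    J[np.diag_indices_from(J)] -= system.beta
    return J


# --------------------------------------------------------------------------
# Building genotype systems from an F1 parameter set
# --------------------------------------------------------------------------

_SLOT_ORDER = ("u", "v", "u_hat", "v_hat")
_SLOT_ROLE = {
    "u": "activator",
    "v": "inhibitor",
    "u_hat": "activator",
    "v_hat": "inhibitor",
}
_SLOT_TF = {"u": "u", "v": "v", "u_hat": "u", "v_hat": "v"}


def build_diploid_system(
    params: MultigenParamSet, genotype: Genotype
) -> ReactionSystem:
    """The full four-variable system (u, v, u_hat, v_hat) for ``genotype``.

    Each species carries the rate triple of its own allele; the Hill weight
    at position (regulated species, binding species) is the association
    constant keyed by (regulated TF+allele, binding TF+allele).  For the
    doubly heterozygous genotype this reproduces the F1 system; for a
    doubly homozygous genotype the u/u_hat (and v/v_hat) equations are
    identical.
    """
    assignment = assign_parameters(genotype, params)
    species = []
    for reg in _SLOT_ORDER:
        allele = assignment.species_alleles[reg]
        rates = params.rates[(_SLOT_TF[reg], allele)]
        num = [0.0] * 4
        inh = [0.0] * 4
        for j, bind in enumerate(_SLOT_ORDER):
            key = assignment.kappa_keys[(reg, bind)]
            try:
                value = params.kappa[key]
            except KeyError as exc:
                raise SystemError_(
                    f"parameter set lacks binding constant {key.label}"
                ) from exc
            if _SLOT_TF[bind] == "u":
                num[j] = value
            else:
                inh[j] = value
        species.append(
            Species(
                name=reg,
                role=_SLOT_ROLE[reg],
                alpha=rates.alpha,
                beta=rates.beta,
                gamma=rates.gamma,
                hill=HillSpec(tuple(num), tuple(inh)),
            )
        )
    return ReactionSystem(
        species=tuple(species), D_u=params.D_u, D_v=params.D_v, genotype=genotype
    )


def contract_system(system: ReactionSystem) -> ReactionSystem:
    """Merge allele pairs at homozygous loci into total-concentration species.

    Contraction is symbolic: at a homozygous locus the pair (x, x_hat) is
    replaced by x_bar = x + x_hat, whose zeroth-order rates (alpha, gamma)
    double while beta is unchanged, and whose incoming Hill weights collapse
    the two identical columns into one.  Heterozygous loci are left split.
    Contraction keys off the genotype only; allele-identical parameters at
    a heterozygous locus are NOT auto-contracted.  Output species order is
    activators first, then inhibitors.
    """
    if system.genotype is None or system.n_species != 4:
        raise SystemError_("contract_system expects a 4-species genotype system")
    genotype = system.genotype
    by_name = {sp.name: sp for sp in system.species}
    old_order = list(system.names)

    # Which species survive, and which old columns each absorbs.
    merged: list[tuple[str, str, list[str], bool]] = []  # (name, role, members, is_merged)
    for tf, pair, barname in (("u", ("u", "u_hat"), "u_bar"), ("v", ("v", "v_hat"), "v_bar")):
        if genotype.is_homozygous(tf):
            merged.append((barname, by_name[pair[0]].role, list(pair), True))
        else:
            for name in pair:
                merged.append((name, by_name[name].role, [name], False))

    new_species = []
    for name, role, members, is_merged in merged:
        rep = by_name[members[0]]
        if is_merged:
            other = by_name[members[1]]
            same = (
                np.isclose(rep.alpha, other.alpha)
                and np.isclose(rep.beta, other.beta)
                and np.isclose(rep.gamma, other.gamma)
            )
            if not same:
                raise SystemError_(
                    f"homozygous pair {members} carries unequal rate constants"
                )
        num = []
        inh = []
        for _, _, col_members, _ in merged:
            cols = [old_order.index(m) for m in col_members]
            wn = [rep.hill.numerator_weights[c] for c in cols]
            wi = [rep.hill.inhibitor_weights[c] for c in cols]
            if len(cols) == 2 and (
                not np.isclose(wn[0], wn[1]) or not np.isclose(wi[0], wi[1])
            ):
                raise SystemError_(
                    f"cannot collapse unequal weights onto merged species"
                )
            num.append(wn[0])
            inh.append(wi[0])
        factor = 2.0 if is_merged else 1.0
        new_species.append(
            Species(
                name=name,
                role=role,
                alpha=factor * rep.alpha,
                beta=rep.beta,
                gamma=factor * rep.gamma,
                hill=HillSpec(tuple(num), tuple(inh)),
            )
        )
    if len(new_species) == 4:
        return system
    return ReactionSystem(
        species=tuple(new_species),
        D_u=system.D_u,
        D_v=system.D_v,
        genotype=genotype,
    )


def genotype_system(params: MultigenParamSet, genotype: Genotype) -> ReactionSystem:
    """Convenience: build the diploid system and contract homozygous loci."""
    return contract_system(build_diploid_system(params, genotype))
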