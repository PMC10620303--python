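"""Symmetric-parent limit: trans/cis binding efficacy and d_star sweeps.

When the two parents are phenotypically identical (rate constants and cis
binding constants independent of allele type) the F1 hybrid differs from
the parents only through the trans binding constants, conveniently
expressed as the trans/cis ratios m_uu, m_uv, m_vu, m_vv.  Under this
symmetry the F1's four equations contract to a two-variable system for the
total concentrations (u_bar = u + u_hat, v_bar = v + v_hat) whose effective
binding constants are kappa * (1 + m) / 2: at m = 1 (trans as effective as
cis) this is exactly the contracted parent system with effective constant
kappa, and at m = 0 the effective constant is halved.  Reduced trans
efficacy of the cross-regulatory pathways (m_vu, m_uv) typically lowers the
critical diffusion ratio d_star, which is how identical unpatterned parents
can produce a patterned hybrid.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import (
    ALLELES,
    AlleleRates,
    BindingKey,
    MultigenParamSet,
    ParameterError,
    TFS,
)
from .stability import (
    AdmissibilityError,
    ConvergenceError,
    NoBifurcationError,
    critical_diffusion_ratio,
    find_steady_state,
)
from .systems import HillSpec, ReactionSystem, Species

PATHWAYS = ("uu", "uv", "vu", "vv")


@dataclass(frozen=True)
class TransEfficacy:
    """Trans/cis binding-constant ratios per regulatory pathway.

    The hybrid regime has 0 <= m < 1 (trans binding weaker than cis);
    m = 1 everywhere recovers the parents.
    """

    m_uu: float = 1.0
    m_uv: float = 1.0
    m_vu: float = 1.0
    m_vv: float = 1.0

    def __post_init__(self) -> None:
        for name in PATHWAYS:
            val = getattr(self, f"m_{name}")
            if not (0.0 <= val <= 1.0):
                raise ParameterError(f"m_{name} must lie in [0, 1], got {val}")

    def get(self, pathway: str) -> float:
        return getattr(self, f"m_{pathway}")

    @classmethod
    def single(cls, pathway: str, value: float) -> "TransEfficacy":
        if pathway not in PATHWAYS:
            raise ParameterError(f"unknown pathway {pathway!r}")
        return cls(**{f"m_{pathway}": value})


def symmetric_f1_system(
    parent_rates: dict[str, AlleleRates],
    parent_kappa: dict[str, float],
    m: TransEfficacy,
    D_u: float = 1.0,
    D_v: float = 2.0,
) -> ReactionSystem:
    """Contracted two-variable F1 system of the symmetric-parent limit.

    ``parent_rates`` maps 'u'/'v' to the (allele-independent) rate triples;
    ``parent_kappa`` maps 'uu', 'uv', 'vu', 'vv' to the cis binding
    constants.  The contracted system for the totals has production terms
    2*alpha and 2*gamma and effective binding constants kappa*(1+m)/2, so
    m = 1 reproduces the contracted parent exactly.
    """
    eff = {p: parent_kappa[p] * (1.0 + m.get(p)) / 2.0 for p in PATHWAYS}
    ru, rv = parent_rates["u"], parent_rates["v"]
    species = (
        Species(
            name="u_bar",
            role="activator",
            alpha=2.0 * ru.alpha,
            beta=ru.beta,
            gamma=2.0 * ru.gamma,
            hill=HillSpec((eff["uu"], 0.0), (0.0, eff["uv"])),
        ),
        Species(
            name="v_bar",
            role="inhibitor",
            alpha=2.0 * rv.alpha,
            beta=rv.beta,
            gamma=2.0 * rv.gamma,
            hill=HillSpec((eff["vu"], 0.0), (0.0, eff["vv"])),
        ),
    )
    return ReactionSystem(species=species, D_u=D_u, D_v=D_v)


def symmetric_param_set(
    parent_rates: dict[str, AlleleRates],
    parent_kappa: dict[str, float],
    m: TransEfficacy,
    D_u: float = 1.0,
    D_v: float = 2.0,
) -> MultigenParamSet:
    """Full 16-constant parameter set realizing the symmetric-parent limit.

    Rates are allele-independent; cis constants equal the parent values for
    both alleles and trans constants are m * cis, so the F1 built from this
    set through the diploid machinery matches :func:`symmetric_f1_system`.
    """
    rates = {
        (tf, al): parent_rates[tf] for tf in TFS for al in ALLELES
    }
    kappa: dict[BindingKey, float] = {}
    for rt in TFS:
        for bt in TFS:
            pathway = rt + bt
            for ra in ALLELES:
                for ba in ALLELES:
                    base = parent_kappa[pathway]
                    factor = 1.0 if ra == ba else m.get(pathway)
                    kappa[BindingKey(rt, ra, bt, ba)] = base * factor
    return MultigenParamSet(rates=rates, kappa=kappa, D_u=D_u, D_v=D_v)


@dataclass(frozen=True)
class SweepResult:
    pathway: str
    m_values: np.ndarray
    d_star: np.ndarray  # math.inf where no Turing bifurcation exists

    def as_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.m_values.tolist(), self.d_star.tolist()))


def dstar_sweep(
    parent_rates: dict[str, AlleleRates],
    parent_kappa: dict[str, float],
    which: str,
    m_grid: np.ndarray | None = None,
) -> SweepResult:
    """Critical diffusion ratio of the symmetric F1 as one trans efficacy varies.

    Only the named pathway's m is varied (the others stay at 1, i.e. at the
    parental value).  Entries where the system has no Turing bifurcation,
    no steady state, or loses reaction stability are recorded as the
    ``inf``/``nan`` sentinels and the sweep continues.
    """
    if which not in PATHWAYS:
        raise ParameterError(f"unknown pathway {which!r}")
    if m_grid is None:
        m_grid = np.linspace(0.0, 1.0, 41)
    m_grid = np.asarray(m_grid, dtype=float)
    out = np.empty_like(m_grid)
    for i, mval in enumerate(m_grid):
        system = symmetric_f1_system(
            parent_rates, parent_kappa, TransEfficacy.single(which, float(mval))
        )
        try:
            ss = find_steady_state(system)
            out[i] = critical_diffusion_ratio(system, ss)
        except (ConvergenceError, NoBifurcationError, AdmissibilityError):
            out[i] = math.nan
    return SweepResult(pathway=which, m_values=m_grid, d_star=out)
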