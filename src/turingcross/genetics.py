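"""Mendelian bookkeeping for a two-locus diploid cross.

Two unlinked loci code for the activator (U) and the inhibitor (V); each
locus carries two alleles drawn from {A, B}.  The heterozygous state AB is
unordered (BA is the same genotype), but within a heterozygous locus the
equations still distinguish which gene product carries which allele, so a
fixed haplotype convention is used: haplotype 1 = A, haplotype 2 = B.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .params import ALL_BINDING_KEYS, BindingKey, MultigenParamSet

LOCUS_STATES = ("AA", "AB", "BB")


class GenotypeError(ValueError):
    """Malformed genotype string or locus state."""


def _normalize_locus(state: str) -> str:
    state = state.upper()
    if state == "BA":
        state = "AB"
    if state not in LOCUS_STATES:
        raise GenotypeError(f"invalid locus state {state!r}; expected AA, AB or BB")
    return state


@dataclass(frozen=True)
class Genotype:
    """Diploid state at the activator (U) and inhibitor (V) loci."""

    locus_u: str
    locus_v: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "locus_u", _normalize_locus(self.locus_u))
        object.__setattr__(self, "locus_v", _normalize_locus(self.locus_v))

    # -------------------------------------------------------------- parsing
    @classmethod
    def parse(cls, text: str) -> "Genotype":
        """Parse the ``"U:AB,V:BB"`` string format used in CLI flags."""
        fields = {}
        try:
            for part in text.split(","):
                locus, state = part.strip().split(":")
                fields[locus.strip().upper()] = state.strip()
            return cls(fields["U"], fields["V"])
        except (ValueError, KeyError) as exc:
            raise GenotypeError(
                f"cannot parse genotype {text!r}; expected e.g. 'U:AB,V:BB'"
            ) from exc

    def __str__(self) -> str:
        return f"U:{self.locus_u},V:{self.locus_v}"

    # ------------------------------------------------------------ structure
    def alleles(self, tf: str) -> tuple[str, str]:
        """Ordered haplotype alleles at the locus coding for TF 'u' or 'v'."""
        state = {"u": self.locus_u, "v": self.locus_v}[tf]
        return (state[0], state[1])

    def is_homozygous(self, tf: str) -> bool:
        a1, a2 = self.alleles(tf)
        return a1 == a2

    @property
    def doubly_homozygous(self) -> bool:
        return self.is_homozygous("u") and self.is_homozygous("v")

    def relabeled(self) -> "Genotype":
        flip = {"AA": "BB", "AB": "AB", "BB": "AA"}
        return Genotype(flip[self.locus_u], flip[self.locus_v])


PARENT_A = Genotype("AA", "AA")
PARENT_B = Genotype("BB", "BB")
F1 = Genotype("AB", "AB")

#: The nine F2 genotypes in row-major (locus U outer, locus V inner) order,
#: so a 3x3 grid has parent A, the F1 and parent B on the diagonal.
F2_GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype(u, v) for u in LOCUS_STATES for v in LOCUS_STATES
)


@dataclass(frozen=True)
class CrossResult:
    """Offspring genotypes of a cross with their Mendelian probabilities."""

    genotypes: tuple[tuple[Genotype, Fraction], ...]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.genotypes)
        if total != 1:
            raise GenotypeError(f"cross probabilities sum to {total}, not 1")

    def probability(self, genotype: Genotype) -> Fraction:
        for g, p in self.genotypes:
            if g == genotype:
                return p
        return Fraction(0)

    def __len__(self) -> int:
        return len(self.genotypes)


def _gametes(state: str) -> dict[str, Fraction]:
    a1, a2 = state[0], state[1]
    if a1 == a2:
        return {a1: Fraction(1)}
    return {a1: Fraction(1, 2), a2: Fraction(1, 2)}


def _locus_offspring(state1: str, state2: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for a, pa in _gametes(state1).items():
        for b, pb in _gametes(state2).items():
            key = _normalize_locus("".join(sorted(a + b)))
            out[key] = out.get(key, Fraction(0)) + pa * pb
    return out


def cross(parent1: Genotype, parent2: Genotype) -> CrossResult:
    """Offspring distribution of parent1 x parent2 (independent loci)."""
    dist_u = _locus_offspring(parent1.locus_u, parent2.locus_u)
    dist_v = _locus_offspring(parent1.locus_v, parent2.locus_v)
    combos = []
    for u in LOCUS_STATES:
        for v in LOCUS_STATES:
            p = dist_u.get(u, Fraction(0)) * dist_v.get(v, Fraction(0))
            if p > 0:
                combos.append((Genotype(u, v), p))
    return CrossResult(tuple(combos))


def enumerate_f2(parent: Genotype = F1) -> CrossResult:
    """Genotype distribution from selfing ``parent`` (F1 x F1 -> F2).

    Selfing the doubly heterozygous F1 segregates 1:2:1 independently at
    each locus, giving 9 distinct genotypes with probabilities
    {1,2,1} x {1,2,1} / 16.
    """
    return cross(parent, parent)


# --------------------------------------------------------------------------
# Parameter assignment per genotype
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterAssignment:
    """Genotype-resolved view of the F1 parameter set.

    species_alleles : per species slot ('u', 'v', 'u_hat', 'v_hat') the
        allele whose rate constants it carries.
    kappa_keys : mapping (regulated slot, binding slot) -> BindingKey for
        the sixteen positions of the four Hill functions.
    """

    genotype: Genotype
    species_alleles: dict[str, str]
    kappa_keys: dict[tuple[str, str], BindingKey]

    def distinct_kappa(self) -> frozenset[BindingKey]:
        return frozenset(self.kappa_keys.values())


_SLOTS = ("u", "v", "u_hat", "v_hat")
_SLOT_TF = {"u": "u", "v": "v", "u_hat": "u", "v_hat": "v"}
_SLOT_HAP = {"u": 0, "v": 0, "u_hat": 1, "v_hat": 1}


def assign_parameters(
    genotype: Genotype, f1_params: MultigenParamSet | None = None
) -> ParameterAssignment:
    """Resolve which rate and binding constants a genotype's equations use.

    Haplotype 1 carries the first allele at each locus and haplotype 2 the
    second; every rate constant takes the superscript of its own allele, and
    every binding constant takes (regulated species' allele, binding
    species' allele).  ``f1_params`` is accepted for interface completeness
    (the assignment depends only on the genotype; with a parameter set the
    caller can look the keys up directly).
    """
    species_alleles = {
        slot: genotype.alleles(_SLOT_TF[slot])[_SLOT_HAP[slot]] for slot in _SLOTS
    }
    kappa_keys = {}
    for reg in _SLOTS:
        for bind in _SLOTS:
            kappa_keys[(reg, bind)] = BindingKey(
                _SLOT_TF[reg],
                species_alleles[reg],
                _SLOT_TF[bind],
                species_alleles[bind],
            )
    return ParameterAssignment(genotype, species_alleles, kappa_keys)


def count_kappa(genotype: Genotype, f1_params: MultigenParamSet | None = None) -> int:
    """Number of distinct binding constants the genotype's equations use.

    Doubly homozygous genotypes use 4 of the F1's 16; singly heterozygous
    genotypes use 9; the doubly heterozygous F1 uses all 16.
    """
    return len(assign_parameters(genotype, f1_params).distinct_kappa())


def referenced_kappa(genotype: Genotype) -> frozenset[BindingKey]:
    return assign_parameters(genotype).distinct_kappa()


def kappa_union(genotypes: Iterable[Genotype]) -> frozenset[BindingKey]:
    out: frozenset[BindingKey] = frozenset()
    for g in genotypes:
        out = out | referenced_kappa(g)
    return out


def heterozygote_only_kappa() -> frozenset[BindingKey]:
    """The 8 mixed-superscript constants no doubly homozygous genotype uses."""
    return frozenset(k for k in ALL_BINDING_KEYS if not k.is_cis)
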