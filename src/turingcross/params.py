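"""Heritable parameterization of the diploid activator-inhibitor network.

A cross between two inbred parents is fully specified by the parameters of
the doubly heterozygous F1 hybrid: one (alpha, beta, gamma) rate triple per
transcription factor per allele (4 triples), sixteen equilibrium association
constants kappa (one per regulated-TF-allele x binding-TF-allele pair), and
the two diffusion coefficients.  Every other genotype of the cross uses a
subset of these numbers.

Concentration units are arbitrary: only the products kappa * concentration
enter the equations, so kappa carries inverse concentration units and the
Hill saturation terms are dimensionless.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

TFS = ("u", "v")
ALLELES = ("A", "B")


class ParameterError(ValueError):
    """A parameter set is incomplete or violates a sign constraint."""


@dataclass(frozen=True)
class AlleleRates:
    """Rate constants of one gene product (one TF from one allele).

    alpha : baseline production rate (concentration / time), > 0
    beta  : first-order degradation rate constant (1 / time), > 0
    gamma : maximal regulated production rate (concentration / time), >= 0
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ParameterError(f"alpha must be positive, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ParameterError(f"beta must be positive, got {self.beta}")
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ParameterError(f"gamma must be nonnegative, got {self.gamma}")


@dataclass(frozen=True, order=True)
class BindingKey:
    """Identity of one association constant.

    ``regulated_tf``/``regulated_allele`` name the gene product whose
    production is being regulated (first subscript/superscript pair of
    kappa); ``binding_tf``/``binding_allele`` name the transcription factor
    doing the binding (second pair).  E.g. the label ``"vu_BA"`` is the
    affinity of the allele-A activator for the binding site regulating the
    allele-B inhibitor.
    """

    regulated_tf: str
    regulated_allele: str
    binding_tf: str
    binding_allele: str

    def __post_init__(self) -> None:
        if self.regulated_tf not in TFS or self.binding_tf not in TFS:
            raise ParameterError(f"invalid TF in {self}")
        if self.regulated_allele not in ALLELES or self.binding_allele not in ALLELES:
            raise ParameterError(f"invalid allele in {self}")

    @property
    def label(self) -> str:
        return (
            f"{self.regulated_tf}{self.binding_tf}"
            f"_{self.regulated_allele}{self.binding_allele}"
        )

    @classmethod
    def from_label(cls, label: str) -> "BindingKey":
        try:
            subs, sups = label.split("_")
            return cls(subs[0], sups[0], subs[1], sups[1])
        except (ValueError, IndexError) as exc:
            raise ParameterError(f"malformed binding-constant label {label!r}") from exc

    @property
    def is_cis(self) -> bool:
        """True when the binding TF and the regulated site share an allele type."""
        return self.regulated_allele == self.binding_allele


#: All sixteen binding-constant identities, in a fixed canonical order.
ALL_BINDING_KEYS: tuple[BindingKey, ...] = tuple(
    BindingKey(rt, ra, bt, ba)
    for rt in TFS
    for bt in TFS
    for ra in ALLELES
    for ba in ALLELES
)

RATE_SLOTS: tuple[tuple[str, str], ...] = tuple(
    (tf, allele) for tf in TFS for allele in ALLELES
)


@dataclass(frozen=True)
class MultigenParamSet:
    """The complete heritable parameterization of one simulated cross.

    rates : mapping (tf, allele) -> AlleleRates, exactly 4 entries
    kappa : mapping BindingKey -> association constant (1/concentration),
            exactly 16 entries, all >= 0
    D_u   : activator diffusion coefficient (length^2/time), > 0
    D_v   : inhibitor diffusion coefficient (length^2/time), > 0; for
            pattern-forming simulations D_v/D_u > 1
    """

    rates: Mapping[tuple[str, str], AlleleRates]
    kappa: Mapping[BindingKey, float]
    D_u: float
    D_v: float

    def __post_init__(self) -> None:
        missing = [f"{tf}_{al}" for tf, al in RATE_SLOTS if (tf, al) not in self.rates]
        if missing:
            raise ParameterError(f"missing rate entries: {', '.join(missing)}")
        missing_k = [k.label for k in ALL_BINDING_KEYS if k not in self.kappa]
        if missing_k:
            raise ParameterError(f"missing binding constants: {', '.join(missing_k)}")
        for key, val in self.kappa.items():
            if not (val >= 0 and math.isfinite(val)):
                raise ParameterError(f"kappa {key.label} must be nonnegative, got {val}")
        if not (self.D_u > 0 and self.D_v > 0):
            raise ParameterError("diffusion coefficients must be positive")
        object.__setattr__(self, "rates", dict(self.rates))
        object.__setattr__(self, "kappa", dict(self.kappa))

    @property
    def d(self) -> float:
        """Inhibitor-to-activator diffusion ratio D_v/D_u."""
        return self.D_v / self.D_u

    # ---------------------------------------------------------------- JSON
    def to_dict(self) -> dict:
        return {
            "rates": {
                f"{tf}_{al}": {
                    "alpha": self.rates[(tf, al)].alpha,
                    "beta": self.rates[(tf, al)].beta,
                    "gamma": self.rates[(tf, al)].gamma,
                }
                for tf, al in RATE_SLOTS
            },
            "kappa": {k.label: self.kappa[k] for k in ALL_BINDING_KEYS},
            "D_u": self.D_u,
            "D_v": self.D_v,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MultigenParamSet":
        try:
            rates_raw = data["rates"]
            kappa_raw = data["kappa"]
            D_u = float(data["D_u"])
            D_v = float(data["D_v"])
        except KeyError as exc:
            raise ParameterError(f"missing top-level key {exc.args[0]!r}") from exc
        rates = {}
        for tf, al in RATE_SLOTS:
            slot = f"{tf}_{al}"
            if slot not in rates_raw:
                raise ParameterError(f"missing rate entry {slot!r}")
            entry = rates_raw[slot]
            try:
                rates[(tf, al)] = AlleleRates(
                    float(entry["alpha"]), float(entry["beta"]), float(entry["gamma"])
                )
            except KeyError as exc:
                raise ParameterError(
                    f"rate entry {slot!r} missing field {exc.args[0]!r}"
                ) from exc
        kappa = {}
        for key in ALL_BINDING_KEYS:
            if key.label not in kappa_raw:
                raise ParameterError(f"missing binding constant {key.label!r}")
            kappa[key] = float(kappa_raw[key.label])
        return cls(rates=rates, kappa=kappa, D_u=D_u, D_v=D_v)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "MultigenParamSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def sha256(self) -> str:
        """Hash of the canonical JSON form, for run manifests."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def relabeled(self) -> "MultigenParamSet":
        """Swap allele labels A and B everywhere (relabeling symmetry)."""
        flip = {"A": "B", "B": "A"}
        return MultigenParamSet(
            rates={(tf, flip[al]): r for (tf, al), r in self.rates.items()},
            kappa={
                BindingKey(
                    k.regulated_tf,
                    flip[k.regulated_allele],
                    k.binding_tf,
                    flip[k.binding_allele],
                ): v
                for k, v in self.kappa.items()
            },
            D_u=self.D_u,
            D_v=self.D_v,
        )
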