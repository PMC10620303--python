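"""Serialization, run manifests and output writing.

Parameter sets travel as JSON (schema mirroring the rate and binding
constant tables: rates keyed ``u_A`` ... ``v_B``, binding constants keyed
``uu_AA`` ... ``vv_BB`` with first pair = regulated TF+allele, second pair
= binding TF+allele), fields as one CSV matrix per species with a JSON
sidecar, sweeps as CSV.  A RunManifest records everything needed to
reproduce an output bit-for-bit: parameter hash, genotype, d, simulation
config, seeds and package version.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import MultigenParamSet
from .solver import ConvergenceRecord, Field2D, SimConfig


def load_params(path: str | Path) -> MultigenParamSet:
    """Load and validate a parameter-set JSON file.

    Raises :class:`turingcross.params.ParameterError` naming the missing or
    invalid key.
    """
    return MultigenParamSet.load(path)


def save_params(params: MultigenParamSet, path: str | Path) -> None:
    params.save(path)


@dataclass(frozen=True)
class RunManifest:
    params_sha256: str
    genotype: str | None
    d: float
    sim_config: dict | None
    seeds: dict
    package_version: str
    command: str
    timestamp: str

    @classmethod
    def create(
        cls,
        params: MultigenParamSet,
        command: str,
        genotype: str | None = None,
        d: float | None = None,
        config: SimConfig | None = None,
        seeds: dict | None = None,
    ) -> "RunManifest":
        from . import __version__

        return cls(
            params_sha256=params.sha256(),
            genotype=genotype,
            d=params.d if d is None else d,
            sim_config=dataclasses.asdict(config) if config else None,
            seeds=seeds or {},
            package_version=__version__,
            command=command,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )


def write_field(field: Field2D, outdir: str | Path, stem: str = "field") -> list[Path]:
    """One CSV matrix per species plus a JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, name in enumerate(field.species):
        path = outdir / f"{stem}_{name}.csv"
        np.savetxt(path, field.values[i], delimiter=",", fmt="%.12g")
        paths.append(path)
    sidecar = outdir / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {"species": list(field.species), "dx": field.dx, "t": field.t},
            indent=2,
        )
        + "\n"
    )
    paths.append(sidecar)
    return paths


def read_field(outdir: str | Path, stem: str = "field") -> Field2D:
    outdir = Path(outdir)
    sidecar = json.loads((outdir / f"{stem}.json").read_text())
    values = np.stack(
        [
            np.loadtxt(outdir / f"{stem}_{name}.csv", delimiter=",", ndmin=2)
            for name in sidecar["species"]
        ]
    )
    return Field2D(
        values=values,
        dx=sidecar["dx"],
        t=sidecar["t"],
        species=tuple(sidecar["species"]),
    )


def write_convergence(record: ConvergenceRecord, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(record), indent=2, sort_keys=True) + "\n"
    )


def write_sweep_csv(m_values, d_star, path: str | Path) -> None:
    """CSV of (m, d_star) pairs; non-finite d_star written as inf/nan."""
    with open(path, "w") as fh:
        fh.write("m,d_star\n")
        for m, ds in zip(m_values, d_star):
            fh.write(f"{m:.10g},{ds:.10g}\n")


def write_dispersion_csv(curve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("k,growth_rate\n")
        for k, s in zip(curve.k_values, curve.growth_rates):
            fh.write(f"{k:.10g},{s:.10g}\n")
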