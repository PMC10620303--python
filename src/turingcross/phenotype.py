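"""Classify simulated fields as petal phenotypes and render figure grids.

Total activator concentration (u + u_hat) is the proxy for anthocyanin
pigment.  A field counts as patterned when its spatial coefficient of
variation exceeds a threshold (default 0.05) — Turing patterns exceed this
by orders of magnitude while relaxed homogeneous fields sit at roundoff
level.  The dominant wavelength comes from the peak of the radially
averaged power spectrum, and spots are connected components above the
midpoint level set.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genetics import F2_GENOTYPES, Genotype
from .params import MultigenParamSet
from .solver import ConvergenceRecord, Field2D, SimConfig, run_to_steady
from .stability import (
    AdmissibilityError,
    check_admissibility,
    find_steady_state,
    max_growth,
)
from .systems import genotype_system

#: Yellow-to-red pseudocolor used for all activator renderings.
ACTIVATOR_CMAP = "autumn_r"

#: Default coefficient-of-variation threshold separating patterned fields
#: from roundoff-level inhomogeneity.
CV_THRESHOLD = 0.05


@dataclass(frozen=True)
class PhenotypeReport:
    patterned: bool
    mean_activator: float
    min_activator: float
    max_activator: float
    amplitude: float
    cv: float
    dominant_wavelength: float | None = None
    spot_count: int | None = None
    labyrinthine: bool = False
    reliable: bool = True

    def to_dict(self) -> dict:
        return {
            "patterned": self.patterned,
            "mean_activator": self.mean_activator,
            "min_activator": self.min_activator,
            "max_activator": self.max_activator,
            "amplitude": self.amplitude,
            "cv": self.cv,
            "dominant_wavelength": self.dominant_wavelength,
            "spot_count": self.spot_count,
            "labyrinthine": self.labyrinthine,
            "reliable": self.reliable,
        }


def radial_power_spectrum(
    u: np.ndarray, dx: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum of a 2D field.

    Returns (k, power) with k in radians per length; the zero mode is
    excluded.  Bin width is one fundamental frequency of the shorter axis.
    """
    ny, nx = u.shape
    F = np.fft.fft2(u - u.mean())
    power = np.abs(F) ** 2
    fy = np.fft.fftfreq(ny, d=dx)
    fx = np.fft.fftfreq(nx, d=dx)
    kmag = 2.0 * np.pi * np.hypot(fy[:, None], fx[None, :])
    dk = 2.0 * np.pi / (dx * min(nx, ny))
    nbins = int(np.ceil(kmag.max() / dk)) + 1
    idx = np.minimum((kmag / dk + 0.5).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=power.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    with np.errstate(invalid="ignore"):
        radial = sums / np.maximum(counts, 1)
    k = np.arange(nbins) * dk
    return k[1:], radial[1:]


def dominant_wavelength(u: np.ndarray, dx: float) -> float:
    """Wavelength (length units) of the spectral peak of the field."""
    k, power = radial_power_spectrum(u, dx)
    return float(2.0 * np.pi / k[int(np.argmax(power))])


def count_spots(u: np.ndarray) -> tuple[int, bool]:
    """Connected components above the (max+min)/2 level set.

    Returns (count, labyrinthine) where labyrinthine flags a largest
    component spanning more than 25% of the domain (stripe/maze patterns
    rather than discrete spots).
    """
    from scipy import ndimage

    level = 0.5 * (u.max() + u.min())
    mask = u > level
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0, False
    sizes = ndimage.sum_labels(np.ones_like(u), labels, index=np.arange(1, n + 1))
    labyrinthine = bool(np.max(sizes) > 0.25 * u.size)
    return int(n), labyrinthine


def classify(
    field: Field2D,
    threshold: float = CV_THRESHOLD,
    record: ConvergenceRecord | None = None,
) -> PhenotypeReport:
    """Summarize a simulated field as a phenotype.

    A non-converged convergence record flags the report unreliable but the
    classification is still computed.
    """
    u = field.total("u")
    mean = float(u.mean())
    cv = float(u.std() / mean) if mean > 0 else 0.0
    patterned = cv > threshold
    reliable = record.converged if record is not None else True
    if not reliable:
        warnings.warn("classifying a non-converged field", stacklevel=2)
    wavelength = spot_count = None
    labyrinthine = False
    if patterned:
        wavelength = dominant_wavelength(u, field.dx)
        spot_count, labyrinthine = count_spots(u)
    return PhenotypeReport(
        patterned=patterned,
        mean_activator=mean,
        min_activator=float(u.min()),
        max_activator=float(u.max()),
        amplitude=float(u.max() - u.min()),
        cv=cv,
        dominant_wavelength=wavelength,
        spot_count=spot_count,
        labyrinthine=labyrinthine,
        reliable=reliable,
    )


def render(
    field: Field2D,
    path=None,
    colormap_range: tuple[float, float] | None = None,
):
    """Yellow-to-red image of total activator; returns the RGBA array.

    ``colormap_range`` fixes (vmin, vmax) so panels of one figure share a
    color scale; defaults to the field's own range.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    u = field.total("u")
    if colormap_range is None:
        vmin, vmax = float(u.min()), float(u.max())
    else:
        vmin, vmax = colormap_range
    if vmax <= vmin:
        vmax = vmin + 1e-12
    norm = Normalize(vmin=vmin, vmax=vmax, clip=True)
    rgba = matplotlib.colormaps[ACTIVATOR_CMAP](norm(u))
    if path is not None:
        plt.imsave(path, rgba)
    return rgba


@dataclass(frozen=True)
class F2GridResult:
    """Reports and fields for the 3x3 genotype grid of an F2 population."""

    reports: dict[Genotype, PhenotypeReport]
    fields: dict[Genotype, Field2D]
    records: dict[Genotype, ConvergenceRecord]
    d_used: float


def f2_grid(
    params: MultigenParamSet,
    d: float | None = None,
    config: SimConfig | None = None,
    require_admissible: bool = True,
) -> F2GridResult:
    """Simulate all nine F2 genotypes and classify each field.

    The 3x3 grid is ordered by activator genotype (rows) and inhibitor
    genotype (columns), so parent A, the F1 and parent B sit on the
    diagonal; with the same seed their panels reproduce standalone runs
    exactly.  Refuses non-admissible parameter sets unless told otherwise.
    """
    d_used = params.d if d is None else d
    config = config or SimConfig()
    if require_admissible:
        report = check_admissibility(params, d_used)
        if not report.verdict:
            raise AdmissibilityError(
                "parameter set not admissible: " + "; ".join(report.reasons)
            )
    reports = {}
    fields = {}
    records = {}
    for genotype in F2_GENOTYPES:
        system = genotype_system(params, genotype)
        ss = find_steady_state(system)
        field, record = run_to_steady(system, d=d_used, config=config, steady_state=ss)
        reports[genotype] = classify(field, record=record)
        fields[genotype] = field
        records[genotype] = record
    return F2GridResult(reports=reports, fields=fields, records=records, d_used=d_used)


def composite_grid_image(result: F2GridResult, path=None):
    """3x3 composite PNG of the F2 grid with genotype labels and a shared
    color scale across panels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = max(r.max_activator for r in result.reports.values())
    vmin = min(r.min_activator for r in result.reports.values())
    fig, axes = plt.subplots(3, 3, figsize=(9, 9))
    states = ("AA", "AB", "BB")
    for i, lu in enumerate(states):
        for j, lv in enumerate(states):
            g = Genotype(lu, lv)
            ax = axes[i][j]
            ax.imshow(
                result.fields[g].total("u"),
                cmap=ACTIVATOR_CMAP,
                vmin=vmin,
                vmax=vmax,
                interpolation="nearest",
            )
            ax.set_title(str(g), fontsize=9)
            ax.set_xticks([])
            ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    plt.close(fig)
    return fig


def linear_verdicts(
    params: MultigenParamSet, d: float | None = None
) -> dict[Genotype, bool]:
    """Turing-instability verdict (True = patterned expected) per genotype,
    from linear analysis at the working diffusion ratio."""
    d_used = params.d if d is None else d
    out = {}
    for genotype in F2_GENOTYPES:
        system = genotype_system(params, genotype)
        ss = find_steady_state(system)
        sigma, _ = max_growth(system, ss.concentrations, d=d_used)
        out[genotype] = sigma > 0.0
    return out
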