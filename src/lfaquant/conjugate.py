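"""Antibody-gold-nanoparticle conjugate characterization arithmetic.

Covers the bookkeeping around a coupling reaction: how many antibodies were
offered per particle, how many fit in a monolayer given the IgG footprint,
the synthesis yield and plasmon-peak shift from UV-Vis spectra, and layer
thickness / number-mean diameter from DLS size distributions.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.constants import Avogadro

from .containers import SizeDistribution, Spectrum
from .errors import DomainError

__all__ = [
    "AntibodyFootprint", "ConjugateRecipe", "DEFAULT_FOOTPRINT",
    "IGG_MOLAR_MASS", "PARTICLES_PER_ML_AT_OD1", "antibodies_per_particle",
    "monolayer_capacity", "excess_factor", "lambda_max", "synthesis_yield",
    "fwhm", "peak_shift_and_width", "layer_thickness", "number_mean_diameter",
]

#: molar mass of an intact IgG antibody, g/mol
IGG_MOLAR_MASS = 150_000.0

#: supplier-nominal particle number concentration of an OD-1 colloid, per ml,
#: keyed by core diameter in nm; overridable per recipe
PARTICLES_PER_ML_AT_OD1 = {20: 7.0e11, 40: 9.0e10}


@dataclass(frozen=True)
class AntibodyFootprint:
    """Projected area one IgG occupies on the particle surface."""

    length_nm: float = 14.5
    width_nm: float = 8.5

    def __post_init__(self) -> None:
        if self.length_nm <= 0 or self.width_nm <= 0:
            raise DomainError("footprint dimensions must be positive")

    @property
    def area_nm2(self) -> float:
        return self.length_nm * self.width_nm


DEFAULT_FOOTPRINT = AntibodyFootprint()


@dataclass(frozen=True)
class ConjugateRecipe:
    """Volumes and concentrations of one antibody-AuNP coupling reaction.

    ``particle_number_concentration`` is particles per ml of an OD-1
    suspension; when omitted it is looked up from
    :data:`PARTICLES_PER_ML_AT_OD1` by core diameter.
    """

    antibody_volume_ul: float
    antibody_concentration_mg_per_ml: float
    particle_diameter_nm: float
    particle_od: float = 1.0
    particle_volume_ml: float = 1.0
    antibody_molar_mass: float = IGG_MOLAR_MASS
    particle_number_concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.antibody_volume_ul < 0:
            raise DomainError("antibody volume must be >= 0")
        for name in ("antibody_concentration_mg_per_ml", "particle_diameter_nm",
                     "particle_od", "particle_volume_ml", "antibody_molar_mass"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def particles(self) -> float:
        """Absolute number of nanoparticles in the reaction."""
        c = self.particle_number_concentration
        if c is None:
            key = int(round(self.particle_diameter_nm))
            if key not in PARTICLES_PER_ML_AT_OD1:
                raise DomainError(
                    f"no nominal particle concentration for {key} nm cores; "
                    "set particle_number_concentration explicitly")
            c = PARTICLES_PER_ML_AT_OD1[key]
        return c * self.particle_od * self.particle_volume_ml

    @property
    def antibody_molecules(self) -> float:
        mass_g = (self.antibody_volume_ul * 1e-3
                  * self.antibody_concentration_mg_per_ml * 1e-3)
        return mass_g / self.antibody_molar_mass * Avogadro

    @classmethod
    def from_json(cls, path: str | Path) -> "ConjugateRecipe":
        return cls(**json.loads(Path(path).read_text()))


def antibodies_per_particle(recipe: ConjugateRecipe) -> int:
    """Antibody molecules offered per nanoparticle, nearest integer."""
    particles = recipe.particles
    if particles <= 0:
        raise DomainError("zero particle count in recipe")
    return int(round(recipe.antibody_molecules / particles))


def monolayer_capacity(particle_diameter_nm: float,
                       footprint: AntibodyFootprint = DEFAULT_FOOTPRINT) -> int:
    """Whole antibodies fitting on the sphere surface: floor(pi d^2 / area).

    Uses the bare core diameter; a fractional antibody cannot bind, hence
    the floor.
    """
    if particle_diameter_nm <= 0:
        raise DomainError("diameter must be positive")
    return math.floor(math.pi * particle_diameter_nm ** 2 / footprint.area_nm2)


def excess_factor(recipe: ConjugateRecipe,
                  footprint: AntibodyFootprint = DEFAULT_FOOTPRINT) -> float:
    """Offered antibodies relative to the monolayer capacity."""
    cap = monolayer_capacity(recipe.particle_diameter_nm, footprint)
    if cap <= 0:
        raise DomainError("zero monolayer capacity")
    return antibodies_per_particle(recipe) / cap


# ---------------------------------------------------------------------------
# UV-Vis
# ---------------------------------------------------------------------------

def lambda_max(spectrum: Spectrum) -> tuple[float, float]:
    """Wavelength and absorbance of the global maximum (lowest nm on ties).

    A flat spectrum or a maximum at the window edge (monotone spectrum) is
    degenerate for peak analysis and triggers a warning.
    """
    ab = spectrum.absorbance
    i = int(np.argmax(ab))
    if np.ptp(ab) == 0:
        warnings.warn("flat spectrum: no defined absorbance maximum",
                      stacklevel=2)
    elif i in (0, ab.size - 1):
        warnings.warn("absorbance maximum at the window edge; spectrum is "
                      "monotone over the acquisition range", stacklevel=2)
    return float(spectrum.wavelengths[i]), float(ab[i])


def synthesis_yield(initial: Spectrum, final: Spectrum) -> float:
    """Particle-retention yield: ratio of final to initial peak absorbance.

    The plasmon-peak OD is proportional to particle concentration at fixed
    size, so the OD ratio measures how many nanoparticles survived the
    synthesis and washing steps.
    """
    od0 = float(initial.absorbance.max())
    od1 = float(final.absorbance.max())
    if od0 <= 0:
        raise DomainError("initial spectrum has non-positive peak OD")
    return od1 / od0


def fwhm(spectrum: Spectrum) -> float:
    """Full width at half maximum by linear interpolation at half height.

    Returns NaN (with a warning) when the half-maximum level is not
    bracketed on both sides of the peak within the acquisition window.
    """
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    i = int(np.argmax(ab))
    half = ab[i] / 2.0
    if ab[i] <= 0:
        warnings.warn("non-positive peak: width undefined", stacklevel=2)
        return float("nan")

    def cross(idx_range, reverse: bool) -> float | None:
        rng = idx_range[::-1] if reverse else idx_range
        prev = i
        for j in rng:
            if ab[j] <= half:
                x0, x1 = wl[prev], wl[j]
                y0, y1 = ab[prev], ab[j]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = j
        return None

    left = cross(range(i - 1, -1, -1), reverse=False)
    right = cross(range(i + 1, ab.size), reverse=False)
    if left is None or right is None:
        warnings.warn("half maximum not bracketed inside the window: "
                      "width undefined", stacklevel=2)
        return float("nan")
    return float(right - left)


def peak_shift_and_width(bare: Spectrum, conjugate: Spectrum
                         ) -> tuple[float, float]:
    """Plasmon shift and broadening of a conjugate relative to bare gold.

    Returns ``(lambda_max(conjugate) - lambda_max(bare), FWHM change)`` in
    nm.  A red shift with broadening indicates a grown dielectric layer
    (antibody coating) and, when strong, agglomeration.
    """
    shift = lambda_max(conjugate)[0] - lambda_max(bare)[0]
    return float(shift), float(fwhm(conjugate) - fwhm(bare))


# ---------------------------------------------------------------------------
# DLS
# ---------------------------------------------------------------------------

def layer_thickness(conjugate_diameter_nm: float,
                    core_diameter_nm: float) -> float:
    """Adsorbed-layer thickness from hydrodynamic diameters: half the growth."""
    if conjugate_diameter_nm < core_diameter_nm:
        raise DomainError("conjugate diameter smaller than core diameter")
    return (conjugate_diameter_nm - core_diameter_nm) / 2.0


def number_mean_diameter(dist: SizeDistribution,
                         peak_fraction: float = 0.05) -> float:
    """Number-weighted mean diameter of the main peak.

    The main peak is the connected run of bins whose weight exceeds
    ``peak_fraction`` of the modal weight and which carries the largest
    total weight; satellite agglomerate shoulders are thereby excluded.
    """
    w = dist.weights
    cut = peak_fraction * w.max()
    above = w > cut
    # connected runs of above-threshold bins
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))
    if not runs:
        raise DomainError("empty size distribution")
    start, stop = max(runs, key=lambda r: w[r[0]:r[1]].sum())
    ww = w[start:stop]
    return float(np.sum(dist.diameters[start:stop] * ww) / ww.sum())
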