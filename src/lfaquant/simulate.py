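"""Synthetic strip images, plasmon spectra and size distributions.

The generator reproduces the statistical structure the downstream analysis
assumes for a competitive (binding-inhibition) lateral-flow assay read out
by a colour camera:

* a structured membrane with four parallel channels separated by ablated
  barrier lines (the fiducials the zone detector locks onto);
* per channel a blank reference zone, a test spot and a control spot, the
  red colorant of the gold label rendered as *green-channel depletion*;
* test-spot intensity following a four-parameter logistic (4PL) in analyte
  concentration, control-spot intensity constant by default;
* optional planar illumination gradient and i.i.d. Gaussian pixel noise.

Every randomized generator takes an explicit seed and is bit-reproducible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro  # noqa: F401  (re-exported for recipes)

from .containers import (FIDUCIAL_LEVEL, Box, SizeDistribution, Spectrum,
                         StripImage, StripLayout, ZONE_ROLES)
from .errors import DomainError, LayoutError

__all__ = [
    "BindingParams", "SimulationConfig", "default_layout", "free_fraction",
    "fourpl_response", "render_strip", "simulate_batch", "synth_spectrum",
    "synth_size_distribution", "ANTI_AMT_BINDING",
]


# ---------------------------------------------------------------------------
# binding model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingParams:
    """Antibody-analyte binding kinetics.

    ka in 1/(M s), kd in 1/s; the equilibrium dissociation constant
    Kd = kd/ka follows exactly.  ``analyte_molar_mass`` (g/mol) converts
    the assay's mass concentrations (ug/l) to molarity.
    """

    ka: float
    kd: float
    analyte_molar_mass: float

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0:
            raise DomainError("rate constants must be positive")
        if self.analyte_molar_mass <= 0:
            raise DomainError("molar mass must be positive")

    @property
    def Kd(self) -> float:
        """Equilibrium dissociation constant in molar."""
        return self.kd / self.ka

    def to_molar(self, conc_ug_per_l) -> np.ndarray:
        """Convert a mass concentration in ug/l to mol/l."""
        return np.asarray(conc_ug_per_l, dtype=float) * 1e-6 / self.analyte_molar_mass


#: kinetics of the anti-amitriptyline antibody used throughout the examples
#: (amitriptyline molar mass 277.4 g/mol)
ANTI_AMT_BINDING = BindingParams(ka=2.4e4, kd=1.3e-3, analyte_molar_mass=277.4)


def free_fraction(concentration, params: BindingParams):
    """Fraction of detection antibody left free at equilibrium.

    Under analyte excess the fraction of conjugate not blocked by free
    analyte follows the Langmuir isotherm ``Kd / (Kd + C)`` with ``C`` the
    molar analyte concentration.  Monotone non-increasing, 1 at zero
    concentration, 1/2 at ``C = Kd``.

    Parameters
    ----------
    concentration
        Analyte mass concentration in ug/l (scalar or array), >= 0.
    params
        Binding kinetics and molar mass for unit conversion.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    kd = params.Kd
    f = kd / (kd + params.to_molar(c))
    return float(f) if np.isscalar(concentration) else f


def fourpl_response(x, a1: float, a2: float, x0: float, p: float):
    """Four-parameter logistic  y = A2 + (A1 - A2) / (1 + (x/x0)^p).

    Defined for x >= 0 with the p > 0 limit y(0) = A1.
    """
    x = np.asarray(x, dtype=float)
    return a2 + (a1 - a2) / (1.0 + (x / x0) ** p)


# ---------------------------------------------------------------------------
# strip geometry
# ---------------------------------------------------------------------------

def default_layout(n_channels: int = 4,
                   channel_height_px: int = 50,
                   spot_radius_px: int = 12) -> StripLayout:
    """Build the canonical 4-channel layout.

    Flow runs left to right: reference zone, test spot, control spot.
    Channels are stacked vertically, separated by 3 px barrier lines; a
    vertical frame line on each side completes the fiducial pattern so the
    detector can recover both offset components.
    """
    t = 3
    width = 176
    height = (n_channels + 1) * t + n_channels * channel_height_px
    box_half = spot_radius_px + 3
    centers_col = {"reference": 34, "test": 84, "control": 134}
    zones = []
    rows = []
    for ch in range(n_channels):
        top = t + ch * (channel_height_px + t)
        rows.append(top - t)
        rc = top + channel_height_px // 2
        zones.append({
            role: Box(rc - box_half, cc - box_half, rc + box_half, cc + box_half)
            for role, cc in centers_col.items()
        })
    rows.append(height - t)
    # bare-membrane points flanking the zones, four per channel
    ref_points = []
    for ch in range(n_channels):
        rc = t + ch * (channel_height_px + t) + channel_height_px // 2
        for cc in (10, 59, 109, 159):
            ref_points.append((rc, cc))
    return StripLayout(
        image_shape=(height, width),
        zones=zones,
        fiducial_rows=tuple(rows),
        fiducial_cols=(0, width - t),
        fiducial_thickness=t,
        reference_points=ref_points,
        spot_radius_px=spot_radius_px,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated calibration experiment.

    The normalized test/control response follows the 4PL ``(a1, a2, x0, p)``;
    concentrations are the calibration series in ug/l.  ``noise_sd`` is the
    additive Gaussian pixel noise (8-bit intensity units) and
    ``gradient_amplitude`` the relative peak-to-peak tilt of a planar
    illumination field.  ``depth_scale`` and ``control_depth`` set the
    green-channel depletion (intensity units) of a fully developed test spot
    and of the control spot; ``background`` is the bare-membrane green level.
    """

    a1: float = 1.0
    a2: float = 0.1
    x0: float = 50.0
    p: float = 1.2
    concentrations: tuple[float, ...] = (0.0, 1.0, 10.0, 30.0, 100.0,
                                         300.0, 1000.0, 10000.0)
    n_strips: int = 3
    noise_sd: float = 2.0
    gradient_amplitude: float = 0.0
    seed: int = 0
    background: int = 210
    depth_scale: float = 170.0
    control_depth: float = 140.0
    control_slope: float = 0.0
    edge_sigma: float = 1.2

    def __post_init__(self) -> None:
        cs = tuple(float(c) for c in self.concentrations)
        if any(c < 0 for c in cs):
            raise DomainError("concentrations must be non-negative")
        if 0.0 not in cs:
            raise DomainError("concentration series must include 0 (the blank)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.p <= 0 or self.x0 <= 0:
            raise DomainError("4PL needs p > 0 and x0 > 0")
        self.concentrations = cs

    def response(self, concentration) -> np.ndarray:
        """True normalized signal at a concentration (4PL)."""
        return fourpl_response(concentration, self.a1, self.a2, self.x0, self.p)


def _spot_profile(box: Box, radius: float, edge_sigma: float) -> np.ndarray:
    """Unit-depth spot: 1 inside ``radius``, Gaussian shoulder outside."""
    h, w = box.shape
    rc, cc = (h - 1) / 2, (w - 1) / 2
    rr, cic = np.mgrid[0:h, 0:w]
    r = np.hypot(rr - rc, cic - cc)
    if edge_sigma <= 0:
        return (r <= radius).astype(float)
    prof = np.where(r <= radius, 1.0,
                    np.exp(-((r - radius) ** 2) / (2 * edge_sigma ** 2)))
    prof[prof < 1e-4] = 0.0
    return prof


def _dither_flat_spot(plane: np.ndarray, box: Box, radius: float,
                      background: float, depth: float) -> None:
    """Write a hard-edged spot whose *mean* depth is exact to O(1/n).

    The target value ``background - depth`` is generally not an integer; the
    interior pixels are split between the two neighbouring 8-bit levels in
    raster order so the zone mean matches the ground truth to within half an
    intensity unit divided by the pixel count.
    """
    h, w = box.shape
    rc, cc = (h - 1) / 2, (w - 1) / 2
    rr, cic = np.mgrid[0:h, 0:w]
    inside = np.hypot(rr - rc, cic - cc) <= radius
    n = int(inside.sum())
    target = background - depth
    lo = np.floor(target)
    m = int(round((target - lo) * n))  # pixels rounded up to lo+1
    vals = np.full(n, lo)
    vals[:m] = lo + 1
    sub = plane[box.slices()]
    sub[inside] = vals  # raster order via boolean indexing
    plane[box.slices()] = sub


def render_strip(config: SimulationConfig, layout: StripLayout,
                 concentration: float,
                 rng: np.random.Generator | None = None,
                 strip_id: str = "strip") -> tuple[StripImage, dict]:
    """Render one strip at a given analyte concentration.

    Returns the 8-bit RGB image together with a ground-truth record holding
    the noise-free zone means, spot depths, per-channel signals and the true
    normalized response.  With ``rng=None`` a fresh generator is seeded from
    ``config.seed``, so repeated calls with the same arguments are
    bit-identical.
    """
    if concentration < 0:
        raise DomainError("concentration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = layout.image_shape
    bg = float(config.background)
    y = float(config.response(concentration))
    y0 = float(config.response(0.0))

    test_depth = config.depth_scale * y
    control_depth = config.control_depth * (
        1.0 + config.control_slope * (1.0 - y / y0))

    green = np.full((h, w), bg)
    red = np.full((h, w), 235.0)
    blue = np.full((h, w), bg * 0.92)

    radius = float(layout.spot_radius_px)
    exact = (config.noise_sd == 0 and config.gradient_amplitude == 0
             and config.edge_sigma <= 0)
    truth_channels = []
    for zmap in layout.zones:
        for role, depth in (("test", test_depth), ("control", control_depth)):
            box = zmap[role]
            if not exact:
                prof = _spot_profile(box, radius, config.edge_sigma)
                green[box.slices()] -= depth * prof
                blue[box.slices()] -= 0.9 * depth * prof
                red[box.slices()] -= 0.12 * depth * prof
        truth_channels.append({
            "test_depth": test_depth,
            "control_depth": control_depth,
            "test_signal": test_depth,
            "control_signal": control_depth,
            "ratio": test_depth / control_depth,
            "test_spot_mean": bg - test_depth,
            "control_spot_mean": bg - control_depth,
            "reference_mean": bg,
        })

    if config.gradient_amplitude != 0:
        a = config.gradient_amplitude
        cols = (np.arange(w) - (w - 1) / 2) / (w - 1)
        rows = (np.arange(h) - (h - 1) / 2) / (h - 1)
        grad = 1.0 + a * cols[None, :] + 0.5 * a * rows[:, None]
        green *= grad
        red *= grad
        blue *= grad

    mask = layout.fiducial_mask()
    for plane in (green, red, blue):
        plane[mask] = FIDUCIAL_LEVEL

    if config.noise_sd > 0:
        for plane in (green, red, blue):
            plane += rng.normal(0.0, config.noise_sd, size=plane.shape)

    planes = []
    for plane in (red, green, blue):
        planes.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))
    rgb = np.stack(planes, axis=-1)

    if exact:
        # idealized render: interior means match ground truth to O(1/n_px)
        gq = rgb[:, :, 1].astype(float)
        for zmap in layout.zones:
            _dither_flat_spot(gq, zmap["test"], radius, bg, test_depth)
            _dither_flat_spot(gq, zmap["control"], radius, bg, control_depth)
        rgb[:, :, 1] = gq.astype(np.uint8)

    truth = {
        "strip_id": strip_id,
        "concentration_ug_per_l": float(concentration),
        "response": y,
        "normalized_response": y / y0,
        "background": bg,
        "channels": truth_channels,
    }
    image = StripImage(pixels=rgb, meta={"strip_id": strip_id,
                                         "concentration_ug_per_l": float(concentration)})
    return image, truth


def simulate_batch(config: SimulationConfig, layout: StripLayout | None = None,
                   out_dir: str | Path | None = None) -> list[tuple[StripImage, dict]]:
    """Render the full calibration series: n_strips strips per concentration.

    Per-strip RNG streams are spawned from ``config.seed`` so the batch is
    reproducible as a whole.  If ``out_dir`` is given, PNG images, the layout
    JSON and a ground-truth JSON are written there.
    """
    if layout is None:
        layout = default_layout()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.concentrations) * config.n_strips)
    records = []
    k = 0
    for conc in config.concentrations:
        for s in range(config.n_strips):
            sid = f"c{conc:g}_s{s}"
            img, truth = render_strip(config, layout, conc,
                                      rng=np.random.default_rng(children[k]),
                                      strip_id=sid)
            records.append((img, truth))
            k += 1
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        layout.save(out / "layout.json")
        truths = []
        for img, truth in records:
            img.save(out / f"{truth['strip_id']}.png")
            truths.append(truth)
        (out / "ground_truth.json").write_text(json.dumps(
            {"config": asdict(config), "strips": truths}, indent=1))
    return records


def simulate_normalized_signals(config: SimulationConfig, sigma: float,
                                n_replicates: int = 4,
                                rng: np.random.Generator | None = None
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Replicate normalized signals straight in the signal domain.

    For Monte-Carlo studies of the calibration stage it is wasteful to
    rasterize strips; this draws ``n_replicates`` normalized responses per
    concentration as ``y(c)/y(0) + N(0, sigma)``, i.e. Gaussian noise on the
    blank-normalized test/control ratio.  Returns flat (concentration,
    signal) arrays.
    """
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conc = np.repeat(config.concentrations, n_replicates)
    y0 = float(config.response(0.0))
    truth = np.asarray(config.response(conc)) / y0
    return conc, truth + rng.normal(0.0, sigma, size=conc.shape)


# ---------------------------------------------------------------------------
# spectra and size distributions
# ---------------------------------------------------------------------------

#: acquisition window of the spectrometer, nm
SPECTRUM_WINDOW = (450.0, 700.0)


def synth_spectrum(peak_nm: float, width_nm: float, od_peak: float) -> Spectrum:
    """Lorentzian plasmon band on the 1-nm acquisition grid 450-700 nm.

    ``width_nm`` is the full width at half maximum, ``od_peak`` the
    absorbance at the maximum.  Bare 20-nm gold peaks near 522 nm; antibody
    coating red-shifts and broadens the band.
    """
    lo, hi = SPECTRUM_WINDOW
    if not (lo <= peak_nm <= hi):
        raise DomainError(f"peak {peak_nm} nm outside acquisition window {SPECTRUM_WINDOW}")
    if width_nm <= 0:
        raise DomainError("width must be positive")
    if od_peak < 0:
        raise DomainError("peak OD must be non-negative")
    wl = np.arange(lo, hi + 1.0, 1.0)
    gamma = width_nm / 2.0
    ab = od_peak * gamma ** 2 / ((wl - peak_nm) ** 2 + gamma ** 2)
    return Spectrum(wl, ab)


def synth_size_distribution(mean_nm: float, sd_nm: float, n: int = 100_000,
                            seed: int = 0, n_bins: int = 120) -> SizeDistribution:
    """Lognormal number-weighted size distribution, binned.

    Draws ``n`` diameters from the lognormal with number mean ``mean_nm``
    and standard deviation ``sd_nm``, then histograms them on a linear grid.
    ``sd_nm = 0`` degenerates to a single bin at the mean.
    """
    if mean_nm <= 0:
        raise DomainError("mean diameter must be positive")
    if sd_nm < 0:
        raise DomainError("sd must be non-negative")
    if sd_nm == 0:
        return SizeDistribution(np.array([mean_nm]), np.array([1.0]))
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p((sd_nm / mean_nm) ** 2)
    mu = np.log(mean_nm) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    counts, edges = np.histogram(draws, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return SizeDistribution(centers[keep], counts[keep].astype(float))
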