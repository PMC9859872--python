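"""Strip-image signal extraction.

The evaluation chain mirrors the structured-membrane readout: locate the
zones from the ablated fiducial pattern, keep only the green colour channel
(the red colorant of the gold label absorbs green), correct planar
illumination drift from bare-membrane reference points, Otsu-segment each
zone into spot vs background, and report the signal as

    signal = mean(reference zone) - mean(spot pixels)

so a stronger red spot gives a larger positive number.  The test signal is
divided by the control signal of the same channel, and the four channels of
one strip yield a mean and sample SD.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Box, StripImage, StripLayout
from .errors import (CorrectionError, DegenerateInputError, DetectionError,
                     FormatError, LayoutError, NoSpotError)

__all__ = [
    "ZoneQuant", "ChannelSignal", "StripResult", "green_plane",
    "correct_illumination", "otsu_threshold", "quantify_zone",
    "detect_zones", "strip_signals", "signals_to_frame",
]


# ---------------------------------------------------------------------------

def green_plane(image: StripImage | np.ndarray) -> np.ndarray:
    """Extract the green colour plane as float64, unchanged values."""
    px = image.pixels if isinstance(image, StripImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise FormatError(f"need an H x W x 3 RGB raster, got shape {px.shape}")
    return px[:, :, 1].astype(float)


def correct_illumination(plane: np.ndarray,
                         reference_points: list[tuple[int, int]],
                         patch: int = 1) -> np.ndarray:
    """Divide out a first-order (planar) illumination field.

    A plane ``a + b*col + c*row`` is least-squares fitted to the intensities
    sampled at the reference points (mean over a ``(2*patch+1)``-square
    neighbourhood to tame pixel noise) and divided out; the result is
    rescaled so the mean reference intensity is preserved.  A flat field is
    returned unchanged and the operation is idempotent on its own output.

    Raises
    ------
    CorrectionError
        Fewer than three points, or all points collinear.
    """
    plane = np.asarray(plane, dtype=float)
    pts = list(reference_points)
    if len(pts) < 3:
        raise CorrectionError("need at least 3 reference points")
    h, w = plane.shape
    vals, rows, cols = [], [], []
    for r, c in pts:
        if not (0 <= r < h and 0 <= c < w):
            raise CorrectionError(f"reference point {(r, c)} outside image")
        r0, r1 = max(0, r - patch), min(h, r + patch + 1)
        c0, c1 = max(0, c - patch), min(w, c + patch + 1)
        vals.append(plane[r0:r1, c0:c1].mean())
        rows.append(r)
        cols.append(c)
    design = np.column_stack([np.ones(len(pts)), cols, rows])
    if np.linalg.matrix_rank(design) < 3:
        raise CorrectionError("reference points are collinear")
    coef, *_ = np.linalg.lstsq(design, np.asarray(vals), rcond=None)
    cc, rr = np.meshgrid(np.arange(w), np.arange(h))
    surface = coef[0] + coef[1] * cc + coef[2] * rr
    if np.any(surface <= 0):
        raise CorrectionError("fitted illumination surface is non-positive")
    return plane / surface * float(np.mean(vals))


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu threshold of a 256-bin intensity histogram.

    Returns the level ``t`` maximizing the between-class variance
    ``w0*w1*(mu0-mu1)^2`` of the split {value < t} vs {value >= t}; ties are
    broken toward the lowest level.

    Raises
    ------
    DegenerateInputError
        Histogram with fewer than two non-empty bins.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise FormatError("expected a 256-bin histogram")
    if np.any(h < 0):
        raise FormatError("negative histogram counts")
    if np.count_nonzero(h) < 2:
        raise DegenerateInputError("histogram has fewer than two occupied levels")
    total = h.sum()
    levels = np.arange(256)
    # cumulative stats of the lower class {value < t} for t = 1..255
    w0 = np.cumsum(h)[:-1]
    m0 = np.cumsum(h * levels)[:-1]
    w1 = total - w0
    mu_all = (h * levels).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_all - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b)) + 1  # argmax -> first (lowest) maximizer


# ---------------------------------------------------------------------------

@dataclass
class ZoneQuant:
    """Quantification of one spot zone against its reference zone."""

    channel: int
    role: str
    spot_mean: float
    reference_mean: float
    signal: float
    n_spot_pixels: int
    threshold: int
    negative_flag: bool = False


@dataclass
class ChannelSignal:
    """Test and control signal of one channel and their ratio."""

    channel: int
    test: ZoneQuant
    control: ZoneQuant

    @property
    def test_signal(self) -> float:
        return self.test.signal

    @property
    def control_signal(self) -> float:
        return self.control.signal

    @property
    def ratio(self) -> float:
        if self.control.signal <= 0:
            raise NoSpotError(
                f"channel {self.channel}: non-positive control signal, "
                "ratio undefined")
        return self.test.signal / self.control.signal


@dataclass
class StripResult:
    """All channel signals of one strip plus summary statistics."""

    strip_id: str
    channels: list[ChannelSignal]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([c.ratio for c in self.channels])

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())

    @property
    def sd_ratio(self) -> float:
        r = self.ratios
        return float(r.std(ddof=1)) if r.size > 1 else 0.0


def quantify_zone(plane: np.ndarray, zone_box: Box, reference_box: Box,
                  channel: int = 0, role: str = "test",
                  on_blank: str = "raise") -> ZoneQuant:
    """Otsu-segment a zone and measure its signal against the reference.

    The zone box is segmented on its own 256-bin histogram; the spot is the
    *low*-intensity class (green depletion).  Signal is
    ``mean(reference box) - mean(spot pixels)`` computed on the (possibly
    illumination-corrected) float plane.  A zone whose histogram is
    single-valued carries no spot: behaviour is controlled by ``on_blank``
    ("raise" -> :class:`NoSpotError`, "zero" -> zero signal, flagged).
    """
    zone = zone_box.extract(plane)
    ref = reference_box.extract(plane)
    q = np.clip(np.rint(zone), 0, 255).astype(np.intp)
    hist = np.bincount(q.ravel(), minlength=256)
    try:
        t = otsu_threshold(hist)
    except DegenerateInputError:
        if on_blank == "zero":
            return ZoneQuant(channel, role, float(zone.mean()),
                             float(ref.mean()), 0.0, 0, 0, negative_flag=True)
        raise NoSpotError(
            f"channel {channel} {role}: no spot (uniform zone)") from None
    mask = q < t
    if not mask.any():
        raise NoSpotError(f"channel {channel} {role}: empty spot class")
    spot_mean = float(zone[mask].mean())
    ref_mean = float(ref.mean())
    signal = ref_mean - spot_mean
    return ZoneQuant(channel, role, spot_mean, ref_mean, signal,
                     int(mask.sum()), t, negative_flag=signal < 0)


def detect_zones(image: StripImage | np.ndarray, layout: StripLayout,
                 max_shift: int = 10, min_correlation: float = 0.5
                 ) -> tuple[list[dict[str, Box]], tuple[int, int]]:
    """Locate the zone boxes from the ablated fiducial pattern.

    The expected barrier-line mask is cross-correlated (Pearson, on the
    green plane) against the image over integer translations within
    ``±max_shift``; the best shift moves every layout box.  Deterministic by
    construction.

    Returns
    -------
    (zones, offset)
        Shifted per-channel zone boxes and the recovered (drow, dcol).

    Raises
    ------
    DetectionError
        Correlation peak below ``min_correlation`` — fiducials missing.
    LayoutError
        Shifted boxes leave the image.
    """
    plane = green_plane(image)
    template = layout.fiducial_mask().astype(float)
    th, tw = template.shape
    h, w = plane.shape
    tm = template - template.mean()
    tnorm = np.sqrt((tm ** 2).sum())
    best, best_off = -np.inf, (0, 0)
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, dr), min(h, th + dr)
            c0, c1 = max(0, dc), min(w, tw + dc)
            win = plane[r0:r1, c0:c1]
            sub = template[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            wm = win - win.mean()
            sm = sub - sub.mean()
            denom = np.sqrt((wm ** 2).sum() * (sm ** 2).sum())
            if denom == 0:
                continue
            # fiducials are dark: anticorrelated with the mask
            score = -(wm * sm).sum() / denom
            if score > best:
                best, best_off = score, (dr, dc)
    if best < min_correlation:
        raise DetectionError(
            f"fiducial barrier lines not found (best correlation {best:.2f} "
            f"< {min_correlation}); missing landmark: channel barriers")
    dr, dc = best_off
    zones = []
    for zmap in layout.zones:
        shifted = {}
        for role, b in zmap.items():
            nb = b.shifted(dr, dc)
            if nb.row0 < 0 or nb.col0 < 0 or nb.row1 > h or nb.col1 > w:
                raise LayoutError(
                    f"zone {role!r} shifted by {best_off} leaves the image")
            shifted[role] = nb
        zones.append(shifted)
    return zones, best_off


def strip_signals(image: StripImage | np.ndarray, layout: StripLayout,
                  correct: bool = True, detect: bool = True,
                  on_blank: str = "raise", strip_id: str = "strip"
                  ) -> StripResult:
    """Run the full evaluation chain on one strip.

    Green plane -> fiducial-based zone detection -> planar illumination
    correction -> per-zone Otsu quantification -> per-channel test/control
    ratio.  Channels that fail are collected in ``StripResult.failures``
    instead of aborting the strip; an all-channel failure is reported by the
    caller.
    """
    plane = green_plane(image)
    if detect:
        zones, offset = detect_zones(image, layout)
    else:
        zones, offset = layout.zones, (0, 0)
    if correct:
        pts = [(r + offset[0], c + offset[1]) for r, c in layout.reference_points]
        plane = correct_illumination(plane, pts)
    channels, failures = [], []
    for ch, zmap in enumerate(zones):
        try:
            ref_box = zmap["reference"]
            tq = quantify_zone(plane, zmap["test"], ref_box, ch, "test",
                               on_blank=on_blank)
            cq = quantify_zone(plane, zmap["control"], ref_box, ch, "control",
                               on_blank=on_blank)
            channels.append(ChannelSignal(ch, tq, cq))
        except (NoSpotError, LayoutError) as exc:
            failures.append((ch, str(exc)))
    if failures:
        warnings.warn(f"strip {strip_id}: {len(failures)} channel(s) failed: "
                      f"{failures}", stacklevel=2)
    return StripResult(strip_id=strip_id, channels=channels, failures=failures)


def signals_to_frame(results: list[StripResult],
                     concentrations: dict[str, float] | None = None) -> pd.DataFrame:
    """Tabulate strip results as one row per (strip, channel).

    Columns: strip_id, channel, test_signal, control_signal, ratio and,
    when ``concentrations`` maps strip ids, concentration_ug_per_l.
    """
    rows = []
    for res in results:
        for cs in res.channels:
            row = {
                "strip_id": res.strip_id,
                "channel": cs.channel,
                "test_signal": cs.test_signal,
                "control_signal": cs.control_signal,
                "ratio": cs.ratio,
            }
            if concentrations is not None:
                row["concentration_ug_per_l"] = concentrations[res.strip_id]
            rows.append(row)
    return pd.DataFrame(rows)
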