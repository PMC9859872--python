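"""Core data containers and their plain-text file formats.

Strip images travel as 8-bit RGB PNG with a JSON layout sidecar; spectra
and size distributions as two-column TSV.  Everything here is deliberately
dumb: containers validate their invariants and (de)serialize, nothing more.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

from .errors import DomainError, FormatError, LayoutError

#: pixel value used for laser-ablation barrier lines in simulated images
FIDUCIAL_LEVEL = 40


@dataclass(frozen=True)
class Box:
    """Half-open pixel rectangle [row0, row1) x [col0, col1)."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise LayoutError(f"empty box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row0 + self.row1 - 1) / 2, (self.col0 + self.col1 - 1) / 2)

    def shifted(self, drow: int, dcol: int) -> "Box":
        return Box(self.row0 + drow, self.col0 + dcol,
                   self.row1 + drow, self.col1 + dcol)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))

    def extract(self, plane: np.ndarray) -> np.ndarray:
        if (self.row0 < 0 or self.col0 < 0
                or self.row1 > plane.shape[0] or self.col1 > plane.shape[1]):
            raise LayoutError(f"box {self} exceeds plane shape {plane.shape}")
        return plane[self.slices()]

    def overlaps(self, other: "Box") -> bool:
        return (self.row0 < other.row1 and other.row0 < self.row1
                and self.col0 < other.col1 and other.col0 < self.col1)


#: roles of the three zones in one channel, in flow order
ZONE_ROLES = ("reference", "test", "control")


@dataclass
class StripLayout:
    """Geometry of a multichannel test strip in pixel coordinates.

    Channels run along the flow direction (columns); the membrane is divided
    into ``n_channels`` lanes by ablated barrier lines.  Each lane holds a
    blank reference zone followed by the test spot and the control spot.

    Parameters
    ----------
    image_shape
        (height, width) of the strip photograph.
    zones
        ``zones[channel][role]`` -> :class:`Box`, role in ``ZONE_ROLES``.
    fiducial_rows, fiducial_cols
        Start rows/cols of horizontal/vertical barrier lines.
    fiducial_thickness
        Line thickness in pixels.
    reference_points
        Bare-membrane (row, col) coordinates used for illumination
        correction.
    channel_width_um
        Physical lane width; 1000 um for the laser-structured membranes
        this layout mirrors.
    """

    image_shape: tuple[int, int]
    zones: list[dict[str, Box]]
    fiducial_rows: tuple[int, ...]
    fiducial_cols: tuple[int, ...]
    fiducial_thickness: int = 3
    reference_points: list[tuple[int, int]] = field(default_factory=list)
    channel_width_um: float = 1000.0
    spot_radius_px: int = 12

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for ch, zmap in enumerate(self.zones):
            boxes = list(zmap.values())
            for role, b in zmap.items():
                if b.row0 < 0 or b.col0 < 0 or b.row1 > h or b.col1 > w:
                    raise LayoutError(
                        f"zone {role!r} of channel {ch} exceeds image bounds")
            for i in range(len(boxes)):
                for j in range(i + 1, len(boxes)):
                    if boxes[i].overlaps(boxes[j]):
                        raise LayoutError(f"overlapping zones in channel {ch}")
            if "reference" in zmap and "test" in zmap:
                if zmap["reference"].col0 >= zmap["test"].col0:
                    raise LayoutError(
                        "reference zone must precede the test spot "
                        "(sample-pad side)")

    @property
    def n_channels(self) -> int:
        return len(self.zones)

    def fiducial_mask(self) -> np.ndarray:
        """Boolean mask of the barrier/frame lines."""
        h, w = self.image_shape
        m = np.zeros((h, w), dtype=bool)
        t = self.fiducial_thickness
        for r in self.fiducial_rows:
            m[r:r + t, :] = True
        for c in self.fiducial_cols:
            m[:, c:c + t] = True
        return m

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "zones": [
                {role: [b.row0, b.col0, b.row1, b.col1]
                 for role, b in zmap.items()}
                for zmap in self.zones
            ],
            "fiducial_rows": list(self.fiducial_rows),
            "fiducial_cols": list(self.fiducial_cols),
            "fiducial_thickness": self.fiducial_thickness,
            "reference_points": [list(p) for p in self.reference_points],
            "channel_width_um": self.channel_width_um,
            "spot_radius_px": self.spot_radius_px,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StripLayout":
        return cls(
            image_shape=tuple(d["image_shape"]),
            zones=[{role: Box(*v) for role, v in zmap.items()}
                   for zmap in d["zones"]],
            fiducial_rows=tuple(d["fiducial_rows"]),
            fiducial_cols=tuple(d["fiducial_cols"]),
            fiducial_thickness=int(d.get("fiducial_thickness", 3)),
            reference_points=[tuple(p) for p in d.get("reference_points", [])],
            channel_width_um=float(d.get("channel_width_um", 1000.0)),
            spot_radius_px=int(d.get("spot_radius_px", 12)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StripLayout":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StripImage:
    """8-bit RGB strip photograph plus provenance metadata."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected an H x W x 3 RGB raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("intensities outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "StripImage":
        img = Image.open(Path(path))
        if img.mode != "RGB":
            if img.mode in ("L", "I", "I;16"):
                raise FormatError(f"{path}: grayscale image, need RGB")
            img = img.convert("RGB")
        return cls(pixels=np.asarray(img), meta={"source": str(path)})


@dataclass
class Spectrum:
    """Absorbance spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise FormatError("wavelength and absorbance arrays differ in length")
        if self.wavelengths.size == 0:
            raise FormatError("empty spectrum")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelengths must be strictly increasing")

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise FormatError("spectra on different wavelength grids")
        return Spectrum(self.wavelengths, self.absorbance + other.absorbance)

    def save(self, path: str | Path) -> None:
        write_two_column(path, self.wavelengths, self.absorbance,
                         header=("wavelength_nm", "absorbance"))

    @classmethod
    def load(cls, path: str | Path) -> "Spectrum":
        wl, ab = read_two_column(path)
        return cls(wl, ab)


@dataclass
class SizeDistribution:
    """Number-weighted particle size distribution.

    ``diameters`` are bin centres in nm; ``weights`` are non-negative and
    normalized to sum to one on construction.
    """

    diameters: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.diameters.shape != self.weights.shape or self.diameters.size == 0:
            raise FormatError("diameters and weights must be equal-length, non-empty")
        if np.any(self.weights < 0):
            raise DomainError("negative weights in size distribution")
        total = self.weights.sum()
        if total <= 0:
            raise DomainError("size distribution has zero total weight")
        self.weights = self.weights / total

    @property
    def number_mean(self) -> float:
        """Number-weighted mean over the whole distribution."""
        return float(np.sum(self.diameters * self.weights))

    def save(self, path: str | Path) -> None:
        write_two_column(path, self.diameters, self.weights,
                         header=("diameter_nm", "weight"))

    @classmethod
    def load(cls, path: str | Path) -> "SizeDistribution":
        d, w = read_two_column(path)
        return cls(d, w)


def write_two_column(path: str | Path, x: np.ndarray, y: np.ndarray,
                     header: tuple[str, str]) -> None:
    lines = [f"{header[0]}\t{header[1]}"]
    lines += [f"{a:.10g}\t{b:.10g}" for a, b in zip(x, y)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column TSV, tolerating a single header line."""
    raw = Path(path).read_text().strip().splitlines()
    if not raw:
        raise FormatError(f"{path}: empty file")
    start = 0
    try:
        float(raw[0].split("\t")[0])
    except ValueError:
        start = 1
    xs, ys = [], []
    for line in raw[start:]:
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys)
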