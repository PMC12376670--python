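"""Shared domain types, image/region/mask/table I/O, configuration and logging.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based and row-major; the pixel at index ``(r, c)``
  has its center at ``(r + 0.5, c + 0.5)`` in pixel units.
* All physical distances are Euclidean distances between pixel centers (or
  nucleus centroids) multiplied by the isotropic pixel size in µm/px.
* Channels are identified by marker-name strings (``"DAPI"``, ``"FN"``,
  ``"FnBPA5"``, ...), decoupling file layout from analysis semantics.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon, box

__all__ = [
    "CONDITIONS",
    "MultiplexImage",
    "RegionSet",
    "BinaryMask",
    "AnalysisConfig",
    "configure_logging",
    "read_multiplex_image",
    "write_multiplex_image",
    "read_regions",
    "rasterize_region",
    "full_region",
    "read_mask",
    "write_mask",
    "write_table",
]

logger = logging.getLogger("fibertension")

#: Recognized tissue condition labels.
CONDITIONS = ("healthy", "DCIS", "invasive_G2", "invasive_G3", "unknown")


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Route package logs to stderr (and optionally a file) with timestamps."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MultiplexImage:
    """Named 2-D intensity channels sharing geometry and pixel size.

    Parameters
    ----------
    channels
        Mapping from marker name to a 2-D array of non-negative, finite
        intensities. All channels must share the same shape.
    pixel_size
        Isotropic pixel size in µm per pixel; must be positive.
    sample_id
        Free-form sample identifier.
    condition_label
        One of :data:`CONDITIONS`.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    sample_id: str = "sample"
    condition_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiplexImage requires at least one channel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.condition_label not in CONDITIONS:
            raise ValueError(f"unknown condition_label {self.condition_label!r}")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1 or any(len(s) != 2 for s in shapes):
            raise ValueError("all channels must be 2-D and share one shape")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def __contains__(self, marker: str) -> bool:
        return marker in self.channels

    def __getitem__(self, marker: str) -> np.ndarray:
        return self.channels[marker]


@dataclass
class RegionSet:
    """A labelled list of closed analysis-region polygons in pixel coordinates."""

    polygons: list[Polygon]
    label: str = "region"

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.polygons):
            if len(poly.exterior.coords) - 1 < 3:
                raise ValueError(f"polygon {i} has fewer than 3 vertices")

    def __len__(self) -> int:
        return len(self.polygons)


@dataclass
class BinaryMask:
    """Per-channel positive-pixel mask restricted to an analysis region."""

    values: np.ndarray
    source_channel: str = ""
    provenance: str = "fixed_threshold"
    positive_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.positive_count = int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class AnalysisConfig:
    """Per-sample analysis configuration.

    ``pixel_size`` carries the acquisition µm-per-pixel calibration and has no
    built-in default: it must come from the acquisition metadata or the user.
    """

    pixel_size: float
    channel_map: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, dict] = field(default_factory=dict)
    bin_width: float = 1.0
    max_profile_distance: float = 20.0
    within_radius: float = 10.0
    ring_width: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.within_radius > self.max_profile_distance:
            raise ValueError("within_radius must be <= max_profile_distance")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from YAML or JSON mirroring the dataclass fields."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "channel_map": dict(self.channel_map),
            "thresholds": dict(self.thresholds),
            "bin_width": self.bin_width,
            "max_profile_distance": self.max_profile_distance,
            "within_radius": self.within_radius,
            "ring_width": self.ring_width,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------


def read_multiplex_image(path: str | Path, config: AnalysisConfig) -> MultiplexImage:
    """Read a single- or multi-page TIFF into a :class:`MultiplexImage`.

    Pages are renamed to marker names via ``config.channel_map``; intensities
    are cast to float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected 2-D pages, got array of shape {pages.shape}")
    n = pages.shape[0]
    channels: dict[str, np.ndarray] = {}
    for marker, idx in config.channel_map.items():
        if not 0 <= idx < n:
            raise IndexError(f"channel index out of range: {marker}={idx}, file has {n} pages")
        channels[marker] = np.asarray(pages[idx], dtype=np.float64)
    return MultiplexImage(channels=channels, pixel_size=config.pixel_size, sample_id=path.stem)


def write_multiplex_image(image: MultiplexImage, path: str | Path) -> None:
    """Write channels as a multi-page float32 TIFF, one page per marker.

    Marker order follows the ``channels`` dict; marker names are recorded in
    each page's description tag.
    """
    stack = np.stack([np.asarray(image.channels[m], dtype=np.float32) for m in image.channels])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(list(image.channels)))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask written by :func:`write_mask` (8-bit, 0/255)."""
    arr = tifffile.imread(path)
    return BinaryMask(values=arr > 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as single-page 8-bit TIFF with values 0/255."""
    tifffile.imwrite(path, (mask.values.astype(np.uint8) * 255))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a header row."""
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


def read_regions(path: str | Path, label: str = "region") -> RegionSet:
    """Parse GeoJSON polygons (pixel coordinates) into a :class:`RegionSet`.

    Polygons are closed automatically; an empty feature list yields an empty
    RegionSet. A polygon with fewer than 3 vertices raises, naming its index.
    """
    data = json.loads(Path(path).read_text())
    features = data.get("features", [])
    polygons: list[Polygon] = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry", feat)
        if geom.get("type") != "Polygon":
            raise ValueError(f"feature {i}: only Polygon geometries are supported")
        ring = geom["coordinates"][0]
        # drop an explicit closing vertex before the >=3 check
        if len(ring) > 1 and tuple(ring[0]) == tuple(ring[-1]):
            ring = ring[:-1]
        if len(ring) < 3:
            raise ValueError(f"malformed polygon at index {i}: fewer than 3 vertices")
        polygons.append(Polygon(ring))
    return RegionSet(polygons=polygons, label=label)


def rasterize_region(regions: RegionSet, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize polygons: a pixel is true iff its center lies inside >=1 polygon.

    Pixel ``(r, c)`` has center ``(r + 0.5, c + 0.5)``; polygon coordinates are
    interpreted as ``(x=column, y=row)`` pairs, the GeoJSON/image convention.
    """
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    out = np.zeros((h, w), dtype=bool)
    frame = box(0.0, 0.0, float(w), float(h))
    cols = np.arange(w) + 0.5
    rows = np.arange(h) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    for poly in regions.polygons:
        clipped = poly.intersection(frame)
        if clipped.is_empty:
            continue
        # bounding-box crop keeps the point-in-polygon test cheap
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)) + 1, w)
        r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        inside = shapely.contains_xy(poly, xx[r0:r1, c0:c1].ravel(), yy[r0:r1, c0:c1].ravel())
        out[r0:r1, c0:c1] |= inside.reshape(r1 - r0, c1 - c0)
    return BinaryMask(values=out, source_channel=regions.label, provenance="fixed_threshold")


def full_region(shape: tuple[int, int]) -> BinaryMask:
    """An all-true analysis region covering the whole frame."""
    return BinaryMask(values=np.ones(shape, dtype=bool), source_channel="frame")
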