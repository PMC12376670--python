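"""Nucleus detection, per-cell marker measurement and composite phenotyping.

Cells are detected from the DAPI channel (smooth, Otsu foreground, watershed
split on the distance transform), sized by their nucleus area, and measured
over the nucleus plus a thin expansion ring so membrane/cytoplasmic markers
(panCK, CD45, ...) are captured. Composite phenotypes such as Ki67+ & panCK+
carcinoma cells or CD4+ & FoxP3+ Tregs are boolean conjunctions of per-marker
mean-intensity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

from .io_core import BinaryMask, MultiplexImage
from .pixelquant import otsu_threshold

__all__ = [
    "CellRecord",
    "PhenotypeRule",
    "CellTable",
    "detect_nuclei",
    "measure_cells",
    "classify_cells",
    "summarize_phenotypes",
    "auto_marker_thresholds",
]


@dataclass
class CellRecord:
    """One detected nucleus: centroid (x, y) in µm, area in µm², marker means."""

    cell_id: int
    centroid_um: tuple[float, float]  # (x, y) = (col, row) * pixel_size
    nucleus_area_um2: float
    mean_intensity: dict[str, float] = field(default_factory=dict)


@dataclass
class PhenotypeRule:
    """A composite phenotype: every (marker, threshold, sense) must hold.

    sense '+' requires mean > threshold, '-' requires mean <= threshold.
    """

    name: str
    required_markers: list[tuple[str, float, str]]

    def __post_init__(self) -> None:
        if not self.required_markers:
            raise ValueError("phenotype rule needs >=1 required marker")
        for _, _, sense in self.required_markers:
            if sense not in ("+", "-"):
                raise ValueError(f"sense must be '+' or '-', got {sense!r}")


@dataclass
class CellTable:
    """Detected cells with per-rule phenotype flags and label raster."""

    cells: list[CellRecord]
    pixel_size: float
    labels: np.ndarray | None = None  # nucleus label image, 0 = background
    phenotype_flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_cells(self) -> int:
        return len(self.cells)

    def centroids_um(self) -> np.ndarray:
        return np.array([c.centroid_um for c in self.cells]).reshape(-1, 2)

    def areas_um2(self) -> np.ndarray:
        return np.array([c.nucleus_area_um2 for c in self.cells])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cells):
            row = {"cell_id": c.cell_id, "x_um": c.centroid_um[0], "y_um": c.centroid_um[1],
                   "area_um2": c.nucleus_area_um2}
            row.update({f"mean_{m}": v for m, v in c.mean_intensity.items()})
            for rule, flags in self.phenotype_flags.items():
                row[rule] = bool(flags[i])
            rows.append(row)
        return pd.DataFrame(rows)


def detect_nuclei(
    dapi: np.ndarray,
    region: BinaryMask,
    pixel_size: float,
    min_area_um2: float = 10.0,
    max_area_um2: float = 500.0,
    smoothing_sigma: float = 1.0,
) -> CellTable:
    """Detect nuclei in the DAPI channel inside the analysis region.

    Gaussian smooth -> Otsu foreground -> watershed split on the smoothed
    distance transform (markers are local maxima separated by at least twice
    the minimum nucleus radius) -> discard components outside
    [min_area, max_area]. Returns geometry only (no marker measurements).
    """
    if region.positive_count == 0:
        raise ValueError("empty analysis region")
    dapi = np.asarray(dapi, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(dapi, smoothing_sigma) if smoothing_sigma > 0 else dapi
    in_region = smoothed[region.values]
    if in_region.min() == in_region.max():
        return CellTable(cells=[], pixel_size=pixel_size,
                         labels=np.zeros(dapi.shape, dtype=np.int32))
    thr = otsu_threshold(smoothed, region)
    fg = (smoothed > thr) & region.values
    if not fg.any():
        return CellTable(cells=[], pixel_size=pixel_size,
                         labels=np.zeros(dapi.shape, dtype=np.int32))
    dist = ndimage.distance_transform_edt(fg)
    dist_s = ndimage.gaussian_filter(dist, 1.0)
    min_radius_px = float(np.sqrt(min_area_um2 / np.pi)) / pixel_size
    min_sep = max(int(round(2.0 * min_radius_px)), 1)
    peaks = peak_local_max(dist_s, min_distance=min_sep, labels=fg, exclude_border=False)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist_s, markers, mask=fg)

    cells: list[CellRecord] = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size**2
        if not (min_area_um2 <= area_um2 <= max_area_um2):
            continue
        r0, c0 = prop.centroid  # pixel-index coordinates
        cells.append(CellRecord(
            cell_id=next_id,
            centroid_um=((c0 + 0.5) * pixel_size, (r0 + 0.5) * pixel_size),
            nucleus_area_um2=float(area_um2),
        ))
        keep[prop.label] = next_id
        next_id += 1
    relabeled = keep[labels]
    return CellTable(cells=cells, pixel_size=pixel_size, labels=relabeled)


def measure_cells(table: CellTable, image: MultiplexImage, ring_width_um: float = 1.5) -> CellTable:
    """Mean marker intensities over nucleus + expansion ring per cell.

    Nuclei are dilated by ``ring_width_um``; contested ring pixels go to the
    nearest nucleus (non-overlapping assignment), clipped to the frame.
    """
    if table.labels is None:
        raise ValueError("table has no label raster")
    if table.labels.shape != image.shape:
        raise ValueError("table geometry does not match image")
    ring_px = ring_width_um / table.pixel_size
    expanded = expand_labels(table.labels, distance=ring_px) if table.total_cells else table.labels
    ids = np.array([c.cell_id for c in table.cells], dtype=np.int64)
    for marker, channel in image.channels.items():
        if table.total_cells:
            means = ndimage.mean(np.asarray(channel, dtype=np.float64), labels=expanded, index=ids)
        else:
            means = []
        for cell, m in zip(table.cells, means):
            cell.mean_intensity[marker] = float(m)
    return table


def classify_cells(table: CellTable, rules: list[PhenotypeRule]) -> CellTable:
    """Evaluate composite phenotype rules on measured cells."""
    for rule in rules:
        flags = np.ones(table.total_cells, dtype=bool)
        for marker, thr, sense in rule.required_markers:
            for cell in table.cells:
                if marker not in cell.mean_intensity:
                    raise ValueError(f"rule {rule.name!r} references unmeasured marker {marker!r}")
            means = np.array([c.mean_intensity[marker] for c in table.cells])
            flags &= (means > thr) if sense == "+" else (means <= thr)
        table.phenotype_flags[rule.name] = flags
    return table


def auto_marker_thresholds(table: CellTable, markers: list[str],
                           min_contrast: float = 0.0) -> dict[str, float]:
    """Per-marker Otsu threshold over the per-cell mean-intensity distribution.

    Mirrors setting a cut on the single-measurement histogram; override per
    marker when a manual threshold is preferred. When the separation between
    the two Otsu classes is below ``min_contrast`` the marker is treated as
    having no positive cells (threshold above the maximum), which guards
    against splitting a pure-background unimodal distribution.
    """
    out = {}
    for marker in markers:
        means = np.array([c.mean_intensity[marker] for c in table.cells], dtype=np.float64)
        if means.size == 0 or means.min() == means.max():
            out[marker] = float("inf")
            continue
        thr = otsu_threshold(means.reshape(1, -1))
        lo, hi = means[means <= thr], means[means > thr]
        if min_contrast > 0 and (hi.size == 0 or hi.mean() - lo.mean() < min_contrast):
            thr = float(means.max())  # strict '>' makes every cell negative
        out[marker] = thr
    return out


def summarize_phenotypes(table: CellTable) -> pd.DataFrame:
    """Per-rule percentage of flagged cells (DAPI-normalized) and nucleus areas."""
    if table.total_cells == 0:
        raise ValueError("empty cell table")
    areas = table.areas_um2()
    rows = []
    for rule, flags in table.phenotype_flags.items():
        n_flagged = int(flags.sum())
        rows.append({
            "phenotype": rule,
            "n_cells": n_flagged,
            "total_cells": table.total_cells,
            "percentage": 100.0 * n_flagged / table.total_cells,
            "mean_area_um2": float(areas[flags].mean()) if n_flagged else float("nan"),
        })
    return pd.DataFrame(rows)
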