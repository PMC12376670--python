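"""Synthetic multiplexed breast-tissue images with exhaustive ground truth.

Patient cryosections are not publicly available, so every downstream stage is
exercised on generated images that carry the statistical structure the
analysis assumes:

* **healthy** — wavy fibronectin/SHG fibers with uniformly distributed
  orientations, a small untensed (FnBPA5+) fraction, sparse TNC, duct/lobule
  rings of myoepithelial (aSMA+) cells around epithelial (panCK+/GATA3+)
  cells, with CD34+ vessel tracks adjacent to the rings.
* **DCIS** — duct-confined panCK+/GATA3+ cell populations inside
  myoepithelial rings; fiber signature like healthy.
* **invasive_G2 / invasive_G3** — near-straight fiber bundles concentrated
  about a common axis, a large FnBPA5+ fraction with a TNC halo, and cancer
  cells, CAFs and T cells placed so their distance to the nearest FnBPA5+
  pixel follows an exponential law; CAFs are kept away from CD34+ vessel
  tracks. The G3 preset is richer in untensed fibers and has larger nuclei
  than G2.

Ground truth (masks, fiber orientations, cell list with phenotypes and true
distances) is captured before the PSF blur and noise are applied, so
recovered quantities can be compared against exact generator values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from .io_core import BinaryMask, MultiplexImage

__all__ = [
    "TissuePreset",
    "GroundTruth",
    "SyntheticSample",
    "PRESETS",
    "PHENOTYPE_MARKERS",
    "MARKERS",
    "synth_fibers",
    "synth_cells",
    "generate_tissue",
    "generate_cohort",
    "write_sample",
]

#: Marker channels a full synthetic sample carries.
MARKERS = ("DAPI", "FN", "FnBPA5", "TNC", "SHG", "panCK", "Ki67", "GATA3",
           "aSMA", "CD34", "CD8", "CD45", "CD4", "FoxP3")

#: Markers rendered positive for each generated phenotype.
PHENOTYPE_MARKERS: dict[str, tuple[str, ...]] = {
    "cancer": ("panCK", "GATA3", "Ki67"),
    "epithelial": ("panCK", "GATA3"),
    "myoepithelial": ("aSMA",),
    "caf": ("aSMA",),
    "endothelial": ("CD34",),
    "t_cytotoxic": ("CD45", "CD8"),
    "treg": ("CD4", "FoxP3"),
    "stromal": (),
}

# rendering constants (intensity a.u. and px), surfaced in truth_meta
BACKGROUND = 10.0
SIGNAL_LO, SIGNAL_HI = 150.0, 220.0
PSF_SIGMA_PX = 0.7
READ_NOISE = 3.0
TNC_HALO_PX = 3
FIBER_WIDTHS_PX = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class TissuePreset:
    """Generator parameters for one tissue archetype.

    ``fiber_waviness`` is (amplitude µm, wavelength µm) of the sinusoidal
    fiber-path undulation; ``fiber_alignment`` is the von Mises concentration
    of fiber orientations about a random common axis (0 = uniform);
    ``fnbpa5_fraction`` is the target fraction of FN+ pixels that are also
    FnBPA5+; ``proximity_scale`` (µm) is the exponential scale of coupled-cell
    distances to FnBPA5+ pixels.
    """

    name: str
    fiber_waviness: tuple[float, float]
    fiber_alignment: float
    fnbpa5_fraction: float
    fnbpa5_tolerance: float
    tnc_background: float
    cell_mix: dict[str, float]
    n_cells: int
    n_fibers: int
    proximity_scale: float
    nucleus_radius_mean: float
    nucleus_radius_jitter: float
    coupled_phenotypes: tuple[str, ...]
    n_rings: int
    n_vessels: int

    def __post_init__(self) -> None:
        for k, v in self.cell_mix.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"cell_mix[{k!r}] outside [0, 1]")
        if not np.isclose(sum(self.cell_mix.values()), 1.0):
            raise ValueError("cell_mix must sum to 1")
        if not 0.0 <= self.fnbpa5_fraction <= 1.0:
            raise ValueError("fnbpa5_fraction outside [0, 1]")
        if self.proximity_scale <= 0:
            raise ValueError("proximity_scale must be > 0")


PRESETS: dict[str, TissuePreset] = {
    "healthy": TissuePreset(
        name="healthy",
        fiber_waviness=(5.0, 30.0),
        fiber_alignment=0.0,
        fnbpa5_fraction=0.08,
        fnbpa5_tolerance=0.02,
        tnc_background=0.01,
        cell_mix={"epithelial": 0.05, "cancer": 0.013, "myoepithelial": 0.12,
                  "endothelial": 0.05, "t_cytotoxic": 0.02, "treg": 0.01,
                  "stromal": 0.737},
        n_cells=450,
        n_fibers=60,
        proximity_scale=4.0,
        nucleus_radius_mean=3.0,
        nucleus_radius_jitter=0.15,
        coupled_phenotypes=(),
        n_rings=3,
        n_vessels=1,
    ),
    "DCIS": TissuePreset(
        name="DCIS",
        fiber_waviness=(4.0, 30.0),
        fiber_alignment=0.5,
        fnbpa5_fraction=0.08,
        fnbpa5_tolerance=0.02,
        tnc_background=0.015,
        cell_mix={"epithelial": 0.50, "cancer": 0.0, "myoepithelial": 0.08,
                  "endothelial": 0.05, "t_cytotoxic": 0.02, "treg": 0.01,
                  "stromal": 0.34},
        n_cells=500,
        n_fibers=60,
        proximity_scale=4.0,
        nucleus_radius_mean=3.2,
        nucleus_radius_jitter=0.15,
        coupled_phenotypes=(),
        n_rings=4,
        n_vessels=2,
    ),
    "invasive_G2": TissuePreset(
        name="invasive_G2",
        fiber_waviness=(0.8, 60.0),
        fiber_alignment=20.0,
        fnbpa5_fraction=0.35,
        fnbpa5_tolerance=0.03,
        tnc_background=0.02,
        cell_mix={"epithelial": 0.35, "cancer": 0.10, "caf": 0.05,
                  "endothelial": 0.05, "t_cytotoxic": 0.05, "treg": 0.03,
                  "stromal": 0.37},
        n_cells=700,
        n_fibers=70,
        proximity_scale=4.0,
        nucleus_radius_mean=3.5,
        nucleus_radius_jitter=0.15,
        coupled_phenotypes=("cancer", "epithelial", "caf", "t_cytotoxic", "treg"),
        n_rings=0,
        n_vessels=3,
    ),
}
PRESETS["invasive_G3"] = replace(
    PRESETS["invasive_G2"],
    name="invasive_G3",
    fnbpa5_fraction=0.45,
    cell_mix={"epithelial": 0.35, "cancer": 0.15, "caf": 0.06,
              "endothelial": 0.05, "t_cytotoxic": 0.05, "treg": 0.03,
              "stromal": 0.31},
    n_cells=800,
    nucleus_radius_mean=4.0,
)

PRESET_TO_CONDITION = {"healthy": "healthy", "DCIS": "DCIS",
                       "invasive_G2": "invasive_G2", "invasive_G3": "invasive_G3"}


@dataclass
class GroundTruth:
    """Pre-noise generator truth: masks, fiber orientations and the cell list.

    ``cells`` columns: x_um, y_um, row, col, area_um2, phenotype, one boolean
    column per marker, and dist_fnbpa5_um (brute-force-consistent distance
    from the nucleus centroid to the nearest true FnBPA5+ pixel).
    """

    true_masks: dict[str, BinaryMask] = field(default_factory=dict)
    fiber_orientation: np.ndarray | None = None
    cells: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def fnbpa5_fraction(self) -> float:
        fn = self.true_masks["FN"].positive_count
        joint = int(np.sum(self.true_masks["FnBPA5"].values & self.true_masks["FN"].values))
        return joint / fn if fn else float("nan")

    def density(self, marker: str) -> float:
        m = self.true_masks[marker]
        return m.positive_count / m.values.size

    def phenotype_fraction(self, phenotype: str) -> float:
        if self.cells is None or len(self.cells) == 0:
            return float("nan")
        return float((self.cells["phenotype"] == phenotype).mean())


@dataclass
class SyntheticSample:
    image: MultiplexImage
    truth: GroundTruth
    preset: TissuePreset
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    sel = dr**2 + dc**2 <= radius**2
    return np.stack([dr[sel], dc[sel]], axis=1)


def _stamp_path(points_rc: np.ndarray, width_px: float, shape: tuple[int, int]) -> np.ndarray:
    """Flat indices of pixels within width/2 of the (float) path points."""
    offsets = _disk_offsets(width_px / 2.0)
    pts = np.round(points_rc).astype(np.int64)
    all_pts = (pts[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    h, w = shape
    ok = ((all_pts[:, 0] >= 0) & (all_pts[:, 0] < h)
          & (all_pts[:, 1] >= 0) & (all_pts[:, 1] < w))
    flat = all_pts[ok, 0] * w + all_pts[ok, 1]
    return np.unique(flat)


def _von_mises_axis(rng: np.random.Generator, mean_axis: float, kappa: float) -> float:
    """Fiber orientation in radians in [0, pi): uniform when kappa == 0."""
    if kappa <= 0:
        return float(rng.uniform(0.0, np.pi))
    if np.isinf(kappa):  # degenerate limit: every fiber on the common axis
        return float(mean_axis % np.pi)
    # axial von Mises: draw on the doubled circle, halve
    return float((mean_axis + rng.vonmises(0.0, kappa) / 2.0) % np.pi)


def _fiber_path(rng: np.random.Generator, shape: tuple[int, int], theta: float,
                amp_px: float, wavelength_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Path points (r, c) and per-point tangent angles (deg, fiber convention)."""
    h, w = shape
    length = int(1.3 * max(h, w))
    t = np.arange(length, dtype=np.float64)
    # direction u = (dr, dc); theta measured from the horizontal (columns) axis
    u = np.array([np.sin(theta), np.cos(theta)])
    n = np.array([-u[1], u[0]])
    start = np.array([rng.uniform(-0.15 * h, 1.15 * h), rng.uniform(-0.15 * w, 1.15 * w)])
    start -= u * length / 2.0
    phase = rng.uniform(0, 2 * np.pi)
    wobble = amp_px * np.sin(2 * np.pi * t / wavelength_px + phase)
    pts = start[None, :] + t[:, None] * u[None, :] + wobble[:, None] * n[None, :]
    # tangent angle from the analytic derivative
    dwob = amp_px * (2 * np.pi / wavelength_px) * np.cos(2 * np.pi * t / wavelength_px + phase)
    tang = u[None, :] + dwob[:, None] * n[None, :]
    ang = (np.degrees(np.arctan2(tang[:, 0], tang[:, 1]))) % 180.0
    ok = ((pts[:, 0] > -8) & (pts[:, 0] < h + 8) & (pts[:, 1] > -8) & (pts[:, 1] < w + 8))
    return pts[ok], ang[ok]


def _apply_noise(channel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """PSF blur then Poisson shot noise plus Gaussian read noise."""
    blurred = ndimage.gaussian_filter(channel + BACKGROUND, PSF_SIGMA_PX)
    noisy = rng.poisson(blurred).astype(np.float64)
    noisy += rng.normal(0.0, READ_NOISE, size=noisy.shape)
    return np.clip(noisy, 0.0, None)


def _smooth_track(rng: np.random.Generator, shape: tuple[int, int],
                  through: np.ndarray | None = None) -> np.ndarray:
    """A gently curved vessel path; optionally passing through a given point."""
    h, w = shape
    theta = rng.uniform(0, np.pi)
    u = np.array([np.sin(theta), np.cos(theta)])
    n = np.array([-u[1], u[0]])
    anchor = (np.asarray(through, dtype=np.float64) if through is not None
              else np.array([rng.uniform(0, h), rng.uniform(0, w)]))
    length = int(0.9 * max(h, w))
    t = np.arange(-length // 2, length // 2, dtype=np.float64)
    curve = rng.uniform(-1, 1) * 30.0 * np.sin(2 * np.pi * t / (2.5 * length))
    pts = anchor[None, :] + t[:, None] * u[None, :] + curve[:, None] * n[None, :]
    ok = ((pts[:, 0] > -4) & (pts[:, 0] < h + 4) & (pts[:, 1] > -4) & (pts[:, 1] < w + 4))
    return pts[ok]


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------


def synth_fibers(
    preset: TissuePreset,
    shape: tuple[int, int] = (1024, 1024),
    seed=0,
    pixel_size: float = 0.5,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render the fiber channels (FN, FnBPA5, TNC, SHG) and their truth.

    Fibers are smooth curves 2–6 px wide. The healthy preset draws
    sinusoidally undulating curves with orientations uniform in [0, 180);
    invasive presets draw near-straight curves concentrated about a random
    common axis. A contiguous subset of whole fibers (plus one partial fiber)
    is copied into the FnBPA5 channel until the target fraction of FN+ pixels
    is reached; TNC is a dilated halo around FnBPA5+ fibers plus sparse
    background; SHG mirrors the fiber geometry. PSF blur and noise are
    applied after the truth is captured.
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("shape must be at least 64 x 64")
    rng = _rng(seed)
    amp_px = preset.fiber_waviness[0] / pixel_size
    wav_px = max(preset.fiber_waviness[1] / pixel_size, 4.0)
    mean_axis = rng.uniform(0.0, np.pi)
    # preset counts are stated for the 1024 px reference frame; fiber length
    # scales with the frame, so the count scales with its linear size
    n_fibers = max(int(round(preset.n_fibers * max(h, w) / 1024)), 6)

    fiber_pixels: list[np.ndarray] = []
    fn_mask = np.zeros(h * w, dtype=bool)
    orient = np.full(h * w, np.nan)
    fn_img = np.zeros(h * w)
    shg_img = np.zeros(h * w)
    for _ in range(n_fibers):
        theta = _von_mises_axis(rng, mean_axis, preset.fiber_alignment)
        pts, ang = _fiber_path(rng, shape, theta, amp_px, wav_px)
        if pts.shape[0] < 4:
            fiber_pixels.append(np.empty(0, dtype=np.int64))
            continue
        width = float(rng.choice(FIBER_WIDTHS_PX))
        flat = _stamp_path(pts, width, shape)
        fiber_pixels.append(flat)
        fn_mask[flat] = True
        # tangent angle per stamped pixel via projection onto the path axis
        rr, cc = flat // w, flat % w
        proj = np.clip(np.round(
            ((rr - pts[0, 0]) * (pts[-1, 0] - pts[0, 0]) + (cc - pts[0, 1]) * (pts[-1, 1] - pts[0, 1]))
            / max(np.sum((pts[-1] - pts[0]) ** 2), 1e-9) * (pts.shape[0] - 1)),
            0, pts.shape[0] - 1).astype(np.int64)
        orient[flat] = ang[proj]
        amp = rng.uniform(SIGNAL_LO, SIGNAL_HI)
        fn_img[flat] = np.maximum(fn_img[flat], amp)
        shg_img[flat] = np.maximum(shg_img[flat], rng.uniform(SIGNAL_LO, SIGNAL_HI))

    fn_total = int(fn_mask.sum())
    if fn_total == 0:
        raise RuntimeError("no fiber pixels rendered")

    # --- contiguous FnBPA5 subset targeting fnbpa5_fraction of FN+ pixels ---
    target = preset.fnbpa5_fraction
    tol = preset.fnbpa5_tolerance
    order = rng.permutation(len(fiber_pixels))
    fnbpa5_mask = np.zeros(h * w, dtype=bool)
    achieved = 0.0
    for fi in order:
        flat = fiber_pixels[fi]
        if flat.size == 0:
            continue
        before = fnbpa5_mask.copy()
        fnbpa5_mask[flat] = True
        achieved = fnbpa5_mask.sum() / fn_total
        if achieved >= target:
            if achieved - target > tol / 2:
                # partial fiber: take a contiguous prefix of this fiber's
                # pixels along its dominant axis to land on the target count
                fnbpa5_mask = before
                rr, cc = flat // w, flat % w
                axis_vals = rr if np.ptp(rr) >= np.ptp(cc) else cc
                sorted_px = flat[np.argsort(axis_vals, kind="stable")]
                need = int(round(target * fn_total)) - int(before.sum())
                novel = np.cumsum(~before[sorted_px])
                take = sorted_px[:int(np.searchsorted(novel, need))]
                fnbpa5_mask[take] = True
                achieved = fnbpa5_mask.sum() / fn_total
            break
    if abs(achieved - target) > tol:
        raise RuntimeError(
            f"unreachable fnbpa5_fraction {target}: achieved {achieved:.3f}")

    fnbpa5_img = np.where(fnbpa5_mask, fn_img * rng.uniform(0.8, 1.1), 0.0)

    # --- TNC: halo around FnBPA5 fibers + sparse background dots ---
    fnbpa5_2d = fnbpa5_mask.reshape(h, w)
    halo = ndimage.binary_dilation(fnbpa5_2d, structure=_disk_structure(TNC_HALO_PX))
    tnc_mask = halo.copy()
    n_dots = int(preset.tnc_background * h * w / 13)  # ~13 px per dot
    if n_dots:
        dot_r = rng.integers(0, h, n_dots)
        dot_c = rng.integers(0, w, n_dots)
        dots = np.zeros((h, w), dtype=bool)
        dots[dot_r, dot_c] = True
        tnc_mask |= ndimage.binary_dilation(dots, structure=_disk_structure(2))
    tnc_img = np.where(tnc_mask, rng.uniform(SIGNAL_LO, SIGNAL_HI), 0.0)

    truth = GroundTruth(
        true_masks={
            "FN": BinaryMask(fn_mask.reshape(h, w), "FN", "fixed_threshold"),
            "FnBPA5": BinaryMask(fnbpa5_2d, "FnBPA5", "fixed_threshold"),
            "TNC": BinaryMask(tnc_mask, "TNC", "fixed_threshold"),
            "SHG": BinaryMask(fn_mask.reshape(h, w), "SHG", "fixed_threshold"),
        },
        fiber_orientation=orient.reshape(h, w),
        meta={
            "fnbpa5_fraction_achieved": float(achieved),
            "fiber_widths_px": list(FIBER_WIDTHS_PX),
            "tnc_halo_px": TNC_HALO_PX,
            "psf_sigma_px": PSF_SIGMA_PX,
            "mean_axis_deg": float(np.degrees(mean_axis)),
        },
    )
    channels = {
        "FN": _apply_noise(fn_img.reshape(h, w), rng),
        "FnBPA5": _apply_noise(fnbpa5_img.reshape(h, w), rng),
        "TNC": _apply_noise(tnc_img, rng),
        "SHG": _apply_noise(shg_img.reshape(h, w), rng),
    }
    return channels, truth


def _disk_structure(radius: int) -> np.ndarray:
    dr, dc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return dr**2 + dc**2 <= radius**2


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------


class _OverlapChecker:
    """Incremental non-overlap test on nucleus centers (vectorized)."""

    def __init__(self, margin_px: float) -> None:
        self.rows: list[float] = []
        self.cols: list[float] = []
        self.radii: list[float] = []
        self.margin = margin_px

    def ok(self, r: float, c: float, radius: float) -> bool:
        if not self.rows:
            return True
        dr = np.asarray(self.rows) - r
        dc = np.asarray(self.cols) - c
        lim = np.asarray(self.radii) + radius + self.margin
        return bool(np.all(dr * dr + dc * dc > lim * lim))

    def add(self, r: float, c: float, radius: float) -> None:
        self.rows.append(r)
        self.cols.append(c)
        self.radii.append(radius)


def synth_cells(
    preset: TissuePreset,
    fiber_truth: GroundTruth,
    shape: tuple[int, int] = (1024, 1024),
    seed=0,
    pixel_size: float = 0.5,
    n_cells: int | None = None,
    cell_mix: dict[str, float] | None = None,
    max_retries: int = 200,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Place non-overlapping nuclei, render DAPI + marker channels, log truth.

    Phenotypes are drawn from ``cell_mix``. In invasive presets, coupled
    phenotypes are placed so their centroid distance to the nearest true
    FnBPA5+ pixel follows an exponential law with scale ``proximity_scale``
    (rejection sampling on the FnBPA5 distance transform); CAFs additionally
    reject positions within 25 µm of CD34+ vessel tracks. Healthy/DCIS
    presets arrange epithelial and myoepithelial cells in duct/lobule ring
    motifs near untensed-fiber patches, with a vessel track adjacent to each
    healthy ring. All remaining phenotypes are placed uniformly.
    """
    h, w = shape
    rng = _rng(seed)
    if n_cells is None:  # preset counts refer to the 1024 px reference frame
        n_cells = max(int(round(preset.n_cells * (h * w) / 1024**2)), 20)
    cell_mix = preset.cell_mix if cell_mix is None else cell_mix
    phenos = sorted(cell_mix)
    counts = rng.multinomial(n_cells, [cell_mix[p] for p in phenos])
    n_by_pheno = dict(zip(phenos, counts))

    fnbpa5 = fiber_truth.true_masks["FnBPA5"].values
    edt_fnbpa5 = ndimage.distance_transform_edt(~fnbpa5) * pixel_size
    flat_d = edt_fnbpa5.ravel()
    d_order = np.argsort(flat_d, kind="stable")
    d_sorted = flat_d[d_order]
    d_max = float(d_sorted[-1])

    # --- vessel tracks (CD34 geometry), rings need them adjacent in healthy --
    ring_centers: list[np.ndarray] = []
    if preset.n_rings:
        near = np.argwhere((edt_fnbpa5 > 8.0) & (edt_fnbpa5 < 18.0))
        for _ in range(preset.n_rings):
            if near.size:
                ring_centers.append(near[rng.integers(near.shape[0])].astype(np.float64))
            else:
                ring_centers.append(np.array([rng.uniform(0.1 * h, 0.9 * h),
                                              rng.uniform(0.1 * w, 0.9 * w)]))
    tracks: list[np.ndarray] = []
    ring_radius_px = 20.0 / pixel_size
    for center in ring_centers:
        offset_dir = rng.uniform(0, 2 * np.pi)
        through = center + (ring_radius_px + 8.0 / pixel_size) * np.array(
            [np.sin(offset_dir), np.cos(offset_dir)])
        tracks.append(_smooth_track(rng, shape, through=through))
    for _ in range(preset.n_vessels):
        tracks.append(_smooth_track(rng, shape))
    cd34_mask = np.zeros(h * w, dtype=bool)
    for pts in tracks:
        if pts.shape[0] >= 2:
            cd34_mask[_stamp_path(pts, 3.0, shape)] = True
    cd34_mask = cd34_mask.reshape(h, w)
    edt_cd34 = ndimage.distance_transform_edt(~cd34_mask) * pixel_size if cd34_mask.any() \
        else np.full(shape, np.inf)

    # --- placement -----------------------------------------------------------
    mean_r_px = preset.nucleus_radius_mean / pixel_size
    checker = _OverlapChecker(margin_px=1.0)
    records: list[dict] = []

    def nucleus_radius() -> float:
        jitter = 1.0 + rng.uniform(-preset.nucleus_radius_jitter, preset.nucleus_radius_jitter)
        return mean_r_px * jitter

    def try_place(r: float, c: float, radius: float) -> bool:
        if not (radius < r < h - radius - 1 and radius < c < w - radius - 1):
            return False
        return checker.ok(r, c, radius)

    def commit(r: float, c: float, radius: float, phenotype: str) -> None:
        checker.add(r, c, radius)
        records.append({"row": int(r), "col": int(c), "radius_px": radius,
                        "phenotype": phenotype})

    # ring motifs consume epithelial / myoepithelial quotas in healthy & DCIS
    if ring_centers:
        n_myo = n_by_pheno.get("myoepithelial", 0)
        n_epi = n_by_pheno.get("epithelial", 0)
        myo_per_ring = n_myo // len(ring_centers) if ring_centers else 0
        epi_per_ring = n_epi // len(ring_centers) if ring_centers else 0
        for center in ring_centers:
            placed_m = 0
            angles = rng.permutation(np.linspace(0, 2 * np.pi, max(myo_per_ring, 1),
                                                 endpoint=False))
            for a in angles:
                if placed_m >= myo_per_ring:
                    break
                rad = nucleus_radius()
                rr = center[0] + ring_radius_px * np.sin(a) + rng.normal(0, 1.5)
                cc = center[1] + ring_radius_px * np.cos(a) + rng.normal(0, 1.5)
                if try_place(rr, cc, rad):
                    commit(rr, cc, rad, "myoepithelial")
                    placed_m += 1
            n_by_pheno["myoepithelial"] = n_by_pheno.get("myoepithelial", 0) - placed_m
            placed_e = 0
            for _ in range(epi_per_ring * max_retries):
                if placed_e >= epi_per_ring:
                    break
                rad = nucleus_radius()
                rho = (ring_radius_px - 3.0 / pixel_size) * np.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * np.pi)
                rr, cc = center[0] + rho * np.sin(a), center[1] + rho * np.cos(a)
                if try_place(rr, cc, rad):
                    commit(rr, cc, rad, "epithelial")
                    placed_e += 1
            n_by_pheno["epithelial"] = n_by_pheno.get("epithelial", 0) - placed_e

    # endothelial cells sit along the vessel tracks
    n_endo = n_by_pheno.get("endothelial", 0)
    if n_endo and tracks:
        all_track_pts = np.vstack([t for t in tracks if t.shape[0]])
        placed = 0
        for _ in range(n_endo * max_retries):
            if placed >= n_endo:
                break
            p = all_track_pts[rng.integers(all_track_pts.shape[0])]
            rad = nucleus_radius()
            rr = p[0] + rng.normal(0, 2.0)
            cc = p[1] + rng.normal(0, 2.0)
            if try_place(rr, cc, rad):
                commit(rr, cc, rad, "endothelial")
                placed += 1
        n_by_pheno["endothelial"] = n_endo - placed

    # coupled phenotypes: exponential distance law to FnBPA5+ pixels.
    # On an overlap rejection the *same* target distance is retried at other
    # candidate pixels before a new distance is drawn, so local crowding near
    # fibers does not bias the marginal distance distribution outward.
    bin_tol = pixel_size / 2.0  # accepted |EDT - target| window
    for pheno in preset.coupled_phenotypes:
        n_p = n_by_pheno.get(pheno, 0)
        if n_p <= 0:
            continue
        placed = 0
        draws = 0
        while placed < n_p and draws < n_p * max_retries:
            draws += 1
            d_target = rng.exponential(preset.proximity_scale)
            if d_target > d_max:
                continue
            lo = np.searchsorted(d_sorted, d_target - bin_tol)
            hi = np.searchsorted(d_sorted, d_target + bin_tol)
            if hi <= lo:
                continue
            rad = nucleus_radius()
            for _ in range(300):
                flat = d_order[rng.integers(lo, hi)]
                rr, cc = float(flat // w), float(flat % w)
                if pheno == "caf" and edt_cd34[int(rr), int(cc)] <= 25.0:
                    break  # vessel exclusion: redraw the distance
                if try_place(rr, cc, rad):
                    commit(rr, cc, rad, pheno)
                    placed += 1
                    break
        if placed < n_p:
            raise RuntimeError(f"could not place {n_p} {pheno} cells without overlap "
                               f"(placed {placed})")
        n_by_pheno[pheno] = 0

    # everything left is placed uniformly
    for pheno in phenos:
        n_p = n_by_pheno.get(pheno, 0)
        if n_p <= 0:
            continue
        placed = 0
        for _ in range(n_p * max_retries):
            if placed >= n_p:
                break
            rad = nucleus_radius()
            rr = rng.uniform(rad + 1, h - rad - 2)
            cc = rng.uniform(rad + 1, w - rad - 2)
            if try_place(rr, cc, rad):
                commit(rr, cc, rad, pheno)
                placed += 1
        if placed < n_p:
            raise RuntimeError(f"could not place {n_p} {pheno} cells without overlap")

    # --- render -------------------------------------------------------------
    dapi = np.zeros(shape)
    marker_imgs = {m: np.zeros(shape) for m in
                   ("panCK", "Ki67", "GATA3", "aSMA", "CD8", "CD45", "CD4", "FoxP3")}
    cell_rows = []
    for rec in records:
        r0, c0, rad = rec["row"], rec["col"], rec["radius_px"]
        a = rad * (1.0 + rng.uniform(-0.1, 0.1))
        b = rad**2 / a  # keep the area near pi * rad^2
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=shape, rotation=rot)
        dapi[rr, cc] = np.maximum(dapi[rr, cc], rng.uniform(SIGNAL_LO, SIGNAL_HI))
        area_um2 = rr.size * pixel_size**2
        # markers cover nucleus + a thin cytoplasmic rim
        mr, mc = draw_ellipse(r0, c0, a + 2, b + 2, shape=shape, rotation=rot)
        for marker in PHENOTYPE_MARKERS[rec["phenotype"]]:
            if marker not in marker_imgs:  # CD34 is rendered with the vessel tracks
                continue
            img = marker_imgs[marker]
            img[mr, mc] = np.maximum(img[mr, mc], rng.uniform(SIGNAL_LO, SIGNAL_HI))
        row = {
            "x_um": (c0 + 0.5) * pixel_size,
            "y_um": (r0 + 0.5) * pixel_size,
            "row": r0,
            "col": c0,
            "area_um2": area_um2,
            "phenotype": rec["phenotype"],
            "dist_fnbpa5_um": float(edt_fnbpa5[r0, c0]) if fnbpa5.any() else float("nan"),
        }
        for marker in marker_imgs:
            row[marker] = marker in PHENOTYPE_MARKERS[rec["phenotype"]]
        row["CD34"] = rec["phenotype"] == "endothelial"
        cell_rows.append(row)

    cd34_img = np.where(cd34_mask, rng.uniform(SIGNAL_LO, SIGNAL_HI), 0.0)
    for rec in records:  # endothelial cell bodies add to the CD34 channel
        if rec["phenotype"] != "endothelial":
            continue
        rr, cc = draw_ellipse(rec["row"], rec["col"], rec["radius_px"] + 2,
                              rec["radius_px"] + 2, shape=shape)
        cd34_img[rr, cc] = np.maximum(cd34_img[rr, cc], SIGNAL_LO)

    cells_df = pd.DataFrame(cell_rows)
    truth = GroundTruth(
        true_masks={"CD34": BinaryMask(cd34_mask | (cd34_img > 0), "CD34", "fixed_threshold")},
        cells=cells_df,
        meta={"n_cells_placed": len(records),
              "nucleus_radius_mean_um": preset.nucleus_radius_mean},
    )
    channels = {"DAPI": _apply_noise(dapi, rng), "CD34": _apply_noise(cd34_img, rng)}
    for marker, img in marker_imgs.items():
        channels[marker] = _apply_noise(img, rng)
    return channels, truth


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def generate_tissue(
    preset_name: str,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = 0.5,
    seed: int = 0,
) -> SyntheticSample:
    """Generate one complete synthetic sample (image + ground truth)."""
    if preset_name not in PRESETS:
        raise KeyError(f"unknown preset {preset_name!r}")
    preset = PRESETS[preset_name]
    rng = np.random.default_rng(seed)
    fiber_channels, fiber_truth = synth_fibers(preset, shape, rng, pixel_size)
    cell_channels, cell_truth = synth_cells(preset, fiber_truth, shape, rng, pixel_size)
    truth = GroundTruth(
        true_masks={**fiber_truth.true_masks, **cell_truth.true_masks},
        fiber_orientation=fiber_truth.fiber_orientation,
        cells=cell_truth.cells,
        meta={**fiber_truth.meta, **cell_truth.meta, "preset": preset_name,
              "seed": seed, "pixel_size_um": pixel_size},
    )
    channels = {**cell_channels, **fiber_channels}
    ordered = {m: channels[m] for m in MARKERS if m in channels}
    image = MultiplexImage(channels=ordered, pixel_size=pixel_size,
                           sample_id=f"{preset_name}_s{seed}",
                           condition_label=PRESET_TO_CONDITION[preset_name])
    return SyntheticSample(image=image, truth=truth, preset=preset, seed=seed)


def generate_cohort(
    n_per_condition: dict[str, int],
    base_seed: int = 0,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = 0.5,
) -> list[SyntheticSample]:
    """Generate independent samples with per-sample seeds base_seed + index."""
    samples = []
    index = 0
    for preset_name in n_per_condition:
        for _ in range(int(n_per_condition[preset_name])):
            samples.append(generate_tissue(preset_name, shape, pixel_size,
                                           seed=base_seed + index))
            index += 1
    return samples


def write_sample(sample: SyntheticSample, out_dir: str | Path) -> None:
    """Write image.ome.tiff, truth masks, truth_cells.csv and truth_meta.json."""
    from .io_core import write_mask, write_multiplex_image

    out = Path(out_dir)
    (out / "truth_masks").mkdir(parents=True, exist_ok=True)
    write_multiplex_image(sample.image, out / "image.ome.tiff")
    for marker, mask in sample.truth.true_masks.items():
        write_mask(mask, out / "truth_masks" / f"{marker}.tiff")
    if sample.truth.cells is not None:
        sample.truth.cells.to_csv(out / "truth_cells.csv", index=False)
    meta = dict(sample.truth.meta)
    meta["channel_order"] = list(sample.image.channels)
    (out / "truth_meta.json").write_text(json.dumps(meta, indent=2))
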