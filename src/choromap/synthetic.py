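"""Synthetic macular-cube generator with per-pixel ground truth.

Emulates the acquisition protocol of a 61-B-scan macular cube (scan length
8.6 mm, scan depth 1.8 mm, axial resolution 3.9 um) with a simplified anatomy:
a flat-to-smooth retina block, an RPE boundary, a choroid band of bright
stroma with dark elliptical vessel lumina, and sclera beneath. Retinal-vessel
shadows appear as attenuated vertical bands, and speckle-like variability is
modelled as additive Gaussian noise clipped to [0, 255].

Vessel lumina are placed by rejection sampling, stratified per grid-column
block (one 120-um cell width), so that the realized lumen areal fraction is
within +-0.01 of the requested fraction at the cell scale — the granularity at
which the vascularity index is later measured. Overlapping vessels are
allowed; the fraction is measured on the union mask.

A separate cohort generator works directly at the 60x60 grid level: it embeds
a prescribed group-difference profile (linear or quadratic in eccentricity)
into per-cell metrics with multiplicative log-normal eye-level and cell-level
variation, and records the embedded truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import quant, templates
from .quant import CellMetricsGrid, ColumnMetrics, band_rows
from .volume_io import OCTVolume

# truth label codes
RETINA, STROMA, LUMEN, SCLERA, SHADOW = 0, 1, 2, 3, 4
LABEL_NAMES = {0: "retina", 1: "stroma", 2: "lumen", 3: "sclera", 4: "shadow"}


def _depth_field(value, x_um, y_um):
    """Evaluate a scalar-or-callable depth field on fovea-centred coords."""
    if callable(value):
        return np.broadcast_to(np.asarray(value(x_um, y_um), dtype=float),
                               np.shape(x_um)).copy()
    return np.full(np.shape(x_um), float(value))


@dataclass
class SceneParams:
    """Ground-truth scene description for one synthetic eye.

    ``rpe_depth_um`` and ``choroid_thickness_um`` may be scalars or callables
    of fovea-centred ``(x_um, y_um)``. Intensities are mean gray levels in
    [0, 255] with ``lumen_intensity < stroma_intensity``. Identical seeds give
    bit-identical output.
    """

    rpe_depth_um: float | Callable = 500.0
    choroid_thickness_um: float | Callable = 300.0
    lumen_fraction: float = 0.5
    stroma_intensity: float = 180.0
    lumen_intensity: float = 60.0
    noise_sd: float = 10.0
    vessel_axes_um: tuple[float, float] = (20.0, 80.0)
    n_shadow_columns: int = 3
    shadow_attenuation: float = 0.5
    shadow_width_px: tuple[int, int] = (3, 8)
    seed: int = 0
    # acquisition geometry (standard macular cube)
    n_bscans: int = 61
    n_ascans: int = 768
    scan_length_mm: float = 8.6
    scan_depth_um: float = 1800.0
    axial_res_um: float = 3.9
    scan_span_um: float = 7200.0
    quality_db: float = 30.0
    laterality: str = "OD"
    # fixed ancillary anatomy/intensities
    retina_thickness_um: float = 220.0
    retina_intensity: float = 140.0
    vitreous_intensity: float = 20.0
    sclera_intensity: float = 100.0

    def validate(self) -> None:
        if not 0.0 <= self.lumen_fraction <= 1.0:
            raise ValueError("lumen_fraction must be in [0, 1]")
        if self.lumen_intensity >= self.stroma_intensity:
            raise ValueError("lumen_intensity must be < stroma_intensity")
        if self.shadow_attenuation <= 0 or self.shadow_attenuation > 1:
            raise ValueError("shadow_attenuation must be in (0, 1]")
        lo, hi = self.vessel_axes_um
        if lo <= 0 or hi < lo:
            raise ValueError("vessel_axes_um must be a positive (lo, hi) range")
        if self.n_bscans < 1:
            raise ValueError("n_bscans must be >= 1")

    # derived geometry -----------------------------------------------------
    @property
    def height_px(self) -> int:
        return int(round(self.scan_depth_um / self.axial_res_um))

    @property
    def ascan_spacing_um(self) -> float:
        return self.scan_length_mm * 1000.0 / self.n_ascans

    def bscan_spacing_um(self, n_bscans: int | None = None) -> float:
        n = n_bscans or self.n_bscans
        return self.scan_span_um / (n - 1) if n > 1 else self.scan_span_um

    def fovea_xy_um(self, n_bscans: int | None = None) -> tuple[float, float]:
        n = n_bscans or self.n_bscans
        fy = (n - 1) * self.bscan_spacing_um(n) / 2
        return (self.scan_length_mm * 1000.0 / 2, fy)


@dataclass
class BScanTruth:
    """Per-pixel truth for one B-scan."""

    labels: np.ndarray        # (H, W) uint8, codes RETINA..SHADOW (partition)
    lumen_mask: np.ndarray    # (H, W) bool, tissue truth (shadow-independent)
    shadow_cols: np.ndarray   # (W,) bool
    rpe: np.ndarray           # (W,) float, pixel rows
    csj: np.ndarray           # (W,) float, pixel rows


@dataclass
class GroundTruth:
    """Volume-level truth: label stack, boundary curves, per-cell metrics."""

    bscans: list[BScanTruth]
    cell_truth: CellMetricsGrid

    @property
    def label_stack(self) -> np.ndarray:
        return np.stack([b.labels for b in self.bscans])


def _place_vessels(rng, tops, bots, block_cols, target, axes_px_range,
                   max_attempts=6000):
    """Union lumen mask over one column block, fraction within +-0.01 of target.

    ``axes_px_range`` is ((ax_lo, ax_hi), (dep_lo, dep_hi)) in pixels. On
    overshoot the proposal is rejected and the upper sampling bound shrinks
    toward the minimum axis; an unreachable target raises after a bounded
    number of proposals.
    """
    cols = np.asarray(block_cols)
    heights = np.maximum(bots[cols] - tops[cols], 0)
    n_px = int(heights.sum())
    H = int(bots[cols].max()) if n_px else 0
    mask = np.zeros((H, cols.size), dtype=bool)
    if n_px == 0 or target <= 0.01:
        return cols, mask
    band = np.zeros_like(mask)
    for jj, c in enumerate(cols):
        band[tops[c]:bots[c], jj] = True
    lo_n, hi_n = (target - 0.01) * n_px, (target + 0.01) * n_px
    (ax_lo, ax_hi), (dp_lo, dp_hi) = axes_px_range
    scale = 1.0
    current = 0
    attempts = 0
    rr = np.arange(H)[:, None]
    cc = np.arange(cols.size)[None, :]
    while current < lo_n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"lumen_fraction {target} unreachable in a column block after "
                f"{max_attempts} placement attempts"
            )
        jj = rng.integers(cols.size)
        c = cols[jj]
        if bots[c] <= tops[c]:
            continue
        r0 = rng.uniform(tops[c], bots[c])
        a = max(rng.uniform(ax_lo, ax_lo + (ax_hi - ax_lo) * scale), 0.6)
        b = max(rng.uniform(dp_lo, dp_lo + (dp_hi - dp_lo) * scale), 0.6)
        ell = (((cc - jj) / a) ** 2 + ((rr - r0) / b) ** 2) <= 1.0
        new = ell & band & ~mask
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if current + n_new > hi_n:
            scale = max(scale * 0.6, 0.0)
            continue
        mask |= new
        current += n_new
    return cols, mask


def generate_bscan(scene: SceneParams, bscan_index: int,
                   n_bscans: int | None = None) -> tuple[np.ndarray, BScanTruth]:
    """Render one B-scan and its ground truth.

    Deterministic in ``(scene.seed, bscan_index)``. Raises on invalid scene
    parameters or an unreachable lumen fraction.
    """
    scene.validate()
    n_bscans = n_bscans or scene.n_bscans
    if not 0 <= bscan_index < n_bscans:
        raise ValueError(f"bscan_index {bscan_index} out of range")
    rng = np.random.default_rng([int(scene.seed) % (2**31), bscan_index])

    H, W = scene.height_px, scene.n_ascans
    sp = scene.ascan_spacing_um
    fx, fy = scene.fovea_xy_um(n_bscans)
    x = (np.arange(W) + 0.5) * sp - fx
    y = bscan_index * scene.bscan_spacing_um(n_bscans) - fy

    rpe = _depth_field(scene.rpe_depth_um, x, np.full(W, y)) / scene.axial_res_um
    thick = _depth_field(scene.choroid_thickness_um, x, np.full(W, y))
    if np.any(thick <= 0):
        raise ValueError("choroid_thickness_um must be > 0 everywhere")
    csj = rpe + thick / scene.axial_res_um
    if np.any(csj > H):
        raise ValueError("choroid extends below the scan depth")
    surface = np.maximum(rpe - scene.retina_thickness_um / scene.axial_res_um, 0)

    tops = np.array([band_rows(rpe[j], csj[j])[0] for j in range(W)])
    bots = np.array([band_rows(rpe[j], csj[j])[1] for j in range(W)])

    # vessel lumina, stratified per grid-column block
    lumen = np.zeros((H, W), dtype=bool)
    axes_px = (
        (scene.vessel_axes_um[0] / sp, scene.vessel_axes_um[1] / sp),
        (scene.vessel_axes_um[0] / scene.axial_res_um,
         scene.vessel_axes_um[1] / scene.axial_res_um),
    )
    block_id = np.floor((x + templates.GRID_SPAN_UM / 2) / templates.CELL_UM)
    for bid in np.unique(block_id):
        cols = np.nonzero(block_id == bid)[0]
        cols_out, mask = _place_vessels(
            rng, tops, bots, cols, scene.lumen_fraction, axes_px)
        if mask.size:
            lumen[: mask.shape[0], cols_out] |= mask

    # assemble intensities
    rr = np.arange(H)[:, None]
    img = np.full((H, W), scene.vitreous_intensity)
    img = np.where(rr >= np.ceil(surface)[None, :], scene.retina_intensity, img)
    img = np.where(rr >= tops[None, :], scene.stroma_intensity, img)
    img = np.where(lumen, scene.lumen_intensity, img)
    img = np.where(rr >= bots[None, :], scene.sclera_intensity, img)
    # a zero-height band leaves no stroma/lumen rows by construction

    labels = np.full((H, W), RETINA, dtype=np.uint8)
    labels[(rr >= tops[None, :]) & (rr < bots[None, :])] = STROMA
    labels[lumen] = LUMEN
    labels = np.where((rr >= bots[None, :]), SCLERA, labels).astype(np.uint8)

    # retinal-vessel shadow bands; identity attenuation means no shadow at all
    shadow_cols = np.zeros(W, dtype=bool)
    for _ in range(scene.n_shadow_columns):
        w = int(rng.integers(scene.shadow_width_px[0],
                             scene.shadow_width_px[1] + 1))
        start = int(rng.integers(0, max(W - w, 1)))
        shadow_cols[start:start + w] = True
    if scene.shadow_attenuation >= 1.0:
        shadow_cols[:] = False
    if shadow_cols.any():
        att = np.where(rr >= np.ceil(surface)[None, :], scene.shadow_attenuation, 1.0)
        img = np.where(shadow_cols[None, :], img * att, img)
        labels[(rr >= np.ceil(rpe)[None, :]) & shadow_cols[None, :]] = SHADOW

    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = BScanTruth(labels=labels, lumen_mask=lumen,
                       shadow_cols=shadow_cols, rpe=rpe, csj=csj)
    return img, truth


def _truth_cell_grid(scene: SceneParams, truths: list[BScanTruth],
                     n_bscans: int) -> CellMetricsGrid:
    """True per-cell CT/LA/SA/CVI, excluding shadowed columns (as measured)."""
    metrics = []
    for t in truths:
        W = t.rpe.size
        lum = np.zeros(W, dtype=int)
        strom = np.zeros(W, dtype=int)
        for j in range(W):
            top, bot = band_rows(t.rpe[j], t.csj[j])
            n_l = int(t.lumen_mask[top:bot, j].sum())
            lum[j] = n_l
            strom[j] = (bot - top) - n_l
        metrics.append(ColumnMetrics(
            ct_um=(t.csj - t.rpe) * scene.axial_res_um,
            lumen_px=lum, stroma_px=strom, valid=~t.shadow_cols))
    return quant.aggregate_to_grid(
        metrics,
        ascan_spacing_um=scene.ascan_spacing_um,
        bscan_spacing_um=scene.bscan_spacing_um(n_bscans),
        axial_res_um=scene.axial_res_um,
        fovea_xy_um=scene.fovea_xy_um(n_bscans),
        laterality=scene.laterality,
    )


def generate_volume(scene: SceneParams, n_bscans: int | None = None
                    ) -> tuple[OCTVolume, GroundTruth]:
    """Render a full macular cube (default 61 B-scans) plus its ground truth."""
    scene.validate()
    n = n_bscans or scene.n_bscans
    images, truths = [], []
    for i in range(n):
        img, t = generate_bscan(scene, i, n_bscans=n)
        images.append(img)
        truths.append(t)
    volume = OCTVolume(
        images=np.stack(images),
        ascan_spacing_um=scene.ascan_spacing_um,
        bscan_spacing_um=scene.bscan_spacing_um(n),
        axial_res_um=scene.axial_res_um,
        quality_db=np.full(n, scene.quality_db),
        laterality=scene.laterality,
        fovea_xy_um=scene.fovea_xy_um(n),
        rpe_curve=np.stack([t.rpe for t in truths]),
        csj_curve=np.stack([t.csj for t in truths]),
    )
    truth = GroundTruth(bscans=truths,
                        cell_truth=_truth_cell_grid(scene, truths, n))
    return volume, truth


# ---------------------------------------------------------------------------
# grid-level cohorts with embedded eccentricity effect profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectProfile:
    """Symmetric percent change as a polynomial in eccentricity r (mm)."""

    coeffs: tuple  # highest degree first, numpy poly convention

    def __call__(self, r_mm):
        return np.polyval(self.coeffs, np.asarray(r_mm, dtype=float))


def linear_profile(m: float, k: float) -> EffectProfile:
    return EffectProfile((m, k))


def quadratic_profile(a: float, b: float, c: float) -> EffectProfile:
    return EffectProfile((a, b, c))


def null_profile() -> EffectProfile:
    return EffectProfile((0.0,))


def default_baselines() -> dict[str, np.ndarray]:
    """Smooth, strictly positive baseline grids for the control group.

    CT declines gently with eccentricity and CVI is slightly elevated at the
    fovea, mimicking the topography of healthy choroid; LA/SA are derived so
    that CVI = LA / (LA + SA) holds at baseline.
    """
    r = templates.cell_eccentricity_mm()
    ct = 300.0 - 8.0 * r
    cvi = 0.65 - 0.015 * r
    total = ct * templates.CELL_UM
    return {"CT": ct, "CVI": cvi, "LA": total * cvi, "SA": total * (1 - cvi)}


@dataclass
class CohortSpec:
    """Two matched groups of per-eye metric grids with a known effect.

    The effect profile gives the true symmetric percent change between
    group-median cells as a function of the cell's eccentricity-bin centre
    (the abscissa the downstream regression uses). Eye-level and cell-level
    variation are multiplicative log-normal so metrics stay positive.
    ``between_eye_sd`` and ``cell_sd_pct`` are percents (log-scale SD / 100).
    """

    n_per_group: int = 40
    baseline_grid: dict[str, np.ndarray] | None = None
    effect_profile: dict[str, EffectProfile | Callable] = field(default_factory=dict)
    between_eye_sd: float = 3.0
    cell_sd_pct: float = 2.0
    seed: int = 0
    laterality: str = "OD"

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.between_eye_sd < 0 or self.cell_sd_pct < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CohortTruth:
    """The embedded generative truth, for recovery tests."""

    profiles: dict[str, Callable]
    true_pct: dict[str, np.ndarray]      # (60, 60) true symmetric % change
    baselines: dict[str, np.ndarray]


def _grids_from_metrics(values: dict[str, np.ndarray], laterality: str
                        ) -> CellMetricsGrid:
    valid = np.ones((templates.N_CELLS,) * 2, dtype=bool)
    return CellMetricsGrid(
        ct_um=values["CT"], la_um2=values["LA"], sa_um2=values["SA"],
        cvi=values["CVI"], valid_mask=valid, laterality=laterality)


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[CellMetricsGrid], list[CellMetricsGrid], CohortTruth]:
    """Generate (iAMD grids, control grids, truth) at the 60x60 grid level."""
    spec.validate()
    base = spec.baseline_grid or default_baselines()
    for name, grid in base.items():
        if np.any(np.asarray(grid) <= 0):
            raise ValueError(f"baseline for {name} must be strictly positive")

    r_bin = templates.bin_center_mm(templates.eccentricity_bin_grid())
    true_pct: dict[str, np.ndarray] = {}
    scale: dict[str, np.ndarray] = {}
    for name in base:
        prof = spec.effect_profile.get(name)
        p = np.zeros_like(r_bin) if prof is None else np.asarray(prof(r_bin), float)
        if np.any(p <= -200) or np.any(p >= 200):
            raise ValueError(
                f"effect profile for {name} leaves the open (-200, 200) band; "
                "the implied metric would be non-positive or infinite")
        true_pct[name] = p
        scale[name] = (200.0 + p) / (200.0 - p)

    rng = np.random.default_rng(int(spec.seed) % (2**31))
    sd_eye = spec.between_eye_sd / 100.0
    sd_cell = spec.cell_sd_pct / 100.0
    shape = (templates.N_CELLS, templates.N_CELLS)

    def draw_eye(metric_base: dict[str, np.ndarray]) -> CellMetricsGrid:
        vals = {}
        for name in ("CT", "CVI", "LA", "SA"):
            eps = rng.normal(0.0, sd_eye) if sd_eye > 0 else 0.0
            eta = rng.normal(0.0, sd_cell, shape) if sd_cell > 0 else 0.0
            vals[name] = metric_base[name] * np.exp(eps + eta)
        return _grids_from_metrics(vals, spec.laterality)

    controls = [draw_eye(base) for _ in range(spec.n_per_group)]
    iamd_base = {name: base[name] * scale[name] for name in base}
    iamd = [draw_eye(iamd_base) for _ in range(spec.n_per_group)]

    profiles = {name: (spec.effect_profile.get(name) or null_profile())
                for name in base}
    truth = CohortTruth(profiles=profiles, true_pct=true_pct,
                        baselines={k: np.asarray(v) for k, v in base.items()})
    return iamd, controls, truth
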