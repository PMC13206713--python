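"""Choroid binarization and per-cell metric extraction.

The choroid band of each B-scan (between the RPE and the choroidoscleral
junction, CSJ) is split into hypo-reflective lumen and hyper-reflective stroma
by multiscale median-cut quantization: within each local column window the
band's intensity distribution is recursively split at its median into a small
number of buckets, the darkest half of the buckets is labelled lumen, and the
per-pixel labels from several window widths are combined by majority vote.

Columns shadowed by overlying retinal vessels are detected from their mean
band intensity and excluded. Valid columns are then pooled into a fovea-centred
60x60 grid (120 um cells over 7200 x 7200 um): choroidal thickness (CT) as the
median column thickness, luminal/stromal area (LA/SA) as pixel counts scaled to
um^2, and the choroidal vascularity index CVI = LA / (LA + SA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .templates import CELL_UM, GRID_SPAN_UM, N_CELLS


def band_rows(rpe: float, csj: float) -> tuple[int, int]:
    """Integer pixel-row range [top, bottom) of the choroid band for one column.

    Boundary curves are real-valued; a pixel row r belongs to the band iff
    ``rpe <= r < csj`` evaluated on integer rows, i.e. rows
    ``ceil(rpe) .. ceil(csj) - 1``. The same rule is used by the synthetic
    generator so pixel counts agree exactly.
    """
    return int(np.ceil(rpe)), int(np.ceil(csj))


@dataclass(frozen=True)
class BinarizationParams:
    """Settings for multiscale median-cut binarization.

    n_levels
        Number of median-cut buckets per window; a power of two, >= 2. The
        darkest half of the buckets is labelled lumen.
    window_widths_px
        Column-window widths of the multiscale pass; ``None`` denotes the
        whole choroid region of the B-scan.
    combine_rule
        How per-scale labels are merged: "majority" (strict majority of
        scales), "any", or "all".
    """

    n_levels: int = 4
    window_widths_px: tuple = (32, 64, None)
    combine_rule: str = "majority"

    def __post_init__(self):
        n = self.n_levels
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"n_levels must be a power of two >= 2, got {n}")
        for w in self.window_widths_px:
            if w is not None and w <= 0:
                raise ValueError("window widths must be positive")
        if self.combine_rule not in ("majority", "any", "all"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


@dataclass
class ColumnMetrics:
    """Per-A-scan choroid metrics for one B-scan (vectors of length W)."""

    ct_um: np.ndarray
    lumen_px: np.ndarray
    stroma_px: np.ndarray
    valid: np.ndarray


@dataclass
class CellMetricsGrid:
    """Per-cell CT/LA/SA/CVI on the 60x60 macular grid.

    Invalid cells carry NaN in the metric arrays and False in ``valid_mask``;
    they are never silently zero.
    """

    ct_um: np.ndarray
    la_um2: np.ndarray
    sa_um2: np.ndarray
    cvi: np.ndarray
    valid_mask: np.ndarray
    cell_size_um: float = CELL_UM
    laterality: str = "OD"

    METRICS = ("CT", "LA", "SA", "CVI")

    def metric(self, name: str) -> np.ndarray:
        arr = {"CT": self.ct_um, "LA": self.la_um2, "SA": self.sa_um2,
               "CVI": self.cvi}.get(name.upper())
        if arr is None:
            raise KeyError(f"unknown metric {name!r}")
        return arr


def _median_cut_buckets(values: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Recursive median-cut of a 1-D intensity sample into <= n_levels buckets.

    Each split is at the median *value*: pixels strictly below go to the dark
    side. If that leaves a side empty (the median equals the minimum, as on a
    discrete plateau), the split falls back to <= / >, so a two-valued sample
    always separates into its two plateaus exactly. A segment that cannot be
    split (constant) stays a single bucket.

    Returns index arrays (into ``values``), ordered dark to bright.
    """
    buckets = [np.arange(values.size)]
    depth = int(np.log2(n_levels))
    for _ in range(depth):
        new: list[np.ndarray] = []
        for idx in buckets:
            v = values[idx]
            if idx.size < 2 or v.min() == v.max():
                new.append(idx)
                continue
            m = np.median(v)
            low = v < m
            if not low.any():
                low = v <= m
            if low.all():
                new.append(idx)
                continue
            new.append(idx[low])
            new.append(idx[~low])
        buckets = new
    buckets.sort(key=lambda idx: values[idx].mean())
    return buckets


def _label_window(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Boolean lumen labels for one window's pixel sample (dark half of buckets)."""
    lumen = np.zeros(values.size, dtype=bool)
    if values.size == 0:
        return lumen
    buckets = _median_cut_buckets(values, n_levels)
    if len(buckets) == 1:
        # constant-intensity window: by convention, all stroma
        return lumen
    for idx in buckets[: len(buckets) // 2]:
        lumen[idx] = True
    return lumen


def binarize_choroid(
    bscan: np.ndarray,
    rpe_curve: np.ndarray,
    csj_curve: np.ndarray,
    params: BinarizationParams | None = None,
) -> np.ndarray:
    """Lumen mask (H x W boolean, True = lumen) of one B-scan's choroid band.

    The mask is restricted to the band between ``rpe_curve`` and ``csj_curve``;
    everything outside is False. A constant-intensity band produces an
    all-stroma mask with a warning.
    """
    params = params or BinarizationParams()
    img = np.asarray(bscan, dtype=float)
    H, W = img.shape
    tops = np.empty(W, dtype=int)
    bots = np.empty(W, dtype=int)
    for j in range(W):
        t, b = band_rows(rpe_curve[j], csj_curve[j])
        tops[j], bots[j] = max(t, 0), min(max(b, 0), H)
    heights = np.maximum(bots - tops, 0)
    if heights.sum() == 0:
        raise ValueError("choroid band is empty at every column")

    # flat index list of band pixels, column-major so windows are contiguous
    cols = np.repeat(np.arange(W), heights)
    rows = np.concatenate(
        [np.arange(tops[j], bots[j]) for j in range(W)]
    ) if heights.sum() else np.empty(0, int)
    values = img[rows, cols]
    col_start = np.concatenate([[0], np.cumsum(heights)])

    votes = np.zeros(values.size, dtype=int)
    n_scales = len(params.window_widths_px)
    constant_band = values.size > 0 and values.min() == values.max()
    for w in params.window_widths_px:
        width = W if w is None else int(w)
        labels = np.zeros(values.size, dtype=bool)
        for start in range(0, W, width):
            stop = min(start + width, W)
            lo, hi = col_start[start], col_start[stop]
            labels[lo:hi] = _label_window(values[lo:hi], params.n_levels)
        votes += labels

    if params.combine_rule == "majority":
        lumen_flat = votes * 2 > n_scales
    elif params.combine_rule == "any":
        lumen_flat = votes > 0
    else:  # all
        lumen_flat = votes == n_scales

    if constant_band:
        warnings.warn(
            "constant-intensity choroid band: labelled all stroma", stacklevel=2
        )
    mask = np.zeros((H, W), dtype=bool)
    mask[rows, cols] = lumen_flat
    return mask


def detect_shadow_columns(
    bscan: np.ndarray,
    rpe_curve: np.ndarray,
    csj_curve: np.ndarray,
    k: float = 2.0,
) -> np.ndarray:
    """Column validity mask (True = usable) for one B-scan.

    For each A-scan column the mean intensity of the band below the RPE (down
    to the scan bottom, so single dark choroidal vessels do not dominate) is
    compared with the robust spread of those means across the B-scan: columns
    below ``median - k * MAD`` (MAD scaled to be sigma-consistent) are shadow
    candidates. Because a heavily vascularized column is also dark below the
    RPE, a candidate is only confirmed when the retinal band just above the
    RPE — which a genuine overlying-vessel shadow must darken too — is below
    the same robust cut of its own distribution. Confirmed columns are dilated
    by one column on each side. Columns with an empty band are left valid
    (they carry no pixels).
    """
    img = np.asarray(bscan, dtype=float)
    H, W = img.shape
    means = np.full(W, np.nan)
    retina = np.full(W, np.nan)
    retina_band_px = 40
    for j in range(W):
        t = max(int(np.ceil(rpe_curve[j])), 0)
        if H > t:
            means[j] = img[t:, j].mean()
        r0 = max(t - retina_band_px, 0)
        if t > r0:
            retina[j] = img[r0:t, j].mean()
    usable = ~np.isnan(means)
    valid = np.ones(W, dtype=bool)
    if not usable.any():
        return valid
    med = np.median(means[usable])
    mad = 1.4826 * np.median(np.abs(means[usable] - med))
    flagged = usable & (means < med - k * mad)
    r_usable = ~np.isnan(retina)
    if r_usable.any():
        med_r = np.median(retina[r_usable])
        mad_r = 1.4826 * np.median(np.abs(retina[r_usable] - med_r))
        flagged &= r_usable & (retina < med_r - k * mad_r)
    flagged = binary_dilation(flagged, structure=np.ones(3, dtype=bool))
    if flagged[usable].all():
        warnings.warn(
            "every column flagged as shadowed; B-scan should be QC-excluded",
            stacklevel=2,
        )
    valid[flagged] = False
    return valid


def compute_column_metrics(
    bscan: np.ndarray,
    rpe_curve: np.ndarray,
    csj_curve: np.ndarray,
    lumen_mask: np.ndarray,
    validity: np.ndarray,
    axial_res_um: float = 3.9,
) -> ColumnMetrics:
    """Per-column CT (um) and lumen/stroma pixel counts for one B-scan.

    CT is computed on the real-valued boundary curves,
    ``ct = (csj - rpe) * axial_res_um``; pixel counts use the integer band
    rows. A column with ``csj < rpe`` is marked invalid.
    """
    img = np.asarray(bscan)
    H, W = img.shape
    ct = np.zeros(W)
    lumen = np.zeros(W, dtype=int)
    stroma = np.zeros(W, dtype=int)
    valid = np.asarray(validity, dtype=bool).copy()
    for j in range(W):
        d = csj_curve[j] - rpe_curve[j]
        if d < 0:
            valid[j] = False
            continue
        ct[j] = d * axial_res_um
        t, b = band_rows(rpe_curve[j], csj_curve[j])
        t, b = max(t, 0), min(max(b, 0), H)
        if b > t:
            n_lum = int(lumen_mask[t:b, j].sum())
            lumen[j] = n_lum
            stroma[j] = (b - t) - n_lum
    return ColumnMetrics(ct_um=ct, lumen_px=lumen, stroma_px=stroma, valid=valid)


def aggregate_to_grid(
    column_metrics: list[ColumnMetrics],
    ascan_spacing_um: float,
    bscan_spacing_um: float,
    axial_res_um: float,
    fovea_xy_um: tuple[float, float],
    laterality: str = "OD",
    min_valid_frac: float = 0.5,
) -> CellMetricsGrid:
    """Pool per-column metrics from all B-scans into the 60x60 grid.

    Each (A-scan, B-scan) sample is mapped to one cell by its fovea-centred
    coordinates (grid rows follow x along the B-scan, grid columns follow y
    across B-scans); samples landing exactly on the +3600 um edge are assigned
    to the last cell so the 61st B-scan of the standard cube is retained. Per
    cell: CT = median of valid column CTs, LA/SA = summed pixel counts x pixel
    area, CVI = LA/(LA+SA). A cell is valid iff at least ``min_valid_frac`` of
    its geometrically expected samples are valid.
    """
    half = GRID_SPAN_UM / 2
    fx, fy = fovea_xy_um

    ct_lists: dict[tuple[int, int], list[float]] = {}
    lum = np.zeros((N_CELLS, N_CELLS), dtype=np.int64)
    strom = np.zeros((N_CELLS, N_CELLS), dtype=np.int64)
    expected = np.zeros((N_CELLS, N_CELLS), dtype=np.int64)
    n_valid = np.zeros((N_CELLS, N_CELLS), dtype=np.int64)

    outside_samples = 0
    total_samples = 0
    for i, cm in enumerate(column_metrics):
        W = cm.ct_um.size
        y = i * bscan_spacing_um - fy
        x = (np.arange(W) + 0.5) * ascan_spacing_um - fx
        # clamp the closed upper edge into the last cell
        ycl = half - 1e-9 if y == half else y
        xcl = np.where(x == half, half - 1e-9, x)
        col = int(np.floor((ycl + half) / CELL_UM))
        rows = np.floor((xcl + half) / CELL_UM).astype(int)
        in_x = (rows >= 0) & (rows < N_CELLS)
        total_samples += W
        if col < 0 or col >= N_CELLS:
            outside_samples += W
            continue
        outside_samples += int((~in_x).sum())
        for j in np.nonzero(in_x)[0]:
            r = int(rows[j])
            expected[r, col] += 1
            if cm.valid[j]:
                n_valid[r, col] += 1
                lum[r, col] += cm.lumen_px[j]
                strom[r, col] += cm.stroma_px[j]
                ct_lists.setdefault((r, col), []).append(cm.ct_um[j])

    if total_samples and outside_samples > 0.2 * total_samples:
        warnings.warn(
            "more than 20% of samples fall outside the 7200x7200 um grid "
            "(fovea far off-centre?); affected cells are invalid",
            stacklevel=2,
        )

    valid_mask = (expected > 0) & (n_valid >= min_valid_frac * expected)
    ct = np.full((N_CELLS, N_CELLS), np.nan)
    for (r, c), vals in ct_lists.items():
        if valid_mask[r, c]:
            ct[r, c] = float(np.median(vals))
    px_area = ascan_spacing_um * axial_res_um
    la = np.where(valid_mask, lum * px_area, np.nan)
    sa = np.where(valid_mask, strom * px_area, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cvi = la / (la + sa)
    return CellMetricsGrid(
        ct_um=ct, la_um2=la, sa_um2=sa, cvi=cvi,
        valid_mask=valid_mask, laterality=laterality,
    )


def quantify_volume(volume, params: BinarizationParams | None = None,
                    excluded_bscans=()) -> CellMetricsGrid:
    """Full per-eye quantification: shadows, binarization, grid aggregation.

    ``excluded_bscans`` (e.g. from QC) contribute no samples: their grid rows
    become invalid rather than zero.
    """
    params = params or BinarizationParams()
    excluded = set(excluded_bscans)
    metrics: list[ColumnMetrics] = []
    for i in range(volume.n_bscans):
        img = volume.images[i]
        rpe, csj = volume.rpe_curve[i], volume.csj_curve[i]
        if i in excluded:
            W = img.shape[1]
            metrics.append(ColumnMetrics(
                ct_um=np.zeros(W), lumen_px=np.zeros(W, int),
                stroma_px=np.zeros(W, int), valid=np.zeros(W, bool)))
            continue
        validity = detect_shadow_columns(img, rpe, csj)
        lumen = binarize_choroid(img, rpe, csj, params)
        metrics.append(compute_column_metrics(
            img, rpe, csj, lumen, validity, volume.axial_res_um))
    return aggregate_to_grid(
        metrics,
        ascan_spacing_um=volume.ascan_spacing_um,
        bscan_spacing_um=volume.bscan_spacing_um,
        axial_res_um=volume.axial_res_um,
        fovea_xy_um=volume.fovea_xy_um,
        laterality=volume.laterality,
    )
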