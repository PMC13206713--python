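"""Group difference maps, spatial statistics and eccentricity modelling.

Differences between an iAMD and a control group are expressed per grid cell
as a symmetric percent change of the group-median cell values,

    100 * (x - c) / ((x + c) / 2),

which is bounded in (-200, 200) for positive inputs and antisymmetric under
group swap; the raw form ``100 * (x - c) / x`` is also available for
comparison but is unbounded when the denominator approaches zero.

The statistics mirror a nonparametric reporting style: Wilcoxon signed-rank
for global paired comparisons, Kruskal-Wallis across ETDRS rings, per-sector
one-sample Wilcoxon with Holm correction, Spearman correlation between
metrics, and Shapiro-Wilk normality checks. Eccentricity responses (per-bin
medians of cell values) are fitted with ordinary least squares of degree 1
and 2; the quadratic is preferred only when it improves R^2 by more than a
small tie tolerance, since the nested model never fits worse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import templates
from .quant import CellMetricsGrid

#: R^2 gain the quadratic must show over the linear fit to be chosen.
R2_TIE_TOLERANCE = 0.01


def symmetric_percent_change(x, c, mode: str = "symmetric"):
    """Percent change of ``x`` (iAMD) versus ``c`` (control).

    ``symmetric``: 100*(x-c)/((x+c)/2), bounded in (-200, 200] for positive
    inputs. ``raw``: 100*(x-c)/x, unbounded as x -> 0. Non-positive
    denominators yield NaN rather than infinities.
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "symmetric":
            denom = (x + c) / 2.0
            out = np.where(denom > 0, 100.0 * (x - c) / denom, np.nan)
        elif mode == "raw":
            out = np.where(x > 0, 100.0 * (x - c) / x, np.nan)
        else:
            raise ValueError(f"mode must be 'symmetric' or 'raw', got {mode!r}")
    return float(out) if out.ndim == 0 else out


@dataclass
class DifferenceMap:
    """60x60 percent-change map between two groups for one metric."""

    values: np.ndarray
    metric: str
    n_iamd: int
    n_control: int
    valid_mask: np.ndarray
    mode: str = "symmetric"
    laterality: str = "OD"


def _metric_stack(grids: list[CellMetricsGrid], metric: str):
    vals = np.stack([g.metric(metric) for g in grids])
    valid = np.stack([g.valid_mask & np.isfinite(g.metric(metric)) for g in grids])
    return vals, valid


def difference_map(iamd: list[CellMetricsGrid], control: list[CellMetricsGrid],
                   metric: str, mode: str = "symmetric",
                   min_eye_frac: float = 0.5) -> DifferenceMap:
    """Per-cell percent change of group medians (iAMD vs control).

    A cell is valid iff at least ``min_eye_frac`` of the eyes have a valid
    value in *both* groups and both group medians are positive.
    """
    if len(iamd) < 2 or len(control) < 2:
        raise ValueError("need at least two eyes per group")
    xi, vi = _metric_stack(iamd, metric)
    xc, vc = _metric_stack(control, metric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med_i = np.nanmedian(np.where(vi, xi, np.nan), axis=0)
        med_c = np.nanmedian(np.where(vc, xc, np.nan), axis=0)
    enough = ((vi.sum(axis=0) >= min_eye_frac * len(iamd))
              & (vc.sum(axis=0) >= min_eye_frac * len(control)))
    vals = symmetric_percent_change(med_i, med_c, mode=mode)
    valid = enough & np.isfinite(vals)
    if not valid.any():
        warnings.warn(f"difference map for {metric} has no valid cells",
                      stacklevel=2)
    return DifferenceMap(values=np.where(valid, vals, np.nan), metric=metric,
                         n_iamd=len(iamd), n_control=len(control),
                         valid_mask=valid, mode=mode,
                         laterality=iamd[0].laterality)


@dataclass
class GlobalComparison:
    statistic: float
    p_value: float
    median_pct_change: float
    iqr_pct_change: tuple[float, float]
    test: str
    n: int


def _eye_global(grids: list[CellMetricsGrid], metric: str) -> np.ndarray:
    vals, valid = _metric_stack(grids, metric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(np.where(valid, vals, np.nan), axis=(1, 2))


def global_compare(iamd: list[CellMetricsGrid], control: list[CellMetricsGrid],
                   metric: str, paired: bool = True) -> GlobalComparison:
    """Global (whole-scan median) group comparison.

    Eyes are matched 1:1 by index and compared with the Wilcoxon signed-rank
    test (exact null for n <= 25, zero differences dropped); unmatched group
    sizes fall back to the rank-sum test with a warning. Also reports the
    median and IQR of per-pair symmetric percent changes.
    """
    gi, gc = _eye_global(iamd, metric), _eye_global(control, metric)
    if paired and gi.size == gc.size:
        d = gi - gc
        pct = symmetric_percent_change(gi, gc)
        med = float(np.nanmedian(pct))
        iqr = (float(np.nanpercentile(pct, 25)), float(np.nanpercentile(pct, 75)))
        nz = d[d != 0]
        if nz.size == 0:
            return GlobalComparison(0.0, 1.0, med, iqr, "wilcoxon", gi.size)
        method = "exact" if nz.size <= 25 else "approx"
        try:
            res = stats.wilcoxon(gi, gc, zero_method="wilcox", method=method)
        except ValueError:
            res = stats.wilcoxon(gi, gc, zero_method="wilcox", method="approx")
        return GlobalComparison(float(res.statistic), float(res.pvalue),
                                med, iqr, "wilcoxon", gi.size)
    warnings.warn("groups are not matched 1:1; using rank-sum test", stacklevel=2)
    res = stats.ranksums(gi, gc)
    pct = symmetric_percent_change(float(np.median(gi)), float(np.median(gc)))
    return GlobalComparison(float(res.statistic), float(res.pvalue), pct,
                            (np.nan, np.nan), "ranksums", gi.size)


@dataclass
class SectorTests:
    kruskal_statistic: float
    kruskal_p: float
    sectors: pd.DataFrame  # per-sector median, IQR, W, p, p_holm, significant
    excluded_sectors: list[str] = field(default_factory=list)


def _one_sample_wilcoxon(values: np.ndarray) -> tuple[float, float]:
    nz = values[values != 0]
    if nz.size == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(nz, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def sector_compare(diff_map: DifferenceMap, min_cells: int = 5,
                   alpha: float = 0.05) -> SectorTests:
    """Ring-level Kruskal-Wallis and per-sector tests of a difference map.

    (i) Kruskal-Wallis across the four ETDRS rings on per-cell values;
    (ii) per-sector one-sample Wilcoxon of cell values against 0, Holm-
    corrected across the 13 sectors. Sectors with fewer than ``min_cells``
    valid cells are excluded and flagged.
    """
    labels = templates.sector_label_grid(diff_map.laterality)
    rings = np.array([lab.split("_")[0] if not lab.startswith("near") else "near_periphery"
                      for lab in labels.ravel()]).reshape(labels.shape)
    vals = diff_map.values
    valid = diff_map.valid_mask & np.isfinite(vals)

    ring_groups = [vals[(rings == r) & valid] for r in templates.RINGS]
    ring_groups = [g for g in ring_groups if g.size >= 2]
    flat = np.concatenate(ring_groups) if ring_groups else np.empty(0)
    if len(ring_groups) < 2 or flat.size == 0 or np.ptp(flat) == 0:
        kw_stat, kw_p = 0.0, 1.0  # identical values: no ring separation
    else:
        kw_stat, kw_p = stats.kruskal(*ring_groups)

    rows, excluded = [], []
    for sector in templates.ALL_SECTORS:
        name = str(sector)
        cells = vals[(labels == name) & valid]
        if cells.size < min_cells:
            excluded.append(name)
            continue
        w, p = _one_sample_wilcoxon(cells)
        rows.append({
            "sector": name, "n_cells": int(cells.size),
            "median": float(np.median(cells)),
            "iqr_lo": float(np.percentile(cells, 25)),
            "iqr_hi": float(np.percentile(cells, 75)),
            "W": w, "p": p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        _, p_holm, _, _ = multipletests(df["p"], alpha=alpha, method="holm")
        df["p_holm"] = p_holm
        df["significant"] = df["p_holm"] < alpha
    return SectorTests(float(kw_stat), float(kw_p), df, excluded)


@dataclass
class EccentricityModelFit:
    """Linear and quadratic fits of percent change versus eccentricity (mm)."""

    linear: tuple[float, float, float] | None      # (m, k, R2)
    quadratic: tuple[float, float, float, float] | None  # (a, b, c, R2)
    chosen: str
    p_value: float
    fit_range_mm: tuple[float, float]
    n_bins: int
    bin_centers_mm: np.ndarray = field(default=None, repr=False)
    bin_values: np.ndarray = field(default=None, repr=False)

    @property
    def chosen_coeffs(self) -> tuple:
        return (self.linear[:2] if self.chosen == "linear"
                else self.quadratic[:3])


def _ols(x: np.ndarray, y: np.ndarray, degree: int):
    """Polynomial OLS: coefficients (high->low), R^2, overall F-test p."""
    import statsmodels.api as sm

    if np.ptp(y) == 0:  # constant response: flat fit, R^2 = 0 by convention
        return tuple([0.0] * degree + [float(y.mean())]), 0.0, 1.0
    X = np.vander(x, degree + 1)  # columns x^deg .. 1
    model = sm.OLS(y, X).fit()
    coeffs = tuple(model.params)
    r2 = float(model.rsquared)
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    return coeffs, r2, p


def fit_eccentricity_model(diff_map: DifferenceMap,
                           bin_width_mm: float = 0.05,
                           fit_range_mm: tuple[float, float] = (0.0, 3.0),
                           ) -> EccentricityModelFit:
    """Fit per-bin median percent change against eccentricity-bin centres.

    Cells are grouped into 0.05-mm radial bins by their centre eccentricity;
    the response is the median of valid cell values per bin, the abscissa the
    bin centre. Degree-1 and degree-2 OLS are both fitted; the quadratic is
    chosen only if its R^2 exceeds the linear R^2 by more than
    :data:`R2_TIE_TOLERANCE`.
    """
    bins = templates.eccentricity_bin_grid(bin_width_mm)
    centers = templates.bin_center_mm(np.arange(bins.max() + 1), bin_width_mm)
    vals = diff_map.values
    valid = diff_map.valid_mask & np.isfinite(vals)
    lo, hi = fit_range_mm

    xs, ys = [], []
    for b in range(bins.max() + 1):
        c = centers[b]
        if not (lo <= c <= hi):
            continue
        cell_vals = vals[(bins == b) & valid]
        if cell_vals.size == 0:
            continue
        xs.append(c)
        ys.append(float(np.median(cell_vals)))
    x, y = np.asarray(xs), np.asarray(ys)

    if x.size < 3:
        raise ValueError(
            f"only {x.size} populated eccentricity bins in {fit_range_mm}; "
            "need >= 3 for a linear fit")
    lin_c, lin_r2, lin_p = _ols(x, y, 1)
    linear = (lin_c[0], lin_c[1], lin_r2)
    quadratic = None
    chosen, p_value = "linear", lin_p
    if x.size >= 4:
        quad_c, quad_r2, quad_p = _ols(x, y, 2)
        quadratic = (quad_c[0], quad_c[1], quad_c[2], quad_r2)
        if quad_r2 - lin_r2 > R2_TIE_TOLERANCE:
            chosen, p_value = "quadratic", quad_p
    return EccentricityModelFit(linear=linear, quadratic=quadratic,
                                chosen=chosen, p_value=p_value,
                                fit_range_mm=fit_range_mm, n_bins=x.size,
                                bin_centers_mm=x, bin_values=y)


@dataclass
class ModelFeatures:
    """Geometric features of the chosen eccentricity model (full precision)."""

    crossover_mm: tuple[float, ...]   # roots within the fit range
    vertex_mm: float | None           # quadratic extremum location
    extremal_value_pct: float | None  # value at the vertex

    def report(self, decimals: int = 1) -> dict:
        """Rounded presentation (the reporting convention: 0.1 mm)."""
        return {
            "crossover_mm": tuple(round(float(r), decimals)
                                  for r in self.crossover_mm),
            "vertex_mm": (None if self.vertex_mm is None
                          else round(float(self.vertex_mm), decimals)),
            "extremal_value_pct": (None if self.extremal_value_pct is None
                                   else round(float(self.extremal_value_pct),
                                              decimals)),
        }


def model_features(fit: EccentricityModelFit) -> ModelFeatures:
    """Crossover roots, quadratic vertex and extremal value of the chosen model."""
    lo, hi = fit.fit_range_mm
    if fit.chosen == "linear":
        m, k, _ = fit.linear
        if m == 0:
            return ModelFeatures((), None, None)
        return ModelFeatures((-k / m,), None, None)
    a, b, c, _ = fit.quadratic
    if a == 0:
        return ModelFeatures((), None, None)
    vertex = -b / (2 * a)
    extremal = c - b * b / (4 * a)
    disc = b * b - 4 * a * c
    roots: tuple[float, ...] = ()
    if disc >= 0:
        r1 = (-b - np.sqrt(disc)) / (2 * a)
        r2 = (-b + np.sqrt(disc)) / (2 * a)
        roots = tuple(sorted(r for r in (r1, r2) if lo <= r <= hi))
    return ModelFeatures(roots, float(vertex), float(extremal))


def correlate_metrics(map_a: DifferenceMap, map_b: DifferenceMap,
                      level: str = "bin", bin_width_mm: float = 0.05
                      ) -> tuple[float, float]:
    """Spearman correlation between two difference maps.

    ``level='bin'`` (default) correlates per-bin medians over shared valid
    cells, matching how eccentricity data are presented; ``level='cell'``
    correlates raw shared cells.
    """
    shared = (map_a.valid_mask & map_b.valid_mask
              & np.isfinite(map_a.values) & np.isfinite(map_b.values))
    if level == "cell":
        a, b = map_a.values[shared], map_b.values[shared]
    elif level == "bin":
        bins = templates.eccentricity_bin_grid(bin_width_mm)
        a, b = [], []
        for bi in np.unique(bins[shared]):
            sel = shared & (bins == bi)
            a.append(np.median(map_a.values[sel]))
            b.append(np.median(map_b.values[sel]))
        a, b = np.asarray(a), np.asarray(b)
    else:
        raise ValueError(f"level must be 'bin' or 'cell', got {level!r}")
    if a.size < 3:
        raise ValueError("need at least 3 shared points for a correlation")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000 non-constant values."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk statistic undefined for constant input")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)
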