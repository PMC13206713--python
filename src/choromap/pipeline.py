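"""Reproducible end-to-end runs: simulate -> QC -> quantify -> analyze.

A run is described by a serializable :class:`RunConfig`; all randomness flows
from its single seed through deterministically derived per-eye streams, so a
run re-executed from the saved config reproduces every CSV/JSON artifact
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis, quant, synthetic, templates
from .quant import BinarizationParams, CellMetricsGrid
from .volume_io import qc_filter

METRICS = ("CT", "CVI", "LA", "SA")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    n_eyes_per_group: int = 2
    n_bscans: int = 13
    scene: dict = field(default_factory=dict)       # SceneParams overrides, both groups
    iamd_scene: dict = field(default_factory=dict)  # extra overrides for iAMD eyes
    binarization: dict = field(default_factory=dict)
    min_quality_db: float = 15.0
    max_excluded: int = 2
    formula: str = "symmetric"   # or "raw"
    paired: bool = True
    fit_range_mm: tuple[float, float] = (0.0, 3.0)
    metrics: tuple[str, ...] = METRICS

    def binarization_params(self) -> BinarizationParams:
        return BinarizationParams(**self.binarization)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["fit_range_mm"] = tuple(d.get("fit_range_mm", (0.0, 3.0)))
        d["metrics"] = tuple(d.get("metrics", METRICS))
        return cls(**d)


def _eye_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-eye integer seeds derived from the run seed."""
    ss = np.random.SeedSequence(int(seed) % (2**31))
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def save_grid(grid: CellMetricsGrid, outdir: Path, stem: str) -> list[Path]:
    """Write a CellMetricsGrid as four metric CSV matrices plus validity."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in METRICS:
        p = outdir / f"{stem}_{name}.csv"
        np.savetxt(p, grid.metric(name), delimiter=",", fmt="%.10g")
        paths.append(p)
    p = outdir / f"{stem}_valid.csv"
    np.savetxt(p, grid.valid_mask.astype(int), delimiter=",", fmt="%d")
    paths.append(p)
    return paths


def load_grid(outdir: Path, stem: str, laterality: str = "OD") -> CellMetricsGrid:
    outdir = Path(outdir)
    arrs = {name: np.loadtxt(outdir / f"{stem}_{name}.csv", delimiter=",")
            for name in METRICS}
    valid = np.loadtxt(outdir / f"{stem}_valid.csv", delimiter=",").astype(bool)
    return CellMetricsGrid(ct_um=arrs["CT"], la_um2=arrs["LA"],
                           sa_um2=arrs["SA"], cvi=arrs["CVI"],
                           valid_mask=valid, laterality=laterality)


def grid_to_rgba(values: np.ndarray, valid_mask: np.ndarray,
                 vmin: float | None = None, vmax: float | None = None,
                 cmap: str = "RdBu_r",
                 invalid_color=(200, 200, 200, 255)) -> np.ndarray:
    """Colormap a 60x60 grid to RGBA; invalid cells get a neutral gray.

    For difference maps the palette is centred at zero by default
    (vmin = -vmax = -max|values|).
    """
    import matplotlib
    import matplotlib.colors as mcolors

    if values.shape != (templates.N_CELLS, templates.N_CELLS):
        raise ValueError(f"expected a 60x60 grid, got {values.shape}")
    finite = valid_mask & np.isfinite(values)
    if vmax is None:
        vmax = float(np.nanmax(np.abs(values[finite]))) if finite.any() else 1.0
        vmax = vmax or 1.0
    if vmin is None:
        vmin = -vmax
    norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
    rgba = matplotlib.colormaps[cmap](norm(np.where(finite, values, 0.0)))
    rgba = (rgba * 255).astype(np.uint8)
    rgba[~finite] = np.array(invalid_color, dtype=np.uint8)
    return rgba


def render_map(values: np.ndarray, valid_mask: np.ndarray, path: Path,
               title: str = "", units: str = "%", cmap: str = "RdBu_r",
               vmin: float | None = None, vmax: float | None = None) -> Path:
    """Render a 60x60 map to an image file with a labelled colorbar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.cm as cm
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    rgba = grid_to_rgba(values, valid_mask, vmin=vmin, vmax=vmax, cmap=cmap)
    finite = valid_mask & np.isfinite(values)
    if vmax is None:
        vmax = float(np.nanmax(np.abs(values[finite]))) if finite.any() else 1.0
        vmax = vmax or 1.0
    if vmin is None:
        vmin = -vmax
    fig, ax = plt.subplots(figsize=(5, 4.2))
    ax.imshow(rgba, origin="lower", extent=(-3.6, 3.6, -3.6, 3.6))
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    sm = cm.ScalarMappable(norm=mcolors.Normalize(vmin, vmax), cmap=cmap)
    fig.colorbar(sm, ax=ax, label=units)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute a full synthetic run and write all artifacts to ``outdir``.

    Stages: simulate one volume per eye (iAMD scenes may override scene
    parameters, e.g. a different lumen fraction), QC-filter, quantify to
    60x60 grids, compute per-metric difference maps, sector tables, global
    comparisons, eccentricity fits and model features, and a manifest.
    Raises if QC rejects all eyes of a group.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.binarization_params()
    seeds = _eye_seeds(config.seed, 2 * config.n_eyes_per_group)

    groups: dict[str, list[CellMetricsGrid]] = {"control": [], "iamd": []}
    manifest: dict = {"config": json.loads(config.to_json()), "eyes": [],
                      "outputs": []}
    for g_idx, group in enumerate(("control", "iamd")):
        overrides = dict(config.scene)
        if group == "iamd":
            overrides.update(config.iamd_scene)
        for e in range(config.n_eyes_per_group):
            seed = seeds[g_idx * config.n_eyes_per_group + e]
            scene = synthetic.SceneParams(**overrides, seed=seed,
                                          n_bscans=config.n_bscans)
            volume, _ = synthetic.generate_volume(scene)
            report = qc_filter(volume, config.min_quality_db, config.max_excluded)
            manifest["eyes"].append({"group": group, "index": e, "seed": seed,
                                     "qc_accepted": report.volume_accepted,
                                     "excluded_bscans": report.excluded_bscans})
            if not report.volume_accepted:
                continue
            grid = quant.quantify_volume(volume, params,
                                         excluded_bscans=report.excluded_bscans)
            groups[group].append(grid)
            manifest["outputs"] += [str(p.relative_to(outdir)) for p in
                                    save_grid(grid, outdir / "grids",
                                              f"{group}_{e:02d}")]
    for group, grids in groups.items():
        if not grids:
            raise RuntimeError(f"QC rejected every eye of the {group} group")

    results: dict = {}
    for metric in config.metrics:
        dmap = analysis.difference_map(groups["iamd"], groups["control"],
                                       metric, mode=config.formula)
        np.savetxt(outdir / f"diffmap_{metric}.csv", dmap.values,
                   delimiter=",", fmt="%.10g")
        render_map(dmap.values, dmap.valid_mask,
                   outdir / f"diffmap_{metric}.png",
                   title=f"{metric} difference map", units="%")
        manifest["outputs"] += [f"diffmap_{metric}.csv", f"diffmap_{metric}.png"]

        gc = analysis.global_compare(groups["iamd"], groups["control"], metric,
                                     paired=config.paired)
        sect = analysis.sector_compare(dmap)
        sect.sectors.to_csv(outdir / f"sectors_{metric}.csv", index=False)
        manifest["outputs"].append(f"sectors_{metric}.csv")
        entry = {
            "global": {"statistic": gc.statistic, "p": gc.p_value,
                       "median_pct_change": gc.median_pct_change,
                       "iqr": list(gc.iqr_pct_change), "test": gc.test},
            "kruskal_rings": {"statistic": sect.kruskal_statistic,
                              "p": sect.kruskal_p},
        }
        try:
            fit = analysis.fit_eccentricity_model(
                dmap, fit_range_mm=tuple(config.fit_range_mm))
            feats = analysis.model_features(fit)
            entry["eccentricity_fit"] = {
                "linear": list(fit.linear),
                "quadratic": None if fit.quadratic is None else list(fit.quadratic),
                "chosen": fit.chosen, "p": fit.p_value,
                "features": feats.report(),
            }
        except ValueError as exc:
            entry["eccentricity_fit"] = {"error": str(exc)}
            warnings.warn(f"{metric}: eccentricity fit omitted: {exc}",
                          stacklevel=2)
        results[metric] = entry

    (outdir / "results.json").write_text(
        json.dumps(results, sort_keys=True, indent=2, default=float))
    manifest["outputs"].append("results.json")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2))
    return outdir
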