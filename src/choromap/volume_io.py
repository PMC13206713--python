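"""Open-format I/O for OCT macular cubes and acquisition quality control.

A volume is stored as a multi-page grayscale TIFF (one page per B-scan) plus a
JSON sidecar holding geometry, quality scores, laterality, fovea position and
the two choroid boundary curves (RPE and choroidoscleral junction), which are
required inputs of every downstream stage. The round trip write -> read is
lossless for both pixels and metadata.

QC follows the acquisition protocol: B-scans with a quality score below 15 dB
are excluded, and a volume with three or more excluded B-scans is rejected
outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class FormatError(ValueError):
    """Inconsistent or incomplete on-disk volume."""


@dataclass
class OCTVolume:
    """One eye's macular cube: image stack, geometry and boundary curves.

    images : (n_bscans, H, W) uint8
    rpe_curve, csj_curve : (n_bscans, W) real-valued boundary depths in pixel
        rows (sub-pixel allowed); ``csj >= rpe`` everywhere.
    fovea_xy_um : fovea position in volume coordinates (x along the B-scan,
        y across B-scans, both in um from the volume origin).
    """

    images: np.ndarray
    ascan_spacing_um: float
    bscan_spacing_um: float
    axial_res_um: float
    quality_db: np.ndarray
    laterality: str
    fovea_xy_um: tuple[float, float]
    rpe_curve: np.ndarray
    csj_curve: np.ndarray
    opacity_flag: bool = False  # manual flag: poor choroid visibility
    extra: dict = field(default_factory=dict)

    @property
    def n_bscans(self) -> int:
        return self.images.shape[0]

    def validate(self) -> None:
        if self.images.ndim != 3:
            raise FormatError("images must be a (n_bscans, H, W) stack")
        n, _, W = self.images.shape
        for name in ("ascan_spacing_um", "bscan_spacing_um", "axial_res_um"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if self.laterality not in ("OD", "OS"):
            raise FormatError(f"laterality must be OD or OS, got {self.laterality!r}")
        if np.asarray(self.quality_db).shape != (n,):
            raise FormatError("quality_db must have one value per B-scan")
        for name in ("rpe_curve", "csj_curve"):
            cur = getattr(self, name)
            if cur is None:
                raise FormatError(
                    f"{name} is missing: boundary segmentations are required inputs"
                )
            if np.asarray(cur).shape != (n, W):
                raise FormatError(f"{name} must be (n_bscans, W)")
        if np.any(self.csj_curve < self.rpe_curve):
            raise FormatError("csj_curve must be >= rpe_curve at every A-scan")


@dataclass
class QCReport:
    """Outcome of the quality filter for one volume."""

    excluded_bscans: list[int]
    volume_accepted: bool
    reason: str = ""


def qc_filter(volume: OCTVolume, min_quality_db: float = 15.0,
              max_excluded: int = 2) -> QCReport:
    """Apply the per-B-scan quality rule.

    B-scans with quality strictly below ``min_quality_db`` are excluded
    (15.0 dB passes). The volume is rejected when more than ``max_excluded``
    B-scans are excluded, or when the manual opacity flag is set.
    """
    q = np.asarray(volume.quality_db, dtype=float)
    excluded = [int(i) for i in np.nonzero(q < min_quality_db)[0]]
    if volume.opacity_flag:
        return QCReport(excluded, False, "manual opacity flag set")
    accepted = len(excluded) <= max_excluded
    reason = "" if accepted else (
        f"{len(excluded)} B-scans below {min_quality_db} dB "
        f"(more than {max_excluded} allowed)"
    )
    return QCReport(excluded, accepted, reason)


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write ``volume`` as ``<path>.tiff`` + ``<path>.json`` (path sans suffix)."""
    volume.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tiff = path.with_suffix(".tiff")
    tifffile.imwrite(tiff, np.asarray(volume.images, dtype=np.uint8),
                     photometric="minisblack")
    meta = {
        "n_bscans": volume.n_bscans,
        "ascan_spacing_um": volume.ascan_spacing_um,
        "bscan_spacing_um": volume.bscan_spacing_um,
        "axial_res_um": volume.axial_res_um,
        "quality_db": np.asarray(volume.quality_db, dtype=float).tolist(),
        "laterality": volume.laterality,
        "fovea_xy_um": list(volume.fovea_xy_um),
        "rpe_curve": np.asarray(volume.rpe_curve, dtype=float).tolist(),
        "csj_curve": np.asarray(volume.csj_curve, dtype=float).tolist(),
        "opacity_flag": volume.opacity_flag,
        "extra": volume.extra,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return tiff


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`; validates consistency."""
    path = Path(path)
    tiff, sidecar = path.with_suffix(".tiff"), path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    if not tiff.exists():
        raise FormatError(f"missing TIFF stack {tiff}")
    meta = json.loads(sidecar.read_text())
    images = tifffile.imread(tiff)
    if images.ndim == 2:
        images = images[None]
    if images.shape[0] != meta["n_bscans"]:
        raise FormatError(
            f"n_bscans: sidecar says {meta['n_bscans']} but stack has "
            f"{images.shape[0]} pages"
        )
    for name in ("rpe_curve", "csj_curve"):
        if meta.get(name) is None:
            raise FormatError(
                f"{name} is missing: boundary segmentations are required inputs"
            )
    vol = OCTVolume(
        images=images,
        ascan_spacing_um=meta["ascan_spacing_um"],
        bscan_spacing_um=meta["bscan_spacing_um"],
        axial_res_um=meta["axial_res_um"],
        quality_db=np.asarray(meta["quality_db"], dtype=float),
        laterality=meta["laterality"],
        fovea_xy_um=tuple(meta["fovea_xy_um"]),
        rpe_curve=np.asarray(meta["rpe_curve"], dtype=float),
        csj_curve=np.asarray(meta["csj_curve"], dtype=float),
        opacity_flag=bool(meta.get("opacity_flag", False)),
        extra=meta.get("extra", {}),
    )
    vol.validate()
    return vol


def with_quality(volume: OCTVolume, quality_db) -> OCTVolume:
    """Copy of ``volume`` with replaced per-B-scan quality scores."""
    return replace(volume, quality_db=np.asarray(quality_db, dtype=float))
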