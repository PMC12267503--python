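"""Collagen volume-fraction quantification over named transmural regions.

All counting is exact integer arithmetic; percentages are divided once at
the end and rounded only at presentation (two decimals in CSV, full
precision in JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .volume_io import BINARY_MASK, ROIBox, Volume3D

REGION_LABELS = ("sub-epicardium", "mid-myocardium", "sub-endocardium")


@dataclass
class RegionStats:
    label: str
    percent: float
    n_voxels: int
    n_collagen: int


@dataclass
class CollagenReport:
    """Per-region collagen percentages and their unweighted average."""

    sample_id: str
    regions: list[RegionStats] = field(default_factory=list)

    @property
    def average(self) -> float:
        if not self.regions:
            raise ValidationError("report has no regions")
        return float(np.mean([r.percent for r in self.regions]))

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "regions": [
                {
                    "label": r.label,
                    "percent": r.percent,
                    "n_voxels": r.n_voxels,
                    "n_collagen": r.n_collagen,
                }
                for r in self.regions
            ],
            "average": self.average,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _check_binary(mask: Volume3D, name: str) -> np.ndarray:
    data = np.asarray(mask.data)
    if mask.intensity_kind != BINARY_MASK and not np.isin(np.unique(data), (0, 1)).all():
        raise ValidationError(f"{name} must be a binary {{0,1}} volume")
    return data.astype(bool)


def percent_collagen(
    mask: Volume3D, roi: ROIBox, tissue_mask: Volume3D | None = None
) -> tuple[float, int, int]:
    """Collagen percentage inside an ROI.

    Returns ``(percent, n_collagen, n_voxels)``. With a tissue mask, the
    denominator counts only tissue voxels inside the ROI; otherwise every
    ROI voxel counts.
    """
    data = _check_binary(mask, "collagen mask")
    roi.check_within(data.shape)
    sl = roi.slices()
    if tissue_mask is not None:
        tissue = _check_binary(tissue_mask, "tissue mask")
        if tissue.shape != data.shape:
            raise ValidationError("tissue mask shape does not match collagen mask")
        sel = tissue[sl]
        n_voxels = int(sel.sum())
        n_collagen = int(data[sl][sel].sum())
    else:
        n_voxels = roi.n_voxels
        n_collagen = int(data[sl].sum())
    if n_voxels == 0:
        raise ValidationError(f"ROI {roi.label!r} has an empty denominator")
    return 100.0 * n_collagen / n_voxels, n_collagen, n_voxels


def regional_collagen_report(
    mask: Volume3D,
    rois,
    tissue_mask: Volume3D | None = None,
    sample_id: str = "sample",
) -> CollagenReport:
    """Quantify collagen in labelled ROIs and report the unweighted average."""
    rois = list(rois)
    if not rois:
        raise ValidationError("at least one labelled ROI is required")
    labels = [r.label for r in rois]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate ROI labels: {labels}")
    report = CollagenReport(sample_id=sample_id)
    for roi in rois:
        pct, n_col, n_vox = percent_collagen(mask, roi, tissue_mask)
        report.regions.append(RegionStats(roi.label, pct, n_vox, n_col))
    return report


def reports_to_csv(reports) -> str:
    """Render reports as CSV: rows = regions + Average, columns = samples.

    Percentages are rounded to two decimals at presentation only.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no reports to render")
    labels = [r.label for r in reports[0].regions]
    for rep in reports:
        if [r.label for r in rep.regions] != labels:
            raise ValidationError("all reports must share the same region labels, in order")
    lines = ["region," + ",".join(rep.sample_id for rep in reports)]
    for i, label in enumerate(labels):
        lines.append(label + "," + ",".join(f"{rep.regions[i].percent:.2f}" for rep in reports))
    lines.append("Average," + ",".join(f"{rep.average:.2f}" for rep in reports))
    return "\n".join(lines) + "\n"


def extract_cube(vol_or_mask: Volume3D, center, edge_um: float) -> Volume3D:
    """Extract a cubic sub-volume of physical edge ``edge_um`` around ``center``.

    The edge is converted to voxels per axis and rounded to the nearest odd
    count so the cube is centred on the stated voxel. The cube must fit
    entirely inside the volume — no padding.
    """
    if edge_um <= 0:
        raise ValidationError("edge_um must be positive")
    center = tuple(int(v) for v in center)
    half = []
    for axis, vs in enumerate(vol_or_mask.voxel_size_um):
        n = max(int(round(edge_um / vs)), 1)
        if n % 2 == 0:
            n += 1
        half.append(n // 2)
    lo = tuple(c - h for c, h in zip(center, half))
    hi = tuple(c + h + 1 for c, h in zip(center, half))
    for axis, (a, b, n) in enumerate(zip(lo, hi, vol_or_mask.shape)):
        if a < 0 or b > n:
            raise ValidationError(
                f"cube [{a}, {b}) exceeds volume bounds [0, {n}) on axis {axis}"
            )
    sub = vol_or_mask.data[tuple(slice(a, b) for a, b in zip(lo, hi))].copy()
    return Volume3D(sub, vol_or_mask.voxel_size_um, vol_or_mask.intensity_kind)
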