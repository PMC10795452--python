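"""Segmentation evaluation: Dice, 95th-percentile Hausdorff distance, volume
difference, and per-phase/IGTV report assembly.

Conventions: DSC = 2|A∩B|/(|A|+|B|), defined as 1.0 when both masks are
empty and 0.0 when exactly one is. HD95 extracts surface voxels by
6-connected erosion difference, measures directed surface-to-surface
distances in millimetres with anisotropic spacing (via a Euclidean distance
transform), takes the 95th percentile of each directed set with linear
interpolation and returns the larger of the two; it is undefined (raised,
never reported 0) when a mask is empty. VD = (|B| - |A|) * voxel volume in
cc, signed with B the ground truth, so positive means under-segmentation;
reports also carry |VD| for comparison with magnitude-style tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PhaseMaskSet, merge_igtv

__all__ = [
    "dsc",
    "hd95",
    "vd",
    "surface_voxels",
    "MetricReport",
    "evaluate_subject",
    "aggregate_reports",
]


class EmptyMaskError(ValueError):
    """Raised when a distance metric is requested for an empty mask."""


def _binarize(a):
    return np.asarray(a) > 0


def _check_extents(a, b):
    if a.shape != b.shape:
        raise ValueError(f"mask extents differ: {a.shape} vs {b.shape}")


def dsc(a, b) -> float:
    """Dice similarity coefficient of two binary volumes."""
    a, b = _binarize(a), _binarize(b)
    _check_extents(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def surface_voxels(mask):
    """Boolean map of voxels with at least one face-adjacent background neighbor."""
    mask = _binarize(mask)
    if not mask.any():
        return mask
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1), border_value=0
    )
    return mask & ~interior


def hd95(a, b, spacing) -> float:
    """Symmetrized 95th-percentile surface distance in mm."""
    a, b = _binarize(a), _binarize(b)
    _check_extents(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("HD95 is undefined for an empty mask")
    surf_a = surface_voxels(a)
    surf_b = surface_voxels(b)
    # distance of every voxel to the nearest surface voxel of the other mask
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    d_ab = dist_to_b[surf_a]
    d_ba = dist_to_a[surf_b]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def vd(a, b, spacing) -> float:
    """Signed volume difference ground-truth-minus-prediction in cc."""
    a, b = _binarize(a), _binarize(b)
    _check_extents(a, b)
    voxel_mm3 = float(np.prod(spacing))
    return (int(b.sum()) - int(a.sum())) * voxel_mm3 / 1000.0


@dataclass
class MetricReport:
    """Rows of (phase label, HD95 mm, DSC, VD cc) plus one IGTV row.

    HD95 is None where it is undefined (an empty mask on either side).
    """

    rows: list[dict]

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["phase", "hd95_mm", "dsc", "vd_cc", "abs_vd_cc"])
            writer.writeheader()
            for row in self.rows:
                writer.writerow({k: row[k] for k in writer.fieldnames})

    def row(self, phase_label):
        for r in self.rows:
            if r["phase"] == phase_label:
                return r
        raise KeyError(phase_label)


def evaluate_subject(pred: PhaseMaskSet, truth: PhaseMaskSet, phase_labels=None) -> MetricReport:
    """Per-phase metric rows followed by the IGTV row (union vs union)."""
    if pred.masks.shape != truth.masks.shape:
        raise ValueError(
            f"prediction and truth disagree: {pred.masks.shape} vs {truth.masks.shape}"
        )
    p_count = pred.P
    if phase_labels is None:
        from .core import default_phase_labels

        phase_labels = default_phase_labels(p_count)
    spacing = truth.spacing
    rows = []

    def _row(label, a, b):
        try:
            h = hd95(a, b, spacing)
        except EmptyMaskError:
            h = None
        signed = vd(a, b, spacing)
        return {
            "phase": label,
            "hd95_mm": h,
            "dsc": dsc(a, b),
            "vd_cc": signed,
            "abs_vd_cc": abs(signed),
        }

    for p in range(p_count):
        rows.append(_row(f"GTV{phase_labels[p]}", pred.phase(p), truth.phase(p)))
    pred_igtv = pred.igtv if pred.igtv is not None else merge_igtv(pred).igtv
    truth_igtv = truth.igtv if truth.igtv is not None else merge_igtv(truth).igtv
    rows.append(_row("IGTV", pred_igtv, truth_igtv))
    return MetricReport(rows)


def aggregate_reports(reports) -> MetricReport:
    """Mean ± sd across subjects, row-aligned by phase label.

    Rows gain ``*_sd`` fields; HD95 aggregates over the subjects where it
    is defined.
    """
    labels = [r["phase"] for r in reports[0].rows]
    rows = []
    for i, label in enumerate(labels):
        entry = {"phase": label}
        for key in ("hd95_mm", "dsc", "vd_cc", "abs_vd_cc"):
            vals = [rep.rows[i][key] for rep in reports if rep.rows[i][key] is not None]
            entry[key] = float(np.mean(vals)) if vals else None
            entry[key + "_sd"] = float(np.std(vals)) if vals else None
        rows.append(entry)
    return MetricReport(rows)
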