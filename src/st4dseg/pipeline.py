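"""Two-stage end-to-end workflow: liver segmentation -> ROI crop ->
per-phase dual-path GTV segmentation -> IGTV merge -> evaluation.

The liver stage runs the five-slice single-path model over every phase and
keeps the largest connected component per phase. One ROI — the bounding box
of the UNION of all phase livers, expanded by a margin and padded so the
in-plane sides stay divisible by 16 — is applied to every phase, which
keeps temporal triplets spatially aligned. GTV predictions are made inside
the ROI and re-embedded into the full volume geometry before any metric is
computed. GTV masks are left raw (no post-processing); only the liver gets
the largest-component cleanup.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import FourDCT, PhaseMaskSet, extract_triplet, merge_igtv, normalize_hu, save_mask
from .metrics import MetricReport, evaluate_subject
from .network import DOWNSAMPLE, load_checkpoint
from .training import predict_batch

__all__ = [
    "LiverROI",
    "PipelineConfig",
    "segment_liver",
    "roi_from_liver",
    "segment_gtv",
    "run_pipeline",
]


@dataclass
class LiverROI:
    """Half-open voxel box (h0, h1, w0, w1, k0, k1) shared by all phases."""

    box: tuple[int, int, int, int, int, int]
    margin: int
    source: str = "union"

    def __post_init__(self):
        h0, h1, w0, w1, k0, k1 = self.box
        if not (h1 > h0 and w1 > w0 and k1 > k0):
            raise ValueError(f"degenerate ROI box {self.box}")

    @property
    def shape(self):
        h0, h1, w0, w1, k0, k1 = self.box
        return (h1 - h0, w1 - w0, k1 - k0)


@dataclass
class PipelineConfig:
    liver_checkpoint: str
    gtv_checkpoint: str
    roi_margin: int = 4
    threshold: float = 0.5
    hu_window: tuple[float, float] = (-200.0, 300.0)
    batch_size: int = 8

    def __post_init__(self):
        if self.roi_margin < 0:
            raise ValueError("roi_margin must be >= 0")
        for name in ("liver_checkpoint", "gtv_checkpoint"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} {path} does not exist")


def _predict_phase_masks(ct: FourDCT, model, box, threshold, window, batch_size):
    """Slice-wise inference for every (phase, slice-in-box); returns (H,W,L,P) mask."""
    h0, h1, w0, w1, k0, k1 = box
    out = np.zeros(ct.data.shape, dtype=np.uint8)
    tasks = [(p, k) for p in range(ct.P) for k in range(k0, k1)]
    for start in range(0, len(tasks), batch_size):
        chunk = tasks[start : start + batch_size]
        xs, xt = [], []
        for p, k in chunk:
            pair = extract_triplet(ct, p, k)
            xs.append(normalize_hu(pair.spatial[:, h0:h1, w0:w1], window))
            xt.append(normalize_hu(pair.temporal[:, h0:h1, w0:w1], window))
        prob = predict_batch(model, np.stack(xs), np.stack(xt))
        for (p, k), pr in zip(chunk, prob):
            out[h0:h1, w0:w1, k, p] = (pr >= threshold).astype(np.uint8)
    return out


def _largest_component(mask3d):
    labeled, n = ndimage.label(mask3d)
    if n <= 1:
        return mask3d
    sizes = ndimage.sum_labels(mask3d, labeled, index=range(1, n + 1))
    return (labeled == (1 + int(np.argmax(sizes)))).astype(np.uint8)


def segment_liver(ct: FourDCT, model, threshold=0.5, window=(-200.0, 300.0), batch_size=8) -> PhaseMaskSet:
    """Per-phase liver masks from the five-slice baseline model.

    Keeps the largest 6-connected component per phase; raises when no phase
    produces any voxel above threshold.
    """
    full_box = (0, ct.H, 0, ct.W, 0, ct.L)
    raw = _predict_phase_masks(ct, model, full_box, threshold, window, batch_size)
    if raw.sum() == 0:
        raise ValueError("liver stage produced an empty mask in every phase")
    masks = np.stack(
        [_largest_component(raw[..., p]) for p in range(ct.P)], axis=-1
    ).astype(np.uint8)
    return PhaseMaskSet(masks, ct.spacing)


def _pad_to_multiple(lo, hi, extent, multiple):
    """Grow [lo, hi) so its length is a multiple of ``multiple``, inside [0, extent)."""
    length = hi - lo
    target = int(np.ceil(length / multiple)) * multiple
    if target > extent:
        raise ValueError(f"volume extent {extent} cannot host a side of {target}")
    grow = target - length
    lo = lo - grow // 2
    hi = lo + target
    if lo < 0:
        lo, hi = 0, target
    if hi > extent:
        hi, lo = extent, extent - target
    return lo, hi


def roi_from_liver(liver: PhaseMaskSet, margin=4, pad_multiple=DOWNSAMPLE) -> LiverROI:
    """Bounding box of the union of phase livers, expanded and 16-padded in-plane."""
    union = liver.masks.any(axis=3)
    if not union.any():
        raise ValueError("cannot build an ROI from an empty liver union")
    hh, ww, kk = np.nonzero(union)
    H, W, L = union.shape
    h0, h1 = max(int(hh.min()) - margin, 0), min(int(hh.max()) + 1 + margin, H)
    w0, w1 = max(int(ww.min()) - margin, 0), min(int(ww.max()) + 1 + margin, W)
    k0, k1 = max(int(kk.min()) - margin, 0), min(int(kk.max()) + 1 + margin, L)
    h0, h1 = _pad_to_multiple(h0, h1, H, pad_multiple)
    w0, w1 = _pad_to_multiple(w0, w1, W, pad_multiple)
    return LiverROI((h0, h1, w0, w1, k0, k1), margin)


def segment_gtv(ct: FourDCT, roi: LiverROI, model, threshold=0.5, window=(-200.0, 300.0), batch_size=8) -> PhaseMaskSet:
    """Dual-path GTV inference inside the ROI, re-embedded into full geometry."""
    h0, h1, w0, w1, k0, k1 = roi.box
    for side in (h1 - h0, w1 - w0):
        if side % DOWNSAMPLE:
            raise ValueError(
                f"ROI side {side} not divisible by {DOWNSAMPLE}; "
                "rebuild the ROI with roi_from_liver"
            )
    masks = _predict_phase_masks(ct, model, roi.box, threshold, window, batch_size)
    return PhaseMaskSet(masks, ct.spacing)


def run_pipeline(ct: FourDCT, config: PipelineConfig, truth: PhaseMaskSet | None = None, out_dir=None, log_path=None):
    """Full two-stage run on one subject.

    Returns ``(pred: PhaseMaskSet with igtv, report: MetricReport | None)``;
    writes per-phase masks, the IGTV and a CSV report when ``out_dir`` is
    given, and JSON-lines stage logs when ``log_path`` is given.
    """
    def _log(**entry):
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    t0 = time.time()
    try:
        liver_model = load_checkpoint(config.liver_checkpoint)
        gtv_model = load_checkpoint(config.gtv_checkpoint)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    try:
        liver = segment_liver(
            ct, liver_model, config.threshold, config.hu_window, config.batch_size
        )
    except Exception as exc:
        raise RuntimeError(f"[segment_liver] {exc}") from exc
    _log(stage="segment_liver", seconds=time.time() - t0, liver_voxels=int(liver.masks.sum()))

    t1 = time.time()
    try:
        roi = roi_from_liver(liver, config.roi_margin)
        pred = segment_gtv(
            ct, roi, gtv_model, config.threshold, config.hu_window, config.batch_size
        )
    except Exception as exc:
        raise RuntimeError(f"[segment_gtv] {exc}") from exc
    pred = merge_igtv(pred)
    _log(
        stage="segment_gtv",
        seconds=time.time() - t1,
        roi_box=list(roi.box),
        gtv_voxels=[int(pred.phase(p).sum()) for p in range(pred.P)],
        igtv_voxels=int(pred.igtv.sum()),
    )

    report = None
    if truth is not None:
        report = evaluate_subject(pred, truth, ct.phase_labels)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for p, label in enumerate(ct.phase_labels):
            save_mask(pred.phase(p), ct.spacing, out_dir / f"gtv_phase{label.replace('%', '')}.nii.gz")
        save_mask(pred.igtv, ct.spacing, out_dir / "igtv.nii.gz")
        if report is not None:
            report.to_csv(out_dir / "report.csv")
    return pred, report
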