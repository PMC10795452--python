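"""Desk-scale phantom experiments: the scaled-down recovery study.

This module wires the phantom generator, the two networks, the training
loop and the pipeline into one reproducible experiment: generate a cohort
of synthetic subjects, train the liver-stage model and both GTV models
(dual-path and five-slice baseline) on the training split, and evaluate
end-to-end on held-out test subjects. Problem sizes are chosen for a
single CPU: 64x64x24 volumes, 10 phases, 8 base channels, 48x48 in-plane
training crops. The same entry points back both the test suite and the
results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import aggregate_reports, dsc, evaluate_subject
from .network import BaselineUNet, DualPathUNet, NetworkConfig
from .phantom import PhantomConfig, make_dataset
from .pipeline import roi_from_liver, segment_gtv, segment_liver
from .training import SliceDataset, TrainConfig, train

__all__ = [
    "RecoveryConfig",
    "fixed_roi",
    "train_liver_model",
    "train_gtv_model",
    "evaluate_models",
    "run_recovery",
]

HU_WINDOW = (-200.0, 300.0)


@dataclass
class RecoveryConfig:
    """Problem sizes and budgets of the scaled recovery experiment."""

    n_subjects: int = 10
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    base_channels: int = 8
    crop_side: int = 48
    liver_epochs: int = 3
    liver_steps_per_epoch: int = 30
    gtv_epochs: int = 8
    gtv_steps_per_epoch: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 8
    phantom: PhantomConfig = field(default_factory=PhantomConfig)


def fixed_roi(subject, side=48):
    """A fixed-size in-plane crop centered on the subject's true liver union.

    Training uses one crop size for all subjects so slices batch together;
    the full k range is kept (slices are 2D network inputs).
    """
    union = subject.liver_masks.masks.any(axis=3)
    hh, ww, _ = np.nonzero(union)
    H, W, L = union.shape

    def _window(lo_center, extent):
        lo = int(round(lo_center - side / 2))
        lo = max(0, min(lo, extent - side))
        return lo, lo + side

    h0, h1 = _window((hh.min() + hh.max()) / 2, H)
    w0, w1 = _window((ww.min() + ww.max()) / 2, W)
    return (h0, h1, w0, w1, 0, L)


def _train_config(cfg: RecoveryConfig, seed, epochs, steps):
    return TrainConfig(
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=epochs,
        patience=max(epochs // 2, 2),
        seed=seed,
        hu_window=HU_WINDOW,
        max_steps_per_epoch=steps,
    )


def train_liver_model(train_subjects, val_subjects, cfg: RecoveryConfig, seed=0):
    """Five-slice baseline trained on full-frame slices with liver labels."""
    model = BaselineUNet(NetworkConfig(base_channels=cfg.base_channels, seed=seed))
    tr = SliceDataset(train_subjects, labels="liver_masks", window=HU_WINDOW, seed=seed)
    va = SliceDataset(val_subjects, labels="liver_masks", window=HU_WINDOW, seed=seed + 1)
    best, history = train(model, tr, va, _train_config(cfg, seed, cfg.liver_epochs, cfg.liver_steps_per_epoch))
    return model, best, history


def train_gtv_model(arch, train_subjects, val_subjects, cfg: RecoveryConfig, seed=0):
    """Dual-path or baseline GTV model trained on liver-centered crops."""
    net_cfg = NetworkConfig(base_channels=cfg.base_channels, seed=seed)
    model = DualPathUNet(net_cfg) if arch == "dualpath" else BaselineUNet(net_cfg)

    def _dataset(subjects, ds_seed):
        ds = None
        for subj in subjects:
            part = SliceDataset(
                [subj], labels="masks", roi=fixed_roi(subj, cfg.crop_side),
                window=HU_WINDOW, seed=ds_seed,
            )
            if ds is None:
                ds = part
            else:
                ds.samples.extend(part.samples)
        return ds

    tr = _dataset(train_subjects, seed)
    va = _dataset(val_subjects, seed + 1)
    best, history = train(model, tr, va, _train_config(cfg, seed, cfg.gtv_epochs, cfg.gtv_steps_per_epoch))
    return model, best, history


def evaluate_models(models, test_subjects, liver_model, threshold=0.5, batch_size=8):
    """End-to-end evaluation of several GTV models on the test subjects.

    The liver stage (shared by all models) runs once per subject; each GTV
    model then predicts inside that ROI. Returns, per model name, the list
    of per-subject MetricReports and the mean per-phase test DSC.
    """
    rois = []
    for subj in test_subjects:
        liver = segment_liver(subj.ct, liver_model, threshold, HU_WINDOW, batch_size)
        rois.append(roi_from_liver(liver))
    results = {}
    for name, model in models.items():
        reports = []
        for subj, roi in zip(test_subjects, rois):
            pred = segment_gtv(subj.ct, roi, model, threshold, HU_WINDOW, batch_size)
            reports.append(evaluate_subject(pred, subj.masks, subj.ct.phase_labels))
        phase_dscs = [
            row["dsc"] for rep in reports for row in rep.rows if row["phase"] != "IGTV"
        ]
        igtv_dscs = [rep.row("IGTV")["dsc"] for rep in reports]
        results[name] = {
            "reports": reports,
            "aggregate": aggregate_reports(reports),
            "mean_gtv_dsc": float(np.mean(phase_dscs)),
            "mean_igtv_dsc": float(np.mean(igtv_dscs)),
        }
    return results


def run_recovery(seed=0, cfg: RecoveryConfig | None = None, seeds=(0, 1, 2), progress=None):
    """The full scaled recovery study.

    One phantom cohort and one liver model are shared; for each training
    seed both GTV architectures are trained under an identical budget and
    evaluated end-to-end. Returns per-seed and summary statistics.
    """
    cfg = cfg or RecoveryConfig()
    base = int(seed) % (2**20)
    tr, va, te = make_dataset(cfg.phantom, cfg.n_subjects, cfg.split, seed=base)
    if progress:
        progress(f"generated {cfg.n_subjects} subjects (split {len(tr)}/{len(va)}/{len(te)})")
    liver_model, liver_best, _ = train_liver_model(tr, va, cfg, seed=base + 1)
    if progress:
        progress(f"liver model val DSC {liver_best['val_dsc']:.3f}")

    per_seed = []
    for s in seeds:
        run_seed = base + 1000 * (s + 1)
        models = {}
        for arch in ("dualpath", "baseline"):
            model, best, _ = train_gtv_model(arch, tr, va, cfg, seed=run_seed)
            models[arch] = model
            if progress:
                progress(f"seed {s}: {arch} val DSC {best['val_dsc']:.3f}")
        evals = evaluate_models(models, te, liver_model)
        per_seed.append(
            {
                "seed": s,
                "dualpath": evals["dualpath"],
                "baseline": evals["baseline"],
            }
        )
        if progress:
            progress(
                f"seed {s}: test GTV DSC dual {evals['dualpath']['mean_gtv_dsc']:.3f} "
                f"vs baseline {evals['baseline']['mean_gtv_dsc']:.3f}"
            )

    summary = {
        "liver_val_dsc": liver_best["val_dsc"],
        "dual_gtv_dsc_median": float(np.median([r["dualpath"]["mean_gtv_dsc"] for r in per_seed])),
        "dual_igtv_dsc_median": float(np.median([r["dualpath"]["mean_igtv_dsc"] for r in per_seed])),
        "baseline_gtv_dsc_median": float(np.median([r["baseline"]["mean_gtv_dsc"] for r in per_seed])),
        "dual_gtv_dsc_mean": float(np.mean([r["dualpath"]["mean_gtv_dsc"] for r in per_seed])),
        "baseline_gtv_dsc_mean": float(np.mean([r["baseline"]["mean_gtv_dsc"] for r in per_seed])),
    }
    return {
        "per_seed": per_seed,
        "summary": summary,
        "test_subjects": te,
        "liver_model": liver_model,
        "models": models,  # the final seed's trained GTV models
    }
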