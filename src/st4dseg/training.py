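"""Loss, slice sampling and the optimization loop.

The loss is binary cross-entropy on raw logits (sigmoid folded into the
log-sum-exp form for numerical stability) with an optional positive-class
weight to counter the extreme tumor/background pixel imbalance. Training
samples are slices whose label contains at least one foreground pixel plus
an equal number of randomly drawn negative slices; the only augmentation is
a left-right flip, which preserves the anterior-posterior / superior-
inferior motion semantics. Model selection is by best validation Dice over
epochs with early stopping. Everything is reproducible from a single seed
on one device.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FourDCT, extract_triplet, normalize_hu
from .nn import autograd as ag
from .nn.optim import Adam

__all__ = [
    "TrainConfig",
    "bce_with_logits",
    "pos_weight_from_batch",
    "SliceDataset",
    "train",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 50
    patience: int = 10
    pos_weight_cap: float = 50.0
    pos_weight_policy: str = "batch"  # "batch" | "none"
    threshold: float = 0.5
    augment_flips: bool = True
    hu_window: tuple[float, float] = (-200.0, 300.0)
    seed: int = 0
    val_every: int = 1
    max_steps_per_epoch: int | None = None

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("binarization threshold must lie in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, patience must be positive")


def bce_with_logits(logits, targets, pos_weight=1.0):
    """Mean weighted BCE over a batch of logit maps; returns a scalar Tensor.

    ``targets`` must be strictly binary; ``pos_weight`` multiplies the
    positive-class term.
    """
    t = np.asarray(targets)
    if not np.all((t == 0) | (t == 1)):
        raise ValueError("targets must be strictly binary")
    return ag.bce_with_logits_op(logits, t, pos_weight)


def pos_weight_from_batch(targets, cap=50.0):
    """Background-to-tumor pixel ratio of a batch, clipped to [1, cap].

    An all-background batch falls back to the cap (the imbalance is then
    at its worst and unmeasurable).
    """
    t = np.asarray(targets)
    n_pos = int((t == 1).sum())
    if n_pos == 0:
        return float(cap)
    w = (t.size - n_pos) / n_pos
    return float(np.clip(w, 1.0, cap))


# ---------------------------------------------------------------------------
# slice sampling
# ---------------------------------------------------------------------------

class SliceDataset:
    """Triplet samples from a list of subjects, balanced and optionally cropped.

    Each sample is (spatial 3xHxW, temporal 3xHxW, label HxW) already
    HU-normalized; positive slices (>= 1 tumor pixel) are all kept and an
    equal number of negative slices is drawn at random. ``roi`` is a
    half-open (h0, h1, w0, w1, k0, k1) crop applied identically to every
    phase of a subject.
    """

    def __init__(self, subjects, labels="masks", roi=None, window=(-200.0, 300.0), seed=0, balance=True):
        rng = np.random.default_rng(seed)
        self.samples = []
        for subj in subjects:
            ct: FourDCT = subj.ct
            mask4d = getattr(subj, labels).masks
            box = roi if roi is not None else (0, ct.H, 0, ct.W, 0, ct.L)
            h0, h1, w0, w1, k0, k1 = box
            pos, neg = [], []
            for p in range(ct.P):
                for k in range(k0, k1):
                    (pos if mask4d[h0:h1, w0:w1, k, p].any() else neg).append((p, k))
            if balance:
                keep = rng.permutation(len(neg))[: len(pos)]
                chosen = pos + [neg[i] for i in keep]
            else:
                chosen = pos + neg
            for p, k in chosen:
                pair = extract_triplet(ct, int(p), int(k), with_label=mask4d)
                self.samples.append(
                    (
                        normalize_hu(pair.spatial[:, h0:h1, w0:w1], window),
                        normalize_hu(pair.temporal[:, h0:h1, w0:w1], window),
                        mask4d[h0:h1, w0:w1, int(k), int(p)].astype(np.float32),
                    )
                )
        if not self.samples:
            raise ValueError("empty split: no slices to train on")

    def __len__(self):
        return len(self.samples)

    def batches(self, batch_size, rng, flips=True):
        order = rng.permutation(len(self.samples))
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            xs = np.stack([self.samples[i][0] for i in idx])
            xt = np.stack([self.samples[i][1] for i in idx])
            y = np.stack([self.samples[i][2] for i in idx])[:, None]
            if flips and rng.random() < 0.5:
                # left-right flip: w is the last axis
                xs, xt, y = xs[..., ::-1].copy(), xt[..., ::-1].copy(), y[..., ::-1].copy()
            yield xs, xt, y


def _model_inputs(model, xs, xt):
    if model.arch == "dualpath":
        return (xs, xt)
    # five-slice stack: below, prev-phase, center, next-phase, above
    stack = np.stack([xs[:, 0], xt[:, 0], xs[:, 1], xt[:, 2], xs[:, 2]], axis=1)
    return (stack,)


def predict_batch(model, xs, xt):
    """Eval-mode sigmoid probabilities for a batch of triplet stacks."""
    model.eval()
    logits = model(*_model_inputs(model, xs, xt))
    return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))[:, 0]


def _validation_dsc(model, dataset, batch_size, threshold):
    """Volume Dice of thresholded predictions pooled over all val slices."""
    inter = 0.0
    total = 0.0
    n = len(dataset.samples)
    for start in range(0, n, batch_size):
        chunk = dataset.samples[start : start + batch_size]
        xs = np.stack([c[0] for c in chunk])
        xt = np.stack([c[1] for c in chunk])
        y = np.stack([c[2] for c in chunk])
        prob = predict_batch(model, xs, xt)
        pred = prob >= threshold
        inter += float(np.logical_and(pred, y > 0.5).sum())
        total += float(pred.sum() + (y > 0.5).sum())
    return 2.0 * inter / total if total > 0 else 1.0


def train(model, train_set: SliceDataset, val_set: SliceDataset, config: TrainConfig, log_path=None):
    """Optimize ``model`` and return (best_state, history).

    The checkpoint with the best validation Dice is kept; history is a list
    of per-epoch records (loss, val DSC, wall time) that is also written as
    JSON lines when ``log_path`` is given.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best = {"val_dsc": -1.0, "state": model.state_dict(), "epoch": -1}
    history = []
    stale = 0
    for epoch in range(config.max_epochs):
        model.train()
        t0 = time.time()
        losses = []
        for step, (xs, xt, y) in enumerate(
            train_set.batches(config.batch_size, rng, config.augment_flips)
        ):
            if config.max_steps_per_epoch and step >= config.max_steps_per_epoch:
                break
            w = (
                pos_weight_from_batch(y, config.pos_weight_cap)
                if config.pos_weight_policy == "batch"
                else 1.0
            )
            opt.zero_grad()
            loss = bce_with_logits(model(*_model_inputs(model, xs, xt)), y, w)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "loss": float(np.mean(losses)), "seconds": time.time() - t0}
        if epoch % config.val_every == 0 or epoch == config.max_epochs - 1:
            record["val_dsc"] = _validation_dsc(
                model, val_set, config.batch_size, config.threshold
            )
            if record["val_dsc"] > best["val_dsc"]:
                best = {"val_dsc": record["val_dsc"], "state": model.state_dict(), "epoch": epoch}
                stale = 0
            else:
                stale += 1
        history.append(record)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if stale >= config.patience:
            break
    model.load_state_dict(best["state"])
    model.eval()
    return best, history
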