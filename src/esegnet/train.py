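"""Training loop: AdamW on the compound Dice + cross-entropy loss, with
manifest-driven datasets, optional flip augmentation, checkpointing and
resume."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import io as eio
from .config import ModelConfig, TrainConfig, build_model
from .inference import predict_image, predict_volume
from .losses import CombinedLoss
from .metrics import dsc
from .nn import AdamW
from .phantoms import load_manifest

__all__ = ["load_dataset", "Trainer", "save_checkpoint", "load_checkpoint",
           "foreground_dsc"]


def load_dataset(manifest_path, num_classes: Optional[int] = None):
    """Load every sample referenced by a dataset manifest into memory.

    Returns ``(samples, split)`` where each sample is a dict with
    channel-first float image, integer mask and spacing.  Masks carrying
    labels outside ``range(num_classes)`` are rejected here.
    """
    manifest, root, spec = load_manifest(manifest_path)
    samples = {}
    for entry in manifest["samples"]:
        if spec.dim == 2:
            s = eio.read_sample_2d(root / entry["image"], root / entry["mask"])
            img, mask, spacing = s.image, s.mask, s.spacing[:2]
        else:
            img, spacing = eio.read_volume(root / entry["image"])
            mask, _ = eio.read_volume(root / entry["mask"])
            mask = mask.astype(np.uint8)
        if num_classes is not None and int(mask.max()) >= num_classes:
            raise ValueError(
                f"{entry['id']}: mask label {int(mask.max())} is out of range "
                f"for {num_classes} classes")
        if img.ndim == spec.dim:
            img = img[None]
        samples[entry["id"]] = {"image": img.astype(np.float32),
                                "mask": np.asarray(mask), "spacing": spacing}
    return samples, manifest["split"], spec


def foreground_dsc(pred, gt) -> float:
    """Mean Dice over the foreground classes present in the reference."""
    classes = [c for c in np.unique(gt) if c != 0]
    if not classes:
        return float("nan")
    return float(np.mean([dsc(pred, gt, c) for c in classes]))


def save_checkpoint(path, model, cfg: TrainConfig, *, optimizer=None,
                    epoch=0, extra=None) -> None:
    """Self-describing checkpoint: weights + buffers + optimizer moments +
    the full train config as embedded JSON."""
    payload = {"state:" + k: v for k, v in model.state_dict().items()}
    if optimizer is not None:
        payload["opt:t"] = np.array(optimizer.t)
        for i, m in enumerate(optimizer.m):
            payload[f"opt:m{i}"] = m
        for i, v in enumerate(optimizer.v):
            payload[f"opt:v{i}"] = v
    meta = {"config": asdict(cfg), "epoch": int(epoch)}
    if extra:
        meta.update(extra)
    payload["meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Rebuild (model, train_config, meta, raw_npz) from a checkpoint."""
    with np.load(path) as z:
        data = {k: z[k] for k in z.files}
    meta = json.loads(bytes(data.pop("meta")).decode())
    cfg = TrainConfig(**meta["config"])
    model = build_model(cfg.model)
    model.load_state_dict({k[len("state:"):]: v for k, v in data.items()
                           if k.startswith("state:")})
    return model, cfg, meta, data


class Trainer:
    """Optimizes the compound loss over a manifest dataset."""

    def __init__(self, cfg: TrainConfig, manifest_path, log_path=None):
        self.cfg = cfg
        self.samples, self.split, self.spec = load_dataset(
            manifest_path, cfg.model.num_classes)
        self.model = build_model(cfg.model)
        self.optimizer = AdamW(self.model.parameters(), lr=cfg.lr,
                               weight_decay=cfg.weight_decay)
        w_dice, w_ce = cfg.model.resolved_loss_weights
        self.loss_fn = CombinedLoss(w_dice, w_ce, dim=cfg.model.dim)
        self.rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.history: List[dict] = []
        self.epoch = 0
        self.steps = 0
        self.best_val = -np.inf
        self.log_path = Path(log_path) if log_path else None

    # -- data --------------------------------------------------------------
    def _train_ids(self):
        return self.split["train"]

    def _epoch_batches(self):
        cfg = self.cfg
        dim = cfg.model.dim
        ids = list(self._train_ids())
        if dim == 2 or cfg.patch_size is None:
            self.rng.shuffle(ids)
            for i in range(0, len(ids), cfg.batch_size):
                chunk = ids[i:i + cfg.batch_size]
                xs = [self.samples[j]["image"] for j in chunk]
                ys = [self.samples[j]["mask"] for j in chunk]
                yield np.stack(xs), np.stack(ys)
        else:
            pairs = []
            for _ in range(cfg.patches_per_epoch):
                sid = ids[self.rng.integers(len(ids))]
                s = self.samples[sid]
                seed = int(self.rng.integers(2 ** 31))
                (img, msk, _), = eio.sample_patches(
                    s["image"][0], s["mask"], cfg.patch_size, 1, seed,
                    cfg.fg_bias)
                pairs.append((img[None], msk))
            for i in range(0, len(pairs), cfg.batch_size):
                chunk = pairs[i:i + cfg.batch_size]
                yield (np.stack([c[0] for c in chunk]),
                       np.stack([c[1] for c in chunk]))

    def _augment(self, x, y):
        if not self.cfg.augment_flips:
            return x, y
        for axis in range(self.cfg.model.dim):
            if self.rng.uniform() < 0.5:
                x = np.flip(x, axis=2 + axis)
                y = np.flip(y, axis=1 + axis)
        return np.ascontiguousarray(x), np.ascontiguousarray(y)

    # -- evaluation --------------------------------------------------------
    def _mean_dsc(self, ids) -> float:
        vals = []
        for sid in ids:
            s = self.samples[sid]
            if self.cfg.model.dim == 2:
                pred = predict_image(self.model, s["image"][0])
            else:
                pred = predict_volume(self.model, s["image"][0],
                                      self.cfg.patch_size)
            vals.append(foreground_dsc(pred, s["mask"]))
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def train_dsc(self) -> float:
        return self._mean_dsc(self._train_ids())

    def val_dsc(self) -> float:
        ids = self.split.get("val") or self._train_ids()
        return self._mean_dsc(ids)

    # -- loop --------------------------------------------------------------
    def fit(self, ckpt_dir=None) -> dict:
        cfg = self.cfg
        ckpt_dir = Path(ckpt_dir) if ckpt_dir else None
        if ckpt_dir:
            ckpt_dir.mkdir(parents=True, exist_ok=True)
        self.model.train()
        stopped = False
        while self.epoch < cfg.epochs and not stopped:
            losses = []
            for x, y in self._epoch_batches():
                if cfg.max_steps is not None and self.steps >= cfg.max_steps:
                    stopped = True
                    break
                x, y = self._augment(x, y)
                logits = self.model(x)
                loss, grad, parts = self.loss_fn(logits, y)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss {loss} at step {self.steps} "
                        f"(dice={parts[0]:.4g}, ce={parts[1]:.4g})")
                self.optimizer.zero_grad()
                self.model.backward(grad)
                self.optimizer.step()
                self.steps += 1
                losses.append(loss)
            self.epoch += 1
            rec = {"epoch": self.epoch, "steps": self.steps,
                   "loss": float(np.mean(losses)) if losses else None}
            if self.epoch % cfg.eval_every == 0 or stopped \
                    or self.epoch == cfg.epochs:
                tdsc = self.train_dsc()
                rec["train_dsc"] = tdsc
                vdsc = self.val_dsc()
                rec["val_dsc"] = vdsc
                if ckpt_dir and vdsc >= self.best_val:
                    self.best_val = vdsc
                    save_checkpoint(ckpt_dir / "best.npz", self.model, cfg,
                                    optimizer=self.optimizer,
                                    epoch=self.epoch,
                                    extra={"val_dsc": vdsc})
                if (cfg.stop_train_dsc is not None
                        and tdsc >= cfg.stop_train_dsc):
                    stopped = True
            self.history.append(rec)
            if self.log_path:
                with open(self.log_path, "a") as fh:
                    fh.write(json.dumps(rec) + "\n")
        if ckpt_dir:
            save_checkpoint(ckpt_dir / "last.npz", self.model, cfg,
                            optimizer=self.optimizer, epoch=self.epoch)
        return {"epochs": self.epoch, "steps": self.steps,
                "history": self.history,
                "train_dsc": self.train_dsc()}

    def resume(self, ckpt_path) -> None:
        """Restore model weights, optimizer moments and epoch counter."""
        model, cfg, meta, data = load_checkpoint(ckpt_path)
        self.model.load_state_dict(model.state_dict())
        if "opt:t" in data:
            self.optimizer.load_state_dict({
                "t": int(data["opt:t"]),
                "m": [data[f"opt:m{i}"]
                      for i in range(len(self.optimizer.m))],
                "v": [data[f"opt:v{i}"]
                      for i in range(len(self.optimizer.v))]})
        self.epoch = meta["epoch"]
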