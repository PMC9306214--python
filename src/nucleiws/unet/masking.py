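"""Training and patch-wise inference of the mask/seed U-Nets.

A volume is processed in patches with the model's input shape: single
slices for the 2D variant, 24-slice windows for the 3D one.  Training
windows slide with a 12-slice overlap and are zero-filled where they cross
the stack boundary; inference tiles are non-overlapping except that the
final tile is shifted back to fit, and overlapping probabilities are
averaged.  Every input patch is min-max normalised to [0, 1] on its own.

Predicted masks are thresholded at 0.5 (ties count as foreground).  Seed
probabilities are first multiplied voxel-wise with the mask probability --
so seeds can never leave the mask -- and then thresholded at the lower 0.3,
which compensates for the multiplication and keeps small seeds alive.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from ..volume_core import BinaryMask, LabelVolume, VolumeStack
from .arch import (TrainConfig, Variant, build_network, build_unet,
                   lr_at_epoch)
from .engine import Adam, SigmoidBCE, UNetGraph

MASK_THRESHOLD = 0.5
SEED_THRESHOLD = 0.3

__all__ = ["extract_patches", "make_weight_map", "train_model",
           "predict_masks", "UNetMasker"]


def _normalise(patch: np.ndarray) -> np.ndarray:
    lo, hi = float(patch.min()), float(patch.max())
    if hi <= lo:
        return np.zeros_like(patch, dtype=np.float32)
    return ((patch - lo) / (hi - lo)).astype(np.float32)


def _window(vol: np.ndarray, z0: int, depth: int) -> np.ndarray:
    """Depth-sized z window starting at z0, zero-filled past the stack end."""
    Z = vol.shape[0]
    out = np.zeros((depth,) + vol.shape[1:], dtype=np.float32)
    hi = min(z0 + depth, Z)
    out[: hi - z0] = vol[z0:hi]
    return out


def train_offsets(Z: int, depth: int, stride: Optional[int] = None) -> List[int]:
    """Sliding-window starts: begin at 0, advance by ``stride`` while the
    previous window does not yet reach the end."""
    stride = stride or depth // 2
    offs = [0]
    while offs[-1] + depth < Z:
        offs.append(offs[-1] + stride)
    return offs


def infer_offsets(Z: int, depth: int) -> List[int]:
    """Non-overlapping tiles; the final tile is shifted back to fit."""
    if Z <= depth:
        return [0]
    offs = list(range(0, Z - depth + 1, depth))
    if offs[-1] + depth < Z:
        offs.append(Z - depth)
    return offs


def extract_patches(vs: VolumeStack, variant: Variant, mode: str = "infer",
                    patch_depth: int = 24) -> Tuple[np.ndarray, List[int]]:
    """Normalised patches plus their z offsets (the tiling plan).

    2D: one patch per slice in both modes.  3D: ``patch_depth`` z windows,
    overlapping train windows / shifted-back inference tiles as above.
    """
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    vol = vs.voxels
    Z, Y, X = vol.shape
    if Y % 16 or X % 16:
        raise ValueError(f"slice size {Y}x{X} must be divisible by 16 "
                         "(four 2x2 poolings)")
    if variant == "2D":
        offs = list(range(Z))
        patches = np.stack([_normalise(vol[z]) for z in offs])
    else:
        offs = (train_offsets if mode == "train" else infer_offsets)(Z, patch_depth)
        patches = np.stack([_normalise(_window(vol, z0, patch_depth))
                            for z0 in offs])
    return patches, offs


def make_weight_map(gt_expanded: LabelVolume, w0: float = 10.0,
                    sigma: float = 5.0) -> np.ndarray:
    """Per-voxel loss weights emphasising gaps between neighbouring nuclei.

    Class term: 3 on nucleus voxels, 1 on background.  Boundary term, added
    on background voxels when at least two nuclei exist:
    ``w0 * exp(-(d1 + d2)^2 / (2 sigma^2))`` with d1, d2 the distances to
    the nearest and second-nearest nucleus on the spacing-normalised grid.
    """
    labels = gt_expanded.labels
    w = np.where(labels > 0, 3.0, 1.0)
    ids = gt_expanded.label_ids()
    if ids.size >= 2:
        sampling = (gt_expanded.z_anisotropy, 1.0, 1.0)
        d1 = np.full(labels.shape, np.inf)
        d2 = np.full(labels.shape, np.inf)
        for lab in ids:
            d = ndimage.distance_transform_edt(labels != lab, sampling=sampling)
            closer = d < d1
            d2 = np.where(closer, d1, np.minimum(d2, d))
            d1 = np.where(closer, d, d1)
        bg = labels == 0
        w[bg] += w0 * np.exp(-((d1[bg] + d2[bg]) ** 2) / (2.0 * sigma ** 2))
    return w.astype(np.float32)


def _rotate_patch(patch: np.ndarray, angle: float, order: int) -> np.ndarray:
    """Axial rotation about z: bilinear for intensities, nearest for targets."""
    axes = (1, 2) if patch.ndim == 3 else (0, 1)
    return ndimage.rotate(patch, angle, axes=axes, reshape=False, order=order,
                          mode="constant", cval=0.0, prefilter=False)


def _augment(x: np.ndarray, t: np.ndarray, w: Optional[np.ndarray],
             rng: np.random.Generator, cfg: TrainConfig):
    if rng.random() < cfg.rotation_fraction:
        angle = rng.uniform(0.0, 360.0)
        x = _rotate_patch(x, angle, order=1)
        t = _rotate_patch(t, angle, order=0)
        if w is not None:
            w = _rotate_patch(w, angle, order=0)
    if rng.random() < cfg.mirror_fraction:
        x = x[..., ::-1].copy()
        t = t[..., ::-1].copy()
        if w is not None:
            w = w[..., ::-1].copy()
    return x, t, w


def _forward_loss(net: UNetGraph, loss: SigmoidBCE, xb, tb, wb):
    logits = net.forward(xb[..., None])
    return logits, loss.forward(logits[..., 0], tb, wb)


def train_model(variant: Variant, train_data: Sequence[Tuple[VolumeStack, np.ndarray]],
                val_data: Tuple[VolumeStack, np.ndarray],
                cfg: TrainConfig = TrainConfig(), patch_depth: int = 24,
                weight_maps: Optional[Sequence[np.ndarray]] = None,
                net: Optional[UNetGraph] = None):
    """Train one U-Net; returns (net with best-validation weights, history).

    ``train_data`` pairs an expanded intensity stack with a binary target
    volume of the same shape; ``weight_maps`` optionally aligns per-voxel
    loss weights with the training volumes.  The checkpoint kept is the one
    with the lowest validation loss.  Reproducible for a fixed ``cfg.seed``.
    """
    if not train_data:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    net = net or build_network(variant, seed=int(rng.integers(2 ** 31)))
    loss = SigmoidBCE()
    opt = Adam(net.params())

    xs: List[np.ndarray] = []
    ts: List[np.ndarray] = []
    ws: List[Optional[np.ndarray]] = []
    for i, (vs, target) in enumerate(train_data):
        if target.shape != vs.voxels.shape:
            raise ValueError("target/volume shape mismatch")
        patches, offs = extract_patches(vs, variant, "train", patch_depth)
        for patch, z0 in zip(patches, offs):
            xs.append(patch)
            if variant == "2D":
                ts.append(target[z0].astype(np.float32))
                if weight_maps is not None:
                    ws.append(weight_maps[i][z0].astype(np.float32))
            else:
                ts.append(_window(target.astype(np.float32), z0, patch_depth))
                if weight_maps is not None:
                    ws.append(_window(weight_maps[i].astype(np.float32), z0,
                                      patch_depth))
    if weight_maps is None:
        ws = [None] * len(xs)

    vvs, vtarget = val_data
    vx, voffs = extract_patches(vvs, variant, "train", patch_depth)
    if variant == "2D":
        vt = np.stack([vtarget[z].astype(np.float32) for z in voffs])
    else:
        vt = np.stack([_window(vtarget.astype(np.float32), z, patch_depth)
                       for z in voffs])

    history: Dict[str, list] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    n = len(xs)
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(epoch, cfg.initial_lr)
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            trip = [_augment(xs[i], ts[i], ws[i], rng, cfg) for i in idx]
            xb = np.stack([a for a, _, _ in trip])
            tb = np.stack([b for _, b, _ in trip])
            wb = (np.stack([c for _, _, c in trip])
                  if trip[0][2] is not None else None)
            _, l = _forward_loss(net, loss, xb, tb, wb)
            net.backward(loss.backward()[..., None])
            opt.step(lr)
            ep_loss += l * len(idx)
        val_losses = []
        for i in range(0, len(vx), cfg.batch_size):
            _, vl = _forward_loss(net, loss, vx[i:i + cfg.batch_size],
                                  vt[i:i + cfg.batch_size], None)
            val_losses.append(vl * len(vx[i:i + cfg.batch_size]))
        val_loss = float(np.sum(val_losses) / len(vx))
        history["train_loss"].append(ep_loss / n)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
    net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return net, history


def predict_proba_volume(net: UNetGraph, vs: VolumeStack, variant: Variant,
                         patch_depth: int = 24, batch_size: int = 4) -> np.ndarray:
    """Tile the volume, run the network, average overlapping probabilities."""
    Z = vs.shape[0]
    patches, offs = extract_patches(vs, variant, "infer", patch_depth)
    if variant == "2D":
        prob = np.empty(vs.shape, dtype=np.float32)
        for i in range(0, len(patches), batch_size):
            logits = net.forward(patches[i:i + batch_size][..., None])
            prob[offs[i]:offs[i] + logits.shape[0]] = \
                SigmoidBCE.probabilities(logits[..., 0])
        return prob
    acc = np.zeros(vs.shape, dtype=np.float64)
    cnt = np.zeros(vs.shape, dtype=np.float64)
    for patch, z0 in zip(patches, offs):
        logits = net.forward(patch[None, ..., None])
        p = SigmoidBCE.probabilities(logits[0, ..., 0])
        hi = min(z0 + patch_depth, Z)
        acc[z0:hi] += p[: hi - z0]
        cnt[z0:hi] += 1.0
    return (acc / cnt).astype(np.float32)


class UNetMasker(BaseEstimator):
    """Scikit-learn style estimator wrapping one mask- or seed-predicting U-Net.

    ``fit`` takes lists of expanded intensity stacks and matching binary
    target volumes; ``predict`` returns a thresholded :class:`BinaryMask`
    and ``predict_proba`` the raw probability volume.
    """

    def __init__(self, variant: Variant = "3D", target_kind: str = "M3D",
                 epochs: int = 200, batch_size: Optional[int] = None,
                 initial_lr: float = 1e-3, rotation_fraction: float = 0.67,
                 mirror_fraction: float = 0.50, boundary_weighting: bool = False,
                 w0: float = 10.0, sigma: float = 5.0, patch_depth: int = 24,
                 seed: int = 0):
        self.variant = variant
        self.target_kind = target_kind
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.rotation_fraction = rotation_fraction
        self.mirror_fraction = mirror_fraction
        self.boundary_weighting = boundary_weighting
        self.w0 = w0
        self.sigma = sigma
        self.patch_depth = patch_depth
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        batch = self.batch_size or (16 if self.variant == "2D" else 4)
        return TrainConfig(epochs=self.epochs, batch_size=batch,
                           initial_lr=self.initial_lr,
                           rotation_fraction=self.rotation_fraction,
                           mirror_fraction=self.mirror_fraction,
                           boundary_weighting=self.boundary_weighting,
                           w0=self.w0, sigma=self.sigma, seed=self.seed)

    def fit(self, X: Sequence[VolumeStack], y: Sequence[BinaryMask],
            X_val: Optional[VolumeStack] = None,
            y_val: Optional[BinaryMask] = None,
            gt_for_weights: Optional[Sequence[LabelVolume]] = None):
        if len(X) == 0 or len(X) != len(y):
            raise ValueError("need matching, non-empty volume and target lists")
        X_val = X_val if X_val is not None else X[0]
        y_val = y_val if y_val is not None else y[0]
        weight_maps = None
        if self.boundary_weighting:
            if gt_for_weights is None:
                raise ValueError("boundary weighting needs instance ground truths")
            weight_maps = [make_weight_map(g, self.w0, self.sigma)
                           for g in gt_for_weights]
        data = [(vs, m.voxels.astype(np.float32)) for vs, m in zip(X, y)]
        self.spec_ = build_unet(self.variant, self.target_kind)  # type: ignore[arg-type]
        self.net_, self.history_ = train_model(
            self.variant, data, (X_val, y_val.voxels.astype(np.float32)),
            self._train_config(), patch_depth=self.patch_depth,
            weight_maps=weight_maps)
        self.best_epoch_ = self.history_["best_epoch"]
        return self

    def predict_proba(self, vs: VolumeStack) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("UNetMasker is not fitted")
        return predict_proba_volume(self.net_, vs, self.variant, self.patch_depth)

    def predict(self, vs: VolumeStack) -> BinaryMask:
        prob = self.predict_proba(vs)
        return BinaryMask(prob >= MASK_THRESHOLD, self.target_kind, vs.spacing,
                          space=vs.space, expansion_factor=vs.expansion_factor)


def save_model(model: UNetMasker, path) -> None:
    """Backend-agnostic serialisation: hyperparameters (JSON) + weights (npz)."""
    import json
    from pathlib import Path
    path = Path(path)
    if not hasattr(model, "net_"):
        raise RuntimeError("cannot save an unfitted model")
    weights = model.net_.get_weights()
    np.savez_compressed(path.with_suffix(".npz"),
                        **{f"w{i}": w for i, w in enumerate(weights)})
    path.with_suffix(".json").write_text(json.dumps(model.get_params()))


def load_model(path) -> UNetMasker:
    import json
    from pathlib import Path
    path = Path(path)
    params = json.loads(path.with_suffix(".json").read_text())
    model = UNetMasker(**params)
    data = np.load(path.with_suffix(".npz"))
    weights = [data[f"w{i}"] for i in range(len(data.files))]
    model.net_ = build_network(model.variant)
    model.net_.set_weights(weights)
    model.spec_ = build_unet(model.variant, model.target_kind)
    model.history_ = {}
    return model


def predict_masks(vs: VolumeStack, mask_model: UNetMasker,
                  seed_model: Optional[UNetMasker] = None
                  ) -> Tuple[BinaryMask, Optional[BinaryMask]]:
    """Joint mask/seed prediction with the mask-multiplication contract.

    The seed probability is multiplied voxel-wise by the mask probability
    before thresholding at 0.3, so returned seeds are a subset of the mask.
    """
    prob_m = mask_model.predict_proba(vs)
    kind = mask_model.target_kind if mask_model.target_kind != "seeds" else "M3D"
    mask = BinaryMask(prob_m >= MASK_THRESHOLD, kind, vs.spacing,
                      space=vs.space, expansion_factor=vs.expansion_factor)
    if seed_model is None:
        return mask, None
    prob_s = seed_model.predict_proba(vs) * prob_m
    seeds = BinaryMask((prob_s >= SEED_THRESHOLD) & mask.voxels, "seeds",
                       vs.spacing, space=vs.space,
                       expansion_factor=vs.expansion_factor)
    return mask, seeds
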