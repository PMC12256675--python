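"""Unsupervised training, model selection and inference for registration.

Training minimizes ``-LNCC(I_F, I_M ∘ φ) + λ · Lsmooth(φ)`` with Adam at
learning rate 1e-4 (batch size one volume pair).  ``folds > 1`` runs k-fold
cross-validation over the training pairs and returns the fold model with the
highest validation score — mean organ DSC when the pairs carry masks,
otherwise the negated validation loss.  ``folds = 1`` fits a single model on
all pairs.  All randomness flows from ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ..grids import DisplacementField, Volume3D
from .losses import lncc_loss, total_loss_with_grad
from .layers import Adam
from .network import CNNBaselineNetwork, MTDIRNetwork
from .warp import warp_array


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published training recipe."""

    learning_rate: float = 1e-4
    max_epochs: int = 400
    batch_size: int = 1
    seed: int = 0
    folds: int = 5
    embed_dim: int = 256
    enc_channels: tuple = (16, 16, 32, 32)
    dec_channels: tuple = (32, 16, 8, 8)
    through_plane_factor: int = 4
    baseline_width: int = 16
    flow_scale: float = 20.0
    field_smooth_voxels: float = 2.0
    lncc_window: int = 9
    lambda_smooth: float = 1.0
    model: str = "mtdir"  # "mtdir" | "cnn"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.folds < 1:
            raise ValueError("invalid training configuration")
        if self.model not in ("mtdir", "cnn"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class RegistrationModel:
    """A trained network plus the metadata needed to reuse it."""

    network: object
    config: TrainConfig
    grid_shape: tuple
    spacing: tuple
    history: list = dc_field(default_factory=list)
    validation_score: float | None = None

    def predict_field(self, fixed: Volume3D, moving: Volume3D) -> DisplacementField:
        if fixed.shape != self.grid_shape or moving.shape != self.grid_shape:
            raise ValueError(
                f"model expects grid {self.grid_shape}, got fixed {fixed.shape} "
                f"and moving {moving.shape}; resample first"
            )
        u = self.network.forward(fixed.data, moving.data)
        return DisplacementField(u, fixed.spacing)


def build_network(grid_shape, config: TrainConfig, rng: np.random.Generator):
    if config.model == "mtdir":
        return MTDIRNetwork(
            grid_shape,
            embed_dim=config.embed_dim,
            enc_channels=tuple(config.enc_channels),
            dec_channels=tuple(config.dec_channels),
            through_plane_factor=config.through_plane_factor,
            flow_scale=config.flow_scale,
            field_smooth_voxels=config.field_smooth_voxels,
            rng=rng,
        )
    return CNNBaselineNetwork(
        grid_shape,
        width=config.baseline_width,
        flow_scale=config.flow_scale,
        field_smooth_voxels=config.field_smooth_voxels,
        rng=rng,
    )


def _pair_arrays(pair):
    """Accept PairSample-like objects or (fixed, moving) tuples."""
    if hasattr(pair, "fixed") and hasattr(pair, "moving"):
        return pair.fixed, pair.moving
    fixed, moving = pair[0], pair[1]
    return fixed, moving


def _pair_masks(pair):
    fm = getattr(pair, "fixed_masks", None)
    mm = getattr(pair, "moving_masks", None)
    if fm and mm:
        return fm, mm
    return None


def _validation_score(model: RegistrationModel, pairs, lncc_window: int) -> float:
    """Mean organ DSC over validation pairs; -loss when masks are absent."""
    dscs, losses = [], []
    for pair in pairs:
        fixed, moving = _pair_arrays(pair)
        field = model.predict_field(fixed, moving)
        masks = _pair_masks(pair)
        if masks is not None:
            fixed_masks, moving_masks = masks
            for organ, fmask in fixed_masks.items():
                warped = warp_array(
                    moving_masks[organ].data.astype(np.float64),
                    field.u,
                    fixed.spacing,
                    mode="nearest",
                )
                dscs.append(dsc_arrays(fmask.data, warped > 0.5))
        else:
            warped = warp_array(moving.data, field.u, fixed.spacing)
            losses.append(lncc_loss(fixed.data, warped, n=lncc_window))
    if dscs:
        return float(np.mean(dscs))
    return -float(np.mean(losses))


def dsc_arrays(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("DSC undefined for two empty masks")
    return 2.0 * np.logical_and(a, b).sum() / denom


def _fit(train_pairs, grid_shape, spacing, config: TrainConfig, rng_net, rng_order):
    net = build_network(grid_shape, config, rng_net)
    opt = Adam(net.params(), lr=config.learning_rate)
    history = []
    n = len(train_pairs)
    for epoch in range(config.max_epochs):
        order = rng_order.permutation(n)
        losses = []
        for idx in order:
            fixed, moving = _pair_arrays(train_pairs[idx])
            u = net.forward(fixed.data, moving.data)
            loss, g_u = total_loss_with_grad(
                fixed.data,
                moving.data,
                u,
                spacing,
                lam=config.lambda_smooth,
                n=config.lncc_window,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, pair {idx}"
                )
            opt.zero_grad()
            net.backward(g_u)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return net, history


def train(pairs, config: TrainConfig) -> RegistrationModel:
    """Train a registration model, optionally with k-fold cross-validation."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    fixed0, _ = _pair_arrays(pairs[0])
    grid_shape, spacing = fixed0.shape, fixed0.spacing
    master = np.random.default_rng(config.seed)
    if config.folds == 1:
        net, history = _fit(
            pairs,
            grid_shape,
            spacing,
            config,
            np.random.default_rng(master.integers(2**31)),
            np.random.default_rng(master.integers(2**31)),
        )
        return RegistrationModel(net, config, grid_shape, spacing, history)

    if config.folds > len(pairs):
        raise ValueError(f"{config.folds} folds but only {len(pairs)} pairs")
    perm = master.permutation(len(pairs))
    folds = np.array_split(perm, config.folds)
    best = None
    for fold_idx, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, val_idx)
        net, history = _fit(
            [pairs[i] for i in train_idx],
            grid_shape,
            spacing,
            config,
            np.random.default_rng(master.integers(2**31)),
            np.random.default_rng(master.integers(2**31)),
        )
        model = RegistrationModel(net, config, grid_shape, spacing, history)
        score = _validation_score(model, [pairs[i] for i in val_idx], config.lncc_window)
        model.validation_score = score
        if best is None or score > best.validation_score:
            best = model
    return best


def train_baseline(pairs, config: TrainConfig) -> RegistrationModel:
    """Train the CNN (VoxelMorph-style) comparator with the same recipe."""
    from dataclasses import replace

    return train(pairs, replace(config, model="cnn"))


def register(
    model: RegistrationModel, fixed: Volume3D, moving: Volume3D
) -> tuple[DisplacementField, Volume3D]:
    """Predict the field aligning moving to fixed, and the warped image."""
    field = model.predict_field(fixed, moving)
    warped = Volume3D(
        warp_array(moving.data, field.u, fixed.spacing), fixed.spacing, role="moving"
    )
    return field, warped


def kfold_assignments(n_pairs: int, folds: int, seed: int) -> list[np.ndarray]:
    """Validation indices per fold (each pair in exactly one fold)."""
    perm = np.random.default_rng(seed).permutation(n_pairs)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def save_model(model: RegistrationModel, path) -> None:
    """Serialize weights (npz) with a JSON sidecar holding config and grid."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.network.params())}
    np.savez(path / "weights.npz", **arrays)
    meta = {
        "config": asdict(model.config),
        "grid_shape": list(model.grid_shape),
        "spacing": list(model.spacing),
        "history": model.history,
        "validation_score": model.validation_score,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> RegistrationModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    cfg = meta["config"]
    cfg["enc_channels"] = tuple(cfg["enc_channels"])
    cfg["dec_channels"] = tuple(cfg["dec_channels"])
    config = TrainConfig(**cfg)
    net = build_network(tuple(meta["grid_shape"]), config, np.random.default_rng(0))
    with np.load(path / "weights.npz") as data:
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]
    return RegistrationModel(
        net,
        config,
        tuple(meta["grid_shape"]),
        tuple(meta["spacing"]),
        meta.get("history", []),
        meta.get("validation_score"),
    )
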