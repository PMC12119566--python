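"""Mean-teacher semi-supervised training.

The student network is updated by SGD on
L_sup + L_semi + λ(t)·L_unsup; the teacher is an exponential moving
average of the student and supplies pseudo-labels for unlabeled (and
CutMix-mixed) inputs, seeing its unlabeled inputs under additive Gaussian
noise.  Prediction uses the teacher by default (a flag switches to the
student) with sliding-window patch fusion.

All randomness — patch corners, CutMix draws, teacher noise, parameter
initialization — flows from one seeded generator, so runs are reproducible
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cutmix import apply_mask, sample_box_mask, sample_lambda
from .io import LabelMap, PatchGrid, Volume, extract_patches, read_labelmap, read_volume, recompose
from .losses import LossWeights, supervised_loss, total_loss, unsup_loss
from .network import CBAPVNet, NetworkConfig
from .nn import SGD
from .supervision import build_weightmap

__all__ = [
    "TrainConfig", "TrainState", "ema_update", "training_step", "train",
    "predict_volume", "predict_from_checkpoint", "load_checkpoint",
    "save_checkpoint", "load_items",
]

LOG_COLUMNS = ["iteration", "l_sup", "l_semi", "l_unsup", "lambda", "total"]


@dataclass(frozen=True)
class TrainConfig:
    max_iterations: int = 300
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_poly_power: float = 0.9
    ema_decay: float = 0.95
    noise_sigma: float = 0.1
    patch_shape: tuple[int, int, int] = (16, 16, 16)
    stride: tuple[int, int, int] | None = None
    seed: int = 0
    semi_enabled: bool = True
    cutmix_enabled: bool = True
    cutmix_alpha: float = 1.0
    cutmix_prob: float = 0.5
    decay_weight: float = 0.95
    combine_rule: str = "product"
    source_index: int | str = "middle"
    band_width: int = 1
    ce_dice_ratio: float = 0.5
    epsilon: float = 1e-7
    loss_weights: LossWeights = field(default_factory=LossWeights)
    predict_with_teacher: bool = True

    def validate(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError(f"ema_decay must be in [0, 1), got {self.ema_decay}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class TrainState:
    student: CBAPVNet
    teacher: CBAPVNet
    optimizer: SGD
    rng: np.random.Generator
    iteration: int = 0
    history: list = field(default_factory=list)


# ----------------------------------------------------------------------
# EMA
# ----------------------------------------------------------------------

def _param_arrays(params):
    if hasattr(params, "parameters"):
        return [p.data for p in params.parameters()]
    if isinstance(params, dict):
        return list(params.values())
    return [p.data if hasattr(p, "data") else np.asarray(p) for p in params]


def ema_update(teacher, student, decay: float):
    """θ_teacher ← decay·θ_teacher + (1 − decay)·θ_student, in place.

    Accepts networks, dicts of arrays, or parameter sequences; returns the
    teacher parameters.  Gradients never touch the teacher.
    """
    if not 0.0 <= decay <= 1.0:
        raise ValueError(f"decay must be in [0, 1], got {decay}")
    t_arrays, s_arrays = _param_arrays(teacher), _param_arrays(student)
    if len(t_arrays) != len(s_arrays):
        raise ValueError("teacher and student parameter counts differ")
    for t, s in zip(t_arrays, s_arrays):
        if t.shape != s.shape:
            raise ValueError(f"parameter shape mismatch: {t.shape} vs {s.shape}")
        t *= decay
        t += (1.0 - decay) * s
    return teacher


# ----------------------------------------------------------------------
# data handling
# ----------------------------------------------------------------------

def _zscore(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float32)
    std = data.std()
    return (data - data.mean()) / (std if std > 0 else 1.0)


def load_items(manifest_path, cfg: TrainConfig) -> list[dict]:
    """Load the dataset described by a manifest CSV into memory.

    Volumes are z-score normalized; a multi-view weight map is built per
    volume.  Labels are read only for labeled (and test) items — unlabeled
    rows never contribute label data, whatever their manifest says.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, keep_default_na=False)
    root = manifest_path.parent
    items = []
    for row in table.itertuples():
        volume = read_volume(root / row.volume_path)
        label = None
        if row.split in ("labeled", "test") and row.label_path:
            label = read_labelmap(root / row.label_path).data
        weight = build_weightmap(
            volume.shape,
            decay_weight=cfg.decay_weight,
            combine_rule=cfg.combine_rule,
            source_index=cfg.source_index,
            band_width=cfg.band_width,
        )
        items.append({
            "id": row.id,
            "image": _zscore(volume.data),
            "label": label,
            "weight": weight,
            "split": row.split,
            "spacing": volume.spacing,
        })
    return items


def items_from_arrays(volumes, labels, cfg: TrainConfig) -> list[dict]:
    """Build in-memory training items from arrays (no files involved).

    ``labels`` entries that are None mark unlabeled volumes.
    """
    items = []
    for i, (vol, lab) in enumerate(zip(volumes, labels)):
        data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        weight = build_weightmap(
            data.shape,
            decay_weight=cfg.decay_weight,
            combine_rule=cfg.combine_rule,
            source_index=cfg.source_index,
            band_width=cfg.band_width,
        )
        items.append({
            "id": f"item{i:03d}",
            "image": _zscore(data),
            "label": None if lab is None else np.asarray(
                lab.data if isinstance(lab, LabelMap) else lab
            ).astype(np.uint8),
            "weight": weight,
            "split": "unlabeled" if lab is None else "labeled",
            "spacing": (1.0, 1.0, 1.0),
        })
    return items


def _random_crop(item, patch_shape, rng):
    shape = item["image"].shape
    corner = tuple(int(rng.integers(0, n - p + 1)) for n, p in zip(shape, patch_shape))
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_shape))
    out = {"image": item["image"][sl], "weight": item["weight"][sl]}
    out["label"] = item["label"][sl] if item["label"] is not None else None
    return out


# ----------------------------------------------------------------------
# one optimization step
# ----------------------------------------------------------------------

def _teacher_probs(teacher, x, noise_sigma, rng):
    noisy = x + noise_sigma * rng.standard_normal(x.shape).astype(np.float32)
    pyr = teacher(noisy[None, None])
    return pyr.p_scales[0].data[0]  # (C, *patch), detached


def training_step(state: TrainState, items: list[dict], cfg: TrainConfig) -> TrainState:
    """One SGD step on a batch of one labeled and (if enabled) one
    unlabeled patch, with in-place CutMix replacement, followed by the EMA
    teacher update."""
    rng = state.rng
    t = state.iteration
    labeled = [it for it in items if it["split"] == "labeled"]
    unlabeled = [it for it in items if it["split"] == "unlabeled"]
    if not labeled:
        raise ValueError("training requires at least one labeled item")
    if cfg.semi_enabled and not unlabeled:
        raise ValueError("semi-supervised training requires at least one unlabeled item")

    lab = _random_crop(labeled[int(rng.integers(len(labeled)))], cfg.patch_shape, rng)
    x_l, y_l, w_l = lab["image"], lab["label"], lab["weight"]
    if cfg.cutmix_enabled and rng.random() < cfg.cutmix_prob:
        partner = _random_crop(labeled[int(rng.integers(len(labeled)))], cfg.patch_shape, rng)
        lam = sample_lambda(cfg.cutmix_alpha, rng)
        mask = sample_box_mask(x_l.shape, lam, rng)
        mixed = apply_mask((x_l, y_l), (partner["image"], partner["label"]), mask)
        x_l, y_l = mixed.x_mix, mixed.y_mix
        w_l = np.where(mask.astype(bool), w_l, partner["weight"])

    batch = [x_l]
    pl_u = w_u = None
    if cfg.semi_enabled:
        unl = _random_crop(unlabeled[int(rng.integers(len(unlabeled)))], cfg.patch_shape, rng)
        x_u, w_u = unl["image"], unl["weight"]
        if cfg.cutmix_enabled and rng.random() < cfg.cutmix_prob:
            partner = _random_crop(unlabeled[int(rng.integers(len(unlabeled)))], cfg.patch_shape, rng)
            lam = sample_lambda(cfg.cutmix_alpha, rng)
            mask = sample_box_mask(x_u.shape, lam, rng)
            # pseudo-labels of a mixed input are the teacher's pseudo-labels
            # of the two sources, mixed with the same mask
            pl_a = _teacher_probs(state.teacher, x_u, cfg.noise_sigma, rng).argmax(axis=0)
            pl_b = _teacher_probs(state.teacher, partner["image"], cfg.noise_sigma, rng).argmax(axis=0)
            keep = mask.astype(bool)
            x_u = np.where(keep, x_u, partner["image"])
            pl_u = np.where(keep, pl_a, pl_b).astype(np.uint8)
            w_u = np.where(keep, w_u, partner["weight"])
        else:
            pl_u = _teacher_probs(state.teacher, x_u, cfg.noise_sigma, rng).argmax(axis=0).astype(np.uint8)
        batch.append(x_u)

    x = np.stack(batch)[:, None]  # (N, 1, *patch)
    state.student.zero_grad()
    pyramid = state.student(x)

    l_sup = supervised_loss(pyramid.item(0), y_l, w_l, cfg.ce_dice_ratio, cfg.epsilon)
    if cfg.semi_enabled:
        pyr_u = pyramid.item(1)
        l_semi = supervised_loss(pyr_u, pl_u, w_u, cfg.ce_dice_ratio, cfg.epsilon)
        l_unsup = unsup_loss(pyr_u, cfg.epsilon)
    else:
        l_semi = l_unsup = 0.0
    lam_t = cfg.loss_weights.lambda_at(t)
    loss = total_loss(l_sup, l_semi, l_unsup, t, cfg.loss_weights)

    values = {
        "l_sup": float(l_sup), "l_semi": float(l_semi),
        "l_unsup": float(l_unsup), "total": float(loss),
    }
    for name, v in values.items():
        if not np.isfinite(v):
            raise RuntimeError(f"non-finite loss term {name!r} = {v} at iteration {t}")

    loss.backward()
    state.optimizer.lr = cfg.lr * (1.0 - t / cfg.max_iterations) ** cfg.lr_poly_power
    state.optimizer.step()
    # standard mean-teacher warm-up: early on the teacher tracks the student
    # closely (a plain running average), then settles at the configured decay
    ema_update(state.teacher, state.student, min(1.0 - 1.0 / (t + 1), cfg.ema_decay))
    state.iteration += 1
    state.history.append({"iteration": state.iteration, "l_sup": values["l_sup"],
                          "l_semi": values["l_semi"], "l_unsup": values["l_unsup"],
                          "lambda": lam_t, "total": values["total"]})
    return state


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(path, state: TrainState, net_config: NetworkConfig, cfg: TrainConfig):
    """Weights as .npz plus a JSON sidecar with configs and progress."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, p in state.student.named_parameters():
        arrays[f"student/{name}"] = p.data
    for name, p in state.teacher.named_parameters():
        arrays[f"teacher/{name}"] = p.data
    for i, v in enumerate(state.optimizer._velocity):
        arrays[f"velocity/{i}"] = v
    np.savez(path, **arrays)
    sidecar = {
        "network": net_config.to_dict(),
        "train": _config_to_dict(cfg),
        "iteration": state.iteration,
        "rng_state": state.rng.bit_generator.state,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=int))


def _config_to_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["patch_shape"] = list(d["patch_shape"])
    d["stride"] = list(d["stride"]) if d["stride"] else None
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["patch_shape"] = tuple(d["patch_shape"])
    if d.get("stride"):
        d["stride"] = tuple(d["stride"])
    d["loss_weights"] = LossWeights(**d["loss_weights"])
    return TrainConfig(**d)


def load_checkpoint(path) -> tuple[TrainState, NetworkConfig, TrainConfig]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    net_config = NetworkConfig.from_dict(sidecar["network"])
    cfg = _config_from_dict(sidecar["train"])
    student = CBAPVNet(net_config, seed=cfg.seed)
    teacher = CBAPVNet(net_config, seed=cfg.seed)
    with np.load(path) as data:
        student.load_state_dict(
            {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("student/")}
        )
        teacher.load_state_dict(
            {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("teacher/")}
        )
        velocity = [data[f"velocity/{i}"].copy()
                    for i in range(len([k for k in data.files if k.startswith("velocity/")]))]
    optimizer = SGD(student.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                    weight_decay=cfg.weight_decay)
    optimizer._velocity = velocity
    rng = np.random.default_rng(cfg.seed)
    rng.bit_generator.state = sidecar["rng_state"]
    state = TrainState(student=student, teacher=teacher, optimizer=optimizer,
                       rng=rng, iteration=int(sidecar["iteration"]))
    return state, net_config, cfg


# ----------------------------------------------------------------------
# full runs
# ----------------------------------------------------------------------

def train(
    manifest_path,
    cfg: TrainConfig,
    net_config: NetworkConfig,
    workdir,
    resume_from=None,
) -> tuple[TrainState, Path, Path]:
    """Run the loop to ``cfg.max_iterations``; write the training log CSV
    and a checkpoint holding both student and teacher.  Returns
    (state, checkpoint path, log path)."""
    cfg.validate()
    net_config.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    items = load_items(manifest_path, cfg)

    if resume_from is not None:
        # weights, optimizer state, progress and rng come from the
        # checkpoint; the caller's cfg governs the continued run (e.g. a
        # larger max_iterations)
        state, net_config, _ = load_checkpoint(resume_from)
        log_path = workdir / "training_log.csv"
        if log_path.exists():
            state.history = pd.read_csv(log_path).to_dict("records")
    else:
        student = CBAPVNet(net_config, seed=cfg.seed)
        teacher = CBAPVNet(net_config, seed=cfg.seed)
        teacher.load_state_dict(student.state_dict())
        optimizer = SGD(student.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                        weight_decay=cfg.weight_decay)
        state = TrainState(student=student, teacher=teacher, optimizer=optimizer,
                           rng=np.random.default_rng(cfg.seed))

    while state.iteration < cfg.max_iterations:
        training_step(state, items, cfg)

    log_path = workdir / "training_log.csv"
    pd.DataFrame(state.history, columns=LOG_COLUMNS).to_csv(log_path, index=False)
    ckpt_path = workdir / "checkpoint.npz"
    save_checkpoint(ckpt_path, state, net_config, cfg)
    return state, ckpt_path, log_path


def predict_volume(
    net: CBAPVNet,
    volume: Volume,
    patch_shape,
    stride=None,
) -> LabelMap:
    """Sliding-window inference: extract patches, forward the network's
    full-resolution head, fuse overlapping probabilities by mean, argmax."""
    data = _zscore(volume.data)
    grid = PatchGrid.build(data.shape, patch_shape, stride)
    probs = []
    for patch in extract_patches(data, grid):
        pyr = net(patch[None, None])
        probs.append(pyr.p_scales[0].data[0])
    fused = recompose(probs, grid, data.shape)
    return LabelMap(data=fused.argmax(axis=0).astype(np.uint8),
                    num_classes=net.config.num_classes)


def predict_from_checkpoint(checkpoint_path, volume: Volume, stride=None,
                            use_teacher: bool | None = None) -> LabelMap:
    state, net_config, cfg = load_checkpoint(checkpoint_path)
    if use_teacher is None:
        use_teacher = cfg.predict_with_teacher
    net = state.teacher if use_teacher else state.student
    return predict_volume(net, volume, cfg.patch_shape, stride or cfg.stride)
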