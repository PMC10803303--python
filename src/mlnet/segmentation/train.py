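"""Training, inference and cross-validation for the miniature segmenter."""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..evalstats import dice
from ..nn import Adam, Tensor
from ..phantom.types import BinaryMask, VolumeImage
from .supervision import deep_supervision_loss, downsample_targets
from .types import FeaturePyramid, SegTrainLog, UNetConfig
from .unet import UNet3D, build_unet

__all__ = [
    "case_input",
    "train_segmenter",
    "predict_mask",
    "extract_features",
    "crossval_segmentation",
    "CrossvalResult",
    "save_checkpoint",
    "load_checkpoint",
]


def case_input(image: VolumeImage, input_channels: int) -> np.ndarray:
    """Per-volume z-score normalisation of the first ``input_channels``
    channels (the fixed preprocessing of the pipeline)."""
    if image.data.shape[0] < input_channels:
        raise ValueError(
            f"volume has {image.data.shape[0]} channels, need {input_channels}"
        )
    x = image.data[:input_channels].astype(np.float32)
    out = np.empty_like(x)
    for c in range(x.shape[0]):
        v = x[c]
        sd = v.std()
        out[c] = (v - v.mean()) / (sd if sd > 1e-8 else 1.0)
    return out


def _batch_targets(cases, n_stages):
    per_stage = [[] for _ in range(n_stages)]
    for case in cases:
        for s, t in enumerate(downsample_targets(case.mask, n_stages)):
            per_stage[s].append(t[None])  # channel axis
    return [np.stack(ts) for ts in per_stage]


def train_segmenter(cases, config: UNetConfig, epochs: int, val_cases,
                    batch_size: int = 4, lr: float = 3e-3) -> tuple[UNet3D, SegTrainLog]:
    """Train with deep supervision; checkpoint = best validation Dice epoch."""
    if not cases:
        raise ValueError("empty training set")
    if not val_cases:
        raise ValueError("empty validation set")
    model = build_unet(config)
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(config.seed + 1)
    log = SegTrainLog()
    best_dice, best_state = -1.0, None

    inputs = [case_input(c.image, config.input_channels) for c in cases]
    S = config.n_stages
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(cases))
        total, nb = 0.0, 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            x = Tensor(np.stack([inputs[j] for j in idx]))
            targets = _batch_targets([cases[j] for j in idx], S)
            logits, _ = model(x)
            loss = deep_supervision_loss(logits, targets, config.ds_weights)
            model.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1
        val_dice = float(
            np.mean([dice(predict_mask(model, c.image), c.mask) for c in val_cases])
        )
        log.epochs.append({"epoch": epoch, "train_loss": total / nb, "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = copy.deepcopy(model.state_dict())
            log.checkpoint_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def predict_mask(model: UNet3D, volume: VolumeImage) -> BinaryMask:
    """Binary mask at foreground probability >= 0.5 on the input grid."""
    x = Tensor(case_input(volume, model.config.input_channels)[None])
    logits, _ = model(x)
    pred = (logits[0].data[0, 0] >= 0.0).astype(np.uint8)  # sigmoid(z) >= .5 <=> z >= 0
    return BinaryMask(pred, volume.spacing)


def extract_features(model: UNet3D, volume: VolumeImage) -> FeaturePyramid:
    """Decoder feature volumes (deep-supervision path), stage 1 finest."""
    x = Tensor(case_input(volume, model.config.input_channels)[None])
    _, features = model(x)
    return FeaturePyramid(stages=[f.data[0].copy() for f in features])


@dataclass
class CrossvalResult:
    fold_dices: list[list[float]]
    per_case: dict[str, float] = field(default_factory=dict)
    assignments: dict[str, int] = field(default_factory=dict)

    @property
    def all_dices(self) -> list[float]:
        return [d for fold in self.fold_dices for d in fold]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.all_dices))

    @property
    def std_dice(self) -> float:
        return float(np.std(self.all_dices))

    @property
    def fold_means(self) -> list[float]:
        return [float(np.mean(f)) for f in self.fold_dices]


def crossval_segmentation(cohort, config: UNetConfig, k: int = 4, epochs: int = 10,
                          batch_size: int = 4, lr: float = 3e-3) -> CrossvalResult:
    """k-fold CV: every case is validated exactly once; fold sizes differ by
    at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError("cohort smaller than k")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(cohort))
    folds = np.array_split(perm, k)
    result = CrossvalResult(fold_dices=[])
    for fi, fold in enumerate(folds):
        fold_set = set(int(j) for j in fold)
        train = [cohort[j] for j in range(len(cohort)) if j not in fold_set]
        val = [cohort[int(j)] for j in fold]
        fold_config = copy.deepcopy(config)
        fold_config.seed = config.seed + fi
        model, _ = train_segmenter(train, fold_config, epochs=epochs,
                                   val_cases=val, batch_size=batch_size, lr=lr)
        dices = []
        for case in val:
            d = dice(predict_mask(model, case.image), case.mask)
            dices.append(float(d))
            result.per_case[case.patient_id] = float(d)
            result.assignments[case.patient_id] = fi
        result.fold_dices.append(dices)
    return result


def save_checkpoint(model: UNet3D, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    cfg = model.config
    meta = {
        "n_stages": cfg.n_stages,
        "base_channels": cfg.base_channels,
        "input_channels": cfg.input_channels,
        "convs_per_stage": cfg.convs_per_stage,
        "ds_weights": list(cfg.ds_weights),
        "seed": cfg.seed,
    }
    np.savez(path, __config__=json.dumps(meta), **state)


def load_checkpoint(path) -> UNet3D:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files if k != "__config__"}
    config = UNetConfig(
        n_stages=int(meta["n_stages"]),
        base_channels=int(meta["base_channels"]),
        input_channels=int(meta["input_channels"]),
        convs_per_stage=int(meta["convs_per_stage"]),
        ds_weights=tuple(meta["ds_weights"]),
        seed=int(meta["seed"]),
    )
    model = build_unet(config)
    model.load_state_dict(state)
    return model
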