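"""Classifier training loop: weighted BCE, Adam wrapped in SAM, early
stopping on internal-validation loss."""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from ..nn import SAM, Adam, Tensor, bce_with_logits
from ..segmentation.train import case_input
from .config import VARIANTS, ClassifierConfig, ClsTrainLog
from .resnet import Classifier3D, build_classifier, prepare_injection
from .scores import ScoreSet

__all__ = ["train_classifier", "predict_scores", "run_ablation", "AblationScores"]


def _label(case, task: str) -> int:
    return case.emvi_label if task == "emvi" else case.cr_label


def _prepare(model: Classifier3D, cases, pyramids, task: str):
    """Per-case inputs, injected feature dicts and labels."""
    xs, feats, ys = [], [], []
    need = bool(model.config.injected_stages)
    for case in cases:
        xs.append(case_input(case.image, model.config.input_channels))
        if need:
            if pyramids is None or case.patient_id not in pyramids:
                raise ValueError(f"missing feature pyramid for {case.patient_id}")
            feats.append(
                prepare_injection(model, pyramids[case.patient_id], xs[-1].shape[1:])
            )
        else:
            feats.append(None)
        ys.append(_label(case, task))
    return xs, feats, np.asarray(ys, dtype=np.float32)


def _batch(xs, feats, idx, injected_stages):
    x = Tensor(np.stack([xs[j] for j in idx]))
    injected = None
    if injected_stages:
        injected = {
            s: np.stack([feats[j][s] for j in idx]) for s in sorted(injected_stages)
        }
    return x, injected


def _epoch_loss(model, xs, feats, ys, idx_all, batch_size, pos_weight):
    total, n = 0.0, 0
    for i in range(0, len(idx_all), batch_size):
        idx = idx_all[i : i + batch_size]
        x, injected = _batch(xs, feats, idx, model.config.injected_stages)
        logits = model(x, injected)
        loss = bce_with_logits(logits, ys[idx], pos_weight)
        total += loss.item() * len(idx)
        n += len(idx)
    return total / n


def train_classifier(train_cases, internal_val_cases, pyramids,
                     config: ClassifierConfig, task: str = "emvi",
                     pyramid_channel_spec: dict[int, int] | None = None
                     ) -> tuple[Classifier3D, ClsTrainLog]:
    """Train one variant; returns the best-validation-loss checkpoint."""
    if not train_cases or not internal_val_cases:
        raise ValueError("train and internal validation sets must be nonempty")
    if pyramid_channel_spec is None and pyramids:
        some = next(iter(pyramids.values()))
        pyramid_channel_spec = {s + 1: c for s, c in enumerate(some.channels)}
    model = build_classifier(config, pyramid_channel_spec)

    xs, feats, ys = _prepare(model, train_cases, pyramids, task)
    vxs, vfeats, vys = _prepare(model, internal_val_cases, pyramids, task)

    n_pos, n_neg = int(ys.sum()), int((1 - ys).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training set contains a single class; "
                         "class weight is undefined")
    pos_weight = config.class_weight if config.class_weight is not None else n_neg / n_pos

    opt = SAM(Adam(model.parameters(), lr=config.learning_rate), rho=config.sam_rho)
    rng = np.random.default_rng(config.seed + 17)
    log = ClsTrainLog()
    best_val, best_state, since_best = np.inf, None, 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_cases))
        total, n = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            x, injected = _batch(xs, feats, idx, model.config.injected_stages)
            yb = ys[idx]

            def closure():
                model.zero_grad()
                logits = model(x, injected)
                loss = bce_with_logits(logits, yb, pos_weight)
                loss.backward()
                return loss

            loss = opt.step(closure)
            total += loss.item() * len(idx)
            n += len(idx)
        val_loss = _epoch_loss(model, vxs, vfeats, vys,
                               np.arange(len(internal_val_cases)),
                               config.batch_size, pos_weight)
        log.epochs.append(
            {"epoch": epoch, "train_loss": total / n, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
            log.checkpoint_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    log.stop_epoch = log.epochs[-1]["epoch"]
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def predict_scores(model: Classifier3D, cases, pyramids, task: str = "emvi",
                   batch_size: int = 8) -> ScoreSet:
    """One sigmoid probability per case, deterministic in inference."""
    xs, feats, ys = _prepare(model, cases, pyramids, task)
    scores = np.empty(len(cases), dtype=np.float64)
    for i in range(0, len(cases), batch_size):
        idx = np.arange(i, min(i + batch_size, len(cases)))
        x, injected = _batch(xs, feats, idx, model.config.injected_stages)
        logits = model(x, injected)
        scores[idx] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    return ScoreSet(
        patient_ids=[c.patient_id for c in cases],
        scores=scores,
        labels=ys.astype(int),
    )


@dataclass
class AblationScores:
    internal: ScoreSet
    external: ScoreSet
    log: ClsTrainLog
    model: Classifier3D | None = None


def run_ablation(splits, pyramids, base_config: ClassifierConfig,
                 task: str = "emvi",
                 variants: tuple[str, ...] = VARIANTS) -> dict[str, AblationScores]:
    """Train every variant on identical splits and seeds; score the shared
    internal and external case lists."""
    train_cases, internal_cases, external_cases = splits
    results: dict[str, AblationScores] = {}
    for variant in variants:
        config = copy.deepcopy(base_config)
        config.variant = variant
        model, log = train_classifier(train_cases, internal_cases, pyramids,
                                      config, task=task)
        results[variant] = AblationScores(
            internal=predict_scores(model, internal_cases, pyramids, task),
            external=predict_scores(model, external_cases, pyramids, task),
            log=log,
            model=model,
        )
    return results
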