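"""End-to-end experiment: cohort generation, centre-wise splitting,
segmentation CV, feature inference, classifier ablation, evaluation with
bootstrap CIs, attention maps, and a manifest for reproducibility audits."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd

from ..classification import ScoreSet, run_ablation, train_classifier
from ..classification.train import _prepare
from ..evalstats import auc_rank, clinical_lr, mann_whitney, metric_report, roc_curve, youden_threshold
from ..explain import attention_overlap, gradcam_pp
from ..phantom import default_centres, generate_cohort, summarize_cohort
from ..segmentation import crossval_segmentation, extract_features, train_segmenter
from .config import ExperimentConfig
from .split import centre_split

__all__ = ["run_experiment", "make_report", "ExperimentBundle"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure tagged with the pipeline stage that raised it."""


@dataclass
class ExperimentBundle:
    run_dir: Path
    config: ExperimentConfig
    manifest: dict = field(default_factory=dict)

    def scores_path(self, arm, task, variant, split) -> Path:
        return self.run_dir / "scores" / arm / task / f"{variant}_{split}.csv"

    def report_path(self, arm, task) -> Path:
        return self.run_dir / "reports" / arm / task / "metrics.csv"


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)
            return out, time.time() - t0
        return inner
    return wrap


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig, run_dir) -> ExperimentBundle:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    bundle = ExperimentBundle(run_dir=run_dir, config=config)
    manifest: dict = {"stages": {}, "case_trace": {}, "artifacts": {}}
    plan = config.split_plan()

    # ------------------------------------------------------------ cohort
    @_stage("cohort")
    def _cohort():
        centres = default_centres(config.n_centres, seed=config.seed + 7)
        return generate_cohort(config.n_cases, centres, config.p_emvi, config.p_cr,
                               seed=config.seed, spec=config.phantom_spec())

    cohort, dt = _cohort()
    manifest["stages"]["cohort"] = {"seconds": dt, "n": len(cohort)}

    train_cases, internal_cases, external_cases = centre_split(cohort, plan)
    manifest["case_trace"] = {
        "train": sorted(c.patient_id for c in train_cases),
        "internal_val": sorted(c.patient_id for c in internal_cases),
        "external": sorted(c.patient_id for c in external_cases),
    }

    # ------------------------------------------------------------ summary
    @_stage("summary")
    def _summary():
        summary = summarize_cohort(
            {
                "all": cohort,
                "train": train_cases,
                "internal_val": internal_cases,
                "external": external_cases,
            },
            compare=("train", "external"),
        )
        out = run_dir / "summary" / "cohort_summary.csv"
        out.parent.mkdir(parents=True, exist_ok=True)
        summary.table.to_csv(out, index=False)
        (run_dir / "summary" / "p_values.json").write_text(
            json.dumps(summary.p_values, indent=2)
        )
        return summary

    _summary()

    development = train_cases + internal_cases
    for arm in config.arms:
        arm_seed = config.seed + 1000 * (1 + config.arms.index(arm))
        unet_cfg = config.unet_config(arm)
        unet_cfg.seed = arm_seed

        if config.run_seg_cv:
            @_stage(f"seg_cv[{arm}]")
            def _cv():
                res = crossval_segmentation(
                    development, unet_cfg, k=config.seg_folds,
                    epochs=config.seg_epochs, lr=config.seg_lr,
                )
                out = run_dir / "seg" / arm / "cv_results.json"
                out.parent.mkdir(parents=True, exist_ok=True)
                out.write_text(json.dumps({
                    "fold_means": res.fold_means,
                    "mean_dice": res.mean_dice,
                    "std_dice": res.std_dice,
                    "per_case": res.per_case,
                }, indent=2))
                return res

            _cv()

        @_stage(f"seg_train[{arm}]")
        def _seg_train():
            return train_segmenter(train_cases, unet_cfg, epochs=config.seg_epochs,
                                   val_cases=internal_cases, lr=config.seg_lr)

        (segmenter, seg_log), _ = _seg_train()

        @_stage(f"features[{arm}]")
        def _features():
            return {c.patient_id: extract_features(segmenter, c.image) for c in cohort}

        pyramids, _ = _features()

        for task in config.tasks:
            @_stage(f"ablation[{arm}/{task}]")
            def _ablate():
                base = config.classifier_config(arm, "mlnet")
                return run_ablation(
                    (train_cases, internal_cases, external_cases),
                    pyramids, base, task=task, variants=config.variants,
                )

            results, _ = _ablate()

            @_stage(f"clinical_lr[{arm}/{task}]")
            def _lr():
                internal_scores, model = clinical_lr(development, internal_cases, target=task)
                external_scores = ScoreSet(
                    patient_ids=[c.patient_id for c in external_cases],
                    scores=model.predict(
                        pd.DataFrame([{ "age": c.age, "sex": c.sex, "cT": c.cT,
                                        "cN": c.cN} for c in external_cases])
                    ),
                    labels=np.array([getattr(c, f"{task}_label") for c in external_cases]),
                )
                return internal_scores, external_scores

            try:
                (lr_internal, lr_external), _ = _lr()
            except StageError as exc:
                # tiny cohorts can separate perfectly; drop the LR baseline row
                logger.warning("clinical LR baseline skipped: %s", exc)
                lr_internal = lr_external = None

            @_stage(f"evaluate[{arm}/{task}]")
            def _evaluate():
                rows = []
                score_sets = {}
                if lr_internal is not None:
                    score_sets["LR"] = (lr_internal, lr_external)
                for variant, res in results.items():
                    score_sets[variant] = (res.internal, res.external)
                for name, (internal, external) in score_sets.items():
                    for split, ss in (("internal", internal), ("external", external)):
                        path = bundle.scores_path(arm, task, name, split)
                        ss.to_csv(path)
                    op = youden_threshold(internal)
                    for split, ss in (("internal", internal), ("external", external)):
                        rep = metric_report(ss, threshold=op.threshold,
                                            n_boot=config.n_boot,
                                            seed=config.seed + 31)
                        for row in rep.to_rows():
                            rows.append({"model": name, "split": split,
                                         "threshold": op.threshold, **row})
                df = pd.DataFrame(rows)
                out = bundle.report_path(arm, task)
                out.parent.mkdir(parents=True, exist_ok=True)
                df.to_csv(out, index=False)
                return df

            _evaluate()

            @_stage(f"attention[{arm}/{task}]")
            def _attention():
                cfg = config.classifier_config(arm, "mlnet")
                model, _log = train_classifier(train_cases, internal_cases, pyramids,
                                               cfg, task=task)
                stats = []
                sel = external_cases[: config.n_attention_cases]
                xs, feats, _ys = _prepare(model, sel, pyramids, task)
                for case, x, fd in zip(sel, xs, feats):
                    amap = gradcam_pp(model, x, fd)
                    overlap = attention_overlap(amap, case.mask, quantile=0.9, margin=2)
                    out = run_dir / "attention" / arm / task / f"{case.patient_id}.nii.gz"
                    out.parent.mkdir(parents=True, exist_ok=True)
                    aff = np.diag(list(case.image.spacing) + [1.0])
                    nib.save(nib.Nifti1Image(amap.data, aff), out)
                    stats.append({"patient_id": case.patient_id, "overlap": overlap})
                (run_dir / "attention" / arm / task / "overlap.json").write_text(
                    json.dumps(stats, indent=2)
                )
                return stats

            if config.n_attention_cases > 0:
                _attention()

    # ----------------------------------------------------------- manifest
    for path in sorted(run_dir.rglob("*")):
        if path.is_file() and path.suffix in (".csv", ".json", ".yaml"):
            if path.name == "manifest.json":
                continue
            manifest["artifacts"][str(path.relative_to(run_dir))] = _sha256(path)
    manifest["config_digest"] = _sha256(run_dir / "config.yaml")
    bundle.manifest = manifest
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle


# --------------------------------------------------------------- reporting


def make_report(run_dir) -> dict:
    """Tables (best-per-column flagged), ROC figures and Mann-Whitney
    comparisons between variants, from a completed run directory."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise ValueError(f"incomplete bundle: no manifest in {run_dir}")
    config = ExperimentConfig.from_yaml(run_dir / "config.yaml")
    outputs = {}
    for arm in config.arms:
        for task in config.tasks:
            metrics_path = run_dir / "reports" / arm / task / "metrics.csv"
            if not metrics_path.exists():
                raise ValueError(f"incomplete bundle: missing {metrics_path}")
            df = pd.read_csv(metrics_path)
            ext = df[df["split"] == "external"].copy()
            # wide table: one row per model, point (CI) per metric
            table = ext.pivot(index="model", columns="metric", values="point")
            best = table.idxmax()
            lines = []
            for model in table.index:
                cells = []
                for metric in table.columns:
                    row = ext[(ext["model"] == model) & (ext["metric"] == metric)].iloc[0]
                    cell = f"{row['point']:.2f} ({row['ci_lo']:.2f}-{row['ci_hi']:.2f})"
                    if best[metric] == model:
                        cell = f"**{cell}**"  # bold = per-column best
                    cells.append(cell)
                lines.append(f"| {model} | " + " | ".join(cells) + " |")
            header = "| model | " + " | ".join(table.columns) + " |"
            md = "\n".join([header, "|" + "---|" * (len(table.columns) + 1)] + lines)
            report_dir = run_dir / "reports" / arm / task
            (report_dir / "table.md").write_text(md + "\n")

            fig, ax = plt.subplots(figsize=(5, 5))
            mw_rows = []
            models = sorted(ext["model"].unique())
            scores = {}
            for model in models:
                ss = ScoreSet.from_csv(run_dir / "scores" / arm / task / f"{model}_external.csv")
                scores[model] = ss
                fpr, tpr = roc_curve(ss)
                ax.plot(fpr, tpr, label=f"{model} (AUC {auc_rank(ss):.2f})")
            ax.plot([0, 1], [0, 1], "k--", lw=0.5)
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            ax.legend(fontsize=7)
            fig.savefig(report_dir / "roc.png", dpi=120)
            plt.close(fig)

            for i, a in enumerate(models):
                for b in models[i + 1:]:
                    err_a = np.abs(scores[a].scores - scores[a].labels)
                    err_b = np.abs(scores[b].scores - scores[b].labels)
                    u, p = mann_whitney(err_a, err_b)
                    mw_rows.append({"model_a": a, "model_b": b, "U": u, "p": p})
            pd.DataFrame(mw_rows).to_csv(report_dir / "mann_whitney.csv", index=False)
            outputs[(arm, task)] = {"table": md, "mann_whitney": mw_rows}
    return outputs
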