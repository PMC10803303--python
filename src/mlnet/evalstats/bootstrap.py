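"""Case-level percentile bootstrap confidence intervals and metric reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    auc_rank,
    confusion_metrics,
    youden_threshold,
    _scores_labels,
)

__all__ = ["bootstrap_ci", "MetricReport", "metric_report"]

logger = logging.getLogger(__name__)


def bootstrap_ci(metric, scores, labels=None, n_boot: int = 10_000, seed: int = 0,
                 alpha: float = 0.05, max_redraws: int = 1000):
    """Percentile (alpha/2, 1-alpha/2) interval of ``metric`` over case-level
    resampling with replacement.

    ``metric`` is called as metric(scores, labels) on each resample.
    Resamples on which the metric is undefined (e.g. a missing class) are
    redrawn; persistent failure raises.
    """
    s, y = _scores_labels(scores, labels)
    if s.size < 2:
        raise ValueError("bootstrap needs at least 2 cases")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot, dtype=np.float64)
    redraws = 0
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, s.size, size=s.size)
            try:
                v = metric(s[idx], y[idx])
            except ValueError:
                redraws += 1
                continue
            if np.isnan(v):
                redraws += 1
                continue
            vals[b] = v
            break
        else:
            raise ValueError("metric never computable on bootstrap resamples")
    if redraws:
        logger.debug("bootstrap: %d invalid resamples redrawn", redraws)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    """AUC and threshold metrics, each with a 95% bootstrap CI."""

    threshold: float
    n_boot: int
    n_cases: int
    metrics: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # name -> (point, ci_lo, ci_hi)

    def point(self, name: str) -> float:
        return self.metrics[name][0]

    def ci(self, name: str) -> tuple[float, float]:
        return self.metrics[name][1], self.metrics[name][2]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_boot": self.n_boot,
            "n_cases": self.n_cases,
            "metrics": {k: list(v) for k, v in self.metrics.items()},
        }

    def to_rows(self) -> list[dict]:
        return [
            {"metric": k, "point": v[0], "ci_lo": v[1], "ci_hi": v[2]}
            for k, v in self.metrics.items()
        ]


_THRESHOLD_METRICS = ("sensitivity", "specificity", "ppv", "npv", "f1")


def metric_report(scores, labels=None, threshold: float | None = None,
                  n_boot: int = 10_000, seed: int = 0) -> MetricReport:
    """Full report: AUC + Eqs.-style threshold metrics with bootstrap CIs.

    If ``threshold`` is None the Youden-optimal threshold is computed on this
    score set; when evaluating external data pass the internal-validation
    threshold unchanged.
    """
    s, y = _scores_labels(scores, labels)
    if threshold is None:
        threshold = youden_threshold(s, y).threshold
    report = MetricReport(threshold=float(threshold), n_boot=n_boot, n_cases=s.size)

    report.metrics["auc"] = (
        auc_rank(s, y),
        *bootstrap_ci(auc_rank, s, y, n_boot=n_boot, seed=seed),
    )
    point = confusion_metrics(s, y, threshold=threshold)
    for i, name in enumerate(_THRESHOLD_METRICS):
        pt = getattr(point, name)
        if np.isnan(pt):
            # structurally undefined at this threshold; CI is undefined too
            report.metrics[name] = (pt, float("nan"), float("nan"))
            continue

        def metric(ss, yy, _name=name):
            m = confusion_metrics(ss, yy, threshold=threshold, warn=False)
            return getattr(m, _name)

        lo, hi = bootstrap_ci(metric, s, y, n_boot=n_boot, seed=seed + 1 + i,
                              max_redraws=100)
        report.metrics[name] = (pt, lo, hi)
    return report
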