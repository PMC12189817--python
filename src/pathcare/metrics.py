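"""Evaluation: AUPRC, AUROC, min(+P, Se), bootstrap CIs, gate diagnostics.

All three metrics target imbalanced binary outcomes.  AUPRC (average
precision) is the headline metric: under low prevalence it is far more
informative than AUROC because it ignores the abundant true negatives.
min(+P, Se) — the minimum of precision and sensitivity, maximized over
decision thresholds — summarizes whether any single operating point
balances false alarms against missed cases.

Uncertainty is quantified by bootstrapping patients of the test set with
replacement; resamples that lose one class entirely are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score)


@dataclass
class MetricReport:
    """Point estimate plus bootstrap summary for one metric."""

    metric: str
    estimate: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    seed: int

    def __str__(self) -> str:
        return (f"{self.metric}: {self.estimate:.4f} "
                f"(bootstrap {self.boot_mean:.4f} ± {self.boot_sd:.4f}, "
                f"n={self.n_boot})")


@dataclass
class GateSummary:
    """Mean gate openness toward the future branch, by outcome group.

    The per-patient scalar is the mean of the ``gate_future`` vector; a
    higher group mean means the model leans more on future-predictive
    features for that group.
    """

    per_patient: np.ndarray
    mean_positive: float
    mean_negative: float

    @property
    def difference(self) -> float:
        return self.mean_positive - self.mean_negative


def _check_binary(labels: np.ndarray, scores: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.shape != np.shape(scores):
        raise ValueError("labels and scores must align")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("metric undefined for single-class labels")


def auprc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (average-precision
    estimator: precision-weighted recall increments)."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    _check_binary(labels, scores)
    return float(average_precision_score(labels, scores))


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (normalized Mann-Whitney U; ties get
    half credit)."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    _check_binary(labels, scores)
    return float(roc_auc_score(labels, scores))


def min_p_se(labels: Sequence[int], scores: Sequence[float]) -> float:
    """max over thresholds of min(precision, sensitivity).

    Thresholds are the unique scores (predict positive when score >=
    threshold).  The pointwise minimum balances false alarms against
    missed cases; taking its maximum over thresholds picks the best
    achievable balance.
    """
    labels, scores = np.asarray(labels), np.asarray(scores)
    _check_binary(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # the final (1, 0) point is an artificial endpoint, not a threshold
    return float(np.max(np.minimum(precision[:-1], recall[:-1])))


METRICS: Dict[str, Callable] = {"auprc": auprc, "auroc": auroc,
                                "min_p_se": min_p_se}


def bootstrap(metric: str | Callable, labels: Sequence[int],
              scores: Sequence[float], n_boot: int = 1000,
              seed: int = 42) -> MetricReport:
    """Patient-level bootstrap of a metric.

    Resamples with replacement; draws that contain a single class are
    redrawn (up to 1000 attempts each).  Reports the full-sample point
    estimate and the mean ± sd over replicates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    name = metric if isinstance(metric, str) else fn.__name__
    labels, scores = np.asarray(labels), np.asarray(scores)
    _check_binary(labels, scores)
    rng = np.random.default_rng(seed)
    n = len(labels)
    estimates = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
            n_redrawn += 1
        estimates[b] = fn(labels[idx], scores[idx])
    return MetricReport(metric=name, estimate=fn(labels, scores),
                        boot_mean=float(estimates.mean()),
                        boot_sd=float(estimates.std(ddof=0)),
                        n_boot=n_boot, seed=seed)


def evaluate_all(labels, scores, n_boot: int = 1000,
                 seed: int = 42) -> Dict[str, MetricReport]:
    """Bootstrap reports for AUPRC, AUROC and min(+P, Se)."""
    return {m: bootstrap(m, labels, scores, n_boot, seed) for m in METRICS}


def reports_to_text(reports: Dict[str, MetricReport]) -> str:
    """Delimited text rendering of a set of metric reports."""
    lines = ["metric\testimate\tboot_mean\tboot_sd\tn_boot\tseed"]
    for r in reports.values():
        lines.append(f"{r.metric}\t{r.estimate:.6f}\t{r.boot_mean:.6f}\t"
                     f"{r.boot_sd:.6f}\t{r.n_boot}\t{r.seed}")
    return "\n".join(lines) + "\n"


def gate_summary(diagnostics: Sequence, labels: Sequence[int]) -> GateSummary:
    """Summarize gate openness by outcome group.

    ``diagnostics`` is one or more ForwardDiagnostics from the full
    variant; ``labels`` aligns with the concatenated patient order.
    """
    diags = list(diagnostics) if isinstance(diagnostics, (list, tuple)) \
        else [diagnostics]
    per = []
    for d in diags:
        if d.gate_future is None:
            raise ValueError("gate diagnostics require the full variant")
        per.append(d.gate_future.data.mean(axis=1))
    per_patient = np.concatenate(per)
    labels = np.asarray(labels)
    if labels.shape != per_patient.shape:
        raise ValueError("labels must align with diagnostics patients")
    if not ((per_patient >= 0) & (per_patient <= 1)).all():
        raise ValueError("gate values outside [0, 1]")
    pos, neg = per_patient[labels == 1], per_patient[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("gate summary needs both outcome groups")
    return GateSummary(per_patient=per_patient,
                       mean_positive=float(pos.mean()),
                       mean_negative=float(neg.mean()))


def plot_gate_histogram(summary: GateSummary, labels: Sequence[int],
                        path: Optional[str] = None):
    """Histogram of per-patient gate values by outcome group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    bins = np.linspace(0, 1, 31)
    ax.hist(summary.per_patient[labels == 0], bins=bins, alpha=0.6,
            density=True, label="favorable outcome")
    ax.hist(summary.per_patient[labels == 1], bins=bins, alpha=0.6,
            density=True, label="adverse outcome")
    ax.set_xlabel("mean gate value (future branch)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
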