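"""Performance evaluation: confusion-matrix measures, ROC curves, 10-fold
and leave-one-protein-out (LOPO) cross-validation.

Six measures summarize a binary confusion matrix:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    accuracy    = (TP+TN)/total     PPV         = TP/(TP+FP)
    NPV         = TN/(TN+FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Cross-validation rebuilds the log-odds profiles inside every fold from that
fold's training portion only, so no positional information leaks from the
held-out sequences. LOPO holds out all sequences (binding and non-binding)
tied to one RBP at a time; its summary is the weighted average obtained by
pooling TP/TN/FP/FN over runs, not by averaging per-group metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import SvmConfig, train
from .features import RNA_BLOCKS, build_design_matrix
from .profiles import PositionWeightMatrix, build_pwm
from .seq_io import NEGATIVE, POSITIVE, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            TP=self.TP + other.TP,
            TN=self.TN + other.TN,
            FP=self.FP + other.FP,
            FN=self.FN + other.FN,
        )

    @staticmethod
    def from_predictions(y_true, y_pred) -> "ConfusionCounts":
        """Counts from {+1, -1} label arrays."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return ConfusionCounts(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == -1) & (y_pred == -1)).sum()),
            FP=int(((y_true == -1) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
        }


def _ratio(num: float, den: float) -> float:
    # zero-denominator convention: report 0 and keep batch runs alive
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """The six measures from exact confusion-count ratios.

    Any measure whose denominator is zero is reported as 0.
    """
    if c.total < 1:
        raise ValueError("cannot compute metrics from all-zero counts")
    mcc_den = np.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    return MetricSet(
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        accuracy=(c.TP + c.TN) / c.total,
        ppv=_ratio(c.TP, c.TP + c.FP),
        npv=_ratio(c.TN, c.TN + c.FN),
        mcc=_ratio(c.TP * c.TN - c.FP * c.FN, mcc_den),
    )


@dataclass(frozen=True)
class RocCurve:
    """Operating points swept over the unique decision values, with the
    trapezoid-rule area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(y_true, decision_values) -> RocCurve:
    """ROC curve from true {+1, -1} labels and real-valued decision scores."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(y_true, np.asarray(decision_values), pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the encode -> train -> predict pipeline needs besides the
    sequences themselves."""

    alpha: float = 1.0
    blocks: tuple[str, ...] = RNA_BLOCKS
    svm: SvmConfig = field(default_factory=SvmConfig)
    protein_sequences: Optional[Mapping[str, str]] = None


def _split_classes(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    pos = [r for r in records if r.label == POSITIVE]
    neg = [r for r in records if r.label == NEGATIVE]
    return pos, neg


def fit_fold(
    train_records: Sequence[SequenceRecord],
    config: PipelineConfig,
):
    """Build profiles from the training records, encode and train.

    Returns (trained model, mpwm, dpwm); profiles are None when no profile
    block is requested.
    """
    pos, neg = _split_classes(train_records)
    if not pos or not neg:
        raise ValueError("training records must contain both classes")
    mpwm = dpwm = None
    if "mPWM" in config.blocks or "dPWM" in config.blocks:
        mpwm = build_pwm(pos, neg, k=1, alpha=config.alpha)
        dpwm = build_pwm(pos, neg, k=2, alpha=config.alpha)
    X, y, layout = build_design_matrix(
        train_records,
        mpwm,
        dpwm,
        blocks=config.blocks,
        protein_sequences=config.protein_sequences,
    )
    model = train(X, y, config.svm, layout=layout)
    return model, mpwm, dpwm


def _evaluate_fold(
    model,
    mpwm,
    dpwm,
    test_records: Sequence[SequenceRecord],
    config: PipelineConfig,
):
    X, y, _ = build_design_matrix(
        test_records,
        mpwm,
        dpwm,
        blocks=config.blocks,
        protein_sequences=config.protein_sequences,
    )
    pred, scores = model.predict(X)
    return ConfusionCounts.from_predictions(y, pred), y, scores


@dataclass(frozen=True)
class CvResult:
    pooled: MetricSet
    roc: RocCurve
    fold_counts: tuple[ConfusionCounts, ...]

    @property
    def pooled_counts(self) -> ConfusionCounts:
        return sum(self.fold_counts, ConfusionCounts())


def kfold_cv(
    records: Sequence[SequenceRecord],
    k: int = 10,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> CvResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Profiles are rebuilt from each fold's training portion; confusion counts
    are pooled over folds and the metric set is computed from the pooled
    counts (a fold-averaged variant is available through ``metrics`` on
    ``fold_counts``).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    records = list(records)
    y_all = np.array([1 if r.label == POSITIVE else -1 for r in records])
    # stratify when every class can appear in every fold; beyond that (e.g.
    # the leave-one-out limit k == n) fall back to plain shuffled folds
    min_class = min(np.sum(y_all == 1), np.sum(y_all == -1))
    if k <= min_class:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts = []
    all_true: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    for train_idx, test_idx in skf.split(np.zeros(len(records)), y_all):
        train_recs = [records[i] for i in train_idx]
        test_recs = [records[i] for i in test_idx]
        model, mpwm, dpwm = fit_fold(train_recs, config)
        counts, y_true, scores = _evaluate_fold(model, mpwm, dpwm, test_recs, config)
        fold_counts.append(counts)
        all_true.append(y_true)
        all_scores.append(scores)
    pooled_counts = sum(fold_counts, ConfusionCounts())
    return CvResult(
        pooled=metrics(pooled_counts),
        roc=roc(np.concatenate(all_true), np.concatenate(all_scores)),
        fold_counts=tuple(fold_counts),
    )


@dataclass(frozen=True)
class LopoResult:
    per_group: dict[str, MetricSet]
    per_group_counts: dict[str, ConfusionCounts]
    weighted_average: MetricSet
    pooled_counts: ConfusionCounts
    flagged_groups: tuple[str, ...]


def lopo_cv(
    records: Sequence[SequenceRecord],
    config: PipelineConfig = PipelineConfig(),
) -> LopoResult:
    """Leave-one-protein-out cross-validation.

    Every record must carry an RBP tag; for each RBP in turn, all its
    sequences (both classes) are held out, profiles and classifier are
    refit on the rest, and the held-out group is predicted. The weighted
    average is computed from the summed TP/TN/FP/FN of all runs. Groups
    containing a single class are still evaluated but flagged.
    """
    records = list(records)
    untagged = [r.id for r in records if r.rbp is None]
    if untagged:
        raise ValueError(
            f"{len(untagged)} record(s) lack an RBP tag (e.g. {untagged[0]!r})"
        )
    groups = sorted({r.rbp for r in records})
    if len(groups) < 2:
        raise ValueError("LOPO needs at least 2 RBP groups")

    per_group: dict[str, MetricSet] = {}
    per_counts: dict[str, ConfusionCounts] = {}
    flagged = []
    for group in groups:
        held_out = [r for r in records if r.rbp == group]
        retained = [r for r in records if r.rbp != group]
        labels_present = {r.label for r in held_out}
        if len(labels_present) < 2:
            flagged.append(group)
            logger.warning("LOPO group %r contains a single class", group)
        model, mpwm, dpwm = fit_fold(retained, config)
        counts, _, _ = _evaluate_fold(model, mpwm, dpwm, held_out, config)
        per_counts[group] = counts
        per_group[group] = metrics(counts)
    pooled = sum(per_counts.values(), ConfusionCounts())
    return LopoResult(
        per_group=per_group,
        per_group_counts=per_counts,
        weighted_average=metrics(pooled),
        pooled_counts=pooled,
        flagged_groups=tuple(flagged),
    )


# -- reporting ---------------------------------------------------------------

REPORT_COLUMNS = (
    "group",
    "TP",
    "TN",
    "FP",
    "FN",
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv",
    "npv",
    "mcc",
)


def _report_row(name: str, c: ConfusionCounts) -> str:
    m = metrics(c)
    return "\t".join(
        [
            name,
            str(c.TP),
            str(c.TN),
            str(c.FP),
            str(c.FN),
            f"{m.sensitivity * 100:.2f}%",
            f"{m.specificity * 100:.2f}%",
            f"{m.accuracy * 100:.2f}%",
            f"{m.ppv * 100:.2f}%",
            f"{m.npv * 100:.2f}%",
            f"{m.mcc:.3f}",
        ]
    )


def format_report(counts_by_group: Mapping[str, ConfusionCounts]) -> str:
    """Tab-separated evaluation report: one row per fold/group plus a
    pooled weighted-average row computed from the summed counts."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for name in counts_by_group:
        lines.append(_report_row(name, counts_by_group[name]))
    pooled = sum(counts_by_group.values(), ConfusionCounts())
    lines.append(_report_row("weighted_average", pooled))
    return "\n".join(lines) + "\n"


def write_roc_points(curve: RocCurve, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#FPR\tTPR\n")
        for f, t in zip(curve.fpr, curve.tpr):
            fh.write(f"{f:.17g}\t{t:.17g}\n")
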