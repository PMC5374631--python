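"""High-level modelling interface.

``RnaBindingModel`` bundles a labeled sequence set with the encoding and
kernel configuration; ``fit()`` builds the log-odds profiles, trains the
SVM, and returns an ``RnaBindingResults`` object carrying the fitted state,
diagnostics, a ``summary()`` table, prediction, and the two cross-validation
protocols.

    >>> data = synth_generate(MotifModel.planted(), 500, 500, seed=7)
    >>> result = RnaBindingModel(data).fit()
    >>> print(result.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import SvmConfig, TrainedModel, train
from .datasets import LabeledSequenceSet
from .evaluate import (
    ConfusionCounts,
    CvResult,
    LopoResult,
    PipelineConfig,
    kfold_cv,
    lopo_cv,
    metrics,
)
from .features import RNA_BLOCKS, build_design_matrix
from .profiles import PositionWeightMatrix, build_pwm
from .seq_io import NEGATIVE, POSITIVE, SequenceRecord, read_fasta


class RnaBindingModel:
    """Predictor of protein-binding regions in mRNA.

    Parameters
    ----------
    data
        Labeled training sequences (binding = positive, non-binding =
        negative), all of the same length (the profile window, 25 nt in the
        reference configuration).
    alpha
        Additive pseudocount used when estimating positional k-mer
        frequencies; keeps log-odds finite.
    blocks
        Feature blocks to use, any subset of ("mPWM", "dPWM",
        "composition"); the default is all three.
    protein_sequences
        Optional mapping RBP name -> amino-acid sequence; when given, each
        record's 63-element protein CTD descriptor is appended.
    svm
        Kernel configuration (C, gamma, kernel, feature scaling).
    """

    def __init__(
        self,
        data: LabeledSequenceSet | Sequence[SequenceRecord],
        alpha: float = 1.0,
        blocks: Sequence[str] = RNA_BLOCKS,
        protein_sequences: Optional[Mapping[str, str]] = None,
        svm: SvmConfig = SvmConfig(),
    ):
        if not isinstance(data, LabeledSequenceSet):
            data = LabeledSequenceSet(tuple(data))
        pos, neg = data.positives, data.negatives
        if not pos or not neg:
            raise ValueError("training data must contain both classes")
        lengths = {len(r) for r in data.records}
        if len(lengths) != 1:
            raise ValueError(
                f"training sequences must share one length, got {sorted(lengths)}"
            )
        self.data = data
        self.window = lengths.pop()
        self.config = PipelineConfig(
            alpha=alpha,
            blocks=tuple(b for b in RNA_BLOCKS if b in blocks),
            svm=svm,
            protein_sequences=protein_sequences,
        )
        if not self.config.blocks:
            raise ValueError("at least one feature block must be selected")

    @classmethod
    def from_fasta(
        cls,
        positive_path: str,
        negative_path: str,
        **kwargs,
    ) -> "RnaBindingModel":
        """Build a model from two FASTA files of binding / non-binding
        sequences."""
        pos = [r.with_label(POSITIVE) for r in read_fasta(positive_path)]
        neg = [r.with_label(NEGATIVE) for r in read_fasta(negative_path)]
        return cls(LabeledSequenceSet(tuple(pos) + tuple(neg)), **kwargs)

    def fit(self) -> "RnaBindingResults":
        """Build profiles from the training data, encode, and train the
        classifier."""
        cfg = self.config
        mpwm = dpwm = None
        if "mPWM" in cfg.blocks or "dPWM" in cfg.blocks:
            mpwm = build_pwm(self.data.positives, self.data.negatives, 1, cfg.alpha)
            dpwm = build_pwm(self.data.positives, self.data.negatives, 2, cfg.alpha)
        X, y, layout = build_design_matrix(
            list(self.data.records),
            mpwm,
            dpwm,
            blocks=cfg.blocks,
            protein_sequences=cfg.protein_sequences,
        )
        classifier = train(X, y, cfg.svm, layout=layout)
        pred, _ = classifier.predict(X)
        train_counts = ConfusionCounts.from_predictions(y, pred)
        return RnaBindingResults(
            model=self,
            mpwm=mpwm,
            dpwm=dpwm,
            classifier=classifier,
            layout=layout,
            train_counts=train_counts,
        )


@dataclass
class RnaBindingResults:
    """Fitted predictor: profiles, classifier, and diagnostics."""

    model: RnaBindingModel
    mpwm: Optional[PositionWeightMatrix]
    dpwm: Optional[PositionWeightMatrix]
    classifier: TrainedModel
    layout: tuple[tuple[str, int], ...]
    train_counts: ConfusionCounts

    @property
    def n_features(self) -> int:
        return self.classifier.n_features

    def predict(self, records: Sequence[SequenceRecord]) -> pd.DataFrame:
        """Predict binding for RNA sequences of any length >= 3 nt.

        Returns a DataFrame with columns id, prediction (binding /
        non-binding) and decision (signed distance to the margin).
        """
        cfg = self.model.config
        X, _, _ = build_design_matrix(
            list(records),
            self.mpwm,
            self.dpwm,
            blocks=cfg.blocks,
            protein_sequences=cfg.protein_sequences,
        )
        labels, scores = self.classifier.predict(X)
        return pd.DataFrame(
            {
                "id": [r.id for r in records],
                "prediction": np.where(labels == 1, "binding", "non-binding"),
                "decision": scores,
            }
        )

    def cross_validate(self, k: int = 10, seed: int = 0) -> CvResult:
        """Stratified k-fold cross-validation of the whole pipeline on the
        model's data (profiles rebuilt per fold)."""
        return kfold_cv(list(self.model.data.records), k=k, seed=seed,
                        config=self.model.config)

    def leave_one_protein_out(self) -> LopoResult:
        """LOPO cross-validation on the model's data, one run per RBP tag."""
        return lopo_cv(list(self.model.data.records), config=self.model.config)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = metrics(self.train_counts)
        cfg = self.model.config
        n_pos, n_neg = self.model.data.ratio
        lines = [
            "RNA-binding region prediction model",
            "=" * 51,
            f"{'Window (nt)':<28}{self.model.window:>23}",
            f"{'Training positives':<28}{n_pos:>23}",
            f"{'Training negatives':<28}{n_neg:>23}",
            f"{'Feature blocks':<28}{'+'.join(cfg.blocks):>23}",
            f"{'Features':<28}{self.n_features:>23}",
            f"{'Pseudocount alpha':<28}{cfg.alpha:>23g}",
            f"{'Kernel':<28}{cfg.svm.kernel:>23}",
            f"{'C':<28}{cfg.svm.C:>23g}",
            f"{'gamma':<28}{cfg.svm.gamma:>23g}",
            f"{'Feature scaling':<28}{str(cfg.svm.scale):>23}",
            "-" * 51,
            f"{'Training accuracy':<28}{m.accuracy * 100:>22.2f}%",
            f"{'Training MCC':<28}{m.mcc:>23.3f}",
            "=" * 51,
        ]
        return "\n".join(lines)
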