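"""Top-level quality-control-driven segmenter: train once, segment + QC."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .ensemble import (EnsembleBundle, NetworkSpec, TrainingConfig,
                       predict_scs, preprocess, train_ensemble)
from .evaluate import EvalReport, candidate_triples, evaluate_framework
from .fusion import agreement_matrix, build_candidate_set
from .phantom import PhantomSample
from .quality import DiceRegressorBank, QCResult, fit_quality_model, select_best

__all__ = ["QCDSegmenter"]


class QCDSegmenter(BaseEstimator):
    """Quality-control-driven ensemble segmenter.

    Trains encoder-decoder networks of the requested depths on the training
    split, fits the per-candidate Dice regressors on the *validation* split
    (never on training data), and at inference returns the candidate with
    the highest predicted Dice together with a pass/fail quality flag — all
    without ground truth.

    Parameters
    ----------
    depths : network depths, one ensemble member each (depth-ascending)
    base_filters, input_size : architecture shared by all members
    learning_rate, max_epochs, early_stop_patience, batch_size, seed :
        shared optimisation settings
    threshold : predicted-Dice quality bar for the pass flag

    Attributes
    ----------
    bundle_ : trained :class:`~qcdseg.ensemble.EnsembleBundle`
    quality_model_ : fitted :class:`~qcdseg.quality.DiceRegressorBank`
    """

    def __init__(self, depths: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
                 base_filters: int = 8, input_size: int = 64,
                 learning_rate: float = 5e-5, max_epochs: int = 200,
                 early_stop_patience: int = 10, batch_size: int = 8,
                 threshold: float = 0.7, seed: int = 0):
        self.depths = depths
        self.base_filters = base_filters
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.threshold = threshold
        self.seed = seed

    def _specs(self) -> list[NetworkSpec]:
        return [NetworkSpec(depth=d, base_filters=self.base_filters,
                            input_size=self.input_size)
                for d in sorted(self.depths)]

    def _cfg(self) -> TrainingConfig:
        return TrainingConfig(learning_rate=self.learning_rate,
                              max_epochs=self.max_epochs,
                              early_stop_patience=self.early_stop_patience,
                              batch_size=self.batch_size, seed=self.seed)

    def fit(self, train_samples: Sequence[PhantomSample],
            val_samples: Sequence[PhantomSample]) -> "QCDSegmenter":
        self.bundle_ = train_ensemble(train_samples, val_samples,
                                      self._specs(), self._cfg())
        self.quality_model_ = fit_quality_model(
            candidate_triples(self.bundle_, val_samples))
        return self

    def predict(self, image: np.ndarray) -> QCResult:
        """Segment one raw 2-D image and quality-flag the result."""
        self._check_fitted()
        img, _ = preprocess(image, self.input_size)
        cs = build_candidate_set(predict_scs(self.bundle_, img))
        preds = self.quality_model_.predict(agreement_matrix(cs))
        return select_best(preds, threshold=self.threshold, candidates=cs)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        """The selected binary segmentation for one raw image."""
        res = self.predict(image)
        img, _ = preprocess(image, self.input_size)
        cs = build_candidate_set(predict_scs(self.bundle_, img))
        return cs.masks[res.selected_index]

    def score(self, test_samples: Sequence[PhantomSample]) -> EvalReport:
        """Full evaluation report on a held-out, patient-disjoint test set."""
        self._check_fitted()
        return evaluate_framework(self.bundle_, self.quality_model_,
                                  test_samples, threshold=self.threshold)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.bundle_.save(out / "ensemble")
        self.quality_model_.save(out / "quality_model.json")

    @classmethod
    def load(cls, in_dir: str | Path) -> "QCDSegmenter":
        src = Path(in_dir)
        bundle = EnsembleBundle.load(src / "ensemble")
        est = cls(depths=tuple(m.depth for m in bundle.members),
                  base_filters=bundle.members[0].base_filters,
                  input_size=bundle.input_size,
                  learning_rate=bundle.config.learning_rate,
                  max_epochs=bundle.config.max_epochs,
                  early_stop_patience=bundle.config.early_stop_patience,
                  batch_size=bundle.config.batch_size,
                  seed=bundle.config.seed)
        est.bundle_ = bundle
        est.quality_model_ = DiceRegressorBank.load(src / "quality_model.json")
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "bundle_"):
            raise RuntimeError("QCDSegmenter is not fitted; call fit first")
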