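"""Ground-truth-free segmentation quality prediction and candidate selection.

The core idea: across a diverse candidate pool, mutual agreement is
informative about accuracy — a candidate that diverges from everyone is
probably wrong, one that sits near the consensus is probably right, much
like concordant opinions in a multidisciplinary team.  For each candidate
position i a separate linear regressor maps the candidate's off-diagonal row
of the pairwise-Dice agreement matrix (2N-1 features) to its Dice against
ground truth.  Regressors are fitted on the *validation* split only, so they
are never autocorrelated with the segmentation networks' training data.

At inference the candidate with the highest predicted Dice is selected and
flagged against a quality threshold (default 0.7).  When ground truth is
available for evaluation, the prediction/observation pair is classified as
TP / TN / FP / FN: a false positive is a predicted Dice >= threshold whose
observed Dice is < threshold; a false negative is the reverse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression, Ridge

from .fusion import AgreementMatrix, CandidateSet, dice

__all__ = [
    "DiceRegressorBank", "QualityModel", "QCResult",
    "fit_quality_model", "predict_quality", "select_best",
]


class DiceRegressorBank(BaseEstimator, RegressorMixin):
    """One ordinary-least-squares regressor per candidate position.

    Parameters
    ----------
    ridge_alpha : penalty used only when a fit is under-determined
        (fewer samples than features + intercept); OLS otherwise.

    Attributes
    ----------
    coef_ : (n_candidates, n_candidates - 1) weight matrix
    intercept_ : (n_candidates,) intercepts
    ordering_hash_ : fingerprint of the candidate ordering the features bind to
    n_fit_ : number of validation images used
    residual_mae_ : in-sample mean absolute residual per candidate
    """

    def __init__(self, ridge_alpha: float = 1e-3):
        self.ridge_alpha = ridge_alpha

    def fit(self, matrices: Sequence[AgreementMatrix],
            targets: np.ndarray) -> "DiceRegressorBank":
        """Fit from per-image agreement matrices and true per-candidate Dice.

        ``targets`` has shape (n_images, n_candidates).
        """
        if len(matrices) == 0:
            raise ValueError("need at least one validation image")
        targets = np.asarray(targets, dtype=np.float64)
        n_cand = matrices[0].values.shape[0]
        if targets.shape != (len(matrices), n_cand):
            raise ValueError(
                f"targets shape {targets.shape} does not match "
                f"({len(matrices)}, {n_cand})"
            )
        hashes = {m.ordering_hash for m in matrices}
        if len(hashes) > 1:
            raise ValueError("agreement matrices have inconsistent candidate "
                             "ordering")
        if any(m.values.shape[0] != n_cand for m in matrices):
            raise ValueError("inconsistent candidate count across images")
        self.ordering_hash_ = matrices[0].ordering_hash
        n_feat = n_cand - 1
        if len(matrices) < n_feat + 1:
            warnings.warn(
                f"only {len(matrices)} validation images for {n_feat} features; "
                f"falling back to ridge regression (alpha={self.ridge_alpha})",
                UserWarning,
            )
            make = lambda: Ridge(alpha=self.ridge_alpha)
        else:
            make = lambda: LinearRegression()
        self.coef_ = np.zeros((n_cand, n_feat))
        self.intercept_ = np.zeros(n_cand)
        self.residual_mae_ = np.zeros(n_cand)
        for i in range(n_cand):
            X = np.asarray([m.row_features(i) for m in matrices])
            y = targets[:, i]
            reg = make().fit(X, y)
            self.coef_[i] = reg.coef_
            self.intercept_[i] = reg.intercept_
            self.residual_mae_[i] = float(np.abs(reg.predict(X) - y).mean())
        self.n_fit_ = len(matrices)
        return self

    def predict(self, matrix: AgreementMatrix) -> np.ndarray:
        """Predicted Dice per candidate, clipped to [0, 1]; never reads
        ground truth."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("quality model is not fitted")
        if matrix.ordering_hash != self.ordering_hash_:
            raise ValueError(
                "candidate ordering mismatch: matrix hash "
                f"{matrix.ordering_hash} != fitted {self.ordering_hash_} "
                "(features are position-bound)"
            )
        n_cand = self.coef_.shape[0]
        if matrix.values.shape[0] != n_cand:
            raise ValueError(
                f"matrix has {matrix.values.shape[0]} candidates, model expects "
                f"{n_cand}"
            )
        preds = np.array([
            self.coef_[i] @ matrix.row_features(i) + self.intercept_[i]
            for i in range(n_cand)
        ])
        return np.clip(preds, 0.0, 1.0)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "ordering_hash": self.ordering_hash_,
            "n_fit": self.n_fit_,
            "residual_mae": self.residual_mae_.tolist(),
            "ridge_alpha": self.ridge_alpha,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DiceRegressorBank":
        d = json.loads(Path(path).read_text())
        model = cls(ridge_alpha=d["ridge_alpha"])
        model.coef_ = np.asarray(d["coef"])
        model.intercept_ = np.asarray(d["intercept"])
        model.ordering_hash_ = d["ordering_hash"]
        model.n_fit_ = d["n_fit"]
        model.residual_mae_ = np.asarray(d["residual_mae"])
        return model


# The fitted regressor bank *is* the quality model.
QualityModel = DiceRegressorBank


@dataclass(frozen=True)
class QCResult:
    """Outcome of quality-controlled candidate selection for one image."""

    selected_index: int
    selected_provenance: str
    predicted_dsc: float
    pass_flag: bool
    predictions: np.ndarray
    observed_dsc: float | None = None
    outcome: str | None = None


def fit_quality_model(
    validation_candidates: Sequence[tuple[CandidateSet, AgreementMatrix, np.ndarray]],
    ridge_alpha: float = 1e-3,
) -> QualityModel:
    """Fit the per-candidate regressors on validation images with ground truth."""
    matrices = [m for _, m, _ in validation_candidates]
    targets = np.asarray([
        [dice(mask, gt) for mask in cs.masks]
        for cs, _, gt in validation_candidates
    ])
    return DiceRegressorBank(ridge_alpha=ridge_alpha).fit(matrices, targets)


def predict_quality(model: QualityModel,
                    matrix: AgreementMatrix) -> np.ndarray:
    """Per-candidate predicted Dice in [0, 1]."""
    return model.predict(matrix)


def select_best(predictions: np.ndarray, threshold: float = 0.7,
                candidates: CandidateSet | None = None,
                ground_truth: np.ndarray | None = None) -> QCResult:
    """Select the candidate with the highest predicted Dice.

    Ties break to the lowest candidate index.  With ground truth (evaluation
    only) the observed Dice of the *selected* candidate is computed and the
    prediction classified as TP/TN/FP/FN against the threshold.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    idx = int(np.argmax(predictions))
    pred = float(predictions[idx])
    pass_flag = pred >= threshold
    prov = candidates.provenance[idx] if candidates is not None else f"cand:{idx}"

    observed = outcome = None
    if ground_truth is not None:
        if candidates is None:
            raise ValueError("ground_truth requires the candidate set")
        observed = dice(candidates.masks[idx], ground_truth)
        good = observed >= threshold
        outcome = {(True, True): "TP", (False, False): "TN",
                   (True, False): "FP", (False, True): "FN"}[(pass_flag, good)]
    return QCResult(selected_index=idx, selected_provenance=prov,
                    predicted_dsc=pred, pass_flag=pass_flag,
                    predictions=predictions, observed_dsc=observed,
                    outcome=outcome)
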