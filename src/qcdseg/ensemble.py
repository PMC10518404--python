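"""Segmentation ensemble: encoder-decoder networks of depth 1..D.

The ensemble deliberately varies network depth (receptive field and capacity)
to obtain *diverse* single candidate segmentations of the LV myocardium; the
diversity is what the downstream agreement-based quality predictor exploits.
Each member is trained independently with categorical cross-entropy, Adam and
validation-loss early stopping.

``UNetSegmenter`` wraps one network as a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``); ``train_ensemble`` / ``predict_scs``
are thin functional wrappers used by the pipeline and CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .nn import UNet, TrainingLog, train_network
from .phantom import PhantomSample

__all__ = [
    "NetworkSpec", "TrainingConfig", "EnsembleBundle", "UNetSegmenter",
    "preprocess", "build_network", "train_ensemble", "predict_scs",
    "default_dropout_schedule",
]


def default_dropout_schedule(depth: int, start: float = 0.05,
                             stop: float = 0.5) -> tuple[float, ...]:
    """Linear ramp of dropout rates from the first to the deepest level."""
    return tuple(float(r) for r in np.linspace(start, stop, depth))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one ensemble member."""

    depth: int
    base_filters: int = 8
    dropout_schedule: tuple[float, ...] | None = None
    n_classes: int = 2
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^depth = {2 ** self.depth}"
            )
        sched = self.dropout_schedule
        if sched is None:
            object.__setattr__(self, "dropout_schedule",
                               default_dropout_schedule(self.depth))
            sched = self.dropout_schedule
        if len(sched) != self.depth:
            raise ValueError(
                f"dropout_schedule needs {self.depth} entries, got {len(sched)}"
            )
        if any(not 0.0 <= r < 1.0 for r in sched):
            raise ValueError("dropout rates must be in [0, 1)")
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError("dropout_schedule must be non-decreasing")


@dataclass(frozen=True)
class TrainingConfig:
    """Shared optimisation settings for every ensemble member."""

    learning_rate: float = 5e-5
    max_epochs: int = 200
    optimizer: str = "adam"
    loss: str = "categorical_cross_entropy"
    early_stop_patience: int = 10
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


def preprocess(image_raw: np.ndarray, target_size: int = 64):
    """Min-max scale to [0, 1] and zero-pad symmetrically to a square grid.

    A constant image maps to all zeros.  Padding is centred with the extra
    pixel (odd difference) on the trailing side, i.e. the leading offset is
    ``floor((target - n) / 2)``.

    Returns ``(image, (offset_y, offset_x))`` so masks can be un-padded.
    """
    img = np.asarray(image_raw, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    h, w = img.shape
    if h > target_size or w > target_size:
        raise ValueError(
            f"input {img.shape} exceeds target size {target_size}; "
            "cropping is not supported"
        )
    lo, hi = img.min(), img.max()
    img = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    off_y, off_x = (target_size - h) // 2, (target_size - w) // 2
    out = np.zeros((target_size, target_size), dtype=np.float64)
    out[off_y:off_y + h, off_x:off_x + w] = img
    return out, (off_y, off_x)


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet:
    """Instantiate an untrained network from its spec."""
    return UNet(depth=spec.depth, base_filters=spec.base_filters,
                dropout_schedule=list(spec.dropout_schedule),
                n_classes=spec.n_classes, input_size=spec.input_size,
                seed=seed)


class UNetSegmenter(BaseEstimator):
    """One encoder-decoder segmentation network as an sklearn-style estimator.

    Parameters mirror :class:`NetworkSpec` and :class:`TrainingConfig`.

    Attributes
    ----------
    net_ : the trained :class:`~qcdseg.nn.UNet`
    log_ : :class:`~qcdseg.nn.TrainingLog` with loss curves and best epoch
    """

    def __init__(self, depth: int = 3, base_filters: int = 8,
                 dropout_schedule: tuple[float, ...] | None = None,
                 n_classes: int = 2, input_size: int = 64,
                 learning_rate: float = 5e-5, max_epochs: int = 200,
                 early_stop_patience: int = 10, batch_size: int = 8,
                 seed: int = 0):
        self.depth = depth
        self.base_filters = base_filters
        self.dropout_schedule = dropout_schedule
        self.n_classes = n_classes
        self.input_size = input_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.seed = seed

    @property
    def spec(self) -> NetworkSpec:
        return NetworkSpec(depth=self.depth, base_filters=self.base_filters,
                           dropout_schedule=self.dropout_schedule,
                           n_classes=self.n_classes,
                           input_size=self.input_size)

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "UNetSegmenter":
        """Train on image stack X (n, H, W) with integer label maps y."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X_val is None:
            X_val, y_val = X, y
        spec = self.spec
        self.net_ = build_network(spec, seed=self.seed)
        self.log_ = train_network(
            self.net_, X, y, np.asarray(X_val, np.float32),
            np.asarray(y_val, np.int64),
            lr=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.early_stop_patience, batch_size=self.batch_size,
            seed=self.seed + 1,
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Binary myocardium masks (n, H, W) by per-pixel argmax."""
        self._check_input(X)
        out = []
        for i in range(0, len(X), self.batch_size):
            out.append(self.net_.predict_mask(
                np.asarray(X[i:i + self.batch_size], np.float32)))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_input(X)
        out = []
        for i in range(0, len(X), self.batch_size):
            out.append(self.net_.predict_proba(
                np.asarray(X[i:i + self.batch_size], np.float32)))
        return np.concatenate(out, axis=0)

    def _check_input(self, X: np.ndarray) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        s = self.input_size
        if X.ndim != 3 or X.shape[1] != s or X.shape[2] != s:
            raise ValueError(
                f"expected images of shape (n, {s}, {s}), got {X.shape}"
            )


@dataclass
class EnsembleBundle:
    """Depth-ascending, independently trained ensemble with provenance.

    The member order is fixed and persisted: candidate identity (and hence
    the quality regressors' feature layout) depends on it.
    """

    members: list[UNetSegmenter]
    config: TrainingConfig
    data_hash: str = ""
    train_patients: frozenset[str] = frozenset()
    val_patients: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        depths = [m.depth for m in self.members]
        if len(set(depths)) != len(depths):
            raise ValueError(f"member depths must be distinct, got {depths}")
        if depths != sorted(depths):
            raise ValueError(f"members must be depth-ascending, got {depths}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def input_size(self) -> int:
        return self.members[0].input_size

    @property
    def epochs_run(self) -> list[int]:
        return [m.log_.epochs_run for m in self.members]

    def predict_scs(self, image: np.ndarray) -> list[np.ndarray]:
        return predict_scs(self, image)

    # -- persistence ---------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.__dict__ | {"hash": self.config.hash()},
            "data_hash": self.data_hash,
            "train_patients": sorted(self.train_patients),
            "val_patients": sorted(self.val_patients),
            "members": [],
        }
        for i, m in enumerate(self.members):
            np.savez(out / f"model_{i}.npz", **m.net_.get_state())
            meta["members"].append({
                "params": m.get_params(),
                "epochs_run": m.log_.epochs_run,
                "best_epoch": m.log_.best_epoch,
            })
        (out / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "EnsembleBundle":
        src = Path(in_dir)
        meta = json.loads((src / "bundle.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d.pop("hash", None)
        members = []
        for i, m_meta in enumerate(meta["members"]):
            params = dict(m_meta["params"])
            if params.get("dropout_schedule") is not None:
                params["dropout_schedule"] = tuple(params["dropout_schedule"])
            est = UNetSegmenter(**params)
            est.net_ = build_network(est.spec, seed=est.seed)
            with np.load(src / f"model_{i}.npz") as st:
                est.net_.set_state(dict(st))
            est.log_ = TrainingLog(epochs_run=m_meta["epochs_run"],
                                   best_epoch=m_meta["best_epoch"])
            members.append(est)
        return cls(members=members, config=TrainingConfig(**cfg_d),
                   data_hash=meta["data_hash"],
                   train_patients=frozenset(meta["train_patients"]),
                   val_patients=frozenset(meta["val_patients"]))


def _samples_to_arrays(samples: Sequence[PhantomSample], input_size: int):
    imgs, masks = [], []
    for s in samples:
        img, (oy, ox) = preprocess(s.image, input_size)
        m = np.zeros((input_size, input_size), dtype=np.int64)
        h, w = s.mask.shape
        m[oy:oy + h, ox:ox + w] = s.mask
        imgs.append(img)
        masks.append(m)
    return np.asarray(imgs, np.float32), np.asarray(masks, np.int64)


def data_fingerprint(samples: Sequence[PhantomSample]) -> str:
    keys = sorted((s.patient_id, s.slice_index, s.mode) for s in samples)
    return hashlib.sha1(repr(keys).encode()).hexdigest()[:12]


def train_ensemble(samples_train: Sequence[PhantomSample],
                   samples_val: Sequence[PhantomSample],
                   specs: Sequence[NetworkSpec],
                   cfg: TrainingConfig) -> EnsembleBundle:
    """Train one network per spec, independently, with a shared config.

    Refuses train/validation patient overlap (data-leak guard).
    """
    if not samples_train or not samples_val:
        raise ValueError("train and validation sets must be non-empty")
    train_pat = {s.patient_id for s in samples_train}
    val_pat = {s.patient_id for s in samples_val}
    leak = train_pat & val_pat
    if leak:
        raise ValueError(
            f"patient leakage between train and validation: {sorted(leak)[:5]}"
        )
    input_size = specs[0].input_size
    if any(sp.input_size != input_size for sp in specs):
        raise ValueError("all specs must share input_size")
    x_tr, y_tr = _samples_to_arrays(samples_train, input_size)
    x_va, y_va = _samples_to_arrays(samples_val, input_size)

    members = []
    for i, sp in enumerate(sorted(specs, key=lambda s: s.depth)):
        est = UNetSegmenter(
            depth=sp.depth, base_filters=sp.base_filters,
            dropout_schedule=sp.dropout_schedule, n_classes=sp.n_classes,
            input_size=sp.input_size, learning_rate=cfg.learning_rate,
            max_epochs=cfg.max_epochs,
            early_stop_patience=cfg.early_stop_patience,
            batch_size=cfg.batch_size, seed=cfg.seed + 1000 * (i + 1),
        )
        est.fit(x_tr, y_tr, x_va, y_va)
        members.append(est)
    return EnsembleBundle(
        members=members, config=cfg,
        data_hash=data_fingerprint(list(samples_train) + list(samples_val)),
        train_patients=frozenset(train_pat), val_patients=frozenset(val_pat),
    )


def predict_scs(bundle: EnsembleBundle, image: np.ndarray) -> list[np.ndarray]:
    """One binary mask per ensemble member, in bundle (depth-ascending) order.

    The image must already be preprocessed: values in [0, 1], padded to the
    ensemble's input size.
    """
    s = bundle.input_size
    if image.shape != (s, s):
        raise ValueError(
            f"expected a preprocessed image of shape ({s}, {s}), got {image.shape}"
        )
    batch = image[None].astype(np.float32)
    return [m.predict(batch)[0] for m in bundle.members]
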