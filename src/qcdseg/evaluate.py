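"""Evaluation protocol: accuracy, quality-prediction error, QC accuracy,
and the train/test contrast-crossing experiment grid.

For every test image the full pipeline is run (preprocess -> single
candidates -> rank-filter fusion -> agreement matrix -> predicted Dice ->
selection), the selected candidate is compared with ground truth, and the
aggregate report carries:

* mean Dice +/- population s.d. of the selected segmentations,
* MAE +/- s.d. of |predicted - observed| Dice on the selected candidate,
* binary QC accuracy and the TP/TN/FP/FN confusion at the quality threshold,
* per-contrast-mode subgroup breakdowns and a Wilcoxon signed-rank p-value
  across modes (paired by anatomy when both modes of a slice are present,
  rank-sum fallback otherwise).

The experiment grid crosses training-set composition (one mode, the other,
or both) with test-set composition, for both the deepest single network and
the quality-controlled ensemble, all cells sharing one patient-level split.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .ensemble import (EnsembleBundle, NetworkSpec, TrainingConfig,
                       predict_scs, preprocess, train_ensemble)
from .fusion import agreement_matrix, build_candidate_set, dice
from .phantom import PhantomSample, partition_cohort
from .quality import QualityModel, fit_quality_model, select_best

__all__ = ["EvalReport", "ExperimentGrid", "evaluate_framework",
           "evaluate_single_model", "run_experiment_grid",
           "candidate_triples"]

MODE_BOTH = "both"


@dataclass
class EvalReport:
    """Aggregate evaluation of one method on one test set."""

    mean_dsc: float
    sd_dsc: float
    n_images: int
    mae: float | None = None
    sd_mae: float | None = None
    binary_accuracy: float | None = None
    confusion: dict[str, int] | None = None
    per_mode: dict[str, dict[str, float]] = field(default_factory=dict)
    wilcoxon_p: float | None = None

    def __post_init__(self) -> None:
        if self.confusion is not None:
            total = sum(self.confusion.values())
            if total != self.n_images:
                raise ValueError(
                    f"confusion counts {self.confusion} do not sum to "
                    f"n_images={self.n_images}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def _pad_mask(mask: np.ndarray, offsets: tuple[int, int],
              size: int) -> np.ndarray:
    out = np.zeros((size, size), dtype=np.uint8)
    h, w = mask.shape
    out[offsets[0]:offsets[0] + h, offsets[1]:offsets[1] + w] = mask
    return out


def _check_disjoint(bundle: EnsembleBundle,
                    test_samples: Sequence[PhantomSample]) -> None:
    test_pat = {s.patient_id for s in test_samples}
    leak = test_pat & (set(bundle.train_patients) | set(bundle.val_patients))
    if leak:
        raise ValueError(
            f"patient leakage between test and train/val: {sorted(leak)[:5]}"
        )


def _wilcoxon_across_modes(records: list[dict]) -> float | None:
    """Paired signed-rank test on observed Dice across the two contrast modes."""
    modes = sorted({r["mode"] for r in records})
    if len(modes) != 2:
        return None
    by_key: dict[tuple, dict[str, float]] = {}
    for r in records:
        by_key.setdefault((r["patient_id"], r["slice_index"]), {})[r["mode"]] = \
            r["observed"]
    a = [v[modes[0]] for v in by_key.values() if len(v) == 2]
    b = [v[modes[1]] for v in by_key.values() if len(v) == 2]
    try:
        if len(a) >= 5:
            if np.allclose(a, b):
                return 1.0
            return float(stats.wilcoxon(a, b).pvalue)
        ga = [r["observed"] for r in records if r["mode"] == modes[0]]
        gb = [r["observed"] for r in records if r["mode"] == modes[1]]
        return float(stats.mannwhitneyu(ga, gb).pvalue)
    except ValueError:
        return 1.0


def evaluate_framework(bundle: EnsembleBundle, quality_model: QualityModel,
                       test_samples: Sequence[PhantomSample],
                       threshold: float = 0.7) -> EvalReport:
    """Run the quality-controlled pipeline on a held-out test set."""
    if not test_samples:
        raise ValueError("test set is empty")
    _check_disjoint(bundle, test_samples)
    size = bundle.input_size
    records = []
    for s in test_samples:
        img, off = preprocess(s.image, size)
        gt = _pad_mask(s.mask, off, size)
        scs = predict_scs(bundle, img)
        cs = build_candidate_set(
            scs, image_ref=f"{s.patient_id}/s{s.slice_index}/{s.mode}")
        res = select_best(quality_model.predict(agreement_matrix(cs)),
                          threshold=threshold, candidates=cs, ground_truth=gt)
        records.append({
            "patient_id": s.patient_id, "slice_index": s.slice_index,
            "mode": s.mode, "observed": res.observed_dsc,
            "predicted": res.predicted_dsc, "outcome": res.outcome,
        })
    return _aggregate(records)


def _aggregate(records: list[dict]) -> EvalReport:
    obs = np.array([r["observed"] for r in records])
    err = np.array([abs(r["predicted"] - r["observed"]) for r in records])
    confusion = {k: sum(r["outcome"] == k for r in records)
                 for k in ("TP", "TN", "FP", "FN")}
    per_mode = {}
    for mode in sorted({r["mode"] for r in records}):
        o = np.array([r["observed"] for r in records if r["mode"] == mode])
        e = np.array([abs(r["predicted"] - r["observed"])
                      for r in records if r["mode"] == mode])
        good = sum(r["outcome"] in ("TP", "TN")
                   for r in records if r["mode"] == mode)
        per_mode[mode] = {
            "mean_dsc": float(o.mean()), "sd_dsc": float(o.std()),
            "mae": float(e.mean()),
            "binary_accuracy": good / len(o), "n_images": len(o),
        }
    return EvalReport(
        mean_dsc=float(obs.mean()), sd_dsc=float(obs.std()),
        n_images=len(records),
        mae=float(err.mean()), sd_mae=float(err.std()),
        binary_accuracy=(confusion["TP"] + confusion["TN"]) / len(records),
        confusion=confusion, per_mode=per_mode,
        wilcoxon_p=_wilcoxon_across_modes(records),
    )


def evaluate_single_model(bundle: EnsembleBundle,
                          test_samples: Sequence[PhantomSample],
                          member_index: int = -1) -> EvalReport:
    """Dice-only report for one ensemble member (default: the deepest).

    A single network has no quality-control arm, so MAE / accuracy /
    confusion are absent.
    """
    if not test_samples:
        raise ValueError("test set is empty")
    _check_disjoint(bundle, test_samples)
    size = bundle.input_size
    member = bundle.members[member_index]
    records = []
    for s in test_samples:
        img, off = preprocess(s.image, size)
        gt = _pad_mask(s.mask, off, size)
        pred = member.predict(img[None].astype(np.float32))[0]
        records.append({"patient_id": s.patient_id,
                        "slice_index": s.slice_index, "mode": s.mode,
                        "observed": dice(pred, gt)})
    obs = np.array([r["observed"] for r in records])
    per_mode = {
        mode: {
            "mean_dsc": float(np.mean([r["observed"] for r in records
                                       if r["mode"] == mode])),
            "n_images": sum(r["mode"] == mode for r in records),
        }
        for mode in sorted({r["mode"] for r in records})
    }
    return EvalReport(mean_dsc=float(obs.mean()), sd_dsc=float(obs.std()),
                      n_images=len(records), per_mode=per_mode,
                      wilcoxon_p=_wilcoxon_across_modes(records))


def candidate_triples(bundle: EnsembleBundle,
                      samples: Sequence[PhantomSample]):
    """(CandidateSet, AgreementMatrix, padded gt) per sample — the quality
    model's fitting input."""
    size = bundle.input_size
    triples = []
    for s in samples:
        img, off = preprocess(s.image, size)
        gt = _pad_mask(s.mask, off, size)
        cs = build_candidate_set(
            predict_scs(bundle, img),
            image_ref=f"{s.patient_id}/s{s.slice_index}/{s.mode}")
        triples.append((cs, agreement_matrix(cs), gt))
    return triples


@dataclass
class ExperimentGrid:
    """3x3 training-composition x test-composition grid of reports.

    ``cells[(train_comp, test_comp)]`` holds ``{"deepest": EvalReport,
    "qcd": EvalReport}``; every cell shares the same patient-level split.
    """

    cells: dict[tuple[str, str], dict[str, EvalReport]]
    compositions: tuple[str, ...]

    def to_markdown(self) -> str:
        lines = ["| Model | Training set | " +
                 " | ".join(f"{c}: DSC / MAE / Acc." for c in self.compositions) +
                 " |"]
        lines.append("|" + "---|" * (2 + len(self.compositions)))
        for method, label in (("deepest", "U-Net (deepest)"), ("qcd", "QCD")):
            for tr in self.compositions:
                cells = []
                for te in self.compositions:
                    r = self.cells[(tr, te)][method]
                    if r.mae is None:
                        cells.append(f"{r.mean_dsc:.3f} / — / —")
                    else:
                        cells.append(f"{r.mean_dsc:.3f} / {r.mae:.3f} / "
                                     f"{r.binary_accuracy:.3f}")
                lines.append(f"| {label} | {tr} | " + " | ".join(cells) + " |")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        payload = {
            "compositions": list(self.compositions),
            "cells": {f"{tr}|{te}": {k: asdict(v) for k, v in d.items()}
                      for (tr, te), d in self.cells.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentGrid":
        d = json.loads(Path(path).read_text())
        cells = {}
        for key, methods in d["cells"].items():
            tr, te = key.split("|")
            cells[(tr, te)] = {k: EvalReport(**v) for k, v in methods.items()}
        return cls(cells=cells, compositions=tuple(d["compositions"]))


def _filter_mode(samples: Sequence[PhantomSample], comp: str):
    if comp == MODE_BOTH:
        return list(samples)
    return [s for s in samples if s.mode == comp]


def run_experiment_grid(cohort: Sequence[PhantomSample],
                        specs: Sequence[NetworkSpec],
                        train_cfg: TrainingConfig,
                        threshold: float = 0.7,
                        fractions: tuple[float, float, float] = (0.85, 0.075, 0.075),
                        ) -> ExperimentGrid:
    """Cross training and test contrast compositions on one shared split.

    For each training composition the full pipeline (ensemble + quality
    regressors on the matching validation subset) is retrained from scratch
    with the same seed; each composition is then evaluated on every test
    composition, for both the deepest single network and the
    quality-controlled ensemble.
    """
    modes = sorted({s.mode for s in cohort})
    if len(modes) != 2:
        raise ValueError(
            f"experiment grid needs a dual-mode cohort, found modes {modes}"
        )
    train, val, test = partition_cohort(cohort, fractions=fractions,
                                        seed=train_cfg.seed)
    compositions = (*modes, MODE_BOTH)
    cells: dict[tuple[str, str], dict[str, EvalReport]] = {}
    for tr_comp in compositions:
        bundle = train_ensemble(_filter_mode(train, tr_comp),
                                _filter_mode(val, tr_comp), specs, train_cfg)
        qmodel = fit_quality_model(
            candidate_triples(bundle, _filter_mode(val, tr_comp)))
        for te_comp in compositions:
            te = _filter_mode(test, te_comp)
            cells[(tr_comp, te_comp)] = {
                "deepest": evaluate_single_model(bundle, te),
                "qcd": evaluate_framework(bundle, qmodel, te,
                                          threshold=threshold),
            }
    return ExperimentGrid(cells=cells, compositions=compositions)
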