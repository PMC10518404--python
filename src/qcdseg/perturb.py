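"""Synthetic candidate pools with known true Dice, for quality-model studies.

Builds candidate segmentations directly from a ground-truth mask by graded
morphological erosion/dilation plus random pixel flips — no networks
involved — so the true Dice of every candidate is known exactly.  This is the
calibration bench for the agreement-matrix quality regressors: it decouples
"can the regressors predict Dice from agreement?" from "how well did the
ensemble train?".

Severity is graded across the candidate positions (position 0 mildest), and
scaled per image by a random image-quality draw, a fraction of images being
badly degraded so that true Dice spans both sides of the 0.7 quality
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fusion import AgreementMatrix, CandidateSet, agreement_matrix, \
    build_candidate_set, dice
from .phantom import PhantomConfig, generate_phantom

__all__ = ["PerturbedImage", "perturb_mask", "perturbation_pool"]


@dataclass(frozen=True)
class PerturbedImage:
    """Candidate pool for one synthetic image with its ground truth."""

    candidates: CandidateSet
    matrix: AgreementMatrix
    gt_mask: np.ndarray

    @property
    def true_dice(self) -> np.ndarray:
        return np.asarray([dice(m, self.gt_mask) for m in self.candidates.masks])


def perturb_mask(gt: np.ndarray, severity: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Degrade a binary mask with morphology + pixel flips.

    ``severity`` >= 0: 0 leaves the mask intact; around 1 the result is
    typically below the 0.7 Dice bar for an annular mask a few pixels thick.
    """
    out = np.asarray(gt, dtype=bool)
    n_iter = int(np.floor(2.5 * severity))
    if n_iter > 0:
        if rng.random() < 0.5:
            out = ndimage.binary_erosion(out, iterations=n_iter)
        else:
            out = ndimage.binary_dilation(out, iterations=n_iter)
    flip_frac = 0.01 * severity
    if flip_frac > 0:
        flips = rng.random(out.shape) < flip_frac
        out = out ^ flips
    return out.astype(np.uint8)


def perturbation_pool(n_images: int, seed: int, n_scs: int = 6,
                      grid_size: int = 64,
                      bad_fraction: float = 0.25) -> list[PerturbedImage]:
    """Generate candidate pools over phantom ring masks.

    Per image an overall quality level q is drawn — good images
    q ~ U(0.05, 0.45), a ``bad_fraction`` of images q ~ U(0.75, 1.4) — and
    the i-th single candidate is the ground truth perturbed with severity
    q * (0.5 + 0.5 * (i + 1) / n_scs): graded across candidate positions,
    but floored at half the image level so a badly degraded image has *no*
    good candidate (true-negative QC cases exist).  Combined candidates are
    added by rank filtering, exactly as in the live pipeline.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = PhantomConfig(grid_size=grid_size, noise_sigma=0.0,
                        lesion_probability=0.0, seed=seed,
                        myo_radius_range=(grid_size / 8, grid_size / 5),
                        wall_thickness_range=(grid_size / 16, grid_size / 8),
                        center_jitter=grid_size / 16)
    pool = []
    for j in range(n_images):
        gt = generate_phantom(cfg, f"PB{j:05d}", 0, "LGE_like").mask
        if rng.random() < bad_fraction:
            q = rng.uniform(0.75, 1.4)
        else:
            q = rng.uniform(0.05, 0.45)
        scs = [perturb_mask(gt, q * (0.5 + 0.5 * (i + 1) / n_scs), rng)
               for i in range(n_scs)]
        cs = build_candidate_set(scs, image_ref=f"PB{j:05d}")
        pool.append(PerturbedImage(candidates=cs, matrix=agreement_matrix(cs),
                                   gt_mask=gt))
    return pool
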