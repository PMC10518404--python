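"""Synthetic short-axis cardiac phantoms with paired myocardium masks.

The generator emulates the statistical structure a dual-contrast myocardial
segmentation study relies on: each "patient slice" is a ring-shaped left
ventricular myocardium (dark wall) around a bright blood pool, optionally
carrying a hyperenhanced lesion sector, rendered in two contrast modes
(LGE-like and VNE-like) that share *identical* anatomy and therefore an
identical ground-truth mask.  Anatomy is a deterministic function of
``(seed, patient_id, slice_index)`` only — never of the contrast mode — so
the two modes form exact augmentation pairs, the way a contrast-free virtual
enhancement image pairs with its gadolinium counterpart.

A configurable fraction of patients are "hard cases": their myocardium/blood
contrast is degraded (intensities pulled toward each other) while the mask
stays valid, producing images segmenters genuinely fail on — needed to
exercise ground-truth-free quality control.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "LGE_LIKE",
    "VNE_LIKE",
    "PhantomConfig",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "partition_cohort",
    "save_cohort",
    "load_cohort",
]

LGE_LIKE = "LGE_like"
VNE_LIKE = "VNE_like"
_MODES = (LGE_LIKE, VNE_LIKE)

# Piecewise-constant intensity levels per contrast mode:
# (background, blood pool, myocardium wall, lesion sector).
_LEVELS = {
    LGE_LIKE: (0.15, 0.90, 0.25, 0.80),
    VNE_LIKE: (0.10, 0.80, 0.35, 0.75),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level generator settings.

    Parameters
    ----------
    grid_size : int
        Pixels per side of the square image grid.
    myo_radius_range : (float, float)
        Bounds for the sampled *inner* radius of the myocardial ring, px.
    wall_thickness_range : (float, float)
        Bounds for the sampled wall thickness, px; outer = inner + wall.
    lesion_probability : float
        Per-slice probability of a hyperenhanced lesion sector in [0, 1].
    lesion_arc_range : (float, float)
        Angular extent bounds of the lesion sector, degrees.
    noise_sigma : float
        Gaussian intensity noise s.d. on the [0, 1] scale.
    contrast_modes : tuple of str
        Ordered subset of {"LGE_like", "VNE_like"}.
    hard_case_fraction : float
        Fraction of patients rendered with degraded ring/pool contrast.
    seed : int
        Master seed; identical config + seed gives bit-identical cohorts.
    """

    grid_size: int = 64
    myo_radius_range: tuple[float, float] = (8.0, 13.0)
    wall_thickness_range: tuple[float, float] = (4.0, 8.0)
    lesion_probability: float = 0.3
    lesion_arc_range: tuple[float, float] = (40.0, 120.0)
    noise_sigma: float = 0.05
    contrast_modes: tuple[str, ...] = (LGE_LIKE, VNE_LIKE)
    hard_case_fraction: float = 0.15
    hard_contrast_blend: float = 0.72
    center_jitter: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        lo, hi = self.myo_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid myo_radius_range {self.myo_radius_range}")
        wlo, whi = self.wall_thickness_range
        if not (0 < wlo <= whi):
            raise ValueError(
                f"invalid wall_thickness_range {self.wall_thickness_range}"
            )
        if hi + whi + self.center_jitter >= self.grid_size / 2:
            raise ValueError(
                "outer radius can exceed grid_size/2: shrink radii/thickness "
                f"(max outer {hi + whi:.1f} + jitter {self.center_jitter:.1f} "
                f">= {self.grid_size / 2:.1f})"
            )
        for name in ("lesion_probability", "hard_case_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.contrast_modes:
            raise ValueError("contrast_modes must be non-empty")
        for m in self.contrast_modes:
            if m not in _MODES:
                raise ValueError(f"unknown contrast mode {m!r}; expected {_MODES}")


@dataclass(frozen=True)
class PhantomSample:
    """One 2-D slice: image in [0, 1], binary myocardium mask, identity tags."""

    image: np.ndarray
    mask: np.ndarray
    mode: str
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )


def _anatomy_rng(config: PhantomConfig, patient_id: str, slice_index: int,
                 salt: str = "anatomy") -> np.random.Generator:
    """RNG keyed by (seed, patient, slice) and *not* by mode.

    Hash-based so results are stable across processes and PYTHONHASHSEED.
    """
    h = hashlib.sha256(
        f"{salt}|{config.seed}|{patient_id}|{slice_index}".encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def _is_hard_patient(config: PhantomConfig, patient_id: str) -> bool:
    if config.hard_case_fraction <= 0:
        return False
    h = hashlib.sha256(
        f"hard|{config.seed}|{patient_id}".encode()
    ).digest()
    u = int.from_bytes(h[:8], "little") / 2.0**64
    return u < config.hard_case_fraction


def _sample_anatomy(config: PhantomConfig, patient_id: str, slice_index: int):
    rng = _anatomy_rng(config, patient_id, slice_index)
    c = config.grid_size / 2.0
    cy = c + rng.uniform(-config.center_jitter, config.center_jitter)
    cx = c + rng.uniform(-config.center_jitter, config.center_jitter)
    inner = rng.uniform(*config.myo_radius_range)
    outer = inner + rng.uniform(*config.wall_thickness_range)
    has_lesion = rng.uniform() < config.lesion_probability
    lesion_start = rng.uniform(0.0, 360.0)
    lesion_arc = rng.uniform(*config.lesion_arc_range)
    return cy, cx, inner, outer, has_lesion, lesion_start, lesion_arc


def annulus_mask(grid_size: int, cy: float, cx: float,
                 inner: float, outer: float) -> np.ndarray:
    """Analytic ring membership: inner <= pixel-center distance < outer."""
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return ((d >= inner) & (d < outer)).astype(np.uint8)


def generate_phantom(config: PhantomConfig, patient_id: str,
                     slice_index: int, mode: str) -> PhantomSample:
    """Render one phantom slice in the requested contrast mode.

    Anatomy (center, radii, lesion geometry) depends only on
    ``(config.seed, patient_id, slice_index)``; the two contrast modes differ
    in base intensity levels and in the noise realisation.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown contrast mode {mode!r}; expected one of {_MODES}")
    n = config.grid_size
    cy, cx, inner, outer, has_lesion, lesion_start, lesion_arc = _sample_anatomy(
        config, patient_id, slice_index
    )

    yy, xx = np.mgrid[0:n, 0:n]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    pool = d < inner
    ring = (d >= inner) & (d < outer)

    bg, pool_i, myo_i, lesion_i = _LEVELS[mode]
    if _is_hard_patient(config, patient_id):
        # Degrade contrast: pull pool and wall intensities toward their mean.
        mid = 0.5 * (pool_i + myo_i)
        b = config.hard_contrast_blend
        pool_i = (1 - b) * pool_i + b * mid
        myo_i = (1 - b) * myo_i + b * mid

    image = np.full((n, n), bg, dtype=np.float64)
    image[pool] = pool_i
    image[ring] = myo_i
    if has_lesion:
        theta = (np.degrees(np.arctan2(yy - cy, xx - cx)) - lesion_start) % 360.0
        lesion = ring & (theta < lesion_arc)
        image[lesion] = lesion_i

    if config.noise_sigma > 0:
        noise_rng = _anatomy_rng(config, patient_id, slice_index,
                                 salt=f"noise|{mode}")
        image = image + noise_rng.normal(0.0, config.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return PhantomSample(
        image=image,
        mask=ring.astype(np.uint8),
        mode=mode,
        patient_id=patient_id,
        slice_index=slice_index,
    )


def generate_cohort(config: PhantomConfig, n_patients: int,
                    slices_per_patient: int) -> list[PhantomSample]:
    """Generate ``n_patients * slices_per_patient`` samples per contrast mode.

    Hard patients (degraded contrast) are an exact, deterministically chosen
    subset: ``round(hard_case_fraction * n_patients)`` patients, nearest
    integer with halves rounded up.
    """
    if n_patients < 1 or slices_per_patient < 1:
        raise ValueError("n_patients and slices_per_patient must be >= 1")
    patient_ids = [f"P{idx:04d}" for idx in range(n_patients)]

    n_hard = int(np.floor(config.hard_case_fraction * n_patients + 0.5))
    order = np.random.default_rng(
        _anatomy_rng(config, "cohort", 0, salt="hardpick").integers(2**31)
    ).permutation(n_patients)
    hard_ids = {patient_ids[i] for i in order[:n_hard]}

    samples: list[PhantomSample] = []
    for pid in patient_ids:
        # Force the cohort-level hard flag by overriding the per-patient draw:
        # patients in hard_ids get hard_case_fraction=1, others 0.
        cfg_p = replace(config,
                        hard_case_fraction=1.0 if pid in hard_ids else 0.0)
        for s in range(slices_per_patient):
            for mode in config.contrast_modes:
                samples.append(generate_phantom(cfg_p, pid, s, mode))
    return samples


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return counts


def partition_cohort(
    samples: Sequence[PhantomSample],
    fractions: tuple[float, float, float] = (0.85, 0.075, 0.075),
    seed: int = 0,
) -> tuple[list[PhantomSample], list[PhantomSample], list[PhantomSample]]:
    """Patient-level train/validation/test split.

    All slices and all contrast modes of a patient land in the same split;
    patient counts per split follow largest-remainder rounding of the
    requested fractions after a seeded patient shuffle.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be a (train, val, test) triple")
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 3:
        raise ValueError(
            f"need >= 3 patients to populate train/val/test, got {len(patients)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = [patients[i] for i in rng.permutation(len(patients))]
    counts = _largest_remainder(len(patients), fractions)
    if any(c == 0 for c in counts):
        raise ValueError(
            f"fractions {fractions} leave an empty split for {len(patients)} patients"
        )
    cut1, cut2 = counts[0], counts[0] + counts[1]
    split_of = {}
    for i, pid in enumerate(shuffled):
        split_of[pid] = 0 if i < cut1 else (1 if i < cut2 else 2)
    out: tuple[list, list, list] = ([], [], [])
    for s in samples:
        out[split_of[s.patient_id]].append(s)
    return out


# ---------------------------------------------------------------------------
# Disk I/O: PNG image/mask pairs plus a CSV manifest.

def save_cohort(samples: Sequence[PhantomSample], out_dir: str | Path,
                splits: dict[str, str] | None = None) -> Path:
    """Write 16-bit PNG image/mask pairs and a CSV manifest; returns manifest path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "slice_index", "mode", "split",
                    "image_path", "mask_path"])
        for s in samples:
            stem = f"{s.patient_id}_s{s.slice_index:03d}_{s.mode}"
            img_path = out / f"{stem}_img.png"
            msk_path = out / f"{stem}_msk.png"
            iio.imwrite(img_path, np.round(s.image * 65535).astype(np.uint16))
            iio.imwrite(msk_path, (s.mask * 255).astype(np.uint8))
            split = (splits or {}).get(s.patient_id, "")
            w.writerow([s.patient_id, s.slice_index, s.mode, split,
                        img_path.name, msk_path.name])
    return manifest


def load_cohort(manifest: str | Path) -> list[PhantomSample]:
    """Read samples back from a manifest written by :func:`save_cohort`."""
    import imageio.v3 as iio

    root = Path(manifest).parent
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = iio.imread(root / row["image_path"]).astype(np.float64) / 65535.0
            mask = (iio.imread(root / row["mask_path"]) > 127).astype(np.uint8)
            samples.append(PhantomSample(
                image=image, mask=mask, mode=row["mode"],
                patient_id=row["patient_id"],
                slice_index=int(row["slice_index"]),
            ))
    return samples
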