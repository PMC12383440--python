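"""Volume-to-slice preprocessing: percentile gray-level adjustment, tumor-slice
selection, task-mask derivation, resizing/normalization, and jittered bounding-box
prompt construction.

The pipeline turns 3-D multi-modal volumes into 2-D model-ready samples: voxel
intensities are clamped to the [low, high] percentile band and rescaled to
[0, gray_max]; slices containing the task's tumor region are extracted along Z;
each modality slice is resized to the model resolution, normalized to [0, 1],
and replicated to three channels; the ground-truth mask yields an outward-jittered
bounding-box prompt.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage.transform import resize

from .phantom import ModalityStack

TASKS = ("WT", "TC", "ET")

# composition of the three binary tasks from the label codes, following the
# concentric convention: whole tumor = necrosis + edema + enhancing,
# tumor core = necrosis + enhancing, enhancing tumor alone.
TASK_CODES = {"WT": (1, 2, 3), "TC": (1, 3), "ET": (3,)}


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    low_pct: float = 0.5
    high_pct: float = 99.5
    gray_max: float = 255.0
    model_size: int = 1024
    bbox_jitter_max: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.low_pct < self.high_pct <= 100):
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.model_size <= 0:
            raise ValueError("model_size must be positive")
        if self.bbox_jitter_max < 0:
            raise ValueError("bbox_jitter_max must be nonnegative")


@dataclasses.dataclass
class SliceRecord:
    """One 2-D training/evaluation sample at model resolution."""

    subject_id: str
    z_index: int
    task: str
    modality_images: np.ndarray  # (n_modalities, 3, S, S) in [0, 1]
    gt_mask: np.ndarray          # (S, S) uint8 binary
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), 0-based inclusive

    def validate(self) -> None:
        n, c, s1, s2 = self.modality_images.shape
        if c != 3 or s1 != s2:
            raise ValueError("modality images must be (n, 3, S, S)")
        if self.gt_mask.shape != (s1, s2):
            raise ValueError("mask resolution mismatch")
        if self.modality_images.min() < 0 or self.modality_images.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.gt_mask.sum() == 0:
            raise ValueError("gt_mask must be nonempty")
        x0, y0, x1, y1 = self.bbox
        if not (0 <= x0 <= x1 < s2 and 0 <= y0 <= y1 < s1):
            raise ValueError(f"bbox {self.bbox} outside image bounds")
        tx0, ty0, tx1, ty1 = tight_bbox(self.gt_mask)
        if not (x0 <= tx0 and y0 <= ty0 and x1 >= tx1 and y1 >= ty1):
            raise ValueError("bbox does not contain the tight mask box")


def clip_rescale(volume: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Clamp intensities to the [low_pct, high_pct] percentile band and rescale
    the band affinely to [0, gray_max].

    Percentiles are computed with linear interpolation over *all* voxels of the
    volume, background included.  A constant volume has a degenerate band and is
    mapped to all zeros with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    lo, hi = np.percentile(volume, [config.low_pct, config.high_pct])
    if hi <= lo:
        warnings.warn("constant percentile band; returning all-zero volume")
        return np.zeros_like(volume)
    clipped = np.clip(volume, lo, hi)
    return (clipped - lo) * (config.gray_max / (hi - lo))


def derive_task_mask(labels: np.ndarray, task: str) -> np.ndarray:
    """Binary mask of the task's sub-region (WT ⊇ TC ⊇ ET) from label codes."""
    if task not in TASK_CODES:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    labels = np.asarray(labels)
    bad = set(np.unique(labels).tolist()) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"unknown label code(s) {sorted(bad)}")
    return np.isin(labels, TASK_CODES[task]).astype(np.uint8)


def select_tumor_slices(stack: ModalityStack, task: str) -> list[int]:
    """Ascending z indices whose task mask has at least one positive voxel."""
    mask3d = derive_task_mask(stack.labels, task)
    return np.flatnonzero(mask3d.any(axis=(1, 2))).tolist()


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(x0, y0, x1, y1) tight box of a nonempty binary mask, inclusive corners."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())


def make_bbox_prompt(mask: np.ndarray, config: PreprocessConfig,
                     rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Tight box of the mask, each side pushed outward by an independent
    uniform integer in [0, bbox_jitter_max], clamped to image bounds.

    Outward-only jitter keeps the prompt a superset of the tight box, so the
    perturbation never hides tumor from the decoder.
    """
    x0, y0, x1, y1 = tight_bbox(mask)
    h, w = mask.shape
    j = rng.integers(0, config.bbox_jitter_max + 1, size=4)
    return (
        max(0, x0 - int(j[0])),
        max(0, y0 - int(j[1])),
        min(w - 1, x1 + int(j[2])),
        min(h - 1, y1 + int(j[3])),
    )


def to_model_input(slice_images: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Resize each modality slice to model_size², scale to [0, 1], replicate to
    3 channels.  Bilinear resampling; non-square inputs are stretched
    anisotropically to the single fixed model resolution.
    """
    slice_images = np.asarray(slice_images, dtype=np.float64)
    n = slice_images.shape[0]
    s = config.model_size
    out = np.empty((n, 3, s, s), dtype=np.float32)
    for m in range(n):
        img = resize(slice_images[m], (s, s), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        img = np.clip(img / config.gray_max, 0.0, 1.0)
        out[m] = img[None, :, :]
    return out


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour mask resize to size², preserving binarity."""
    out = resize(mask.astype(np.uint8), (size, size), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def build_slice_dataset(cohort: list[ModalityStack], task: str,
                        config: PreprocessConfig) -> list[SliceRecord]:
    """Full per-subject pipeline: clip/rescale each modality volume, select
    tumor slices for the task, derive masks, resize, and build jittered prompts.

    Deterministic given (cohort, config, config.seed).  Slices whose mask
    becomes empty after resizing to model resolution are dropped.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(config.seed)
    records: list[SliceRecord] = []
    for stack in cohort:
        rescaled = np.stack([clip_rescale(vol, config) for vol in stack.images])
        z_indices = select_tumor_slices(stack, task)
        for z in z_indices:
            gt = resize_mask(derive_task_mask(stack.labels[z], task), config.model_size)
            if gt.sum() == 0:
                continue
            images = to_model_input(rescaled[:, z], config)
            bbox = make_bbox_prompt(gt, config, rng)
            rec = SliceRecord(stack.subject_id, z, task, images, gt, bbox)
            rec.validate()
            records.append(rec)
    return records


def save_slice_dataset(records: list[SliceRecord], out_dir: str) -> None:
    """Cache a slice dataset as compressed arrays plus a CSV manifest."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        np.savez_compressed(
            os.path.join(out_dir, f"slice_{i:05d}.npz"),
            modality_images=rec.modality_images, gt_mask=rec.gt_mask,
        )
        x0, y0, x1, y1 = rec.bbox
        rows.append(dict(idx=i, subject_id=rec.subject_id, z=rec.z_index,
                         task=rec.task, x0=x0, y0=y0, x1=x1, y1=y1))
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)


def load_slice_dataset(in_dir: str) -> list[SliceRecord]:
    import os

    import pandas as pd

    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    records = []
    for row in manifest.itertuples():
        data = np.load(os.path.join(in_dir, f"slice_{row.idx:05d}.npz"))
        records.append(SliceRecord(
            row.subject_id, int(row.z), row.task,
            data["modality_images"], data["gt_mask"],
            (int(row.x0), int(row.y0), int(row.x1), int(row.y1)),
        ))
    return records
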