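"""Synthetic multi-modal brain-tumor phantoms.

Each phantom subject is a stack of co-registered 3-D modality volumes plus a
label volume with the concentric lesion convention used by glioma challenge
datasets: an edema-like shell (code 2) around a core, whose non-enhancing part
is a necrosis analog (code 1) and whose innermost part is an enhancing-tumor
analog (code 3).  The three nested regions are smoothly deformed spheres; each
modality lights the regions according to a contrast matrix, so that e.g. a
FLAIR-like modality carries the whole-lesion signal while a T1gd-like modality
exclusively carries the core/enhancing signal.  This reproduces, in miniature,
the modality-specific information structure that multi-modal fusion and
missing-modality experiments probe.
"""

from __future__ import annotations

import dataclasses
import os
import warnings

import numpy as np

#: label codes
BACKGROUND, NCR, ED, ET = 0, 1, 2, 3

#: default modality names, mirroring the structural MRI sequences the
#: contrast rows are modeled after
DEFAULT_MODALITIES = ("T1", "T1gd", "T2", "FLAIR")

# rows: (whole, core, enhancing) additive contrast per modality.  T1gd is the
# only modality with core/enhancing contrast; FLAIR dominates the whole-lesion
# contrast — the modality-importance structure the robustness experiments need.
DEFAULT_CONTRAST = np.array(
    [
        [0.15, 0.00, 0.00],   # T1-like: faint whole-lesion signal
        [0.00, 0.45, 0.35],   # T1gd-like: core + extra enhancing signal
        [0.35, 0.00, 0.00],   # T2-like: moderate whole-lesion signal
        [0.80, 0.00, 0.00],   # FLAIR-like: bright whole lesion
    ]
)


class InvalidSpecError(ValueError):
    """Raised when a PhantomSpec violates its invariants."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise description of a synthetic cohort.

    ``region_radii`` are the mean radii (voxels) of the whole-lesion, core and
    enhancing regions; they must be strictly decreasing and fit in the volume.
    ``deform_amplitude`` is the maximal radial boundary perturbation in voxels;
    values up to 25% of the smallest inter-region radius gap are safe for
    nesting (larger values raise).
    """

    n_modalities: int = 4
    volume_shape: tuple[int, int, int] = (32, 48, 48)
    region_radii: tuple[float, float, float] = (14.0, 8.0, 4.0)
    contrast_matrix: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_CONTRAST.copy()
    )
    background_level: float = 0.15
    noise_sd: float = 0.04
    deform_amplitude: float = 1.0
    modality_names: tuple[str, ...] = DEFAULT_MODALITIES
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "contrast_matrix", np.asarray(self.contrast_matrix, dtype=float))
        self.validate()

    @property
    def max_safe_deform(self) -> float:
        rw, rc, re = self.region_radii
        return 0.25 * min(rw - rc, rc - re)

    def validate(self) -> None:
        rw, rc, re = self.region_radii
        if not (rw > rc > re > 0):
            raise InvalidSpecError(f"radii must be strictly decreasing and positive, got {self.region_radii}")
        if 2 * rw >= min(self.volume_shape) - 2:
            raise InvalidSpecError(
                f"whole-region diameter {2 * rw} does not fit inside volume {self.volume_shape}"
            )
        cm = self.contrast_matrix
        if cm.shape != (self.n_modalities, 3):
            raise InvalidSpecError(f"contrast_matrix must be ({self.n_modalities}, 3), got {cm.shape}")
        if cm.min() < 0 or cm.max() > 1:
            raise InvalidSpecError("contrast values must lie in [0, 1]")
        if not 0 <= self.background_level <= 1:
            raise InvalidSpecError("background_level must lie in [0, 1]")
        if self.noise_sd < 0 or self.deform_amplitude < 0:
            raise InvalidSpecError("noise_sd and deform_amplitude must be nonnegative")
        if self.deform_amplitude > self.max_safe_deform:
            raise InvalidSpecError(
                f"deform_amplitude {self.deform_amplitude} exceeds the nesting-safe bound "
                f"{self.max_safe_deform:.3f} (25% of smallest radius gap)"
            )
        if len(self.modality_names) != self.n_modalities:
            raise InvalidSpecError("modality_names length must equal n_modalities")


@dataclasses.dataclass
class ModalityStack:
    """One subject: aligned modality volumes plus a lesion label volume."""

    subject_id: str
    images: np.ndarray  # (n_modalities, D, H, W), nonnegative
    labels: np.ndarray  # (D, H, W), codes {0,1,2,3}
    modality_names: tuple[str, ...]

    def validate(self) -> None:
        if self.images.ndim != 4:
            raise ValueError("images must be (n_modalities, D, H, W)")
        if self.images.shape[1:] != self.labels.shape:
            raise ValueError("images and labels must share the volume shape")
        codes = np.unique(self.labels)
        if not set(codes.tolist()) <= {BACKGROUND, NCR, ED, ET}:
            raise ValueError(f"unexpected label codes {codes}")
        if self.images.min() < 0:
            raise ValueError("image intensities must be nonnegative")
        if len(self.modality_names) != self.images.shape[0]:
            raise ValueError("modality_names length mismatch")

    def modality_index(self, name: str) -> int:
        return self.modality_names.index(name)


# angular basis: the l=1 and l=2 real spherical harmonics written in the
# Cartesian components of the unit direction; smooth, cheap to evaluate.
def _angular_basis(ux, uy, uz):
    return np.stack(
        [ux, uy, uz, ux * uy, ux * uz, uy * uz, ux * ux - uy * uy, 3 * uz * uz - 1.0],
        axis=0,
    )


def _region_masks(spec: PhantomSpec, rng: np.random.Generator,
                  radii: tuple[float, float, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean supports of whole ⊃ core ⊃ enhancing, smoothly deformed."""
    d, h, w = spec.volume_shape
    cz, cy, cx = (d - 1) / 2.0, (h - 1) / 2.0, (w - 1) / 2.0
    zz, yy, xx = np.meshgrid(
        np.arange(d) - cz, np.arange(h) - cy, np.arange(w) - cx, indexing="ij"
    )
    r = np.sqrt(zz * zz + yy * yy + xx * xx)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, xx / r, 0.0)
        uy = np.where(r > 0, yy / r, 0.0)
        uz = np.where(r > 0, zz / r, 1.0)
    basis = _angular_basis(ux, uy, uz)

    masks = []
    for radius in radii:
        coeffs = rng.normal(size=basis.shape[0])
        pert = np.tensordot(coeffs, basis, axes=1)
        peak = np.abs(pert).max()
        if peak > 0 and spec.deform_amplitude > 0:
            pert = pert / peak * spec.deform_amplitude
        else:
            pert = np.zeros_like(pert)
        masks.append(r <= radius + pert)
    whole, core, enh = masks
    # radii gaps exceed 2*amplitude by construction, but enforce nesting anyway
    core &= whole
    enh &= core
    return whole, core, enh


def generate_subject(spec: PhantomSpec, subject_index: int) -> ModalityStack:
    """Generate one phantom subject, deterministic given (spec.seed, subject_index)."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, int(subject_index)])
    whole, core, enh = _region_masks(spec, rng, spec.region_radii)

    labels = np.zeros(spec.volume_shape, dtype=np.uint8)
    labels[whole & ~core] = ED
    labels[core & ~enh] = NCR
    labels[enh] = ET

    images = np.empty((spec.n_modalities,) + spec.volume_shape, dtype=np.float64)
    for m in range(spec.n_modalities):
        cw, cc, ce = spec.contrast_matrix[m]
        img = np.full(spec.volume_shape, spec.background_level, dtype=np.float64)
        img += cw * whole + cc * core + ce * enh
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=spec.volume_shape)
        images[m] = np.clip(img, 0.0, None)

    stack = ModalityStack(
        subject_id=f"sub-{subject_index:04d}",
        images=images,
        labels=labels,
        modality_names=tuple(spec.modality_names),
    )
    stack.validate()
    return stack


def generate_cohort(spec: PhantomSpec, n_subjects: int, jitter: float = 0.1) -> list[ModalityStack]:
    """Generate ``n_subjects`` phantoms with bounded per-subject radius/contrast jitter.

    ``jitter`` is the maximal relative perturbation of region radii and contrast
    entries (clipped so spec invariants still hold).  ``jitter=0`` makes subject
    ``i`` identical to ``generate_subject(spec, i)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cohort = []
    for i in range(n_subjects):
        if jitter > 0:
            jrng = np.random.default_rng([spec.seed, 1_000_003, i])
            rw, rc, re = spec.region_radii
            f = 1.0 + jrng.uniform(-jitter, jitter, size=3)
            rw_max = (min(spec.volume_shape) - 2) / 2.0 - 0.01
            radii = (min(rw * f[0], rw_max), rc * f[1], re * f[2])
            # reject pathological draws that break strict nesting
            if not (radii[0] > radii[1] > radii[2] > 0):
                radii = spec.region_radii
            cm = spec.contrast_matrix * (1.0 + jrng.uniform(-jitter, jitter, size=spec.contrast_matrix.shape))
            cm = np.clip(cm, 0.0, 1.0)
            sub_spec = dataclasses.replace(
                spec,
                region_radii=radii,
                contrast_matrix=cm,
                deform_amplitude=min(spec.deform_amplitude, 0.25 * min(radii[0] - radii[1], radii[1] - radii[2])),
            )
        else:
            sub_spec = spec
        cohort.append(generate_subject(sub_spec, i))
    return cohort


def save_cohort_nifti(cohort: list[ModalityStack], out_dir: str) -> None:
    """Write a cohort in the per-subject NIfTI layout real datasets use.

    One directory per subject containing ``<id>_<modality>.nii`` files plus
    ``<id>_segm.nii`` with the label codes.  Uncompressed NIfTI so the files
    remain plain inspectable volumes.
    """
    import nibabel as nib

    for stack in cohort:
        sub_dir = os.path.join(out_dir, stack.subject_id)
        os.makedirs(sub_dir, exist_ok=True)
        affine = np.eye(4)
        for name, vol in zip(stack.modality_names, stack.images):
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), affine),
                os.path.join(sub_dir, f"{stack.subject_id}_{name}.nii"),
            )
        nib.save(
            nib.Nifti1Image(stack.labels.astype(np.uint8), affine),
            os.path.join(sub_dir, f"{stack.subject_id}_segm.nii"),
        )


def load_cohort_nifti(root_dir: str, modality_names: tuple[str, ...] = DEFAULT_MODALITIES) -> list[ModalityStack]:
    """Read a cohort saved by :func:`save_cohort_nifti` (or real data in that layout)."""
    import nibabel as nib

    cohort = []
    for sub_id in sorted(os.listdir(root_dir)):
        sub_dir = os.path.join(root_dir, sub_id)
        if not os.path.isdir(sub_dir):
            continue
        images = []
        for name in modality_names:
            path = os.path.join(sub_dir, f"{sub_id}_{name}.nii")
            if not os.path.exists(path):
                path += ".gz"
            images.append(np.asarray(nib.load(path).dataobj, dtype=np.float64))
        seg_path = os.path.join(sub_dir, f"{sub_id}_segm.nii")
        if not os.path.exists(seg_path):
            seg_path += ".gz"
        labels = np.asarray(nib.load(seg_path).dataobj).astype(np.uint8)
        stack = ModalityStack(sub_id, np.stack(images), labels, tuple(modality_names))
        stack.validate()
        cohort.append(stack)
    if not cohort:
        warnings.warn(f"no subjects found under {root_dir}")
    return cohort
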