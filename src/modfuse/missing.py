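"""Missing-modality training and prediction policies.

A designated modality can be absent at training time (MT, "missing-modality
training") or at prediction time (MP).  An absent modality image is replaced by
a substitute drawn i.i.d. Uniform(0, 1) per element — the same scale as the
normalized inputs — so the network keeps its structure and learns to down-weight
unreliable channels.  During MT the replacement is stochastic: with probability
lambda the real image is kept, otherwise a fresh uniform substitute is used,
drawn independently per designated modality, per sample, per iteration.
lambda = 1 reduces MT to ordinary full-modality training (FT); lambda = 0
replaces the designated modality on every draw.
"""

from __future__ import annotations

import dataclasses

import numpy as np

TRAIN_MODES = ("FT", "MT")
PREDICT_MODES = ("FP", "MP")


@dataclasses.dataclass(frozen=True)
class MissingPolicy:
    """Training/prediction mode, keep-probability lambda, and the designated
    potentially-missing modalities (by name)."""

    train_mode: str = "FT"
    predict_mode: str = "FP"
    lam: float = 0.5
    missing_set: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.train_mode not in TRAIN_MODES:
            raise ValueError(f"train_mode must be one of {TRAIN_MODES}")
        if self.predict_mode not in PREDICT_MODES:
            raise ValueError(f"predict_mode must be one of {PREDICT_MODES}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")


def sample_substitute(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Uniform(0, 1) substitute image of the given (C, H, W) shape."""
    if any(s <= 0 for s in shape):
        raise ValueError(f"substitute shape must be positive, got {shape}")
    return rng.uniform(0.0, 1.0, size=shape)


def apply_training_substitution(images: np.ndarray, modality_names: tuple[str, ...],
                                policy: MissingPolicy, rng: np.random.Generator):
    """Per-iteration MT substitution on one sample's (N, C, H, W) images.

    For each modality in the policy's missing set, draw p ~ U(0,1); keep the
    real image iff p <= lambda, otherwise substitute fresh uniform noise.
    FT returns the input untouched.  Returns (images, substituted_names).
    """
    if policy.train_mode == "FT":
        return images, []
    substituted = []
    out = images
    for name in policy.missing_set:
        idx = modality_names.index(name)
        p = rng.uniform()
        if p > policy.lam:
            if out is images:
                out = images.copy()
            out[idx] = sample_substitute(images.shape[1:], rng)
            substituted.append(name)
    return out, substituted


def apply_inference_substitution(images: np.ndarray, modality_names: tuple[str, ...],
                                 policy: MissingPolicy, rng: np.random.Generator) -> np.ndarray:
    """FP: identity.  MP: every designated modality replaced by fresh noise."""
    if policy.predict_mode == "FP" or not policy.missing_set:
        return images
    out = images.copy()
    for name in policy.missing_set:
        out[modality_names.index(name)] = sample_substitute(images.shape[1:], rng)
    return out
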