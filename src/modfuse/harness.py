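"""Experiment harness: training loop, subject-level cross-validation, the
train/predict mode grid, the lambda sweep, and fused-feature embedding.

Random-number discipline: model initialization, batch shuffling and
missing-modality substitution each draw from separate seeded streams, so that
full-modality training (FT) and missing-modality training with lambda = 1 —
which consumes substitution draws but never substitutes — produce bit-identical
training trajectories, and the FT/MT comparison differs only in the policy.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .metrics import EvalReport, dice_score, hd95, total_loss_and_grad_from_logits
from .missing import MissingPolicy, apply_inference_substitution, apply_training_substitution
from .model import FusionModel, ModelConfig
from .nn import AdamW
from .phantom import ModalityStack, PhantomSpec
from .preprocess import PreprocessConfig, SliceRecord, build_slice_dataset

logger = logging.getLogger("modfuse")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 8
    epochs: int = 50
    folds: int = 5
    policy: MissingPolicy = MissingPolicy()
    model: ModelConfig = ModelConfig(input_size=1024)
    preprocess: PreprocessConfig = PreprocessConfig()
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.epochs) <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2 for cross-validation")


def desk_config(task_seed: int = 0, policy: MissingPolicy = MissingPolicy(),
                epochs: int = 8, lr: float = 3e-3) -> TrainConfig:
    """CPU-scale profile: light encoder at 64 x 64 with a higher learning rate
    and few epochs, sized so a full training run takes seconds."""
    model = ModelConfig(encoder_kind="light_trainable", n_modalities=4,
                        encoder_channels=8, se_reduction=8, decoder_channels=16,
                        input_size=64)
    pre = PreprocessConfig(model_size=64, bbox_jitter_max=3, seed=task_seed)
    return TrainConfig(lr=lr, weight_decay=0.01, batch_size=8, epochs=epochs,
                       folds=5, policy=policy, model=model, preprocess=pre,
                       seed=task_seed)


@dataclasses.dataclass
class TrainResult:
    """A trained model plus its per-epoch mean total-loss curve and the
    per-iteration loss/substitution log."""

    model: FusionModel
    epoch_losses: list
    iteration_log: pd.DataFrame  # columns: epoch, iteration, dice_loss, bce_loss, total, n_substituted
    config: TrainConfig


@dataclasses.dataclass
class ExperimentResult:
    mode_label: str                 # FTFP / FTMP / MTFP / MTMP
    missing_modality: str | None
    fold_reports: list              # list of EvalReport
    loss_curves: list               # one per trained fold
    seeds: dict

    def pooled(self) -> pd.DataFrame:
        return pd.concat([r.per_slice for r in self.fold_reports], ignore_index=True)

    def pooled_aggregates(self) -> dict:
        rows = self.pooled()
        return {
            "n_slices": int(len(rows)),
            "mean_dice": float(rows["dice"].mean()),
            "sd_dice": float(rows["dice"].std(ddof=1)) if len(rows) > 1 else 0.0,
            "mean_hd95": float(rows["hd95"].mean()),
        }


def _stack_dataset(records: list[SliceRecord]):
    images = np.stack([r.modality_images for r in records]).astype(np.float64)
    masks = np.stack([r.gt_mask for r in records]).astype(np.float64)
    bboxes = np.array([r.bbox for r in records], dtype=np.float64)
    return images, masks, bboxes


def train(dataset: list[SliceRecord], config: TrainConfig,
          modality_names: tuple[str, ...] | None = None) -> TrainResult:
    """Optimize the total (Dice + BCE) loss over the model's trainable parts.

    Missing-modality substitution (when the policy's train mode is MT) is
    re-drawn per designated modality, per sample, per iteration.  Deterministic
    given config.seed and the policy seed.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    if modality_names is None:
        modality_names = ("T1", "T1gd", "T2", "FLAIR")[: dataset[0].modality_images.shape[0]]
    policy = config.policy
    model = FusionModel(config.model, seed=config.seed)
    trainable = model.trainable_names()
    opt_params = {k: model.params[k] for k in trainable}
    opt = AdamW(opt_params, lr=config.lr, weight_decay=config.weight_decay,
                no_decay=model.no_decay_names())
    frozen_before = {k: model.params[k].copy() for k in model.params if k not in trainable}

    shuffle_rng = np.random.default_rng([config.seed, 1])
    subst_rng = np.random.default_rng([policy.seed, 2])

    images, masks, bboxes = _stack_dataset(dataset)
    n = len(dataset)
    epoch_losses, log_rows = [], []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        totals = []
        for it, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start:start + config.batch_size]
            batch = images[idx].copy()
            n_subst = 0
            if policy.train_mode == "MT":
                for b in range(len(idx)):
                    batch[b], subst = apply_training_substitution(
                        batch[b], modality_names, policy, subst_rng)
                    n_subst += len(subst)
            logits, cache = model.forward(batch, bboxes[idx])
            loss, dlogits = total_loss_and_grad_from_logits(logits, masks[idx])
            grads = model.backward(dlogits, cache)
            opt.step(opt_params, {k: grads[k] for k in trainable})
            totals.append(loss.total)
            log_rows.append(dict(epoch=epoch, iteration=it, dice_loss=loss.dice_loss,
                                 bce_loss=loss.bce_loss, total=loss.total,
                                 n_substituted=n_subst))
            logger.debug("epoch %d it %d total %.4f (%d substituted)",
                         epoch, it, loss.total, n_subst)
        epoch_losses.append(float(np.mean(totals)))
        logger.info("epoch %d mean total loss %.4f", epoch, epoch_losses[-1])

    for k, v in frozen_before.items():
        assert np.array_equal(v, model.params[k]), f"frozen parameter {k} changed"
    return TrainResult(model, epoch_losses, pd.DataFrame(log_rows), config)


def evaluate(model: FusionModel, dataset: list[SliceRecord], policy: MissingPolicy,
             noise_seed: int = 0,
             modality_names: tuple[str, ...] | None = None) -> EvalReport:
    """Per-slice Dice/HD95 of thresholded predictions under the policy's
    prediction mode (MP replaces designated modalities with fresh noise)."""
    if modality_names is None:
        modality_names = ("T1", "T1gd", "T2", "FLAIR")[: dataset[0].modality_images.shape[0]]
    rng = np.random.default_rng([policy.seed, 3, noise_seed])
    rows = []
    bs = 16
    for start in range(0, len(dataset), bs):
        chunk = dataset[start:start + bs]
        batch = np.stack([r.modality_images for r in chunk]).astype(np.float64)
        for b, rec in enumerate(chunk):
            batch[b] = apply_inference_substitution(batch[b], modality_names, policy, rng)
        bboxes = np.array([r.bbox for r in chunk], dtype=np.float64)
        logits, _ = model.forward(batch, bboxes)
        preds = (logits >= 0.0).astype(np.uint8)
        for b, rec in enumerate(chunk):
            hd, flagged = hd95(rec.gt_mask, preds[b])
            rows.append(dict(subject_id=rec.subject_id, z=rec.z_index, task=rec.task,
                             gt_size=int(rec.gt_mask.sum()),
                             dice=dice_score(rec.gt_mask, preds[b]),
                             hd95=hd, hd95_flagged=flagged))
    return EvalReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# splits


def subject_folds(cohort_ids: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Disjoint, exhaustive subject-level partition into n_folds test sets."""
    ids = sorted(set(cohort_ids))
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} subjects < {n_folds} folds")
    rng = np.random.default_rng([seed, 4])
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return [list(chunk) for chunk in np.array_split(perm, n_folds)]


def holdout_split(cohort_ids: list[str], test_frac: float, seed: int) -> tuple[list[str], list[str]]:
    ids = sorted(set(cohort_ids))
    rng = np.random.default_rng([seed, 4])
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_test = max(1, int(round(test_frac * len(ids))))
    return perm[n_test:], perm[:n_test]


def cross_validate(cohort: list[ModalityStack], task: str, config: TrainConfig) -> ExperimentResult:
    """Subject-level k-fold cross-validation: no subject's slices span folds."""
    dataset = build_slice_dataset(cohort, task, config.preprocess)
    names = cohort[0].modality_names
    folds = subject_folds([s.subject_id for s in cohort], config.folds, config.seed)
    reports, curves = [], []
    for k, test_ids in enumerate(folds):
        train_recs = [r for r in dataset if r.subject_id not in test_ids]
        test_recs = [r for r in dataset if r.subject_id in test_ids]
        result = train(train_recs, config, names)
        reports.append(evaluate(result.model, test_recs, config.policy,
                                noise_seed=k, modality_names=names))
        curves.append(result.epoch_losses)
    label = config.policy.train_mode + config.policy.predict_mode
    missing = config.policy.missing_set[0] if config.policy.missing_set else None
    return ExperimentResult(label, missing, reports, curves,
                            {"seed": config.seed, "policy_seed": config.policy.seed})


# ---------------------------------------------------------------------------
# the Table-3-style mode grid and the lambda sweep


def mode_grid_eval(cohort: list[ModalityStack], task: str, base_config: TrainConfig,
                   missing_modality: str, test_frac: float = 0.3,
                   mp_noise_seeds: int = 3) -> dict[str, ExperimentResult]:
    """Train FT and MT models on a shared subject split and initialization,
    then evaluate each under full (FP) and missing (MP) prediction.

    MP evaluation is stochastic; it is repeated over ``mp_noise_seeds`` fresh
    noise draws and all rows are pooled.  Returns the four cells keyed
    FTFP / FTMP / MTFP / MTMP.
    """
    names = cohort[0].modality_names
    if missing_modality not in names:
        raise ValueError(f"unknown modality {missing_modality!r}")
    dataset = build_slice_dataset(cohort, task, base_config.preprocess)
    train_ids, test_ids = holdout_split([s.subject_id for s in cohort], test_frac,
                                        base_config.seed)
    train_recs = [r for r in dataset if r.subject_id in train_ids]
    test_recs = [r for r in dataset if r.subject_id in test_ids]

    results: dict[str, ExperimentResult] = {}
    trained = {}
    for tm in ("FT", "MT"):
        policy = dataclasses.replace(base_config.policy, train_mode=tm,
                                     missing_set=(missing_modality,))
        cfg = dataclasses.replace(base_config, policy=policy)
        trained[tm] = train(train_recs, cfg, names)
    for tm in ("FT", "MT"):
        for pm in ("FP", "MP"):
            policy = dataclasses.replace(base_config.policy, train_mode=tm,
                                         predict_mode=pm, missing_set=(missing_modality,))
            seeds = range(mp_noise_seeds) if pm == "MP" else [0]
            reports = [evaluate(trained[tm].model, test_recs, policy, noise_seed=s,
                                modality_names=names) for s in seeds]
            results[tm + pm] = ExperimentResult(
                tm + pm, missing_modality, reports, [trained[tm].epoch_losses],
                {"seed": base_config.seed, "policy_seed": policy.seed})
    return results


def grid_table(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    rows = []
    for label, res in results.items():
        agg = res.pooled_aggregates()
        rows.append(dict(mode=label, missing=res.missing_modality, **agg))
    return pd.DataFrame(rows)


def lambda_sweep(cohort: list[ModalityStack], task: str, base_config: TrainConfig,
                 missing_modality: str, lambdas: list[float], test_frac: float = 0.3,
                 mp_noise_seeds: int = 3) -> pd.DataFrame:
    """One MT training per lambda (shared seeds/splits), FP and MP evaluation.

    With lambda = 1, MT never substitutes and the row coincides with FT
    training under identical seeds.
    """
    names = cohort[0].modality_names
    dataset = build_slice_dataset(cohort, task, base_config.preprocess)
    train_ids, test_ids = holdout_split([s.subject_id for s in cohort], test_frac,
                                        base_config.seed)
    train_recs = [r for r in dataset if r.subject_id in train_ids]
    test_recs = [r for r in dataset if r.subject_id in test_ids]
    rows = []
    for lam in lambdas:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda {lam} outside [0, 1]")
        policy = dataclasses.replace(base_config.policy, train_mode="MT", lam=lam,
                                     missing_set=(missing_modality,))
        cfg = dataclasses.replace(base_config, policy=policy)
        result = train(train_recs, cfg, names)
        fp = evaluate(result.model, test_recs,
                      dataclasses.replace(policy, predict_mode="FP"), modality_names=names)
        mp_dices = [evaluate(result.model, test_recs,
                             dataclasses.replace(policy, predict_mode="MP"),
                             noise_seed=s, modality_names=names).mean_dice
                    for s in range(mp_noise_seeds)]
        rows.append(dict(lam=lam, fp_dice=fp.mean_dice,
                         mp_dice=float(np.mean(mp_dices)),
                         mp_dice_sd=float(np.std(mp_dices, ddof=1)) if len(mp_dices) > 1 else 0.0,
                         final_train_loss=result.epoch_losses[-1]))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fused-feature embedding


def embed_fused_features(model: FusionModel, dataset: list[SliceRecord],
                         policies: dict[str, MissingPolicy], seed: int = 0,
                         modality_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Spatially pooled fused features per slice under each named policy,
    projected to 2-D with UMAP; deterministic given seed.

    Returns one row per (slice, mode) with the embedding coordinates, the mode
    label, and the slice's foreground fraction for downstream coloring.
    """
    if len(dataset) < 10:
        raise ValueError("need at least 10 slices for a stable embedding")
    if modality_names is None:
        modality_names = ("T1", "T1gd", "T2", "FLAIR")[: dataset[0].modality_images.shape[0]]
    feats, meta = [], []
    for label, policy in policies.items():
        rng = np.random.default_rng([policy.seed, 5])
        for rec in dataset:
            imgs = apply_inference_substitution(
                rec.modality_images.astype(np.float64), modality_names, policy, rng)
            _, _, state = model.forward(imgs[None], np.array([rec.bbox], dtype=np.float64),
                                        return_state=True)
            feats.append(state.fused.mean(axis=(2, 3))[0])
            meta.append(dict(mode=label, subject_id=rec.subject_id, z=rec.z_index,
                             fg_frac=float(rec.gt_mask.mean())))
    import umap

    emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(np.array(feats))
    out = pd.DataFrame(meta)
    out["x"] = emb[:, 0]
    out["y"] = emb[:, 1]
    return out


# ---------------------------------------------------------------------------
# YAML experiment configuration


def config_from_yaml(path: str):
    """Build (PhantomSpec, TrainConfig) from a YAML file with sections
    ``phantom``, ``preprocess``, ``model``, ``policy`` and ``train``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = PhantomSpec(**_tupled(raw.get("phantom", {}),
                                 ("volume_shape", "region_radii", "modality_names")))
    pre = PreprocessConfig(**raw.get("preprocess", {}))
    model_kw = raw.get("model", {})
    if "trainable_parts" in model_kw:
        model_kw["trainable_parts"] = frozenset(model_kw["trainable_parts"])
    model = ModelConfig(**model_kw)
    policy = MissingPolicy(**_tupled(raw.get("policy", {}), ("missing_set",)))
    train_kw = raw.get("train", {})
    cfg = TrainConfig(policy=policy, model=model, preprocess=pre, **train_kw)
    return spec, cfg


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d
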