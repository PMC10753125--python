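"""Training: patient-level splits, the optimization loop, hyperparameter
grid search, and the raw-inclusion / leave-one-style-out experiment
harnesses.

Splits are made at the patient level - all images of a woman land in the
same partition - by greedily assigning shuffled patients to the test set
until it holds the requested number of images, then to validation, with the
remainder for training.

Training minimizes a class-weighted loss with Adam, evaluates the
validation loss each epoch, and stops once the validation loss has not
improved its running best for ``patience`` consecutive epochs; weights are
restored to the best-validation epoch.

The grid search trains one model per (loss type, alpha_pectoral) candidate
and selects the one with the highest mean validation pectoral dice,
computed only over validation images whose ground truth contains the
pectoral class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy, augment_sample
from .evaluate import evaluate_dataset
from .image_io import LabelGrid, Mammogram, apply_windowing
from .losses import LossConfig, loss_and_logit_grad
from .phantom import PhantomConfig, PhantomSample, VendorStyle, generate_samples
from .unet import SegmentationModel, UNetConfig, build_unet

__all__ = [
    "TrainRecord", "TrainConfig", "SelectedConfig", "TrainingHistory",
    "split_patient_level", "split_samples", "train_model", "grid_search",
    "run_raw_inclusion", "run_leave_one_out",
]


class ConfigurationError(ValueError):
    """The dataset cannot satisfy the requested split sizes."""


class TrainingFailure(RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass
class TrainRecord:
    """One training/evaluation item: an image with its truth mask."""

    mammogram: Mammogram
    truth: LabelGrid
    patient_id: str = "p0"
    image_id: str = ""

    @property
    def image(self) -> np.ndarray:
        """Network-ready intensities in [0, 1] (metadata window, no jitter)."""
        return apply_windowing(self.mammogram, jitter_fraction=0.0)

    @property
    def view(self) -> str:
        return self.mammogram.view

    @property
    def kind(self) -> str:
        return self.mammogram.kind

    @property
    def vendor(self) -> str:
        return self.mammogram.vendor

    @classmethod
    def from_phantom(cls, sample: PhantomSample, use: str = "processed") -> "TrainRecord":
        mg = sample.processed if use == "processed" else sample.raw
        return cls(mammogram=mg, truth=sample.truth, patient_id=sample.patient_id,
                   image_id=f"{sample.patient_id}_{use}_{id(sample) & 0xffff:x}")


@dataclass
class TrainConfig:
    """Everything one training run needs."""

    loss: LossConfig = field(default_factory=LossConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 200
    patience: int = 10
    min_epochs: int = 0   # floor before early stopping may trigger
    seed: int = 0
    include_raw: bool = False

    def __post_init__(self):
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch train/validation loss and validation dice."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def split_patient_level(manifest: pd.DataFrame, n_test: int, n_val: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Assign whole patients to test/validation/train partitions.

    Patients are shuffled, then assigned to the test split until it holds at
    least ``n_test`` images, next to validation until at least ``n_val``
    images; the rest go to training.  Returns the manifest with a ``split``
    column; deterministic given the rng state.
    """
    if "patient_id" not in manifest.columns:
        raise ConfigurationError("manifest needs a patient_id column")
    patients = manifest["patient_id"].unique()
    order = rng.permutation(len(patients))
    counts = manifest["patient_id"].value_counts()
    total = int(counts.sum())
    if total < n_test + n_val + 1:
        raise ConfigurationError(
            f"dataset of {total} images cannot provide {n_test} test + {n_val} "
            "validation images and a non-empty training set")
    assignment: dict[str, str] = {}
    got_test = got_val = 0
    for idx in order:
        pid = patients[idx]
        k = int(counts[pid])
        if got_test < n_test:
            assignment[pid] = "test"
            got_test += k
        elif got_val < n_val:
            assignment[pid] = "validation"
            got_val += k
        else:
            assignment[pid] = "train"
    out = manifest.copy()
    out["split"] = out["patient_id"].map(assignment)
    if not (out["split"] == "train").any():
        raise ConfigurationError("no patients left for training after test/validation")
    return out


def split_samples(samples: list, n_test: int, n_val: int,
                  rng: np.random.Generator) -> tuple[list, list, list]:
    """Patient-level split of in-memory samples into (train, val, test)."""
    manifest = pd.DataFrame({
        "patient_id": [s.patient_id for s in samples],
        "image_id": np.arange(len(samples)),
    })
    split = split_patient_level(manifest, n_test, n_val, rng)["split"].to_numpy()
    train = [s for s, p in zip(samples, split) if p == "train"]
    val = [s for s, p in zip(samples, split) if p == "validation"]
    test = [s for s, p in zip(samples, split) if p == "test"]
    return train, val, test


def _validation_metrics(model: SegmentationModel, val_set: list[TrainRecord],
                        loss_cfg: LossConfig) -> dict:
    from .losses import evaluate_loss
    from .unet import predict_probabilities

    losses, overall, pect = [], [], []
    for rec in val_set:
        probs = predict_probabilities(model, rec.image)
        losses.append(evaluate_loss(probs, rec.truth, loss_cfg))
        pred = LabelGrid(labels=np.argmax(probs, axis=0).astype(np.uint8))
        from .evaluate import dice_per_class, overall_dice
        overall.append(overall_dice(pred, rec.truth))
        d = dice_per_class(pred, rec.truth, 2)
        if d is not None:
            pect.append(d)
    return {
        "val_loss": float(np.mean(losses)),
        "val_overall_dice": float(np.mean(overall)),
        "val_pectoral_dice": float(np.mean(pect)) if pect else float("nan"),
    }


def train_model(model: SegmentationModel, train_set: list[TrainRecord],
                val_set: list[TrainRecord], config: TrainConfig,
                ) -> tuple[SegmentationModel, TrainingHistory]:
    """Optimize the model with early stopping on the validation loss.

    "Improve" means a strict decrease of the epoch-mean validation loss
    below its running best; after ``patience`` consecutive epochs without
    improvement training stops and the best-epoch weights are restored.
    ``min_epochs`` defers the stop so hard tasks can escape their initial
    plateau before the patience rule is allowed to fire.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(lr=config.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_state = None
    stale = 0

    n = len(train_set)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            imgs, masks = [], []
            for i in batch_idx:
                rec = train_set[i]
                x, m = augment_sample(rec.mammogram, rec.truth, config.policy, rng)
                imgs.append(x)
                masks.append(m.labels)
            xb = np.stack(imgs)[:, None].astype(np.float32)
            yb = np.stack(masks)
            logits = model.forward_logits(xb, train=True, rng=rng)
            loss, dlogits = loss_and_logit_grad(logits, yb, config.loss)
            if not np.isfinite(loss):
                raise TrainingFailure(f"non-finite training loss at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)

        metrics = _validation_metrics(model, val_set, config.loss)
        if not np.isfinite(metrics["val_loss"]):
            raise TrainingFailure(f"non-finite validation loss at epoch {epoch}")
        row = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)), **metrics}
        history.epochs.append(row)

        if metrics["val_loss"] < best_loss:
            best_loss = metrics["val_loss"]
            best_state = [p.copy() for p, _ in model.params()]
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience and epoch + 1 >= config.min_epochs:
                break

    if best_state is not None:
        for (p, _), saved in zip(model.params(), best_state):
            p[:] = saved
    return model, history


@dataclass
class SelectedConfig:
    """Grid-search outcome: the winning loss/alpha plus the full table."""

    loss_type: str
    alpha_pectoral: float
    table: pd.DataFrame  # columns: loss_type, alpha_pectoral, val_pectoral_dice, val_overall_dice


def grid_search(train_set, val_set, losses=("cross_entropy", "focal"),
                alphas=(1.0, 1.5, 2.0, 2.5), config: TrainConfig | None = None,
                ) -> SelectedConfig:
    """Train one model per (loss, alpha_pectoral) candidate and pick the
    winner by validation pectoral dice.

    Ties are broken by higher overall dice, then by the lower alpha.
    """
    if config is None:
        config = TrainConfig()
    if not losses or not len(alphas):
        raise ValueError("need at least one candidate")
    rows, errors = [], []
    for loss_type in losses:
        for a in alphas:
            loss_cfg = LossConfig.with_pectoral_weight(loss_type, a,
                                                       gamma=config.loss.gamma)
            cand = replace(config, loss=loss_cfg)
            model = build_unet(cand.unet, seed=cand.seed)
            try:
                model, hist = train_model(model, train_set, val_set, cand)
            except TrainingFailure as exc:
                errors.append(f"{loss_type}/alpha={a}: {exc}")
                continue
            metrics = _validation_metrics(model, val_set, loss_cfg)
            rows.append({
                "loss_type": loss_type, "alpha_pectoral": float(a),
                "val_pectoral_dice": metrics["val_pectoral_dice"],
                "val_overall_dice": metrics["val_overall_dice"],
            })
    if not rows:
        raise TrainingFailure("all grid-search candidates failed: " + "; ".join(errors))
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["val_pectoral_dice", "val_overall_dice", "alpha_pectoral"],
        ascending=[False, False, True], kind="mergesort")
    best = ranked.iloc[0]
    return SelectedConfig(loss_type=str(best["loss_type"]),
                          alpha_pectoral=float(best["alpha_pectoral"]), table=table)


def _records(samples, kinds=("processed",)) -> list[TrainRecord]:
    out = []
    for s in samples:
        for kind in kinds:
            out.append(TrainRecord.from_phantom(s, use=kind))
    return out


def run_raw_inclusion(train_samples, val_samples, test_samples,
                      config: TrainConfig) -> dict:
    """Train with and without raw images; compare raw/processed test dice.

    Reproduces, at phantom scale, the experiment in which a model trained on
    processed images alone is retrained with the raw images added (raw
    images reuse the truth mask of their processed counterpart) and both are
    scored on raw and processed test sets.  Dice lists are compared with
    paired t-tests since both models score the same images.
    """
    val = _records(val_samples)
    test_proc = _records(test_samples)
    test_raw = _records(test_samples, kinds=("raw",))

    results = {}
    for tag, kinds in (("processed_only", ("processed",)),
                       ("processed_and_raw", ("processed", "raw"))):
        model = build_unet(config.unet, seed=config.seed)
        model, hist = train_model(model, _records(train_samples, kinds), val, config)
        rep_proc = evaluate_dataset(model, test_proc)
        rep_raw = evaluate_dataset(model, test_raw)
        results[tag] = {
            "model": model, "history": hist,
            "processed_dice": [s.overall_dice for s in rep_proc.scores],
            "raw_dice": [s.overall_dice for s in rep_raw.scores],
        }

    from .evaluate import compare_groups
    raw_a = results["processed_only"]["raw_dice"]
    raw_b = results["processed_and_raw"]["raw_dice"]
    proc_a = results["processed_only"]["processed_dice"]
    proc_b = results["processed_and_raw"]["processed_dice"]
    results["raw_test"] = compare_groups(raw_a, raw_b, mode="paired_t")
    results["processed_test"] = compare_groups(proc_a, proc_b, mode="paired_t")
    results["raw_dice_delta"] = float(np.mean(raw_b) - np.mean(raw_a))
    results["processed_dice_delta"] = float(np.mean(proc_b) - np.mean(proc_a))
    return results


def run_leave_one_out(styles: list[VendorStyle], phantom_config: PhantomConfig,
                      train_config: TrainConfig, n_patients: int,
                      rng: np.random.Generator, n_test: int = 20, n_val: int = 16,
                      holdouts: list[str] | None = None, alpha: float = 0.05,
                      ) -> pd.DataFrame:
    """Leave-one-style-out vendor-generalization harness.

    For each held-out style, a model is trained on phantoms of all other
    styles and scored on (a) the held-out style and (b) the test split of
    the included styles.  The two dice samples are compared with an unpaired
    t-test at the Bonferroni-adjusted level alpha / k for k styles.
    """
    if len(styles) < 2:
        raise ValueError("need at least two styles")
    k = len(styles)
    names = [s.name for s in styles]
    if holdouts is None:
        holdouts = names

    # one phantom cohort per style, shared across holdout rounds
    cohorts = {}
    for s in styles:
        cfg = replace(phantom_config, styles=[s])
        samples = generate_samples(cfg, n_patients, rng)
        cohorts[s.name] = split_samples(samples, n_test=n_test, n_val=n_val,
                                        rng=rng)

    rows = []
    for name in holdouts:
        train, val, included_test = [], [], []
        for other in names:
            if other == name:
                continue
            tr, va, te = cohorts[other]
            train += tr
            val += va
            included_test += te
        held_out = cohorts[name][0] + cohorts[name][1] + cohorts[name][2]
        model = build_unet(train_config.unet, seed=train_config.seed)
        model, _ = train_model(model, _records(train), _records(val), train_config)
        rep_in = evaluate_dataset(model, _records(included_test))
        rep_out = evaluate_dataset(model, _records(held_out))
        dice_in = [s.overall_dice for s in rep_in.scores]
        dice_out = [s.overall_dice for s in rep_out.scores]
        from .evaluate import compare_groups
        test = compare_groups(dice_out, dice_in, mode="unpaired_t",
                              alpha=alpha, n_comparisons=k)
        rows.append({
            "held_out_style": name,
            "included_dice_mean": float(np.mean(dice_in)),
            "held_out_dice_mean": float(np.mean(dice_out)),
            "dice_difference": float(np.mean(dice_out) - np.mean(dice_in)),
            "statistic": test.statistic, "p_value": test.p_value,
            "alpha_adjusted": test.alpha_adjusted, "significant": test.significant,
        })
    return pd.DataFrame(rows)
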