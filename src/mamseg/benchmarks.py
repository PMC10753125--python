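"""Desk-scale phantom benchmarks of the full segmentation pipeline.

Full-scale mammogram training is a GPU-days problem; these benchmarks
exercise the identical pipeline - phantom generation, patient-level
splitting, augmentation, weighted-loss U-Net training with early stopping,
and dice/detection/statistics evaluation - at sizes a single CPU handles in
minutes.  They are used by the test suite and the acceptance script.

Problem sizes are fixed here as the package's reference configurations:

* ``segmentation_benchmark`` - depth-3 / base-8 U-Net on 200 processed
  phantom images (128 x 128, two vendor styles), cross-entropy loss with
  alpha_pectoral = 2, evaluated on a 50-image held-out patient split.
* ``raw_inclusion_benchmark`` - the raw-image experiment at 64 x 64: the
  same model trained with and without raw images, both scored on raw and
  processed test images.
* ``style_holdout_benchmark`` - leave-one-style-out at 64 x 64: an
  adversarial inverted-contrast style held out of training, plus a null
  case with two identically parameterized styles.

Reduced-width models use dropout 0.1 rather than the full-scale 0.5: with
only 8 feature channels before the head, 0.5 removes half the information
the classifier sees and mixed raw/processed training fails to converge.
Augmentation magnitudes with units of pixels (elastic smoothing, affine
jitter, crop overshoot) scale with image size from their 512-pixel-crop
reference values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .augment import AugmentationPolicy
from .evaluate import EvaluationReport, evaluate_dataset
from .losses import LossConfig
from .phantom import PhantomConfig, default_styles, generate_samples, inverted_style
from .trainer import (TrainConfig, TrainRecord, run_leave_one_out,
                      run_raw_inclusion, split_samples, train_model)
from .unet import UNetConfig, build_unet

__all__ = [
    "reduced_policy", "reduced_train_config",
    "segmentation_benchmark", "raw_inclusion_benchmark", "style_holdout_benchmark",
]


def reduced_policy(size: int) -> AugmentationPolicy:
    """The training augmentation policy scaled to ``size``-pixel images.

    Pixel-valued parameters shrink proportionally from their 512-crop
    reference values (crop overshoot 64 -> size/8, elastic sigma 100 ->
    ~size/5, affine jitter 20 -> size/25); dimensionless parameters (flip
    probability, rotation range, gamma, noise, window jitter) are unchanged.
    """
    return AugmentationPolicy(
        crop_size=size,
        crop_max_outside=size // 8,
        elastic_sigma=size / 5.0,
        elastic_alpha_affine=size / 25.0,
    )


def reduced_train_config(size: int, seed: int, max_epochs: int,
                         learning_rate: float = 2e-3, patience: int = 10,
                         ) -> TrainConfig:
    """Reduced-scale training configuration (depth-3 / base-8 U-Net)."""
    return TrainConfig(
        loss=LossConfig.with_pectoral_weight("cross_entropy", 2.0),
        unet=UNetConfig(depth=3, base_filters=8, dropout_prob=0.1),
        policy=reduced_policy(size),
        learning_rate=learning_rate,
        batch_size=4,
        max_epochs=max_epochs,
        patience=patience,
        seed=seed,
    )


def segmentation_benchmark(seed: int = 7) -> dict:
    """End-to-end phantom segmentation at 128 x 128.

    Trains on 200 processed phantom images of two vendor styles and scores
    the held-out patient split.  Returns the trained model, training
    history, per-image evaluation report and the test records.
    """
    rng = np.random.default_rng(seed)
    pcfg = PhantomConfig(image_size=128, styles=default_styles()[:2],
                         images_per_patient=(2, 3))
    samples = generate_samples(pcfg, 115, rng)
    train_s, val_s, test_s = split_samples(samples, n_test=50, n_val=32, rng=rng)
    train_s = train_s[:200]
    cfg = reduced_train_config(128, seed=seed, max_epochs=20)
    model = build_unet(cfg.unet, seed=seed)
    model, history = train_model(model, [TrainRecord.from_phantom(s) for s in train_s],
                                 [TrainRecord.from_phantom(s) for s in val_s], cfg)
    report = evaluate_dataset(model, [TrainRecord.from_phantom(s) for s in test_s])
    return {"model": model, "history": history, "report": report,
            "test_samples": test_s, "config": cfg}


def raw_inclusion_benchmark(seed: int = 7) -> dict:
    """The raw-image training experiment at 64 x 64.

    Trains a processed-only and a processed+raw model on the same patient
    split and compares their dice on raw and processed test images with
    paired t-tests.
    """
    rng = np.random.default_rng(seed)
    pcfg = PhantomConfig(image_size=64, styles=default_styles()[:2],
                         images_per_patient=(2, 3))
    samples = generate_samples(pcfg, 55, rng)
    train_s, val_s, test_s = split_samples(samples, n_test=30, n_val=20, rng=rng)
    train_s = train_s[:80]
    cfg = reduced_train_config(64, seed=seed, max_epochs=50, learning_rate=2.5e-3)
    # mixed raw/processed training spends its first epochs in a plateau;
    # keep early stopping from firing before optimization escapes it
    cfg.min_epochs = 25
    return run_raw_inclusion(train_s, val_s, test_s, cfg)


def style_holdout_benchmark(seed: int = 7) -> dict:
    """Leave-one-style-out at 64 x 64: adversarial and null cases.

    The adversarial round trains on two ordinary vendor styles and is
    tested on a held-out inverted-contrast style; the null round holds out
    one of two identically parameterized styles, where no dice difference
    should appear.
    """
    size = 64
    cfg = reduced_train_config(size, seed=seed, max_epochs=20,
                               learning_rate=2.5e-3, patience=8)

    styles = default_styles()[:2] + [inverted_style()]
    pcfg = PhantomConfig(image_size=size, styles=styles, images_per_patient=(2, 3))
    adversarial = run_leave_one_out(
        styles, pcfg, cfg, n_patients=20, rng=np.random.default_rng(seed),
        n_test=15, n_val=12, holdouts=["inverted"])

    base = default_styles()[0]
    null_styles = [base, replace(base, name=base.name + "_twin")]
    pcfg_null = PhantomConfig(image_size=size, styles=null_styles,
                              images_per_patient=(2, 3))
    null = run_leave_one_out(
        null_styles, pcfg_null, cfg, n_patients=30, rng=np.random.default_rng(seed),
        n_test=25, n_val=12, holdouts=[null_styles[1].name])

    return {"adversarial": adversarial, "null": null}
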