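"""Training-time augmentations, applied jointly to image and mask.

The stack emulates the intensity and contrast diversity of processed
mammograms from different vendors: display-window (look-up-table) jitter,
horizontal flip, small rotation, elastic deformation, fixed-size random
crop, gamma transform and Gaussian noise - in that order.  Geometric steps
warp image and mask with the identical transform (linear vs nearest-neighbour
interpolation); intensity steps touch the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import LabelGrid, Mammogram, apply_windowing

__all__ = [
    "AugmentationPolicy",
    "random_horizontal_flip",
    "random_rotation",
    "elastic_deformation",
    "random_crop",
    "random_gamma",
    "add_gaussian_noise",
    "augment_sample",
]


@dataclass
class AugmentationPolicy:
    """Parameter set for the training augmentation stack.

    Defaults correspond to the study configuration: +-5% window jitter, flip
    probability 0.5, rotations in +-5 degrees, elastic deformation with
    alpha=1, sigma=100, alpha_affine=20, 512x512 crops allowed at most 64
    pixels outside the image, gamma in (0.5, 1.5) and Gaussian noise with
    standard deviation 5% of the image range.
    """

    lut_jitter: float = 0.05
    flip_prob: float = 0.5
    rotation_deg: float = 5.0
    elastic_alpha: float = 1.0
    elastic_sigma: float = 100.0
    elastic_alpha_affine: float = 20.0
    crop_size: int = 512
    crop_max_outside: int = 64
    gamma_range: tuple[float, float] = (0.5, 1.5)
    noise_sd_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lut_jitter < 1:
            raise ValueError("lut_jitter must be in [0, 1)")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be a probability")
        lo, hi = self.gamma_range
        if not 0 < lo <= hi:
            raise ValueError("gamma_range must be a positive interval")
        if self.crop_max_outside > self.crop_size / 2:
            raise ValueError("crop_max_outside must be <= crop_size/2")

    @classmethod
    def identity(cls, crop_size: int) -> "AugmentationPolicy":
        """A policy with every magnitude zeroed (useful for testing)."""
        return cls(
            lut_jitter=0.0, flip_prob=0.0, rotation_deg=0.0,
            elastic_alpha=0.0, elastic_sigma=1.0, elastic_alpha_affine=0.0,
            crop_size=crop_size, crop_max_outside=0,
            gamma_range=(1.0, 1.0), noise_sd_fraction=0.0,
        )


def _check_shapes(img: np.ndarray, mask: np.ndarray) -> None:
    if img.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape} vs {mask.shape}")


def random_horizontal_flip(img, mask, rng: np.random.Generator, prob: float = 0.5):
    """Mirror both grids about the vertical axis with the given probability."""
    _check_shapes(img, mask)
    if rng.uniform() < prob:
        return img[:, ::-1].copy(), mask[:, ::-1].copy()
    return img, mask


def random_rotation(img, mask, rng: np.random.Generator, range_deg: float = 5.0):
    """Rotate both grids by one angle drawn uniformly from +-range_deg.

    Image uses linear interpolation, mask nearest-neighbour; out-of-bounds
    regions are filled with 0 / background, so the mask value set is
    preserved.
    """
    _check_shapes(img, mask)
    angle = rng.uniform(-range_deg, range_deg)
    if angle == 0.0:
        return img, mask
    out_img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
    out_mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant", cval=0)
    return out_img, out_mask


def _elastic_coordinates(shape, rng, alpha, sigma, alpha_affine):
    """Sampling coordinates for one random elastic + affine warp.

    Displacements are uniform [-1, 1] fields smoothed by a Gaussian of width
    ``sigma`` and scaled by ``alpha``; the affine part jitters three anchor
    points by uniform offsets of scale ``alpha_affine`` and solves for the
    induced affine map.
    """
    h, w = shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rows, cols]).astype(np.float64)

    if alpha_affine > 0:
        center = np.array([h, w], dtype=np.float64) / 2.0
        third = min(h, w) / 3.0
        src = np.array([center + [-third, -third],
                        center + [-third, third],
                        center + [third, -third]])
        dst = src + rng.uniform(-alpha_affine, alpha_affine, size=(3, 2))
        # affine (A, b) with dst = A @ src + b, inverted for pull-back sampling
        src_h = np.hstack([src, np.ones((3, 1))])
        params, *_ = np.linalg.lstsq(src_h, dst, rcond=None)
        A = params[:2].T
        b = params[2]
        Ainv = np.linalg.inv(A)
        flat = coords.reshape(2, -1)
        coords = (Ainv @ (flat - b[:, None])).reshape(2, h, w)

    if alpha > 0:
        for axis in range(2):
            noise = rng.uniform(-1, 1, size=shape)
            coords[axis] += ndimage.gaussian_filter(noise, sigma, mode="constant") * alpha
    return coords


def elastic_deformation(img, mask, rng: np.random.Generator,
                        alpha: float = 1.0, sigma: float = 100.0,
                        alpha_affine: float = 20.0):
    """Apply one random elastic + affine warp jointly to image and mask."""
    _check_shapes(img, mask)
    if alpha < 0 or sigma < 0 or alpha_affine < 0:
        raise ValueError("alpha, sigma and alpha_affine must be non-negative")
    if alpha == 0 and alpha_affine == 0:
        return img, mask
    coords = _elastic_coordinates(img.shape, rng, alpha, sigma, alpha_affine)
    out_img = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
    out_mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant", cval=0)
    return out_img, out_mask


def random_crop(img, mask, rng: np.random.Generator,
                size: int = 512, max_outside: int = 64):
    """Crop a size x size window, allowed at most ``max_outside`` pixels
    beyond each image edge; the out-of-image area is zero/background padded.

    Small inputs are centred and padded rather than rejected.
    """
    _check_shapes(img, mask)
    h, w = img.shape

    def _origin(dim: int) -> int:
        lo, hi = -max_outside, dim - size + max_outside
        if hi < lo:  # image too small for the overshoot rule: centre it
            return (dim - size) // 2
        return int(rng.integers(lo, hi + 1))

    r0, c0 = _origin(h), _origin(w)
    out_img = np.zeros((size, size), dtype=img.dtype)
    out_mask = np.zeros((size, size), dtype=mask.dtype)
    r_lo, r_hi = max(r0, 0), min(r0 + size, h)
    c_lo, c_hi = max(c0, 0), min(c0 + size, w)
    if r_lo < r_hi and c_lo < c_hi:
        out_img[r_lo - r0:r_hi - r0, c_lo - c0:c_hi - c0] = img[r_lo:r_hi, c_lo:c_hi]
        out_mask[r_lo - r0:r_hi - r0, c_lo - c0:c_hi - c0] = mask[r_lo:r_hi, c_lo:c_hi]
    return out_img, out_mask


def random_gamma(img, rng: np.random.Generator, range=(0.5, 1.5)):
    """Power-law intensity transform with gamma uniform in ``range``."""
    if img.min() < 0 or img.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    gamma = rng.uniform(*range)
    return np.power(img, gamma)


def add_gaussian_noise(img, rng: np.random.Generator, sd_fraction: float = 0.05):
    """Add zero-mean Gaussian noise with sd = sd_fraction x image range,
    clipping the result back to [0, 1]."""
    if sd_fraction == 0:
        return img
    rng_span = float(img.max() - img.min())
    noise = rng.normal(0.0, sd_fraction * rng_span, size=img.shape)
    return np.clip(img + noise, 0.0, 1.0)


def augment_sample(
    img: Mammogram,
    mask: LabelGrid,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, LabelGrid]:
    """Run the full augmentation stack on one image/mask pair.

    Order: window jitter -> flip -> rotation -> elastic -> crop -> gamma ->
    noise.  Geometric steps are applied jointly; intensity steps are
    image-only.  Output is a crop_size x crop_size grid in [0, 1] plus the
    matching mask.
    """
    n_windows = max(1, len(img.windows))
    widx = int(rng.integers(0, n_windows))
    x = apply_windowing(img, window_index=widx, jitter_fraction=policy.lut_jitter, rng=rng)
    m = mask.labels
    x, m = random_horizontal_flip(x, m, rng, policy.flip_prob)
    x, m = random_rotation(x, m, rng, policy.rotation_deg)
    x, m = elastic_deformation(x, m, rng, policy.elastic_alpha,
                               policy.elastic_sigma, policy.elastic_alpha_affine)
    x, m = random_crop(x, m, rng, policy.crop_size, policy.crop_max_outside)
    x = np.clip(x, 0.0, 1.0)
    x = random_gamma(x, rng, policy.gamma_range)
    x = add_gaussian_noise(x, rng, policy.noise_sd_fraction)
    return x, LabelGrid(labels=m.astype(np.uint8), spacing_um=mask.spacing_um)
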