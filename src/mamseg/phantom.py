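"""Synthetic mammogram phantoms with exact ground-truth masks.

The generator emulates, at desk scale, the statistical profile of screening
mammogram collections: CC/MLO view geometry with the breast attached to the
chest-wall (left) edge, a pectoral muscle present in ~99% of MLO and ~28%
of CC images occupying on average ~21% (MLO) respectively ~4% (CC) of the
breast area, paired raw/processed renderings of the same anatomy sharing
one truth mask, and parameterized vendor styles that vary gray level,
contrast, texture and noise.

Geometry is deliberately primitive - a tilted half-ellipse breast with a
corner wedge (MLO) or a thin chest-wall crescent (CC) for the pectoral
muscle - sufficient to exercise every pipeline stage, with truth masks exact
by construction.  No claim of anatomical or radiographic realism is made.

The pectoral region is carved out of the breast by thresholding a monotone
"distance from the chest-wall corner" field at the quantile matching the
drawn area fraction, so the realized pectoral/breast area ratio matches the
draw to within one pixel plus ties.

Raw renderings mimic attenuation images: bright unattenuated background,
darker dense tissue, compressed contrast - the opposite polarity of
processed displays, which is what makes models trained on processed images
alone fail on raw input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image_io import LabelGrid, Mammogram, write_mask

__all__ = [
    "VendorStyle", "PhantomConfig", "PhantomSample",
    "default_styles", "inverted_style", "film_style",
    "apply_style", "generate_phantom", "generate_samples", "generate_dataset",
]


@dataclass(frozen=True)
class VendorStyle:
    """Display-processing style of a (synthetic) vendor."""

    name: str
    gamma: float = 1.0
    contrast_gain: float = 0.9
    background_level: float = 0.05
    texture_scale: float = 6.0
    noise_sd: float = 0.02
    film_artifacts: bool = False
    invert: bool = False

    def __post_init__(self):
        if not 0 <= self.background_level < 1:
            raise ValueError("background_level must be in [0, 1)")
        if self.gamma <= 0 or self.contrast_gain <= 0 or self.noise_sd < 0:
            raise ValueError("gamma/contrast_gain must be positive, noise_sd >= 0")


def default_styles() -> list[VendorStyle]:
    """Three distinct digital-vendor-like styles."""
    return [
        VendorStyle("vendorA", gamma=1.0, contrast_gain=0.90, background_level=0.05,
                    texture_scale=6.0, noise_sd=0.020),
        VendorStyle("vendorB", gamma=0.70, contrast_gain=0.80, background_level=0.12,
                    texture_scale=9.0, noise_sd=0.030),
        VendorStyle("vendorC", gamma=1.35, contrast_gain=1.00, background_level=0.02,
                    texture_scale=4.0, noise_sd=0.015),
    ]


def inverted_style() -> VendorStyle:
    """An adversarial style with inverted display polarity."""
    return VendorStyle("inverted", gamma=1.0, contrast_gain=0.9,
                       background_level=0.05, noise_sd=0.02, invert=True)


def film_style() -> VendorStyle:
    """A digitized-film-like style with bright labels and film edges."""
    return VendorStyle("film", gamma=0.85, contrast_gain=0.75, background_level=0.15,
                       texture_scale=8.0, noise_sd=0.035, film_artifacts=True)


@dataclass
class PhantomConfig:
    """Study-condition parameters of the phantom population.

    Prevalence and size defaults mirror the data profile the pipeline is
    meant for: pectoral muscle visible in 99% of MLO and 28% of CC images;
    pectoral/breast area fraction ~ Normal(0.21, 0.14) for MLO and
    Normal(0.04, 0.03) for CC, clipped to the feasible range.
    """

    image_size: int = 256
    spacing_um: float = 400.0
    mlo_fraction: float = 0.5
    pectoral_prob: dict = field(default_factory=lambda: {"MLO": 0.99, "CC": 0.28})
    pectoral_area: dict = field(default_factory=lambda: {
        "MLO": (0.21, 0.14), "CC": (0.04, 0.03)})
    styles: list[VendorStyle] = field(default_factory=default_styles)
    images_per_patient: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mlo_fraction <= 1:
            raise ValueError("mlo_fraction must be a probability")
        for v, p in self.pectoral_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"pectoral_prob[{v}] must be a probability")


@dataclass
class PhantomSample:
    """One phantom: paired raw/processed images plus the shared truth mask."""

    raw: Mammogram
    processed: Mammogram
    truth: LabelGrid
    patient_id: str
    style: str
    view: str
    pectoral_fraction: float | None = None  # the drawn area fraction, if any

    @property
    def image(self) -> np.ndarray:
        """Processed intensities in [0, 1] (the default network input)."""
        return self.processed.pixels

    @property
    def vendor(self) -> str:
        return self.style

    @property
    def kind(self) -> str:
        return "processed"


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field with given correlation length."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _draw_area_fraction(rng, mean: float, sd: float) -> float:
    """Clipped-normal area-fraction draw; falls back to the mean if 100
    consecutive draws land outside the feasible range."""
    for _ in range(100):
        f = rng.normal(mean, sd)
        if 0.005 < f < 0.9:
            return float(f)
    return float(mean)


def _breast_geometry(rng, size: int, view: str):
    """Boolean breast mask attached to the left edge, plus its row centre.

    MLO breasts are taller, reach the top-left corner (where the pectoral
    wedge sits) and are slightly tilted; CC breasts are vertically centred
    half-ellipses.
    """
    h = w = size
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if view == "MLO":
        rc = rng.uniform(0.38, 0.48) * h
        a = rc + rng.uniform(0.08, 0.25) * h       # reaches past the top edge
        b = rng.uniform(0.50, 0.68) * w
        shear = rng.uniform(0.05, 0.25)
        r_eff = (rr - rc) + shear * cc
    else:
        rc = rng.uniform(0.45, 0.55) * h
        a = rng.uniform(0.30, 0.42) * h
        b = rng.uniform(0.45, 0.62) * w
        r_eff = rr - rc
    implicit = (r_eff / a) ** 2 + (cc / b) ** 2
    wobble = 0.06 * _smooth_field(rng, (h, w), size / 8)
    breast = implicit <= 1.0 + wobble
    breast[:, 0] |= np.abs(rr[:, 0] - rc) < a * 0.95  # guarantee chest-wall attachment
    return breast, rc


def _pectoral_region(rng, breast: np.ndarray, view: str, rc: float,
                     fraction: float) -> np.ndarray:
    """Carve a pectoral region of the requested breast-area fraction.

    A monotone corner field g is thresholded at its k-th smallest value over
    breast pixels with k = round(fraction * |breast|): a wedge grown from
    the top-left corner (MLO) or a thin half-ellipse hugging the chest wall
    (CC).
    """
    h, w = breast.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if view == "MLO":
        u_r = rng.uniform(0.9, 1.4)
        u_c = rng.uniform(0.5, 0.9)
        g = rr / (u_r * h) + cc / (u_c * w)
    else:
        rc_p = rc + rng.uniform(-0.08, 0.08) * h
        vh = rng.uniform(0.30, 0.45) * h
        vw = rng.uniform(0.06, 0.12) * w
        g = np.sqrt(((rr - rc_p) / vh) ** 2 + (cc / vw) ** 2)
    vals = g[breast]
    k = int(round(fraction * vals.size))
    if k <= 0:
        return np.zeros_like(breast)
    k = min(k, vals.size)
    thr = np.partition(vals, k - 1)[k - 1]
    return breast & (g <= thr)


def apply_style(intensity: np.ndarray, style: VendorStyle,
                rng: np.random.Generator,
                background: np.ndarray | None = None) -> np.ndarray:
    """Render a normalized tissue map through a vendor display style.

    Monotone in the input apart from noise: gain and background offset, a
    gamma curve, optional polarity inversion, additive Gaussian noise, and -
    for film styles - bright label/edge artifacts outside the breast.
    """
    if intensity.min() < 0 or intensity.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    out = style.background_level + style.contrast_gain * intensity
    out = np.clip(out, 0.0, 1.0) ** style.gamma
    if style.invert:
        out = 1.0 - out
    if style.noise_sd > 0:
        out = out + rng.normal(0.0, style.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    if style.film_artifacts:
        h, w = out.shape
        # bright film label in the far (non-chest) background corner
        lh, lw = max(2, h // 10), max(2, w // 7)
        r0 = int(rng.uniform(0.05, 0.25) * h)
        c0 = int(rng.uniform(0.70, 0.85) * w)
        out[r0:r0 + lh, c0:c0 + lw] = rng.uniform(0.85, 1.0)
        out[:, -max(1, w // 64):] = rng.uniform(0.8, 1.0)  # digitized film edge
        if background is not None:
            out = np.where(background | (out > 0), out, out)
    return out


def generate_phantom(config: PhantomConfig, rng: np.random.Generator,
                     view: str | None = None, style: VendorStyle | None = None,
                     patient_id: str = "p0") -> PhantomSample:
    """Generate one phantom sample (raw + processed + truth)."""
    size = config.image_size
    if view is None:
        view = "MLO" if rng.uniform() < config.mlo_fraction else "CC"
    if style is None:
        style = config.styles[int(rng.integers(len(config.styles)))]

    breast, rc = _breast_geometry(rng, size, view)
    labels = breast.astype(np.uint8)
    frac = None
    if rng.uniform() < config.pectoral_prob[view]:
        mean, sd = config.pectoral_area[view]
        frac = _draw_area_fraction(rng, mean, sd)
        pect = _pectoral_region(rng, breast, view, rc, frac)
        labels[pect] = 2

    # breast/pectoral contrast dominates texture so the pectoral class is a
    # clearly bimodal component of the breast-interior histogram, as it must
    # be for Otsu-based mask initialization to be meaningful on this data
    texture = _smooth_field(rng, (size, size), style.texture_scale)
    tissue = np.zeros((size, size))
    tissue[labels == 1] = np.clip(0.52 + 0.08 * texture[labels == 1], 0.30, 0.75)
    tissue[labels == 2] = np.clip(0.85 + 0.04 * texture[labels == 2], 0.70, 1.00)

    processed_px = apply_style(tissue, style, rng, background=breast)
    # attenuation-like raw: bright background, darker dense tissue, low contrast
    raw_px = np.clip(0.93 - 0.40 * tissue + rng.normal(0.0, 0.01, tissue.shape), 0.0, 1.0)

    spacing = (config.spacing_um, config.spacing_um)
    common = dict(spacing_um=spacing, view=view, laterality="L", vendor=style.name)
    processed = Mammogram(pixels=processed_px, kind="processed",
                          windows=[(0.5, 1.0)], **common)
    raw = Mammogram(pixels=raw_px, kind="raw", **common)
    truth = LabelGrid(labels=labels, spacing_um=spacing)
    return PhantomSample(raw=raw, processed=processed, truth=truth,
                         patient_id=patient_id, style=style.name, view=view,
                         pectoral_fraction=frac)


def generate_samples(config: PhantomConfig, n_patients: int,
                     rng: np.random.Generator) -> list[PhantomSample]:
    """Generate an in-memory phantom cohort (1..k images per patient)."""
    lo, hi = config.images_per_patient
    out = []
    for p in range(n_patients):
        pid = f"p{p:04d}"
        for _ in range(int(rng.integers(lo, hi + 1))):
            out.append(generate_phantom(config, rng, patient_id=pid))
    return out


def generate_dataset(config: PhantomConfig, n_patients: int,
                     rng: np.random.Generator, out_dir: str | Path,
                     include_raw: bool = True):
    """Write a phantom dataset to disk and return its manifest.

    Produces 16-bit PNG images, {0,1,2} PNG masks and a manifest CSV with
    the columns the training/evaluation stages expect.
    """
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    samples = generate_samples(config, n_patients, rng)
    rows = []

    def _write_png(px: np.ndarray, path: Path) -> None:
        arr = np.round(np.clip(px, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(arr).save(path)

    for i, s in enumerate(samples):
        image_id = f"img{i:05d}"
        mask_path = out_dir / "masks" / f"{image_id}.png"
        write_mask(s.truth, mask_path)
        kinds = [("processed", s.processed)] + ([("raw", s.raw)] if include_raw else [])
        for kind, mg in kinds:
            img_path = out_dir / "images" / f"{image_id}_{kind}.png"
            try:
                _write_png(mg.pixels, img_path)
            except OSError as exc:
                raise OSError(f"failed writing {img_path}: {exc}") from exc
            rows.append({
                "patient_id": s.patient_id, "image_id": f"{image_id}_{kind}",
                "path": str(img_path), "mask_path": str(mask_path),
                "view": s.view, "laterality": "L", "kind": kind,
                "vendor": s.style, "spacing_um": config.spacing_um,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
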