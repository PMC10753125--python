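"""Reading, writing and resampling of mammograms and label masks.

A :class:`Mammogram` couples a 2-D intensity grid with the acquisition
metadata downstream stages need: pixel spacing, view (CC/MLO), laterality,
image kind (raw / processed / digitized film), vendor tag, display windows
and photometric convention.  A :class:`LabelGrid` is the paired integer mask
with 0 = background, 1 = breast, 2 = pectoral muscle.

All images are brought to a canonical form before segmentation: a common
pixel spacing (400 um by default) and chest wall on the left image edge, so
pectoral-muscle logic never has to branch on laterality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

__all__ = [
    "Mammogram",
    "LabelGrid",
    "MetadataError",
    "MaskFormatError",
    "read_image",
    "read_mask",
    "write_mask",
    "resample_to_spacing",
    "resample_mask",
    "apply_windowing",
    "orient_chest_wall_left",
    "read_manifest",
]

VIEWS = ("CC", "MLO")
KINDS = ("raw", "processed", "sfm")


class MetadataError(ValueError):
    """Required acquisition metadata is missing or invalid."""


class MaskFormatError(ValueError):
    """A mask file violates the {0,1,2} single-channel contract."""


@dataclass
class Mammogram:
    """A 2-D mammographic image plus acquisition metadata.

    ``pixels`` stores non-negative intensities with higher value = more
    radio-opaque (white-is-low sources are inverted on load and the original
    convention recorded in ``photometric``).  ``windows`` holds (center,
    width) display-window pairs; processed images always carry at least one
    (a full-range window is synthesized when metadata lacks it).
    """

    pixels: np.ndarray
    spacing_um: tuple[float, float]
    view: str = "MLO"
    laterality: str = "L"
    kind: str = "processed"
    vendor: str = "unknown"
    windows: list[tuple[float, float]] = field(default_factory=list)
    photometric: str = "white-is-high"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        sr, sc = self.spacing_um
        if sr <= 0 or sc <= 0:
            raise ValueError("spacing_um must be positive")
        self.spacing_um = (float(sr), float(sc))
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind in ("processed", "sfm") and not self.windows:
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            width = max(hi - lo, 1.0)
            self.windows = [((lo + hi) / 2.0, width)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelGrid:
    """Integer segmentation mask: 0 background, 1 breast, 2 pectoral."""

    labels: np.ndarray
    spacing_um: tuple[float, float] = (400.0, 400.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int64)
        vals = np.unique(self.labels)
        if not np.isin(vals, (0, 1, 2)).all():
            raise MaskFormatError(f"labels outside {{0,1,2}}: {vals}")
        sr, sc = self.spacing_um
        if sr <= 0 or sc <= 0:
            raise ValueError("spacing_um must be positive")
        self.spacing_um = (float(sr), float(sc))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _round_half_away(x: float) -> int:
    """Round half away from zero (bankers' rounding would bias dimensions)."""
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def read_manifest(path: str | Path):
    """Load a manifest CSV describing raster images.

    Expected columns: patient_id, image_id, path, view, laterality, kind,
    vendor, spacing_um and optionally split.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"patient_id", "image_id", "path", "view", "laterality", "kind", "vendor", "spacing_um"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"manifest lacks columns: {sorted(missing)}")
    return df


def _read_dicom(path: Path, kind: str | None) -> Mammogram:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array.astype(np.float64)
    except Exception as exc:  # noqa: BLE001 - surface as input error
        raise IOError(f"unreadable DICOM file {path}: {exc}") from exc

    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise MetadataError(f"{path}: no pixel spacing in DICOM metadata")
    spacing_um = (float(spacing[0]) * 1000.0, float(spacing[1]) * 1000.0)

    photometric = "white-is-high"
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        # white-is-low: invert so that higher value = more radio-opaque
        pixels = pixels.max() - pixels
        photometric = "white-is-low"

    windows: list[tuple[float, float]] = []
    wc = getattr(ds, "WindowCenter", None)
    ww = getattr(ds, "WindowWidth", None)
    if wc is not None and ww is not None:
        centers = wc if isinstance(wc, pydicom.multival.MultiValue) else [wc]
        widths = ww if isinstance(ww, pydicom.multival.MultiValue) else [ww]
        windows = [(float(c), float(w)) for c, w in zip(centers, widths)]

    view = str(getattr(ds, "ViewPosition", "MLO") or "MLO").upper()
    if view not in VIEWS:
        view = "MLO"
    laterality = str(
        getattr(ds, "ImageLaterality", None) or getattr(ds, "Laterality", "L") or "L"
    ).upper()
    if laterality not in ("L", "R"):
        laterality = "L"
    if kind is None:
        # PresentationIntentType distinguishes FOR PROCESSING / FOR PRESENTATION
        intent = str(getattr(ds, "PresentationIntentType", "FOR PRESENTATION"))
        kind = "raw" if "PROCESSING" in intent.upper() else "processed"

    return Mammogram(
        pixels=pixels,
        spacing_um=spacing_um,
        view=view,
        laterality=laterality,
        kind=kind,
        vendor=str(getattr(ds, "Manufacturer", "unknown") or "unknown"),
        windows=windows,
        photometric=photometric,
    )


def read_image(path: str | Path, kind: str | None = None, manifest_row=None) -> Mammogram:
    """Read a DICOM or raster mammogram.

    For raster files (PNG/TIFF) the acquisition metadata comes from
    ``manifest_row`` (a mapping with view/laterality/kind/vendor/spacing_um
    keys); DICOM files carry their own.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        return _read_dicom(path, kind)

    try:
        arr = np.asarray(Image.open(path), dtype=np.float64)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    if manifest_row is None:
        raise MetadataError(f"{path}: raster image requires a manifest row for metadata")
    spacing = float(manifest_row["spacing_um"])
    return Mammogram(
        pixels=arr,
        spacing_um=(spacing, spacing),
        view=str(manifest_row["view"]).upper(),
        laterality=str(manifest_row.get("laterality", "L")).upper(),
        kind=kind or str(manifest_row["kind"]),
        vendor=str(manifest_row.get("vendor", "unknown")),
    )


def resample_to_spacing(img: Mammogram, target_um: float = 400.0) -> Mammogram:
    """Linearly resample an image to an isotropic target pixel spacing.

    The new grid dimension along each axis is round(old_dim * old_spacing /
    target), rounding half away from zero.  An image already at the target
    spacing is returned unchanged.
    """
    if target_um <= 0:
        raise ValueError("target_um must be positive")
    sr, sc = img.spacing_um
    if sr == target_um and sc == target_um:
        return img
    h, w = img.pixels.shape
    new_h = max(1, _round_half_away(h * sr / target_um))
    new_w = max(1, _round_half_away(w * sc / target_um))
    out = resize(img.pixels, (new_h, new_w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return replace(img, pixels=out, spacing_um=(float(target_um), float(target_um)))


def resample_mask(mask: LabelGrid, target_um: float) -> LabelGrid:
    """Nearest-neighbour resample of a label mask (value set preserved)."""
    if target_um <= 0:
        raise ValueError("target_um must be positive")
    sr, sc = mask.spacing_um
    if sr == target_um and sc == target_um:
        return mask
    h, w = mask.labels.shape
    new_h = max(1, _round_half_away(h * sr / target_um))
    new_w = max(1, _round_half_away(w * sc / target_um))
    out = resize(mask.labels, (new_h, new_w), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True).astype(mask.labels.dtype)
    return LabelGrid(labels=out, spacing_um=(float(target_um), float(target_um)))


def apply_windowing(
    img: Mammogram,
    window_index: int = 0,
    jitter_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    raw_log_transform: bool = False,
) -> np.ndarray:
    """Map stored intensities to display values in [0, 1] via a linear ramp.

    The (center, width) pair is taken from the image metadata; with
    ``jitter_fraction`` > 0 both are perturbed multiplicatively by
    independent uniform draws in [-jitter, +jitter], emulating the
    training-time look-up-table jitter.  ``jitter_fraction=0`` reproduces the
    metadata window exactly (the test-time "normal" setting).

    Raw images bypass windowing: they are min-max normalized to [0, 1],
    optionally after a log(1 + x) transform (``raw_log_transform``).
    """
    if not 0 <= jitter_fraction < 1:
        raise ValueError("jitter_fraction must be in [0, 1)")
    x = img.pixels
    if img.kind == "raw":
        if raw_log_transform:
            x = np.log1p(x - x.min())
        lo, hi = float(x.min()), float(x.max())
        return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)
    if not img.windows:
        raise MetadataError("no display window available")
    center, width = img.windows[int(window_index) % len(img.windows)]
    if width <= 0:
        raise MetadataError(f"non-positive window width {width}")
    if jitter_fraction > 0:
        if rng is None:
            rng = np.random.default_rng()
        u1, u2 = rng.uniform(-jitter_fraction, jitter_fraction, size=2)
        center = center * (1.0 + u1)
        width = width * (1.0 + u2)
    lo = center - width / 2.0
    return np.clip((x - lo) / width, 0.0, 1.0)


def _infer_chest_side(pixels: np.ndarray) -> str:
    """Guess which vertical edge carries the chest wall.

    The breast is attached to the chest wall, so the edge third with more
    above-median intensity mass is taken as the chest side.
    """
    thr = np.median(pixels)
    fg = pixels > thr
    w = pixels.shape[1]
    third = max(1, w // 3)
    left_mass = int(fg[:, :third].sum())
    right_mass = int(fg[:, -third:].sum())
    return "left" if left_mass >= right_mass else "right"


def orient_chest_wall_left(
    img: Mammogram, mask: LabelGrid | None = None
) -> tuple[Mammogram, LabelGrid | None, bool]:
    """Flip the image (and mask) so the chest wall touches the left edge.

    Right-laterality images are mirrored; unknown laterality falls back to
    inferring the chest side from where the breast mass sits.  The returned
    flag records whether a flip happened so predictions can be un-flipped.
    """
    if img.laterality == "R":
        flip = True
    elif img.laterality == "L":
        flip = False
    else:
        flip = _infer_chest_side(img.pixels) == "right"
    if not flip:
        return img, mask, False
    out_img = replace(img, pixels=img.pixels[:, ::-1].copy(), laterality="L")
    out_mask = None
    if mask is not None:
        out_mask = LabelGrid(labels=mask.labels[:, ::-1].copy(), spacing_um=mask.spacing_um)
    return out_img, out_mask, True


def read_mask(path: str | Path) -> LabelGrid:
    """Read a single-channel {0,1,2} PNG mask."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise MaskFormatError(f"{path}: mask must be single-channel")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1, 2)).all():
        raise MaskFormatError(f"{path}: values outside {{0,1,2}}: {vals}")
    return LabelGrid(labels=arr.astype(np.uint8))


def write_mask(mask: LabelGrid, path: str | Path) -> None:
    """Write a mask as single-channel 8-bit PNG (lossless round-trip)."""
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
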