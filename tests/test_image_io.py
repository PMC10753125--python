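"""Image/mask I/O, resampling, windowing and orientation."""

import numpy as np
import pytest
from PIL import Image

from mamseg.image_io import (LabelGrid, Mammogram, MaskFormatError, MetadataError,
                             apply_windowing, orient_chest_wall_left, read_image,
                             read_mask, resample_mask, resample_to_spacing,
                             write_mask)


def _mammogram(pixels, kind="processed", **kw):
    return Mammogram(pixels=np.asarray(pixels, dtype=float),
                     spacing_um=kw.pop("spacing_um", (400.0, 400.0)),
                     kind=kind, **kw)


class TestResampling:
    @pytest.mark.parametrize(
        "shape, spacing, target, expected",
        [
            ((100, 100), 200.0, 400.0, (50, 50)),      # factor-2 decimation
            ((512, 100), 70.0, 400.0, (90, 18)),       # round(512*70/400) = 90
            ((333, 333), 85.0, 400.0, (71, 71)),       # round(333*85/400) = 70.76 -> 71
        ],
    )
    def test_output_dimensions(self, shape, spacing, target, expected, rng):
        img = _mammogram(rng.uniform(size=shape), spacing_um=(spacing, spacing))
        out = resample_to_spacing(img, target)
        assert out.pixels.shape == expected
        assert out.spacing_um == (target, target)

    def test_identity_at_target_spacing(self, rng):
        img = _mammogram(rng.uniform(size=(40, 40)))
        assert resample_to_spacing(img, 400.0) is img

    def test_smooth_image_mean_preserved(self, rng):
        # smooth synthetic image: global mean within 2% after resampling
        r, c = np.meshgrid(np.linspace(0, 1, 200), np.linspace(0, 1, 200), indexing="ij")
        img = _mammogram(0.3 + 0.4 * np.sin(3 * r) * np.cos(2 * c) ** 2,
                         spacing_um=(150.0, 150.0))
        out = resample_to_spacing(img, 400.0)
        assert out.pixels.mean() == pytest.approx(img.pixels.mean(), rel=0.02)

    def test_nonpositive_target_rejected(self, rng):
        img = _mammogram(rng.uniform(size=(10, 10)))
        with pytest.raises(ValueError):
            resample_to_spacing(img, 0.0)

    def test_mask_constant_and_value_set(self, rng):
        const = LabelGrid(np.full((30, 30), 2, dtype=np.uint8), spacing_um=(100.0, 100.0))
        out = resample_mask(const, 400.0)
        assert set(np.unique(out.labels)) == {2}
        mixed = LabelGrid(rng.integers(0, 3, size=(64, 64)).astype(np.uint8),
                          spacing_um=(200.0, 200.0))
        out = resample_mask(mixed, 400.0)
        assert set(np.unique(out.labels)) <= {0, 1, 2}

    def test_mask_round_trip_agreement(self, rng):
        # large blocky mask survives resample + inverse-resample >= 95%
        blocks = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
        labels = np.kron(blocks, np.ones((16, 16), dtype=np.uint8))
        mask = LabelGrid(labels, spacing_um=(400.0, 400.0))
        down = resample_mask(mask, 600.0)
        back = resample_mask(down, 400.0)
        agree = (back.labels == labels).mean()
        assert agree >= 0.95


class TestWindowing:
    def test_ramp_midpoint_and_clipping(self):
        img = _mammogram([[100.0, 200.0, 300.0, 50.0, 350.0]],
                         windows=[(200.0, 200.0)])
        out = apply_windowing(img, jitter_fraction=0.0)
        assert out[0, 1] == pytest.approx(0.5)        # pixel at the center
        assert out[0, 3] == 0.0                       # below center - width/2
        assert out[0, 4] == 1.0                       # above center + width/2

    def test_jitter_statistics(self, rng):
        # realized centers stay within +-5% of base and fill that range
        img = _mammogram(np.linspace(0, 400, 64).reshape(8, 8),
                         windows=[(200.0, 100.0)])
        lo = apply_windowing(img, jitter_fraction=0.0)
        centers = []
        for _ in range(10_000):
            out = apply_windowing(img, jitter_fraction=0.05, rng=rng)
            # recover the realized center: intensity 0.5 crossing of the ramp
            # out = clip((x - c' + w'/2) / w'), solve via two sample points
            x0, x1 = img.pixels.flat[30], img.pixels.flat[35]  # inside every jittered ramp
            y0, y1 = out.flat[30], out.flat[35]
            w = (x1 - x0) / (y1 - y0)
            c = x0 - w * (y0 - 0.5)
            centers.append(c)
        centers = np.asarray(centers)
        assert centers.min() >= 200.0 * 0.95 - 1e-6
        assert centers.max() <= 200.0 * 1.05 + 1e-6
        # uniform law on +-5%: sd = 0.05 * 200 / sqrt(3)
        assert centers.std() == pytest.approx(0.05 * 200 / np.sqrt(3), rel=0.05)
        assert np.array_equal(lo, apply_windowing(img, jitter_fraction=0.0))

    def test_monotone_in_intensity(self, rng):
        img = _mammogram(np.sort(rng.uniform(0, 500, size=(1, 100))),
                         windows=[(250.0, 150.0)])
        out = apply_windowing(img, jitter_fraction=0.05, rng=rng)
        assert np.all(np.diff(out[0]) >= 0)

    def test_raw_images_min_max_normalized(self, rng):
        img = _mammogram(rng.uniform(10, 90, size=(16, 16)), kind="raw")
        out = apply_windowing(img)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_nonpositive_width_rejected(self):
        img = _mammogram(np.ones((4, 4)), windows=[(10.0, 0.0)])
        with pytest.raises(MetadataError):
            apply_windowing(img)


class TestMaskIO:
    def test_round_trip_lossless(self, tmp_path, rng):
        labels = rng.integers(0, 3, size=(37, 41)).astype(np.uint8)
        path = tmp_path / "m.png"
        write_mask(LabelGrid(labels), path)
        assert np.array_equal(read_mask(path).labels, labels)

    def test_empty_mask_round_trip(self, tmp_path):
        path = tmp_path / "z.png"
        write_mask(LabelGrid(np.zeros((8, 8), dtype=np.uint8)), path)
        assert read_mask(path).labels.sum() == 0

    def test_out_of_range_value_rejected(self, tmp_path):
        path = tmp_path / "bad.png"
        Image.fromarray(np.full((8, 8), 3, dtype=np.uint8), mode="L").save(path)
        with pytest.raises(MaskFormatError):
            read_mask(path)


class TestDicom:
    @pytest.fixture()
    def dicom_path(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        arr = np.arange(64, dtype=np.uint16).reshape(8, 8)
        ds.Rows, ds.Columns = arr.shape
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.SamplesPerPixel = 1
        ds.PixelRepresentation = 0
        ds.PhotometricInterpretation = "MONOCHROME1"
        ds.PixelSpacing = [0.07, 0.07]
        ds.WindowCenter, ds.WindowWidth = 30.0, 40.0
        ds.ViewPosition = "MLO"
        ds.ImageLaterality = "R"
        ds.PixelData = arr.tobytes()
        path = tmp_path / "img.dcm"
        ds.save_as(path, enforce_file_format=True)
        return path

    def test_metadata_and_inversion(self, dicom_path):
        img = read_image(dicom_path)
        assert img.spacing_um == (70.0, 70.0)         # 0.07 mm -> 70 um
        assert img.view == "MLO" and img.laterality == "R"
        assert img.windows == [(30.0, 40.0)]
        assert img.photometric == "white-is-low"
        # MONOCHROME1: the max stored value maps to the min loaded intensity
        assert img.pixels[-1, -1] == img.pixels.min()


class TestRasterManifest:
    def test_fields_from_manifest_row(self, tmp_path, rng):
        arr = (rng.uniform(size=(16, 16)) * 65535).astype(np.uint16)
        path = tmp_path / "img.png"
        Image.fromarray(arr).save(path)
        row = {"view": "MLO", "laterality": "L", "kind": "processed",
               "vendor": "acme", "spacing_um": 85.0}
        img = read_image(path, manifest_row=row)
        assert img.view == "MLO" and img.vendor == "acme"
        assert img.spacing_um == (85.0, 85.0)

    def test_raster_without_manifest_rejected(self, tmp_path):
        path = tmp_path / "img.png"
        Image.fromarray(np.zeros((4, 4), dtype=np.uint8)).save(path)
        with pytest.raises(MetadataError):
            read_image(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(IOError):
            read_image(tmp_path / "nope.png")


class TestOrientation:
    def test_right_laterality_flipped(self, rng):
        px = rng.uniform(size=(8, 8))
        img = _mammogram(px, laterality="R")
        out, _, flipped = orient_chest_wall_left(img)
        assert flipped and np.array_equal(out.pixels, px[:, ::-1])

    def test_left_unchanged_and_idempotent(self, rng):
        img = _mammogram(rng.uniform(size=(8, 8)), laterality="L")
        out, _, flipped = orient_chest_wall_left(img)
        assert not flipped
        out2, _, flipped2 = orient_chest_wall_left(out)
        assert not flipped2 and np.array_equal(out2.pixels, out.pixels)

    def test_mask_flipped_with_image(self, rng):
        labels = rng.integers(0, 3, size=(8, 8)).astype(np.uint8)
        img = _mammogram(rng.uniform(size=(8, 8)), laterality="R")
        _, mask_out, _ = orient_chest_wall_left(img, LabelGrid(labels))
        assert np.array_equal(mask_out.labels, labels[:, ::-1])

    def test_inference_on_phantoms(self):
        # laterality withheld: the chest side must be inferred from breast mass
        from mamseg.phantom import PhantomConfig, generate_phantom

        cfg = PhantomConfig(image_size=64)
        gen = np.random.default_rng(11)
        correct = 0
        for i in range(100):
            s = generate_phantom(cfg, gen)
            flip_truth = bool(gen.integers(2))
            px = s.processed.pixels[:, ::-1] if flip_truth else s.processed.pixels
            img = Mammogram(pixels=px.copy(), spacing_um=(400.0, 400.0),
                            laterality="U", kind="processed", view=s.view)
            _, _, flipped = orient_chest_wall_left(img)
            correct += flipped == flip_truth
        assert correct >= 99
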