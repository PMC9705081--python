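"""Padding, resizing, rotation and manifest IO contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pterynet import preprocess_io as pio


def _img(h, w, seed=0):
    rng = np.random.default_rng(seed)
    return pio.AnteriorSegmentImage(rng.integers(0, 256, (h, w, 3), dtype=np.uint8))


# ---------------------------------------------------------------------------
# pad_to_square
# ---------------------------------------------------------------------------

def test_pad_landscape_frame_gets_two_56px_bands():
    """A 336(W)x224(H) frame pads to 336x336 with equal gray bands."""
    out = pio.pad_to_square(_img(224, 336))
    assert (out.height, out.width) == (336, 336)
    assert (out.pixels[:56] == 128).all() and (out.pixels[-56:] == 128).all()
    assert np.array_equal(out.pixels[56:280], _img(224, 336).pixels)


def test_pad_square_image_unchanged():
    img = _img(100, 100)
    assert np.array_equal(pio.pad_to_square(img).pixels, img.pixels)


def test_pad_7x4_matches_index_shift_oracle():
    """Band placement on odd remainders: extra pixel to the bottom/right."""
    img = _img(4, 7, seed=3)  # H=4, W=7 -> pad rows: 1 top, 2 bottom
    out = pio.pad_to_square(img, fill_value=200)
    expected = np.full((7, 7, 3), 200, np.uint8)
    expected[1:5, :, :] = img.pixels
    assert np.array_equal(out.pixels, expected)


@settings(max_examples=30, deadline=None)
@given(h=st.integers(1, 40), w=st.integers(1, 40), fill=st.integers(0, 255))
def test_pad_then_crop_recovers_original(h, w, fill):
    img = _img(h, w, seed=h * 41 + w)
    sq = pio.pad_to_square(img, fill)
    assert sq.height == sq.width == max(h, w)
    back = pio.crop_from_square(sq, h, w)
    assert np.array_equal(back.pixels, img.pixels)


def test_pad_rejects_bad_fill():
    with pytest.raises(pio.InvalidInputError):
        pio.pad_to_square(_img(4, 4), fill_value=300)


# ---------------------------------------------------------------------------
# resize
# ---------------------------------------------------------------------------

def test_resize_square_to_473():
    out = pio.resize_bilinear(_img(300, 300), 473, 473)
    assert (out.height, out.width) == (473, 473)


def test_resize_identity_is_exact():
    img = _img(37, 53, seed=5)
    assert np.array_equal(pio.resize_bilinear(img, 37, 53).pixels, img.pixels)


def test_resize_2x2_to_4x4_matches_closed_form():
    """Corner-aligned bilinear: output j samples source at j/3 on each axis."""
    src = np.zeros((2, 2, 3), np.uint8)
    src[:, :, 0] = [[0, 90], [180, 240]]
    out = pio.resize_bilinear(pio.AnteriorSegmentImage(src), 4, 4).pixels[:, :, 0]
    a = np.array([[0, 90], [180, 240]], float)
    expected = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            fy, fx = i / 3, j / 3
            expected[i, j] = ((1 - fy) * (1 - fx) * a[0, 0] + (1 - fy) * fx * a[0, 1]
                              + fy * (1 - fx) * a[1, 0] + fy * fx * a[1, 1])
    assert np.array_equal(out, np.rint(expected).astype(np.uint8))


def test_resize_rejects_nonpositive_target():
    with pytest.raises(pio.InvalidInputError):
        pio.resize_bilinear(_img(4, 4), 0, 4)


def test_mask_resize_stays_binary():
    rng = np.random.default_rng(8)
    mask = pio.SegMask(rng.integers(0, 2, (21, 13), dtype=np.uint8))
    out = pio.resize_mask_nearest(mask, 64, 64)
    assert set(np.unique(out.pixels)) <= {0, 1}
    assert (out.height, out.width) == (64, 64)


# ---------------------------------------------------------------------------
# rotation
# ---------------------------------------------------------------------------

def test_zero_rotation_is_identity():
    img, mask = _img(20, 20, 2), pio.SegMask(np.eye(20, dtype=np.uint8))
    out_img, out_mask = pio.random_rotate(img, mask, (0.0, 0.0), seed=1)
    assert np.array_equal(out_img.pixels, img.pixels)
    assert np.array_equal(out_mask.pixels, mask.pixels)


def test_rotation_deterministic_under_seed():
    img, mask = _img(24, 24, 4), pio.SegMask(np.zeros((24, 24), np.uint8))
    a = pio.random_rotate(img, mask, (-3, 3), seed=9)
    b = pio.random_rotate(img, mask, (-3, 3), seed=9)
    assert np.array_equal(a[0].pixels, b[0].pixels)
    assert np.array_equal(a[1].pixels, b[1].pixels)


def test_single_pixel_rotation_matches_rotation_matrix():
    """One on-pixel rotated 3 deg lands where the 2x2 rotation matrix says."""
    n = 41
    center = (n - 1) / 2
    mask = np.zeros((n, n), np.uint8)
    r0, c0 = 5, 30
    mask[r0, c0] = 1
    img = pio.AnteriorSegmentImage(np.zeros((n, n, 3), np.uint8))
    _, rotated = pio.rotate_pair(img, pio.SegMask(mask), 3.0)
    # content moves by R(-theta) in array coords (CCW on screen);
    # equivalently output (r,c) samples source at R(+theta) offsets.
    theta = math.radians(3.0)
    dy, dx = r0 - center, c0 - center
    # forward map of the source pixel:
    ex = math.cos(theta) * dx + math.sin(theta) * dy + center
    ey = -math.sin(theta) * dx + math.cos(theta) * dy + center
    on = np.argwhere(rotated.pixels == 1)
    assert len(on) >= 1
    dists = np.hypot(on[:, 0] - ey, on[:, 1] - ex)
    assert dists.min() <= 0.75  # nearest-neighbor quantization of one pixel


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_joint_rotation_preserves_binarity_and_dims(seed):
    img = _img(30, 30, seed)
    rng = np.random.default_rng(seed)
    mask = pio.SegMask((rng.random((30, 30)) < 0.2).astype(np.uint8))
    out_img, out_mask = pio.random_rotate(img, mask, (-3, 3), seed=seed)
    assert (out_img.height, out_img.width) == (out_mask.height, out_mask.width) == (30, 30)
    assert set(np.unique(out_mask.pixels)) <= {0, 1}


def test_rotation_rejects_inverted_range():
    with pytest.raises(pio.InvalidInputError):
        pio.random_rotate(_img(8, 8), None, (3, -3), seed=0)


# ---------------------------------------------------------------------------
# IO and manifests
# ---------------------------------------------------------------------------

def test_mask_roundtrip_lossless(tmp_path):
    rng = np.random.default_rng(12)
    mask = pio.SegMask(rng.integers(0, 2, (64, 64), dtype=np.uint8))
    pio.save_mask(mask, tmp_path / "m.png")
    assert np.array_equal(pio.load_mask(tmp_path / "m.png").pixels, mask.pixels)


def test_image_roundtrip_lossless(tmp_path):
    img = _img(33, 47, 6)
    pio.save_image(img, tmp_path / "i.png")
    assert np.array_equal(pio.load_image(tmp_path / "i.png").pixels, img.pixels)


def test_missing_and_non_image_files_raise_distinct_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        pio.load_image(tmp_path / "absent.png")
    bad = tmp_path / "bad.png"
    bad.write_text("not an image")
    with pytest.raises(pio.NotAnImageError):
        pio.load_mask(bad)


def test_manifest_dimension_mismatch_names_record(tmp_path):
    pio.save_image(_img(10, 10), tmp_path / "a.png")
    pio.save_mask(pio.SegMask(np.zeros((8, 8), np.uint8)), tmp_path / "a_mask.png")
    (tmp_path / "manifest.csv").write_text(
        "image,label,mask,split\na.png,pterygium,a_mask.png,train\n")
    with pytest.raises(pio.DimensionMismatchError, match="a.png"):
        pio.load_manifest(tmp_path / "manifest.csv")


def test_manifest_roundtrip(tmp_path):
    records = [pio.ManifestRecord("x.png", "normal", None, "train"),
               pio.ManifestRecord("y.png", "pterygium", "y_m.png", "val")]
    pio.save_manifest(pio.Manifest(records), tmp_path / "m.csv")
    loaded = pio.load_manifest(tmp_path / "m.csv", validate=False)
    assert [r.image for r in loaded.records] == ["x.png", "y.png"]
    assert loaded.records[0].mask is None and loaded.records[1].mask == "y_m.png"


def test_split_367_records_gives_330_37():
    """The 9:1 split of a 367-image training pool: 330 train / 37 validation."""
    records = [pio.ManifestRecord(f"{i}.png", "pterygium") for i in range(367)]
    out = pio.split_train_val(records, seed=0)
    splits = [r.split for r in out]
    assert splits.count("train") == 330 and splits.count("val") == 37


def test_split_deterministic_under_seed():
    records = [pio.ManifestRecord(f"{i}.png", "normal") for i in range(50)]
    a = [r.split for r in pio.split_train_val(records, seed=4)]
    b = [r.split for r in pio.split_train_val(records, seed=4)]
    c = [r.split for r in pio.split_train_val(records, seed=5)]
    assert a == b
    assert a != c


def test_segmentation_pipeline_pads_gray_then_resizes():
    img = _img(100, 150, 7)
    rng = np.random.default_rng(7)
    mask = pio.SegMask((rng.random((100, 150)) < 0.1).astype(np.uint8))
    out_img, out_mask = pio.prepare_for_segmentation(img, mask, size=473)
    assert (out_img.height, out_img.width) == (473, 473)
    assert (out_mask.height, out_mask.width) == (473, 473)
    assert set(np.unique(out_mask.pixels)) <= {0, 1}
    # the gray letterbox survives into the top band of the resized image
    assert np.abs(out_img.pixels[0].astype(int) - 128).max() <= 1
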