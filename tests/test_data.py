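"""Preprocessing, splitting and augmentation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carunet.data import (
    DEFAULT_TRANSFORMS,
    ImagePair,
    Transform,
    apply_transform,
    assign_split,
    build_augmentation_plan,
    preprocess,
    read_pairs,
    split_counts,
    write_pairs,
)
from carunet.errors import ConfigurationError, ShapeError


# --------------------------------------------------------------------------
# preprocess
# --------------------------------------------------------------------------

def test_preprocess_constant_images():
    assert np.allclose(preprocess(np.full((512, 512), 255, np.uint8)), 1.0)
    out = preprocess(np.zeros((256, 256), np.uint8))
    assert out.shape == (256, 256) and np.all(out == 0.0)


def test_preprocess_matches_bruteforce_bilinear():
    rng = np.random.default_rng(0)
    raw = (rng.integers(0, 2, size=(8, 8)) * 255).astype(np.uint8)  # checkerboard-ish
    out = preprocess(raw, size=4)

    # independent pixel-by-pixel bilinear resampler (half-pixel centres)
    expect = np.zeros((4, 4))
    for r in range(4):
        for c in range(4):
            sr = min(max((r + 0.5) * 2 - 0.5, 0), 7)
            sc = min(max((c + 0.5) * 2 - 0.5, 0), 7)
            r0, c0 = int(np.floor(sr)), int(np.floor(sc))
            r1, c1 = min(r0 + 1, 7), min(c0 + 1, 7)
            wr, wc = sr - r0, sc - c0
            expect[r, c] = ((1 - wr) * (1 - wc) * raw[r0, c0]
                            + (1 - wr) * wc * raw[r0, c1]
                            + wr * (1 - wc) * raw[r1, c0]
                            + wr * wc * raw[r1, c1]) / 255.0
    assert np.allclose(out, expect, atol=1e-6)


def test_preprocess_rejects_bad_input():
    with pytest.raises(ShapeError):
        preprocess(np.zeros((4, 4, 3)))
    with pytest.raises(ShapeError):
        preprocess(np.zeros((0, 4)))


# --------------------------------------------------------------------------
# split
# --------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected", [
    (662, (530, 66, 66)),
    (138, (110, 14, 14)),
    (10, (8, 1, 1)),
    (247, (197, 25, 25)),
])
def test_split_counts_examples(n, expected):
    c = split_counts(n)
    assert (c.n_train, c.n_val, c.n_test) == expected


@given(st.integers(3, 10_000))
@settings(max_examples=300, derandomize=True, deadline=None)
def test_split_counts_partition_property(n):
    c = split_counts(n)
    assert c.total == n
    if n >= 10:
        assert c.n_train >= c.n_val >= c.n_test >= 0


def test_split_counts_rejects_tiny():
    with pytest.raises(ConfigurationError):
        split_counts(2)


def test_assign_split_partition_and_determinism():
    ids = [f"s{i}" for i in range(30)]
    counts = split_counts(30)
    a = assign_split(ids, counts, seed=4)
    b = assign_split(ids, counts, seed=4)
    assert a == b
    sizes = {k: sum(1 for v in a.values() if v == k) for k in ("train", "val", "test")}
    assert sizes == {"train": 24, "val": 3, "test": 3}
    assert set(a) == set(ids)
    c = assign_split(ids, counts, seed=5)
    assert c != a and {k: sum(1 for v in c.values() if v == k) for k in sizes} == sizes


def test_assign_split_rejects_duplicates():
    with pytest.raises(ConfigurationError):
        assign_split(["a", "a", "b"], split_counts(3), seed=0)


# --------------------------------------------------------------------------
# augmentation planning
# --------------------------------------------------------------------------

def test_plan_budget_8000_over_110_sources():
    ids = [f"mc{i}" for i in range(110)]
    plan = build_augmentation_plan(ids, 8000, seed=1)
    counts = plan.per_source_counts()
    assert len(plan.assignments) == 8000
    assert set(counts.values()) == {72, 73}
    assert sorted(counts.values(), reverse=True).count(73) == 8000 - 110 * 72


def test_plan_exact_cover_and_empty():
    ids = ["a", "b"]
    plan = build_augmentation_plan(ids, 22, transforms=DEFAULT_TRANSFORMS, seed=0)
    combos = {(sid, t.tag) for sid, t in plan.assignments}
    assert len(combos) == 22  # every (source, transform) pair exactly once
    assert build_augmentation_plan(ids, 0).assignments == ()


def test_plan_reproducible_and_balanced_grid():
    for n, budget in [(3, 10), (7, 50), (11, 110), (13, 8)]:
        ids = [f"s{i}" for i in range(n)]
        p1 = build_augmentation_plan(ids, budget, seed=9)
        p2 = build_augmentation_plan(ids, budget, seed=9)
        assert p1 == p2
        counts = p1.per_source_counts()
        if budget >= n:
            assert max(counts.values()) - min(counts.values()) <= 1


def test_plan_errors():
    with pytest.raises(ConfigurationError):
        build_augmentation_plan([], 5)
    with pytest.raises(ConfigurationError):
        build_augmentation_plan(["a"], -1)


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------

def _pair(size=16, seed=0):
    rng = np.random.default_rng(seed)
    img = rng.uniform(0, 1, (size, size)).astype(np.float32)
    msk = (rng.uniform(0, 1, (size, size)) > 0.7).astype(np.uint8)
    return ImagePair(img, msk, id="p")


def test_flips_are_involutions_and_klein_group():
    p = _pair()
    for kind in ("hflip", "vflip", "hvflip"):
        t = Transform(kind)
        twice = apply_transform(apply_transform(p, t), t)
        assert np.array_equal(twice.image, p.image)
        assert np.array_equal(twice.mask, p.mask)
    hv = apply_transform(apply_transform(p, Transform("hflip")), Transform("vflip"))
    direct = apply_transform(p, Transform("hvflip"))
    assert np.array_equal(hv.image, direct.image)
    assert np.array_equal(hv.mask, direct.mask)


def test_rotate90_four_cycle_exact():
    p = _pair()
    q = p
    for _ in range(4):
        q = apply_transform(q, Transform("rotate", angle=90))
    assert np.array_equal(q.image, p.image)
    assert np.array_equal(q.mask, p.mask)


def test_rotate15_single_pixel_matches_coordinate_oracle():
    size = 21
    msk = np.zeros((size, size), np.uint8)
    msk[4, 15] = 1
    p = ImagePair(np.zeros((size, size), np.float32), msk, id="dot")
    out = apply_transform(p, Transform("rotate", angle=15)).mask

    # independent oracle: inverse-map every output pixel centre and test
    # whether its nearest input pixel is the lit one
    theta = np.deg2rad(15)
    centre = (size - 1) / 2
    expect = np.zeros_like(msk)
    for r in range(size):
        for c in range(size):
            u, v = r - centre, c - centre
            src_r = np.cos(theta) * u + np.sin(theta) * v + centre
            src_c = -np.sin(theta) * u + np.cos(theta) * v + centre
            if round(src_r) == 4 and round(src_c) == 15:
                expect[r, c] = 1
    assert np.array_equal(out, expect)


def test_geometry_applies_jointly_and_mask_stays_binary():
    p = _pair(size=20, seed=3)
    for t in [Transform("rotate", angle=-45), Transform("rotate", angle=30),
              Transform("hflip")]:
        out = apply_transform(p, t)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert out.image.min() >= 0 and out.image.max() <= 1
        # mask transported exactly like a nearest-neighbour image
        img_as_mask = ImagePair(p.mask.astype(np.float32), p.mask, id="m")
        assert np.array_equal(apply_transform(img_as_mask, t).mask, out.mask)


def test_photometric_touches_image_only():
    p = _pair(seed=5)
    bright = apply_transform(p, Transform("brightness", factor=1.1))
    blur = apply_transform(p, Transform("gaussian_blur", sigma=0.8))
    assert np.array_equal(bright.mask, p.mask)
    assert np.array_equal(blur.mask, p.mask)
    assert np.allclose(bright.image, np.clip(p.image * 1.1, 0, 1), atol=1e-6)
    assert not np.array_equal(blur.image, p.image)


def test_unknown_transform_kind_rejected():
    with pytest.raises(ConfigurationError):
        Transform("shear")


# --------------------------------------------------------------------------
# PNG round trip
# --------------------------------------------------------------------------

def test_png_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    img = (rng.integers(0, 256, (16, 16)) / 255).astype(np.float32)
    msk = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
    pairs = [ImagePair(img, msk, id="x0")]
    write_pairs(pairs, tmp_path)
    back = read_pairs(tmp_path)
    assert back[0].id == "x0"
    assert np.array_equal(back[0].mask, msk)
    assert np.allclose(back[0].image, img, atol=1 / 255)
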