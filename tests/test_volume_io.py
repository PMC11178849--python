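"""NIfTI I/O and preprocessing operators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triunet.phantom import PhantomParams, sample_phantom
from triunet.volume_io import (
    AMYGDALA,
    HIPPOCAMPUS,
    AlignmentError,
    LabelMap,
    RegionSpec,
    Volume,
    crop_or_pad_center,
    extract_region,
    normalize_intensity,
    read_labelmap,
    read_volume,
    split_left_right,
    trim_zero_margins,
    write_labelmap,
    write_volume,
)


def _random_volume(rng, shape=(10, 10, 10), spacing=(1.0, 1.5, 2.0)):
    return Volume(rng.normal(size=shape).astype(np.float32), spacing)


# -- I/O ----------------------------------------------------------------------

def test_volume_roundtrip_is_exact(tmp_path, rng):
    v = _random_volume(rng)
    path = write_volume(v, tmp_path / "v.nii.gz")
    back = read_volume(path)
    assert np.max(np.abs(back.values - v.values)) == 0.0
    assert back.spacing == pytest.approx(v.spacing)


def test_labelmap_roundtrip_is_exact(tmp_path):
    p = PhantomParams()
    _, lab = sample_phantom(50, "HC", p, seed=0)
    path = write_labelmap(lab, tmp_path / "l.nii.gz")
    back = read_labelmap(path)
    assert np.array_equal(back.labels, lab.labels)


def test_reading_non_3d_image_raises(tmp_path):
    import nibabel as nib

    img = nib.Nifti1Image(np.zeros((8, 8), dtype=np.float32), np.eye(4))
    nib.save(img, str(tmp_path / "flat.nii.gz"))
    with pytest.raises(ValueError, match="3D"):
        read_volume(tmp_path / "flat.nii.gz")


def test_reading_cohort_gives_consistent_shapes(tmp_path):
    p = PhantomParams()
    paths = []
    for i in range(5):
        v, _ = sample_phantom(30 + 10 * i, "HC", p, seed=i)
        paths.append(write_volume(v, tmp_path / f"s{i}.nii.gz"))
    vols = [read_volume(pth) for pth in paths]
    assert len({v.shape for v in vols}) == 1


# -- normalization ------------------------------------------------------------

def test_normalize_whole_grid_contract(rng):
    out = normalize_intensity(_random_volume(rng, (8, 8, 8)))
    assert abs(float(out.values.mean())) < 1e-5
    assert abs(float(out.values.std()) - 1) < 1e-5


def test_normalize_constant_volume_rejected():
    v = Volume(np.full((6, 6, 6), 3.0, dtype=np.float32))
    mask = LabelMap(np.ones((6, 6, 6), dtype=np.int16))
    with pytest.raises(ValueError, match="variance"):
        normalize_intensity(v, mask)


def test_masked_normalization_matches_bruteforce(rng):
    v = _random_volume(rng, (9, 9, 9))
    labels = (rng.random((9, 9, 9)) < 0.4).astype(np.int16)
    mask = LabelMap(labels)
    out = normalize_intensity(v, mask)
    # brute-force recomputation over the listed in-mask voxels
    sel = [v.values[i, j, k] for i in range(9) for j in range(9) for k in range(9) if labels[i, j, k] > 0]
    mu, sd = np.mean(sel), np.std(sel)
    expected = (v.values - mu) / sd
    assert np.allclose(out.values, expected, atol=1e-5)
    in_mask = out.values[labels > 0]
    assert abs(in_mask.mean()) < 1e-5 and abs(in_mask.std() - 1) < 1e-4


# -- crop / pad ---------------------------------------------------------------

def test_crop_preserves_center_voxel(rng):
    v = _random_volume(rng, (20, 20, 20))
    out = crop_or_pad_center(v, 8)
    assert out.shape == (8, 8, 8)
    assert out.values[4, 4, 4] == v.values[10, 10, 10]


def test_pad_adds_zero_margins(rng):
    v = Volume(np.abs(_random_volume(rng, (5, 5, 5)).values) + 1.0)
    out = crop_or_pad_center(v, 9)
    assert out.shape == (9, 9, 9)
    assert out.values[0, 0, 0] == 0.0 and out.values[-1, -1, -1] == 0.0
    assert out.values[4, 4, 4] == v.values[2, 2, 2]


def test_crop_to_same_edge_is_identity(rng):
    v = _random_volume(rng, (7, 7, 7))
    out = crop_or_pad_center(v, 7)
    assert np.array_equal(out.values, v.values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(size=st.integers(3, 12), edge=st.integers(1, 15), data=st.data())
def test_crop_then_pad_restores_retained_voxels(size, edge, data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 16)))
    v = Volume(rng.normal(size=(size, size, size)).astype(np.float32))
    once = crop_or_pad_center(v, edge)
    back = crop_or_pad_center(once, size)
    if edge >= size:
        assert np.array_equal(back.values, v.values)
    else:
        kept = crop_or_pad_center(back, edge)
        assert np.array_equal(kept.values, once.values)
    assert back.spacing == v.spacing


# -- region extraction --------------------------------------------------------

def test_extract_region_masking_contract(rng):
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    flat = rng.choice(64, size=5, replace=False)
    labels.reshape(-1)[flat] = 17
    v = Volume(np.abs(rng.normal(size=(4, 4, 4))).astype(np.float32) + 1)
    out = extract_region(v, LabelMap(labels), HIPPOCAMPUS)
    assert int(np.count_nonzero(out.values)) == 5
    assert np.array_equal(out.values[labels == 17], v.values[labels == 17])


def test_extract_region_absent_labels_warns_and_zeroes(rng):
    labels = np.ones((4, 4, 4), dtype=np.int16)  # no hippocampus/amygdala codes
    v = _random_volume(rng, (4, 4, 4))
    with pytest.warns(UserWarning, match="matched no voxels"):
        out = extract_region(v, LabelMap(labels), AMYGDALA)
    assert out.empty_region and not out.values.any()


def test_extract_region_grid_mismatch_raises(rng):
    v = _random_volume(rng, (4, 4, 4))
    with pytest.raises(AlignmentError):
        extract_region(v, LabelMap(np.zeros((5, 5, 5), dtype=np.int16)), HIPPOCAMPUS)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16))
def test_extract_region_count_matches_bruteforce_scan(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 60, size=(5, 5, 5)).astype(np.int16)
    v = Volume(np.abs(rng.normal(size=(5, 5, 5))).astype(np.float32) + 1)
    spec = RegionSpec("r", frozenset(rng.choice(60, size=4, replace=False).tolist()))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = extract_region(v, LabelMap(labels), spec)
    expected = sum(
        1
        for i in range(5)
        for j in range(5)
        for k in range(5)
        if int(labels[i, j, k]) in spec.labels
    )
    assert int(np.count_nonzero(out.values)) == expected
    # idempotence: extracting again changes nothing
    again = extract_region(out, LabelMap(labels), spec)
    assert np.array_equal(again.values, out.values)


def test_split_left_right_partitions_the_region():
    p = PhantomParams()
    v, lab = sample_phantom(40, "HC", p, seed=0)
    left, right = split_left_right(v, lab, HIPPOCAMPUS)
    both = extract_region(v, lab, HIPPOCAMPUS)
    nl = int(np.count_nonzero(left.values))
    nr = int(np.count_nonzero(right.values))
    assert nl > 0 and nr > 0
    assert nl + nr == int(np.count_nonzero(both.values))
    # voxel-by-voxel disjointness of the nonzero supports
    assert not np.any((left.values != 0) & (right.values != 0))


def test_overlapping_left_right_sets_rejected_at_construction():
    with pytest.raises(ValueError, match="disjoint"):
        RegionSpec("bad", frozenset({1, 2}), frozenset({1}), frozenset({1, 2}))


def test_split_requires_laterality_subsets():
    spec = RegionSpec("mono", frozenset({17}))
    p = PhantomParams()
    v, lab = sample_phantom(40, "HC", p, seed=0)
    with pytest.raises(ValueError, match="left/right"):
        split_left_right(v, lab, spec)


# -- trimming -----------------------------------------------------------------

def test_trim_bounding_box_contract(rng):
    vals = np.zeros((10, 10, 10), dtype=np.float32)
    vals[4:7, 4:7, 4:7] = 1.0
    out = trim_zero_margins(Volume(vals), pad=0)
    assert out.shape == (3, 3, 3)
    padded = trim_zero_margins(Volume(vals), pad=2)
    assert padded.shape == (7, 7, 7)


def test_trim_all_zero_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        trim_zero_margins(Volume(np.zeros((5, 5, 5), dtype=np.float32)))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16))
def test_trim_matches_bruteforce_index_scan(seed):
    rng = np.random.default_rng(seed)
    vals = (rng.random((8, 8, 8)) < 0.05).astype(np.float32)
    if not vals.any():
        vals[3, 4, 5] = 1.0
    idx = [(i, j, k) for i in range(8) for j in range(8) for k in range(8) if vals[i, j, k]]
    lows = [min(t[a] for t in idx) for a in range(3)]
    highs = [max(t[a] for t in idx) for a in range(3)]
    out = trim_zero_margins(Volume(vals))
    assert out.shape == tuple(h - l + 1 for l, h in zip(lows, highs))


def test_operators_preserve_spacing(rng):
    v = _random_volume(rng, (8, 8, 8), spacing=(0.5, 1.0, 2.5))
    lab = LabelMap(np.ones((8, 8, 8), dtype=np.int16), v.spacing)
    assert normalize_intensity(v).spacing == v.spacing
    assert crop_or_pad_center(v, 6).spacing == v.spacing
    assert extract_region(v, lab, RegionSpec("all", frozenset({1}))).spacing == v.spacing
    v.values[0, 0, 0] = 1.0
    assert trim_zero_margins(v).spacing == v.spacing
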