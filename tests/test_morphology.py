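"""Morphological primitives against brute-force oracles and lattice laws."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import liverseg as ls
from liverseg import morphology as mo
from liverseg.volume_io import ValidationError


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def shifted(arr, off):
    """arr sampled at p+off, out-of-bounds False."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def brute_erode(arr, offsets):
    out = np.ones_like(arr)
    for off in offsets:
        out &= shifted(arr, off)
    return out


def brute_dilate(arr, offsets):
    out = np.zeros_like(arr)
    for off in offsets:
        out |= shifted(arr, off)
    return out


def offsets_for(se, ndim):
    offs = se.offsets
    if se.kind == "disk2d" and ndim == 3:
        offs = np.hstack([offs, np.zeros((len(offs), 1), int)])
    return offs


# ---------------------------------------------------------------------------
# Structuring elements
# ---------------------------------------------------------------------------

def test_digital_disk_and_sphere_cardinality():
    assert len(mo.disk(2).offsets) == 13
    assert len(mo.sphere(3).offsets) == 123
    offs = mo.disk(2).offsets
    # symmetric about the origin and within Euclidean radius
    assert {tuple(-o) for o in offs} == {tuple(o) for o in offs}
    assert np.all((offs**2).sum(axis=1) <= 4)


def test_structuring_element_validation():
    with pytest.raises(ValidationError):
        mo.disk(0)
    with pytest.raises(ValidationError):
        mo.StructuringElement("blob", 2)
    with pytest.raises(ValidationError):
        mo.erode(np.zeros((4, 4), bool), mo.sphere(2))


# ---------------------------------------------------------------------------
# Erode / dilate / open / close
# ---------------------------------------------------------------------------

def test_erode_full_mask_leaves_interior_band():
    se = mo.disk(2)
    full = np.ones((9, 9), bool)
    out = mo.erode(full, se)
    np.testing.assert_array_equal(out, brute_erode(full, se.offsets))
    assert not out[0, :].any() and not out[1, 4]  # border band of width 2 gone
    assert out[4, 4]


def test_erode_single_pixel_vanishes():
    arr = np.zeros((9, 9), bool)
    arr[4, 4] = True
    assert not mo.erode(arr, mo.disk(2)).any()


def test_dilate_point_gives_digital_disk():
    arr = np.zeros((9, 9), bool)
    arr[4, 4] = True
    out = mo.dilate(arr, mo.disk(2))
    assert out.sum() == 13
    rr, cc = np.where(out)
    assert np.all((rr - 4) ** 2 + (cc - 4) ** 2 <= 4)


def test_dilate_empty_is_empty():
    assert not mo.dilate(np.zeros((5, 5, 5), bool), mo.sphere(3)).any()


@pytest.mark.parametrize("shape,se", [((16, 16), mo.disk(2)),
                                      ((16, 16, 8), mo.disk(2)),
                                      ((12, 12, 12), mo.sphere(3))])
def test_erode_dilate_match_brute_force(rng, shape, se):
    offs = offsets_for(se, len(shape))
    for _ in range(5):
        arr = rng.random(shape) < 0.6
        np.testing.assert_array_equal(mo.erode(arr, se), brute_erode(arr, offs))
        np.testing.assert_array_equal(mo.dilate(arr, se), brute_dilate(arr, offs))


def test_open_close_equal_composition(rng):
    """Opening/closing equal the erode/dilate composition on the padded domain
    (closing's intermediate dilation legitimately overhangs the grid)."""
    se = mo.disk(2)
    r = se.radius
    for _ in range(5):
        arr = rng.random((32, 32)) < 0.5
        np.testing.assert_array_equal(mo.open_mask(arr, se),
                                      mo.dilate(mo.erode(arr, se), se))
        padded = np.pad(arr, r, constant_values=False)
        oracle = brute_erode(brute_dilate(padded, se.offsets), se.offsets)[r:-r, r:-r]
        np.testing.assert_array_equal(mo.close_mask(arr, se), oracle)


def test_opening_removes_speckles_closing_fills_hole():
    speckles = np.zeros((12, 12), bool)
    speckles[2, 2] = speckles[7, 9] = True
    assert not mo.open_mask(speckles, mo.disk(2)).any()

    square = np.zeros((12, 12), bool)
    square[2:10, 2:10] = True
    holed = square.copy()
    holed[5, 5] = False
    np.testing.assert_array_equal(mo.close_mask(holed, mo.disk(2)), square)


def test_opening_anti_extensive_idempotent_closing_extensive(rng):
    se = mo.disk(2)
    for _ in range(20):
        arr = rng.random((32, 32)) < rng.uniform(0.3, 0.7)
        opened = mo.open_mask(arr, se)
        closed = mo.close_mask(arr, se)
        assert np.all(opened <= arr)  # anti-extensive
        assert np.all(closed >= arr)  # extensive
        np.testing.assert_array_equal(mo.open_mask(opened, se), opened)
        np.testing.assert_array_equal(mo.close_mask(closed, se), closed)


def test_duality_on_interior(rng):
    """dilate(m) == ~erode(~m) away from the border (padding breaks it there)."""
    se = mo.disk(2)
    for _ in range(10):
        arr = rng.random((20, 20)) < 0.5
        dil = mo.dilate(arr, se)
        dual = ~mo.erode(~arr, se)
        np.testing.assert_array_equal(dil[2:-2, 2:-2], dual[2:-2, 2:-2])


@given(st.integers(0, 2**32 - 1))
def test_monotonicity_of_opening_and_closing(seed):
    """A ⊆ B implies open(A) ⊆ open(B) and close(A) ⊆ close(B)."""
    rng = np.random.default_rng(seed)
    b = rng.random((24, 24)) < 0.6
    a = b & (rng.random((24, 24)) < 0.7)
    se = mo.disk(2)
    assert np.all(mo.open_mask(a, se) <= mo.open_mask(b, se))
    assert np.all(mo.close_mask(a, se) <= mo.close_mask(b, se))


# ---------------------------------------------------------------------------
# Connected components / area filters / largest / holes
# ---------------------------------------------------------------------------

def test_components_two_cubes():
    arr = np.zeros((8, 8, 8), bool)
    arr[0:2, 0:2, 0:2] = True
    arr[5:7, 5:7, 5:7] = True
    lab, counts = mo.connected_components(arr)
    assert counts.tolist() == [8, 8]
    assert lab.max() == 2


def test_corner_contact_connectivity():
    """Voxels touching only at a vertex: separate under face, merged under full."""
    arr = np.zeros((4, 4, 4), bool)
    arr[1, 1, 1] = True
    arr[2, 2, 2] = True
    _, counts_face = mo.connected_components(arr, "face")
    _, counts_full = mo.connected_components(arr, "full")
    assert len(counts_face) == 2
    assert len(counts_full) == 1


def test_components_empty_and_partition(rng):
    lab, counts = mo.connected_components(np.zeros((4, 4, 4), bool))
    assert counts.size == 0 and not lab.any()
    arr = rng.random((16, 16, 8)) < 0.3
    lab, counts = mo.connected_components(arr)
    assert counts.sum() == arr.sum()  # partition of the foreground
    assert np.array_equal(lab > 0, arr)
    assert np.all(np.diff(counts) <= 0)  # sorted by decreasing size


def test_area_filter_strict_inequality():
    """min_area=1500 keeps a 1501-px object, drops a 1500-px object."""
    arr = np.zeros((80, 80, 1), bool)
    arr[0:25, 0:60, 0] = True  # 25 x 60 = 1500 px exactly
    arr[48:67, 1:80, 0] = True  # 19 x 79 = 1501 px
    out = mo.filter_by_area(arr, 1500, per_slice=True)
    _, counts = mo.connected_components(out[:, :, 0])
    assert counts.tolist() == [1501]


def test_area_filter_zero_threshold_is_identity(rng):
    arr = rng.random((16, 16, 4)) < 0.4
    np.testing.assert_array_equal(mo.filter_by_area(arr, 0), arr)


def test_area_filter_matches_brute_force(rng):
    """Per-slice area filter equals an independent BFS labeling oracle."""

    def brute(arr2d, min_area):
        seen = np.zeros_like(arr2d)
        keep = np.zeros_like(arr2d)
        for r0, c0 in zip(*np.where(arr2d)):
            if seen[r0, c0]:
                continue
            comp = [(r0, c0)]
            seen[r0, c0] = True
            queue = [(r0, c0)]
            while queue:
                r, c = queue.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < arr2d.shape[0] and 0 <= cc < arr2d.shape[1]
                                and arr2d[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            comp.append((rr, cc))
                            queue.append((rr, cc))
            if len(comp) > min_area:
                for r, c in comp:
                    keep[r, c] = True
        return keep

    for _ in range(5):
        arr = rng.random((20, 20, 3)) < 0.45
        out = mo.filter_by_area(arr, 20, per_slice=True)
        for z in range(arr.shape[2]):
            np.testing.assert_array_equal(out[:, :, z], brute(arr[:, :, z], 20))


def test_keep_largest():
    arr = np.zeros((20, 10, 4), bool)
    arr[0:5, 0:5, 0:4] = True  # 100
    arr[8:12, 0:5, 0:2] = True  # 40
    arr[15, 8, 0:3] = True  # 3
    out = mo.keep_largest(arr)
    assert out.sum() == 100 and out[2, 2, 2]

    single = np.zeros((5, 5, 5), bool)
    single[1:3, 1:3, 1:3] = True
    np.testing.assert_array_equal(mo.keep_largest(single), single)


def test_keep_largest_tie_is_deterministic():
    arr = np.zeros((10, 4, 4), bool)
    arr[6:8, 0:2, 0:2] = True  # later lexicographic seed
    arr[1:3, 0:2, 0:2] = True  # earlier seed, same size
    out1 = mo.keep_largest(arr)
    out2 = mo.keep_largest(arr.copy())
    np.testing.assert_array_equal(out1, out2)
    assert out1[1, 0, 0] and not out1[6, 0, 0]  # smaller lexicographic seed wins


def test_fill_holes_shell_and_open_concavity():
    shell = np.zeros((7, 7, 7), bool)
    shell[1:6, 1:6, 1:6] = True
    shell[2:5, 2:5, 2:5] = False
    filled = mo.fill_holes(shell)
    assert filled[3, 3, 3] and filled.sum() == 125

    concave = np.zeros((5, 5, 3), bool)
    concave[0:5, 0:2, :] = True
    concave[0:5, 3:5, :] = True  # slot open to the border
    np.testing.assert_array_equal(mo.fill_holes(concave), concave)


def test_fill_holes_matches_border_flood_oracle(rng):
    """fill = complement of background components reaching the grid border."""
    from scipy import ndimage

    for _ in range(5):
        arr = rng.random((12, 12, 8)) < 0.55
        bg_lab, n = ndimage.label(~arr, structure=ndimage.generate_binary_structure(3, 1))
        border_labels = set()
        for axis in range(3):
            for idx in (0, -1):
                border_labels |= set(np.unique(np.take(bg_lab, idx, axis=axis)))
        border_labels.discard(0)
        oracle = ~np.isin(bg_lab, sorted(border_labels)) | arr
        np.testing.assert_array_equal(mo.fill_holes(arr), oracle)


def test_binary_mask_wrapper_round_trip(rng):
    m = ls.BinaryMask(rng.random((8, 8, 4)) < 0.5, (1.0, 1.0, 2.0))
    out = mo.open_mask(m, mo.disk(2))
    assert isinstance(out, ls.BinaryMask)
    assert out.spacing == m.spacing
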