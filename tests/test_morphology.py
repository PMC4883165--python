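"""Binary morphology against set-definition enumeration and algebraic laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import axialseg as ax
from axialseg.io_formats import BinaryMask
from axialseg.morphology import StructuringElement

from conftest import random_mask, random_se
from oracles import close_enum, dilate_enum, erode_enum, open_enum


def M(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


def _interior_mask(rng, se, shape=(20, 20)):
    """Random mask whose foreground stays clear of the border by twice the
    SE reach, so finite-raster border effects cannot intrude."""
    mask = rng.random(shape) < 0.5
    margin = 2 * int(np.abs(se.offsets).max()) + 1
    mask[:margin] = mask[-margin:] = False
    mask[:, :margin] = mask[:, -margin:] = False
    return M(mask)


S3 = StructuringElement.square(1)
S1 = StructuringElement(np.ones((1, 1), dtype=bool), (0, 0))


class TestElementConstruction:
    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((3, 3), dtype=bool), (1, 1))

    def test_origin_outside_window_rejected(self):
        with pytest.raises(ValueError):
            StructuringElement(np.ones((3, 3), dtype=bool), (3, 0))

    def test_disk_support(self):
        d = StructuringElement.disk(1)
        assert d.window.sum() == 5  # 4-neighbourhood plus centre

    def test_reflect_negates_offsets(self):
        se = StructuringElement(np.array([[1, 1], [0, 1]]), (0, 0))
        got = {tuple(o) for o in se.reflect().offsets}
        assert got == {(0, 0), (0, -1), (-1, -1)}


class TestAgainstEnumeration:
    """Exact agreement with pixel-by-pixel evaluation of the definitions."""

    @pytest.mark.parametrize("n_cases", [60])
    def test_random_masks_and_elements(self, n_cases):
        rng = np.random.default_rng(42)
        ops = [
            (ax.erode, erode_enum),
            (ax.dilate, dilate_enum),
            (ax.opening, open_enum),
            (ax.closing, close_enum),
        ]
        for i in range(n_cases):
            mask = random_mask(rng, p=float(rng.uniform(0.2, 0.8)))
            se = random_se(rng)
            for op, oracle in ops:
                got = op(mask, se).pixels
                want = oracle(mask.pixels, se.window, se.origin)
                np.testing.assert_array_equal(got, want, err_msg=f"case {i} {op.__name__}")

    def test_centered_square_fast_path_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for hw in (1, 2):
            se = StructuringElement.square(hw)
            mask = random_mask(rng)
            np.testing.assert_array_equal(
                ax.erode(mask, se).pixels, erode_enum(mask.pixels, se.window, se.origin)
            )
            np.testing.assert_array_equal(
                ax.dilate(mask, se).pixels, dilate_enum(mask.pixels, se.window, se.origin)
            )


class TestWorkedExamples:
    def test_erode_full_3x3_by_3x3_keeps_center(self):
        out = ax.erode(M(np.ones((3, 3))), S3).pixels
        want = np.zeros((3, 3), dtype=bool)
        want[1, 1] = True  # only position where the SE fits (outside = 0)
        np.testing.assert_array_equal(out, want)

    def test_single_pixel_dilates_to_3x3_block(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        out = ax.dilate(M(mask), S3).pixels
        want = np.zeros((5, 5), dtype=bool)
        want[1:4, 1:4] = True
        np.testing.assert_array_equal(out, want)

    def test_1x1_element_is_identity(self):
        rng = np.random.default_rng(0)
        mask = random_mask(rng)
        np.testing.assert_array_equal(ax.erode(mask, S1).pixels, mask.pixels)
        np.testing.assert_array_equal(ax.dilate(mask, S1).pixels, mask.pixels)

    def test_empty_and_full_saturate(self):
        empty = M(np.zeros((8, 8)))
        full = M(np.ones((8, 8)))
        assert ax.erode(empty, S3).area == 0
        assert ax.dilate(full, S3).area == 64
        assert ax.opening(full, S3).area == 64
        assert ax.closing(empty, S3).area == 0

    def test_closing_fills_interior_hole(self):
        disk = StructuringElement.disk(3).window.copy()
        holed = disk.copy()
        holed[3, 3] = False
        out = ax.closing(M(holed), S3).pixels
        assert out[3, 3]

    def test_opening_removes_isolated_pixel_keeps_block(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[1:4, 1:4] = True
        mask[7, 7] = True
        out = ax.opening(M(mask), S3).pixels
        assert not out[7, 7]
        assert out[1:4, 1:4].all()


class TestAlgebraicLaws:
    def test_duality_erosion_is_complement_of_dilated_complement(self):
        # both operators use the translated-origin set form, so duality
        # needs no SE reflection; it holds away from the raster border,
        # where the outside-is-background convention breaks the complement
        rng = np.random.default_rng(3)
        for _ in range(40):
            mask = random_mask(rng)
            se = random_se(rng)
            m = int(np.abs(se.offsets).max()) + 1
            lhs = ax.erode(mask, se).pixels[m:-m, m:-m]
            rhs = ~ax.dilate(M(~mask.pixels), se).pixels[m:-m, m:-m]
            np.testing.assert_array_equal(lhs, rhs)

    def test_monotonicity_in_the_mask(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            small = random_mask(rng, p=0.3)
            big = M(small.pixels | (rng.random(small.shape) < 0.3))
            se = random_se(rng)
            for op in (ax.erode, ax.dilate, ax.opening, ax.closing):
                assert not (op(small, se).pixels & ~op(big, se).pixels).any()

    def test_opening_and_closing_idempotent_for_symmetric_elements(self):
        # idempotence requires the erosion/dilation adjoint pair, i.e. a
        # symmetric SE under the shared translated-origin convention; the
        # stripping loop only ever uses centered squares
        rng = np.random.default_rng(5)
        for _ in range(25):
            se = (
                StructuringElement.square(int(rng.integers(1, 3)))
                if rng.random() < 0.5
                else StructuringElement.disk(int(rng.integers(1, 3)))
            )
            mask = _interior_mask(rng, se)
            once = ax.opening(mask, se)
            np.testing.assert_array_equal(ax.opening(once, se).pixels, once.pixels)
            conce = ax.closing(mask, se)
            np.testing.assert_array_equal(ax.closing(conce, se).pixels, conce.pixels)

    def test_extensivity_for_symmetric_origin_elements(self):
        rng = np.random.default_rng(6)
        for hw in (1, 2):
            se = StructuringElement.square(hw)
            mask = _interior_mask(rng, se)
            assert not (mask.pixels & ~ax.closing(mask, se).pixels).any()  # close grows
            assert not (ax.opening(mask, se).pixels & ~mask.pixels).any()  # open shrinks


class TestXor:
    def test_self_xor_is_empty_and_zero_is_identity(self):
        rng = np.random.default_rng(8)
        mask = random_mask(rng)
        assert ax.mask_xor(mask, mask).area == 0
        np.testing.assert_array_equal(
            ax.mask_xor(mask, M(np.zeros(mask.shape))).pixels, mask.pixels
        )

    def test_disk_xor_ringless_disk_is_the_ring(self):
        full = StructuringElement.disk(5).window
        inner = np.zeros_like(full)
        inner[1:-1, 1:-1] = StructuringElement.disk(4).window
        ring = full & ~inner
        np.testing.assert_array_equal(ax.mask_xor(M(full), M(inner)).pixels, ring)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ax.mask_xor(M(np.zeros((4, 4))), M(np.zeros((5, 5))))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_xor_commutative_and_self_inverse(self, seed):
        rng = np.random.default_rng(seed)
        a = random_mask(rng)
        b = random_mask(rng)
        ab = ax.mask_xor(a, b)
        np.testing.assert_array_equal(ab.pixels, ax.mask_xor(b, a).pixels)
        np.testing.assert_array_equal(ax.mask_xor(ab, b).pixels, a.pixels)


class TestFillHoles:
    def test_closed_ring_becomes_solid_disk(self):
        ring = np.zeros((9, 9), dtype=bool)
        ring[2, 2:7] = ring[6, 2:7] = ring[2:7, 2] = ring[2:7, 6] = True
        out = ax.fill_holes(M(ring)).pixels
        want = np.zeros_like(ring)
        want[2:7, 2:7] = True
        np.testing.assert_array_equal(out, want)

    def test_no_enclosed_background_unchanged(self):
        rng = np.random.default_rng(9)
        mask = M(np.zeros((8, 8)))
        np.testing.assert_array_equal(ax.fill_holes(mask).pixels, mask.pixels)

    def test_broken_ring_not_filled(self):
        # C-shape: the interior is 4-connected to the border through the break
        ring = np.zeros((7, 7), dtype=bool)
        ring[1, 1:6] = ring[5, 1:6] = ring[1:6, 1] = ring[1:6, 5] = True
        ring[3, 5] = False  # break
        out = ax.fill_holes(M(ring)).pixels
        np.testing.assert_array_equal(out, ring)

    def test_diagonal_gap_does_not_leak(self):
        # 8-connected foreground ring with single-pixel diagonal steps still
        # encloses its interior under the 4-connected background convention
        inner = np.pad(StructuringElement.disk(3).window, 1)
        ring = StructuringElement.disk(4).window & ~inner
        pad = np.pad(ring, 1)
        filled = ax.fill_holes(M(pad)).pixels
        assert filled[5, 5]
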