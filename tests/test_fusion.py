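import numpy as np
import pytest

from contourkit import (
    ConfidenceConfig,
    ConfidenceMap,
    ImageVolume,
    Trimap,
    VoxelGrid,
    apply_threshold,
    assemble_channels,
    build_trimap,
    confidence_map,
    fuse,
    fused_agreement_map,
    mask_logic,
    select_threshold,
)
from contourkit.fusion import BACKGROUND, FOREGROUND, UNCERTAIN, normalize_ct
from conftest import cube_mask, random_blob_mask


def chain_fixture(k: int):
    """1-D uncertain chain of length k between a foreground and a background end."""
    n = k + 2
    grid = VoxelGrid((n, 1, 1), (1, 1, 1))
    state = np.full(grid.shape, UNCERTAIN, dtype=np.uint8)
    state[0, 0, 0] = BACKGROUND
    state[-1, 0, 0] = FOREGROUND
    tm = Trimap(grid, state)
    ct = ImageVolume(grid, np.zeros(grid.shape))
    return grid, ct, tm


class TestTrimap:
    def test_identical_masks_no_uncertain(self, grid10, rng):
        m = random_blob_mask(grid10, rng)
        tm = build_trimap([m, m.replace(source="b")])
        assert not tm.uncertain.any()
        assert np.array_equal(tm.foreground, m.occupancy)

    def test_disjoint_masks_empty_foreground(self, grid10):
        a = cube_mask(grid10, (0, 0, 0), (3, 3, 3))
        b = cube_mask(grid10, (6, 6, 6), (3, 3, 3))
        tm = build_trimap([a, b])
        assert not tm.foreground.any()
        assert np.array_equal(tm.uncertain, a.occupancy | b.occupancy)

    def test_nested_masks(self, grid10):
        inner = cube_mask(grid10, (3, 3, 3), (3, 3, 3))
        outer = cube_mask(grid10, (2, 2, 2), (6, 6, 6))
        tm = build_trimap([inner, outer])
        assert np.array_equal(tm.foreground, inner.occupancy)
        assert np.array_equal(tm.uncertain, outer.occupancy & ~inner.occupancy)

    def test_partition(self, grid10, rng):
        masks = [random_blob_mask(grid10, rng) for _ in range(4)]
        tm = build_trimap(masks)
        assert np.all(tm.foreground.astype(int) + tm.background + tm.uncertain == 1)

    def test_arity_error(self, grid10, rng):
        with pytest.raises(ValueError):
            build_trimap([random_blob_mask(grid10, rng)])


class TestAgreementMap:
    def test_vote_fraction(self, grid10):
        masks = [cube_mask(grid10, (0, 0, 0), (3, 3, 3)) for _ in range(3)]
        masks.append(cube_mask(grid10, (6, 6, 6), (2, 2, 2)))
        am = fused_agreement_map(masks)
        assert am[1, 1, 1] == pytest.approx(0.75)
        assert am[6, 6, 6] == pytest.approx(0.25)

    def test_identical_masks_indicator(self, grid10, rng):
        m = random_blob_mask(grid10, rng)
        am = fused_agreement_map([m, m.replace(source="b")])
        assert np.array_equal(am.astype(bool), m.occupancy)

    def test_vote_conservation(self, grid10, rng):
        masks = [random_blob_mask(grid10, rng) for _ in range(4)]
        am = fused_agreement_map(masks)
        assert am.sum() * 4 == pytest.approx(sum(m.voxel_count for m in masks))


class TestConfidenceMap:
    def test_empty_uncertain_equals_indicator(self, grid10, rng):
        m = random_blob_mask(grid10, rng)
        tm = build_trimap([m, m.replace(source="b")])
        ct = ImageVolume(grid10, np.zeros(grid10.shape))
        cm = confidence_map(ct, tm)
        assert np.array_equal(cm.confidence == 1.0, m.occupancy)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_uniform_chain_linear_profile(self, k):
        """Uniform intensities: harmonic solution is linear, c(m) = m/(k+1)."""
        _, ct, tm = chain_fixture(k)
        cm = confidence_map(ct, tm)
        profile = cm.confidence[:, 0, 0]
        expected = np.arange(k + 2) / (k + 1)
        assert np.allclose(profile, expected, atol=1e-8)

    def test_beta_zero_ignores_ct(self):
        grid = VoxelGrid((8, 8, 1), (1, 1, 1))
        rng = np.random.default_rng(2)
        state = np.full(grid.shape, UNCERTAIN, np.uint8)
        state[0, :, :] = FOREGROUND
        state[-1, :, :] = BACKGROUND
        tm = Trimap(grid, state)
        ct_noisy = ImageVolume(grid, rng.normal(0, 100, grid.shape))
        ct_flat = ImageVolume(grid, np.zeros(grid.shape))
        c0 = confidence_map(ct_noisy, tm, ConfidenceConfig(beta=0.0)).confidence
        c1 = confidence_map(ct_flat, tm, ConfidenceConfig(beta=5.0)).confidence
        assert np.allclose(c0, c1, atol=1e-8)

    def test_maximum_principle_uniform_affinity(self):
        grid = VoxelGrid((6, 6, 3), (1, 1, 1))
        state = np.full(grid.shape, UNCERTAIN, np.uint8)
        state[0, :, :] = FOREGROUND
        state[-1, :, :] = BACKGROUND
        tm = Trimap(grid, state)
        ct = ImageVolume(grid, np.zeros(grid.shape))
        c = confidence_map(ct, tm).confidence
        for idx in np.argwhere(state == UNCERTAIN):
            i, j, k = idx
            nbs = []
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                p = idx + d
                if all(0 <= p[a] < grid.shape[a] for a in range(3)):
                    nbs.append(c[tuple(p)])
            assert min(nbs) - 1e-9 <= c[i, j, k] <= max(nbs) + 1e-9

    def test_isolated_uncertain_components_get_limits(self):
        """No path to foreground -> 0; no path to background -> 1."""
        grid = VoxelGrid((9, 1, 1), (1, 1, 1))
        state = np.zeros(grid.shape, np.uint8)
        state[1, 0, 0] = UNCERTAIN                       # only background around
        state[4, 0, 0] = FOREGROUND
        state[3, 0, 0] = state[5, 0, 0] = UNCERTAIN      # between fg and bg: solved
        ct = ImageVolume(grid, np.zeros(grid.shape))
        c = confidence_map(ct, Trimap(grid, state)).confidence[:, 0, 0]
        assert c[1] == 0.0
        assert c[4] == 1.0
        assert 0 < c[3] < 1 and 0 < c[5] < 1

    def test_distance_ratio_fallback_bounds(self, grid10, rng):
        masks = [random_blob_mask(grid10, rng) for _ in range(3)]
        tm = build_trimap(masks)
        ct = ImageVolume(grid10, np.zeros(grid10.shape))
        cm = confidence_map(ct, tm, ConfidenceConfig(method="distance_ratio"))
        assert np.all(cm.confidence[tm.foreground] == 1.0)
        assert np.all(cm.confidence[tm.background] == 0.0)


class TestThreshold:
    def test_parameter_bounds(self, grid10, rng):
        masks = [random_blob_mask(grid10, rng) for _ in range(2)]
        tm = build_trimap(masks)
        cm = ConfidenceMap(grid10, tm.foreground.astype(float))
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                apply_threshold(tm, cm, bad)

    def test_high_threshold_gives_foreground(self):
        _, ct, tm = chain_fixture(3)
        cm = confidence_map(ct, tm)
        out = apply_threshold(tm, cm, 0.99)
        assert np.array_equal(out.occupancy, tm.foreground)

    def test_low_threshold_gives_union(self):
        _, ct, tm = chain_fixture(3)
        cm = confidence_map(ct, tm)
        out = apply_threshold(tm, cm, 1e-6)
        assert np.array_equal(out.occupancy, tm.foreground | tm.uncertain)

    def test_half_threshold_on_chain_closed_form(self):
        _, ct, tm = chain_fixture(3)
        cm = confidence_map(ct, tm)
        out = apply_threshold(tm, cm, 0.5)
        # c(m) = m/4 >= 0.5 at chain positions m = 2, 3 plus the foreground end
        assert out.occupancy[:, 0, 0].tolist() == [False, False, True, True, True]

    def test_monotone_nesting_and_sandwich(self, rng):
        grid = VoxelGrid((12, 12, 6), (1, 1, 2))
        for _ in range(20):
            masks = [random_blob_mask(grid, rng, fill=0.2) for _ in range(3)]
            ct = ImageVolume(grid, rng.normal(0, 30, grid.shape))
            tm = build_trimap(masks)
            cm = confidence_map(ct, tm)
            inter = mask_logic(masks, "intersection").occupancy
            union = mask_logic(masks, "union").occupancy
            prev = None
            for t in (0.2, 0.4, 0.6, 0.8):
                out = apply_threshold(tm, cm, t).occupancy
                assert np.all(inter <= out) and np.all(out <= union)
                if prev is not None:
                    assert np.all(out <= prev)  # higher threshold -> subset
                prev = out


class TestSelectThreshold:
    def _cases(self, rng, reference_of, n_cases=3):
        grid = VoxelGrid((10, 10, 5), (1, 1, 1))
        cases = []
        for _ in range(n_cases):
            masks = [random_blob_mask(grid, rng, fill=0.25) for _ in range(3)]
            ct = ImageVolume(grid, rng.normal(0, 20, grid.shape))
            cases.append((ct, masks, reference_of(masks)))
        return cases

    def test_union_reference_selects_grid_minimum(self, rng):
        sel = select_threshold(self._cases(rng, lambda ms: mask_logic(ms, "union")))
        assert sel.threshold == pytest.approx(0.05)

    def test_intersection_reference_selects_grid_maximum(self, rng):
        sel = select_threshold(self._cases(rng, lambda ms: mask_logic(ms, "intersection")))
        assert sel.threshold == pytest.approx(0.95)

    def test_selected_threshold_attains_curve_maximum(self, rng):
        cases = self._cases(rng, lambda ms: ms[0])
        sel = select_threshold(cases)
        i = sel.grid.index(sel.threshold)
        assert sel.mean_dsc[i] == pytest.approx(max(sel.mean_dsc))

    def test_no_training_cases_error(self):
        with pytest.raises(ValueError):
            select_threshold([])


class TestFuse:
    def test_identical_masks_returned_unchanged(self, grid10, rng):
        m = random_blob_mask(grid10, rng)
        ct = ImageVolume(grid10, rng.normal(0, 20, grid10.shape))
        for t in (0.1, 0.5, 0.9):
            out = fuse(ct, [m, m.replace(source="b")], t)
            assert np.array_equal(out.occupancy, m.occupancy)

    def test_disjoint_masks_bounded_by_union(self, grid10, rng):
        a = cube_mask(grid10, (0, 0, 0), (3, 3, 3))
        b = cube_mask(grid10, (6, 6, 6), (3, 3, 3))
        ct = ImageVolume(grid10, rng.normal(0, 20, grid10.shape))
        out = fuse(ct, [a, b], 0.5)
        assert np.all(out.occupancy <= (a.occupancy | b.occupancy))

    def test_deterministic(self, grid10, rng):
        masks = [random_blob_mask(grid10, rng) for _ in range(3)]
        ct = ImageVolume(grid10, rng.normal(0, 20, grid10.shape))
        out1 = fuse(ct, masks, 0.5)
        out2 = fuse(ct, masks, 0.5)
        assert np.array_equal(out1.occupancy, out2.occupancy)


class TestChannels:
    def test_agreement_channel_votes(self, grid10):
        masks = [cube_mask(grid10, (0, 0, 0), (3, 3, 3)) for _ in range(2)]
        masks += [cube_mask(grid10, (6, 6, 6), (2, 2, 2)) for _ in range(2)]
        ct = ImageVolume(grid10, np.zeros(grid10.shape))
        cm = ConfidenceMap(grid10, np.zeros(grid10.shape))
        stack = assemble_channels(ct, masks, cm)
        assert stack.agreement[1, 1, 1] == pytest.approx(0.5)

    def test_constant_ct_normalizes_to_zero(self, grid10):
        masks = [cube_mask(grid10, (0, 0, 0), (3, 3, 3)) for _ in range(2)]
        ct = ImageVolume(grid10, np.full(grid10.shape, 77.0))
        cm = ConfidenceMap(grid10, np.zeros(grid10.shape))
        stack = assemble_channels(ct, masks, cm)
        assert np.all(stack.ct == 0.0)

    def test_normalize_window_clip(self):
        vals = np.array([[[-500.0, -200.0, 50.0, 300.0, 900.0]]])
        out = normalize_ct(vals)
        assert out[0, 0, 0] == 0.0 and out[0, 0, 1] == 0.0
        assert out[0, 0, 3] == 1.0 and out[0, 0, 4] == 1.0
        assert out[0, 0, 2] == pytest.approx(250 / 500)

    def test_stack_roundtrips_float32_nifti(self, tmp_path, grid10, rng):
        from contourkit.io import read_image_nifti, write_image_nifti
        from contourkit import ImageVolume as IV

        masks = [random_blob_mask(grid10, rng) for _ in range(2)]
        ct = ImageVolume(grid10, rng.normal(0, 50, grid10.shape))
        tm = build_trimap(masks)
        cmap = confidence_map(ct, tm)
        stack = assemble_channels(ct, masks, cmap)
        for name, chan in [("ct", stack.ct), ("agree", stack.agreement), ("conf", stack.confidence)]:
            p = tmp_path / f"{name}.nii.gz"
            write_image_nifti(IV(grid10, chan.astype(np.float32)), p)
            back = read_image_nifti(p)
            assert np.array_equal(np.asarray(back.intensities), chan.astype(np.float32))
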