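"""3D FISH quantification: filters, EDM, distances, contacts, volumes."""

import numpy as np
import pytest

from chromopos.fish3d import (
    BinaryMask3D,
    VoxelGrid,
    edm_slice,
    hybrid_median_despeckle,
    interlocus_distance,
    ki67_index,
    lamina_contact,
    quantify_nucleus,
    read_stack,
    segment_mask,
    signal_centroid,
    territory_min_edge_distance,
    territory_volume,
    write_stack,
)
from chromopos.synthetic_data import (
    NucleusTruth,
    make_nucleus_stack,
    rasterize_truth,
)

VOX = (0.1, 0.1, 0.12)


def brute_force_hybrid_median(img):
    pad = np.pad(img, 1, mode="reflect")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = pad[i : i + 3, j : j + 3]
            plus = np.median([w[1, 1], w[0, 1], w[2, 1], w[1, 0], w[1, 2]])
            cross = np.median([w[1, 1], w[0, 0], w[0, 2], w[2, 0], w[2, 2]])
            out[i, j] = np.median([plus, cross, w[1, 1]])
    return out


def brute_force_edm(mask, spacing):
    du, dv = spacing
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    for i, j in np.argwhere(mask):
        d2 = ((bg[:, 0] - i) * du) ** 2 + ((bg[:, 1] - j) * dv) ** 2
        out[i, j] = np.sqrt(d2.min()) if len(bg) else np.inf
    return out


def brute_force_min_edge_3d(territory, nucleus, voxel):
    """Min anisotropic distance from territory voxels to the nucleus edge
    (the boundary voxel layer counts as distance 0)."""
    from scipy import ndimage

    dx, dy, dz = voxel
    interior = ndimage.binary_erosion(nucleus)
    bg = np.argwhere(~interior) * np.array([dz, dy, dx])
    fg = np.argwhere(territory) * np.array([dz, dy, dx])
    best = np.inf
    for p in fg:
        best = min(best, float(np.sqrt(((bg - p) ** 2).sum(axis=1)).min()))
    return best


class TestHybridMedian:
    def test_constant_image_unchanged(self):
        img = np.full((7, 7), 3.5)
        np.testing.assert_allclose(hybrid_median_despeckle(img), img)

    def test_single_speckle_suppressed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        assert hybrid_median_despeckle(img)[4, 4] == 0.0

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 255, size=(9, 9)).astype(float)
            np.testing.assert_allclose(
                hybrid_median_despeckle(img), brute_force_hybrid_median(img)
            )

    def test_tiny_slice_returned_unchanged_with_warning(self):
        img = np.ones((2, 2))
        with pytest.warns(UserWarning):
            out = hybrid_median_despeckle(img)
        np.testing.assert_array_equal(out, img)


class TestSegmentMask:
    def test_bimodal_volume_matches_truth_within_boundary_band(self):
        truth = NucleusTruth(semi_axes_um=(3, 2.5, 2), snr=None)
        grid, _ = make_nucleus_stack(truth, voxel_size_xy=0.1, voxel_size_z=0.12)
        mask = segment_mask(grid.channel("dapi"), keep_largest=True).mask
        true_mask = rasterize_truth(truth, VOX)["nucleus"]
        # disagreements confined to a 1-voxel band around the surface
        from scipy import ndimage

        band = ndimage.binary_dilation(true_mask) & ~ndimage.binary_erosion(true_mask)
        assert not (mask ^ true_mask)[~band].any()

    def test_interior_cavity_filled(self):
        vol = np.zeros((5, 20, 20))
        vol[2, 5:15, 5:15] = 10.0
        vol[2, 9:11, 9:11] = 0.0  # dark cavity
        mask = segment_mask(vol, method="fixed", threshold=5.0).mask
        assert mask[2, 9:11, 9:11].all()

    def test_nucleus_mode_keeps_largest_component(self):
        vol = np.zeros((3, 30, 30))
        vol[1, 2:20, 2:20] = 10.0
        vol[1, 25:28, 25:28] = 10.0
        mask = segment_mask(vol, method="fixed", threshold=5.0, keep_largest=True).mask
        assert mask[1, 5, 5] and not mask[1, 26, 26]

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            segment_mask(np.zeros((3, 10, 10)))


class TestEdmSlice:
    def test_all_background_is_zero(self):
        np.testing.assert_array_equal(
            edm_slice(np.zeros((6, 6), bool), (0.1, 0.2)), np.zeros((6, 6))
        )

    def test_single_foreground_pixel(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 3] = True
        assert edm_slice(mask, (0.3, 0.1))[3, 3] == pytest.approx(0.1)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(25):
            mask = rng.random((12, 12)) < 0.6
            mask[0, 0] = False  # guarantee background
            spacing = tuple(rng.uniform(0.05, 0.3, 2))
            np.testing.assert_allclose(
                edm_slice(mask, spacing), brute_force_edm(mask, spacing), atol=1e-9
            )


class TestTerritoryMinEdgeDistance:
    def sphere_fixture(self, territory_offset, territory_radius=1.0, R=4.0):
        truth = NucleusTruth(
            semi_axes_um=(R, R, R),
            territory_specs=[(territory_offset, territory_radius)],
            snr=None,
        )
        masks = rasterize_truth(truth, VOX)
        return (
            BinaryMask3D(masks["territory_1"]),
            BinaryMask3D(masks["nucleus"]),
            truth.true_min_edge_distances_um[0],
        )

    def test_tangent_territory_scores_zero(self):
        terr, nuc, true = self.sphere_fixture((3.0, 0, 0))
        assert true == 0.0
        assert territory_min_edge_distance(terr, nuc, VOX) == 0.0

    def test_centered_territory_in_sphere(self):
        terr, nuc, true = self.sphere_fixture((0, 0, 0), R=5.0)
        measured = territory_min_edge_distance(terr, nuc, VOX)
        diag = np.sqrt(sum(v**2 for v in VOX))
        assert measured == pytest.approx(true, abs=diag)

    def test_two_plane_upper_bounds_full_3d(self, rng):
        """The x-y/x-z two-pass minimum can only overestimate the true 3D
        distance; on random blob masks it is >= both the 3D transform and
        a brute-force anisotropic oracle (which agree)."""
        from scipy import ndimage

        for trial in range(6):
            nuc = rng.random((14, 16, 16)) < 0.7
            nuc[0] = nuc[-1] = False
            nuc[:, 0] = nuc[:, -1] = False
            nuc[:, :, 0] = nuc[:, :, -1] = False
            nuc = ndimage.binary_closing(nuc)
            if not nuc.any():
                continue
            terr = np.zeros_like(nuc)
            fg = np.argwhere(nuc)
            for k in rng.choice(len(fg), size=min(5, len(fg)), replace=False):
                terr[tuple(fg[k])] = True
            t, n = BinaryMask3D(terr), BinaryMask3D(nuc)
            two_plane = territory_min_edge_distance(t, n, VOX, mode="two-plane")
            full3d = territory_min_edge_distance(t, n, VOX, mode="3d")
            oracle = brute_force_min_edge_3d(terr, nuc, VOX)
            assert full3d == pytest.approx(oracle, abs=1e-9)
            assert two_plane >= full3d - 1e-9

    def test_translation_invariance(self):
        terr, nuc, _ = self.sphere_fixture((1.0, 0, 0), R=3.0)
        d0 = territory_min_edge_distance(terr, nuc, VOX)
        shift = (1, 2, 3)
        t2 = BinaryMask3D(np.roll(terr.mask, shift, axis=(0, 1, 2)))
        n2 = BinaryMask3D(np.roll(nuc.mask, shift, axis=(0, 1, 2)))
        assert territory_min_edge_distance(t2, n2, VOX) == pytest.approx(d0, abs=1e-9)

    def test_empty_territory_rejected(self):
        _, nuc, _ = self.sphere_fixture((0, 0, 0))
        with pytest.raises(ValueError, match="empty"):
            territory_min_edge_distance(
                BinaryMask3D(np.zeros(nuc.mask.shape, bool)), nuc, VOX
            )


class TestInterlocusDistance:
    def test_identical_points(self):
        assert interlocus_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_pythagorean_triple(self):
        assert interlocus_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_matches_componentwise_oracle(self, rng):
        for _ in range(20):
            p1, p2 = rng.normal(0, 5, (2, 3))
            expected = np.sqrt(((p1 - p2) ** 2).sum())
            assert interlocus_distance(p1, p2) == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            interlocus_distance((np.nan, 0, 0), (0, 0, 0))


class TestLaminaContact:
    def shell_and_signal(self, gap_voxels):
        shape = (9, 15, 15)
        lamin = np.zeros(shape, bool)
        lamin[:, :, 12] = True  # flat shell plane
        signal = np.zeros(shape, bool)
        signal[4, 7, 10 - gap_voxels] = True
        return BinaryMask3D(signal), BinaryMask3D(lamin)

    def test_shared_voxel_contacts(self):
        sig = np.zeros((3, 5, 5), bool)
        sig[1, 2, 2] = True
        assert lamina_contact(BinaryMask3D(sig), BinaryMask3D(sig.copy())) == 1

    def test_flip_exactly_at_adjacency_boundary(self):
        # signal at column 10-gap vs shell at column 12:
        # gap=-1 -> adjacent (26-neighborhood), gap>=0 -> separated
        sig, lam = self.shell_and_signal(-1)
        assert lamina_contact(sig, lam) == 1
        sig, lam = self.shell_and_signal(0)
        assert lamina_contact(sig, lam) == 0
        sig, lam = self.shell_and_signal(2)
        assert lamina_contact(sig, lam) == 0

    def test_empty_signal_rejected(self):
        _, lam = self.shell_and_signal(0)
        with pytest.raises(ValueError):
            lamina_contact(BinaryMask3D(np.zeros(lam.mask.shape, bool)), lam)


class TestTerritoryVolume:
    def test_territory_equal_nucleus_gives_ratio_one(self):
        mask = np.zeros((5, 8, 8), bool)
        mask[1:4, 2:6, 2:6] = True
        m = territory_volume(BinaryMask3D(mask), BinaryMask3D(mask.copy()), VOX)
        assert m.volume_ratio == pytest.approx(1.0)
        assert m.volume_um3 == pytest.approx(mask.sum() * 0.1 * 0.1 * 0.12)

    def test_sphere_volume_within_5_percent(self):
        truth = NucleusTruth(
            semi_axes_um=(4, 4, 4), territory_specs=[((0, 0, 0), 2.0)], snr=None
        )
        masks = rasterize_truth(truth, voxel_size=(0.08, 0.08, 0.12))
        m = territory_volume(
            BinaryMask3D(masks["territory_1"]),
            BinaryMask3D(masks["nucleus"]),
            (0.08, 0.08, 0.12),
        )
        analytic = 4 / 3 * np.pi * 8.0
        assert m.volume_um3 == pytest.approx(analytic, rel=0.05)

    def test_empty_territory_gives_zero(self):
        nuc = np.ones((3, 4, 4), bool)
        m = territory_volume(BinaryMask3D(np.zeros_like(nuc)), BinaryMask3D(nuc), VOX)
        assert m.volume_um3 == 0.0 and m.volume_ratio == 0.0

    def test_empty_nucleus_rejected(self):
        t = np.ones((3, 4, 4), bool)
        with pytest.raises(ValueError):
            territory_volume(BinaryMask3D(t), BinaryMask3D(np.zeros_like(t)), VOX)


class TestKi67Index:
    @pytest.mark.parametrize(
        "pos, total, frac, cls",
        [
            (88, 100, 0.88, "young"),
            (1, 100, 0.01, "senescent"),
            (40, 100, 0.40, "intermediate"),  # boundary -> intermediate
            (2, 100, 0.02, "intermediate"),  # boundary -> intermediate
            (47, 100, 0.47, "young"),
        ],
    )
    def test_classification(self, pos, total, frac, cls):
        f, c = ki67_index(pos, total)
        assert f == pytest.approx(frac)
        assert c == cls

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ki67_index(1, 0)
        with pytest.raises(ValueError):
            ki67_index(5, 3)


class TestPipelineAndIO:
    def test_quantify_nucleus_recovers_planted_truth(self):
        truth = NucleusTruth(
            semi_axes_um=(3.5, 3.5, 3.5),
            territory_specs=[((1.5, 0, 0), 1.0)],
            signal_positions=[(0, 0, 0, "signal_1"), (1.2, 1.6, 0, "signal_2")],
            snr=25.0,
            seed=42,
        )
        grid, truth = make_nucleus_stack(truth, voxel_size_xy=0.1, voxel_size_z=0.12)
        res = quantify_nucleus(
            grid,
            territory_channels=["territory_1"],
            signal_channels=["signal_1", "signal_2"],
        )
        diag = np.sqrt(0.1**2 + 0.1**2 + 0.12**2)
        m = res["territories"]["territory_1"]
        assert m.min_edge_distance_um == pytest.approx(
            truth.true_min_edge_distances_um[0], abs=diag
        )
        assert m.volume_ratio == pytest.approx(truth.true_volume_ratios[0], rel=0.08)
        d = interlocus_distance(
            res["signals"]["signal_1"].centroid_um,
            res["signals"]["signal_2"].centroid_um,
        )
        assert d == pytest.approx(truth.true_pair_distance_um, abs=diag)

    def test_contact_scoring_peripheral_vs_interior(self):
        """Planted peripheral signals contact the shell; deep-interior
        signals never do."""
        R = 3.5
        truth = NucleusTruth(
            semi_axes_um=(R, R, R),
            signal_positions=[(R - 0.35, 0, 0, "signal_1"), (0, 0, 0, "signal_2")],
            snr=30.0,
            seed=3,
        )
        grid, _ = make_nucleus_stack(truth, voxel_size_xy=0.1, voxel_size_z=0.12)
        res = quantify_nucleus(
            grid, signal_channels=["signal_1", "signal_2"]
        )
        assert res["signals"]["signal_1"].contact == 1
        assert res["signals"]["signal_2"].contact == 0

    def test_stack_round_trip(self, tmp_path):
        truth = NucleusTruth(semi_axes_um=(2, 2, 2), snr=10.0, seed=1)
        grid, _ = make_nucleus_stack(truth, voxel_size_xy=0.15, voxel_size_z=0.2)
        sidecar = write_stack(grid, tmp_path, name="n1")
        back = read_stack(sidecar)
        assert back.voxel_size == grid.voxel_size
        for label in grid.channels:
            np.testing.assert_allclose(back.channels[label], grid.channels[label])

    def test_signal_centroid_weighted(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 1] = 1.0
        vol[2, 2, 3] = 3.0
        mask = BinaryMask3D(vol > 0)
        x, y, z = signal_centroid(vol, mask, (1.0, 1.0, 1.0))
        assert x == pytest.approx(2.5)  # weighted toward the brighter voxel
        assert (y, z) == (pytest.approx(2.0), pytest.approx(2.0))
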