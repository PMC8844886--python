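"""Image quantification: masking, LoG detection, co-localization rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ribofish import imaging
from ribofish.imaging import (
    NEIGHBORHOOD_OFFSETS,
    colocalize,
    compute_mask,
    dendrite_density,
    density_per_mask_volume,
    detect_puncta,
    el22_normalized_intensity,
    project_substack,
    punctum_neighborhood,
    soma_counts,
    soma_neighborhood_2d,
)
from ribofish.simulate import FishStackParams, gen_fish_stack
from ribofish.types import (
    DendriteTrace,
    ImageField,
    NeuriteMask,
    PunctaSet,
    Punctum,
    SomaROI,
)
from conftest import greedy_match_f1


def _field(arr, voxel_size=(0.5, 0.5, 0.5), role="FISH_probe"):
    return ImageField(np.asarray(arr, float)[None], voxel_size, {0: role})


def _puncta(centroids, shape=None):
    pts = [
        Punctum(centroid=tuple(map(float, c)), diameter=0.7, quality=1.0,
                contrast=1.0, total_intensity=1.0)
        for c in centroids
    ]
    return PunctaSet(puncta=pts, image_shape=shape)


class TestProjection:
    def test_constant_stack_projects_to_constant(self):
        f = _field(np.full((10, 8, 8), 3.0), voxel_size=(1.0, 0.5, 0.5))
        proj = project_substack(f, 10.0)
        assert np.all(proj.voxels == 3.0)
        assert proj.shape[0] == 1

    def test_single_bright_voxel_survives(self):
        arr = np.zeros((10, 8, 8))
        arr[4, 2, 5] = 7.0
        f = _field(arr, voxel_size=(1.0, 0.5, 0.5))
        proj = project_substack(f, 10.0)
        assert proj.voxels[0, 0, 2, 5] == 7.0

    def test_matches_slicewise_maximum_oracle(self):
        rng = np.random.default_rng(0)
        arr = rng.random((12, 6, 7))
        f = _field(arr, voxel_size=(1.0, 0.5, 0.5))
        proj = project_substack(f, 10.0)  # 10 slices at 1 μm spacing
        oracle = arr[:10].max(axis=0)
        assert np.array_equal(proj.voxels[0, 0], oracle)

    def test_invalid_depth_rejected(self):
        f = _field(np.zeros((4, 4, 4)), voxel_size=(1.0, 0.5, 0.5))
        with pytest.raises(ValueError):
            project_substack(f, 0.0)
        with pytest.raises(ValueError):
            project_substack(f, 100.0)


class TestMask:
    def test_constant_image_gives_empty_mask(self):
        f = _field(np.full((4, 8, 8), 5.0), role="IF_TH")
        m = compute_mask(f, "IF_TH")
        assert m.n_voxels == 0

    def test_half_zero_half_ten_at_k0(self):
        arr = np.zeros((2, 4, 8))
        arr[..., 4:] = 10.0
        f = _field(arr, role="IF_TH")
        m = compute_mask(f, "IF_TH", k_sd=0.0)  # threshold = mean = 5
        assert np.array_equal(m.mask, arr > 5)

    def test_recovers_synthetic_tube(self):
        p = FishStackParams(shape=(12, 96, 128), tube_intensity=200.0,
                            background_mean=100.0, background_sd=10.0,
                            n_puncta=0, seed=1)
        field, truth = gen_fish_stack(p)
        m = compute_mask(field, "IF_TH", k_sd=2.0)
        tube = truth.neurite_mask_true
        assert (m.mask & tube).sum() / tube.sum() >= 0.95
        assert (m.mask & ~tube).sum() / (~tube).sum() <= 0.01


class TestDetection:
    def test_single_blob_no_noise(self):
        p = FishStackParams(shape=(12, 64, 64), n_puncta=1, frac_inside=0.0,
                            background_sd=0.0, amplitude=100.0, seed=2)
        field, truth = gen_fish_stack(p)
        ps = detect_puncta(field, quality_threshold=5.0)
        assert len(ps) == 1
        err = np.abs(ps.centroids[0] - truth.centroids_vox[0])
        assert (err <= 1.0).all()
        lo, hi = ps.diameter_range
        assert lo <= ps.puncta[0].diameter <= hi

    def test_two_blobs_far_apart(self):
        shape, vs = (12, 64, 64), (0.25, 0.2, 0.2)
        from ribofish.simulate import _render_blobs

        img = np.full(shape, 100.0)
        img += _render_blobs(shape, vs, np.array([[1.5, 4.0, 4.0], [1.5, 4.0, 9.0]]),
                             100.0, 0.2)
        field = ImageField(img[None], vs, {0: "FISH_probe"})
        ps = detect_puncta(field, quality_threshold=5.0)
        assert len(ps) == 2

    def test_constant_image_returns_empty_not_exception(self):
        f = ImageField(np.full((1, 8, 32, 32), 7.0), (0.25, 0.2, 0.2),
                       {0: "FISH_probe"})
        assert len(detect_puncta(f)) == 0

    def test_absent_channel_rejected(self, small_stack):
        field, _ = small_stack
        with pytest.raises(KeyError):
            detect_puncta(field, "IF_HA")

    def test_unresolvable_diameter_rejected(self, small_stack):
        field, _ = small_stack
        with pytest.raises(ValueError):
            detect_puncta(field, diameter_range=(0.05, 0.1))

    def test_f1_on_noisy_stack(self, small_stack):
        field, truth = small_stack  # SNR 5, 30 planted puncta
        ps = detect_puncta(field)
        f1, _, _ = greedy_match_f1(ps.centroids, truth.centroids_vox)
        assert f1 >= 0.95

    def test_detection_invariant_under_intensity_rescaling(self, small_stack):
        field, _ = small_stack
        q = 40.0
        a = detect_puncta(field, quality_threshold=q)
        scaled = ImageField(field.voxels * 10, field.voxel_size,
                            dict(field.channel_roles))
        b = detect_puncta(scaled, quality_threshold=10 * q)
        assert np.array_equal(a.centroids, b.centroids)


class TestNeighborhood:
    def test_interior_centroid_has_23_voxels(self):
        coords = punctum_neighborhood((5, 5, 5), (11, 11, 11))
        assert len(coords) == 23

    def test_corner_centroid_clipped_in_bounds(self):
        coords = punctum_neighborhood((0, 0, 0), (8, 8, 8))
        assert len(coords) < 23
        assert (coords >= 0).all()

    @given(
        st.tuples(
            st.floats(1.0, 8.0), st.floats(1.0, 8.0), st.floats(1.0, 8.0)
        )
    )
    def test_matches_offset_enumeration_oracle(self, centroid):
        """Brute force: all 27 offsets, drop the 4 central-slice corners."""
        shape = (10, 10, 10)
        center = np.floor(np.asarray(centroid) + 0.5).astype(int)
        expected = set()
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == 0 and abs(dy) == 1 and abs(dx) == 1:
                        continue
                    v = center + (dz, dy, dx)
                    if ((v >= 0) & (v < shape)).all():
                        expected.add(tuple(v))
        got = {tuple(c) for c in punctum_neighborhood(centroid, shape)}
        assert got == expected

    def test_2d_soma_neighborhood_is_5_pixels(self):
        assert len(soma_neighborhood_2d((4, 4), (9, 9))) == 5

    def test_offsets_constant_is_23(self):
        assert NEIGHBORHOOD_OFFSETS.shape == (23, 3)


class TestColocalize:
    def test_fully_inside_mask(self):
        mask = np.ones((9, 9, 9), bool)
        rep = colocalize(_puncta([(4, 4, 4)]), mask)
        row = rep.per_punctum.iloc[0]
        assert row.overlap_fraction == 1.0 and row.colocalized

    def test_strict_60_percent_boundary(self):
        """14/23 overlapping voxels pass; 13/23 fail."""
        coords = punctum_neighborhood((4, 4, 4), (9, 9, 9))
        for k, expect in [(14, True), (13, False)]:
            mask = np.zeros((9, 9, 9), bool)
            mask[tuple(coords[:k].T)] = True
            rep = colocalize(_puncta([(4, 4, 4)]), mask)
            row = rep.per_punctum.iloc[0]
            assert row.colocalized == expect
            assert row.overlap_fraction == pytest.approx(k / 23)

    def test_empty_mask_nothing_colocalized(self):
        rep = colocalize(_puncta([(4, 4, 4), (2, 2, 2)]), np.zeros((9, 9, 9), bool))
        assert rep.n_colocalized == 0
        assert (rep.per_punctum.overlap_fraction == 0).all()

    def test_monotone_in_mask(self):
        rng = np.random.default_rng(3)
        small = rng.random((9, 12, 12)) > 0.6
        big = small | (rng.random((9, 12, 12)) > 0.6)
        pts = _puncta([(4, 5, 5), (4, 8, 3), (2, 2, 9), (6, 6, 6)])
        rep_small = colocalize(pts, small)
        rep_big = colocalize(pts, big)
        assert (
            rep_big.per_punctum.colocalized >= rep_small.per_punctum.colocalized
        ).all()

    def test_shape_mismatch_rejected(self):
        pts = _puncta([(4, 4, 4)], shape=(9, 9, 9))
        with pytest.raises(ValueError):
            colocalize(pts, np.zeros((5, 5, 5), bool))


class TestDensity:
    def test_arithmetic(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.flat[:1000] = True  # 1000 voxels
        rep = colocalize(_puncta([(5, 5, 5)]), np.ones((10, 10, 10), bool))
        # 10 colocalized puncta over 1000 voxels of 0.2×0.2×0.5 μm
        rep.n_colocalized = 10
        assert density_per_mask_volume(rep, mask, (0.5, 0.2, 0.2)) == pytest.approx(0.5)

    def test_zero_colocalized_gives_zero(self):
        rep = colocalize(_puncta([(1, 1, 1)]), np.zeros((9, 9, 9), bool))
        assert density_per_mask_volume(rep, np.ones((9, 9, 9), bool), (1, 1, 1)) == 0.0

    def test_empty_mask_signals(self):
        rep = colocalize(_puncta([]), np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError):
            density_per_mask_volume(rep, np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestDendriteDensity:
    def _trace(self, n=101, vs=0.5):
        path = np.array([(3, 3, x) for x in range(n)])
        mask = np.zeros((7, 7, n), bool)
        for dz in range(-2, 3):
            for dy in range(-2, 3):
                mask[3 + dz, 3 + dy, :] = True
        return DendriteTrace(path=path, filled_mask=mask,
                             path_length=(n - 1) * vs, voxel_size=(vs, vs, vs))

    def test_five_puncta_on_50um_trace(self):
        trace = self._trace()
        pts = _puncta([(3, 3, x) for x in (5, 20, 40, 60, 90)])
        d = dendrite_density(pts, trace)
        assert d["per_um"] == pytest.approx(0.1)
        assert d["per_10um"] == pytest.approx(1.0)

    def test_puncta_off_the_fill_do_not_count(self):
        trace = self._trace()
        pts = _puncta([(3, 3, 50), (0, 0, 50)])  # second is outside the fill
        assert dendrite_density(pts, trace)["n_puncta"] == 1

    def test_planted_rate_recovered(self):
        from ribofish.simulate import gen_dendrite_fixture

        total_count, total_len = 0, 0.0
        for s in range(40):
            trace, centroids = gen_dendrite_fixture(
                100.0, puncta_per_um=0.2, tortuosity=0.0, seed=s
            )
            d = dendrite_density(_puncta(centroids), trace)
            total_count += d["n_puncta"]
            total_len += trace.path_length
        rate = total_count / total_len
        se = np.sqrt(0.2 * total_len) / total_len
        assert abs(rate - 0.2) <= 3 * se


class TestSomaCounts:
    def test_centered_punctum_counted_once(self):
        roi = SomaROI(mask=np.ones((9, 9), bool), label=1)
        assert soma_counts(np.array([[4.0, 4.0]]), [roi]) == {1: 1}

    def test_outside_all_rois_counted_nowhere(self):
        m = np.zeros((9, 9), bool)
        m[:3, :3] = True
        roi = SomaROI(mask=m, label=1)
        assert soma_counts(np.array([[7.0, 7.0]]), [roi]) == {1: 0}

    def test_tie_goes_to_lower_label(self):
        full = np.ones((9, 9), bool)
        a, b = SomaROI(mask=full, label=2), SomaROI(mask=full.copy(), label=5)
        assert soma_counts(np.array([[4.0, 4.0]]), [b, a]) == {2: 1, 5: 0}

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(4)
        rois = []
        for label in (1, 2):
            m = np.zeros((12, 12), bool)
            y, x = rng.integers(2, 9, 2)
            m[y - 2 : y + 3, x - 2 : x + 3] = True
            rois.append(SomaROI(mask=m, label=label))
        pts = rng.uniform(1, 10, size=(30, 2))
        got = soma_counts(pts, rois)
        expected = {1: 0, 2: 0}
        for yx in pts:
            coords = soma_neighborhood_2d(yx, (12, 12))
            best, best_frac = None, 0.60
            for roi in rois:
                frac = roi.mask[tuple(coords.T)].sum() / len(coords)
                if frac > best_frac:
                    best, best_frac = roi.label, frac
            if best is not None:
                expected[best] += 1
        assert got == expected


class TestEl22:
    def test_constant_image_gives_zero(self):
        f = ImageField(np.full((1, 1, 8, 8), 9.0), (1, 1, 1), {0: "IF_HA"})
        mask = np.zeros((1, 8, 8), bool)
        mask[0, :4] = True
        assert el22_normalized_intensity(f, mask) == 0.0

    def test_enriched_marker_pixels(self):
        ha = np.full((1, 10, 10), 50.0)
        mask = np.zeros((1, 10, 10), bool)
        mask[0, :5] = True  # half the field
        ha[mask] = 150.0  # field mean = 100
        f = ImageField(ha[None], (1, 1, 1), {0: "IF_HA"})
        assert el22_normalized_intensity(f, mask) == pytest.approx(50.0)

    def test_tag_free_fixture_near_zero(self):
        rng = np.random.default_rng(5)
        ha = rng.normal(100, 5, size=(1, 64, 64))
        mask = np.zeros((1, 64, 64), bool)
        mask[0, 20:40] = True
        f = ImageField(ha[None], (1, 1, 1), {0: "IF_HA"})
        val = el22_normalized_intensity(f, mask)
        assert abs(val) < 3 * 5 / np.sqrt(mask.sum())

    def test_empty_mask_signals(self):
        f = ImageField(np.zeros((1, 1, 4, 4)), (1, 1, 1), {0: "IF_HA"})
        with pytest.raises(ValueError):
            el22_normalized_intensity(f, np.zeros((1, 4, 4), bool))


def test_percent_colocalized_tracks_planted_fraction():
    """End-to-end: detection + 60%-rule recovers the planted inside fraction."""
    p = FishStackParams(shape=(14, 128, 160), n_puncta=60, frac_inside=0.9, seed=6)
    field, truth = gen_fish_stack(p)
    ps = detect_puncta(field)
    mask = compute_mask(field, "IF_TH")
    rep = colocalize(ps, mask)
    f = truth.inside_flags.mean()
    se = 100 * np.sqrt(f * (1 - f) / rep.n_puncta)
    assert abs(rep.percent_colocalized - 100 * f) <= 3 * se + 1e-9
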