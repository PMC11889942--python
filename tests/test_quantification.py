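"""ΔR2* maps, hypointensity read-outs and tumor volumetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spioquant as sq
from spioquant.quantification import (
    ContourSet,
    ROIMask,
    SliceContour,
    contour_volume,
    delta_rate,
    hypointense_fraction,
    hypointense_increase,
    mask_volume,
)


def _rate_map(values, valid=None, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, float)
    if valid is None:
        valid = np.ones(values.shape, bool)
    return sq.RelaxationMap(values, "R2*", spacing, valid)


class TestDeltaRate:
    def test_identical_maps_give_zero(self):
        m = _rate_map(np.full((2, 2, 2), 14.07))
        d = delta_rate(m, m)
        assert np.all(d.values[d.valid] == 0.0)

    def test_anchor_rate_subtraction(self):
        pre = _rate_map(np.full((1, 1, 1), 14.07))
        post = _rate_map(np.full((1, 1, 1), 76.34))
        d = delta_rate(pre, post)
        assert d.values[0, 0, 0] == pytest.approx(62.27)

    def test_masked_increment(self, rng):
        base = rng.uniform(10, 30, (8, 8, 8))
        bump = np.zeros((8, 8, 8))
        bump[2:5, 2:5, 2:5] = 5.0
        d = delta_rate(_rate_map(base), _rate_map(base + bump))
        np.testing.assert_allclose(d.values, bump, atol=1e-12)

    def test_antisymmetry(self, rng):
        a = _rate_map(rng.uniform(5, 50, (4, 4, 4)))
        b = _rate_map(rng.uniform(5, 50, (4, 4, 4)))
        np.testing.assert_allclose(delta_rate(a, b).values,
                                   -delta_rate(b, a).values, rtol=1e-14)

    def test_validity_is_intersection(self):
        v1 = np.zeros((2, 1, 1), bool); v1[0] = True
        v2 = np.zeros((2, 1, 1), bool); v2[1] = True
        d = delta_rate(_rate_map(np.ones((2, 1, 1)), v1),
                       _rate_map(np.ones((2, 1, 1)), v2))
        assert not d.valid.any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            delta_rate(_rate_map(np.ones((2, 2, 2))), _rate_map(np.ones((3, 2, 2))))

    def test_time_kind_rejected(self):
        t = sq.RelaxationMap(np.ones((1, 1, 1)), "T2*", (1, 1, 1),
                             np.ones((1, 1, 1), bool))
        with pytest.raises(ValueError, match="rate-kind"):
            delta_rate(t, t)


class TestHypointensity:
    def _rois(self, shape=(10, 10, 10), split=5):
        tumor = np.zeros(shape, bool); tumor[:split] = True
        ref = np.zeros(shape, bool); ref[split:] = True
        return ROIMask(tumor, (1, 1, 1)), ROIMask(ref, (1, 1, 1))

    def test_uniform_image_gives_zero_percent(self):
        tumor, ref = self._rois()
        pct, thr = hypointense_fraction(np.full((10, 10, 10), 50.0), tumor, ref)
        assert pct == 0.0 and thr == 50.0  # strict inequality at sigma_ref=0

    def test_constructed_quarter_fraction(self):
        """250 of 1000 tumor voxels pushed far below threshold -> 25%."""
        img = np.full((20, 10, 10), 100.0)
        img[10:] += np.linspace(-1, 1, 1000).reshape(10, 10, 10)  # ref spread
        tumor, ref = self._rois(shape=(20, 10, 10), split=10)
        idx = np.argwhere(tumor.mask)[:250]
        img[tuple(idx.T)] = 0.0
        pct, _ = hypointense_fraction(img, tumor, ref, k=2.0)
        assert pct == 25.0

    def test_threshold_below_minimum_gives_zero(self, rng):
        img = rng.uniform(100, 110, (10, 10, 10))
        tumor, ref = self._rois()
        pct, _ = hypointense_fraction(img, tumor, ref, k=1e6)
        assert pct == 0.0

    def test_empty_or_overlapping_rois_rejected(self, rng):
        img = rng.random((4, 4, 4))
        empty = ROIMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        full = ROIMask(np.ones((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            hypointense_fraction(img, empty, full)
        with pytest.raises(ValueError, match="disjoint"):
            hypointense_fraction(img, full, full)

    def test_identical_pre_post_gives_zero_increase(self, rng):
        img = rng.uniform(50, 150, (10, 10, 10))
        tumor, ref = self._rois()
        q = hypointense_increase(img, img, tumor, ref)
        assert q.hypo_increase_pct == 0.0
        assert q.hypo_pre_pct == q.hypo_post_pct

    def test_threshold_comes_from_pre_reference(self, rng):
        """Darkening the post reference must not move the threshold."""
        pre = rng.uniform(90, 110, (10, 10, 10))
        post = pre.copy()
        tumor, ref = self._rois()
        post[ref.mask] -= 50.0
        q = hypointense_increase(pre, post, tumor, ref)
        mu, sd = pre[ref.mask].mean(), pre[ref.mask].std()
        assert q.threshold == pytest.approx(mu - 2.0 * sd)
        assert q.hypo_increase_pct == 0.0  # tumor voxels untouched

    def test_scene_uptake_darkening_matches_truth_fraction(self):
        """In a noiseless scene the hypointense increase equals the uptake
        share of the tumor, computed from ground-truth voxel counts."""
        spec = sq.reference_scene_spec(noise_sigma=0.0, shape=(32, 32, 32),
                                       conc=7.0)
        pre, post, truth = sq.simulate_scene(spec)
        e = int(np.argmin(np.abs(pre.echo_times - 12.0)))
        tumor = ROIMask(truth.tumor_mask, spec.spacing)
        ref = ROIMask(~truth.tumor_mask, spec.spacing)
        q = hypointense_increase(pre.data[..., e], post.data[..., e],
                                 tumor, ref, k=2.0)
        expected = 100.0 * truth.uptake_mask.sum() / truth.tumor_mask.sum()
        assert q.hypo_pre_pct == 0.0
        assert q.hypo_increase_pct == pytest.approx(expected, abs=0.5)

    def test_no_uptake_scene_gives_zero_increase(self):
        spec = sq.reference_scene_spec(noise_sigma=0.0, shape=(16, 16, 16),
                                       conc=0.0)
        pre, post, truth = sq.simulate_scene(spec)
        q = hypointense_increase(pre.data[..., 0], post.data[..., 0],
                                 ROIMask(truth.tumor_mask, spec.spacing),
                                 ROIMask(~truth.tumor_mask, spec.spacing))
        assert q.hypo_increase_pct == 0.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(k=st.floats(0.0, 5.0), k2=st.floats(0.0, 5.0))
    def test_bounded_and_monotone_in_k(self, k, k2):
        rng = np.random.default_rng(99)
        img = rng.uniform(0, 100, (8, 8, 8))
        tumor = np.zeros((8, 8, 8), bool); tumor[:4] = True
        ref = ~tumor
        t, r = ROIMask(tumor, (1, 1, 1)), ROIMask(ref, (1, 1, 1))
        lo, hi = sorted([k, k2])
        p_lo, _ = hypointense_fraction(img, t, r, k=lo)
        p_hi, _ = hypointense_fraction(img, t, r, k=hi)
        assert 0.0 <= p_hi <= p_lo <= 100.0


class TestVolumetry:
    def test_single_voxel_volume_at_protocol_spacing(self):
        mask = ROIMask(np.ones((1, 1, 1), bool), (0.0625, 0.0625, 0.75))
        assert mask_volume(mask) == pytest.approx(0.0029297, abs=1e-7)

    def test_empty_mask_zero_volume(self):
        assert mask_volume(ROIMask(np.zeros((3, 3, 3), bool), (1, 1, 1))) == 0.0

    def test_digital_sphere_matches_analytic_volume(self):
        """2 mm radius ball at 0.1 mm spacing vs 4/3*pi*r^3 = 33.510 mm^3."""
        ell = sq.Ellipsoid(center=(24, 24, 24), semi_axes=(20, 20, 20))
        mask = ROIMask(ell.mask((49, 49, 49)), (0.1, 0.1, 0.1))
        analytic = 4.0 / 3.0 * np.pi * 2.0 ** 3
        assert mask_volume(mask) == pytest.approx(analytic, rel=0.02)

    def test_unit_square_contour(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        cs = ContourSet([SliceContour(0, square)], 1.0, (1.0, 1.0))
        assert contour_volume(cs) == pytest.approx(1.0)
        cs_thin = ContourSet([SliceContour(0, square)], 0.75, (1.0, 1.0))
        assert contour_volume(cs_thin) == pytest.approx(0.75)

    def test_anisotropic_spacing_scales_area(self):
        square = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float)
        cs = ContourSet([SliceContour(0, square)], 0.5, (0.5, 0.25))
        # 2x2 voxel square -> 1.0 x 0.5 mm -> area 0.5 mm^2 x 0.5 mm
        assert contour_volume(cs) == pytest.approx(0.25)

    def test_polygon_circle_stack_matches_analytic(self):
        """64-gon of radius 10 on 3 slices, 0.5 mm thick: within 0.5% of
        3 * 0.5 * pi * 100 mm^3."""
        theta = np.linspace(0, 2 * np.pi, 65)[:-1]
        verts = 10.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        cs = ContourSet([SliceContour(z, verts) for z in range(3)],
                        0.5, (1.0, 1.0))
        analytic = 3 * 0.5 * np.pi * 100.0
        assert contour_volume(cs) == pytest.approx(analytic, rel=0.005)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            SliceContour(0, np.array([[0, 0], [1, 1]]))
        with pytest.raises(ValueError):
            ContourSet([], 1.0, (1.0, 1.0)) and contour_volume(
                ContourSet([], 1.0, (1.0, 1.0)))

    def test_contour_of_voxel_mask_converges_to_mask_volume(self):
        """Marching-squares contours of a disc approach the voxel-count
        volume as resolution doubles."""
        from skimage import measure
        errs = []
        for n in (40, 80):
            r = n / 2 - 2
            yy, xx = np.mgrid[:n, :n]
            disc = ((xx - n / 2 + 0.5) ** 2 + (yy - n / 2 + 0.5) ** 2) <= r ** 2
            spacing = 10.0 / n  # keep the physical disc the same size
            mvol = mask_volume(ROIMask(disc[..., None], (spacing, spacing, 1.0)))
            contour = measure.find_contours(disc.astype(float), 0.5)[0]
            cs = ContourSet([SliceContour(0, contour[:, ::-1])], 1.0,
                            (spacing, spacing))
            errs.append(abs(contour_volume(cs) - mvol) / mvol)
        assert errs[1] < errs[0]
        assert errs[1] < 0.05


def test_full_pipeline_detects_uptake(small_scene_noisy):
    """Seeded noisy scene with uptake: hypointense volume increases and the
    recovered concentration is higher inside the uptake region than outside."""
    from spioquant.pipeline import map_scene_concentration
    from spioquant.relaxometry import FitConfig
    spec, pre, post, truth = small_scene_noisy
    e = int(np.argmin(np.abs(pre.echo_times - 12.0)))
    q = hypointense_increase(pre.data[..., e], post.data[..., e],
                             ROIMask(truth.tumor_mask, spec.spacing),
                             ROIMask(~truth.tumor_mask, spec.spacing))
    assert q.hypo_increase_pct > 0.0
    res = map_scene_concentration(pre, post, relaxivity=spec.relaxivity,
                                  fit_config=FitConfig(noise_sigma=spec.noise_sigma))
    inside = res.conc.valid & truth.uptake_mask
    outside = res.conc.valid & ~truth.tumor_mask
    assert res.conc.values[inside].mean() > res.conc.values[outside].mean()
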