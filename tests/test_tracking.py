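"""Deterministic tracker behavior on constructed direction fields, plus the
edema-crossing property on the default phantom."""

import numpy as np
import pytest

from edematrack.exceptions import ParameterError
from edematrack.io_formats import ImageGrid
from edematrack.tracking import (
    RoiSet,
    StopRule,
    count_traversing,
    filter_by_rois,
    track,
    tract_mask,
)


def _straight_field(shape=(11, 11, 41), voxel=2.5, axis=2, metric_inside=0.8, radius=2.0):
    """A tube of unit vectors along ``axis`` with a high metric inside and
    zero outside; returns (direction_field, metric, tube_mask, affine)."""
    affine = np.diag([voxel] * 3 + [1.0])
    ii, jj, kk = np.meshgrid(*map(np.arange, shape), indexing="ij")
    cx, cy = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    tube = (ii - cx) ** 2 + (jj - cy) ** 2 <= radius**2
    field = np.zeros(shape + (3,))
    field[tube, axis] = 1.0
    metric = np.where(tube, metric_inside, 0.0)
    return (
        ImageGrid(field, affine),
        ImageGrid(metric, affine),
        tube,
        affine,
    )


@pytest.fixture()
def tube_setup():
    field, metric, tube, affine = _straight_field()
    seed = np.zeros(tube.shape, dtype=np.uint8)
    seed[tube] = 1
    seed[..., 3:] = 0  # seed only near the bottom
    return field, metric, ImageGrid(seed, affine), tube, affine


class TestTrack:
    def test_endpoints_reach_tube_caps(self, tube_setup):
        """In a uniform straight tube every accepted streamline runs cap to
        cap: endpoints within one voxel of the tube ends (geometry oracle)."""
        field, metric, seed, tube, affine = tube_setup
        t = track(field, StopRule(metric, "floor", 0.20), seed, target_count=50, rng_seed=0)
        assert len(t) == 50
        zmax = (tube.shape[2] - 1) * 2.5
        for sl in t.streamlines:
            z = sorted([sl[0, 2], sl[-1, 2]])
            assert z[0] <= 2.5 and z[1] >= zmax - 2.5

    def test_spacing_angle_and_length_invariants(self, tube_setup):
        field, metric, seed, _, _ = tube_setup
        rule = StopRule(metric, "floor", 0.20)
        t = track(field, rule, seed, target_count=30, rng_seed=1)
        for sl in t.streamlines:
            steps = np.diff(np.asarray(sl, dtype=float), axis=0)
            norms = np.linalg.norm(steps, axis=1)
            np.testing.assert_allclose(norms, rule.step_mm, rtol=1e-5)
            cosang = np.sum(steps[:-1] * steps[1:], axis=1) / (norms[:-1] * norms[1:])
            assert np.all(cosang >= np.cos(np.deg2rad(rule.max_angle_deg)) - 1e-6)
        lengths = t.lengths_mm()
        assert np.all((lengths >= rule.min_length_mm) & (lengths <= rule.max_length_mm))

    def test_threshold_above_metric_starves(self, tube_setup):
        field, metric, seed, _, _ = tube_setup
        t = track(field, StopRule(metric, "floor", 0.99), seed, target_count=10,
                  rng_seed=0, attempt_factor=5)
        assert len(t) == 0 and t.starved

    def test_same_seed_identical(self, tube_setup):
        field, metric, seed, _, _ = tube_setup
        a = track(field, StopRule(metric, "floor", 0.2), seed, 20, rng_seed=42)
        b = track(field, StopRule(metric, "floor", 0.2), seed, 20, rng_seed=42)
        assert len(a) == len(b)
        for x, y in zip(a.streamlines, b.streamlines):
            np.testing.assert_array_equal(x, y)

    def test_ceiling_rule_blocks_high_metric_region(self):
        """A high-ODI slab mid-tube terminates ceiling-mode propagation."""
        field, metric, tube, affine = _straight_field()
        odi = np.where(tube, 0.05, 1.0)
        odi[:, :, 18:23] = 0.9  # dispersed slab
        seed = np.zeros(tube.shape, np.uint8)
        seed[tube] = 1
        seed[..., 3:] = 0
        t = track(field, StopRule(ImageGrid(odi, affine), "ceiling", 0.45),
                  ImageGrid(seed, affine), 20, rng_seed=0)
        for sl in t.streamlines:
            assert np.asarray(sl)[:, 2].max() < 18 * 2.5


class TestRoiFilter:
    def _three_streamlines(self):
        # world coordinates on a 10-voxel 1mm grid
        a = np.column_stack([np.full(10, 5.0), np.full(10, 5.0), np.arange(10.0)])
        b = a.copy(); b[:, 2] = np.linspace(0, 4, 10)  # only lower half
        c = a.copy(); c[:, 0] = 1.0  # runs through the exclusion slab
        return [a.astype(np.float32), b.astype(np.float32), c.astype(np.float32)]

    def _rois(self):
        affine = np.eye(4)
        shape = (10, 10, 10)
        low = np.zeros(shape, np.uint8); low[:, :, :2] = 1
        high = np.zeros(shape, np.uint8); high[:, :, 8:] = 1
        excl = np.zeros(shape, np.uint8); excl[:2] = 1
        g = lambda m: ImageGrid(m, affine)
        return RoiSet([g(low), g(high)], [g(excl)]), g(low)

    def test_inclusion_and_exclusion_logic(self):
        from edematrack.io_formats import Streamlines

        sls = self._three_streamlines()
        rois, grid = self._rois()
        t = Streamlines(sls, step_size_mm=1.0)
        kept = filter_by_rois(t, rois, grid=grid)
        assert len(kept) == 1  # a: both caps, no exclusion
        np.testing.assert_array_equal(kept.streamlines[0], sls[0])

    def test_empty_inclusion_rejected(self):
        from edematrack.io_formats import Streamlines

        t = Streamlines(self._three_streamlines(), step_size_mm=1.0)
        with pytest.raises(ParameterError):
            filter_by_rois(t, RoiSet([], []), grid=None)


class TestTractMask:
    def test_empty_tractogram_gives_empty_mask(self):
        from edematrack.io_formats import Streamlines

        grid = ImageGrid(np.zeros((5, 5, 5)), np.eye(4))
        m = tract_mask(Streamlines([], step_size_mm=0.5), grid)
        assert m.data.sum() == 0

    def test_axis_aligned_streamline_marks_expected_voxels(self):
        from edematrack.io_formats import Streamlines

        grid = ImageGrid(np.zeros((12, 12, 12)), np.eye(4))
        pts = np.column_stack([np.full(10, 3.0), np.full(10, 3.0), np.arange(10.0)])
        m = tract_mask(Streamlines([pts.astype(np.float32)], step_size_mm=1.0), grid)
        assert m.data.sum() == 10
        assert m.data[3, 3, :10].sum() == 10

    def test_mask_volume_at_2p5mm_voxels(self):
        from edematrack.io_formats import Streamlines

        grid = ImageGrid(np.zeros((8, 8, 8)), np.diag([2.5, 2.5, 2.5, 1.0]))
        pts = np.column_stack([np.full(4, 5.0), np.full(4, 5.0), 2.5 * np.arange(4.0)])
        m = tract_mask(Streamlines([pts.astype(np.float32)], step_size_mm=2.5), grid)
        assert m.data.sum() * m.voxel_volume == pytest.approx(4 * 15.625)


class TestEdemaCrossing:
    def test_dtifails_noddipasses(self, phantom_run):
        """The central qualitative contrast: at SNR 30 the tensor arm never
        carries a streamline through the edema block, while the dispersion
        arm reaches the full quota and nearly all of it traverses."""
        r = phantom_run
        assert count_traversing(r.t_dti, r.edema) == 0
        assert len(r.t_noddi) == 3000 and not r.t_noddi.starved
        frac = count_traversing(r.t_noddi, r.edema) / len(r.t_noddi)
        assert frac >= 0.90
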