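"""Deterministic streamline tractography with a pluggable stopping rule.

The tracker integrates bidirectionally from random seed positions with a
fixed Euler step (default 0.5 mm), sign-aligning the local direction with
the incoming one at every step.  Propagation terminates when the stopping
metric crosses its threshold (FA floor for tensor tracking, ODI ceiling for
dispersion-based tracking), when the turning angle reaches its maximum
(default 60 deg), or when the streamline leaves the grid.  Streamlines
shorter than 30 mm or longer than 300 mm are discarded; seeding repeats
until the requested number of streamlines is accepted or an attempt cap is
reached (in which case the partial result carries a starvation flag).

Direction lookup is nearest-neighbor; the stopping metric is interpolated
trilinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, ParameterError
from .io_formats import ImageGrid, Streamlines

__all__ = ["StopRule", "RoiSet", "track", "filter_by_rois", "tract_mask", "count_traversing"]


@dataclass
class StopRule:
    """Termination rule: a scalar metric map plus a floor or ceiling threshold."""

    metric: ImageGrid
    mode: str  # 'floor' (stop when metric <= threshold) or 'ceiling' (>=)
    threshold: float
    max_angle_deg: float = 60.0
    step_mm: float = 0.5
    min_length_mm: float = 30.0
    max_length_mm: float = 300.0

    def __post_init__(self) -> None:
        if self.mode not in ("floor", "ceiling"):
            raise ParameterError("mode must be 'floor' or 'ceiling'")
        if not (0.0 < self.max_angle_deg <= 90.0):
            raise ParameterError("max turning angle must lie in (0, 90] degrees")
        if self.step_mm <= 0:
            raise ParameterError("step must be positive")

    def passes(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        if self.mode == "floor":
            return value > self.threshold
        return value < self.threshold


@dataclass
class RoiSet:
    """Inclusion and exclusion masks for tract selection."""

    inclusion: list[ImageGrid] = field(default_factory=list)
    exclusion: list[ImageGrid] = field(default_factory=list)


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask.data if isinstance(mask, ImageGrid) else mask) > 0


class _Tracker:
    def __init__(self, direction_field: ImageGrid, stop: StopRule, valid_mask=None):
        if direction_field.data.ndim != 4 or direction_field.data.shape[3] != 3:
            raise ParameterError("direction field must be (X, Y, Z, 3)")
        if not direction_field.same_grid(stop.metric):
            raise GeometryError("metric map must share the tracking grid")
        self.field = np.asarray(direction_field.data, dtype=float)
        self.metric = np.asarray(stop.metric.data, dtype=float)
        # pad by one voxel so trilinear lookup never needs bounds checks;
        # out-of-grid / unfitted corners contribute 0 (a terminating value
        # for a floor rule and a permissive one for a ceiling rule, but the
        # -0.5/shape-0.5 position check fires first at the true edge)
        pad = np.zeros(tuple(s + 2 for s in direction_field.shape3))
        pad[1:-1, 1:-1, 1:-1] = np.nan_to_num(self.metric, nan=0.0)
        self._metric_pad = pad
        self.stop = stop
        self.shape = np.array(direction_field.shape3)
        self.affine = direction_field.affine
        self.inv = np.linalg.inv(self.affine)
        self.valid = None if valid_mask is None else _as_bool(valid_mask)
        self.cos_max = np.cos(np.deg2rad(stop.max_angle_deg))

    def _vox(self, xyz):
        return xyz @ self.inv[:3, :3].T + self.inv[:3, 3]

    def _metric_at(self, vxyz) -> float:
        """Trilinear interpolation at a continuous voxel coordinate."""
        f = np.floor(vxyz).astype(int)
        w = vxyz - f
        i, j, k = f + 1  # padded-array offset
        c = self._metric_pad[i : i + 2, j : j + 2, k : k + 2]
        cx = c[0] * (1.0 - w[0]) + c[1] * w[0]
        cy = cx[0] * (1.0 - w[1]) + cx[1] * w[1]
        return float(cy[0] * (1.0 - w[2]) + cy[1] * w[2])

    def _direction_at(self, vxyz):
        """Nearest-neighbor direction lookup; None when undefined/invalid."""
        ijk = np.round(vxyz).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.shape):
            return None
        if self.valid is not None and not self.valid[tuple(ijk)]:
            return None
        d = self.field[tuple(ijk)]
        if not np.all(np.isfinite(d)):
            return None
        n = np.linalg.norm(d)
        if n < 1e-8:
            return None
        return d / n

    def _ok(self, vxyz) -> bool:
        if np.any(vxyz < -0.5) or np.any(vxyz > self.shape - 0.5):
            return False
        return self.stop.passes(self._metric_at(vxyz))

    def _march(self, seed_xyz, d0, max_steps):
        """One-sided march; returns the list of points beyond the seed."""
        pts = []
        pos = seed_xyz
        prev = d0
        for _ in range(max_steps):
            new = pos + self.stop.step_mm * prev
            v = self._vox(new)
            if not self._ok(v):
                break
            d = self._direction_at(v)
            if d is None:
                break
            if d @ prev < 0:  # sign-align with the incoming direction
                d = -d
            if d @ prev < self.cos_max:  # turning angle >= maximum: stop
                break
            pts.append(new)
            pos, prev = new, d
        return pts

    def run_from(self, seed_xyz):
        """Bidirectional streamline through one seed; None if the seed is dead."""
        v = self._vox(seed_xyz)
        if not self._ok(v):
            return None
        d0 = self._direction_at(v)
        if d0 is None:
            return None
        cap = int(np.ceil(self.stop.max_length_mm / self.stop.step_mm)) + 1
        fwd = self._march(seed_xyz, d0, cap)
        bwd = self._march(seed_xyz, -d0, cap)
        pts = bwd[::-1] + [seed_xyz] + fwd
        length = (len(pts) - 1) * self.stop.step_mm
        if length < self.stop.min_length_mm or length > self.stop.max_length_mm:
            return None
        return np.asarray(pts, dtype=np.float32)


def track(
    direction_field: ImageGrid,
    stop: StopRule,
    seed_mask,
    target_count: int = 3000,
    rng_seed: int = 0,
    rois: RoiSet | None = None,
    valid_mask=None,
    attempt_factor: int = 100,
) -> Streamlines:
    """Deterministic streamline tracking from random seeds inside a mask.

    Seeds are drawn uniformly: a random seed-mask voxel, then a uniform
    position within it.  When ``rois`` is given, the acceptance count is
    post-filtering (a streamline must hit every inclusion mask and no
    exclusion mask to count toward ``target_count``).  ``valid_mask``
    optionally restricts propagation to voxels where the direction field is
    trustworthy (e.g. fit-converged, non-CSF voxels).
    """
    tracker = _Tracker(direction_field, stop, valid_mask=valid_mask)
    seeds = np.argwhere(_as_bool(seed_mask))
    if len(seeds) == 0:
        raise ParameterError("empty seed mask")
    inc, exc = _roi_arrays(rois, direction_field) if rois is not None else ([], [])
    rng = np.random.default_rng(rng_seed)
    accepted: list[np.ndarray] = []
    attempts = 0
    cap = attempt_factor * target_count
    A, off = direction_field.affine[:3, :3], direction_field.affine[:3, 3]
    while len(accepted) < target_count and attempts < cap:
        attempts += 1
        vox = seeds[rng.integers(len(seeds))]
        pos_vox = vox + rng.uniform(-0.5, 0.5, size=3)
        seed_xyz = A @ pos_vox + off
        sl = tracker.run_from(seed_xyz)
        if sl is None:
            continue
        if inc or exc:
            if not _roi_pass(sl, inc, exc, tracker):
                continue
        accepted.append(sl)
    starved = len(accepted) < target_count
    prov = {
        "mode": stop.mode,
        "threshold": stop.threshold,
        "max_angle_deg": stop.max_angle_deg,
        "target_count": target_count,
        "attempts": attempts,
        "rng_seed": rng_seed,
    }
    return Streamlines(accepted, step_size_mm=stop.step_mm, provenance=prov, starved=starved)


def _roi_arrays(rois: RoiSet, ref: ImageGrid):
    inc, exc = [], []
    for m in rois.inclusion:
        if isinstance(m, ImageGrid) and not m.same_grid(ref):
            raise GeometryError("inclusion ROI not on the tracking grid")
        inc.append(_as_bool(m))
    for m in rois.exclusion:
        if isinstance(m, ImageGrid) and not m.same_grid(ref):
            raise GeometryError("exclusion ROI not on the tracking grid")
        exc.append(_as_bool(m))
    return inc, exc


def _points_to_voxels(points: np.ndarray, inv: np.ndarray, shape) -> np.ndarray:
    v = np.round(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    keep = np.all((v >= 0) & (v < np.asarray(shape)), axis=1)
    return v[keep]


def _roi_pass(sl: np.ndarray, inc, exc, tracker: _Tracker) -> bool:
    v = _points_to_voxels(sl, tracker.inv, tracker.shape)
    if len(v) == 0:
        return False
    idx = tuple(v.T)
    for m in exc:
        if np.any(m[idx]):
            return False
    for m in inc:
        if not np.any(m[idx]):
            return False
    return True


def filter_by_rois(t: Streamlines, rois: RoiSet, grid: ImageGrid | None = None) -> Streamlines:
    """Keep streamlines intersecting every inclusion mask and no exclusion mask."""
    if not rois.inclusion:
        raise ParameterError("at least one inclusion ROI is required")
    ref = grid if grid is not None else rois.inclusion[0]
    if not isinstance(ref, ImageGrid):
        raise ParameterError("a reference ImageGrid is required to place ROI masks")
    inv = np.linalg.inv(ref.affine)
    shape = ref.shape3
    inc = [_as_bool(m) for m in rois.inclusion]
    exc = [_as_bool(m) for m in rois.exclusion]
    kept = []
    for sl in t.streamlines:
        v = _points_to_voxels(sl, inv, shape)
        if len(v) == 0:
            continue
        idx = tuple(v.T)
        if any(np.any(m[idx]) for m in exc):
            continue
        if all(np.any(m[idx]) for m in inc):
            kept.append(sl)
    return Streamlines(kept, step_size_mm=t.step_size_mm, provenance=dict(t.provenance), starved=t.starved)


def tract_mask(t: Streamlines, grid: ImageGrid) -> ImageGrid:
    """Binary map of voxels visited by at least one streamline point."""
    out = np.zeros(grid.shape3, dtype=np.uint8)
    inv = np.linalg.inv(grid.affine)
    for sl in t.streamlines:
        v = _points_to_voxels(sl, inv, grid.shape3)
        if len(v):
            out[tuple(v.T)] = 1
    return ImageGrid(out, grid.affine)


def count_traversing(t: Streamlines, mask: ImageGrid) -> int:
    """Number of streamlines that pass *through* the mask: at least one point
    inside it with points outside both before and after (entering and
    exiting, not merely terminating at the boundary)."""
    m = _as_bool(mask)
    inv = np.linalg.inv(mask.affine)
    shape = np.asarray(mask.shape3)
    n = 0
    for sl in t.streamlines:
        v = np.round(sl @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        inb = np.all((v >= 0) & (v < shape), axis=1)
        inside = np.zeros(len(sl), dtype=bool)
        inside[inb] = m[tuple(v[inb].T)]
        idx = np.flatnonzero(inside)
        if len(idx) and idx[0] > 0 and idx[-1] < len(sl) - 1:
            n += 1
    return n
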