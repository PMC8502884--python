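"""Edematous-tract quantification: DN / D-only / N-only conditions, PIV,
lesion-to-tract distance, and LTD-weighted indices.

Within the edema mask, voxels traversed by streamlines are classified by
which reconstruction found them: both tensor- and dispersion-derived (DN),
tensor only (D-only), or dispersion only (N-only).  Each condition's volume
is normalized by the whole-tract volume (PIV = percentage of involved
volume) and optionally weighted by the minimum 3D distance from the lesion
boundary to the tract (LTD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, ParameterError, UndefinedMetricError
from .io_formats import ImageGrid

__all__ = [
    "ConditionMasks",
    "TractMetrics",
    "condition_masks",
    "piv",
    "ltd",
    "weighted_indices",
    "fraction_summary",
    "compute_tract_metrics",
]


def _arr(m) -> np.ndarray:
    return np.asarray(m.data if isinstance(m, ImageGrid) else m) > 0


def _check_grids(*grids):
    imgs = [g for g in grids if isinstance(g, ImageGrid)]
    for g in imgs[1:]:
        if not imgs[0].same_grid(g):
            raise GeometryError("masks must share a grid")


@dataclass
class ConditionMasks:
    """Pairwise-disjoint edema-condition masks (boolean arrays)."""

    dn: np.ndarray
    d_only: np.ndarray
    n_only: np.ndarray

    def volumes_mm3(self, voxel_volume: float) -> dict[str, float]:
        return {
            "dn": float(self.dn.sum()) * voxel_volume,
            "d_only": float(self.d_only.sum()) * voxel_volume,
            "n_only": float(self.n_only.sum()) * voxel_volume,
        }


def condition_masks(dti_mask, noddi_mask, edema_mask) -> ConditionMasks:
    """Classify edema voxels by which tractography traversed them."""
    _check_grids(dti_mask, noddi_mask, edema_mask)
    d, n, e = _arr(dti_mask), _arr(noddi_mask), _arr(edema_mask)
    if not (d.shape == n.shape == e.shape):
        raise GeometryError("masks must share a shape")
    return ConditionMasks(dn=d & n & e, d_only=d & ~n & e, n_only=n & ~d & e)


def piv(condition_volume: float, cst_volume: float) -> float:
    """Percentage of involved volume: condition volume / whole-CST volume."""
    if cst_volume <= 0:
        raise UndefinedMetricError("PIV undefined: CST volume is zero")
    if condition_volume < 0 or condition_volume > cst_volume:
        raise ParameterError("condition volume must lie in [0, CST volume]")
    return condition_volume / cst_volume


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Lesion boundary voxels: mask voxels with a non-mask 6-neighbor
    (voxels on the volume edge count as boundary)."""
    six = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=six, border_value=0)
    return mask & ~interior


def ltd(lesion_mask, cst_mask, voxel_size=None) -> float:
    """Lesion-to-tract distance: minimum Euclidean world-mm distance from a
    lesion *boundary* voxel center to any tract voxel center; 0 when the
    masks overlap."""
    _check_grids(lesion_mask, cst_mask)
    lesion, cst = _arr(lesion_mask), _arr(cst_mask)
    if lesion.shape != cst.shape:
        raise GeometryError("masks must share a shape")
    if lesion.sum() == 0 or cst.sum() == 0:
        raise ParameterError("LTD needs non-empty lesion and tract masks")
    if voxel_size is None:
        if isinstance(lesion_mask, ImageGrid):
            voxel_size = lesion_mask.voxel_size
        else:
            voxel_size = 1.0
    sampling = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    if np.any(lesion & cst):
        return 0.0
    dist = ndimage.distance_transform_edt(~cst, sampling=sampling)
    return float(dist[_boundary(lesion)].min())


def weighted_indices(volume: float, piv_value: float, ltd_mm: float):
    """LTD-weighted indices (volume/LTD, PIV/LTD); None (flagged) when the
    tract touches the lesion (LTD = 0)."""
    if ltd_mm < 0:
        raise ParameterError("LTD cannot be negative")
    if ltd_mm == 0:
        return None, None
    return volume / ltd_mm, piv_value / ltd_mm


def fraction_summary(noddi_fit, condition_mask) -> tuple[float, float, float]:
    """Mean absolute volume fractions (VF_ic, VF_ec, VF_iso) over a mask."""
    m = _arr(condition_mask)
    if m.sum() == 0:
        raise ParameterError("empty condition mask")
    vf_ic = float(np.nanmean(noddi_fit.vf_ic[m]))
    vf_ec = float(np.nanmean(noddi_fit.vf_ec[m]))
    vf_iso = float(np.nanmean(noddi_fit.vf_iso[m]))
    return vf_ic, vf_ec, vf_iso


@dataclass
class TractMetrics:
    """Per-subject edematous-tract metrics row."""

    volumes_mm3: dict[str, float]
    cst_volume_mm3: float
    pivs: dict[str, float]
    ltd_mm: float
    volume_ltd: dict[str, float | None]
    piv_ltd: dict[str, float | None]
    fraction_means: dict[str, tuple[float, float, float] | None]

    def as_row(self) -> dict:
        row: dict = {"cst_volume_mm3": self.cst_volume_mm3, "ltd_mm": self.ltd_mm}
        for cond in ("dn", "d_only", "n_only"):
            row[f"{cond}_volume_mm3"] = self.volumes_mm3[cond]
            row[f"{cond}_piv"] = self.pivs[cond]
            row[f"{cond}_volume_ltd"] = self.volume_ltd[cond]
            row[f"{cond}_piv_ltd"] = self.piv_ltd[cond]
        for cond in ("dn", "n_only"):
            f = self.fraction_means.get(cond)
            if f is not None:
                row[f"{cond}_vf_ic"], row[f"{cond}_vf_ec"], row[f"{cond}_vf_iso"] = f
        return row


def compute_tract_metrics(
    dti_mask: ImageGrid,
    noddi_mask: ImageGrid,
    edema_mask: ImageGrid,
    lesion_mask: ImageGrid,
    noddi_fit=None,
) -> TractMetrics:
    """All edema-condition metrics for one subject.

    The PIV denominator is the volume of the *union* of the tensor- and
    dispersion-derived tract masks (counting a voxel once even when both
    reconstructions hit it).
    """
    _check_grids(dti_mask, noddi_mask, edema_mask, lesion_mask)
    vv = dti_mask.voxel_volume
    conds = condition_masks(dti_mask, noddi_mask, edema_mask)
    vols = conds.volumes_mm3(vv)
    cst_union = _arr(dti_mask) | _arr(noddi_mask)
    cst_vol = float(cst_union.sum()) * vv
    pivs = {k: piv(v, cst_vol) for k, v in vols.items()}
    ltd_mm = ltd(lesion_mask, ImageGrid(cst_union.astype(np.uint8), dti_mask.affine))
    vw, pw = {}, {}
    for k in vols:
        vw[k], pw[k] = weighted_indices(vols[k], pivs[k], ltd_mm)
    fracs = {}
    if noddi_fit is not None:
        for k, m in (("dn", conds.dn), ("n_only", conds.n_only)):
            fracs[k] = fraction_summary(noddi_fit, m) if m.sum() else None
    return TractMetrics(
        volumes_mm3=vols,
        cst_volume_mm3=cst_vol,
        pivs=pivs,
        ltd_mm=ltd_mm,
        volume_ltd=vw,
        piv_ltd=pw,
        fraction_means=fracs,
    )
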