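"""Diffusion-tensor fit on the low-b shell: FA, MD, principal eigenvector.

The tensor is estimated per voxel by signal^2-weighted log-linear least
squares on the sub-scheme with b < 1,500 s/mm^2 (only the b=0 and b=1,000
frames of the two-shell protocol), which is deterministic and exact on
noise-free single-tensor data.  The principal eigenvector drives the
DTI-mode tracker; FA is its termination metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, SchemeError
from .io_formats import GradientScheme, ImageGrid

__all__ = ["DtiModel", "DtiResults", "fit_dti", "fa", "md"]

_LOG_FLOOR = 1e-6  # signal floor relative to S0 before taking logs


def fa(eigenvalues) -> float | np.ndarray:
    """Fractional anisotropy sqrt(3/2) ||lam - mean|| / ||lam||; 0 for the zero tensor."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ParameterError("need 3 eigenvalues")
    if np.any(lam < 0):
        raise ParameterError("negative eigenvalue")
    dev = lam - lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.divide(num, den, out=np.zeros_like(den), where=den > 0)
    return float(out) if out.ndim == 0 else out


def md(eigenvalues) -> float | np.ndarray:
    """Mean diffusivity: arithmetic mean of the eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ParameterError("need 3 eigenvalues")
    if np.any(lam < 0):
        raise ParameterError("negative eigenvalue")
    out = lam.mean(axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass
class DtiResults:
    """Voxelwise tensor fit: eigen-decomposition, FA/MD, diagnostics."""

    tensor: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    evals: np.ndarray  # (..., 3) sorted descending, negatives clamped to 0
    e1: np.ndarray  # (..., 3) principal eigenvector, unit where fitted
    fa_map: np.ndarray
    md_map: np.ndarray
    s0: np.ndarray
    fitted: np.ndarray  # bool: voxel attempted
    clamped: np.ndarray  # bool: negative eigenvalue or floored signal
    affine: np.ndarray
    model: "DtiModel | None" = None

    def map(self, name: str) -> ImageGrid:
        return ImageGrid(np.nan_to_num(getattr(self, name), nan=0.0), self.affine)

    def summary(self) -> str:
        m = self.fitted
        lines = [
            "DTI fit summary",
            "===============",
            f"voxels fitted  : {int(m.sum())}",
            f"flagged voxels : {int(self.clamped.sum())}",
        ]
        if m.any():
            lines += [
                f"FA             : mean {np.nanmean(self.fa_map[m]):.4f}  "
                f"sd {np.nanstd(self.fa_map[m]):.4f}",
                f"MD (mm^2/s)    : mean {np.nanmean(self.md_map[m]):.3e}",
            ]
        return "\n".join(lines)


class DtiModel:
    """Single-tensor model bound to DWI data, fitted on frames with b < b_max."""

    def __init__(
        self,
        dwi: ImageGrid,
        scheme: GradientScheme,
        mask=None,
        b_max: float = 1500.0,
    ) -> None:
        if dwi.data.ndim != 4:
            raise ParameterError("DtiModel needs 4D DWI data")
        if dwi.data.shape[3] != len(scheme):
            raise SchemeError("DWI frame count differs from scheme length")
        keep = scheme.bvals < b_max
        sub = scheme.subset(keep)
        ndir = np.count_nonzero(~sub.b0_mask)
        if ndir < 6:
            raise SchemeError(f"only {ndir} directions with 0 < b < {b_max}")
        if not np.any(sub.b0_mask):
            raise SchemeError("no b=0 frame below b_max")
        g = sub.bvecs[~sub.b0_mask]
        rank = np.linalg.matrix_rank(
            np.column_stack(
                [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                 g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]]
            )
        )
        if rank < 6:
            raise SchemeError("gradient directions are rank-deficient for a tensor fit")
        self.dwi = dwi
        self.scheme = scheme
        self.keep = keep
        self.sub = sub
        if mask is None:
            mask_arr = np.ones(dwi.shape3, dtype=bool)
        else:
            mask_arr = np.asarray(mask.data if isinstance(mask, ImageGrid) else mask) > 0
        self.mask = mask_arr
        b = sub.bvals
        v = sub.bvecs
        # design: ln S = ln S0 - b g' D g
        self.design = np.column_stack(
            [
                np.ones_like(b),
                -b * v[:, 0] ** 2,
                -b * v[:, 1] ** 2,
                -b * v[:, 2] ** 2,
                -2 * b * v[:, 0] * v[:, 1],
                -2 * b * v[:, 0] * v[:, 2],
                -2 * b * v[:, 1] * v[:, 2],
            ]
        )

    def fit(self) -> DtiResults:
        shape = self.dwi.shape3
        data = np.asarray(self.dwi.data, dtype=float)[..., self.keep]
        vox = np.argwhere(self.mask)
        n_vox = len(vox)
        X = self.design
        sig = data[tuple(vox.T)]  # (n_vox, n_frames)
        b0m = self.sub.b0_mask
        s0 = sig[:, b0m].mean(axis=1)
        usable = np.isfinite(s0) & (s0 > 0)
        floor = _LOG_FLOOR * np.where(usable, s0, 1.0)[:, None]
        floored = sig < floor
        y = np.log(np.maximum(sig, floor))
        w = np.maximum(sig, 0.0) ** 2  # signal^2 weights
        # batched weighted normal equations
        xtwx = np.einsum("ni,vn,nj->vij", X, w, X)
        xtwy = np.einsum("ni,vn->vi", X, w * y)
        beta = np.full((n_vox, 7), np.nan)
        ok = usable.copy()
        good = ok & (np.linalg.cond(xtwx) < 1e12)
        beta[good] = np.linalg.solve(xtwx[good], xtwy[good][..., None])[..., 0]

        tensor6 = np.full(shape + (6,), np.nan)
        evals = np.full(shape + (3,), np.nan)
        e1 = np.full(shape + (3,), np.nan)
        fa_map = np.full(shape, np.nan)
        md_map = np.full(shape, np.nan)
        s0_map = np.full(shape, np.nan)
        fitted = np.zeros(shape, dtype=bool)
        clamped = np.zeros(shape, dtype=bool)

        D = np.zeros((n_vox, 3, 3))
        bb = beta[:, 1:7]
        D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = bb[:, 0], bb[:, 1], bb[:, 2]
        D[:, 0, 1] = D[:, 1, 0] = bb[:, 3]
        D[:, 0, 2] = D[:, 2, 0] = bb[:, 4]
        D[:, 1, 2] = D[:, 2, 1] = bb[:, 5]
        lam = np.full((n_vox, 3), np.nan)
        vec1 = np.full((n_vox, 3), np.nan)
        gidx = np.flatnonzero(good)
        if len(gidx):
            w_, v_ = np.linalg.eigh(D[gidx])  # ascending
            lam[gidx] = w_[:, ::-1]
            vec1[gidx] = v_[:, :, 2]
        neg = good & np.any(lam < 0, axis=1)
        lam_cl = np.clip(lam, 0.0, None)

        coords = tuple(vox.T)
        fitted[coords] = good
        clamped[coords] = neg | np.any(floored & good[:, None], axis=1)
        tensor6[coords] = beta[:, 1:7]
        evals[coords] = lam_cl
        e1[coords] = vec1
        dev = lam_cl - lam_cl.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(lam_cl, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa_v = np.where(
                nrm > 0, np.sqrt(1.5) * np.linalg.norm(dev, axis=1) / nrm, 0.0
            )
        fa_map[coords] = np.where(good, fa_v, np.nan)
        md_map[coords] = lam_cl.mean(axis=1)
        s0_map[coords] = np.where(good, np.exp(beta[:, 0]), np.nan)

        return DtiResults(
            tensor=tensor6,
            evals=evals,
            e1=e1,
            fa_map=fa_map,
            md_map=md_map,
            s0=s0_map,
            fitted=fitted,
            clamped=clamped,
            affine=self.dwi.affine,
            model=self,
        )


def fit_dti(dwi: ImageGrid, scheme: GradientScheme, mask=None, b_max: float = 1500.0) -> DtiResults:
    """Functional wrapper around :class:`DtiModel`."""
    return DtiModel(dwi, scheme, mask, b_max=b_max).fit()
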