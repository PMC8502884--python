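"""Volume, gradient-table, mask and tractogram I/O.

Containers
----------
``ImageGrid``
    A 3D/4D array plus its NIfTI affine.  All maps produced by the package
    (DWI, FA/MD, NODDI indices, masks) live on such grids.  Voxel indices are
    0-based and world coordinates follow the NIfTI convention (affine maps
    voxel index -> world mm).
``GradientScheme``
    FSL-dialect b-values and unit gradient directions.
``Streamlines``
    Ordered world-mm point sequences with a fixed step size, written/read as
    MRtrix TCK (world-mm coordinates, so no grid coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import TckFile
from nibabel.streamlines import Tractogram as _NibTractogram

from .exceptions import FormatError, GeometryError, ParameterError, ValidationError

__all__ = [
    "ImageGrid",
    "GradientScheme",
    "Streamlines",
    "read_dwi",
    "read_image",
    "write_image",
    "read_mask",
    "write_tractogram",
    "read_tractogram",
]

_B0_TOL = 1e-6
_UNIT_TOL = 1e-4


@dataclass
class ImageGrid:
    """A volumetric map: 3D/4D data with a voxel->world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValidationError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "ImageGrid", tol: float = 1e-4) -> bool:
        return self.shape3 == other.shape3 and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class GradientScheme:
    """Multi-shell acquisition: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), unit norm where b > 0

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError("bvecs must be (n, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise ValidationError("bvals and bvecs length mismatch")
        if np.any(self.bvals < 0):
            raise ValidationError("negative b-value")
        if not np.any(self.b0_mask):
            raise ValidationError("scheme has no b=0 entry")
        dwi = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(norms < _UNIT_TOL):
            raise ValidationError("zero gradient direction at b > 0")
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            # renormalize mild deviations; reject was handled above
            self.bvecs = self.bvecs.copy()
            self.bvecs[dwi] /= norms[:, None]

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= _B0_TOL

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[~self.b0_mask])

    def subset(self, keep: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.bvals[keep], self.bvecs[keep])


@dataclass
class Streamlines:
    """A bundle of streamlines: world-mm point sequences at a fixed step."""

    streamlines: list[np.ndarray]
    step_size_mm: float = 0.5
    provenance: dict = field(default_factory=dict)
    starved: bool = False  # seeding gave up before reaching the target count

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=np.float32) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValidationError("each streamline needs >= 2 three-D points")

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths_mm(self) -> np.ndarray:
        return np.array(
            [(len(s) - 1) * self.step_size_mm for s in self.streamlines], dtype=float
        )


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_image(path) -> ImageGrid:
    img = nib.load(str(path))
    return ImageGrid(np.asarray(img.dataobj), img.affine)


def write_image(grid: ImageGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(grid.data), grid.affine), str(path))


def read_dwi(volume_path, bval_path, bvec_path) -> tuple[ImageGrid, GradientScheme]:
    """Load a 4D DWI volume plus FSL-dialect bval/bvec text files.

    The bval file holds one whitespace-delimited row of b-values; the bvec
    file holds three rows (x, y, z components).  Directions are renormalized
    to unit length; the number of 4D frames must equal the scheme length.
    """
    grid = read_image(volume_path)
    if grid.data.ndim != 4:
        raise FormatError(f"{volume_path}: expected 4D DWI, got {grid.data.ndim}D")
    try:
        bvals = np.loadtxt(str(bval_path), ndmin=2)
        bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    except ValueError as exc:  # non-numeric tokens
        raise FormatError(f"unreadable bval/bvec text: {exc}") from exc
    if bvals.shape[0] != 1:
        raise FormatError(f"{bval_path}: expected 1 row of b-values, got {bvals.shape[0]}")
    if bvecs.shape[0] != 3:
        raise FormatError(f"{bvec_path}: expected 3 rows of components, got {bvecs.shape[0]}")
    bvals = bvals.ravel()
    bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise FormatError("bval/bvec column counts differ")
    if len(bvals) != grid.data.shape[3]:
        raise FormatError(
            f"{grid.data.shape[3]} DWI frames but {len(bvals)} scheme entries"
        )
    return grid, GradientScheme(bvals, bvecs)


def write_dwi(grid: ImageGrid, scheme: GradientScheme, volume_path, bval_path, bvec_path) -> None:
    if grid.data.ndim != 4 or grid.data.shape[3] != len(scheme):
        raise ValidationError("DWI frame count must equal scheme length")
    write_image(grid, volume_path)
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.9g")


_SNAP_TOL = 1e-6


def read_mask(path, reference: ImageGrid) -> ImageGrid:
    """Read a binary NIfTI mask defined on ``reference``'s grid.

    Values within 1e-6 of {0,1} are snapped; anything else (a resampled /
    interpolated mask) is rejected rather than silently thresholded.
    """
    grid = read_image(path)
    if grid.data.ndim != 3:
        raise ValidationError("mask must be 3D")
    if not grid.same_grid(reference):
        raise GeometryError(f"{path}: mask grid/affine differs from reference")
    data = np.asarray(grid.data, dtype=float)
    snapped = np.round(data)
    if np.any(np.abs(data - snapped) > _SNAP_TOL) or np.any((snapped != 0) & (snapped != 1)):
        raise ValidationError(f"{path}: mask values not in {{0,1}}")
    return ImageGrid(snapped.astype(np.uint8), grid.affine)


# ---------------------------------------------------------------------------
# TCK tractograms


def write_tractogram(t: Streamlines, path) -> None:
    tg = _NibTractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    hdr = {"step_size_mm": repr(t.step_size_mm)}
    for k, v in t.provenance.items():
        hdr[str(k)] = str(v)
    TckFile(tg, header=hdr).save(str(path))


def read_tractogram(path) -> Streamlines:
    try:
        tck = TckFile.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TCK file ({exc})") from exc
    sls = [np.asarray(s, dtype=np.float32) for s in tck.tractogram.streamlines]
    hdr = dict(tck.header)
    try:
        step = float(hdr.pop("step_size_mm"))
    except (KeyError, ValueError):
        # foreign TCK: infer the step from the data, fall back to 0.5
        step = float(np.linalg.norm(sls[0][1] - sls[0][0])) if sls else 0.5
    prov = {k: v for k, v in hdr.items() if not k.startswith(("magic", "count", "datatype", "file", "timestamp"))}
    return Streamlines(sls, step_size_mm=step, provenance=prov)
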