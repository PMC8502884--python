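"""Shared fixtures: small phantoms for unit tests and one full default-scale
phantom run (simulate -> fit both models -> track both modes) reused by the
acceptance-level tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from edematrack.dti import DtiModel
from edematrack.io_formats import ImageGrid
from edematrack.noddi import NoddiModel
from edematrack.phantom import PhantomSpec, build_phantom, make_protocol, simulate_dwi
from edematrack.tracking import RoiSet, StopRule, filter_by_rois, track, tract_mask

SEED = 7  # single fixed study seed for the default phantom conditions


@pytest.fixture(scope="session")
def protocol():
    return make_protocol(seed=SEED)


@pytest.fixture(scope="session")
def default_phantom(protocol):
    spec = PhantomSpec(rng_seed=SEED)
    gt = build_phantom(spec)
    dwi = simulate_dwi(gt, protocol)  # snr 30 from the spec default
    return gt, dwi


@dataclass
class PhantomRun:
    gt: object
    scheme: object
    dwi: object
    dti: object
    noddi: object
    t_dti: object  # length-accepted tensor-mode streamlines (pre-ROI)
    t_dti_cst: object  # after two-ROI selection
    t_noddi: object  # dispersion-mode streamlines, ROI-filtered quota
    dti_mask: object
    noddi_mask: object
    rois: RoiSet
    edema: ImageGrid


@pytest.fixture(scope="session")
def phantom_run(default_phantom, protocol) -> PhantomRun:
    """The default study conditions end to end (the expensive fixture)."""
    gt, dwi = default_phantom
    mask = gt.analysis_mask
    dres = DtiModel(dwi, protocol, mask).fit()
    nres = NoddiModel(dwi, protocol, mask).fit(init_orientations=dres.e1)
    aff = gt.affine
    rois = RoiSet(
        [ImageGrid(m.astype(np.uint8), aff) for m in gt.inclusion_rois],
        [ImageGrid(m.astype(np.uint8), aff) for m in gt.exclusion_rois],
    )
    seed_mask = rois.inclusion[0]
    edema = gt.grid("edema")
    t_dti = track(
        ImageGrid(np.nan_to_num(dres.e1), aff),
        StopRule(dres.map("fa_map"), "floor", 0.20),
        seed_mask,
        target_count=3000,
        rng_seed=SEED + 1,
    )
    t_dti_cst = filter_by_rois(t_dti, rois, grid=seed_mask)
    valid = ImageGrid((nres.fitted & (nres.vf_iso < 0.99)).astype(np.uint8), aff)
    t_noddi = track(
        ImageGrid(np.nan_to_num(nres.mu), aff),
        StopRule(nres.map("odi"), "ceiling", 0.45),
        seed_mask,
        target_count=3000,
        rng_seed=SEED + 2,
        rois=rois,
        valid_mask=valid,
    )
    return PhantomRun(
        gt=gt,
        scheme=protocol,
        dwi=dwi,
        dti=dres,
        noddi=nres,
        t_dti=t_dti,
        t_dti_cst=t_dti_cst,
        t_noddi=t_noddi,
        dti_mask=tract_mask(t_dti, edema),
        noddi_mask=tract_mask(t_noddi, edema),
        rois=rois,
        edema=edema,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
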