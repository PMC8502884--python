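"""End-to-end phantom pipeline: simulate -> fit -> track -> quantify -> ROC.

A run is driven by a plain-text key-value config (``key = value`` lines,
``#`` comments).  Every stage's randomness is funneled through explicit
seeds derived from the single mandatory ``seed`` key, and a JSON manifest
records every artifact, the parameter set and the package version, so a
rerun with the same config reproduces the same numbers bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibrate_odi_threshold, default_threshold_grid
from .dti import DtiModel
from .exceptions import ValidationError
from .io_formats import ImageGrid, write_dwi, write_image, write_tractogram
from .noddi import NoddiModel
from .phantom import PhantomSpec, build_phantom, simulate_dwi
from .quantify import compute_tract_metrics
from .stats import load_table1, roc
from .tracking import RoiSet, StopRule, filter_by_rois, track, tract_mask

log = logging.getLogger("edematrack")

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


@dataclass
class RunConfig:
    """Validated pipeline configuration; ``seed`` has no default on purpose."""

    seed: int
    snr: float = 30.0
    grid: int = 40
    edema_halfwidth: int = 6
    edema_viso: float = 0.9
    count: int = 3000
    odi_threshold: float = 0.45
    fa_threshold: float = 0.20
    angle: float = 60.0
    step: float = 0.5
    min_len: float = 30.0
    max_len: float = 300.0
    viso_guard: float = 0.99
    calibrate: bool = False
    calibrate_count: int = 300
    calibrate_step: float = 0.05

    _FLOATS = ("snr", "edema_viso", "odi_threshold", "fa_threshold", "angle",
               "step", "min_len", "max_len", "viso_guard", "calibrate_step")
    _INTS = ("seed", "grid", "edema_halfwidth", "count", "calibrate_count")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            raw[k] = v
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: dict, source: str = "<config>") -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{source}: unknown config keys {sorted(unknown)}")
        if "seed" not in raw:
            raise ValidationError(f"{source}: mandatory key 'seed' is missing")
        kw = {}
        for k, v in raw.items():
            if k in cls._INTS:
                kw[k] = int(v)
            elif k in cls._FLOATS:
                kw[k] = float(v)
            elif k == "calibrate":
                kw[k] = _BOOL[str(v).strip().lower()]
            else:
                kw[k] = v
        return cls(**kw)


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _noddi_valid_mask(nres, viso_guard: float) -> ImageGrid:
    valid = nres.fitted & (nres.vf_iso < viso_guard)
    return ImageGrid(valid.astype(np.uint8), nres.affine)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage on the phantom; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "seeds": {
            "phantom": config.seed,
            "dti_track": config.seed + 1,
            "noddi_track": config.seed + 2,
            "calibration": config.seed + 3,
        },
        "artifacts": {},
    }
    art = manifest["artifacts"]

    # --- simulate -----------------------------------------------------
    log.info("simulate: %d^3 grid, snr=%g, seed=%d", config.grid, config.snr, config.seed)
    spec = PhantomSpec(
        grid_shape=(config.grid,) * 3,
        edema_halfwidth_vox=config.edema_halfwidth,
        edema_viso=config.edema_viso,
        snr=config.snr,
        rng_seed=config.seed,
    )
    gt = build_phantom(spec)
    from .phantom import make_protocol

    scheme = make_protocol(seed=config.seed)
    dwi = simulate_dwi(gt, scheme)
    write_dwi(dwi, scheme, out / "dwi.nii.gz", out / "dwi.bval", out / "dwi.bvec")
    art["dwi"] = ["dwi.nii.gz", "dwi.bval", "dwi.bvec"]
    for name in ("edema", "lesion"):
        write_image(gt.grid(name), out / f"{name}.nii.gz")
        art[name] = f"{name}.nii.gz"
    for i, m in enumerate(gt.inclusion_rois, 1):
        write_image(ImageGrid(m.astype(np.uint8), gt.affine), out / f"roi_include_{i}.nii.gz")
    for i, m in enumerate(gt.exclusion_rois, 1):
        write_image(ImageGrid(m.astype(np.uint8), gt.affine), out / f"roi_exclude_{i}.nii.gz")
    art["rois"] = [f"roi_include_{i}.nii.gz" for i in (1, 2)] + [
        f"roi_exclude_{i}.nii.gz" for i in (1, 2)
    ]
    mask = ImageGrid(gt.analysis_mask.astype(np.uint8), gt.affine)
    write_image(mask, out / "analysis_mask.nii.gz")
    art["analysis_mask"] = "analysis_mask.nii.gz"

    # --- model fits ---------------------------------------------------
    log.info("fit-dti: %d voxels", int(gt.analysis_mask.sum()))
    dres = DtiModel(dwi, scheme, mask).fit()
    for name in ("fa_map", "md_map"):
        write_image(dres.map(name), out / f"{name.split('_')[0]}.nii.gz")
    write_image(ImageGrid(np.nan_to_num(dres.e1), dres.affine), out / "dti_e1.nii.gz")
    art["dti_maps"] = ["fa.nii.gz", "md.nii.gz", "dti_e1.nii.gz"]
    log.info("%s", dres.summary())

    log.info("fit-noddi")
    nres = NoddiModel(dwi, scheme, mask).fit(init_orientations=dres.e1)
    for name in ("odi", "vf_ic", "vf_ec", "vf_iso", "kappa"):
        write_image(nres.map(name), out / f"{name}.nii.gz")
    write_image(ImageGrid(np.nan_to_num(nres.mu), nres.affine), out / "noddi_mu.nii.gz")
    art["noddi_maps"] = [
        "odi.nii.gz", "vf_ic.nii.gz", "vf_ec.nii.gz", "vf_iso.nii.gz",
        "kappa.nii.gz", "noddi_mu.nii.gz",
    ]
    log.info("%s", nres.summary())

    # --- tracking (both modes) ---------------------------------------
    rois = RoiSet(
        inclusion=[ImageGrid(m.astype(np.uint8), gt.affine) for m in gt.inclusion_rois],
        exclusion=[ImageGrid(m.astype(np.uint8), gt.affine) for m in gt.exclusion_rois],
    )
    seed_mask = rois.inclusion[0]
    common = dict(
        max_angle_deg=config.angle, step_mm=config.step,
        min_length_mm=config.min_len, max_length_mm=config.max_len,
    )
    log.info("track: DTI mode, FA floor %.2f", config.fa_threshold)
    # the DTI arm is tracked without ROI selection first: when the edema
    # fully occludes the bundle no streamline reaches both caps, and the
    # partial (length-accepted) tract is exactly what enters the shallow
    # edema and defines the D-involved voxels
    t_dti = track(
        ImageGrid(np.nan_to_num(dres.e1), dres.affine),
        StopRule(dres.map("fa_map"), "floor", config.fa_threshold, **common),
        seed_mask, target_count=config.count, rng_seed=config.seed + 1,
    )
    t_dti_cst = filter_by_rois(t_dti, rois, grid=seed_mask)
    log.info("  accepted %d streamlines (starved=%s); %d pass both ROI caps",
             len(t_dti), t_dti.starved, len(t_dti_cst))
    log.info("track: NODDI mode, ODI ceiling %.2f", config.odi_threshold)
    valid = _noddi_valid_mask(nres, config.viso_guard)
    t_noddi = track(
        ImageGrid(np.nan_to_num(nres.mu), nres.affine),
        StopRule(nres.map("odi"), "ceiling", config.odi_threshold, **common),
        seed_mask, target_count=config.count, rng_seed=config.seed + 2,
        rois=rois, valid_mask=valid,
    )
    log.info("  accepted %d streamlines (starved=%s)", len(t_noddi), t_noddi.starved)
    write_tractogram(t_dti, out / "cst_dti.tck")
    write_tractogram(t_noddi, out / "cst_noddi.tck")
    ref = gt.grid("edema")
    m_dti = tract_mask(t_dti, ref)
    m_noddi = tract_mask(t_noddi, ref)
    write_image(m_dti, out / "cst_dti_mask.nii.gz")
    write_image(m_noddi, out / "cst_noddi_mask.nii.gz")
    art["tractograms"] = ["cst_dti.tck", "cst_noddi.tck"]
    art["tract_masks"] = ["cst_dti_mask.nii.gz", "cst_noddi_mask.nii.gz"]
    manifest["tracking"] = {
        "dti_count": len(t_dti), "dti_starved": t_dti.starved,
        "dti_roi_count": len(t_dti_cst),
        "noddi_count": len(t_noddi), "noddi_starved": t_noddi.starved,
    }

    # --- optional ODI-threshold calibration ---------------------------
    if config.calibrate:
        log.info("calibrate: sweep with %d streamlines per threshold", config.calibrate_count)

        def tractor(theta: float):
            t = track(
                ImageGrid(np.nan_to_num(nres.mu), nres.affine),
                StopRule(nres.map("odi"), "ceiling", theta, **common),
                seed_mask, target_count=config.calibrate_count,
                rng_seed=config.seed + 3, rois=rois, valid_mask=valid,
            )
            return tract_mask(t, ref)

        sweep = calibrate_odi_threshold(
            [m_dti], [tractor], default_threshold_grid(config.calibrate_step)
        )
        pd.DataFrame(
            {"threshold": sweep.thresholds, "mean_dice": sweep.mean_dice}
        ).to_csv(out / "calibration.tsv", sep="\t", index=False)
        art["calibration"] = "calibration.tsv"
        manifest["calibration"] = {"optimal_odi": sweep.optimal_threshold}
        log.info("%s", sweep.summary())

    # --- quantification -----------------------------------------------
    metrics = compute_tract_metrics(m_dti, m_noddi, ref, gt.grid("lesion"), nres)
    row = metrics.as_row()
    pd.DataFrame([row]).to_csv(out / "metrics.tsv", sep="\t", index=False)
    art["metrics"] = "metrics.tsv"
    manifest["metrics"] = {k: (None if v is None else float(v)) for k, v in row.items()}
    log.info("metrics: %s", json.dumps(manifest["metrics"], indent=None))

    # --- clinical ROC on the packaged cohort --------------------------
    tbl = load_table1()
    rows = []
    for col, cut in (("edema_volume_mm3", 20260.0), ("ltd_mm", 16.9)):
        r = roc(tbl[col].values, ~tbl["motor_decline"].astype(bool), "greater")
        from .stats import sens_spec_at

        sens, spec = sens_spec_at(
            tbl[col].values, ~tbl["motor_decline"].astype(bool), cut, "greater"
        )
        rows.append({"index": col, "auc": r.auc, "threshold": cut,
                     "sensitivity": sens, "specificity": spec})
    pd.DataFrame(rows).to_csv(out / "clinical_roc.tsv", sep="\t", index=False)
    art["clinical_roc"] = "clinical_roc.tsv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("manifest written to %s", out / "manifest.json")
    return manifest
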