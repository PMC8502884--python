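# edematrack

Deterministic tractography of white-matter tracts concealed by peritumoral
vasogenic edema, driven by the Watson-NODDI microstructure model instead of
the diffusion tensor.

## The problem

Around aggressive brain tumors, vasogenic edema floods the extracellular
space with free water. The single-tensor (DTI) picture of such a voxel
collapses: fractional anisotropy (FA) drops below the usual tracking floor
(FA ≤ 0.20) even when the axons underneath are intact, so conventional
deterministic tractography terminates at the edema boundary and the
corticospinal tract (CST) appears to vanish — a false negative with direct
consequences for surgical planning.

The three-compartment NODDI model separates the signal instead of averaging
it:

    A(b, g) = (1 − VF_iso) · [ v_ic · A_ic + (1 − v_ic) · A_ec ] + VF_iso · e^(−b·d_iso)

with restricted sticks `A_ic` whose orientations follow a Watson
distribution W(μ, κ), a tortuosity-coupled hindered compartment `A_ec`, and
free water `e^(−b·d_iso)` (d∥ = 1.7×10⁻³ mm²/s, d_iso = 3.0×10⁻³ mm²/s).
The orientation dispersion index

    ODI = (2/π) · arctan(1/κ)

is computed from the tissue compartment only, so it survives free-water
contamination. Tracking along the fitted Watson axis μ with an ODI
*ceiling* (propagate while ODI < 0.45) instead of an FA floor recovers the
tract through the edema.

`edematrack` implements the full pipeline — multi-shell phantom simulation,
DTI and Watson-NODDI fitting, deterministic streamline tracking with
pluggable stopping rules, ODI-threshold calibration by Dice overlap, and
edematous-tract quantification (DN / D-only / N-only condition volumes,
percentage of involved volume PIV, lesion-to-tract distance LTD,
LTD-weighted indices, ROC/Youden diagnostics, Wilcoxon comparisons) —
validated end to end on a synthetic phantom with known ground truth, plus a
packaged 24-patient clinical summary table for the diagnostic statistics.

## Worked example

```python
import numpy as np
from edematrack import (PhantomSpec, build_phantom, make_protocol, simulate_dwi,
                        DtiModel, NoddiModel, StopRule, RoiSet, track,
                        tract_mask, count_traversing)
from edematrack.io_formats import ImageGrid

gt = build_phantom(PhantomSpec(rng_seed=7))          # CST-like tube + edema
scheme = make_protocol(seed=7)                       # 4 b0 + 30@b1000 + 60@b2000
dwi = simulate_dwi(gt, scheme)                       # Rician noise, SNR 30

mask = gt.grid("analysis_mask")
dres = DtiModel(dwi, scheme, mask).fit()
nres = NoddiModel(dwi, scheme, mask).fit(init_orientations=dres.e1)
print(nres.summary())

aff = gt.affine
rois = RoiSet([ImageGrid(m.astype(np.uint8), aff) for m in gt.inclusion_rois],
              [ImageGrid(m.astype(np.uint8), aff) for m in gt.exclusion_rois])
valid = ImageGrid((nres.fitted & (nres.vf_iso < 0.99)).astype(np.uint8), aff)
t = track(ImageGrid(np.nan_to_num(nres.mu), aff),
          StopRule(nres.map("odi"), "ceiling", 0.45),
          rois.inclusion[0], target_count=3000, rng_seed=8,
          rois=rois, valid_mask=valid)
n_cross = count_traversing(t, gt.grid("edema"))
print(len(t), t.starved, n_cross)
```

Output (the numbers the pipeline prints for these seeds):

```
Watson-NODDI fit summary
========================
voxels fitted        : 2040
converged            : 1999
VF_iso               : mean 0.5289  sd 0.3537
VF_ic                : mean 0.2531  sd 0.1809
VF_ec                : mean 0.2180  sd 0.1958
ODI                  : mean 0.4650  sd 0.2617
median |residual|    : 0.2944
3000 False 3000
```

Reading: the fit covers the bundle, its one-voxel shell and the edema
block; the dispersion-terminated tracker reaches its full 3,000-streamline
quota without starvation, and all 3,000 streamlines pass *through* the
edema block — the contrast with tensor-mode tracking (`mode="floor"` on the
FA map), which accepts streamlines but carries none of them through the
edema.

A one-command version of the same run (plus quantification and the clinical
ROC table):

```bash
printf 'seed = 7\n' > config.txt
edematrack demo config.txt out/
```

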