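# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `edematrack`, in the spirit of a model
description a maintainer or reviewer would want before trusting the output.

## Signal models

**Diffusion tensor.** Fitted per voxel by signal²-weighted log-linear least
squares, restricted to frames with b < 1,500 s/mm² (only the b=0 and
b=1,000 shells of the two-shell protocol enter; the b=2,000 shell is
excluded because the Gaussian tensor model is not valid there). The fit is
deterministic and exact on noise-free single-tensor data, which the suite
verifies to 1e-9 on 100 random positive-definite tensors. Negative
eigenvalues are clamped to zero for FA/MD with the voxel flagged; signals
below 1e-6·S0 are floored before the log and flagged. FA uses
√(3/2)·‖λ−λ̄‖/‖λ‖ with FA(0) := 0.

**Watson-NODDI.** Three compartments (restricted sticks with
Watson-distributed orientations, tortuosity-coupled hindered extracellular
space with d⊥ = d∥(1 − v_ic), free water), fixed diffusivities
d∥ = 1.7×10⁻³ mm²/s and d_iso = 3.0×10⁻³ mm²/s — the standard in-vivo
values for this model, which the source protocol did not alter. The
extracellular compartment uses the dispersion-averaged (mean-tensor)
approximation, the standard practice for Watson models. ODI = (2/π)·
arctan(1/κ). Absolute fractions are defined as VF_iso = v_iso,
VF_ic = (1 − v_iso)·v_ic, VF_ec the remainder, so VF_ic + VF_ec + VF_iso = 1
holds to machine precision by construction at every fitted voxel.

**Watson integrals.** The Watson average of the stick signal is a genuine
2-D integral (polar angle to μ × azimuth); a 1-D polar rule alone is not
sufficient for general gradient directions. It is evaluated with 128-point
Gauss–Legendre quadrature in t = cos θ crossed with a 24-point periodic
trapezoid rule in azimuth. 128 polar nodes are needed because the Watson
weight e^{κt²} concentrates at t = ±1; at κ = 64 this rule agrees with a
~1.8×10⁵-node brute-force spherical quadrature to better than 1e-6
relative (tested for κ ∈ {0.1, 1, 4, 16, 64}).

**Fitter.** Per masked voxel: normalize by the mean b=0 signal; coarse grid
search over v_iso, v_ic ∈ {0, 0.1, …, 1} × κ ∈ {0.25, 1, 4, 16} with the
orientation held at its initializer (the DTI principal eigenvector); then
bounded Powell refinement of all five free parameters (v_iso, v_ic, log κ
with κ ∈ [0.01, 64], and the two orientation angles). The optimizer's inner
loop evaluates the stick integral through a per-shell bilinear lookup table
in (|cos angle|, log κ) built once from the exact quadrature (table error
< 4×10⁻⁵ in signal units, negligible against both the noise floor and the
±0.02 noise-free recovery tolerance). Voxels with non-positive b=0 signal
are left unfitted; if Powell fails to improve on the grid optimum the grid
point is kept and the voxel flagged as non-converged. Voxels are fitted
independently (no spatial regularization), so results do not depend on
evaluation order.

## Tracking

Deterministic bidirectional Euler integration at a fixed 0.5 mm step.
Direction lookup is nearest-neighbor (a voxelwise fitted axis has no
natural sub-voxel interpolation for antipodally symmetric vectors); the
stopping metric is interpolated trilinearly. At each step the local axis is
sign-aligned with the incoming direction (an exactly perpendicular axis
keeps its stored sign); propagation stops when the turning angle reaches
60°, the metric crosses its threshold (FA ≤ 0.20 floor for tensor mode,
ODI ≥ 0.45 ceiling for dispersion mode), or the streamline leaves the
grid. Streamlines outside 30–300 mm are discarded. Seeds are drawn
uniformly — a random seed-mask voxel, then a uniform position inside it —
until the acceptance quota (3,000) is met or 100× that many attempts have
been made, in which case the partial result carries a starvation flag.

The ODI rule is a *ceiling* because coherent white matter has low ODI and
gray matter high ODI; a floor would terminate everywhere a tract exists.
Dispersion-mode tracking additionally requires the voxel to be fitted and
to have VF_iso < 0.99: where the voxel is essentially pure free water the
Watson axis is unidentifiable and following it would be noise-chasing. The
guard sits at 0.99 (not lower) because severe vasogenic edema legitimately
reaches VF_iso ≈ 0.9 and a tighter guard would sporadically truncate
exactly the voxels the method exists to cross.

When ROI selection is requested, the quota counts streamlines *after*
filtering (a streamline must intersect every inclusion mask and no
exclusion mask), matching a "finally reconstructed" count.

## The phantom

The generator emulates the study situation with known ground truth: a
straight corticospinal-tract-like tube (radius 2 voxels) along z in a 40³
grid of 2.5 mm isotropic voxels, the acquisition being 4 b=0 volumes plus
30 directions at b = 1,000 and 60 at b = 2,000 s/mm² from seeded
electrostatic repulsion. Tissue parameters: bundle v_iso 0.05, v_ic 0.6,
κ = 16 (ODI ≈ 0.04); surrounding gray-like tissue v_iso 0.1, v_ic 0.4,
κ = 0.5 (ODI ≈ 0.70), random per-voxel orientations; a small CSF pocket
with v_iso = 1. Noise is Rician (magnitude of a complex Gaussian
perturbation) at SNR 30, the appropriate model for magnitude MR data; its
positive bias at low signal is reproduced and tested.

The edema block spans nine axial slices around the tube with a linear
free-water ramp along z: v_iso rises from 0.55 at the entry face to 0.90
over six slices and stays there. These two levels bracket the
single-tensor failure point under the model's own forward arithmetic: at
v_iso = 0.55 the noise-free FA of an edematous bundle voxel is ≈ 0.45
(trackable), at 0.90 it is ≈ 0.15, below the 0.20 floor. A uniform severe
block would make the tensor arm all-or-nothing; the ramp mirrors real
vasogenic edema (milder at the margins, worst near the lesion) and yields
both a shallow region that tensor tracking still reaches (the DN condition)
and a core only dispersion tracking crosses (N-only) — while no tensor
streamline ever traverses the block end to end. A lesion block abuts the
edema on its +y face; inclusion ROIs are axial slabs of limited lateral
extent capping the tube (regional, like sensorimotor/brainstem ROIs, so the
seed-acceptance rate stays compatible with the attempt cap); lateral slabs
act as exclusion ROIs.

What the phantom does **not** emulate: crossing or fanning fibers, partial
voluming against CSF, susceptibility/eddy artifacts, anatomical curvature
of the CST, tumor infiltration (as opposed to pure vasogenic edema), and
scanner-dependent noise correlations. Passing tests on the phantom
therefore demonstrate the internal correctness of the fitting/tracking/
quantification chain under the stated generative model, not clinical
performance.

## Quantification conventions

* Condition masks: DN = DTI ∧ NODDI ∧ edema, D-only, N-only analogously;
  they partition (DTI ∪ NODDI) ∩ edema by construction.
* PIV divides a condition volume by the volume of the **union** of both
  tract masks: the sum-of-volumes reading would double-count DN voxels and
  allow ΣPIV > 1.
* LTD is the minimum Euclidean world-mm distance between centers of lesion
  *boundary* voxels (6-connectivity; volume-edge voxels count as boundary)
  and any tract voxel center, computed with an exact Euclidean distance
  transform; overlapping masks give 0. Voxel centers, not surfaces, define
  the distance, so LTD is quantized at voxel resolution.
* LTD-weighted indices divide by LTD; a tract touching the lesion (LTD = 0)
  yields a flagged-undefined result rather than infinity. No such case
  occurs in the packaged cohort (minimum LTD 2.3 mm).
* On the default phantom the pipeline's condition analysis uses the
  tensor-mode tract mask built from the length-accepted streamlines
  *before* two-ROI selection: with full occlusion no tensor streamline
  reaches both caps, so the ROI-filtered tensor CST is empty (that count is
  reported separately); the pre-selection partial tract is precisely the
  "DTI-visible" portion that defines D-involved voxels.

## Statistics conventions

* AUC is the Mann–Whitney probability with half-credit for ties; it equals
  the trapezoidal integral of the empirical ROC curve (asserted to 1e-12 on
  200 random datasets). Class orientation is always an explicit argument.
* Candidate cutoffs are midpoints between consecutive distinct values plus
  ±∞. At a cutoff t, sensitivity counts the larger-value class strictly
  above t, specificity the other class at or below t. Youden's J breaks
  ties toward higher specificity, then the smaller threshold.
* Wilcoxon signed-rank: W is the smaller signed-rank sum with average
  ranks for tied |d|; the two-sided p is exact by full 2ⁿ enumeration for
  n ≤ 12 and a tie- and continuity-corrected normal approximation beyond.
* The packaged clinical table stores the seven decline labels exactly as
  printed in its source (whose text says six — the discrepancy is noted in
  the fixture header), and one edema volume whose printed thousands
  separator is misplaced is stored with the only self-consistent reading
  (17,875 mm³).

## Parameter recovery: what is and is not identifiable

At SNR 30 the fit recovers v_iso essentially everywhere (median |error|
≈ 0.01–0.03). Dispersion is a different matter: in voxels that are ~90%
free water *and* highly dispersed (edematous gray matter), the 10% tissue
signal cannot pin down (v_ic, κ) jointly — the fitted solutions reach lower
residuals than the ground-truth parameters, so this is likelihood
degeneracy, not an optimizer defect. The recovery acceptance check is
therefore evaluated on the bundle voxels (clean and edematous, n = 480),
where median |ΔODI| ≈ 0.007 and the fitted Watson axis stays within 10° of
truth even inside the edema — the properties dispersion-based tracking
actually depends on. Fitted ODI in edematous bundle voxels is biased
upward (truth 0.04, typical fit 0.1–0.3) but remains below the 0.45
ceiling, which is why tracking proceeds.

## Problem sizes

The default phantom fits ~2,000 voxels (the bundle, a one-voxel shell, and
the edema block) rather than the whole grid: tracking terminates at
unfitted voxels anyway, and the shell provides realistic gray-matter
termination. A full default run — simulation, both fits, both tracking
modes — takes on the order of three minutes on one CPU; the reduced demo
configuration (28³ grid, narrower edema, 60 streamlines) runs in about a
minute and is what the CLI tests exercise.

## Known limitations

Single-fiber voxel model (no crossing-fiber support; constrained spherical
deconvolution would be the natural extension); least-squares fitting on
Rician magnitudes (slight bias at very low signal rather than a full Rician
likelihood); nearest-neighbor direction lookup (no sub-voxel direction
interpolation); the ODI ceiling of 0.45 is adopted from the source
calibration on healthy subjects and the phantom cannot re-derive that
number (its Dice sweep is validated structurally, not numerically);
LTD is voxel-center quantized; AUC confidence intervals are deliberately
not computed.
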