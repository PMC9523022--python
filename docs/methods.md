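# Methods

## Contact mechanics and the measurement chain

The elasticity model is the Hertz–Sneddon law for a rigid cone of
half-angle α indenting an incompressible elastic half-space:

    F(δ) = (2·tan α / π) · E/(1 − µ²) · δ²

with Poisson ratio µ = 0.5 (cells treated as incompressible) and α = 36°
by default (a common pyramidal-probe approximation). The instrument never
measures (δ, F) directly; it records cantilever deflection *d* against
piezo position *z*. The two are linked through the cantilever compliance:

    F = k·d,    δ = (z − z₀) − d,    k·d = F((z − z₀) − d)

Every stage of the package respects this coupling:

- **Generator.** Synthetic curves are produced by solving the force
  balance for *d* in closed form (a quadratic per sample), so noise-free
  curves satisfy the contact law to machine precision and are independent
  of sampling density. Baseline offset/tilt and white Gaussian deflection
  noise are added on top, in meters or (via a sensitivity) in photodiode
  volts.
- **Sensitivity.** The deflection sensitivity (m/V) is the inverse
  contact-region slope of a reference curve on the rigid dish bottom,
  located with a linear-contact detector that is exact on the sample grid.
  Processing the reference through the calibration subtraction returns
  identically zero indentation — the identity the reference-curve procedure
  relies on, asserted to 1e-12 m in the tests.
- **Baseline.** A straight line fitted to the pre-contact region is
  subtracted. The pre-contact region is first estimated by a two-segment
  line fit plus threshold crossing; after contact detection the baseline is
  refitted strictly before the detected contact (`prepare_curve`). The
  second pass matters: a 0.5 kPa cell deflects the lever by barely a
  nanometer over the first few hundred nanometers of indentation, so any
  threshold-based pass inevitably leaks early contact into the baseline
  window, tilting it by enough to corrupt shallow-window moduli tens of
  percent.
- **Contact point.** Stage one scans every candidate sample with a
  two-piece model (zero before z₀, a·(z − z₀)² after; amplitude solved in
  closed form) and refines the winner by parabolic interpolation of the
  residual profile. Stage two refines (z₀, stiffness) by nonlinear least
  squares of the full compliance-coupled force balance. The scan alone is
  biased by ~0.1 µm on soft cells because it ignores the lever's own
  compliance; the NLS model is exact for homogeneous samples and puts all
  noise in the ordinate, making the refined z₀ unbiased. Both stages are
  deterministic.
- **Window fit.** The apparent modulus over a depth window [0, δ_max] is,
  by default, a one-parameter least-squares fit of the contact law in
  deflection-vs-travel coordinates (reconstructed exactly from (δ, F) via
  s = δ + F/k), with the window cut on the noise-free travel axis at the
  travel where the model reaches δ_max, iterated once as the stiffness
  updates. The textbook linearized estimator — the origin-constrained slope
  of F against δ² — is available as `method="linear"` and is identical on
  noise-free data, but it squares a noisy abscissa that is anti-correlated
  with the ordinate and censors noise at the window edges, which biases
  soft-sample shallow windows by tens of percent; the default avoids all
  three effects. Non-positive linearized slopes are flagged, never clipped,
  and excluded from aggregation with a counted reason.

## Aggregation and statistics

Per-curve estimates (6×6 map per cell) are averaged per cell and window;
group statistics (mean, median, SD with n−1, 25th/75th percentiles under
linear interpolation — the boxplot convention) are computed over per-cell
means. Group pairs are compared with the two-sided Mann–Whitney U test:
exact null distribution when n₁+n₂ ≤ 14 and the pooled sample is tie-free,
tie-corrected normal approximation with continuity correction otherwise;
the reported U is min(U₁, U₂). Three or more groups use tie-corrected
Kruskal–Wallis with a χ² p on k−1 degrees of freedom. Significance stars
follow the convention *p<0.05, **p<0.01, ***p<0.001. No multiple-testing
correction is applied by default (per-comparison reporting); a Holm
step-down helper exists. Exactness is established in the tests against a
full permutation-enumeration oracle for every sample-size pair up to 7+7.

## Morphometry and assays

Images are binarized with Otsu's threshold by default (fixed and
percentile thresholds selectable; constant images are an explicit error).
Nuclei are counted as 8-connected components of at least 30 px (default),
replacing the manual counting such protocols traditionally use. The
effective single-cell surface area is total cell area over nucleus count;
the N/C ratio is reported per image as total nucleus area over total cell
area (algebraically identical to the ratio of per-cell effective areas). A
per-component variant matching each nucleus to its enclosing cell blob is
available behind a flag, since "mean per-cell ratio" and "ratio of totals"
differ when cell sizes vary; the per-image form is the default because it
is insensitive to touching-cell segmentation errors. Pixel areas count
fully (no subpixel boundary correction).

LDH viability is 1 − expLDH/maxLDH with maximum error
(ΔexpLDH + (expLDH/maxLDH)·ΔmaxLDH)/maxLDH (first-order propagation with
absolute-valued sensitivities). maxLDH is a tabulated input (optionally
assembled as a sum of named lysis-buffer condition means), not recomputed
from well layouts. Viability above 1 or below 0 is returned as-is with a
warning flag. MTS absorbances are divided by the control-condition mean,
making the control average exactly 1 and the statistic scale-invariant.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| spring constant k | 0.03 | N/m | soft lever nominal for cell work |
| half-angle α | 36 | deg | conical approximation of the pyramidal tip |
| Poisson µ | 0.5 | — | incompressible cell |
| depth windows | 400, 1200 | nm | cortex-dominated vs. bulk response |
| ramp length | 10 | µm | see below |
| samples per curve | 512 | — | standard force-curve resolution |
| contact position | 4 | µm | 40% pre-contact baseline |
| deflection noise | 2 | nm | realistic photodiode/thermal noise |
| cell modulus distribution | log-normal, mean 2.4 kPa, SD 1.31 kPa | — | positive, right-skewed; control-group scale |
| nucleus min size | 30 | px | speck suppression |

The deep ramp is deliberate: on a 0.5 kPa cell with 2 nm noise, the
contact point is identified by the curvature of the *deep* contact region,
and generous post-contact travel is what makes shallow-window moduli
usable. The synthetic population draws per-cell moduli log-normally
(linear-space mean/SD parametrization) with deterministic per-cell
sub-seeds (root seed + cell index), so growing a population never
reshuffles existing cells; within-cell map-point variation is exposed as a
free coefficient of variation (default 0) because published work rarely
reports it.

## Two-layer fixture

Depth-dependent stiffness is modelled as piecewise-constant modulus —
`modulus_shallow` above a transition depth, `modulus_deep` below — with the
*force* kept continuous by integrating the piecewise stiffness. This is a
verification device for depth-windowed fitting, not a claim about cell
architecture: it guarantees the sign of the (400 nm vs 1200 nm) window
contrast and provides a closed-form effective (secant) modulus to test
against. Contact detection assumes a homogeneous sample; on strongly
layered curves the NLS refinement inherits a model misfit and can settle
in local minima (an optional shallow-restricted refinement pass mitigates
but does not eliminate this), so layered-sample tests pin the contact point
to generator truth and the limitation is documented here.

## What the generator does and does not emulate

Emulated: compliance coupling, baseline offset/tilt, white deflection
noise, volt-unit recording, grid force maps, log-normal cell-to-cell
spread, rigid-reference curves, disk-shaped cell/nucleus masks with exact
pixel areas, plate tables with known condition means. Not emulated:
hydrodynamic drag, viscoelastic creep, adhesion on retract, thermal drift,
correlated (1/f) noise, microscope point-spread functions, touching or
irregular cells, uneven illumination. Passing tests therefore demonstrate
correctness of the estimation chain under the stated noise model, not
robustness to every instrument artifact; on real data the contact-point
and baseline stages are the components most exposed to the unmodelled
effects.

## Numerical choices and degenerate inputs

Deterministic throughout: the contact scan is exhaustive, the NLS stages
use fixed tolerances (1e-15) and data-derived starting points, and the
window fit is a bounded scalar minimization on log-stiffness (xatol 1e-12;
agreement with the closed-form slope on noise-free data is at the
optimizer's ~1e-7 relative tolerance, far below the 0.1% round-trip
tolerance asserted in tests). Flat curves, all-contact curves, windows with
fewer than 10 samples, empty masks, zero nuclei, zero control means, and
non-positive maxLDH are explicit errors, not silent values. Curves that
fail inside the batch pipeline are logged and counted (`n_failed`), and
flagged fits are reported both raw and filtered, since how failed fits
enter the per-group accounting is a reporting choice the user should see.

## Problem sizes

The test suite and the acceptance script run the study design at 60 cells
per group with 36 curves per cell (512 samples each) and use 200-replicate
Monte-Carlo blocks for recovery medians and type-I calibration; these sizes
reproduce the study-scale statistics while keeping a full run around a
minute on one CPU.
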