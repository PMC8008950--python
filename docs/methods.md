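# Methods

## Scope

The package turns pressure-myograph recordings of cannulated artery
segments into the standard passive-mechanics read-outs — in-vivo axial
stretch (IVS), biaxial Cauchy stress–stretch curves, tangent moduli — and
runs the cohort-level comparisons. A forward simulator provides
ground-truth recordings so that every stage can be validated against
closed-form answers; it stands in for animal experiments, for which no
public raw data exist in this protocol's format.

## Simulator model

The wall is an incompressible thin-walled (membrane) cylinder with a
four-fiber-family strain energy per unit reference volume

    W = c/2 (I1 − 3) + Σ_k c1_k/(4 c2_k) [exp(c2_k (I4_k − 1)²) − 1],

I4_k = λ_θ² cos²α_k + λ_z² sin²α_k, with α measured from the
circumferential axis: a circumferential family (α = 0), an axial family
(α = π/2), and a symmetric ±α diagonal pair. With λ_r = 1/(λ_θ λ_z) and
zero radial stress the Cauchy stresses are σ_θ = λ_θ ∂Ŵ/∂λ_θ and
σ_z = λ_z ∂Ŵ/∂λ_z. Fiber stress is kept smooth through compression (no
tension-only switch): the usual convention for phenomenological fits to
inflation data, and necessary here because the activation kink at
I4 = 1 otherwise prevents windowed tangent-modulus estimates from
converging to the analytic derivative near λ_θ = 1 at any sampling
density.

Equilibrium ties pressure to geometry through the Laplace relation
P = σ_θ h / r_i, with (r_i, h) given in closed form by incompressibility
and the mid-wall stretch convention. Each simulated point solves this
relation for λ_θ by a bracketed scan plus bisection, vectorized over
whole (pressure × stretch) grids; the emitted residual is at machine
precision (checked < 1e-8 relative). The instrument observables are the
outer diameter 2 r_o and the transducer force

    f = σ_z π h (2 r_i + h) − P π r_i²

(total axial wall load minus the pressure-on-cap term), with additive
Gaussian noise on OD and force only — pressure and axial stretch are
servo-controlled and treated as exact.

### Default parameters

| parameter | value | rationale |
|---|---|---|
| unloaded OD / H | 400 / 40 μm | mouse common-carotid scale (380 μm cannulas) |
| c (matrix) | 10 kPa | elastin-dominated low-stretch response |
| circumferential family (c1, c2) | 8 kPa, 1.0 | loaded OD plateau ~530 μm at 140 mmHg |
| axial family (c1, c2) | 3 kPa, 0.15 | axial force of a few mN near the IVS |
| diagonal pair (c1, c2) | 2 kPa, 1.5 | sharp, near-common force–length crossover |
| diagonal angle α | calibrated, ≈ 30–35° | sets the ground-truth IVS (below) |
| noise SD (OD, force) | 2 μm, 0.05 mN | video-edge and transducer resolution scale |

The resulting vessel inflates from ~290 to ~535 μm OD over 0–140 mmHg at
its IVS, carries ~100–300 kPa hoop stress in the physiological range, and
its three force–length curves mutually cross within ~0.008 stretch — the
near-common intersection the protocol exploits.

### Ground-truth IVS and calibration

The ground-truth IVS is defined operationally, not as a model parameter:
the argmin over a fine λ_z grid (step 1e-4, coarse-to-fine) of the
relative across-pressure spread (max−min)/mean of noiseless transducer
force. Calibration to a setpoint (1.85 control-like, 1.79 stiff-like)
bisects the **diagonal-fiber angle**. The angle is the right knob because
a purely axial fiber contributes a pressure-independent force term that
cancels between force–length curves at different pressures — axial
stiffness alone cannot move the crossover. A stiffened phenotype is
produced by multiplying the collagen-like (circumferential + diagonal)
c1 values; this left-shifts the circumferential stress–stretch curve and
raises the tangent modulus pointwise, with the angle re-calibrated to the
group's IVS setpoint. Biological variability enters as Gaussian jitter of
the IVS setpoint — each sample draws its own setpoint (clipped to the
calibratable band 1.67–2.05) and re-calibrates its own angle, because a
linearized angle jitter would right-skew the IVS distribution (IVS is a
convex function of the angle) — plus 3% lognormal jitter of the unloaded
geometry.

## Analysis pipeline

* **Loaded geometry.** r_i = sqrt(r_o² − (R_o² − R_i²)/λ_z); λ_θ uses the
  mid-wall radius ratio (r_i + h/2)/(R_i + H/2) by default, with the
  inner-wall ratio available by configuration. Wall-volume conservation
  holds to 1e-10 relative for every output by construction; measured
  diameters below the incompressibility bound raise a degenerate-geometry
  error naming the sample and point.
* **IVS.** Force–length curves are piecewise-linearly interpolated (a
  spline would be fragile at the 10%-increment grid density) and each
  pair's crossing is the zero of the difference. With several zeros, the
  physically expected upward crossings (higher-pressure curve passing
  from below to above) are preferred, and the **median** upward zero is
  taken: noise wiggles the difference into a cluster of zeros around the
  true crossover, and the median is the symmetric, bias-free choice
  (closest-to-midpoint selection showed a measurable −0.003 bias in
  500-replicate Monte Carlo). The sample IVS is the arithmetic mean of
  all defined pairwise crossings; the max deviation of crossings from
  that mean is kept as a diagnostic, and fewer than two usable crossings
  among ≥3 curves flags the result low-confidence.
* **QC.** On the pressure sweep recorded at the IVS, samples whose axial
  force deviates from the across-pressure mean by more than the 25%
  threshold are excluded. Steps below 20 mmHg are left out of the spread
  statistic — near zero pressure the axial force can approach zero and
  the relative deviation becomes unstable; the exclusion rule's intent is
  pressure-dependence at working pressures. A non-positive mean force
  makes the statistic undefined and quarantines the sample.
* **Stresses.** Mean-wall Laplace forms (README formulas); mmHg→kPa at
  0.133322. σ_θ = P r_i/h is the exact through-thickness mean of the hoop
  stress, and agrees with the thick-wall Lamé mid-radius stress within
  O(h/r_i). A geometry-unit switch on the axial formula keeps stresses
  independent of whether geometry is carried in μm or mm.
* **Tangent modulus.** Default: slope of a local least-squares line over
  a sliding 5-point window centered on each interior point, one-sided at
  the ends; central differences selectable. Curves shorter than the
  window shrink it with an explicit warning. On densely sampled noiseless
  simulator curves (0.5-mmHg sweep steps; 0.01 stretch steps) the
  windowed estimate matches the analytic derivative within 2% on interior
  points; at the protocol's coarse grids the discretization itself, not
  the formula, limits accuracy — which is why the closed-form agreement
  checks use dense sampling.
* **Statistics.** Group curves are summarized pointwise on the matched
  pressure (or stretch) grid — mean with SE for circumferential panels
  and SD for axial panels, following the field's presentation convention.
  Two-way ANOVA with interaction (group × grid point, statsmodels OLS
  with Type-II sums of squares, equal to the classic cell-means
  computation in the balanced case) compares curves; pressure-matched
  points within one artery are treated as independent observations, i.e.
  no subject random effect. Mann–Whitney tests on IVS are exact by full
  enumeration of rank splits (mid-ranks for ties) whenever m+n ≤ 16, else
  a normal approximation with tie and continuity corrections; enumeration
  with mid-ranks also yields p = 1 for identical samples, which the
  approximation's continuity correction would not. Holm–Šidák step-down
  adjustment (via statsmodels, checked against the hand formula) handles
  post-test families. Stars: * P<0.05, ** P<0.01, *** P<0.001.

## Problem sizes

Monte-Carlo checks use: 200 replicate cohorts of 7 samples per setpoint
for IVS recovery (bias vs 2 SE); 500 replicates for the ANOVA null
calibration; 40 replicates per effect size (multipliers 1.0, 1.02, 1.05,
2.0 at n = 7 vs 6) for the power curve; 1000 replicates for the
noise-expectation check. These sizes give Monte-Carlo errors comfortably
below the quantities being tested while keeping any single run to a
few minutes at most.

## What the simulator does and does not emulate

Emulated: strain-stiffening pressure–diameter behavior, force–stretch
curves that nearly (not exactly) share a crossing, instrument noise on OD
and force, between-animal spread of IVS and geometry, and a
collagen-stiffened phenotype. Not emulated: preconditioning hysteresis
and reference-state drift (the real protocol's 15-min hold at stretch 1.7
and 100 mmHg changes the reference state of living tissue), smooth-muscle
tone, viscoelasticity, residual stress (opening angle), and axial
force-transducer drift. Passing tests therefore demonstrate correctness
of the analysis chain under the stated error model, not robustness to
every artifact of living tissue.

## Numerical choices

Equilibrium scan bracket λ_θ ∈ [max(0.3, validity floor), 4] over 160
points with 70 bisection iterations (machine precision; the outermost
sign change selects the stable strain-stiffening branch). Oracle grid
coarse-to-fine: 1e-3 everywhere, then 1e-4 in a ±3e-3 window around the
coarse minimum. Calibration bisects the angle in [27°, 42°] to a 5e-4
IVS tolerance. Fiber exponentials are capped at exp(700) so unphysical
scan points stay finite. CSV output uses pandas defaults (RFC-4180,
UTF-8, '.' decimal) with units embedded in column names.

## Known limitations

* The curve-wise two-way ANOVA ignores within-artery correlation; with
  real between-animal variance its type-I error is inflated (we measured
  ~0.5 at nominal 0.05 with the generator's default biological jitter).
  The package keeps the convention because it is the field's, documents
  it here, and runs its calibration/power checks in the measurement-noise
  regime where the test is exact. A mixed model would be the principled
  alternative and is deliberately out of scope.
* The IVS estimator inherits an O(1e-4) interpolation bias from the
  10%-increment grid; it is far below the between-animal SD (~0.05) but
  visible in large noiseless ensembles.
* Thin-wall stress formulas are mean-wall quantities; transmural
  gradients (Lamé-scale, O(h/r) ≈ 10%) are not resolved.
* The exclusion rule's pressure floor (20 mmHg) and the mid-wall stretch
  convention are configuration defaults where the protocol itself is
  silent; both alternatives are implemented and switchable.
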