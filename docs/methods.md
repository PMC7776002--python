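# Methods

## Signal model and coil-tensor algebra

A voxel at position r experiences the effective gradient `g_eff = L(r) g`
rather than the imposed `g`; equivalently the diffusion weighting is the
effective b-matrix `B_eff = L B Lᵀ` with `b_eff = trace(B_eff)`.  `L` is
dimensionless, close to the identity, and is accepted either directly or as
the deviation `ΔL = L − I` (scalar, diagonal, or full 3×3).  All fiber
directions are antipodally symmetric; reported directions are canonicalized
to the hemisphere whose first nonzero component is positive.  Effective
directions are computed as the principal eigenvector of `B_eff`, which
coincides with `Lg/‖Lg‖` for rank-1 imposed b-matrices and also covers
b-matrices read from files without stored gradient vectors.

The scalar sensitivity model `ΔS = exp(−b L² D) − exp(−b D)`, `L = 1 + ΔL`,
quantifies how much a mono-exponential signal at diffusivity `D` is
perturbed; its maximizer `b* = log(L²)/(D (L² − 1))` falls between 1500 and
2000 s/mm² for `D = 0.7·10⁻³ mm²/s` and ΔL between −15% and −5%, which is
why the artifact is *not* confined to high b-values.

## Deconvolution

**dRL.** The FOD is a vector of amplitudes on a fixed dictionary of n = 300
electrostatically optimized hemisphere directions.  The response is an
axially symmetric tensor (λ = 1.7·10⁻³, β = 0.2·10⁻³ mm²/s by default) and
`H_ij = exp(−b_i(λcos²θ_ij + β(1−cos²θ_ij)))`.  Signals are normalized by
the mean b=0 signal; b=0 rows are excluded from H (they would be
uninformative rows of ones).  Fifty multiplicative updates
`f ← f (1 + u (HᵀS − HᵀHf)/(HᵀHf + ε))` are run from a uniform positive
start with ε = 10⁻¹⁰; no convergence test is applied.  The damping vector is
`u_j = f_j^ν / (f_j^ν + η^ν)` with ν = 8 and η = 4% of the current FOD
maximum, recomputed each iteration: large lobes update freely, small ones
are frozen, suppressing spurious peaks.  Both parameters are configurable
and `u ≡ 1` (undamped Richardson–Lucy) is available; at the study
conditions the angular-error medians are insensitive to these choices
(sweeps over ν, η, undamped, and 10–200 iterations move medians by well
under 0.1°).  With 0 ≤ u ≤ 1 the update can be written
`f((1−u)HᵀHf + u HᵀS)/(HᵀHf)`, hence non-negativity is preserved exactly.

**dRL-mod** rebuilds H per voxel from `b_i,eff` and the angles to `ĝ_i,eff`;
with an identity coil it reduces exactly to the uniform H, and the volume
driver delegates an all-identity coil field to the uniform fast path so the
two modes agree bit-for-bit in that case.

**CSD.** Signals on a shell are fitted with real even SH up to order 8 (45
coefficients; basis orthonormal, m<0 ↦ √2·Im Y, m>0 ↦ √2·Re Y) and
deconvolved by the zonal projection `r_l` of the tensor response, obtained
by 64-node Gauss–Legendre quadrature over cosθ; convolution follows
Funk–Hecke, `s_lm = √(4π/(2l+1)) r_l f_lm`.  Degrees the kernel does not
transmit (|r_l| ≈ 0, e.g. an isotropic response) are pinned at zero — the
data carry no information about them and the flat solution is the
maximum-entropy choice.  Non-negativity is imposed iteratively: amplitudes
on the 300-direction constraint mesh (the dRL dictionary, for comparability)
below τ = 10% of the current iterate's mean positive amplitude select
penalty rows driven to zero with weight λ; the augmented normal equations
are re-solved until the constraint set stabilizes (≤ 50 iterations).  The
unit regularization factor is normalized to the strongly-constrained
regime — the penalty block is weighted an order of magnitude above norm
parity with the data block — which suppresses negative lobes to the floor
the order-8 truncation permits without distorting the main lobe.  That floor
is not zero: the 45 coefficients are uniquely determined by band-limited
data, so non-negativity can only be traded against data misfit, and residual
Gibbs ringing of a few tenths of a percent of the peak persists for sharp
kernels at any λ.  The initial estimate is an unconstrained order-4 fit
zero-padded to order 8; with fewer than 45 directions the order is reduced
with a warning.

**CSD-mod** replaces the fit directions by `ĝ_i,eff` and rebuilds `r_l` at
the shell-averaged `b̄_eff = (1/m) Σ b_i,eff`.  The correction is partial by
construction: the per-direction spread of `b_i,eff` (several hundred s/mm²
under a −13…−14% deviation) is collapsed to its mean, and the response is
rescaled, not rotated per direction.  It removes most of the orientation
bias for anisotropic deviations but can be neutral or slightly adverse in
corner cases (e.g. a deviation purely along the fiber), consistent with the
implementation-dependent behavior reported for this heuristic.

## Peak extraction and metrics

Dictionary FODs are fitted with order-8 SH (least squares on the 300
directions) and maxima are located by evaluating on a subdivision-4
icosphere (2562 vertices ≈ 1281 unique orientations), taking strict mesh
local maxima, and refining each candidate by Newton ascent in the local
tangent plane (finite-difference gradient/Hessian, backtracking, gradient
norm < 10⁻⁶).  Peaks closer than 5° are merged and peaks below 10% of the
largest amplitude are discarded.  Angular deviation is `arccos|a·b|` in
[0°, 90°].  With several ground-truth fibers, peaks are assigned
one-to-one by minimum-total-angle matching; unmatched truths are flagged as
detection failures.  Amplitude normalization divides by the method-specific
mean primary-peak amplitude from single fibers without deviation.

## Monte Carlo design

Scenarios: (I) single fibers along x/y/z at b = 3000 s/mm², 60 hemisphere
directions, ΔL = diag(−0.13, −0.14, −0.05), SNR 30; (II) the same at
b = 2000 and 1000 s/mm² plus the opposite-sign deviation for the x fiber;
(III) a y fiber with 90 directions and single-axis deviations of −10%/−20%;
(IV) SNR ∈ {10…50}; (V) crossings at 90°/75°/60°/45° with fractions
[0.5, 0.5] and ΔL = ±0.15·I.  Default 10⁴ Rician replicates (σ = S0/SNR,
S0 = 1); noise is also applied to the b=0 volume (flag-controlled), and
signals are renormalized by the noisy b=0 mean as a pipeline would.  Every
method and condition of a cell shares the same Gaussian draws (paired
design), and seeding uses one master seed with per-cell substreams, so
results are reproducible and scheduling-independent.  The acceptance script
uses the full 10⁴ replicates; the test suite uses 2·10³, at which medians
carry a Monte Carlo standard error of roughly 0.01–0.02°.

The phantom replaces a tensor field estimated from real data with a
parametric stand-in: a grid (default 20×20×10) with a smoothly rotating
single-fiber orientation field and a diagonal coil deviation growing
quadratically with normalized distance from the isocenter to
(−15%, −10%, −5%) per axis at the corners.  The per-axis gains are
deliberately anisotropic: an isotropic diagonal deviation only rescales
b-values and cannot tilt effective directions, so it would not exercise the
orientation bias the phantom is meant to probe.  The phantom reproduces the
reported spatial structure — noiseless uniform-fit deviations up to ~3°
rank-correlated (Spearman ρ ≈ 0.9) with ‖ΔL‖_F, corrected fits < 0.1°.

What the generator does *not* emulate: real fiber-orientation and
crossing-geometry distributions, spatially varying S0/T2, partial volume
with gray matter and CSF, off-diagonal coil-tensor terms, motion, eddy
currents and susceptibility distortions.  Passing tests therefore show that
the estimators behave correctly under the stated tensor-plus-Rician model,
not that in vivo accuracy is reproduced.

## Accuracy expectations and known limitations

The *mechanisms* of the reference study reproduce cleanly here: deviations
raise the uniform-fit medians for fibers along strongly deviated axes and
broaden their distributions; the corrected dRL restores the no-deviation
baseline (and recovers noiseless fibers to < 1° for deviations up to ±20%);
CSD is comparatively robust; phantom deviation maps track ‖ΔL‖_F.  The
*absolute* medians of this implementation are smaller than previously
printed ones for the dRL variants (e.g. ~0.75° rather than 1.26° for the
x-fiber deviation cell; the −20%-along-fiber cell rises by ×1.4 rather than
×1.9).  Two observations bound the discrepancy: an independent weighted
log-linear tensor fit on identical noisy replicates has a 0.78° median
angular error at the same conditions, so sub-0.8° deconvolution medians are
physically plausible and the noise scale is correct; and the reported values
stem from a closed-source implementation whose damping/regularization
settings (to which, per its authors, the results are sensitive) are not
public.  Parameter sweeps here (damping, iterations, constraint weights)
move medians by < 0.1°, so the gap is structural, not a tuning residue; the
CSD median (~0.77°) matches the reported ~0.8°.

Numerical details: direction sets are L-BFGS-minimized antipodal Coulomb
energies, shipped as fixtures for n = 60/90/300 and regenerated
deterministically otherwise; SH bases use scipy's spherical harmonics; the
zero-b-matrix direction is undefined and flagged; all-zero signals yield a
flagged empty FOD; degenerate peak extraction (isotropic FOD) returns an
empty peak set rather than an arbitrary direction.  Out of scope: in vivo
preprocessing, data-calibrated or multi-tissue responses, tractography and
connectivity analysis.
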