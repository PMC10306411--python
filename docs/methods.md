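# Methods

## Signal model and conventions

All analysis operates on difference scattering curves ΔS(q) sampled on a
strictly increasing q-grid (Å⁻¹) and time delays in ps. Projections and
inner products use ΔS itself; the qΔS scaling common in figures is a
display convention only and never enters the analysis vectors. The forward
model is

ΔS(q, t) = (1/R)·Σ_k f_k(t)·SADS_k(q) + ΔT(t)·(∂S/∂T)ρ + Δρ(t)·(∂S/∂ρ)T,

with R the solvent:solute number ratio (solute signals are reported per
solvent molecule), f_k the molar fraction of species k, and SADS_k the
species-associated difference curve including the solvation-cage term.

## Projection (PEPC)

Each time-delay column is a vector in q-space. Given trivial components
T = [trv_1 … trv_m] the per-delay weights solve min_w ‖x − T w‖ via an SVD
least-squares solve with relative singular-value cutoff 1e-10; on rank
deficiency the minimum-norm solution is reported so weights are
deterministic while the residual — which depends only on span(T) — is
unique. The solve is unweighted (plain dot-product geometry); a
σ-weighted variant exists in the hydrodynamics module where weighting has
a statistical meaning, but the projection step follows the geometric
definition. An independent cross-check (`orthonormal_projection_oracle`)
computes the same residual by modified Gram–Schmidt with one
re-orthogonalization pass and sequential subtraction; the two routes are
compared in the tests on random instances including rank-deficient sets.

Consequences used throughout: the residual is orthogonal to every trivial
component; projection is idempotent and linear; the residual is invariant
under invertible recombination of the trivial set; and two datasets
differing only in the trivial components' time profiles (e.g. ΔT(t),
Δρ(t)) give identical residuals — the removed components' kinetics is
eliminated exactly, while every species fraction outside the span
survives (at the price of each SADS being distorted to its perpendicular
component, see below).

## SVD, rank selection and global fitting

The economy SVD is sign-fixed by making the largest-magnitude element of
each left singular vector positive. Significance of component i is scored
by the lag-1 autocorrelation a(v) = Σ v_j v_{j+1} / Σ v_j² of both its
singular vectors (near 1 for smooth signal, near 0 for white noise) and by
the singular-value ratio sv_i/sv_1. The selected rank is the longest
prefix with both autocorrelations > 0.6 and ratio > 1e-3; both thresholds
are configurable and an explicit override wins. The formula and the
defaults are conventional choices — different groups use slightly
different diagnostics — and the tests exercise them against constructed
ranks and pure-noise matrices.

The k significant RSVs are fitted simultaneously with Σ_j A_ij·h(t; τ_j),
where h is the causal exponential convolved with a Gaussian IRF of FWHM w
(σ = w/√(8 ln 2)):

h(t) = ½·exp(σ²/2τ² − (t−t0)/τ)·erfc(σ/(τ√2) − (t−t0)/(σ√2)),

evaluated through the scaled complement erfcx where the direct exponent
would overflow, so the expression is stable over µs-wide log grids;
τ = ∞ degenerates to the IRF-broadened step and w = 0 to the sharp
exponential. The fit is a variable projection: for trial τ (optimized in
log10-space, bounds [0.1·Δt_min, 10·t_max]) the amplitudes are eliminated
by a linear solve, leaving n_exp nonlinear parameters. Five deterministic
log-shifted starting vectors are tried; the best final cost wins, ties
broken by the lexicographically smallest τ vector. t0 and the IRF width
are fixed by default (fitting t0 is opt-in); per-RSV constant offsets and
singular-value weighting are available but off by default. Standard
errors come from the Gauss–Newton covariance of the profiled objective;
they describe the local quadratic approximation and inherit its usual
caveats. The whole fit contains no random numbers and is bit-reproducible.

## Kinetic models and SADS extraction

Sequential chains A₁→A₂→…→ground use Bateman closed forms with every
exponential mode replaced by its IRF-convolved counterpart; arbitrary
first-order networks are eigendecomposed with per-mode convolution. Rates
repeated within 1e-9 relative (the non-diagonalizable limit) fall back to
a matrix-exponential propagation convolved with the IRF by 61-node
Gauss–Hermite quadrature. Fractions are clipped to [0, 1] only for
sub-1e-6 rounding excursions; larger violations raise.

Kinetics-constrained analysis solves ΔS_PEPC ≈ (1/R)·SADS·Cᵀ by least
squares over delays. When a rank is supplied the data are first replaced
by their rank-k truncation, making each extracted SADS exactly a linear
combination of the retained LSVs. An ill-conditioned concentration matrix
(condition number > 1e8) raises with the condition number reported rather
than silently regularizing: indistinguishable kinetics is a modeling
problem the user must see.

## SADS distortion and correction

Removing span(T) also removes the in-span part of every species curve:
the extracted SADS is SADS_⊥ = SADS − Σ_i d_i·trv_i with d the projection
coefficients (Gram solve, same machinery as the projection step). For a
candidate true curve the correction SADS_⊥ + Σ_i α_i·trv_i is fitted to
the candidate by *linear* least squares — α is never a free nonlinear
parameter, so testing a candidate structure costs one analytic solve and
the number of independent structural parameters is unchanged. χ² is the
(optionally σ-weighted) residual sum of squares over dof = n_q − m. Only
a candidate whose out-of-span component matches the data can reach small
χ², which is what makes the ranking discriminate structures even though
the in-span part is free.

The toy Debye calculator uses q-independent scattering factors (f ≈ Z);
Cromer–Mann form factors, DFT structures and MD-derived cage terms are
out of scope — cage contributions can be supplied as curves or as the
parameterized damped sinusoid A·exp(−q²w²)·sinc(q r₀).

## Hydrodynamics

After subtracting the solute-related term built from the corrected SADS
and the model concentrations, ΔT(t) and Δρ(t) come from a per-delay
linear solve on the one or two solvent differentials with no coupling
across delays. The condition number is computed on the column-normalized
basis so it measures geometry (the angle between the differentials), not
amplitudes; values above 100 set an ill-conditioning flag. For water-like
solvents, whose two differentials are nearly indistinguishable in shape,
the `temperature_only` mode fits a single combined amplitude — the
standard treatment for aqueous data. Trace units follow the basis curves
(kelvin per unit of (∂S/∂T)ρ, etc.) and are carried as metadata only.

## Synthetic data

The simulator assembles the forward model from: IRF-convolved first-order
kinetics; species curves from toy structures via the Debye equation (or
explicit curves); solvent differentials built from sums of Gaussians in q
with the pair's cosine similarity set *exactly* — 0.9999 in `water_like`
mode (nearly indistinguishable shapes, condition number ≈ 141, which
correctly trips the >100 ill-conditioning flag) and 0.2 in `distinct`
mode; and ΔT/Δρ profiles composed of an IRF-limited step plus a slower
exponential rise (thermalization; delayed rise for density). Noise is
additive i.i.d. Gaussian, seeded; "5% noise" means σ = 0.05 × the RMS of
the noiseless matrix (element-wise relative noise would diverge at zero
crossings). A per-q amplitude curve (e.g. 1/q) is supported.

Default grids: q ∈ [0.3, 9.0] Å⁻¹ with 300 points, 60 log-spaced positive
delays plus four negative reference delays; both configurable — typical
liquidography ranges, since no canonical grid exists.

The gold-trimer-like scenario uses three sequential species with
τ = 1.7 ps / 1000 ps / 114 000 ps and a 0.48 ps IRF, toy Au-chain
structures, R = 100, and a species-curve amplitude giving a solute-related
signal about twice the heating signal at early delays — representative of
heavy-atom solutes, whose strong difference features are the favorable
case the technique targets. The iodoform-like scenario has two
known-pathway species plus one hidden isomer; its trivial set (two solvent
differentials + two known species curves) deliberately omits the hidden
species, and `calibrate_hidden_scale` pins the hidden curve's out-of-span
RMS at a chosen multiple of the noise for power studies.

What the simulator does *not* emulate: experimentally calibrated solvent
differentials, q-dependent form factors, detector artifacts (e.g. the
horizontal-stripe artifacts of real detectors), delay-dependent noise
correlations, and non-exponential kinetics. Passing tests therefore
demonstrate the correctness of the algebra and estimators under the
stated model, not robustness to every pathology of real beamline data.

## Null-hypothesis residual test

The statistic is ‖ΔS_PEPC‖_F/‖ΔS‖_F compared against factor × noise
floor, the floor estimated from the negative-delay (reference) columns —
which contain no signal by construction — or, absent those, from the σ
matrix. The default factor 3 is this package's operationalization of "a
significant amplitude remains" (no quantitative criterion is standard)
and is configurable; a 1e-12 absolute floor keeps exact-arithmetic data
inside the span from tripping the test. Per-delay residual norms are
reported so the time course of any hidden species is visible, and the
first residual RSV can be compared directly with candidate concentration
profiles.

## Numerical choices and limitations

- Least squares everywhere via SVD-based solvers with explicit cutoffs;
  no iterative refinement is needed at these sizes.
- Grid alignment is linear interpolation onto the first item's grid
  restricted to the common overlap; higher-order schemes were rejected to
  keep alignment monotonicity-preserving and easy to verify.
- Text I/O emits 17 significant digits so write→read is exact for float64.
- The global fit can, like any multiexponential fit, merge constants that
  the delay grid cannot separate (ratios ≲ 3 at realistic noise); the
  reported covariance flags this through large correlated errors but the
  fit will not refuse.
- Structure refinement loops (optimizing atomic coordinates against the
  corrected SADS) are intentionally not shipped; the analytic α-solve is
  designed to sit inside such an outer optimizer.
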