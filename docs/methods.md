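# Methods

## Model and assumptions

The package solves the continuous-wave and time-domain diffusion
approximation to radiative transfer in a layered cylinder.  Assumptions
inherited from that approximation: scattering dominates absorption
(μs′ ≫ μa), source–detector separations exceed a transport mean free path
(ρ ≳ 0.5 cm for tissue-like media), and the incident beam is replaced by an
isotropic point source at depth z₀ = 1/μs′₁ on the axis.  All layers share
one refractive index (mixed internal indices are rejected: the interface
conditions used — continuity of Φ and of D ∂Φ/∂z — are only valid for
matched indices).  Units are fixed: lengths cm, coefficients cm⁻¹, time ns,
c₀ = 29.9792458 cm/ns.

The boundary coefficient A is computed by numerical quadrature of the
unpolarized Fresnel reflectance moments (R_φ, R_j, then
A = (1+R_eff)/(1−R_eff)); it can be overridden (`A_override`) to pin a
literature value.  The computed A(1.4) ≈ 2.9485.

## Green's-function assembly

Per transverse frequency s and Laplace variable s̄, each layer has
α_k = sqrt((μa_k + s̄/c)/D_k + s²) (principal square root, Re α > 0).  The
two-point boundary-value problem is solved by a reflection-coefficient
sweep from the bottom extrapolated boundary upward:

    ρ_N    = −exp(−2 α_N z_b,bot)
    ρ_k    = (Δβ + Σβ x) / (Σβ + Δβ x),   x = ρ_{k+1} E_{k+1}²,
             Δβ = β_k − β_{k+1},  Σβ = β_k + β_{k+1},
             β = D α,  E_k = exp(−α_k l_k)

after which the top-layer amplitudes follow from the source terms and the
top boundary condition.  Every stored exponential has a non-positive real
exponent, so the construction cannot overflow; exponentials that underflow
evaluate to exactly 0 (the physically correct limit).  This recursion is
algebraically identical to the explicit topmost/bottommost layer
expressions one obtains by eliminating the interior amplitudes, and is
validated against the single-slab closed form at 1e-13 relative.

Interior layers fall out of the same sweep; only the top and bottom layers
are exposed publicly (reflectance and transmittance are the measured
quantities).  Fluence at depths strictly inside the medium is rejected
unless `allow_interior=True`, which admits depths within the top or bottom
layer — needed to register against Monte Carlo depth bins.

## Hankel summation and truncation

The finite inverse Hankel transform sums over precomputed zeros of J₀
(McMahon 4-term asymptotic start + Newton polish at the target precision;
tables cached on disk as plain text keyed by (n_max, precision_bits), with
the 1/J₁² weights stored alongside).  The dynamic stopping rule terminates
once the last 10 consecutive terms each fall below rel_tol × |partial sum|
(default rel_tol 1e-12, n_min 50, n_max 50,000): the J₀ factor passes
through zeros, so single-term tests would stop spuriously.  Steady-state
values whose magnitude is below the cancellation noise floor can come out
slightly negative; they are clamped to 0 and flagged, never hidden.

Convergence is governed by the decay scale exp(−s·z₀) of the source term
when the detector sits at z = 0, so the required root count grows with
μs′₁ (z₀ = 1/μs′₁), with the radius (denser root lattice), and near z ≈ z₀
— and is nearly independent of deeper-layer properties.

## Fast reflectance approximation

For z = 0 and μs′₁ > 2 cm⁻¹ the source term and its top-boundary image are
removed from the Hankel sum and added back as the closed-form dipole

    [exp(−μeff r₁)/r₁ − exp(−μeff r₂)/r₂] / (4π D₁),
    r₁ = sqrt(ρ² + z₀²),  r₂ = sqrt(ρ² + (z₀ + 2 z_b)²),

leaving a residual (computed in closed form, no cancellation) that decays
on the exp(−2 α l₁) scale instead of exp(−α z₀): at μs′ = 80 cm⁻¹ the
residual converges with ≳ 100× fewer terms.  Outside the validity domain
the routine warns and falls back to the exact sum.  Grouping the image term
with the source (rather than leaving it in the residual) is this package's
choice; with the source term alone the residual still decays on the
z₀ + 2z_b scale and the speedup is only ~5×.

## Inverse Laplace transform

Hyperbola s̄(w) = μ_c (1 + sin(iw − φ)), midpoint rule with step h,
`N_evals` nodes on the upper half (the conjugate half is folded in as twice
the real part; `N_evals` therefore counts actual transform evaluations, the
unit in which the evaluation-count-vs-dynamic-range calibration of
`choose_N` — 4 evaluations per decade — is expressed).  The parameters
(μ_c, φ, h) are chosen per (N, t₁, Λ = t₂/t₁) by a deterministic
Nelder-Mead balance of four error exponents:

* upper/lower aliasing: strip shifts limited by the contour collapsing onto
  the negative real axis (where the kernel's poles sit) and by opening into
  the right half plane, with the e^{Re s̄ t₂} growth factor at the shifted
  waist;
* truncation of the parameter line at |w| = N h, evaluated at
  max(t₁, t₂/20) in double precision and at t₁ in extended precision — a
  single shared contour cannot serve the earliest twentieth of a very wide
  double-precision window, and that trade is accepted rather than inflating
  N (extended precision has the exponent headroom to serve the full
  window);
* the roundoff floor log(eps) + max summand magnitude of the working
  precision.

The optimization credits the transform's own decay along the contour —
for the diffusion kernel exp(−r·Re sqrt((μa + s̄/c)/D)) with r the closest
query distance and the slowest-attenuating layer — which is what makes very
wide windows (Λ up to several thousand) affordable at N ≈ 20.  When
`fluence_td` builds its own window it pads 25% below the earliest requested
time, because midpoint-rule accuracy rolls off exactly at the window edge;
an explicit `t_window` is honored as given.

For extended precision the nodes and weights are regenerated in mpmath
arithmetic from the stored (φ, h, μ_c): double-rounded nodes would put an
eps_double-relative floor under the reconstruction.  For the same reason
geometry sums such as z₀ + z_b are formed inside the arithmetic context,
and μa·c is never pre-rounded in the closed-form reference.  Nodes are
independent; the reduction order is fixed, so serial and any hypothetical
parallel evaluation give bit-identical results.  Everything here runs
serially (one core).

## Precision contexts

`double` (numpy, vectorized over roots), `quad` (113-bit mpmath) and `oct`
(237-bit mpmath) share one kernel implementation through a small context
interface.  Extended-precision J₀/J₁ use an in-package evaluator — Taylor
series with e^{2x} guard digits below x ≈ 0.37·bits, Hankel asymptotic
expansion above (optimal-truncation error ≲ 2^{−bits}) — because generic
multiprecision Bessel routines are orders of magnitude too slow for
50,000-root reference sums; the evaluator is validated against
mpmath.besselj.

## Monte Carlo validator

Weighted photon walk in a laterally infinite layer stack: exponential step
sampling against μt = μa + μs with μs = μs′/(1−g), Henyey–Greenstein
deflections (g = 0.8 in validations), partial absorption w·μa/μt per
collision, unpolarized Fresnel reflection at the external faces only
(internal interfaces are index-matched), Russian roulette below 1e-4
(survival 0.1).  Fluence is tallied with the collision estimator (w/μt per
collision, normalized by bin volume), which equals track-length scoring in
expectation; arrival time is the geometric path × n_r/c₀.  The run is split
into 32 batches and per-bin standard errors come from batch means.  Energy
bookkeeping (absorbed + escaped + roulette residual − roulette gain =
launched) is Kahan-compensated and holds to 1e-12.

What the MC emulates: multiple anisotropic scattering, boundary refraction,
and finite layer thicknesses — i.e. genuine transport physics beyond the
diffusion approximation.  What it does not: the cylindrical side wall
(comparisons use large radii so the wall is negligible), polarization,
refractive-index heterogeneity within the stack, and real detector
geometry/IRF.  Passing comparisons therefore validate the diffusion solver
in the regime where diffusion theory itself holds (ρ ≳ 0.5 cm, enough
scattering events), not instrument-level agreement.

## Monte Carlo comparison protocol

Validation runs score the surface fluence in a 1 mm deep shell (rather
than the 0.27 mm histogram resolution) so the collision tally is well
sampled at 10⁶-ish photon counts; the diffusion side computes the matching
shell average (5-point midpoint rule in depth), making the registration
unbiased instead of comparing a thin-bin average against the z = 0
boundary value (a ~7% bias at 0.27 mm bins).  Time-domain histograms keep
the native 0.02 ns and 0.99 mm bins and are aggregated (5 time bins, 3
adjacent annuli) before comparison, with the diffusion curve averaged over
the same sub-bins (area-weighted in radius).  Bins enter the comparison where the MC relative standard error
is below 1% (2% for the skin/fat/muscle range, whose claim tolerance is
0.1), and ρ < 0.5 cm is always excluded.  Time-domain bins with
c·t < 3ρ are excluded as well: on the rising edge the arriving paths are
barely longer than the ballistic distance and diffusion theory genuinely
overestimates the fluence there (measured ~11% at c·t/ρ ≈ 2, falling to
~3% by c·t/ρ ≈ 3.6) — the time-domain analogue of the near-source
exclusion.  Desk-scale runs use 1.2–2.5
million photons (the published comparisons used 5×10⁷); the well-sampled
range shrinks accordingly and is reported, never extrapolated.

## Scenario notes

The skin/fat/muscle and head-model parameter sets follow the published
three- and five-layer tissue tables; the head model's CSF layer uses
μs′ = 3.5 cm⁻¹ on the diffusion side (diffusion theory misbehaves for the
raw μs′ = 0.25, which the Monte Carlo arm keeps).  The white-matter bottom
layer is taken 4 cm thick (effectively semi-infinite); the published table
is ambiguous about this cell.  Scenario radii for the laterally infinite
MC comparisons are set to 20 cm so the side wall is negligible.

## Known limitations

* Reflectance/transmittance only (surface queries); arbitrary interior
  depths are supported only within the top/bottom layer and only for
  registration purposes.
* The extreme-dynamic-range configuration (μa = 0.6, ρ ∈ {3, 6} cm,
  t ∈ [0.1, 6] ns) has a physical fluence span of 48.3 decades; claims of
  "50 orders of magnitude" on this geometry are a rounding of that figure —
  the octuple pipeline tracks every sampled point (relative error < 2% at
  the window edge, < 1e-13 elsewhere), so the measured span equals the
  physical one.
* The contour-parameter optimizer's error model is asymptotic; observed
  errors track it to within 1–2 orders of magnitude of the predicted
  exponent, which the acceptance margins absorb.
* No instrument response convolution, no frequency-sweep tooling (a purely
  imaginary s̄ can be passed to the kernels directly), no inverse fitting.
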