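# Methods

## Scope and model

`focalcbs` post-processes tabulated electronic energies; it never runs an
electronic-structure calculation.  Its inputs are absolute energies in
hartree, indexed by system, fragment role (dimer / monomer A / monomer B),
method component (HF, MP2 correlation, CCSD(T) correlation), basis
cardinal number X ∈ {2, 3, 4, 5} of the aug-cc-pVXZ series, and basis
context (dimer basis vs. own basis).  Interaction energies are kJ/mol with
ΔE < 0 meaning binding; 1 hartree = 2625.499639 kJ/mol (CODATA-derived).
Tabulated magnitudes are negated only at presentation time, never in the
data model.

The supermolecular interaction energy is the counterpoise-corrected
difference ΔE = E(dimer) − E(A in dimer basis) − E(B in dimer basis),
evaluated per method component.  Monomer deformation is out of scope:
geometries are rigid, so ΔE is purely the supermolecular difference.
Symmetric dimers are stored as two monomer records with equal energies; no
deduplication is attempted.

## Extrapolation kernels

Each energy component converges differently with X, so each gets its own
model:

* mean-field: E(X) = E_CBS + A·exp(α√X), α < 0.  Two points eliminate
  (E_CBS, A): E_CBS = [w(x_hi)·E(x_lo) − w(x_lo)·E(x_hi)] / [w(x_hi) −
  w(x_lo)] with w = exp(α√X).
* correlation: E(X) = E_CBS + A·X^(−β), β > 0; β = 3 reproduces the
  conventional cubic two-point rule.
* post-MP2: the CCSD(T)-correlation pair is extrapolated with its own
  exponent γ and the MP2 pair with β; the correction is the difference of
  the two limits.  With β = γ this collapses algebraically to
  extrapolating the differences directly.
* three-point mixed Gaussian/exponential: E(X) = E_CBS + B·exp[−(X−1)] +
  C·exp[−(X−1)²] over three consecutive cardinals.  The exponents are
  fixed constants, so the solve is an exact 3×3 linear system — no
  iteration, and the forward model reproduces its inputs to < 1e−10
  hartree.

Numerical guard: if the two extrapolation weights agree to better than
1e−12 relative (or both underflow), the kernel raises an
ill-conditioned-extrapolation error instead of returning a catastrophic
cancellation.  Degenerate cardinal pairs (x_lo = x_hi) are rejected.

## Composite schemes

All composition acts on CP-corrected interaction components; by linearity
this is identical to composing absolute energies, and it keeps the schemes
applicable when only interaction components were archived.

* `a5z-focal` — HF and MP2-correlation components at X = 5, post-MP2 at
  X = 3, no extrapolation.  The reference composition.
* `atz-aqz-focal` — HF at X = 4 unextrapolated (the mean-field part is
  near-converged at quadruple-zeta, and the published composite carries no
  extrapolation on it), correlation parts extrapolated (3, 4) with the
  cubic rule.
* `adz-atz-fit` — all three parts extrapolated from (2, 3) with refit
  exponents.  Defaults α = −4.473, β = 2.796, γ = 2.741, the values
  obtained by refitting against quintuple-zeta reference data for this
  basis pair; conventional per-basis-pair tabulated exponents are
  deliberately not bundled (they are known to degrade ΔE for this use
  case), but any user-supplied exponents are accepted.
* `three-point` — cross-check scheme: the mixed Gaussian/exponential form
  applied per fragment and component over three cardinals, recombined by
  counterpoise.  Because the solve is linear in the energies,
  per-component extrapolation and summation commute.

## Exponent refitting

Each exponent is fit by unweighted nonlinear least squares: the two-point
extrapolation from the cheap basis pair is matched to a reference value
per observation (a quintuple-zeta energy for α and β; a converged post-MP2
value for γ, with β held fixed — β = 0 or negative is rejected).  The
kernels are linear in the energies, so observations may carry absolute
fragment energies or CP-corrected interaction components interchangeably;
the interaction-level reading is the documented default for γ, honouring
the fact that the correction is only meaningful as a difference.

Minimization uses a Levenberg–Marquardt trust-region (scipy
`least_squares`, method `lm`) from fixed starting points (α₀ = −4.0,
β₀ = γ₀ = 3.0 — the conventional exponents; the basins were verified
against a dense grid search).  Convergence tolerances are 1e−12 on the
relative parameter and cost change within 600 function evaluations;
non-convergence is flagged, never silently accepted.  Problems whose
residuals do not depend on the exponent (already-converged, constant
energies) are flagged `rank_deficient` via the Jacobian norm.  Results are
reported at full precision and rounded to four significant digits, the
customary quoting precision.  The fit itself contains no randomness.

## SAPT bookkeeping

DFT-SAPT decompositions carry the four printed components (polarization/
electrostatics, exchange, induction, dispersion) and the reported total.
The stored total must agree with the component sum to 0.25 kJ/mol (printed
components lose up to ~0.1 kJ/mol to rounding); a negative exchange
component warns but is not rejected.  The dispersion-to-polarization ratio
is defined as |Edisp|/|Epol|; this definition reproduces the quoted ratios
of the bundled table and separates its three classes cleanly (observed
group ranges ≤ 0.36, 0.69–1.09, ≥ 1.76).  Classification thresholds
default to (0.5, 1.5) and are configurable.  For systems with repulsive
electrostatics (positive Epol, e.g. the guanine trimer) the ratio's
published interpretation is ambiguous, so such rows are kept in the table
but excluded from ratio-based validation.

## Validation statistics

Agreement between two ΔE vectors is certified by OLS regression (slope,
intercept, adjusted R² with the two-parameter formula
1 − (1 − R²)(n−1)/(n−2), residual SD with n−2 degrees of freedom), the
mean absolute and root-mean-square deviations, and the worst absolute and
relative offenders with their system labels.  Relative deviations are
taken against the reference (x) vector; zero-reference entries are skipped
for the relative part.  Constant predictors raise a degenerate-regression
error.  Note rmsd ≥ mad is not asserted anywhere — only rmsd² ≥ mad²
(Jensen) is a true invariant.

## Synthetic data

The generator plants a CBS decomposition (ΔE_HF, ΔE_MP2corr, ΔE_postMP2)
and builds absolute fragment energies from per-fragment CBS baselines plus
decay terms following exactly the kernels' models.  Dimer amplitudes are
the monomer amplitudes plus an interaction amplitude, so CP-corrected
components decay with the same models and zero-noise round trips are exact.
Default amplitudes are sized to realistic basis-set errors: tens of
millihartree on absolute mean-field energies, a few tenths of a hartree on
correlation energies, and ~0.5–2 kJ/mol on CP-corrected interaction
components at double-zeta.

Two perturbations emulate real data: additive Gaussian noise on absolute
energies (hartree), and a model-violation scale that multiplicatively
perturbs each system's decay exponents — the mechanism that actually
limits cheap extrapolation schemes in practice.  Benchmarks default to the
validation conditions this package targets: 47 systems, planted totals
uniform in (−89, −2) kJ/mol, an even three-way class mix, with SAPT rows
constructed to satisfy the classifier for the assigned class (per-class
ranges of the dispersion-to-polarization ratio, polarization magnitude and
induction fraction are drawn well inside the thresholds).  All randomness
is seeded via `numpy.random.default_rng`; no global state.

What passing tests on this generator do **not** show: robustness to real
model violation (real components do not follow any single exponent), to
DLPNO truncation error (carried only as free-text provenance), or to
geometry/deformation effects.  The closed-form `finite_basis_residual`
quantifies what the unextrapolated reference composition misses on
model-consistent data; on real data that residual is only approximate.

## Problem sizes and numerical choices

The test suite and the acceptance script use synthetic benchmarks of 8–47
systems, 58-observation fitting sets (the natural training-set size when 7
of 22 dimers are symmetric: 3 fragments × 22 − 8), 1,000-instance solver
cross-checks and dense grid searches at 1e−4 resolution; everything runs
in seconds on one CPU.  Grid searches and closed-form normal equations
serve as independent oracles for the minimizer and the regression,
respectively.  Exact-recovery assertions use 1e−9 kJ/mol (interaction
level) or 1e−10 hartree (kernel level); looser stochastic tolerances
(0.05–0.1 on recovered exponents at σ = 1e−5 hartree) reflect the
estimator's actual spread under the stated conditions.

## Known limitations

* No parser for quantum-chemistry program output; energies arrive as CSV.
* Higher-order SAPT terms and δ(HF) corrections are not modelled; the four
  printed components are taken as-is.
* The three-point form's exponents are fixed by construction and cannot be
  refit.
* The bundled refit exponents are specific to the (aDZ, aTZ) pair with
  counterpoise-corrected components; applying them to other pairs or
  uncorrected data is unsupported extrapolation in both senses of the word.
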