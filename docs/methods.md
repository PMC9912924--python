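# Methods

This note documents the models, conventions and numerical choices behind
`sasreport`. The package computes every derivable field of the standard
reporting tables for biomolecular small-angle scattering (SAS): structural
parameters from the data, particle size and mass estimates, composition-based
contrasts and match points, goodness-of-fit statistics, and the two-component
decompositions used for neutron contrast-variation series.

## Scattering profiles and units

A profile is `(q, I, sigma)` with q in Å⁻¹ (strictly increasing, positive),
I in cm⁻¹ (absolute scale) or arbitrary units, and optional 1-σ
uncertainties. Files whose q-range extends beyond 2 Å⁻¹ are assumed to be in
nm⁻¹ and converted on read (biomolecular solution data essentially never
exceed ~1 Å⁻¹). Zero and negative intensities are retained — they are
physical near neutron match points — but negative uncertainties are not.

## Composition engine

Masses, X-ray and neutron scattering lengths, exchangeable-hydrogen counts
and packing volumes are accumulated per residue from embedded tables and
combined per chain:

* Protein chains: residue = amino acid − H₂O; one water per chain closure;
  the terminal amine and carboxyl hydrogens are labile. Residue packing
  volumes follow the Perkins (1986) consensus crystal volumes.
* Oligonucleotide chains: residue = nucleoside − H₂O + HPO₃ with a neutral
  P–OH phosphodiester (its hydrogen is exchangeable); chains are terminated
  5′-OH/3′-OH with no counterions, matching synthetic oligos as supplied.
  Nucleotide volumes are the package's reference set, chosen once to be
  consistent with crystallographic packing volumes of B-DNA (≈ 284–316 Å³
  per nucleotide, 5-methylation +22 Å³). 5-methylcytosine is modelled as
  cytosine + CH₂.
* Neutron scattering lengths: non-exchangeable hydrogens carry
  b = b_H + d·(b_D − b_H) at perdeuteration fraction d; exchangeable
  hydrogens carry b = b_H + x·f·(b_D − b_H) at solvent D₂O volume fraction
  f. The exchange fraction x defaults to 1 (all labile hydrogens
  equilibrate); it is an explicit argument everywhere.
* Solvent scattering-length density is the volume-fraction-weighted mix of
  pure H₂O and D₂O (per-molecule volumes 29.97 / 30.11 Å³ from the molar
  volumes at 20 °C). Buffer solutes at ≲200 mM shift ρ_s by ≲1% and are
  ignored by default.

Because both the solvent SLD and the exchange model are linear in f, the
particle contrast Δρ(f) is affine, so the calculated match point is the
closed-form root of a straight line; a root outside [0, 1] is reported as
"no match point" with the endpoint contrasts.

Derived quantities: ν = V·N_A/M (cm³ g⁻¹), ρ = Σb/V, Δρ = ρ − ρ_s,
Δρ_M = Δρ·ν. The identity V = M·ν/N_A holds to 1e-9 relative by
construction.

The embedded nucleotide volumes reproduce the published particle parameters
of a methylated 27-bp duplex (ν within 0.003 cm³ g⁻¹, X-ray Δρ within
0.1%); the amino-acid set gives typical protein ν ≈ 0.73–0.75 cm³ g⁻¹.

## Guinier analysis

`guinier_fit` is a weighted linear regression of ln I on q² with
σ_lnI = σ_I/I; Rg = √(−3·slope), I(0) = exp(intercept), uncertainties from
the regression covariance (variance inflated by reduced χ² when > 1).
Windows are 1-based datapoint indices, matching how reporting tables quote
"(datapoint range)".

`auto_guinier_range` scans start points, grows each window greedily while
q_max·Rg ≤ limit (default 1.3, the globular convention; reduce to ~1.0 for
elongated particles), and scores every admissible window by the geometric
mean of three sub-scores in [0, 1]:

* fit quality, 1/(1 + max(0, χ²_red − 1)/3);
* window coverage, the window length over the maximal admissible window
  anchored at the first datapoint (skipping usable leading points costs
  proportionally);
* Rg stability under one-point changes of the window ends,
  1/(1 + δRg/Rg / 0.02).

The composite is reported as the window's *fidelity*. It is this package's
own score: qualitative agreement with other tools' linear-fit quality
metrics is expected, numerical identity is not.

## P(r) inversion, smearing, desmearing

The indirect Fourier transform solves

    I(q) = 4π ∫₀^dmax P(r) sinc(qr) dr

on a fixed 201-point r-grid with P(0) = P(dmax) = 0 pinned, by penalized
weighted least squares: χ² + α‖P″‖², optionally with P ≥ 0 (default on;
disable for multi-phase contrast data where P(r) may go negative).
α = "auto" scans 21 log-spaced values and takes the corner (maximum
discrete curvature) of the L-curve (log residual norm vs log roughness
seminorm). The reported reduced χ² divides by N − tr(H), where tr(H) is
the trace of the hat matrix of the penalized problem on the active set —
the effective number of parameters, typically 10–20, far below the grid
size. Moments give I(0) = 4π∫P dr and Rg² = ∫r²P dr / 2∫P dr.

Slit geometry uses a trapezoidal beam-length profile W(t) parameterized by
plateau and base half-widths in Å⁻¹;

    I_s(q) = ∫W(t) I(√(q² + t²)) dt / ∫W dt.

For printed "AH/LH = 0.29/0.15" beam descriptions the mapping base = 0.29,
plateau = 0.15 Å⁻¹ is a documented assumption (which symbol denotes which
half-width is not standardized). When fitting slit data the forward kernel
itself is smeared, so the returned P(r) describes the ideal particle.
Smearing a tabulated curve extends it beyond its last point with a Porod
tail I = B + K/q⁴ fitted on the final decade of points (which reduces to
the exact constant for flat curves). Desmearing multiplies the data
point-by-point with the ratio of the unsmeared to the smeared intensity of
the fitted P(r) model, scaling σ by the same factor.

`scan_dmax` scores each candidate by fit χ² plus penalties for extra local
extrema of P(r), negative excursions, and P(r) not approaching zero at
dmax, then picks the *smallest* dmax whose score is within 5% (or 0.02) of
the best — overestimating dmax rarely worsens a fit, so parsimony breaks
the tie. A χ² spread below 10% across the whole grid flags "unstable
d_max" (typical of structureless data).

## Size and mass estimators

* Porod volume: V_P = 2π²I(0)/Q with Q = ∫q²(I − B) dq. The constant
  background B and Porod constant K come from the linearized Porod plot
  q⁴I = K + Bq⁴ on the window q ≥ max(0.2, 4/Rg) — far better conditioned
  on oscillatory form factors than fitting I = B + K/q⁴ directly. The
  integral is extended to q = 0 with the Guinier model and beyond the data
  with the analytic K/q_max tail. On a noiseless sphere sampled to qR = 12
  the estimate is within ~2% (documented tolerance 5%).
* Concentration-dependent mass: M = N_A·(I(0)/c)/(Δρ·ν)², requiring
  absolute-scale I(0) (cm⁻¹) and c converted from mg/ml to g/cm³. This is
  exactly inverse to the forward expression.
* Concentration-independent mass: the volume of correlation
  V_c = I(0)/∫qI dq, Q_R = V_c²/Rg, and the Rambo–Tainer power laws
  (protein: M = Q_R/0.1231; nucleic acids: M = (Q_R/0.00934)^(1/0.808)).
  Data truncated below q = 0.25 Å⁻¹ get a warning. A Bayesian-consensus
  mass interval is out of scope; the method tag records which estimator
  filled the concentration-independent slot.

## Goodness of fit

Reduced χ² uses the analytic optimal scale s = Σ(I_d I_m/σ²)/Σ(I_m²/σ²)
when a multiplicative factor is fitted (consuming one degree of freedom);
both N−k and N normalizations are stored since published values do not
always say which was used. The CorMap-style P-value is the probability
that n independent fair sign flips contain a run at least as long as the
longest observed run of identical residual signs, computed exactly from
the composition recurrence (number of binary strings with all runs ≤ m),
using integer arithmetic — no Monte Carlo. Zero residuals count as
positive (deterministic tie-break). The q-interval of the longest run is
reported, which localizes systematic misfit.

## Contrast-variation analysis

* Experimental match point: weighted straight-line fit of
  sign·√(I(0)/c) against f_D₂O; the root is the match point, its
  uncertainty comes from the fit covariance by the delta method. Signs are
  positive below the |I(0)| minimum and negative above; the minimum
  condition itself is tried with both signs and the better (weighted) fit
  kept, preferring on ties the assignment that brackets the crossing. An
  all-one-sided series yields an extrapolated root, flagged as such.
* Stuhrmann analysis: weighted quadratic fit
  Rg²_obs = Rm² + α/Δρ̄ − β/Δρ̄², exact for three points, with an option to
  constrain β = 0. Columns are equilibrated to unit norm before solving —
  powers of 1/Δρ̄ (cm²) differ by ~20 orders of magnitude and destroy an
  unscaled normal-equation solve.
* Parallel-axis analysis: weighted least squares for (R1², R2², D²) in
  Rg²_obs = f₁R1² + f₂R2² + f₁f₂D² with contrast-weighted fractions
  f_i = Δρ_iV_i/ΣΔρ_jV_j. Negative solutions are flagged rather than
  raised. Uncertainties on Rg² propagate as 2·Rg·σ_Rg.
* Composite scattering functions: at each q the system
  I_k = Δρ₁ₖ²I₁₁ + Δρ₁ₖΔρ₂ₖI₁₂ + Δρ₂ₖ²I₂₂ is solved across conditions k
  by σ-weighted least squares (contrasts rescaled to order unity first);
  requires rank 3. I_homogeneous = I₁₁ + I₁₂ + I₂₂ by construction, and
  at q → 0 coherence forces I₁₂² = 4·I₁₁·I₂₂.

On noiseless synthetic two-body data the three routes agree to better than
1%: Rm² equals the parallel-axis expression at the infinite-contrast
fractions, and the composite functions are recovered to solver precision.
Low-contrast conditions enter all fits only through their (large)
uncertainties; no special-casing.

## Validation rules

`validate` encodes the cross-checks of a careful table reader as stable
rules; each threshold quantifies deliberately qualitative reporting
language and is a configuration key:

| rule | check | default |
|------|-------|---------|
| R1 | Guinier vs P(r) Rg | within 2 combined σ, else warn |
| R2 | Guinier vs P(r) I(0) | within 5% relative, else warn |
| R3 | Guinier window | qRg_max ≤ 1.3, else info |
| R4 | V_P/M | [1.1, 1.8] Å³/Da protein, [1.1, 1.4] nucleic acid |
| R5 | M from I(0)/c vs composition | ±25% warn, ±10% info |
| R6 | CorMap P of any fit | ≥ 0.01, else warn with misfit interval |
| R7 | reduced χ² of any fit | within [0.5, 2], else info |

## Synthetic data

The generator produces homogeneous spheres and displaced two-sphere
particles (exact amplitudes, Debye cross term sin(qD)/(qD)), optional slit
smearing, and full contrast-variation series whose per-body SLDs may be
constants or composition-derived functions of f_D₂O (carrying the exchange
dependence). Noise is Gaussian with σ(q) = relative_level·I(q) + floor and
a mandatory seed; noiseless output is seed-independent and bit-reproducible.
Every series carries its exact ground truth (match point, component Rg,
separation, composite functions, per-condition whole-particle Rg), so every
estimator in the package is tested as a recovery problem with no external
data. Default simulation sizes (300–500 q-points to 0.25–0.4 Å⁻¹, 1%
relative noise, 6–7 contrast conditions) mirror a well-measured laboratory
experiment.

What the generator does **not** emulate: counting (Poisson) statistics,
inter-particle interference, aggregation, incoherent backgrounds,
wavelength smearing, or a hydration layer of distinct density. Passing
recovery tests therefore demonstrates correctness of the estimators, not
robustness against every pathology of real data — the validation rules
exist precisely because real data can fail in ways ideal simulations do
not.

## Known limitations

* The composition tables cover proteins, DNA and RNA; glycans, lipids and
  detergents are out of scope (glycan accessions are format-checked only).
* The automatic Guinier fidelity score and the L-curve choice of α are
  this package's own conventions; published values produced with other
  software will differ in the third digit even when Rg and I(0) agree.
* Published reduced-χ² values for P(r) fits depend on the producing
  program's regularization and are treated as qualitative references.
* Whether printed component volumes include bound metals, and the exact
  exchange fraction behind printed match points, are usually unstated;
  both are explicit parameters here.
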