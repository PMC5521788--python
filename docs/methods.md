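# Methods

This note records the models implemented in `invitrodose`, their
assumptions, the defaults that matter, and the numerical and design choices
made where more than one reasonable option existed.

## Decay chains and cumulated activity

The packaged alpha chain is

    Bi-213 ──(BR 0.9784, beta)──> Po-213 ──> Pb-209
    Bi-213 ──(BR 0.0216, alpha)──> Tl-209 ──> Pb-209

with half-lives 45.59 min (²¹³Bi), 4.2 μs (²¹³Po), 2.16 min (²⁰⁹Tl),
3.253 h (²⁰⁹Pb); ¹⁷⁷Lu (6.647 d) ships as a single-nuclide "chain". The
45.59 min value is the evaluated physical half-life; a commonly quoted
rounded value is 46 min, but the cumulated-activity coefficient is sensitive
to the difference at the fourth significant digit. ²⁰⁹Pb is treated as the
chain terminus: its daughter ²⁰⁹Bi is effectively stable, and the S-value
tables carry no entries beyond ²⁰⁹Pb. Chain data live in versioned CSVs and
can be overridden by user-supplied files.

Activities of every member are propagated through the chain as sums of
exponentials (Bateman solutions); cumulated activity over a window
integrates each term in closed form, using `expm1` so short windows and
small decay constants lose no precision, with the exact no-decay limit
Ã = A₀·(t₁−t₀) as λ → 0.

**Secular-equilibrium handling.** When a daughter's decay constant exceeds
that of a feeding exponential by more than 10⁶ (²¹³Po vs ²¹³Bi: ratio
~6.5×10⁸), the daughter's own transient term `exp(-λ_d t)` underflows within
milliseconds and its Bateman coefficient suffers catastrophic cancellation.
The implementation then drops the transient and lets the daughter inherit
the feeding exponential scaled by the branching ratio. This is exact to
better than λ_parent/λ_daughter (~10⁻⁹ here) for windows long against the
daughter half-life; the documented contract is 10⁻⁴ relative.

Degenerate chains with two equal decay constants would need t·e^(−λt) terms;
they do not occur in the packaged data and are rejected with an error rather
than silently mis-solved. General deep chains are supported by the same
recursion but validated only to three generations with branching — the
depth the packaged chains need; the test suite checks all closed forms
against an independent stiff-ODE (LSODA) integration of the atom-number
balance at rtol 10⁻¹⁰, to 10⁻⁶ relative outside the equilibrium regime.

A daughter decaying *slower* than 90% of its parent's stock takes longer
than ln(10)/λ_parent of the parent alone; `fraction_of_decays_by` is the
single-nuclide statement 1 − e^(−λt) and deliberately makes no claim about
dose-delivery completion of a chain with progeny build-up.

## Well-medium dose

During incubation the activity is assumed homogeneously distributed in the
2 mL medium of a 6-well cavity, with the cells on the bottom. The mean dose
to the bottom 25 μm scoring layer is

    D̄(layer←fluid) = Σ_nuclide Σ_class Ã_nuclide × S(layer←fluid; nuclide, class) × 10⁻³ Gy

with S in mGy/(MBq·s) and Ã in MBq·s. The packaged S-value table covers the
²¹³Bi chain per radiation class (alpha, beta, Auger/IC electrons, gamma),
derived from Monte Carlo transport in the well geometry; absorbed fractions
are stored as fractions (the printed source uses percent). Only the
bottom-layer values are packaged — a full depth profile is not — so the
module reports the cell-layer dose, not a depth-resolved one, and the
whole-fluid mean dose is not recomputed. ¹⁷⁷Lu layer S-values are not
packaged; medium dose for ¹⁷⁷Lu requires a user-supplied table for the
geometry at hand. Per-nuclide class sums agree with the source's printed
totals within one unit in the last printed digit; the package always sums
the class components.

The daughters start at zero at t = 0 (fresh-eluate assumption). Dose is
linear in A₀ and additive over nuclides and classes; an energy-conservation
ceiling (dose ≤ Ã × emitted energy per decay / layer mass) is enforced in
the test suite as a sanity bound.

## Cellular self-dose from bound activity

Bound activity delivers dose through MIRD cellular S-values for a 6 μm
radius cell: S(C←C) for activity distributed in the cell, S(C←CS) for
activity on the membrane, combined with the internalised/membrane partition
(f_int, f_mem), f_int + f_mem = 1:

    D̄_cell = Σ_nuclide Ã_cell,nuclide × [f_int S(C←C) + f_mem S(C←CS)] × 10⁻³ Gy

Per parent decay the chain members contribute with their cumulative
branching fractions (1, 0.9784, 0.0216, 1 for ²¹³Bi, ²¹³Po, ²⁰⁹Tl, ²⁰⁹Pb),
giving combined S-values of 50.2 (self) and 33.7 (surface) mGy/MBq·s.

Conventions and choices:

* The bound activity `a_cell` is specified **at the start of the follow-up
  window** (the end of the 1 h incubation), progeny at zero there, and the
  chain is integrated over the window duration (default 1 h → 12 d). Dose
  accrued during the incubation itself is attributed to the medium
  component, not the cellular one.
* No clearance: once bound, activity stays with the cell for the whole
  colony-formation period. For the ²¹³Bi chain the 12 d window is
  numerically infinite (>99.99% of decays); for ¹⁷⁷Lu it is not, and the
  window matters — extending it changes the dose by the closed-form factor
  (1 − e^(−λT₂))/(1 − e^(−λT₁)).
* The packaged set carries per-nuclide values only. The source's
  chain-combined *cross-dose* entries are not reproducible as
  branching-weighted sums of its per-nuclide rows (weighted 50 μm sum
  ≈ 0.40 vs a printed 0.52) and are therefore excluded; the per-nuclide
  values are treated as authoritative.
* `cross_dose_bound` returns an upper bound using the nearest tabulated
  distance not exceeding the requested one, and 0 with an out-of-range flag
  beyond the table or where the emission range is exceeded. In sparsely
  plated assays (inter-cell distances of hundreds of μm against an ~80 μm
  alpha range) the cross-fire term is negligible, which is why a bound
  suffices.
* Mean absorbed dose only: stochastic single-track microdosimetry is out of
  scope; at the molecule-per-cell loads of interest the track structure is
  averaged over.

## Uptake kinetics and molecules per cell

At tracer-level concentration the internalised fraction grows linearly with
incubation time (slope in %A/min) over the first hour while the
membrane-bound fraction sits at a constant plateau — an empirical
description valid far from receptor saturation and for times short against
trafficking equilibria. Versus peptide concentration [M] (μmol/L, over
~0.015–0.39 μmol/L) the total uptake follows the empirical saturation curve
u([M]) = A·e^(−k[M]) + B, monotone non-increasing and bounded in [B, A+B].
This is a fit shape, not a mechanistic Bmax/Kd model, and its default
parameters (A = 1.0 %A, k = 39 L/μmol, B = 0.38 %A) describe a regime of
low uptake and low R², which the fitter must tolerate (wide intervals, not
failures).

Scaling an uptake percentage measured with 0.5×10⁶ assay cells to the 500
cells of a clonogenic well uses proportional (dilute-limit) scaling
f × n_target/n_assay: with receptors far from saturation, bound fraction is
proportional to the receptor pool present. Molecules per cell follow from
the applied activity A, molar activity MA (MBq/nmol), bound fraction f and
cell count n as (A/MA) × 10⁻⁹ × N_A × f / n. Published molecule-per-cell
figures depend on unprinted molar activities and are not reproduction
targets; the arithmetic is.

%A and %IA are treated as the same unit (percent of applied activity).

## Clonogenic survival fitting

Surviving fraction per well is SF = colonies/(seeded × pe) with pe pooled
from the unirradiated control wells; its standard error uses the binomial
approximation. Dose response is LQ, SF(D) = exp(−αD − βD²), or one-phase
(β = 0) for high-LET curves; α, β ≥ 0 is enforced, and a fit whose α
constraint binds is flagged `alpha_at_bound` with a profile-style ("as if
free") standard error, matching the "α < bound" reporting convention for
curvature-dominated curves.

**Fit objective.** The default is maximum likelihood on the colony counts,
colonies ~ Poisson(seeded · e^(θ₀) · SF(D)) with θ₀ = ln pe estimated
jointly — a log-link Poisson GLM solved by L-BFGS-B plus Fisher-scoring
polish, with covariance from the Fisher information. The classical
alternative, unweighted least squares on −ln SF, is retained as
`objective="lsq"` and as `fit_sf_curve` for published survival-fraction
points without underlying counts. The likelihood default is a deliberate
design choice: where survival is low the expected counts are of order one,
and in that regime the log-domain least squares is structurally biased (the
convexity of −ln at small counts, plus the forced exclusion of zero-colony
wells, drags curvature out of β into α) and its nominal 95% intervals
cover the truth barely half the time in simulation, while the Poisson fit
is unbiased with near-nominal coverage. Replicate wells always enter
jointly, never as per-dose means; zero-colony wells contribute through the
likelihood (and are excluded, with a logged warning, only in the log-domain
objective, which cannot represent them).

Derived quantities: D at survival S solves αD + βD² = −ln S via the
cancellation-free positive root 2L/(α + √(α² + 4βL)); α/β carries a
delta-method standard error using the full covariance; RBE is the ratio of
reference to test dose at the same endpoint. Confidence intervals are
two-sided t-intervals on the fit degrees of freedom.

## Synthetic data

The generators are pure functions of a `SimulationConfig`; the seed fixes
every output bit-for-bit. Defaults reproduce the assay designs the package
targets: triplicate wells at doses 0.5–10 Gy with 500 cells seeded and
plating efficiency 0.4 under α = 0.21 Gy⁻¹, β = 0.05 Gy⁻²; seven time
points over 0–60 min with slope 0.096 %A/min, membrane plateau 0.56 %A and
σ = 0.1 %A; eight concentrations over 0.015–0.39 μmol/L with A = 1.0,
k = 39, B = 0.38 and σ = 0.15 %A (a deliberately low-R² regime).

Colony noise is Poisson — counts of independent surviving clonogens — and
uptake noise is homoscedastic Gaussian in %A, clipped at zero. What the
generators do **not** emulate: overdispersion from pipetting or counting
error, colony-merging at high density, receptor-number variability between
cells, dissociation/externalisation of bound ligand, and the stochastics of
individual alpha traversals. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated sampling models, not
that real assays are free of these additional error sources.

## Pipeline

`run_pipeline` converts each condition's activities to absorbed dose
(well-medium component per MBq plus, when a bound fraction is given, the
cellular component), fits the requested survival model, and reports D₁₀,
D₂₀ and RBE against the reference condition, as JSON and TSV. Conditions
whose maximum absorbed dose is below 10⁻³ Gy are flagged sub-threshold and
get no fit or D₁₀ — there is no fittable dose range, mirroring how
non-binding controls behave in practice. Re-runs on the same inputs are
byte-identical.

## Problem sizes and tolerances

Closed forms are validated against the ODE oracle at 10⁻⁶ relative (10⁻⁴ in
the equilibrium regime) over half-lives 0.5 s–10⁴ s and windows 1 s–10⁶ s;
decay-count conservation is checked at T = 3×10⁶ s (≈37 ²⁰⁹Pb half-lives).
Statistical properties use 200 seeded replicates per scenario and n = 10⁴
wells for mean-convergence checks — sizes at which the Monte Carlo error of
the checks themselves is a few per mille. Noise-free recoveries are asserted
at 10⁻⁶.

## Known limitations

* Only bottom-layer well S-values are packaged; other plate geometries,
  volumes or nuclides need user-supplied tables.
* Cell geometry is fixed by the S-value set (6 μm radius); no geometric
  dosimetry is computed.
* Cross-dose is bounded, not transported; clustered-cell geometries where
  cross-fire matters (notably for beta emitters) are underestimated by
  construction.
* The uptake models are empirical; no receptor-saturation mechanism, no
  competition/IC₅₀ analysis.
* The LQ machinery assumes survival is a function of mean absorbed dose;
  very low mean doses with few tracks per cell violate this and are handled
  only by the sub-threshold flag, not by a stochastic dose model.
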