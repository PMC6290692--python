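# Methods

This note documents the demographic models and numerical choices behind
`lifedisp`, in the spirit of a model-description vignette: what is
computed, under which assumptions, with which defaults, and what the
synthetic test bed does and does not establish about real data.

## Period life tables

A life table is built from age-specific death rates m(x) on either a
single-year grid (0, 1, ..., 109, open interval 110+) or an abridged
5-year grid (0, 5, ..., 85+ for cause-of-death work). The closure is the
standard period one:

    q(x) = n·m(x) / (1 + (n − a(x))·m(x)),   capped at 1,

with a(x) = n/2 in all closed intervals except the first year of life,
where a Coale–Demeny-style rule a(0) = 0.07 + 1.7·m(0) (capped at 0.5)
is applied on single-year grids. The open interval is closed with
q = 1, a(ω) = e(ω) = 1/m(ω), i.e. a constant hazard beyond the last age.
If the q formula saturates mid-table, that interval absorbs all remaining
deaths and survivorship is zero afterwards.

Two properties of this closure worth knowing:

* For a constant hazard μ the midpoint closure is *exact* at any interval
  width — q = nμ/(1 + nμ/2) makes the person-year sum telescope to 1/μ —
  so grid-refinement convergence tests against the exponential limit are
  trivially satisfied; the suite asserts the error stays below 10⁻⁹ at
  5-, 1- and 0.1-year widths.
* Σ dₓ equals the radix to machine precision by construction, which the
  decomposition machinery relies on.

Robustness scenarios supported: multiplying the age-0 rate by a per-year
schedule (the bundled schedule doubles infant mortality before 1990,
relaxes linearly to 10 % inflation by 2000 and stays at 10 % after), and
conditioning on survival to a chosen age by re-basing the radix there.

## Life disparity and related measures

Life disparity e† = ∫ d(a)e(a) da is evaluated with e linearly
interpolated at the mean age at death within each interval:

    e† = Σ_closed dₓ·[(1 − aₓ/n)·eₓ + (aₓ/n)·e_{x+n}] + d(ω)·e(ω).

This converges to the continuous integral as the grid refines and matches
standard spreadsheet practice. Keyfitz entropy is computed by an
*independent* route, H = (−∫ l ln l dx)/e₀ by trapezoid with the
open-interval tail in closed form (l_ω(Λ_ω + 1)/m_ω under the constant
tail hazard); the identity e† = H·e₀ then serves as a cross-check between
two discretizations rather than a tautology — it holds to ≈0.1 % on
single-year grids in the test suite, with 1 % the asserted bound. The
life-table Gini G = 1 − (1/e₀)∫ l² dx (trapezoid, exponential tail
l_ω²/(2 m_ω)) is validated against a brute-force pairwise
|age-at-death difference| oracle on the dₓ atoms.

The threshold age a† is defined behaviourally: a marginal mortality
reduction below it decreases e†, above it increases e†. It is located by
sweeping a finite-difference sensitivity — e† after a 1 % proportional
hazard reduction in a band of width 1 year centred at a, minus baseline
e† — over the grid, with fractional band/interval overlap making the
sensitivity continuous in the band centre, and refining each sign change
by Brent root finding. Cells where survivorship has already hit exact
zero have identically zero sensitivity and are excluded before crossings
are counted. If several crossings exist the oldest below the open
interval is reported (all are available). A schedule whose sensitivity
never changes sign (e.g. a constant hazard, where any saving expands
variation relative to none) raises an error rather than fabricating an
age.

## Decomposition

Changes in e₀ or e† between two rate vectors are attributed to covariates
with the Horiuchi line-integral algorithm: the straight-line path between
the endpoints is split into n equal segments, and at each segment
midpoint every covariate is advanced and retarded by half a step, the
central differences accumulating into the covariate's contribution. The
default is n = 20 steps, adequate for year-pair-sized changes (relative
residual ≲ 10⁻⁷); the residual shrinks ~quadratically in n, and the
full-pipeline default is n = 80 because regime-sized changes (a
working-age factor moving 0.95 → 1.5) need the finer path to stay under
the pipeline's 10⁻⁶ abort tolerance. Decomposing end→start negates every
contribution (path symmetry), and a change confined to one covariate
lands entirely on it.

For the age × cause decomposition the covariates are
m(x, c) = m(x)·p(x, c), the abridged all-cause rates split by per-year
cause-proportion tables; the functional is evaluated on the cause sums so
that covariates and functional share one 5-year grid with the open
interval at the truncation age 85, and all open-interval mortality is
carried by the residual category. The split conserves all-cause rates
exactly, and cause totals agree with the age-only decomposition on the
same grid to ≲10⁻⁴ years.

Causes of death are grouped into seven categories chosen around
hazardous alcohol consumption: wholly alcohol-attributable (F10, K70,
K74, X45), circulatory disease (the printed I-chapter ranges plus G45),
transport accidents (V01–V99), other external causes (the W/X/Y ranges),
infectious & respiratory, cancers, and a residual. Overlaps resolve by
first match in that order, so alcohol poisoning (X45) takes precedence
over the external-cause block. The exact ranges for cancers (C00–C97)
and infectious & respiratory (A00–B99, J00–J99) are a documented package
assumption; the alcohol-related groups follow the standard
amenable-to-alcohol classification verbatim.

## Trends and segmentation

Rates of mortality improvement ρ(x, t) = −100·Δ_t ln m(x, t) are computed
on surfaces smoothed by two-dimensional penalized least squares on the
log scale (second-order difference penalties along age and year,
generalized cross-validation over a log-spaced grid when penalty weights
are not supplied). This is a deliberate simplification of Poisson
P-spline surface smoothing: ρ is descriptive here, the tested contract is
the ±0.5 % improvement/worsening/little-change categorisation, and the
penalty null space (bilinear log surfaces) passes through untouched.
Zero rates are floored at 10⁻⁸ before logging.

Multiple change points in a yearly series (the cross-country coefficient
of variation of e₀, by default) are found divisively: at each stage the
split maximizing the between-segment energy-distance statistic
Q = mn/(m+n)·[2·E|X−Y| − E|X−X′| − E|Y−Y′|] (Euclidean, exponent 1) over
all current segments is tested against a permutation null (observations
permuted within the current segmentation; 199 permutations; seeded), and
accepted splits recurse until no candidate is significant at α = 0.05
with segments of at least 5 years. The series is standardized first, so
detection is exactly invariant to affine transforms. The permutation
count, exponent and minimum segment are package defaults — the algorithm
family fixes none of them — and are exposed as parameters. Statistical
breaks within 4 years of a canonical boundary {1980, 1988, 1994, 2000}
are snapped to it (the historical rounding of the 1976 break to 1980 sets
the width); more distant breaks are kept and flagged non-canonical. When
the snapped set is exactly canonical the five named periods (stagnation,
improvements, deterioration, divergence, convergence) are emitted.

Quadrant analysis classifies paired yearly first differences (Δe₀, Δe†) —
absolute, or relative to the previous year's level — by sign quadrant
within each analysis period, with normal-approximation binomial 95 % CIs
truncated to [0, 1]. Exact-zero differences are excluded from
denominators by default (togglable); both the CI method and the
zero-handling are conventions the underlying studies leave unstated, so
they are flagged here for sensitivity analysis.

## Synthetic data

The generator emulates the structural features the analysis needs:

* hazard μ(x) = a₁e^(−b₁x) + c + a₂e^(b₂x) + h·exp(−(x−κ)²/2σ²) — Siler
  plus a young-adult hump. The pinned CEE-male preset gives a baseline
  e₀ ≈ 69 and e† ≈ 13.8 with threshold age ≈ 70, inside the 63–70 /
  13–19-year envelope the region's male series occupied;
* per-year multipliers on the working-age band 20–60 tracing the five
  regimes, either as a piecewise-linear ramp (stagnation drift to 1.10,
  improvement to 0.95, crisis ramp to 1.50 by 1994, plateau 1.40, decline
  to 0.85) or as one level per regime (1.12 / 0.95 / 1.50 / 1.40 / 1.00).
  A boundary year carries the outgoing regime's level, so the 1988→1994
  decomposition spans the full deterioration. Optional small seeded
  log-normal jitter keeps within-period variance positive for the
  permutation tests;
* the two-country fixture pairs a crisis country with a stable partner;
  their e₀ gap makes the cross-country CV encode every regime boundary as
  a level shift, which the change-point stage recovers within ±1 year;
* seven-cause proportion tables from parametric age profiles (logistic
  rises for circulatory and cancers, young-adult Gaussians for alcohol,
  transport and other external causes, a declining infectious &
  respiratory profile), normalized per age group, everything at 85+
  residual, with the alcohol/external shares inflated during the crisis
  regime.

Rate surfaces are deterministic; Poisson death counts (seeded) are
available as optional noise. Deliberately *not* emulated: migration,
cohort effects, country-specific calibration to real CEE series, infant
live-birth definition artefacts, and old-age data-quality problems.
Consequently, passing tests demonstrate the correctness and internal
consistency of the estimators and pipeline — closed forms, identities,
additivity, locality, recovery of planted structure — not the historical
accuracy of any particular country's published figures, which require
the registered archival data.

## Problem sizes and defaults

Tests and the acceptance script run on: 111-age single-year grids,
55-year surfaces (1960–2014), 18-group abridged grids, 20–50 randomized
schedules per identity check, 20 endpoint pairs for additivity, and 200
seeded replicates each for the change-point recovery (5σ staircase
shifts, 10-year segments) and false-positive studies on 30-year series.
These sizes make every property estimable with comfortable margins while
the whole suite stays interactive.

## Known limitations

* The e† discretization and the entropy quadrature agree to ~0.1 % on
  single-year grids but degrade on coarse abridged grids; cause-level
  results are therefore reported on the shared 5-year grid only, and the
  single-age/5-year grid choice below 85 is a documented sensitivity.
* The threshold-age search assumes an adult-senescent schedule; bathtub
  schedules with multiple genuine crossings report all of them but
  return the oldest, per convention.
* GCV for the surface smoother optimizes a homoscedastic Gaussian
  criterion on log rates; sparse-death cells (very young ages in small
  populations) would favour the Poisson machinery this smoother
  deliberately replaces.
* The quadrant CIs treat country-year pairs as independent; serial
  correlation within countries makes them approximate.
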