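# Methods

This note documents the models implemented in `healtheff`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model and preprocessing

A `PanelDataset` is a dense block of strictly positive indicator values
over `n` DMUs × `T` periods, with each indicator registered as a DEA input
or output and each DMU carrying a region label in {E, NE, C, W}. Indicator
derivation from raw counts follows the registry formulas: simple ratios
(per-capita expenditure, average hospitalization duration), per-1000
population rates (facilities, personnel, beds, visits) and the bed
utilization percentage (used/available × 100).

**Min–max normalization.** DEA requires strictly positive data, and the
SBM objective divides by the evaluated unit's own values, so each
indicator is affinely mapped onto [0.1, 1.0] (configurable; the lower
bound must be positive). The min and max are pooled over *all* DMUs and
periods, not per year: cross-period Malmquist distance functions compare a
year-t point against a year-t+1 frontier, which is only meaningful if both
are on one common scale. Constant columns carry no discriminating
information and are mapped to the upper bound, preserving positivity.
Normalization is idempotent and rank-preserving by construction.

## PCA aggregation of the output block

PCA operates on the Pearson correlation matrix of the pooled panel (all
DMU-period rows as observations). Columns are z-standardized with the
sample (n−1) standard deviation; the convention is configurable and
matters only in third-decimal effects for the diagnostics. Components
with eigenvalue strictly greater than 1 are retained (Kaiser criterion;
ties at exactly 1 are excluded).

Adequacy diagnostics:

* **KMO** = Σ r²ᵢⱼ / (Σ r²ᵢⱼ + Σ q²ᵢⱼ) over i ≠ j, with anti-image
  partial correlations qᵢⱼ = −Rinvᵢⱼ/√(Rinvᵢᵢ Rinvⱼⱼ). A condition-number
  guard (10¹²) rejects numerically singular matrices.
* **Bartlett sphericity** χ² = −(n − 1 − (2p+5)/6)·ln det R on
  p(p−1)/2 degrees of freedom.

Eigenvector signs are arbitrary; each is oriented so its largest-absolute
entry is positive, and comparisons against published loading tables should
use absolute values. Score coefficients are the unit eigenvectors, so a
coefficient column equals the loading column divided by √eigenvalue; with
this convention component scores of z-standardized data have mean zero
and variance equal to the eigenvalue. An SPSS-style regression-coefficient
alternative (loading/eigenvalue, unit-variance scores) is available via
`convention="regression"`. Component scores may be negative; positivity
for the DEA stage is restored by the min–max rescaling above.

The packaged reference matrix is a published pooled correlation matrix of
2 expenditure inputs and 11 output indicators over 31 provinces × 10
years (n = 310, inferred from the printed degrees of freedom and
numerically consistent with the printed Bartlett statistic). Because it
is transcribed at three printed decimals, matrix inversion amplifies the
rounding: the recomputed KMO is reliable to about ±0.05 and the Bartlett
statistic to a few percent, while the eigenvalues are stable to ±0.02.

## SBM and super-SBM efficiency

The fractional SBM program (see README for the formula) is linearized by
the Charnes–Cooper transformation: multiply numerator and denominator by a
scale t > 0, substitute Λ = tλ, S = ts, normalize the denominator to 1,
and minimize the now-linear numerator. The LP is solved with HiGHS
(scipy.optimize.linprog); t is bounded below by 10⁻⁹ to keep the
back-substitution λ = Λ/t well defined. Scores within 10⁻⁷ of 1 are
reported as exactly 1 (a rounding guard consistent with the
score = 1 ⇔ max-slack ≤ 10⁻⁷ equivalence that the tests assert).

Super-SBM evaluates an SBM-efficient unit against the convex (VRS) or
conical (CRS) hull of the *other* units: the reference point
(xₖ + s⁻, yₖ − s⁺) must be producible by the peers, the objective inverts
the slack roles, and δ ≥ 1 measures how far the unit sits beyond the
peer frontier. Reference outputs are constrained nonnegative. Under VRS
the program can be infeasible (no convex peer combination dominates);
this is reported as a status, and the cross-section driver substitutes a
score of 1.0 with an explicit `superSBM_infeasible` flag so that score
tables stay complete while marking the cell. Super-SBM is computed only
for SBM-efficient units — inefficient units keep their SBM score — which
is the convention that produces tables mixing sub-unity and super-unity
values.

Alternate optimal bases are accepted as-is: λ is generally not unique at
an SBM optimum, so tests assert scores and slacks, never λ itself.

## Malmquist productivity index

Distances are radial, input-oriented Farrell efficiencies
θ = min{θ : Xλ ≤ θx₀, Yλ ≥ y₀}, computed under CRS for
tfpch/effch/techch and under VRS (within-period only) for pech — the
Färe–Grosskopf–Norris–Zhang convention. The geometric-mean index between
adjacent periods t, t+1 is

    tfpch = [ θᵗ(t+1)/θᵗ(t) · θᵗ⁺¹(t+1)/θᵗ⁺¹(t) ]^{1/2},
    effch = θᵗ⁺¹(t+1)/θᵗ(t),  techch = tfpch/effch,
    pech  = θᵗ⁺¹_VRS(t+1)/θᵗ_VRS(t),  sech = effch/pech,

so all components exceed 1 when the DMU improves, the decomposition
identities hold to machine precision by construction, and the index is
time-reversible (forward × backward = 1). Cross-period VRS programs can
be infeasible — a known phenomenon — and CRS cross-period distances may
exceed 1; a DMU-pair with any failed distance is marked incomplete and
excluded from aggregates rather than imputed.

**Aggregation.** Component tables aggregate by geometric means (per DMU,
per period pair, per region, or overall), which is the only averaging
scheme that preserves tfpch = effch × techch in every aggregate row;
arithmetic means are available as an option for replicating tables built
with other software. Static efficiency scores aggregate arithmetically.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes —
not any particular real data set. For DMU j, period t:

* inputs xᵢⱼₜ log-uniform on [1, 10] (m = 2 by default);
* frontier output y* = Aₜ Πᵢ xᵢ^βᵢ e^{−u}, with β = (0.4, 0.4) by default
  (Σβ < 1: strictly concave, VRS-consistent; set β summing to 1 for CRS),
  Hicks-neutral drift A_{t+1} = (1+γ)Aₜ with γ = 0.03/period, and
  half-normal inefficiency u ~ |N(0, σ_u²)|, σ_u = 0.3 (a standard
  stochastic-frontier convention);
* one u = 0 DMU per period (the period's minimal u is zeroed), so the
  true frontier is always attained and frontier-shift recovery is exact;
* 11 observable output indicators = softplus(2 + f·loading + σ_e ε) with
  σ_e = 0.5, where the 4 latent factors split the indicators into blocks
  of 3/3/3/2, factor 1 is the standardized log of y*, and small uniform
  cross-loadings (±0.1) keep the structure realistic. Softplus keeps
  indicators positive and monotone in their factor while approximately
  preserving the factor correlation block structure, so Kaiser selection
  recovers 4 components.

Recovery designs used by the tests and the acceptance script set
n_inputs = 1, β = (1.0) (CRS) and score the *aggregate* output y*
noise-free; there the SBM ranking reproduces the true e^{−u} ranking and
estimated techch equals 1+γ to solver precision. These are the designs'
intended behavior, not a general claim: with noisy indicators, multiple
inputs, or PCA-compressed outputs, estimated efficiency is a biased,
bounded-support approximation of the truth, and passing tests show the
machinery is correct, not that real-data efficiency estimates are
unbiased.

## Problem sizes and determinism

The test suite and acceptance script run panels up to the default
31 DMUs × 10 periods and property suites over 100 random technologies of
8 DMUs with 2 inputs/2 outputs — sizes at which every LP solves in
milliseconds and the whole pipeline in seconds, chosen as representative
of the provincial-panel scale the package targets. All randomness flows
through explicit integer seeds (numpy default_rng); a pipeline run writes
a manifest (config hash, seed, version) that fully determines its
outputs, and reruns are byte-identical.

## Known limitations

* Only input-oriented radial distances back the Malmquist stage; an
  SBM-distance Malmquist variant is not implemented.
* No bootstrap confidence intervals, weight restrictions, window DEA, or
  undesirable-output (Malmquist–Luenberger) extensions.
* The transcribed reference correlation matrix is limited by its three
  printed decimals (see tolerances above); it validates the PCA stage
  only — the corresponding raw panel is not publicly deposited, so
  published efficiency tables themselves are not reproduction targets.
* Second-stage regressions of efficiency on covariates (e.g. Tobit) are
  out of scope.
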