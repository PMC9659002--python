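# Methods

This note documents the models, conventions and design choices behind
`fim-riskweight`: what each stage computes, where the underlying published
procedure left details open and how this implementation fixed them, what
the synthetic generator does and does not emulate, and the numerical
conventions used throughout.

## Observation unit and quintile classification

The study design reports 100 countries over 2006–2016 yet counts 1097
observations; only country-*years* (100 × 11 = 1100, minus 3 missing
units) reproduce that count, so the default observation unit is the
country-year, with `unit="country"` (mean annual deaths over mean annual
population) available for country-level analyses.

Quintile risk levels are assigned per variable by stably sorting the
crude rates (ties keep original row order, so the procedure is
deterministic and seed-free) and cutting at sorted ranks ⌈n·k/5⌉,
k = 1..4. At n = 1097 this yields group sizes (220, 219, 220, 219, 219);
the published frequencies (219, 221, 217, 221, 219) imply a slightly
different, unstated tie-handling, and downstream stages consume only the
level assignments, so no attempt is made to match those counts exactly.
A constant column carries no ordering information and is assigned level 1
throughout, with a warning. Observations missing any variable are
dropped listwise before classification.

## Chi-square weights (A1)

The published worked example prints a 2×5 "observed" table with
fractional entries and column totals far from the level counts; the
construction behind it is not recoverable. The implemented construction
is chosen to be computable from in-pipeline quantities while conserving
the observation count: the factor row holds, per outcome level, the sum
of the factor's *share* of each observation's total crude rate across all
30 factors, and the complement row tops each column up to the level's
observation count. Column totals therefore equal the outcome level
frequencies and the grand total equals n. The chi-square computation
itself (margins-product expected table, per-cell (O−E)²/E with zero
contribution where E = 0, df = 4, upper-tail p) is tested directly
against the published worked example and against
`scipy.stats.chi2_contingency(correction=False)`, independently of this
construction. No Yates correction is applied; fractional entries are
accepted as-is.

A consequence worth stating plainly: because the 2×5 cells are sums of
small fractional shares rather than unit counts, the Pearson statistic
under the no-association null has far less variance than the chi-square
sampling model assumes, and its p-values concentrate near 1 instead of
being uniform. The weights (ratios of statistics) are unaffected, but the
p-values should be read as descriptive indices, not calibrated tests.

## RIDIT weights (A2)

The reference distribution is the pooled outcome level frequency vector;
its mid-rank ridits `(N_{<l} + n_l/2)/N` coincide with the
Wilcoxon/mid-rank construction and have frequency-weighted mean exactly
0.5. The published per-variable "RIDIT value" column is not reconcilable
with group-mean ridits (which would all be ≈ 0.5) and its formula is not
stated; the implemented per-factor score is a standard effect-size
reading of Bross's method — the frequency-weighted mean absolute
deviation of group-conditional mean outcome ridits from 0.5, ranging from
0 (no association) to 0.5 (perfect separation), invariant to relabeling
of the factor's level identities. The published normalization contract
(value column / printed total = weight column) is preserved.

## AHP weights (A3)

The packaged 30×30 Delphi matrix violates reciprocity in three pairs
(e.g. a(UWS, USN) = 8 but a(USN, UWS) = 1). Reciprocity is therefore
*checked and reported*, never enforced, and all computations run on the
matrix as given — reproducibility over orthodoxy, with loud diagnostics.

The default prioritization method is column normalization followed by row
means, selected for two reasons: the published matrix prints its column
sums (the signature intermediate of that variant), and the published
priority vector is reproduced by it to ~1e-4 — once one notices that the
published values were computed in the matrix's row order but printed
against the variable list's order, which swaps the Smoking and IDY
labels. Geometric-mean and principal-eigenvector (power iteration,
tolerance 1e-10, ≤ 10 000 iterations, λ_max estimated as mean of
(A·w)/w) methods are selectable; all three agree to 1e-9 on consistent
matrices. Saaty's RI table covers n ≤ 15 and is extrapolated linearly
above with a logged caveat; CR is defined 0 for n < 3. At n = 30 the
packaged matrix has CR ≈ 0.21 — above the conventional 0.1 bar, reported
but not acted on.

## Membership matrix, reference vector and nearness

The fuzzy membership matrix R is under-specified in the source
procedure; the implemented entry for factor v and class l is the level-l
agreement rate — the fraction of observations at level l of v whose
outcome level is also l — with each row renormalized to sum 1. This uses
only in-pipeline quantities and reduces to intuitive degenerate cases (a
point mass for a single observation, a uniform row for a factor identical
to, or independent of, the outcome). All-zero rows are replaced by
uniform rows with a warning.

The reference vector C defaults to the outcome's own rate mass by level,
`C_l = Σ rates at level l / Σ rates` (increasing across levels whenever
higher levels hold higher rates), and may be supplied directly in config
— the packaged published nearness table does exactly that. Composed
vectors `B = A·R` are normalized after composition, consistent with the
published table whose reconstructed vectors sum to ≈ 100%.

Nearness uses the lattice form σ = ½[(B⊗C) + 1 − (B⊙C)] with ⊗ = max-min
and ⊙ = min-max; σ is symmetric, lies in [0, 1], and the selected group
is the argmax with ties broken by the fixed order chisq, ridit, ahp (with
a logged notice). All internal math is in proportions; percentages appear
only at I/O.

## Random-forest stage

The forest is scikit-learn's `RandomForestClassifier` (Gini impurity)
constrained to the published tree design: depth ≤ 5, ≥ 10 cases to split
a node, ≥ 5 per leaf. The ensemble size is unstated in the source; the
default is 100 trees for stable importances (a single-tree mode is one
config field away). The 663/1097 training fraction is applied as a
stratified-by-outcome-level split (stratification is unstated in the
source but avoids degenerate folds with 5 classes); importances are
normalized mean impurity decreases, and the ranking breaks ties
alphabetically. The outcome is the 5-class LCM level. Published
accuracy on the original extract is not a target here: it depends on
external data, and with permutation-noise levels the test accuracy sits
at the 0.2 chance level, as it should.

## Synthetic generator

The generator emulates the *structure* of a GBD result extract, not its
marginals: 100 countries × 11 years, 30 factor rates plus the outcome,
3 missing country-year units (so 1097 observations per variable, matching
the study scale). Each country draws a latent severity z ~ N(0,1) and a
lognormal population around 1e7; each variable draws a per-country
baseline log-rate N(μ_v, σ_v) (defaults: log 5e-5, sd 0.6; outcome log
4e-4, sd 0.6) plus per-year noise N(0, 0.2). Informative factors
(default: Smoking, LPA, CW, LBW, IDY at effect 1.0) add effect·z to their
log-rate; the outcome adds z itself. Deaths are rounded rate×population
(tiny rates may round to zero deaths; the pipeline consumes rates, so
this is harmless). A single shared latent factor is the simplest
structure producing the monotone factor–outcome association the quintile
cross-classification is designed to detect.

What passing tests on this generator do **not** show: robustness to real
GBD features such as heavy-tailed country effects, secular time trends,
spatial correlation, age-structure confounding, or non-monotone
associations. Note also that years within a country share its baseline,
so the effective number of independent units is the number of countries;
null-association checks are calibrated against √(n_countries), not
√(n_observations).

## Problem sizes and runtime

Tests run the full study scale (1097 observations, 31 variables) where
the claim depends on it — parameter recovery and null calibration use 20
seeds at full scale — and small instances (25–40 countries, 3 years)
elsewhere. A complete end-to-end synthetic run takes a few seconds on one
CPU; the whole test suite runs in well under a minute.

## Known limitations

- The chi-square p-values are descriptive, not calibrated (see above);
  the weights and rankings built from the statistics are unaffected.
- The RIDIT per-variable score and the membership-matrix construction are
  principled substitutes for under-specified published steps; their
  downstream consumers are tested independently via the published
  composition tables.
- The AHP stage consumes one expert matrix as given; no multi-expert
  aggregation or Delphi-round simulation.
- No cartographic or GBD-download functionality; inputs are local CSVs.
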