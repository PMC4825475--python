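# Methods

## Model and fitting

Cell counts of the multiway visit-frequency table are modelled by
hierarchical log-linear models under multinomial sampling. A model is
identified by its generating class (the maximal interaction terms);
every non-empty subset of a generating term is implied. Expected
frequencies are the maximum-likelihood fit, computed by iterative
proportional fitting (IPF): starting from a flat table, cycle through
the generating terms rescaling the fitted table to each observed margin.

Numerical choices:

- Convergence: maximum absolute margin discrepancy < 1e-8, at most
  1,000 cycles. The tables here have at most 72 cells, so the tight
  tolerance costs nothing; the five-way published model converges in a
  few dozen cycles. Non-convergence returns the fit flagged rather than
  raising.
- Zero observed margins force the matching fitted cells to zero (the
  boundary ML solution) with a warning. The published table has no zero
  cells (minimum 2); no flattening constant is added by default. For
  sparse user data the CLI exposes `--delta`-style flattening by adding
  0.5 before fitting (`FrequencyTable(axes, counts + 0.5)`).
- Goodness of fit: G² = 2 Σ o·ln(o/f) with 0·ln(0/f) ≡ 0; Pearson
  X² = Σ (o−f)²/f over cells with f > 0. Degrees of freedom are cells
  minus free parameters, one block of Π(sizeᵢ−1) parameters per implied
  term plus the grand mean. IPF fits were cross-checked against an
  independent dummy-coded Poisson GLM (statsmodels) to 1e-4 in G².

## Model selection

Backward elimination from the saturated model: at each step every
maximal term of the current class is a deletion candidate; deleting a
term replaces it with its one-smaller subsets not already implied
(keeping the model hierarchical). The candidate with the largest
likelihood-ratio p-value (ΔG² on Δdf against χ²) is removed while that
p-value exceeds α = 0.05. Ties prefer the higher-order term, then
alphabetical order, for determinism. Candidates are maximal terms only;
on this data, allowing any implied effect as a candidate (deleting its
ancestors with it) selects the same classes.

On the packaged table this reproduces the published GP-model class
{L·A·S, A·S·G} and SD-model class {L·V, L·A·S, A·S·V} exactly. For the
five-way model the published class {L·V, L·A·S·G, A·S·G·V} is **not**
recovered at α = 0.05: the four-way L·A·S·G term is removable with
p ≈ 0.15–0.17 in every elimination context (LR or Pearson change, any
candidate rule, with or without 0.5 flattening), and elimination
continues to {L·V, L·A·S, A·S·G·V}. The published class is recovered
only near α = 0.2, consistent with the original report flagging the
L·A·S·G-derived contrasts at "90% significance". The selector therefore
keeps the stated α = 0.05 default, while the table-reproduction routine
(`reproduce_tables`, `carequity reproduce`) fits the *published* classes
— its purpose is to recompute the published odds-ratio tables — and
reports the selector's own outcome alongside. The corresponding
acceptance test states the published five-way class and fails; this is
a property of the data, not of the implementation.

## Odds ratios and intervals

Conditional odds ratios come from fitted cells at fixed strata. A free
axis with no model term joining it to both the outcome and the contrast
leaves the OR identical at every level (checked to 1e-8 relative); it is
then reported once. When a joint interaction exists (the five-way
model's GP-by-SES contrast, which the A·S·G·V term makes depend on the
specialist axis), an evaluation convention is required: the default
evaluates at the interacting axis's reference level (not-visited, the
last category), matching a dummy-coded parameter contrast as in the
original software's output; a geometric mean across levels is available as
an alternative (`--or-convention geomean`; the two differ by < 0.2
here).

Confidence intervals are Woolf intervals, exp(ln OR ± z·se) with
se = √(1/a+1/b+1/c+1/d) on the *observed* 2×2 obtained by fixing the
strata and summing over generalized axes; z = 1.96 at 95%, exact normal
quantiles otherwise. Observed (not fitted) counts reproduce the one
hand-checkable published interval, (1.54, 2.20), exactly. The two
starred five-way rows are reported at the 90% level (z = 1.645), which
reproduces their printed bounds exactly and matches the original
report's "90% significance" remark (its table header says 95%). Two
printed intervals (specialist use among young GP-visitors) are wider
than any margin-based interval — model-based standard errors from the
original software's information matrix, which this package does not
attempt (point estimates still agree).

## Reproduction tolerances

Recomputed point estimates are compared with the published tables at
one unit in the last printed digit (±0.01), except the specialist-model
(Model SD) rows at ±0.04. Twenty of 24 rows agree exactly at 2 dp. The
four that do not are printing/rounding artifacts of the original
tables, not fitting differences:

- GP model elderly/young ratio: margins give (529/1007)/(908/7685) =
  4.4462 → 4.45 vs printed 4.46 (the original text itself rounds it
  to "4.5").
- SD model rows 1.05 / 4.66 / 2.93 vs computed 1.058 / 4.691 / 2.948
  (≤ 0.7% apart) — consistent with the original values being chained
  exponentials of 2-dp-rounded software output.

The acceptance tests assert the stricter bands (exact at 2 dp for the
GP block, ±0.02 for the SD block), so the 4.46 and 4.66 cases fail by
design; the remaining 19 published values pass.

## SES index

Raw codes are grouped monotonely onto 1–5: occupation {1}{2,3}{4–6}
{7–9}{10,11}, education {0,1}{2}{3}{4,5}{6}, SEC clusters in pairs. The
original report does not print its groupings; these near-even, monotone
defaults are configurable per run. The housing item is
1 + 4·(ln(rooms·SEC) − min)/(max − min), clipped to [1, 5], with the
min/max taken from the analysis dataset and stored in the run metadata
(the original says only "adjusted"). The composite score is the item
mean; tertiles use closed-right intervals (score ≤ cutoff → lower
group), so printed cutoffs act as boundaries belonging to the lower
tertile. Respondents with any missing item are excluded and counted.
Cronbach's alpha is the definitional variance formula (ddof = 1), plus
the standardized variant from the mean inter-item correlation. The
published cutoffs (2.31/3.18) and alphas (0.68/0.70) require the
undeposited microdata and are documentation, not test targets.

## Synthetic data

The generator defines a full joint truth over (location, age, SES,
GP visit, SD visit): cell probabilities ∝ exp(Σ λ-terms) with
reference-category (dummy) coding, so exponentiated λ contrasts are
conditional odds ratios at reference strata. Tables are multinomial
draws; microdata additionally receives raw-coded SES items from a
shared latent trait (itemⱼ = z + εⱼ), quantile-mapped onto the survey
code ranges. Defaults: mean inter-item correlation 0.37 (puts alpha for
k = 4 items near 0.70; the realized value lands in [0.6, 0.8] after
discretization), tertile latent means (−1.2, 0, 1.2) with spread 0.55,
visit counts 1 + Poisson(0.4) for visitors.

The `survey_like_spec` preset mirrors the survey's published structure:
location mix ≈ (16%, 31%, 53%), ~15% elderly, ~13% GP and ~6%
specialist visitors, SES-by-location gradient (55% low SES peripheral
vs 26% central), pro-poor elderly GP use (≈1.8) and pro-rich young
specialist use (≈0.5). These magnitudes are presets for demonstration
and testing, not estimates of the real survey.

What the generator does and does not emulate: it reproduces the joint
categorical structure and the index's measurement design, including the
fact that the housing item ln(rooms·SEC) mechanically shares the SEC
cluster with the cluster item — so even with a zero latent correlation
target, alpha retains a structural floor ≈ 0.2 (cluster–housing r ≈
0.65, all other pairs ≈ 0). It does not simulate household clustering,
nonresponse, survey weights, or item-specific response styles; passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to those real-data
features.

Recovery checks (all seeded, run in the test suite): fitted conditional
ORs track exp(λ) within 3 Monte-Carlo standard errors over 20
multinomial draws of n = 50,000; backward elimination recovers a
three-term generative class with |λ| ≥ 0.3 in ≥ 90% of 50 replicates at
n = 50,000. Problem sizes were chosen so the whole suite runs in a few
seconds on one CPU.

## Known limitations

- Model-based (information-matrix) standard errors and profile
  likelihood intervals are out of scope; intervals are Woolf-on-margins.
- Selection p-values are nominal χ² without correction for the stepwise
  search.
- Survey weights are not supported (the original analysis uses
  unweighted counts).
- The printed source table totals 28,968 respondents while the original
  demographic table prints 28,962; the fixture follows the printed
  cells, whose location-by-age margins match the demographic table
  exactly.
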