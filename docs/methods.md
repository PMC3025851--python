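# Methods

## The assay model

The unit of analysis is one receptor construct (a GAL4 DNA-binding domain
fused to a corticosteroid receptor ligand-binding domain) treated with one
steroid at a ladder of molar doses, read out as luciferase luminescence.
All activity is expressed as *fold-activation*: raw luminescence divided by
the mean luminescence of the vehicle (ethanol) wells of the same construct.
Vehicle wells define the baseline and are consumed by normalization; they
are never fitted as data points.

Dose dependence is modeled as a logistic in dose. The default
three-parameter form (3PL) pins the zero-dose response at the
vehicle-normalized baseline of 1:

    f(x) = β₁ + (1 − β₁) / (1 + (x/β₂)^β₃)

with β₁ the upper bound (fold units), β₂ the EC50 (molar, the dose of
half-maximal response) and β₃ a dimensionless shape. The four-parameter
form (4PL) frees the zero-dose asymptote β₀:

    f(x) = β₁ + (β₀ − β₁) / (1 + (x/β₂)^β₃)

and is intended for constructs that show measurable activity at even the
lowest doses, where forcing the curve through 1 distorts the fit. With
β₀ = 1 the 4PL reduces exactly to the 3PL, and the test suite checks that
the two fits then agree.

## High-dose exclusion (the d_M rule)

Transactivation responses frequently rise and then *fall* with increasing
steroid dose, a pattern attributed to cytotoxicity at high doses. Fitting
through the decline biases the upper bound, and consequently the EC50,
downward. The pipeline therefore computes the per-dose mean response,
takes d_M as the dose of maximum mean, and fits only points at doses
≤ d_M. Two deliberate choices:

- **Ties.** If the maximum mean is attained at several doses, d_M is the
  largest of them. The rule exists to remove a decline; a tie is not a
  decline, so nothing between tied maxima is dropped.
- **Idempotence.** After truncation the maximum mean sits at the largest
  remaining dose, so re-applying the rule is a no-op (property-tested).

## Multistart least squares and fit selection

Nonlinear logistic fits can converge to local minima, so every fit is run
from a grid of starting points: β₁ ∈ {2, max observed mean, 2× max},
log₁₀ β₂ at the 25/50/75% quantiles of the observed log-doses, β₃ ∈
{0.5, 1, 2} — 27 starts (β₀ starts at 1 for the 4PL). Each start is
minimized with bounded trust-region least squares (`scipy.optimize.
least_squares`) on log₁₀(dose), with the EC50 parameterized as log₁₀ β₂
for numerical symmetry across a five-decade ladder. Bounds: β₁ ∈
(0, 10 × max observed mean), β₂ ∈ (10⁻¹³, 10⁻³) M, β₃ ∈ (0.05, 10),
β₀ ∈ (0, 5). Cost/step/gradient tolerances are 10⁻¹⁰ (configurable via
`FitConfig`).

Among converged starts, the smallest residual sum of squares (RSS) wins.
When several fits tie within 1% relative RSS, the fit whose EC50 lies
inside the observed dose range is preferred, and failing that the smallest
EC50 — an EC50 extrapolated beyond the ladder is not trustworthy, and this
operationalizes "most reasonable fit" reproducibly. Setting the tie window
to zero recovers strict best-of-starts RSS dominance, which is how the
dominance property is tested.

By default all replicate observations enter the least squares
(`fit_means=True` switches to per-dose means). A series whose responses
all lie within 0.05 fold-units of baseline is flagged `no_activation`
rather than fitted; its EC50 is undefined and `estimate_ec50` raises.
EC50s are reported in nM (β₂ × 10⁹), the natural scale for a
10⁻¹¹–10⁻⁶ M ladder.

## Single-dose screening

The screen asks, per receptor × ligand at one dose (default 10⁻⁷ M),
whether mean fold-activation exceeds 1: a one-sample t-test, one-sided
because only activation (not repression) is the hypothesis, at α = 0.05.
Calls: `+` if significant with mean > 1, `0` otherwise, `NA` when fewer
than two replicates or zero variance make the test undefined (the reason
is recorded). No multiple-testing correction is applied by default,
matching per-ligand testing practice in this assay literature; a Holm
option exists. α, dose and sidedness are package decisions surfaced in
`ScreenConfig`, not facts about any particular published screen.

## Discriminating-site scan

A column is discriminating iff every group-A sequence carries one residue,
every group-B sequence carries a single different residue, and no grouped
sequence has a gap in the column. Gap-bearing columns are excluded
outright because indel differences are not substitutions. Exactly two
groups are supported — the sensitive/insensitive design — and alignment
coordinates are 1-based. Coordinate mapping to full-length receptors is an
offset table (`mouse: +537`, `human: +531`, extensible), so LBD position 1
maps to 538/532.

## Trait lability on trees

Binary-character lability is quantified as the minimum number of state
changes on a rooted tree, computed by unit-cost small parsimony via
postorder dynamic programming (Sankoff with a 0/1 cost matrix). This
handles polytomies natively and is invariant to root placement because the
cost is symmetric. Tips with state `unknown` (or absent from the state
table) contribute no constraint. The report calls the trait
*single-origin consistent* iff the minimum is ≤ 1 — one origin (or one
loss) suffices; a count ≥ 2 means the sensitivity pattern cannot be
explained by shared ancestry alone. Parsimony rather than a likelihood
model was chosen deliberately: the question is qualitative and a single
integer answers it without a rate model; branch lengths are ignored.

## Synthetic data: what it emulates and what it does not

The dose-response generator draws raw luminescence as
`vehicle_mean · f(x) · c(x)` times multiplicative Gaussian noise
(sd = CV × mean, truncated at zero — reporter noise scales with signal),
where `c(x) = 1 / (1 + (x/tox_dose)^tox_shape)` is a smooth Hill-type
cytotoxic decline. The published record motivating this package notes the
decline qualitatively but not its magnitude or form; the Hill factor was
chosen for smoothness and two interpretable parameters, and its defaults
(half-effect well above the ladder) are free simulation knobs, not
calibrated quantities. Defaults mirror standard assay design: six ten-fold
doses 10⁻¹¹–10⁻⁶ M, three replicates, CV 0.1 (a typical luciferase
replicate scatter), baseline 100 counts.

The alignment generator plants discriminating columns on a fully conserved
background plus distractor columns that are non-discriminating by
construction (within-group variation, residues shared across groups, or
gap-bearing columns at a configurable rate).

Not emulated: transfection-efficiency variation, plate/batch effects,
heteroscedasticity beyond the CV model, receptor expression differences,
or realistic phylogenetic correlation among alignment sequences. Passing
tests therefore demonstrate correctness of the *procedures* under the
stated noise model, not robustness to every artifact of real reporter
data.

## Recovery experiments and problem sizes

Because raw measurements behind published corticosteroid EC50 tables are
not available, EC50 accuracy is assessed by parameter recovery: 200
simulated series per planted EC50 under the default conditions, each run
through the full pipeline, summarized by the median fitted EC50
(`corspec.recovery.ec50_recovery`; per-series sub-seeds spawn
deterministically from one seed). 200 series gives a median stable to a
few percent while keeping a five-entry experiment around two minutes on
one core. Median recovery is within ~10% of the planted value across the
0.2–120 nM range; a small upward bias at sub-nM EC50s is a property of
the d_M truncation interacting with multiplicative noise near the bottom
of the ladder, and sits well inside the 25% band used by the acceptance
checks.

## Known limitations

- EC50s more than ~10× outside the dose ladder are reported but flagged
  (`ec50_outside_dose_range`); they are extrapolations.
- The no-activation flat tolerance (0.05 fold-units) is a heuristic; weak
  true activation below it is indistinguishable from baseline.
- The screen's false-positive rate equals α per pair by design; callers
  screening many ligands may prefer the Holm option.
- The parsimony count treats the tree as known and error-free; uncertainty
  in the topology is not propagated.
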