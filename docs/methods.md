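# Methods

## The model

`crit` links a feature of the first matrix in a chain to features of the
last when the matrices do not share a single common index, only pairwise
ones: the columns of matrix *k* are indexed by the same identifier set as
the rows of matrix *k+1*. Writing the chain M¹, M², …, Mⁿ with index sets
I⁰, I¹, …, Iⁿ, an initial two-class labeling L⁰ of M¹'s columns is obtained
from a chosen source feature; at step *k* the labeling is transferred to the
rows of Mᵏ⁺¹, the rows are sliced by label, each column *j* is tested for a
difference between the slices, and the calls form the next labeling
Lᵏ = fᵏ(Mᵏ, Lᵏ⁻¹). After the final step, every column labeled *sensitive*
is paired with the source feature as a *cross pattern*, annotated with the
final step's p and q, the traversed label path, and the per-step
statistics.

The motivating structure is chemogenomic: a drug-property table (properties
× drugs), a drug × deletion-strain fitness-defect connector (larger value =
more growth disruption), and a protein-property table. A drug property is
median-split into hi/lo drugs; proteins whose fitness-defect profiles
separate hi from lo drugs become property-sensitive; protein properties
that separate sensitive from insensitive proteins close the pattern.

### Assumptions

- Each step's test is a two-group comparison; multi-class discriminators
  are deliberately out of scope.
- Per-step inference: the significance attached to a cross pattern is the
  final step's p/q. No chain-wise combined error rate is computed — the
  intermediate tables are all retained so the inference chain can be
  audited, but propagated uncertainty across steps is an open problem.
- One source feature per run. The sweep mode iterates runs over source
  features with per-run, per-step correction; no correction is applied
  across source features.

## Discriminators and labelers

**Median split** labels identifiers *hi* when strictly above the median of
the non-missing values (even count: mean of the central pair), *lo*
otherwise; ties at the median go *lo* — a fixed convention for determinism.
Missing values stay unlabeled and propagate as untestable.

**Welch's t** is the continuous discriminator's test:
t = (x̄ − ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ), df by Welch–Satterthwaite, two-sided p.
Both variances zero with equal means gives (t=0, p=1); with unequal means
the column is untestable ("degenerate variance"). Slices smaller than
`min_group_size` (default 3, the smallest n giving a defined Welch df on
both sides) are untestable ("min_group_size"). Missing entries are dropped
column-wise, which is strictly more permissive than discarding whole rows;
a `drop_missing_rows` preprocessing directive recovers the stricter
behaviour. Tests are two-sided throughout; the sign of t is retained so
directional patterns remain recoverable.

**Sensitivity score.** Alongside t, the continuous discriminator records
(mean_hi − mean_lo)/(se_hi − se_lo) with se = s/√n. The denominator is a
*difference* of standard errors: it can be zero (score reported missing) or
negative, so the score is a descriptive field only — inference always uses
Welch's t. Whether that denominator was meant to be the pooled standard
error √(se_hi² + se_lo²) is unknowable from the source prose; both the
verbatim score and the Welch statistic appear in every step table.

**Hypergeometric tail** is the binary discriminator's test: with the rows
holding value 1 as the white balls (m), value 0 as black (n), and the rows
carrying the first label as the draws (k), p = P(X ≥ x) inclusive, where x
is the observed number of white draws. Computed via scipy's stable survival
function; exactness for small urns is verified against exhaustive draw
enumeration. Categorical matrices are first expanded to one binary feature
per category (`col=category`, sorted order; multi-category cells set
several features; empty cells are all-zero).

**Multiple testing.** Benjamini–Hochberg step-up q-values, computed per
step across that step's testable columns only; untestable columns are
excluded before correction and labeled insensitive. A column is called
sensitive when q < α (default 0.05), or p < α when a step is configured
with `correction: none` — the chemogenomic screen used uncorrected
P < 0.05, so correction is per-step configuration.

## Preprocessing

Mirrors the filters a fitness-defect connector needs: `variance_filter`
keeps rows/columns whose sample variance strictly exceeds a threshold
(1.5 in the original screen — below that one is only in the noise);
`drop_rows` removes named strains (e.g. efflux/transport mutants affected
non-specifically); `clip_resistance` masks negative-defect entries
(strains growing *better* under drug), since resistance is a different
phenomenon from sensitivity. The sign convention (higher = more disrupted)
is explicit configuration.

## Numerical and degenerate-input choices

- Identifier matching is exact, case-sensitive string equality.
- Chains are validated as *sets* and row orders canonicalised to the
  previous matrix's column order, so positional transfer is valid and
  chain construction is invariant to input row permutations.
- A step that produces a single-class labeling before the chain is
  exhausted ends the run with a structured partial result (`halted`,
  `halted_after`) rather than an exception, keeping sweeps over hundreds of
  source features alive on degenerate splits.
- Tier assignment uses strict inequality (p < threshold), matching the
  "P < c" figure conventions; the two printed threshold triples
  (10⁻⁴/10⁻³/0.05 and 10⁻³/0.01/0.05) ship as constants.
- The distribution-overlap summary integrates the minimum of two
  proportion-normalised histograms on a shared 64-bin grid — a
  deterministic, figure-free analogue of overlapping density plots.

## The synthetic generator

`SyntheticSpec` builds a three-matrix chain with planted ground truth:
sources are split 50/50 into hi/lo and the continuous source property is
drawn strictly above/below zero consistent with the split, so the median
split recovers the planted labels exactly and the full path — labeler,
transfer, slicing, testing — is exercised. The connector is Gaussian noise
(sd `noise_sd`, default 1) with the truly *sensitive* mid columns
(`frac_sensitive_mid`, default 0.25) shifted by `effect_size`·`noise_sd`
(default 3) in hi-source rows; the final table is standard Gaussian with
*informative* features (`frac_informative_final`, default 0.25) shifted by
`final_effect_size` (default 2) in sensitive-mid rows. Defaults describe a
moderate chemogenomic-style study: 100 sources, 200 mid entities, 50 final
features. A binary-connector variant flips Bernoulli rates (0.1 → 0.9)
between slices for the hypergeometric discriminator.

Gaussian mean shifts were chosen because they make the Welch screen's
power and FDR analytically predictable, which is what the calibration
tests assert. The generator does **not** imitate heavy-tailed real fitness
distributions, correlated features, or batch structure — passing tests
show the inference machinery is calibrated under its stated model, not
that any particular biological dataset satisfies that model.

## What the validation computes

`scripts/acceptance.py` and the test suite measure, at fixed problem sizes
chosen to exercise the study design (1,000 null columns for uniformity;
200 replicates for FDR/power; 100 replicates end-to-end):

- KS uniformity of step-1 p-values under a null chain, and mean BH false
  discoveries per null run;
- empirical FDR of the step-1 screen at a moderate shift (δ=1.5, 25%
  sensitive) and empirical power at δ=2;
- power and FDR of full-chain cross-pattern recovery under the default
  planted design;
- byte-identical determinism of repeated runs, engine/discriminator
  equivalence on two-matrix chains, and label-path replay consistency.

## Known limitations

- No combined chain-wise error rate; q-values control FDR within a step.
- Two-label discriminators only.
- Dense in-memory matrices only (the motivating instances are a few
  hundred by a few thousand).
- The asymmetric variant of the property × property count table is not
  provided: the intended row/column semantics of the original asymmetric
  table are unclear, so only symmetric pairwise-intersection counts are
  emitted.
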