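# Methods

`tfrtrace` models multicolor Cre-lox ("Confetti"/Brainbow2.1) lineage
tracing of FoxP3+ regulatory T cells — peripheral Tregs and follicular Tfr —
in mixed bone-marrow chimeras, and implements the clonality statistics used
to read such experiments out. This note records the model, its assumptions,
the defaults and why they were chosen, and what the synthetic cohorts do and
do not capture.

## Cassette recombination model

Each cassette copy gets a single Bernoulli recombination chance during the
tamoxifen pulse, with probability `r` per copy; a recombined copy commits to
one of four fluorophores (nGFP, YFP, RFP, mCFP) with probabilities
`p = (p_nGFP, p_YFP, p_RFP, p_mCFP)`. Copies are independent and share
`(r, p)`. For a homozygous carrier (two copies) the observable states are
"unlabeled", 4 single colors, and 6 two-color combinations — ten labeled
states, because two copies recombined to the same fluorophore are
indistinguishable from one. Closed form:

    P(unlabeled)  = (1 − r)²
    P(single a)   = 2r(1 − r)·p_a + r²·p_a²
    P(pair {a,b}) = 2r²·p_a·p_b            (a ≠ b)

and `P(labeled) = 1 − (1 − r)^copies`. Assumptions: no inter-copy
interference, no continuous "leaky" labeling after the pulse (the protocol
is a single gavage), and no spectral channel overlap — misclassification is
available separately as an optional row-stochastic confusion matrix applied
at observation time. `p` defaults to uniform (¼ each); empirical Brainbow
outcome frequencies are non-uniform, so the divergence baseline can instead
be estimated from observed counts (`baseline_from_counts`), and that
empirical route is preferred whenever counts are available.

Whether nGFP is reliably separable from mCFP/YFP in a given imaging setup is
instrument-dependent; the model keeps all four fluorophores and leaves any
exclusion to configuration.

## Synthetic cohorts

A `ScenarioConfig` specifies one in-silico chimera experiment:

* **Chimerism.** Donor compartments are mixed in stated parts (e.g. 1:1:1,
  so a single Confetti donor contributes one-third of the Treg pool);
  radio-resistant host Tregs are a single configurable fraction. Origin
  genotypes are multinomial in these fractions.
* **Labeling.** Labelable FoxP3+ cells draw a color state from the cassette
  model at day 0.
* **Founding.** Per mouse, follicles are founded by
  `founders_per_follicle` cells sampled without replacement from the FoxP3+
  pool (plus a T-zone compartment with `tzone_founders` founders); color and
  origin are clonally heritable. No inter-follicle migration is modeled —
  whether Tfr clones redistribute between neighboring follicles is an open
  biological question, and the no-migration default is an explicit
  assumption of this simulator.
* **Growth.** Each day, per compartment, clone sizes are redrawn
  multinomially around Dirichlet-perturbed previous proportions with
  concentration `α·k` (`α = expansion_concentration`, `k` = live clones).
  Expected proportions are preserved, so `α → ∞` is exchangeable
  (polyclonal) growth and small `α` produces oligoclonal takeover — one
  knob spans exactly the contrast the statistics are meant to detect. The
  compartment grows multiplicatively by `growth_rate` per day up to
  `homeostatic_target`, which doubles as the carrying capacity before and
  after ablation; no published growth law exists for these populations, so
  this is the package's own minimal choice.
* **Go-dark.** Each labeled clone is independently replaced by an unlabeled
  clone of equal size with per-day probability `go_dark_rate` — whole-clone
  replacement, the simplest mechanism by which pooled labeling density can
  wane while follicles that remain labeled keep their labeled-cell counts.
* **Ablation.** Each DTX administration removes each cell of ablatable
  origin independently with probability `ablation_efficiency`; survivors
  then expand back to `homeostatic_target`, either proportionally to size
  (polyclonal recovery) or Dirichlet-reweighted (oligoclonal recovery).
  Only the schedule (start day, cadence) and outcome ratios are constrained
  by observation; the per-dose kill rate is a free parameter.
* **Observation.** Per follicle, `cells_sampled_per_follicle` cells are
  drawn without replacement (the T-zone is censused and serves as the
  empirical baseline pool); the optional misclassification matrix is
  applied to labeled states only. Tissue labels are annotation-only.

Seeds are mandatory and identical configurations produce byte-identical
output tables.

### What the generator does not emulate

No germinal-center B-cell dynamics, no antibody output, no spatial geometry
or imaging point-spread, no tissue-specific dynamics, no TCR-level clonal
identity (color is the only clonal mark, as in the experiment, so distinct
clones sharing a color are conflated), and no mouse-level random effects.
Passing tests therefore demonstrate internal consistency of the model and
statistics, not fidelity to any particular biological dataset.

## Clonality statistics

* **Labeling density** — labeled (XFP+) fraction of a gated population.
* **Clonal dominance** — frequency of the most abundant color state among
  labeled cells; ties report the canonically first state.
* **Clonal divergence index** — distance between observed labeled-state
  frequencies and a baseline ("random") color distribution. Default metric
  is total variation distance, `½ Σ|f_s − b_s|`, which is bounded in [0,1]
  and interpretable as the largest discrepancy in probability assigned to
  any set of states; Euclidean distance is available by option. No
  published formula exists for the divergence index used in the motivating
  imaging protocol, so the metric is configurable and the default is
  documented rather than guessed.

Unlabeled cells are excluded (frequencies renormalized) before dominance
and divergence. The baseline defaults to the empirical pooled T-zone
labeled-state frequencies of the cohort when available — the T-zone Treg
pool is the natural non-clonally-selected reference — else the theoretical
labeled distribution from the cassette model.

Both statistics are biased upward at small counts: a handful of cells from
a perfectly polyclonal pool looks dominant and divergent. `bias_profile`
quantifies this (null mean vs n, asserted non-increasing), and all
inference is against a multinomial null at the matched sample size.
Follicles with fewer than `min_cells` labeled cells (default 5) report
missing values rather than meaningless ones.

### Resampling null and p-values

`null_statistics` draws `reps` (default 10,000) multinomial samples at the
observed n from the baseline and computes the statistic on each. P-values
are upper-tail with the add-one construction, `(#{null ≥ obs} + 1)/(reps + 1)`,
which is valid (super-uniform) under the null even with ties. Because the
statistics are discrete, tied null samples make this conservative; a
randomized tie-breaking variant (`p_value(obs, rng=...)`) is exactly
uniform under the null and is what the calibration tests exercise.
`classify_expansion` calls a compartment oligoclonal when the divergence
p-value falls below `alpha` (default 0.05), indeterminate below the cell
threshold.

## Group comparison

`compare_groups` is the two-sided Wilcoxon–Mann–Whitney test. When both
groups have ≤ 12 observations the p-value is exact by full enumeration over
all C(n1+n2, n1) assignments of the midranks (counted by subset-sum dynamic
programming); larger samples use the normal approximation with tie
correction. Follicles are treated as the statistical unit; mouse-level
clustering is noted in report metadata but not modeled.

## Power analysis

`power_analysis` collapses the clone-growth model to the color level: a
follicle's color proportions are Dirichlet-perturbed around the baseline
with concentration `effect·k`, `n_cells` cells are drawn, and
`classify_expansion` is applied. Power is the oligoclonal-call fraction.
The polyclonal limit (`effect = ∞`) reduces to the null, so power ≈ alpha
there; at `n_cells = 1` the statistic is degenerate (every draw ties the
null), the add-one p-value is 1, and power collapses to 0 — single cells
carry no clonality information.

## Packaged scenarios

Four fixture configurations run in seconds each:

* `waning_godark` — monoclonally founded follicles (fast growth to capacity
  before the first observation, so counts depend on go-dark only) with
  `go_dark_rate = 0.05`/day, observed at days 4/18/32; pooled labeling
  density wanes geometrically while still-labeled follicles keep counts.
* `baseline_polyclonal` — stable polyclonal follicles, no ablation.
* `ablation_polyclonal` — 1:1:1 mix (one-third labelable, two-thirds
  ablatable), DTX every 3 days at per-dose efficiency 0.6 from day 4,
  proportional recovery; follicular labeled counts rise sharply while
  dominance and divergence distributions do not shift.
* `ablation_oligoclonal` — same schedule with strongly skewed
  (concentration 0.04) Dirichlet growth and recovery; follicles that retain
  labeled cells are called oligoclonal.

Default cohort sizes (3 mice, 12–40 follicles/mouse, carrying capacity 150
cells, 40 cells sampled per follicle, tens of labeled cells per follicle)
were chosen to match the scale of two-photon per-follicle counting
experiments — tens of follicles per group, few to tens of labeled cells
each.

## Numerical choices and edge cases

Probability vectors must sum to 1 within 1e-12 (state distributions) or
1e-9 (baselines, misclassification rows). Canonical state order (nGFP <
YFP < RFP < mCFP; singletons before pairs) fixes serialization and all
tie-breaks. Degenerate inputs: zero gated cells, empty compartments after
total ablation, and under-seeded founder pools produce explicit
below-threshold results or warnings rather than errors. All file outputs
use LF newlines and sorted JSON keys; identical seeds reproduce outputs
byte-for-byte.

## Known limitations

The go-dark mechanism is whole-clone replacement at a constant rate, not
gradual dilution; ablation efficiency is constant per dose; colors, not
TCR sequences, define clones; and the homeostatic carrying capacity is a
single shared constant per compartment type. These are the minimal
mechanisms consistent with the phenomena being modeled, not fitted
quantities.
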