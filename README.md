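# tfrtrace

In-silico multicolor lineage tracing of follicular regulatory T cells.

Germinal centers (GCs) are policed by FoxP3+ T-follicular regulatory cells
(Tfr). Whether Tfr populations clonally expand, wane, or stay polyclonal
during chronic autoimmune GC responses can be read out with the
Confetti/Brainbow2.1 reporter: a tamoxifen pulse stochastically commits each
cassette copy to one of four fluorophores, so homozygous cells display one
of ten color combinations that are inherited clonally. `tfrtrace` makes
that whole experimental chain reproducible in silico for researchers
analyzing such experiments or planning their statistics: a generative model
of cassette recombination, a seeded simulator of mixed bone-marrow chimera
cohorts (labeling, follicle founding, clone growth, diphtheria-toxin
ablation with homeostatic recovery, labeled-clone "go dark" replacement,
per-follicle sampling), and the clonality statistics with matched-n
resampling nulls.

## Model and statistics

With per-copy recombination probability *r* and fluorophore probabilities
*p* (independent copies), the observable-state distribution of a homozygous
cell is closed-form:

    P(unlabeled)  = (1 − r)²
    P(single a)   = 2r(1 − r)·p_a + r²·p_a²
    P(pair {a,b}) = 2r²·p_a·p_b        (a ≠ b)

so the labeling density is 1 − (1 − r)². On observed cells the package
computes, per follicle:

* **labeling density** — XFP+ fraction of gated cells;
* **clonal dominance** — max_s f_s, the frequency of the most abundant
  color state among labeled cells;
* **clonal divergence index** — ½ Σ_s |f_s − b_s|, the total variation
  distance from a baseline ("random") color distribution *b*.

Both dominance and divergence are biased upward at small counts, so
inference is against multinomial(n, b) resampling nulls at the matched n,
with upper-tail add-one p-values; `classify_expansion` turns this into a
polyclonal-vs-oligoclonal call. Group contrasts use the exact
Wilcoxon–Mann–Whitney test (full enumeration for small groups). See
`docs/methods.md` for the full model.

## Worked example

Simulate partial Treg ablation with proportional homeostatic recovery, the
key perturbation experiment: one-third of the marrow is Confetti-labelable,
two-thirds is ablatable, and DTX is given every 3 days.

```python
from tfrtrace import RecombinationModel, state_distribution, labeled_fraction
from tfrtrace.io import fixture_config
from tfrtrace.pipeline import run_scenario, compare_groups

model = RecombinationModel(allele_recombination_prob=0.6)
print(f"P(labeled) = {labeled_fraction(model):.2f}")

bundle = run_scenario(fixture_config("ablation_polyclonal"))
fol = bundle.follicle_stats.query("compartment == 'follicle'")
pre, post = fol[fol.day == 3], fol[fol.day == 15]
print(f"labeled cells/follicle: day 3 = {pre.n_labeled.mean():.1f}, "
      f"day 15 = {post.n_labeled.mean():.1f}")
gc = compare_groups(pre.n_labeled.to_numpy(), post.n_labeled.to_numpy())
print(f"rank-sum p = {gc.p_value:.2e}")
for col in ("dominance", "divergence"):
    gc = compare_groups(pre[col].dropna().to_numpy(),
                        post[col].dropna().to_numpy())
    print(f"{col}: day3 {pre[col].mean():.3f} vs day15 {post[col].mean():.3f}, "
          f"p = {gc.p_value:.3f}")
```

prints

```
P(labeled) = 0.84
labeled cells/follicle: day 3 = 11.4, day 15 = 31.6
rank-sum p = 2.38e-11
dominance: day3 0.509 vs day15 0.567, p = 0.263
divergence: day3 0.575 vs day15 0.617, p = 0.318
```

Read: at r = 0.6 a homozygous cassette labels 84% of labelable cells.
Ablating the unlabeled-origin two-thirds of the compartment nearly triples
the Confetti+ count per follicle (homeostatic expansion of survivors,
p ≈ 10⁻¹¹), while clonal dominance and divergence do not shift (p > 0.05) —
the signature of *polyclonal* recovery. Swapping in the
`ablation_oligoclonal` fixture (skewed Dirichlet growth) instead drives
dominance toward 1 and the divergence test calls follicles oligoclonal.

The same pipeline is scriptable from the shell:

```sh
tfrtrace fixtures --out fixtures/
tfrtrace simulate --config fixtures/ablation_polyclonal.yaml --out out/
tfrtrace stats --cells out/cells.csv --baseline empirical
tfrtrace null --stat divergence --n 30 --reps 10000 --seed 1
```

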