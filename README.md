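# herbmine

Classical Chinese medical formularies record tens of thousands of
multi-herb prescriptions, but the texts are unsegmented and the herb
pairings buried in them are hard to survey systematically — a real
obstacle for researchers looking for substitute herbs (for instance,
replacements for ingredients from endangered species). `herbmine` is a
small toolkit for mining such texts end to end:

1. **Entity extraction** — structural regular expressions for the
   recurring entry shapes (herb lists with parenthesized preparation
   notes such as 乾薑(炮); 治…方 symptom lines; 湯-named formula blocks)
   plus a greedy longest-match-first dictionary tagger for unsegmented
   text, run iteratively with a review-list workflow that grows the
   lexicon.
2. **Association-rule mining** — a from-scratch Apriori implementation
   over the per-entry herb itemsets ("transactions"), reporting
   support, confidence, lift, leverage, and conviction:
   `supp(X→Y) = P(X∪Y)`, `conf = P(X∪Y)/P(X)`,
   `lift = P(X∪Y)/(P(X)·P(Y))`, `leverage = P(X∪Y) − P(X)P(Y)`,
   `conviction = (1−P(Y))/(1−conf)`.
3. **Co-occurrence statistics** — phylum (disease-chapter) × herb and
   gene–herb literature-count contingency tables, tested with Pearson's
   chi-square (grand total > 30) or an exact Freeman–Halton/Fisher test
   (total ≤ 30), both implemented from first principles.
4. **Network export** — the weighted herb/formula co-occurrence graph
   as edge-list TSV and GraphML.
5. **Generation** — a keyword-level LSTM language model (pure numpy:
   forward, BPTT, Adam, temperature sampling) that proposes novel herb
   compositions from the mined sequences.

Because the source e-books cannot be redistributed, the package ships a
first-class synthetic-corpus generator that emulates the entry shapes
and plants herb-pair dependencies with exact target support and
confidence, together with ground-truth annotations — every downstream
stage is testable offline against known truth.

## Worked example

```python
from herbmine import corpus_synth as cs, extraction as ex
from herbmine.association import apriori, generate_rules, rank_rules, rules_to_dataframe

spec = cs.default_spec(n_entries=2000, seed=0)   # plants 蜜–甘草 at s=0.93, c=0.99
texts, gt = cs.generate_corpus(spec)
entries = [(t.entry_id, x) for t, x in zip(gt.transactions, texts)]
annotated = ex.annotate_corpus(entries, spec.lexicon)
transactions = [t.items for t in ex.build_transactions(annotated)]
rules = rank_rules(generate_rules(apriori(transactions, 0.8)), key="support")
print(rules_to_dataframe(rules[:2]).to_string(index=False))
```

prints

```
antecedents consequents  antecedent support  consequent support  support  confidence  lift  leverage  conviction
     ['甘草']       ['蜜']               0.933               0.940    0.933       1.000 1.064     0.056         inf
      ['蜜']      ['甘草']               0.940               0.933    0.933       0.993 1.064     0.056       8.997
```

The mined honey→licorice support (0.933) sits within sampling error of
the planted 0.93, and the mined confidence (0.993) matches the planted
0.99: the miner recovers the dependency structure the generator put in.

The bundled reference count matrix (eight widely used herbs across
eleven disease chapters of a classified formulary) reproduces the
published independence test:

```python
from herbmine.reference import phylum_herb_counts
from herbmine.stats import chi_square_independence

res = chi_square_independence(phylum_herb_counts())
print(f"Statistic: {res.statistic!r}.")
print(f"Degree of freedom: {res.dof}.")
```

```
Statistic: 695.2055226775681.
Degree of freedom: 70.
```

with p ≈ 1.0e-103 — herb usage is strongly chapter-dependent.

## Command line

```bash
herbmine run-all --out-dir runs/demo --n-entries 500 --seed 0
```

runs synth → extract → mine → stats → network → train → generate, each
stage writing its declared plain-text outputs plus a manifest (package
and library versions, seeds, SHA-256 of inputs). Individual subcommands
(`synth`, `extract`, `mine`, `stats`, `network`, `train`, `generate`)
accept a flat YAML config via `--config`; flags override the file.
Defaults follow the study settings: `min_support 0.8`,
`sample_threshold 30`.

## Documentation

`docs/methods.md` describes the models, the synthetic-data design and
its limitations, numerical choices, and default parameters.
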