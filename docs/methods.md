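# Methods

## Entity extraction

Classical formulary text has no word separators, so extraction never
tokenizes: it operates on the raw character sequence.

**Structural patterns.** Five regular expressions cover the recurring
entry shapes: (1) an herb token immediately followed by a parenthesized
preparation/dosage note (both full-width （） and half-width () are
accepted; the note is captured separately and excluded from the herb
term); (2) a 治…方 symptom/prescription line; (3) a formula name ending
in 湯 on its own line followed by a 治… indication block; (4) a
one-line 治…用… entry; (5) its two-line variant with the 用… usage on
the next line. The herb-list splitter returns each whitespace-delimited
token as an (herb, preparation) pair; an unbalanced parenthesis flags
the entry with a warning and returns the pairs found before the defect.

**Dictionary tagging.** The tagger scans left to right and, at each
position, tags the longest lexicon term starting there; the scan
resumes after the span, so tagged characters can never be re-segmented
into a second match. This is a deliberate design choice over global
longest-match: it is linear-time, order-stable, and it is the behaviour
implied by sorting a tagging dictionary longest-first. Its one known
bias — a long term starting earlier wins over an even longer term
starting one character later — does not arise in whitespace-delimited
herb lists.

**Iteration.** Patterns propose candidate terms; a plain-text review
list (term TAB category) stands in for interactive curation and is the
only way a candidate enters the lexicon; accepted terms are union-merged
(set union, duplicate exclusion, category conflicts resolved
formula > herb > adjunct and logged) and the corpus is re-tagged until
a fixpoint or the iteration cap. Review terms never proposed by any
pattern are warned about and skipped.

Honey (蜜) and vinegar (醋) are processing adjuncts rather than
therapeutic herbs; they are tagged with category `adjunct` and included
in transactions by default (mined tables from real corpora contain
them), with an exclusion flag in `build_transactions` and the `mine`
subcommand.

## Synthetic corpora

The generator emulates what the downstream stages need from a real
formulary — entry shapes, parenthetical notes, unsegmented text,
itemset dependencies — not classical prose. Each entry draws one of the
four structural shapes above (weights 0.4/0.2/0.2/0.2), a symptom
phrase from a fixed pool, preparation notes from a fixed pool, and
optional noise tokens from a character pool disjoint from every lexicon
term.

**Planted dependencies.** For each planted pair (X, Y, s, c) the
antecedent is drawn with probability s/c and the consequent with
probability c given the antecedent; the consequent does not otherwise
occur (planted herbs are excluded from the independent background
draw, default rate 0.3 per herb). This makes the pair support exactly s
and the forward confidence exactly c in expectation, independently
controllable. Two consequences worth knowing: planted pairs must be
pairwise disjoint (shared herbs would couple the samplers; the spec
validator enforces this), and the reverse-direction confidence
P(X | Y) is exactly 1 because Y never appears without X — visible in
mined output as conviction = inf for the reverse rule. Real corpora
have neither property; passing recovery tests shows the miner measures
what the sampler planted, not that real herb pairs behave this way.

Default planted levels follow the headline mined pairs from the
published tables: 蜜–甘草 at support 0.93 / confidence 0.99, an
angelica-type pair at 0.91 / 0.98, and 大黄–黄芩 at 0.801 / 0.94, with
n = 2000 entries.

The emitted ground truth (0-based half-open character spans per entry;
one itemset per entry) is exact by construction, which is what makes
the round-trip criterion (tagging recovers ground truth with
precision = recall = 1 at zero noise) a meaningful test of the tagger
rather than of the generator. What the corpus does **not** model:
linguistically coherent prose, dosage semantics, herbs appearing inside
symptom text, OCR noise, or lexicon gaps (those are tested separately
via withheld-term review fixtures).

## Association mining

Level-wise Apriori with transaction-id-set intersection for exact
counting; candidates are joined from (k−1)-itemsets sharing a prefix
and pruned by anti-monotonicity. An itemset is frequent when
count/n ≥ min_support (float comparison on the exact ratio). Rules are
emitted for every frequent itemset and every nonempty proper subset as
antecedent, with no confidence cut-off and no size cap (published
tables show 4-item antecedents); ranking is a stable sort with
lexicographic tie-breaks. Conviction uses +inf as the sentinel at
confidence 1. Display rounds to 3 decimals; internal values are full
precision. The default mining threshold is `min_support = 0.8`, the
study setting.

A note on reproducing published metric columns from published supports:
supports printed at 3 decimals propagate to roughly ±0.002 in
confidence and lift, so only some printed rows reproduce exactly at 3
decimals (the honey↔licorice confidences and rhubarb↔skullcap lifts do;
a few others differ in the last digit). The bundled reference rows are
checked exactly where exact reproduction is arithmetically possible and
within 0.002 everywhere. Published conviction columns are not checked:
they are not consistent with the printed (rounded) supports under any
standard definition, indicating they were computed from unrounded
values not available to us.

## Contingency statistics

`choose_test` switches on the grand total of the table: chi-square
above the threshold (default 30), exact test at or below it — the
boundary goes to the exact test as the conservative choice. The
"sample" in the rule is read as the table's grand total; expected
counts below 5 trigger a warning but never switch the method.

Chi-square: E = (row ⊗ col)/N, X² = Σ(O−E)²/E, dof = (r−1)(c−1), no
continuity correction, p from the χ² survival function.

Exact test: one generic Freeman–Halton path for any r×c — a
depth-first enumeration of all tables with the observed margins (cells
bounded by remaining row/column totals, last row and column forced),
summing multivariate hypergeometric probabilities ≤ the observed
table's probability (relative tolerance 1e-7 for float ties, matching
common practice). For 2×2 this reduces to the usual two-sided Fisher
test and agrees with scipy to ~1e-15. Enumeration is capped
(default 2×10⁶ tables) and raises beyond the cap, pointing to
chi-square.

Gene–herb tables are 3×2: candidate herb / control herb (licorice
plays this role in practice) / positive-control preparation as rows,
literature counts for a gene pair as columns. Live literature queries
are out of scope; a query-string builder and a counts-CSV reader stand
at the boundary. Significance stars: ** below 0.01, * below 0.05. No
multiple-testing correction is applied by default, matching the
published analysis; a Benjamini–Hochberg column (statsmodels) is
available behind a flag. The heat-map transform is log2(count + 1) —
the pseudo-count keeps zero counts at zero and preserves monotonicity.

## Network

Herb–herb edge weight = number of transactions containing both
endpoints; when an entry carries a formula name, bipartite formula–herb
edges are added by the same counting rule (the published figure shows
both node kinds without stating its edge rule; co-membership is our
documented choice). `sample_pairs` draws k edges uniformly without
replacement with a seeded generator, returning everything with a
warning when k exceeds the pair count. Layout and visualization are out
of scope; exports are edge-list TSV and GraphML.

## LSTM generator

Token unit is the extracted keyword, not the character — the corpus the
model sees is the comma-separated keyword serialization of extraction,
so characters would re-open the segmentation problem the lexicon
already solved. Each transaction encodes as
`BOS [formula] SEP herb₁ … herb_k EOS` with herbs in first-appearance
order (itemsets are unordered; a sequence model needs an order; the
choice is recorded in the transaction files and reversible).

The model is a stacked LSTM (gates i, f, g, o; forget-gate bias
initialized to 1) with tied-nothing embedding, implemented entirely in
numpy — forward, backpropagation through time, Adam (β = 0.9/0.999),
global-norm gradient clipping at 5 — and gradient-checked against
central finite differences in the test suite. Training is next-token
cross-entropy with end-padding; padded targets are masked, and because
padding is terminal the masked positions contribute exactly zero
gradient. A non-finite loss aborts with a diagnostic. Defaults are desk
scale: embedding 64, hidden 128, 1 layer, dropout 0.1, batch 32,
lr 1e-3, configurable epochs. CPU is the supported mode.

Sampling is autoregressive with temperature scaling (temperature 0 =
greedy); PAD is masked out of the support, generation stops at EOS or
`max_len`, and the reported log-probability is the model's
temperature-1 log-probability of the continuation. Determinism: a fixed
config seed fixes initialization and the training batch order, and a
fixed sampling seed fixes generations; checkpoints (single .npz with
parameters, vocabulary, and config) reload to identical outputs.

There is no accepted quality metric for generated formulas; the desk
test is memorization — a one-sequence corpus trained 200 epochs must be
reproduced verbatim by greedy decoding (final loss < 0.1 nats/token) —
plus a loss-decrease check (epoch-10 < epoch-1 mean loss) on the
synthetic corpus.

## Problem sizes and tolerances

The test suite runs on 300-entry corpora for fixtures and 2,000-entry
corpora for the round-trip and parameter-recovery checks — 2,000
entries is where the 3σ binomial bound (≈0.017 at s = 0.93) becomes a
tight, meaningful recovery criterion while the whole suite stays in
seconds. Oracle comparisons use 200 random datasets (≤10 items, ≤64
transactions) for Apriori and 100 random 2×2/3×2 tables with total ≤ 40
for the exact test; both equalities hold to float precision
(p-difference ≤ 1e-10 asserted, ~1e-15 observed). Support/confidence
recovery tolerances are the binomial sampling bound and ±0.05
respectively; they are properties of the planted design, not tuned
numbers.

## Known limitations

- Left-to-right greedy tagging is a documented choice, not the only
  reading of "sort keywords by length"; a global-longest-match variant
  could tag differently on adversarial lexicons.
- The synthetic corpus validates mechanics, not linguistics: precision
  and recall of 1.0 there say nothing about recall on real classical
  prose with lexicon gaps.
- The exact-test enumeration is exponential in table size; it is meant
  for the small literature-count tables the selection rule routes to
  it.
- The generator's samples are itemset-shaped text, not clinically
  meaningful prescriptions, and no clinical claim is made or
  implied.
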