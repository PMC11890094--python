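# Methods

## Problem and model

GEM-style metadata associates genome-editing (GE) articles with genes but
not with the role each gene played in the study. `geinfo` models that role
resolution as a structured-extraction task followed by a supervised
evaluation and an unsupervised ranking. The unit of curation and evaluation
is the *annotation pair* — one (gene, article) combination. Two roles are
scored:

* **GE_target**: the gene was directly edited. Curation label 1 = confirmed
  target; 0 = not a target; 2 = target in a non-default (non-human)
  species, with the correct species recorded in a memo column.
* **GE_deg**: the gene's expression changed because *other* genes were
  edited. Label 1/0 as above; label 2 marks pairs excluded from GE_deg
  scoring because they are already targets — an extraction model may infer
  expression changes in an edited gene without textual support, so scoring
  those pairs would reward hallucination.

Counting rules: label 1 → TP if the extracted list contains the gene else
FN; label 0 → TN if absent else FP; label 2 → TP only if the gene is
present *and* the extracted species matches the memo. A label-2 pair that
fails the species check is counted FN, including when the gene itself was
extracted: the gene-in-context was not correctly recovered. Only the TP
condition for label 2 is externally fixed; FN for the remainder is this
package's convention, and such cases are logged distinctly so a user can
re-score them as FP.

Metrics are the standard confusion-matrix ratios; values are reported
rounded to 4 decimal places (half-up, matching conventional display
precision). Undefined ratios (no predicted or no condition positives) are
NaN with a warning rather than 0, so degenerate runs are visible.

## Matching conventions

Gene matching between curation, query and extracted lists is
case-insensitive exact string equality after trimming; both the symbol and
the numeric gene ID of a pair are tried. No alias expansion is performed —
exact matching is auditable, and alias tables can be applied upstream.
Species matching is case-insensitive substring containment in either
direction after a small common-name table maps vernacular names (human,
mouse, rat, …) to binomials. Both conventions are deliberately simple; they
are stated here because the choice is not externally constrained.

## Prompts and parsing

Two built-in templates are shipped as plain-text files with `{{SLOT}}`
placeholders: `round1` (title + abstract, adds three free-text summary
fields) and `round2` (title, abstract, methods, results plus GEM tool
context; adds phenotypes). Rendering is pure substitution — list slots are
joined with ", ", absent sections become empty strings — so prompts are
byte-reproducible. Each required slot must occur exactly once; an
unrecognized slot is fatal.

Backend output parsing takes the longest balanced brace-delimited span that
parses as an object, trying strict JSON first and a Python-literal fallback
for single-quoted output, after discarding code fences; a final fallback
strips `//` comments. The `'Not mentioned'` sentinel the prompts request is
normalized to an empty list, extended to `None` and empty-string variants
(case-insensitive, trailing period tolerated) to absorb spelling drift. A
missing field becomes an empty list with a logged warning; an unparseable
response yields a `parse_failed` record with empty lists, never an
exception. Backends get one retry on failure so batch length stays equal to
article count.

## Ranking

Per-gene `ge_target_count` and `ge_deg_count` are **distinct-article**
counts: the available granularity is the article, and a gene repeated
within one record counts once. Each metric column is min–max normalized;
lower-is-better metrics are complemented (1 − x′) so understudied genes
rank higher. A constant column normalizes to all zeros: no spread means no
information, and the convention avoids division by zero. The cumulative
score is Σ w·x′; weights need not sum to 1 and scores are reported
unscaled (rankings are invariant under positive rescaling of all weights —
property-tested). Ties break by ascending gene symbol for deterministic
output. Defaults: weights 0.35 / 0.15 / 0.45 / 0.05 for `ge_target_count`,
`ge_deg_count`, `meta_analysis_score`, `pd_score`, with `ge_target_count`
and `pd_score` lower-is-better; all configurable via the flat YAML config.
When no custom-metric table is supplied, the CLI scores on the two
literature-derived metrics alone rather than failing on absent columns.

## Synthetic corpus and mock extractor

The generator emulates the statistical shape of a curated GE literature
subset, not its language. Each article draws 1–3 genes (weights
0.75/0.20/0.05), and each (gene, article) pair independently draws a role:
target with probability 0.39, differentially-expressed 0.24, collection
error 0.08, otherwise studied-but-unrelated. These defaults mirror the
category proportions observed in manual curation of GEM annotation pairs
(~39% targets, ~24% deg, with a noticeable artifact fraction); the default
scale is 260 articles, matching the size of a manually curatable benchmark.
15% of articles study a non-default species, exercising the label-2
pathway with the species memo filled. Role facts are realized as one
unambiguous sentence per fact from fixed templates (e.g. "*GENE* was
knocked out using *TOOL* in *SPECIES*."), so a regex-based mock extractor
recovers the truth exactly; collection-error genes appear in the entry
table but nowhere in the text. Articles, GEM entries, ground-truth records
and the curation table are cross-validated on every generation and emitted
in exactly the formats the pipeline readers consume.

The mock backend resolves the article from the prompt's TITLE section,
recovers the truth, then injects errors per an error profile: each true
gene is dropped with the role's FN rate, and each decoy candidate is added
with the FP rate. Decoys are drawn from the article's own entry-table genes
excluding true positives — and, for GE_deg, excluding targets — so every
injected error corresponds to a curated pair that actually enters
evaluation, making the injection log an exact oracle for the confusion
matrices. Draws are seeded per article from (profile seed, pmid), so
results are deterministic and independent of batch order. The default
profile reproduces the per-pair FP/FN rates implied by the confusion
matrices of a strong published extraction run (FP 9/163 and FN 4/103 for
targets; FP 18/98 and FN 6/65 for deg), i.e. it emulates a realistic
model's tendency to over-interpret context (more FP than FN).

What passing synthetic tests shows — and does not. They verify the
selection, prompting, parsing, evaluation and ranking machinery exactly,
including error accounting at configured rates. They say nothing about any
real language model's extraction quality on real articles: real text is
ambiguous, multi-species, and not sentence-templated. Live-service numbers
(database retrieval counts, a specific published gene ranking) depend on
database snapshots and commercial model outputs and are out of scope;
optional live adapters are deliberately not bundled.

## Numerical and design choices

* Rounding: metrics 4 decimals, percentages 2, both half-up via `decimal`.
* Duplicate (gene, pmid) pairs collapse to one during selection; symbol
  matching for selection uses the same normalization as evaluation.
* List-valued CSV cells use a configurable `|` delimiter (export dialects
  vary).
* Invalid entry rows are rejected with their row index and logging by
  default (`strict=True` raises), so one bad row does not discard a table.
* Config is declarative YAML with unknown keys rejected, rather than
  executable configuration; exit codes are 0 / 1 / 2 for ok / user error /
  internal error.
* The acceptance script derives all seeds from `--seed` and uses the
  study-condition defaults above; problem sizes are 260 articles for
  end-to-end runs and 1000 articles where ≥1000 negative pairs are needed
  for binomial rate checks.

## Known limitations

* The gold-standard schema assumes one species memo per pair; extraction
  records store species at article level, as the prompts do, so
  multi-species articles with per-gene species qualifiers are not
  representable.
* The common-name species table is intentionally tiny; unusual vernacular
  names fall back to substring matching and may miss.
* Evaluation requires a record for every curated pmid and fails loudly
  otherwise; partial extraction runs must be filtered before scoring.
* The synthetic generator's one-fact-per-sentence articles make parsing
  trivially easy by construction; realism is explicitly not a goal.
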