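# Methods

This note documents the models, conventions and design choices behind
`seqdash`, in the order data flows through the package.

## Input model

The universal input is a gene × sample count matrix with genes in rows and
samples in columns. Readers never guess orientation; a transposed matrix is
the caller's error, surfaced as a key mismatch when tables attach. Counts may
be fractional (upstream quantifiers emit expected counts); non-negativity and
finiteness are the only value constraints. Sample covariates and gene
annotations are plain tables keyed by `sample_id` / `gene_id`; attachment
reorders them to the matrix order and treats any unmatched key on either side
as an error rather than a silent drop. Missing p-values in a DE table are
rejected at read time rather than imputed, because every downstream view
sorts or filters on them. Missing annotation fields (e.g. a gene without a
symbol) are carried as nulls and display as empty table cells.

## log-CPM

`log2((y + c) / (N + 2c) × 10⁶)` with prior count `c > 0` (default 0.5) and
library size `N` the column sum. The `2c` denominator offset pairs with the
numerator prior so the transform is monotone in the count at fixed library
size and finite everywhere, including all-zero samples. The prior is exposed
as a parameter on every entry point that computes expression values.

## Leading-logFC distance and MDS

Between two samples the distance is the root mean square of the `top`
largest absolute log-CPM differences (`top` defaults to 500, capped at the
gene count). Two gene-selection modes are exposed: `pairwise` picks the top
genes independently for each sample pair (the default, most sensitive to
pair-specific structure); `common` picks one gene set — the `top` genes with
largest log-CPM variance across all samples — and uses it for every pair.
With `top ≥ n_genes` both reduce to the full RMS distance of log-CPM
columns, and the distance is invariant to adding a per-gene constant.

Embedding is classical (Torgerson) scaling: `B = −½ J D² J` with `J` the
centering operator, symmetric eigendecomposition, coordinates
`v_k √λ_k` for positive eigenvalues, requested `k = n_samples − 1`.
Numerical conventions:

- Eigenvalues within `n · eps · max(|λ|)` of zero are treated as zero.
- Negative eigenvalues (non-Euclidean distances — possible because the
  leading-logFC distance is not guaranteed Euclidean) are dropped from both
  the coordinates and the variance-explained denominator; their total
  magnitude is logged at INFO level.
- Variance explained is `λ_i / Σ_{λ>0} λ`, i.e. proportions over positive
  eigenvalues only, reported per retained dimension and non-increasing.
- Each coordinate column's sign is flipped if needed so its
  largest-magnitude entry is positive. MDS is sign-ambiguous; fixing the
  convention makes exported documents byte-reproducible.
- Asymmetry beyond 1e-8 in a supplied distance matrix is an error, not
  silently symmetrized.

Two-sample inputs are allowed with a warning (the single dimension is
trivial); the widget exposes every retained dimension in its axis dropdowns
rather than a fixed count.

## Multiple testing and status calls

`bh_adjust` is the Benjamini–Hochberg step-up: sort ascending, compute
`p_(i) · m / i`, enforce monotonicity with a running minimum from the largest
rank downward, cap at 1, return in input order. The automatic status call
uses the supplied `adj_p` column when present, otherwise BH on the raw
p-values at `alpha = 0.05` — the documented default of the upstream
decide-tests conventions this mirrors — with `lfc_min = 0` (no fold-change
floor) by default, since the auto-highlight behaviour being reproduced does
not state one; both are parameters. An explicit status vector always wins,
as the escape hatch for callers with their own calling rules.

For volcano axes, `p = 0` is clamped to half the smallest nonzero p in the
vector (fallback 1e-300 if all are zero): finite axes without a fixed magic
ceiling.

## Widget documents

A widget document is a plain JSON-serializable record: embedded data tables,
field→channel encodings per panel, control descriptors (dropdowns, search,
numeric inputs, buttons) with options and defaults, an interaction contract,
and meta (schema version, creation parameters, palette names). The internal
validator checks that every encoded field exists in its panel's table, that
every dropdown has options, and that serialize→parse→serialize is an
identity; documents are rendered with sorted keys and no timestamps so
rendering is deterministic.

Conventions worth noting:

- The expression panel's x-tick labels carry a −45° rotation attribute
  (45° anticlockwise) so many group labels stay legible.
- `max_y_axis` fixes the expression y-domain upper bound; the lower bound is
  then `min(0, data minimum)` (only the maximum is user-fixed). Without it,
  the panel auto-scales per selected gene.
- The shape channel is restricted to discrete covariates with at most 8
  categories — the number of glyphs the runtime guarantees; excess
  categories are an error rather than glyph recycling. Continuous covariates
  get continuous colour ramps, discrete ones categorical palettes; the
  defaults (`viridis`, `category10`) are recorded in `meta` for
  reproducibility.
- MA and volcano documents embed identical expression payloads for identical
  inputs; only the summary encodings differ.

## Selection state machine

Linked-view behaviour is a two-mode machine: `IDLE` (no selection) and
`GRAPH_SELECT` (non-empty selection), with the invariant `IDLE ⇔ selection
empty` enforced structurally. Point clicks and table-row clicks share one
toggle semantic; the selection preserves insertion order and tracks the most
recently added member for the expression panel; `search` is an orthogonal
table filter that never touches the selection; `clear` empties it. The
machine is a pure function (`apply_event`) returning the new state plus view
directives, which makes the full behaviour testable by exhaustive
enumeration — every event sequence of length ≤ 4 over a 3-gene universe is
checked against a click-parity oracle. Hover tooltips remain active in all
modes; nothing in the contract suppresses them while a selection exists.

## HTML export

Standalone rendering inlines the runtime script, styles and interaction glue
into one document; the widget document itself travels as a JSON data island
(`<script type="application/json">`) with `</` escaped as `<\/` so arbitrary
content cannot terminate the tag, and is recovered bit-exactly by
`extract_payload`. The runtime is a compact hand-written SVG renderer
vendored with the package (scatter panels, bar panel, linked table, tooltip,
selection strip, PNG/SVG/CSV save buttons); it is deliberately small so a
rendered file's size is dominated by the data and grows linearly with gene
count. Fragments get sequenced container ids so several widgets coexist in
one page. Pixel-level correctness of the PNG/SVG rasterization is delegated
to the browser and not asserted anywhere; tests cover the wiring (buttons,
formats, scopes) and the payload round trip.

## Synthetic data

The simulator emulates a small bulk RNA-seq design: baseline per-gene means
log-uniform over a 1–1024 relative-abundance range; a chosen number of DE
genes receive ±`lfc_magnitude` (random sign) in the last group; per-sample
library sizes uniform over 0.8–1.2 million reads; counts negative binomial
with common dispersion 0.05 (biological CV ≈ 0.22, typical of genetically
identical model-organism samples — the demonstration scale this package
targets is three replicates per cell population). All draws flow through one
seeded generator, so fixtures are bit-reproducible. Default problem sizes in
tests and the acceptance script — 1000 genes, two groups of three, 100 DE
genes at |logFC| = 2, 20 seeds — are desk-scale renditions of that design.

What the generator does **not** model: single-cell zero inflation, batch
effects, gene–gene correlation, length/GC biases, or outlier samples.
Passing end-to-end tests therefore demonstrate that the pipeline recovers
planted structure under a clean NB model, not that any particular real
dataset will separate or yield a given recall.

The fixture DE test is a per-gene pooled-variance two-sample t-test on
log-CPM (logFC = difference of group means, ave_expr = overall mean). Genes
with zero pooled variance get p = 1 — no evidence rather than undefined — so
the output is total. It exists to produce structurally realistic DE tables
for the dashboards and tests; it is not a recommended tester, and with three
samples per group its power is modest by design (end-to-end checks use
loose bounds: mean recall > 0.5, mean empirical FDR ≤ 0.10, which guard
plumbing rather than power claims).

Column sub-sampling for cell-level matrices is uniform without replacement,
order-preserving, seed-reproducible, with the sample table subset
consistently; the sub-sample size is entirely the caller's choice.

## CSV export

One row per in-scope gene: annotation columns (everything in the DE table
that is not a recognised statistic), then statistics
(`logfc`, `ave_expr`, `p_value`, optional `adj_p`, optional `status`), then
one column per sample of log-CPM. Floats are written in their shortest
round-trip representation so re-imports are exact; fields containing
delimiters, quotes or newlines are RFC-4180 quoted. `scope="selected"` with
an empty selection is an error that points the caller to `scope="all"`.

## Known limitations

- The in-browser runtime favours clarity over scale: payloads embed dense
  log-CPM matrices, so matrices beyond a few thousand columns should be
  sub-sampled (or pseudo-bulked upstream) first.
- Only classical MDS is provided; no UMAP/t-SNE fronts.
- The CLI speaks TSV/CSV/MatrixMarket files; serialized R objects are out of
  scope by design — export tables from your upstream workflow instead.
- Panel linking is fixed (summary ↔ expression ↔ table); it is not a
  configurable dashboard framework.
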