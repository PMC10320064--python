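# Methods

## Model and procedure

The package estimates the *preferential* activity of a biological process in
a context: activity relative to the other contexts of the input matrix, not
absolute pathway activity. The input is a differential-expression matrix
*D* (genes × contexts, log2 fold-change-like values; missing entries
allowed), plus a process catalog mapping process ids to gene sets.

For process *p* and context *c*:

1. collect the values `D(g, c)` of the genes of *p* that are present in the
   matrix and non-missing in *c* (count `n_genes_observed`);
2. if `n_genes_observed < min_genes`, emit the record with the score flagged
   unavailable (NaN) — never silently drop it;
3. otherwise the score is the outlier-trimmed mean of those values
   (`n_genes_used` reports how many survived trimming).

The assumptions are minimal: values are comparable across genes within a
column (true of log fold-changes), and a process's genes are exchangeable
evidence for its activity. No inter-gene correlation structure is modeled;
the gene-sampling null below therefore tests against a background of
uncorrelated same-size gene sets.

### Trimming

`TrimConfig(fraction=0.10, mode="extreme")` is the default. "Extreme" mode
ranks values by absolute deviation from the process median and removes the
`ceil(fraction · n)` most deviant, in either direction. This reading — 10%
*total*, by extremity — targets the motivating failure mode: one gene
dramatically differentially expressed relative to the rest of its process,
in either direction. `ceil` (rather than `floor`) keeps trimming effective
for the small processes that dominate a 3–100-gene band, where
`floor(0.1 · n)` would be zero for n < 10. Ties on deviation break toward the
larger |value|, then input order, making the statistic deterministic.
A classical symmetric alternative (`mode="tails"`: drop
`floor(fraction · n / 2)` from each end) is provided for users who expect a
textbook trimmed mean, and `mode="none"` gives the plain mean. The
configuration used is frozen into `ScoreTable.params`.

Degenerate cases: if trimming would remove every value the plain mean is
returned with `n_used = n`; empty or non-finite inputs are errors.

Note one deliberate consequence of the sign-aware tie-break: translation
equivariance of the trimmed mean (shifting a column by δ shifts its scores by
δ) holds exactly except on inputs with exact ties in deviation from the
median, where the |v| tie-break may select a different value before and after
the shift. Ties have measure zero for continuous data; the property tests
assume tie-free inputs.

### Expressed-gene band

Processes are scored only if 3–100 of their genes are present in the matrix
(`filter_catalog`, closed band, counting *expressed* genes rather than raw
annotation size — a term with 500 annotated genes but 50 in the matrix is
scorable). Below 3 genes a trimmed mean is meaningless; above 100 the process
is too broad to be context-informative. Retained terms keep their full
annotated gene set plus the expressed count. Gene matching is exact and
case-sensitive by default (`case_insensitive=True` opts into upper-cased
matching); silently mixing symbol conventions is worse than a strict default.

Catalog parsing is flat: BioMart-style two-column dumps and GMT files are
used exactly as listed, with no GO-hierarchy propagation. For two-column
files, a first line whose second column matches `GO:\d+` is data; otherwise
it is skipped as a header only when its fields look like header tokens
("gene", "process_id", "term", ...). The weaker rule "non-GO second column ⇒
header" would silently swallow the first row of catalogs with non-GO
identifiers (hallmark sets, synthetic fixtures).

### Significance: gene-sampling null

The null asks: *how large a trimmed-mean score would a random gene set of the
same size produce in this same context?* For each record with
`k = n_genes_observed`, `n_null` (default 1000) size-*k* sets are drawn
uniformly without replacement from the genes observed in that context and
scored with the identical trimmed mean; null distributions are cached per
(context, k) and the draws are seeded. Then

    z = (score − null_mean) / null_sd,   p = 2 · Φ(−|z|)

Two-sided, because both preferential activity and downregulation are of
interest. The null conditions on the two obvious nuisances — the context's
value distribution and the set size — but not on inter-gene correlation; on
correlated real data p-values are anti-conservative to an unknown degree and
should be read as rankings more than calibrated probabilities. On synthetic
data with independent genes, type-I error at p < 0.05 measures 0.047 over
2000 records (`scripts/acceptance.py`). The normal approximation of the null
is the standard choice for a mean of k ≥ 3 values; `n_null ≥ 100` is
enforced, and a zero-variance null (e.g. a constant column, or k equal to the
number of observed genes) sets z = 0, p = 1 and flags the record
`degenerate_null` instead of dividing by zero. Null sd uses the sample
estimator (ddof = 1).

BH adjustment is applied across all (process, context) records as one family
by default (`bh_family="per_context"` is available; which family is intended
is genuinely open, and the table records the choice). `bh_adjust` implements
the step-up rule q(i) = min_{j≥i} p(j)·m/j directly; tests cross-check it
against statsmodels.

### Input transforms

Wide TSV is the native matrix format; long marker tables (gene, cluster,
avg_log2FC — the shape Seurat's `FindAllMarkers` writes) are pivoted, with
absent (gene, cluster) pairs flagged missing by default rather than imputed
as zero, since marker tables usually omit non-significant genes and zero is a
modeling decision the user must opt into (`fill_missing="zero"`). Missing
entries are excluded from every mean rather than imputed; the per-record gene
counts expose how much evidence each score used.

From a per-subset mean-expression table, preferential expression is computed
as a leave-one-out log-ratio:

    value(g, s) = log2( (me(g, s) + ε) / (mean_{s'≠s} me(g, s') + ε) ),  ε = 1

The pseudocount ε guards zeros and is an explicit parameter; the exact
transform used upstream of published preferential-expression matrices varies,
so this is exposed as a pluggable, documented choice rather than hidden.

### Cell-type annotation

Groups (cell type → process ids) are plain means of member process scores —
trimming applies only at the gene level, where single-gene outliers live; a
group's processes are few and already stabilized. Members without an
available score reduce `n_processes_scored` instead of contributing zeros
(zeros would bias toward small groups). Ranks are per subset, descending
score, ties broken lexicographically by label for determinism. Groups with
very few scored members are reported with their count rather than filtered;
interpreting a rank-1 group supported by one process is left to the user.

## Estimator surface

`ProcessActivityScorer` is a scikit-learn transformer (samples = contexts,
input features = genes, output features = processes); `CellTypeAnnotator`
maps a score matrix to group scores (`transform`) or top labels (`predict`).
The functional API (`compute_scores`, `score_significance`, `group_scores`,
query functions) wraps the estimators. Every plot written by `render` has a
TSV twin of the plotted values, so figures never need pixel-level testing;
heatmap color scales are diverging and anchored at 0.

## Synthetic data: what it emulates, what it does not

The generator (`PlantSpec`, `make_*`) produces the method's *input layer*:

- background values i.i.d. Normal(0, `noise_sd`) on the log2FC scale
  (default `noise_sd = 0.5`, a realistic between-context spread for most
  genes);
- planted (process, context, effect) mean shifts, defaults around
  2 log2FC for clearly context-specific biology;
- outliers as point replacements at ±10·`noise_sd` with probability
  `outlier_rate`, emulating single dramatically differentially expressed
  genes (a separate random stream, so toggling outliers preserves the
  background);
- cell-type benchmarks: disjoint term groups, each subset assigned a true
  identity whose terms are planted positively.

It does **not** emulate: inter-gene correlation, library-size or dropout
artifacts of raw scRNA-seq counts, gene-set overlap between planted terms, or
compositional coupling between contexts. Passing tests therefore demonstrate
correctness of the computation and recovery under clean planted signal, not
calibrated inference on correlated real data (see the null caveat above).

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is statistically sharp:
trimmed-mean and BH oracles on 1000 random inputs; score-table oracle on a
200-gene × 5-context × 20-term fixture; null calibration on 2000 records
(100 terms × 20 contexts, `n_null = 1000`); effect recovery and trimming
robustness over 100 seeded replicates (effect 2, `noise_sd` 0.1, term sizes
20–50, outlier rate 0.1); cell-type recovery over 100 replicates (6 cell
types × 6 subsets, 3 processes each, effect 2, `noise_sd` 0.5). The whole
suite runs in seconds to a few minutes on one CPU.

## Known limitations

- The gene-sampling null ignores gene–gene correlation (see above).
- Annotations are taken as listed; no ontology-aware propagation or
  redundancy handling between overlapping terms.
- Scores across contexts are coupled through the input matrix itself (each
  column is already "relative to the others"); adding or removing contexts
  changes the meaning of every value, which is inherent to preferential
  activity.
- The shipped interfaces read plain-text formats only (TSV, GMT); binary
  single-cell containers are out of scope — export a marker table or a wide
  matrix first.
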