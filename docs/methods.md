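# Methods

## Input model

A dataset is the triplet a Monocle3-style trajectory is flattened into:
cell metadata (`cell_id, cell_state[, covariates…]`), a genes × cells raw
count matrix (wide CSV with a `gene_id` column, or MatrixMarket plus index
files), and the trajectory itself — milestone vertices with 2-D embedding
coordinates, undirected milestone edges with nonnegative length weights, and
a cell → milestone assignment. No public schema exists for this conversion,
so the CSV dialect here is a declared convention: one trajectory file with
`[vertices]`, `[edges]` and `[assignment]` sections. A missing edge weight
means 1.0 (hop metric), since principal-graph exports do not always carry
lengths. Gene symbols are upper-cased on load and duplicates after folding
are an error rather than being summed silently. Cells present in the
metadata but absent from the assignment are retained: trajectory fitting can
drop cells from the principal graph, and such cells may still be used once
assigned.

Milestone annotation assigns each milestone the most prevalent cell state
among its cells, with ties broken to the lexicographically smallest label
(deterministic and order-independent) and the sentinel `unassigned` for
empty milestones.

## Lineage search

A candidate lineage between a start and an end cell state is a **simple
path** on the milestone graph whose first and last milestones carry those
prevalent states. All simple paths are enumerated up to `max_length` edges
(default 10) and `max_paths` results (default 100, with a truncation flag);
simple paths avoid cycling through the principal graph, and the budgets
bound the worst case. Results sort by (edge count, total weight, milestone
sequence). Endpoint matching uses milestone prevalent states, not individual
cells, because the milestone is the unit the annotation defines.

Region selection replaces interactive lasso selection with a deterministic
equivalent: the cells of a chosen subset of path milestones dilated by
`n_neighbors` graph hops (the "number of neighbors" parameter is read as
graph hops; embedding-space k-NN would be the alternative reading).

Pseudotime is single-source shortest-path distance from a user-chosen origin
milestone under edge weights — the standard principal-graph surrogate when
no velocity information is available — with an explicit `inf` sentinel for
milestones outside the origin's component. Cells inherit their milestone's
value. Terminal states are pseudotime **local maxima** (no neighbor with
strictly greater pseudotime) within the origin's component, the origin
qualifying only when isolated. This, together with the driver-gene ranking
below, is a deliberately simple, fully specified surrogate for Markov-chain
absorption machinery: it produces the same user-facing outputs (terminal
states and fate-associated genes) from quantities this package already
defines.

## Differential expression

Two self-contained methods over two disjoint regions of ≥ 3 cells each;
genes detected in fewer than `min_cells_expressing` (default 3) cells of the
union are excluded before testing, and Benjamini–Hochberg adjustment runs
over exactly the tested set.

* **wilcoxon** (default): two-sided Mann–Whitney rank-sum on log1p CPM,
  robust at small cell numbers. Rows with no rank variance get p = 1.
* **nb_wald**: per-gene negative binomial Wald test. Counts are scaled to a
  common library size, dispersion is pooled method-of-moments
  φ = (s² − μ)/μ² floored at 1e-8, and the Wald statistic compares log means
  with delta-method standard errors against a t reference with
  n_a + n_b − 2 degrees of freedom.

Reported effect size is `log2((mean_cpm_a + 1)/(mean_cpm_b + 1))` with a
pseudocount of 1 on mean CPM.

**Composition correction.** Per-cell CPM is biased whenever a minority of
genes genuinely changes: their counts inflate the library total of one
region and drag every other gene the opposite way. With 20 four-fold genes
among 500, region-A libraries grow ≈ 12%, which alone produces dozens of
spurious down-calls at 50 cells per region. Both tests therefore apply one
**between-region median-of-ratios factor** — the median over tested genes of
(mean_a + 1)/(mean_b + 1), computed as a log-space median so it is exactly
antisymmetric under region swap, and split evenly across the two regions.
This is the DESeq/TMM idea applied at the pseudobulk level; a per-cell
median-of-ratios was tried and rejected because single-cell ratio noise
leaves a systematic residual. The same phenomenon affects driver ranking,
where each cell's log1p-CPM is centered by its per-cell **median over
genes**, which tracks the shared composition trend along pseudotime and
removes it from every gene.

Calibration under the synthetic null (identical NB distributions in both
regions, 1000 genes, 50 cells/region) gives type-I error ≈ 0.04–0.05 for
both methods; with 20 planted 4-fold genes, power is ~1.0 at BH 0.05 with
pooled empirical FDR ≈ 0.03–0.05 across 20 generator seeds. Exact
concordance with external DGE packages is not a goal.

## Driver genes

Within a region whose cells all carry finite pseudotime (≥ 10 cells, ≥ 2
distinct values), each gene's composition-centered log1p-CPM is correlated
with cell pseudotime by Spearman's ρ, computed as a vectorized
rank-transform + Pearson with two-sided p from the t approximation with
n − 2 degrees of freedom; constant rows get ρ = 0, p = 1. Results carry a
direction (up/down = sign of ρ), BH adjustment, and sort by |ρ| descending.

## Preranked GSEA

The ranking metric defaults to sign(log2fc) · (−log10 p) with p clamped at
1e-300 (log2fc is available as an alternative); ties break by gene symbol
for bit-reproducibility. For a gene set S with 0 < |S ∩ list| < N, the
running sum adds |s_i|^p / Σ_{hits}|s|^p at hits and subtracts 1/(N − N_S)
at misses (weight p defaults to 1; at p = 0 this is the classical KS
statistic). ES is the extremum by absolute value, clamped to [−1, 1] against
float overshoot; when the positive and negative peaks tie exactly in
magnitude the first extremum wins, so the ES sign is tie-break-dependent in
that degenerate case. The leading edge is the in-set genes at or before the
extremum (at or after, for negative ES).

Significance uses **gene-set permutation**: `n_perm` (default 1000)
uniformly random same-size sets, one null sample per distinct overlap size,
reproducible under the seed. NES divides ES by the mean |null ES| of
matching sign; the empirical p is two-tailed on |ES|. FDR q is the
sign-stratified ratio-of-tails over the pooled null NES, clamped to [0, 1],
with a monotonicity pass so a more extreme |NES| never receives a larger q.
Sets are intersected with the ranked universe before size filtering
(min 5, max 500). Phenotype-label permutation is out of scope.

## LLM augmentation and the veracity filter

A minimal provider contract (`complete(prompt, temperature, seed) → text`)
has three backends: a **scripted mock** — a pure function of (prompt, seed)
used by every test — and OpenAI-compatible and Ollama-compatible HTTP
backends for live use only (API keys come from an environment variable
named in the config, never stored). Temperature defaults to 0.7.

The **engineered** hypothesis prompt supplies the experiment description and
the state inventory and demands, per proposed transition, at least three
supporting publication titles in a fenced line-oriented layout
(`TRANSITION: A -> B`, `RATIONALE: …`, `TITLE: …`); the **naive** prompt
asks only for transitions. The parser tolerates prose outside the fence and
is strict inside it, raising a structured error that retains the raw text.
Parsed transitions are restricted to the dataset's inventory (out-of-
inventory and self transitions are dropped with a logged reason, duplicates
merged); an engineered response with fewer than three titles is flagged
non-compliant rather than silently accepted.

Title verification normalizes both sides — unicode fold, lowercase,
punctuation stripped with hyphens as separators, digits kept, and each token
stemmed by a Porter-family stemmer implemented in `_porter.py`. Two
deliberate extensions to classic Porter: the endings `-sis`/`-ses` both
reduce to `-s` so Greco-Latin pairs like analysis/analyses unify (classic
Porter sends them to different stems), and each token is stemmed to a fixed
point so normalization is idempotent. The match statistic is the longest
common **contiguous** stemmed-token run, computed by dynamic programming; a
candidate is verified when the best run over returned titles reaches the
threshold (default 5). Note that deleting a middle token can *increase* the
run against a reference (it can bridge two runs), so monotonicity holds only
under restriction to contiguous substrings. A claim is `supported` when at
least one provider-proposed title verifies. The offline PubMed client ranks
a JSON fixture store by shared stemmed tokens; the live client targets NCBI
E-utilities at ≤ 3 requests/second with exponential backoff and is never
exercised by tests.

Prompt evaluation reports per-run precision = |pred ∩ truth|/|pred| and
recall = |pred ∩ truth|/|truth| with mean and sample standard deviation
across runs. An empty prediction set scores precision 1.0 (no false
positives) and is flagged; empty truth flags recall as undefined.

## Synthetic data

`SyntheticSpec` defaults define the study conditions: 3 states on a
6-milestone chain (topologies: chain, branch, star, random tree), 100 cells
per milestone with state purity 0.9, 500 genes of which 20 are
differentially expressed at 4-fold and 10 are drivers, NB dispersion 0.1
(variance = μ + φμ²), background means μ_g ~ LogNormal(ln 5, 1). Milestones
take designated states in contiguous blocks along a BFS order from the root;
true transitions are the designated-state pairs along edges oriented away
from the root. The DE region is the upper half of scaled pseudotime; driver
genes scale μ by exp(β · pt) with pt normalized to [0, 1] and β = ln 4. All
generators are pure functions of spec + seed.

The PubMed fixture holds one ≥ 6-word title per true transition (containing
both state names) plus decoys drawn from a disjoint vocabulary and screened
to share no 5-run with any true title. Mock LLM scripts come in three
fidelities: *faithful* (exactly the true transitions, three genuine titles
each), *noisy* (per seed variant, the true transitions plus an equal number
of spurious in-inventory transitions carrying fabricated titles — the
substrate for the engineered-vs-naive contrast), and *adversarial*
(malformed outputs for parser fuzzing).

What the generator does **not** emulate: cell-level library-size variation,
dropout/zero inflation beyond the NB, batch effects, doublets, or velocity.
Passing tests therefore demonstrate correctness of the algorithms under a
clean NB world with planted signal, not robustness to those artifacts. The
default sizes are desk-scale (600 cells, 500 genes) so the full suite and
the acceptance script run in seconds on one CPU; the generators accept
larger values where more realistic scale is wanted.

## Numerical and design notes

- BH adjustment is delegated to statsmodels; graph components, simple-path
  enumeration and Dijkstra distances to networkx; the rank-sum test to
  scipy. The enrichment statistic, permutation null, NES/FDR, NB Wald test,
  Spearman ranking, stemmer and run matcher are implemented here.
- All stochastic procedures take explicit seeds; the mock provider selects
  response variants by seed, making every LLM-dependent operation
  bit-reproducible offline.
- Degenerate inputs are errors, not silent results: zero-library cells,
  empty regions, constant pseudotime, overlapping DGE regions, gene sets
  with zero or full overlap, unparseable provider output.
- The CLI writes a run manifest (command, parameters, input content digests,
  seed, version, timestamp, outputs) beside each command's first file
  output, or to the structured stderr log for commands that only print.

## Limitations

- Pseudotime as geodesic distance ignores within-edge cell placement and
  directionality; terminal-state detection inherits this.
- The composition corrections assume most genes are unchanged (majority-null
  assumption shared with median-of-ratios normalization generally).
- Verification matches titles only; it cannot assess whether a matched
  publication actually supports the claim's substance, and fixture-based
  tests say nothing about PubMed coverage.
- Live LLM and PubMed backends are best-effort integrations, not evaluated
  here.
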