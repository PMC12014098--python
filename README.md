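# evocell

Headless lineage identification and LLM-augmented interpretation for
single-cell trajectory exports.

A single-cell experiment routinely spans tens of thousands of cells and on
the order of 30 cell states, so the space of possible cell-state transitions
is large (2 · C(30, 2) = 870 ordered pairs) and picking the biologically
relevant lineage out of a principal-graph trajectory is hard even for domain
experts. `evocell` takes the flattened export of a trajectory (as produced
from a Monocle3 `cell_data_set`: a cell metadata table, a raw count matrix,
and the milestone graph with a cell→milestone assignment) and provides, as a
scriptable library and CLI rather than an interactive dashboard:

- **Lineage search** — each milestone is labelled with its most prevalent
  cell state; candidate lineages are the simple paths m₁…mₖ on the milestone
  graph whose endpoints carry user-chosen start and end states, bounded by a
  length and count budget. Pseudotime is geodesic distance d(origin, m)
  under edge weights; cells inherit their milestone's value.
- **Downstream statistics** — differential expression between two cell
  regions (Wilcoxon rank-sum on log1p CPM with a between-region
  median-of-ratios composition factor, or a per-gene negative-binomial Wald
  test with method-of-moments dispersion, var = μ + φμ²; BH-adjusted
  p-values); terminal states as pseudotime local maxima; driver genes ranked
  by Spearman correlation ρ(expression, pseudotime).
- **Preranked GSEA, from scratch** — weighted Kolmogorov–Smirnov running
  sum (hits add |s|ᵖ/Σ|s|ᵖ, misses subtract 1/(N−N_set); ES is the walk's
  extremum), gene-set permutation null, NES = ES / mean |null ES| of
  matching sign, and sign-stratified ratio-of-tails FDR q-values.
- **LLM augmentation with a veracity filter** — an engineered prompt asks a
  provider (scripted mock, OpenAI-compatible, or Ollama) for plausible
  cell-state transitions restricted to the dataset's state inventory, each
  with at least three supporting publication titles; candidate titles are
  verified against PubMed by requiring a run of ≥ 5 consecutive matching
  word stems with a real title. Precision/recall evaluation quantifies the
  engineered-vs-naive prompting contrast. Everything is testable offline via
  a scripted mock provider and a fixture PubMed store.
- **Synthetic data** — seeded generators for the full input bundle with
  planted ground truth: trajectory topologies, NB counts with planted
  differential and driver genes, GMT collections, PubMed fixtures and mock
  LLM scripts at faithful/noisy/adversarial fidelity.

## Worked example

Generate a synthetic dataset (a 6-milestone chain, 100 cells per milestone,
500 genes, with a G1S → S → G0 state progression) and run the workflow:

```sh
evocell simulate --seed 42 --out-dir demo
evocell paths --metadata demo/metadata.csv --counts demo/counts.csv \
    --trajectory demo/trajectory.csv --start G1S --end G0
```

Four candidate lineages are reported; the longest is the full chain
`m01 -> m02 -> m03 -> m04 -> m05 -> m06`. Select the two ends of the lineage
as cell regions and compare them:

```sh
evocell region ... --path-id P1 --neighbors 1 --milestones m02 --out ra.csv
evocell region ... --path-id P1 --neighbors 1 --milestones m05 --out rb.csv
evocell dge ... --region-a rb.csv --region-b ra.csv --out dge.csv
```

The top of `dge.csv` (sorted by adjusted p):

```
 gene   log2fc      p_value   p_adjusted       mean_a       mean_b
G0003 1.799865 1.411716e-98 3.672641e-96 17138.395007  4921.459324
G0005 1.756855 1.469057e-98 3.672641e-96 63265.885370 18719.197003
G0019 1.769594 7.489397e-97 1.248233e-94  7494.417721  2197.339995
```

These are planted 4-fold genes: log2fc ≈ 1.8 rather than 2.0 because the
fold is measured on composition-corrected mean CPM. GSEA against the bundled
gene sets puts the planted set first with FDR q = 0:

```
     set_name       es      nes  p_value    fdr_q
PLANTED_DE_UP 0.989583 1.120984 0.000999 0.000000
     DECOY_15 0.865726 0.980680 0.513487 0.885154
```

`evocell terminal --origin m01` reports milestone `m06` (state `G0`) as the
single terminal state — the pseudotime local maximum of the chain. Finally,
the veracity filter confirms a claim against the offline PubMed fixture:

```sh
evocell verify --claim "G1S cells transition into S cells" \
    --provider mock --script demo/llm_script.json \
    --pubmed demo/pubmed_fixture.json
```

returns verdict `supported` with the matching title and a consecutive-stem
run of 11 tokens.

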