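# Methods

## Scope and model

`eccdriver` implements a two-stage model of eccDNA-mediated transcriptional
change. Stage one assumes that an eccDNA can drive a gene's overexpression
through two mechanisms: as a transcriptional template (the gene is encoded
on the circle) or as a mobile enhancer platform (an enhancer on the circle
retargets a gene). Stage two assumes that, among such genes, those whose
PPI neighborhood is enriched for differentially expressed genes are the
most plausible drivers of the observed transcriptional state.

Both stages are deliberately conservative. Containment is *strict*: the
entire element — transcript plus 35 bp of upstream promoter, or the entire
enhancer — must lie within the circle, because a truncated gene without its
promoter, or an enhancer fragment without its TF-binding core, cannot be
assumed functional. This favors precision over recall; partial-overlap
calling is retained as an explicit `partial` mode for comparison with
earlier catalogues, and full-mode calls are provably a subset of
partial-mode calls.

## Coordinates and containment

All coordinates are BED-style (0-based, half-open) internally; GTF/GFF3
input (1-based, closed) is converted on read. eccDNA records are treated as
linear spans: elements crossing the circularization junction are not
representable and are out of scope. Containment of an element `[s, e)` in a
circle `[S, E)` requires `S <= s` and `e <= E` on the same chromosome;
partial overlap requires at least 1 bp in common (the standard
interval-intersection default). Queries run over per-chromosome interval
trees, so calling is O((n+m) log n) and invariant to record order.

The promoter pad is strand-aware: 35 bp to the left of the start on `+`,
35 bp to the right of the end on `-`, clamped at position 0. The default of
35 bp reflects base-pair-resolution models of human transcription
initiation, in which the core initiation signal is confined to the
immediate upstream window. Transcripts with unknown strand are an error by
default; an explicit opt-in treats them as `+` with a logged warning.

Per gene, the EEG rule is *any-transcript*: one contained (padded)
transcript suffices, since genes are the reporting unit. Per enhancer, the
ERG rule is *top-1*: only the highest-S_GE target is emitted; equal scores
break by ascending gene id — the score source defines no tie rule, and
determinism requires one. Enhancers are unstranded.

## EDG catalog and CEDGs

EEG and ERG calls merge into one call per gene carrying both class labels
and the full supporting evidence (circle ids and element ids), which can be
re-verified against the inputs. Protein-coding genes form the *general*
EDG set used for ranking; all other biotypes (and genes missing from the
biotype table, with a warning) form the non-coding partition. Common EDGs
across datasets are computed at the gene level: a gene qualifies when its
coding-EDG status holds in more than `min_fraction` of datasets (default
0.5, strict majority; `min_fraction=1, strict=False` gives the exact
intersection). Gene-level rather than region-level intersection was chosen
because genes are the unit every downstream step consumes.

## Driver ranking

Candidates absent from the reference PPI are removed first. For each
surviving candidate (source) the depth-2 local network contains:

* the source;
* *targets*: DEGs at hop distance 1 or 2;
* *intermediates*: hop-1 nodes adjacent to at least one hop-2 DEG (a hop-1
  DEG that also bridges is both).

Hop-1 non-DEG neighbors with no DEG behind them are excluded; edges are the
induced PPI subgraph. N(v) and Q(v) are computed *within* the local
network by default, because the influence being measured is defined on the
local network; a flag allows full-PPI counting for sensitivity analysis.
K(v) is always the full-PPI degree.

The weighting coefficient α = ΣN²/ΣQ is computed once per run over the
analyzed candidate set (candidates with empty local networks contribute
N = Q = 0), not per gene. When ΣQ = 0 — possible with an empty DEG set —
α is defined as 0, so C_WL degrades gracefully to N and the ranking reduces
to ordering by K+1. The fixed depth of 2 trades the classical four-hop
semi-local neighborhood for accuracy (via the α weighting) and lower
complexity.

DEG filtering uses strict inequalities exactly as stated: |log2FC| > 1 and
q < 0.01. The differential-expression analysis itself is an upstream
concern; the package consumes its output table (or a precomputed gene
list). Ranking sorts by EGIS descending with deterministic tie-breaks
(K descending, then gene id ascending); ranks are a gap-free permutation
1..n and the top 100 (configurable) form the candidate-driver set, while
the full table is always written.

## Benchmark metrics

Accuracy, precision and recall follow the standard confusion-matrix
definitions over an explicit gene universe. The universe is a required
parameter because TN — and therefore accuracy — is meaningless without it;
the pipeline defaults to the union of PPI nodes and annotated genes and
logs the choice. Zero denominators report the metric as 0 with a
`*_defined = False` flag rather than NaN.

## The 17-gene risk signature

The packaged model is a fixed linear combination of 17 genes from the
chromosome 11q13 common-EDG region, shipped with its published
coefficients verbatim (11 positive, 6 negative; sum 0.5178). Two gene
tokens are older aliases (MTL5 → TESMIN, SAPS3 → PPP6R3); an alias map is
provided, and matching them to a given expression matrix's annotation
vintage is left to the caller. Model *fitting* (Cox screening, LASSO,
stepwise selection) is out of scope — only the fitted model is applied.

Normalization is per-gene z-scoring across samples with the population
standard deviation (ddof = 0); mean-only centering is available. Constant
genes z-score to zero with a warning; a single-sample matrix is an error.
The per-sample score is the coefficient-weighted sum of z-scores, strictly
linear. Risk groups split at the cohort median with ties assigned to the
low-risk group (`score > median` defines high risk); the published
procedure does not state a tie rule, and assigning border cases to low
risk is the conservative clinical choice.

## Synthetic data

The generators produce every input type with planted, machine-checkable
truth; all are pure functions of their arguments including the seed (one
`numpy` Generator per call, no global state).

* **Annotation** — one transcript per gene and scored enhancers laid out by
  slab allocation (one element per equal-width chromosome slab, ~15% of the
  chromosome left empty for background circles), so elements never collide
  and overlap occurs only where planted. ~80% of genes are protein-coding;
  enhancers carry 1–3 targets with distinct S_GE.
* **Circles** — per planted EEG/ERG, one circle strictly containing the
  padded transcript or the enhancer within its slab; per decoy, a circle
  starting strictly inside an enhancer (≥1 bp overlap, never containment);
  plus background circles in the element-free tail.
* **Network** — Erdős–Rényi (default, mean degree 6 at n = 200) or
  preferential-attachment graphs; the planted driver gains 10 extra random
  neighbors, and DEG labels are Bernoulli(p_near = 0.9) within two hops of
  the driver versus Bernoulli(p_background = 0.05) elsewhere, with log2FC
  and q-values synthesized consistently with the strict thresholds.
* **Expression** — Gaussian matrices with per-gene mean shifts.

These fixtures emulate the *logic* of real inputs, not their marginal
distributions: real eccDNA length spectra, PPI degree laws, S_GE score
distributions and expression dispersion are all simplified. Passing tests
therefore demonstrate correctness of the calling, ranking and scoring
rules, not performance on real data — the headline numbers reported for
real cervical-cancer eccDNA against curated driver lists depend on
external resources (GeneHancer, STRING, TCGA, CGC) that are not bundled.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100 random graphs of ≤50 nodes
for oracle equivalence (agreement required to 1e-12; observed deviation is
exactly 0 since all quantities are small-integer ratios), 50 random planted
fixtures for mode-nesting, and 100 seeded 200-node networks for
planted-driver recovery — sizes at which the planted effect (p_near = 0.9
vs p_background = 0.05) is overwhelming by design, as the recovery
criterion is a correctness check of the wiring, not a power analysis.

## Known limitations

* Junction-spanning elements are invisible (linear-coordinate model).
* The STRING-style confidence cutoff defaults to 700/1000 but the
  appropriate value is resource- and version-dependent.
* The CEDG intersection operates on genes, not genomic regions; region-level
  sharing analyses would need the raw element coordinates.
* S_GE scores are taken as given; no re-derivation of enhancer–target
  assignments is attempted.
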