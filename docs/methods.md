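# Methods

## The model

`mirtox` formalizes a screen for miRNA toxicity to a cell type as four
composable steps. The underlying assumptions, made explicit:

* **Commonality ⇒ essentiality.** In a pre-sorted, homogeneous cell
  population, a gene whose expression exceeds a detection cutoff in every
  single cell is assumed indispensable for that cell type. This is an
  expression-based surrogate for essentiality, not a knockout screen: it
  will include ubiquitous housekeeping genes and can miss essential genes
  with bursty transcription (dropouts read as absence). The strict
  inequality at the cutoff (`> 0.1` RPKM, values exactly at the cutoff
  excluded) and the all-cells requirement are taken literally;
  `min_fraction < 1` is provided as a documented relaxation
  (`ceil(min_fraction·n_cells)` cells required).
* **Prediction-score ranking.** Targets are ranked by the cumulative
  weighted context++ score ascending (more negative = stronger predicted
  repression), ties broken lexicographically by symbol for determinism.
  Target prediction itself is out of scope; the package consumes tables.
* **Cross-species symbol matching.** Prediction tables and single-cell
  annotations mix human- and mouse-style casing; matching is by uppercased
  symbol. This is a deliberate simplification — no ortholog mapping — and
  can mismatch the rare symbols that differ between species beyond case.
* **Seed families.** Mature miRNAs sharing nucleotides 2–8 (the 7-mer
  seed) are collapsed into one family, the standard family convention; an
  explicit name→family map can override it, which also lets profiles
  without sequences be grouped. Per-family target sets are the union over
  the family label and member names found in the target table.
* **The verdict is a conjunction.** `predicted_toxic` requires burden
  `≥ fold_threshold × k̄` (baseline mean), enrichment (any term q < alpha),
  and no endogenous expression of the candidate. An endogenously expressed
  miRNA is evidently tolerated, so expression disqualifies flagging by
  default (`require_not_expressed`, overridable). When the baseline mean
  is 0 and the candidate has hits, the fold is `inf`; with 0 hits it is 0.
  `indeterminate` is returned when the target table lacks the candidate or
  no abundance profile is available, with an explicit `stage_failure`
  marker.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `cutoff` | 0.1 | RPKM | detection threshold per cell; 0.5 yields a much smaller set (sensitivity exposed via `cutoff_sensitivity`) |
| `min_fraction` | 1.0 | — | the literal all-cells criterion |
| `top_n` | 500 | targets | conventional TargetScan retrieval depth |
| `k_families` | 10 | families | dominant families carrying ~90% of miRNA content |
| `alpha` | 0.05 | — | FDR threshold for "enriched" |
| `fold_threshold` | 2.0 | — | burden multiple of baseline mean; decision plumbing, not a biological constant — the motivating case sits at ~3× |
| `min_term_size` | 2 | genes | suppress singleton terms |

The **background universe** for enrichment defaults to the genes detected
in the expression matrix, configurable to any list. This choice dominates
over-representation results and is the single largest reproducibility gap
when comparing against published enrichment outputs, which rarely state
their background; packaged tests therefore assert behavior on constructed
fixtures, not on any external tool's term list.

## Numerical choices

* RPKM: `counts · 1e9 / (cell_total · gene_length)`; per-cell totals, no
  library-size trimming; zero counts map to exactly 0; rejects zero-total
  cells and missing lengths by name.
* The required-cell count uses `ceil(f·n − 1e−9)` to absorb binary float
  artifacts (`0.9 × 20 = 18.000000000000004`).
* Hypergeometric p-values via `scipy.stats.hypergeom.sf(k−1, M, K, n)`;
  tests cross-check against exact rational summation for `M ≤ 50`.
  BH q-values via `statsmodels` (`fdr_bh`); tests verify the definitional
  step-up form `q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j`. Results sort by p, ties by
  term id.
* Abundance shares round half-up to one decimal (matching printed-table
  precision; Python's banker's rounding would differ at exact halves).
  The cumulative share is computed from the unrounded sum, then rounded —
  the rounded per-family shares may sum to one ulp less.
* Only `is_a` and `part_of` edges propagate annotations (conventional
  true-path choice; `regulates` excluded). Obsolete terms are dropped;
  `alt_id`s resolve to primaries; cyclic ontologies are rejected listing a
  cycle.
* Duplicate (miRNA, gene) records collapse to the most negative score;
  malformed lines are skipped and counted, never silently dropped.
* Foot-process width uses pooled sums within each group
  (`π/4 · Σlength/Σcount`), not a mean of per-image ratios — the two
  disagree whenever images differ in density, and the pooled form is the
  one the formula states. Length units pass through unchanged.

## The synthetic generators

The generators (`mirtox.synthetic`) emulate the statistical structure the
pipeline assumes, with all randomness derived from `SimConfig.seed`
(bit-reproducible):

* **Expression**: planted essential genes get per-cell
  `floor + mean_g · lognormal noise` with `floor = 0.2` RPKM, strictly
  above the 0.1 cutoff in every cell by construction; dispensable genes
  are silenced per cell by Bernoulli dropout (rate 0.5, a typical
  single-cell dropout magnitude). Gene-level lognormal means
  (σ = 1.5) with multiplicative cell noise (σ = 0.8) put the median
  pairwise cell Pearson r in the 0.1–0.5 band observed in real single-cell
  data (calibrated over 20 seeds). Defaults are 400 genes × 20 cells with
  40 essential for test speed; `SimConfig.podocyte_scale()` gives the
  611-essential / 12,000-gene / top-500 setting.
* **Targets**: the planted toxic miRNA's N predictions contain
  `round(0.064·N)` essential genes (the 32/500 proportion of the
  motivating case); benign miRNAs and endogenous families draw targets
  only from dispensable genes. Scores are negative with planted targets
  ranked at least as strongly.
* **Profile**: family abundance shares default to the published podocyte
  distribution (top-10 families ≈ 90% of content, let-7 ≈ 44%); members
  of a family share a randomly drawn seed; the toxic candidate is absent
  by construction.
* **Ontology**: a small random DAG (50 terms) with one planted term
  covering a chosen fraction of the toxic hits plus background-rate
  (0.05) noise annotations.

What passing tests on this synthetic data do **not** show: robustness to
ambient RNA, doublets, batch effects, zero-inflated overdispersion beyond
Bernoulli dropout, isomiRs, or prediction-table noise. The generators are
a correctness harness for the pipeline's logic, not a realism benchmark.

## Reference data

Two published podocyte tables ship with the package (`mirtox.reference`):
the 32 miR-145-5p hits among the 611 podocyte essential genes (symbol,
mean single-podocyte RPKM, context++ score) and the top-10 endogenous
family baseline (abundances, per-family essential-target lists; shares
computed against the full-profile total of 189,784 RPKM, which exceeds the
top-10 subtotal of 171,016). The full 611-gene essential list is not
redistributed. Note that the per-family target lists union to 78 distinct
genes under case-insensitive matching; summary counts quoted elsewhere for
this union may differ depending on symbol normalization.

## Known limitations

* Essentiality is inferred, not demonstrated; the criterion is sensitive
  to cell count and cutoff choice.
* No ortholog mapping; uppercase symbol matching only.
* The fold-threshold/alpha pair is an open modeling choice — no published
  quantitative boundary between toxic and safe burdens exists; defaults
  are exposed in `ToxicityConfig` and should be varied in sensitivity
  analyses.
* Whether per-family target selection should use top-N per family or per
  member miRNA is unresolvable from published summaries; the per-family
  member-union is implemented.
* Enrichment reproduces a procedure (hypergeometric + BH), not any
  specific tool's output; term-level results depend on the ontology and
  annotation release supplied by the caller.
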