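# Methods

## Problem and approach

Imprinted genes are expressed from only one parental chromosome, under the
control of a germline differentially methylated region (DMR) at the
imprinting control region (ICR). The *normally active* allele of an
imprinted gene is additionally subject to ordinary developmental
regulation. The two repression mechanisms — imprinting repression of the
normally inactive allele and developmental repression of the normally
active one — can be distinguished statistically by how histone-mark
enrichment at transcription start sites (TSSs) covaries with (a) promoter-DMR
status and (b) developmental expression status, across cell types.

`imprintmarks` formalizes that analysis as a pipeline over BED-like
enrichment-call sets (one per mark × cell type × calling method), a gene
annotation table with identifier aliases, expression tables and a
DMR/ICR annotation list:

1. **Extraction** — exact, case-insensitive id/alias resolution of the
   imprinted query list against the annotation table. Unmatched queries are
   reported as "not present"; a query hitting two records is reported
   ambiguous and never assigned. This replaces free-text pattern matching
   over source files, which is vulnerable to substring false positives.
2. **Enrichment calling** — a TSS is called enriched for a mark when the
   symmetric window `[TSS − flank, TSS + flank)` overlaps a called interval
   by ≥ 1 bp (half-open coordinates; book-ended intervals do not touch).
   Intervals are merged on load (overlaps and book-ends), so counts are
   independent of how call files were split.
3. **Profile classification** — each gene's enriched-mark subset maps to
   exactly one label of a taxonomy: named combinations of interest,
   "Other" for unnamed non-empty subsets, "None" for no enrichment. Two
   presets ship: three marks (H3K4me3 / H3K27me3 / H3K9me3, with named
   classes for the two co-enrichment combinations K4+K27 and K4+K9) and the
   two-mark bivalency taxonomy (K4 only / K27 only / K4+K27 / None).
4. **State integration** — per gene × cell type: mark booleans, profile
   label, expression status, DMR/ICR annotation. Genes missing from a layer
   are retained with `unknown`, never dropped, so every reported n is
   auditable; unknowns are excluded from statistical groups but counted.
5. **Signatures** — the ICR tri-mark (H3K4me3 ∧ H3K9me3 ∧ H4K20me3) is
   evaluated on region intervals directly (intergenic ICRs have no TSS);
   H3K27me3 is deliberately not part of the signature, because it is not
   present at all ICRs, but can be carried as an annotation column.
   Bivalency transitions between a pluripotent and a differentiated cell
   type are classified as resolved-to-K4 / resolved-to-K27 /
   resolved-to-none / retained, coupled to an expression outcome
   (activated, still repressed, still expressed, silenced, unknown).
6. **Statistics** — Yates-continuity-corrected chi-square for 2×2 tables,
   plain Pearson chi-square for r×c, both with a validity verdict attached
   (below). Counts can be reconstructed from printed percentages and group
   sizes by nearest-integer rounding.

## Expression calling

A gene is **repressed** when its microarray-style signal intensity is
strictly below the threshold (default 25, configurable); at or above the
threshold it is **expressed** — the boundary value 25.0 is expressed, since
only values *below* the threshold indicate repression. Missing values are
`unknown`. When several assays provide binary calls, they are consolidated
by unanimity: any disagreement yields `unknown` rather than a majority
vote, because inconsistent evidence should not be classified.

## Chi-square validity rule

A two-tier Cochran-style rule on the expected counts:

* **invalid** — any expected count < 1; the statistic is still computed for
  2×2 tables (callers decide), but the verdict marks the test as not
  meeting its conditions. Degenerate tables (an all-zero row or column)
  are invalid with the statistic omitted.
* **valid_with_warning** — all expected ≥ 1 but some < 5;
* **valid** — all expected ≥ 5.

The two-tier form is needed for internal consistency of the worked
examples this package reproduces: a 20%-of-54 vs 0%-of-17,761 comparison
has smallest expected count ≈ 0.03 and must be refused, while a
7%-of-54 vs 2%-of-17,761 comparison (smallest expected ≈ 1.09) is
legitimately testable with a warning. A blanket "all expected ≥ 5" rule
would forbid both; "any expected > 0" would allow both.

The Yates correction is `(|O − E| − 0.5)` clamped at zero before squaring,
so near-null tables cannot acquire a positive statistic from the
correction itself. Both statistics are computed from the textbook formulas
in `stats.py`; only the χ² tail probability comes from `scipy.stats.chi2`.
`scipy.stats.chi2_contingency` is used in the test suite as an independent
oracle (agreement to 1e-9 on 1,000 random tables), never as the
implementation.

## Transition-classifier totality

Resolution classes apply only when the starting state is bivalent. To keep
the classifier total over all 4×4 state pairs (required for property
testing), a non-bivalent start that gains bivalency is classed
`gained_marks`, and any other non-bivalent start `not_applicable`.

## Synthetic data generator

No raw data ships with the package; the generator produces complete input
bundles (annotation table, BED call sets, expression tables, DMR/ICR
annotations, query list) from a generative model with retained ground
truth. It emulates:

* a genome of `n_genes` (default 17,761) with `n_imprinted` (default 54)
  imprinted genes, matching the scale of genome-wide mouse surveys;
* promoter-DMR classes for imprinted genes, split germline/somatic/none
  (default 0.24/0.24/0.52, i.e. ≈ 26 of 54 genes with a promoter DMR);
  germline-DMR promoters are ICRs except one flagged non-ICR germline DMR
  (the known exception class); a configurable number of intergenic ICRs;
* the repressive pair H3K9me3 ∧ H4K20me3 drawn per gene conditional on the
  DMR class — default probability 1.0 at germline ICR promoters and 0 at
  somatic-DMR, non-DMR and non-ICR-germline promoters (the exclusivity
  structure), with a small background rate (0.005) genome-wide. Wherever
  the pair is present, H3K4me3 is forced on: the tri-mark rides on the
  unmethylated-allele K4 plus methylated-allele K9/K20;
* expression: P(expressed) = 0.71 with a promoter DMR, 0.48 without
  (imprinted genes), 0.55 background; on differentiation, repressed genes
  activate with probability 0.30 and expressed genes silence with 0.15;
* K4/K27 category conditional on expression status: in the pluripotent
  state P(bivalent | repressed) = 0.53, P(bivalent | expressed) = 0.25,
  with K27-only absent (these pluripotent-state conditionals are the
  published structure); differentiated-state conditionals and the
  resolution-class split (0.30/0.30/0.20/0.20 for resolved-to-K4 /
  resolved-to-K27 / resolved-to-none / retained) are fixed once to echo
  the reported direction of bivalency resolution — more K27-only among
  repressed genes, near-zero bivalency gain — not any printed table;
* two calling methods: the second ("HMM") flips each gene's enrichment
  with probability 0.019 relative to the first ("WI") for the three
  WI-called marks; H4K20me3 exists only under the more stringent HMM
  method and reports carry a standing underrepresentation caveat;
* per-layer missingness (default 8% of genes absent from each expression
  table), emulating genes not present in a given study's files.

**Geometry.** Genes sit on a fixed grid (19 chromosomes, 10 kb spacing,
TSS mid-slot); an enriched mark is realized as a 1 kb peak jittered by
±300 bp around the TSS, so every realized peak covers its TSS and no peak
reaches a neighbouring gene's window at the default 1 kb flank. Decoy
intervals (rate 0.02/gene/mark) are placed in a guaranteed-empty zone of
each slot to exercise parsing and merging without perturbing calls. ICR
regions are 2 kb.

Because of this geometry the pipeline's overlap stage is exact on
synthetic data: estimation error in recovery tests is pure binomial
sampling of the latent draws. That is deliberate — the generator tests the
*logic* (interval realization → overlap → classification → stratification
→ statistics), not robustness to peak-calling noise. Real data differ in
ways the generator does not model: peaks may miss or only partially
overlap TSS windows, enrichment probabilities are not homogeneous within a
class, marks are correlated beyond the encoded conditionals, and
annotation TSSs can be wrong. Passing recovery tests therefore validates
the pipeline's bookkeeping and statistics, not biological inference on
real call sets.

**Determinism.** All draws come from one `numpy` generator seeded from the
config; identical (config, seed) produce byte-identical written bundles,
and the truth record (latent classes, true mark states, region signature
indicators, flipped genes, missing genes) is returned alongside.

## Parameter recovery

`recover_parameters` compares empirical conditional frequencies computed
from the *pipeline's* state table (never the truth record) against the
configured probabilities: P(K9∧K20 | DMR class), P(expressed | DMR
presence), P(bivalent | expression status). Each estimate is reported with
the binomial standard error at the configured value; the acceptance
property requires every estimate within 3 SE for conditioning groups of
≥ 200 genes (5,000-gene bundles with 1,500 imprinted genes — the
published-scale 54 imprinted genes cannot form 3-SE-testable groups).
Probability-0 and probability-1 parameters must be recovered exactly.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `flank` | 1,000 bp | TSS window half-width; the window choice is not dictated by the data and is echoed in every report header |
| `expression_threshold` | 25 | intensity below which a gene is repressed |
| overlap rule | ≥ 1 bp | no minimum-fraction option |
| validity rule | 1 / 5 | expected-count thresholds for invalid / warning |
| `p_method_discordance` | 0.019 | per-gene WI-vs-HMM flip rate |
| `peak_width`, `peak_jitter` | 1,000, 300 bp | realized peak geometry |

## Problem sizes

Default analyses run at the published scale (17,761 genes × 3 cell types);
a full pipeline run takes a few seconds on one CPU. The test suite uses
300–5,000-gene bundles; recovery acceptance uses 5,000 genes / 1,500
imprinted. Seeds for all stochastic checks are fixed in the tests and
derived from `--seed` in `scripts/acceptance.py`.

## Known limitations

* Interval overlap is exact and binary; no enrichment scores, no
  minimum-overlap fraction, no peak summits.
* Strand enters only through the annotation's strand-aware TSS coordinate;
  windows are symmetric.
* The generator draws marks independently across cell types given the
  category model; it does not model lineage-specific persistence of
  K9/K20 nor inter-gene spatial correlation (domains).
* Cross-species analysis is limited to the `species` field on records; no
  orthology mapping or liftover.
* The all-genes comparison group includes the imprinted genes themselves
  (groups are used as printed in the sources being reconstructed); at
  54 / 17,761 the contamination is negligible.
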