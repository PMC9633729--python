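# Methods

This note documents the models and procedures implemented in
`riborescue`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generators do and do not
emulate.

## Experimental design being modelled

The package analyses a four-condition, two-assay rescue experiment on
the SCF^Fbxo4^–hnRNPK axis: wild-type cells (`WT`), Fbxo4 knock-out
(`KO`), and each with hnRNPK knock-down (`WT_KD`, `KO_KD`), profiled by
both RNA-seq (`RNA`) and ribosome footprinting (`RPF`), in biological
duplicates. Conditions are always named explicitly; no roman-numeral
condition codes are used anywhere, because numeral schemes are
ambiguous across figure layouts. All contrasts are referenced to `WT`.

## Read pre-processing (`fastq_prep`)

Stages run in a fixed order: quality filter → duplicate collapse →
adapter trim → UMI extraction → size selection.

* **Quality filter.** A read survives if at least 70% of its bases have
  ≥ 99% base-call accuracy. Accuracy 99% is encoded as Phred ≥ 20
  (P(error) ≤ 0.01) under the standard Phred+33 convention. The rule
  removes only reads with *less than* 70% such bases, so a 10-base read
  with exactly 7 passing bases is kept.
* **Duplicate collapse** keys on the full raw sequence. Because
  collapsing precedes any trimming, the two embedded 4-nt UMIs are part
  of the identity key, which is what makes sequence-identity collapsing
  a UMI-aware deduplication. Position-aware deduplication (requiring
  identical mapping coordinates) is not implemented; at footprint
  lengths of 26–34 nt plus 8 UMI nt, sequence identity is an
  effectively equivalent and alignment-free criterion.
* **Adapter trimming** is a semi-global suffix-vs-prefix match: the
  leftmost read suffix matching a prefix of the 3′ adapter with
  mismatch rate ≤ 0.1 and overlap ≥ 3 is removed. Only the last
  `len(adapter)` bases can participate (a suffix longer than the
  adapter cannot equal one of its prefixes). `N` matches nothing. The
  default adapter is the 21-nt Illumina TruSeq small-RNA 3′ adapter.
* **UMI extraction** moves the first and last 4 nt into the read's
  `umi` field (5′ block first). Reads with no interior after removal
  are discarded and counted. The operation is a no-op on reads that
  already carry a UMI, which makes every pipeline stage idempotent.
* **Size selection** keeps 26–34-mers inclusive. In the wet protocol
  this is a gel-extraction step, so it is applied to footprint
  libraries by default and can be disabled for RNA-seq.

Reads containing `N` are kept (there is no separate N-content rule);
`N` simply never matches an adapter base or a motif code.

## Differential testing (`de_core`)

A deliberately simple negative-binomial Wald layer, applied
independently to the RNA and RPF count matrices.

* **Normalization** is median-of-ratios: per sample, the median over
  all-positive genes of count / geometric-mean-across-samples,
  rescaled to geometric mean 1.
* **Dispersion.** Counts are modelled as NB with Var = μ + αμ². Per
  gene, α is estimated by method of moments, `max(0, (s² − m̄)/m̄²)`, on
  normalized counts within each condition group (≥ 2 replicates),
  averaged across groups with group-size weights and floored at 1e-8.
  Two methods are exposed: `moments` keeps the per-gene estimates;
  `pooled` (the default used by `wald_test`) replaces them by their
  across-gene mean. The pooled default is a deliberate design choice:
  at duplicate/triplicate replication the per-gene moment estimate is
  extremely noisy, and plugging it into a Wald statistic referred to
  the standard normal inflates the type-I error to ~0.11 at n = 3;
  pooling across genes restores calibration to ~0.05 (the generators
  use a shared dispersion, and real Ribo-seq dispersions are strongly
  stabilised across genes in practice by shrinkage for the same
  reason). The cost is insensitivity to gene-specific overdispersion;
  a mean–dispersion trend would be the natural refinement.
* **Wald test.** For groups with normalized means m_ref, m_test and
  sizes n_ref, n_test:

      lfc  = log2((m_test + c) / (m_ref + c)),          c = 0.5
      se²  = (1/ln 2)² Σ_g [ 1/(n_g (m_g + c)) + α/n_g ]
      z    = lfc / se,   p = 2 Φ(−|z|)

  The se is the delta-method variance of the log2 ratio of NB group
  means. The pseudocount c = 0.5 (half-count convention) keeps lfc
  finite at zero counts and is config-exposed. Genes with all-zero
  counts are dropped with a logged count before testing.
* **Multiple testing** is Benjamini–Hochberg step-up (delegated to
  `statsmodels`), with no independent filtering: every tested gene
  enters the correction. This is simpler and conservative.
* **Direction calls**: `up` iff padj < α and lfc ≥ 1 (2-fold,
  boundary included), symmetric for `down`, else `ns`.

This layer does not attempt numeric identity with a GLM-based tool
(no dispersion shrinkage toward a trend, no outlier refitting, no LFC
shrinkage); its accuracy surface is calibration and effect recovery on
synthetic data, which the acceptance suite measures.

## Translation efficiency and events (`te_events`)

Apparent TE of a gene in a condition is
`(mean normalized RPF + c) / (mean normalized RNA + c)` with c = 0.5.
Group means (not per-replicate ratios) are used because the design has
duplicate-level replication, where per-replicate ratios are unstable.

Events for a contrast partition the shared gene universe into exactly
five classes from the two direction calls: `concordant` (both layers,
same direction), `rna_only` (mRNA buffered away from the ribosome),
`rpf_only` (translational regulation), `discordant` (opposite
directions), `none`. The five-class scheme is this package's
definition of the "TE event" partition; genes missing from one table
fall in `none`. No interaction-term test for ΔTE significance is
performed — the partition is descriptive.

## Rescue screen (`rescue_screen`)

A gene is an axis target when, on at least one layer:

* **Criterion I** — |lfc_KO| ≥ 1 (2-fold) on that layer, with
  adjusted p < 0.05 for the KO contrast on *either* layer. The
  either-layer significance clause reflects the design's "RNA and/or
  RPF" logic; fold, rescue and criterion-III checks always stay on the
  same layer, and a gene qualifies through any single layer (mixing
  layers within one criterion chain is not allowed — the more
  conservative of the two readings).
* **Criterion II** — rescue fraction
  `(lfc_KO − lfc_KO_KD) / lfc_KO ≥ 0.25`, computed on log2 fold
  changes, with no p-value gate (point estimates only). The log2 scale
  treats up- and down-regulated genes symmetrically; a linear-scale
  variant (fraction of the linear departure from WT reverted) is
  available behind `rescue_scale="linear"`. The fraction may exceed 1
  (over-rescue) or go negative (aggravation).
* **Criterion III** — the knock-down-only response is opposite in sign
  to the KO response, *or* lies inside a "no effect" band
  |lfc_WT_KD| < log2(1.5) ≈ 0.585. The band quantifies "no effect" as
  the midpoint between null and the 2-fold response threshold and is
  config-exposed (`null_lfc`).

Raising `rescue_min` or lowering `alpha` can only shrink the target
set, and negating every lfc leaves the calls unchanged; both are
enforced by property tests together with an exact naïve per-gene
oracle.

## Coverage and pausing (`coverage_pause`)

Each footprint is reduced to one assigned position — its 5′ end by
default (matching plain interval-intersection counting), or an offset
P-site (`start + 12`, clipped to the read's last base) behind a flag.
Coverage profiles are reads per nucleotide per million library reads.

The pause statistic counts distinct reads assigned within the
symmetric 25-nt window `[center − 12, center + 12]` (1-based,
inclusive; halfwidth configurable, windows truncated at transcript
ends), normalizes each replicate's count to per-million, and applies a
pooled-variance two-sided Student's t test (df = nA + nB − 2; Welch is
available behind a flag but pooled is the default, matching the plain
"Student's t" convention). Window *counts* — not p-values — are what
gets library-normalized. Degenerate inputs: zero pooled variance with
equal means gives t = 0, p = 1; with unequal means the result is
flagged and p reported as 0. Focal centers are interpreted in whatever
coordinate system the position table uses (transcript coordinates in
the synthetic data); the package does not project genome to
transcript.

`scan_pauses` generalizes the focal test: per-nucleotide rpm profiles
are window-summed per replicate, and candidate sites are positions
where the condition-mean windowed ratio (B + 0.1)/(A + 0.1) reaches
`min_ratio` (default 2) and is a strict local maximum; each candidate
carries its windowed t test.

## Synthetic data (`synthetic_data`)

The generators produce data with exactly the structure the analysis
assumes, paired with ground truth, so every stage is testable without
any external download. All randomness flows from one seed;
identical specs give byte-identical outputs.

* **Counts.** Baseline gene means are log-uniform on [20, 2000] at
  1e6-read scale; libraries default to 5e6 reads with ±20% per-sample
  jitter (so normalization is exercised); counts are NB with
  dispersion 0.05; replication is biological duplicates — all matching
  the modelled study's scale. The default class table plants 4% true
  axis targets (|lfc_KO| = 2 on both layers, 60% rescued in KO_KD,
  null in WT_KD) and 4% non-rescued KO responders among 92% nulls, the
  scenario the screen's recovery guarantees are stated for. A
  translation-shift scenario (`TRANSLATION_SHIFT_CLASSES`, 4% genes
  with the KO effect on RPF only) exercises the TE classifier;
  knock-down-only responders are also available.
* **Positions.** A 2,400-nt transcript receives 20,000 footprints per
  sample (a deeply covered, c-Myc-like focal transcript) from a
  uniform background whose per-nucleotide intensity is multiplied
  3-fold within ±12 nt of nt 442 in the peaked conditions. At this
  depth the scan localizes the planted peak to within ±2 nt in
  effectively all simulations; at 10,000 reads the rate is ~98%.
* **FASTQ.** Reads are UMI(4) + insert(26–34 nt) + UMI(4) + as much
  adapter prefix as fits a 50-nt read; 10% PCR duplicates are exact
  copies under fresh ids; optional planted low-quality reads set half
  the bases to Phred 10 (below the 70%-at-Q20 bar); optional uniform
  base errors. With errors off the prep pipeline recovers 100% of true
  inserts, which is the intended oracle condition.

What the generators do **not** emulate: alignment artifacts,
multimapping, rRNA contamination, positional or GC bias, mean-dependent
dispersion trends, codon-level periodicity, and batch structure.
Passing recovery tests therefore demonstrates the correctness of the
statistical machinery under its own model, not robustness to the full
messiness of real libraries.

## Motifs and overlaps (`set_enrichment`)

Gene-set overlap is scored with the exact upper-tail hypergeometric
test over an explicit universe (members outside the universe are
dropped with a logged count). The significance test is this package's
addition to what is otherwise a descriptive percentage-overlap
analysis; the choice of universe (detected genes vs annotated genes)
materially changes p and is left to the caller.

Motif counting matches an IUPAC pattern at every position, overlaps
allowed, U ≡ T. `N` matches nothing on either side — a deliberate
strictness rule: an ambiguous base in the sequence never evidences a
motif instance, and a pattern `N` (which would otherwise match
everything) is treated as unmatchable rather than vacuous. Enrichment
compares per-kilobase instance densities between two sequence groups
with a two-sided Mann–Whitney test; for small groups the permutation
null is enumerated exactly (deterministic), otherwise the
tie-corrected normal approximation is used. This is a stated
simplification of database-driven RBP-motif scanning: it takes
user-supplied patterns and sequences rather than a PWM database.

## Numerical and testing choices

* Quality-fraction comparisons carry a 1e-12 epsilon so the exact-70%
  boundary is decided by arithmetic, not floating-point luck.
* Size factors are computed in log space; the geometric-mean-1
  constraint is checked to 1e-9.
* The null calibration checks run at 10,000 genes (Wald) and 1,000
  simulations (pause test); recovery checks run the full 5,000-gene
  default simulation and 200 position simulations — sizes chosen to
  keep the whole suite in the minutes range while leaving the binomial
  noise on each measured rate well inside the asserted bands.
* The acceptance script pools four replicate 5,000-gene simulations
  for the screen's sensitivity/FDP, reducing the Monte-Carlo noise of
  the reported proportions.

## Known limitations

* The Wald layer is moment-based; very low counts (means ≪ 20) and
  gene-specific dispersion are outside its accuracy envelope.
* The rescue fraction is a ratio of noisy estimates; near-threshold
  knock-out responses (|lfc_KO| just above 1) produce unstable
  fractions, and non-rescued responders are the dominant
  false-positive class in simulation (~10–15% of calls at the default
  thresholds).
* The pause test inherits the small-sample behaviour of a df = 2 t
  test at duplicate replication; per-window counts in the hundreds are
  needed for reliable detection of ~3-fold accumulation.
* Gene-level counting only: no isoform deconvolution, and pause
  centers are not mapped between CDS and transcript coordinate
  systems.
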