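# riborescue

Analysis toolkit for rescue-screen ribosome profiling: given RNA-seq
and ribosome-footprint (RPF) data over a four-condition design —
wild type (`WT`), knock-out of an E3-ligase adaptor (`KO`), knock-down
of an RNA-binding protein (`WT_KD`), and the double perturbation
(`KO_KD`) — it identifies the genes whose dysregulation upon knock-out
is *rescued* by co-depleting the RNA-binding protein, i.e. the
downstream targets of the ligase–RBP axis, and locates positions of
local ribosome accumulation ("pausing") on transcripts of interest.

It is aimed at people analysing Ribo-seq/RNA-seq rescue designs
(e.g. the SCF^Fbxo4^–hnRNPK–c-Myc axis) who want a small, transparent,
fully tested pipeline rather than a stack of external tools, and a
seeded synthetic-data generator that makes every stage verifiable
against planted ground truth.

## What it computes

* **Read pre-processing** (`fastq_prep`): quality filter (≥ 70% of
  bases at Phred ≥ 20), UMI-aware duplicate collapse, 3′ adapter
  trimming, dual 4-nt UMI extraction, 26–34-nt footprint size
  selection.
* **Differential testing** (`de_core`): median-of-ratios
  normalization, negative-binomial dispersion (pooled method-of-moments),
  and a per-gene Wald test on log2 fold changes,

      z = lfc / se,  se² = (1/ln 2)² Σ_groups [1/(n(m+c)) + α/n],

  with Benjamini–Hochberg correction; `up`/`down` calls at
  |lfc| ≥ 1 and padj < 0.05.
* **Translation efficiency** (`te_events`): TE = (RPF + c)/(RNA + c)
  on normalized group means, and the five-way event partition
  (concordant / rna_only / rpf_only / discordant / none) per contrast.
* **Rescue screen** (`rescue_screen`): the three-criterion selection —
  (I) ≥ 2-fold KO response, adjusted p < 0.05 on either assay layer;
  (II) rescue fraction (lfc_KO − lfc_KO_KD)/lfc_KO ≥ 25%;
  (III) knock-down-only response opposite in sign or inside a
  1.5-fold no-effect band — evaluated per layer.
* **Set enrichment** (`set_enrichment`): exact hypergeometric overlap
  with reference gene sets (GMT/CLIP lists) and IUPAC motif-density
  rank-sum enrichment (default motif `TCCCW`, poly-C class).
* **Pausing** (`coverage_pause`): reads-per-nucleotide-per-million
  coverage profiles, the 25-nt-window Student's t test of footprint
  accumulation at a focal nucleotide, and a transcript-wide scan for
  candidate pause sites.
* **Synthetic data** (`synthetic_data`): seeded NB count matrices with
  planted rescued/non-rescued gene classes, footprint positions with
  planted pause peaks, and raw FASTQ with UMIs/adapters/duplicates —
  each paired with a ground-truth table.

## Worked example

The numbered scripts under `analysis/` run the whole study on
synthetic data (seed 0 shown; outputs land under `results/`):

```sh
python analysis/01_simulate_data.py --seed 0
python analysis/02_preprocess_reads.py
python analysis/03_differential_expression.py
python analysis/05_rescue_screen.py
python analysis/07_ribosome_pausing.py
```

prints, among other things:

```
counts: 5000 genes x 16 samples, 200 true axis targets planted
recovered 100.0% of the 1800 true unique inserts exactly
de_ko_rna: 198 up / 210 down of 5000 (|lfc| >= 1, padj < 0.05)
criteria funnel: {"genes": 5000, "rna_crit_i": 408, "rna_crit_i_ii": 217,
                  "rna_pass": 209, ..., "targets": 238}
vs truth: sensitivity 1.000 (200/200 planted targets recovered),
          false-discovery proportion 0.160 (38/238 calls)
nt 442 window (25 nt): normalized counts WT=[201.0, 210.0]
          KO=[575.0, 589.0]; t = 45.24, df = 2, p = 0.000488
scan: 1 candidate site(s); strongest at nt 442 (ratio 2.83, p = 0.000488)
```

Reading: of 5,000 simulated genes, ~410 respond ≥ 2-fold to the
knock-out on each layer; the three criteria funnel these down to 238
called targets, which recover all 200 planted axis targets (the
remaining calls are dominated by planted *non-rescued* responders whose
noisy rescue fraction crosses the 25% bar). On the focal transcript,
the 3-fold planted footprint peak at nt 442 is found by the scan at
exactly that position, and the windowed t test on library-normalized
counts (per-million; duplicates, so df = 2) confirms the accumulation.

The same machinery is available as a CLI (`riborescue prep|de|te|
rescue|overlap|motif|coverage|pause|simulate`) and as plain library
calls; `04_translation_efficiency.py` and `06_set_enrichment.py` cover
the TE event partition and the overlap/motif analyses.

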