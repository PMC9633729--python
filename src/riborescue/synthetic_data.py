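"""Seeded generators for the statistical structure the pipeline assumes.

Three generators, each paired with a ground-truth table:

* :func:`generate_counts` — negative-binomial RNA and RPF count
  matrices over the four-condition rescue design (WT, KO, WT_KD, KO_KD)
  with planted gene classes (true axis targets that are rescued by the
  double depletion, non-rescued knock-out responders, knock-down-only
  responders, translation-only shifts, and nulls).
* :func:`generate_positions` — footprint position tables on a synthetic
  transcript with planted pause peaks in selected conditions.
* :func:`generate_fastq` — raw footprint reads built as
  UMI + insert + UMI + adapter-prefix with injected PCR duplicates and
  optional planted low-quality reads, for exercising the pre-processing
  pipeline end to end.

All randomness flows from ``SimSpec.seed`` through one
``numpy.random.default_rng`` stream per generator call, so a fixed spec
reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage_pause import ReadPositionTable
from .de_core import CountMatrix, SampleSheet
from .fastq_prep import DEFAULT_ADAPTER, Read

logger = logging.getLogger(__name__)

CLASS_NAMES = ("null", "rescued", "nonrescued_responder", "wtkd_only",
               "rpf_only_shift")


@dataclass(frozen=True)
class ClassSpec:
    """One planted gene class.

    ``lfc_rna``/``lfc_rpf`` are the knock-out effects (log2 vs WT) on
    each assay layer; each gene gets a random sign, applied to both
    layers jointly. ``rescue_fraction`` is the fraction of the KO effect
    reverted in KO_KD; ``lfc_wt_kd`` the knock-down-only effect.
    """

    name: str
    proportion: float
    lfc_rna: float = 0.0
    lfc_rpf: float = 0.0
    rescue_fraction: float = 0.0
    lfc_wt_kd: float = 0.0


#: The default class table: 5,000-gene scale with 4% true (rescued) axis
#: targets at |lfc| = 2 and 60% rescue and 4% non-rescued knock-out
#: responders. Knock-down-only responders (``wtkd_only``) and
#: translation-only shifts (``rpf_only_shift``) are available for
#: scenario-specific class tables (see :data:`TRANSLATION_SHIFT_CLASSES`).
DEFAULT_CLASSES = (
    ClassSpec("null", 0.92),
    ClassSpec("rescued", 0.04, lfc_rna=2.0, lfc_rpf=2.0, rescue_fraction=0.6),
    ClassSpec("nonrescued_responder", 0.04, lfc_rna=2.0, lfc_rpf=2.0),
)

#: Scenario with planted translation-only (RPF) shifts for exercising
#: the TE event classifier.
TRANSLATION_SHIFT_CLASSES = (
    ClassSpec("null", 0.96),
    ClassSpec("rpf_only_shift", 0.04, lfc_rpf=2.0),
)


@dataclass(frozen=True)
class PauseSpec:
    """Design of the footprint-position generator.

    ``background_reads`` footprints per sample are placed on a
    transcript of ``length`` nt; in ``peak_conditions`` the
    per-nucleotide intensity within +/- ``halfwidth`` of each peak
    center is multiplied by ``peak_fold``.
    """

    transcript_id: str = "synthetic_tx"
    length: int = 2400
    n_reads: int = 20000
    replicates: int = 2
    conditions: tuple[str, ...] = ("WT", "KO")
    peak_conditions: tuple[str, ...] = ("KO",)
    peak_centers: tuple[int, ...] = (442,)  # 1-based
    peak_fold: float = 3.0
    halfwidth: int = 12
    library_size: float = 1e6
    read_len_range: tuple[int, int] = (26, 34)


@dataclass(frozen=True)
class FastqSpec:
    """Design of the raw-read generator (UMI + insert + UMI + adapter)."""

    n_reads: int = 2000
    insert_len_range: tuple[int, int] = (26, 34)
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = 4
    duplicate_rate: float = 0.1
    read_length: int = 50
    high_quality_phred: int = 36
    low_quality_fraction: float = 0.0
    low_quality_phred: int = 10
    base_error_rate: float = 0.0


@dataclass(frozen=True)
class SimSpec:
    """Full simulation design; the defaults are the study-like scale:
    5,000 genes, biological duplicates, 5e6-read libraries, NB
    dispersion 0.05, baseline means log-uniform in [20, 2000] at
    1e6-read scale."""

    seed: int = 0
    n_genes: int = 5000
    replicates: int = 2
    library_size: float = 5e6
    library_jitter: float = 0.2
    dispersion: float = 0.05
    baseline_range: tuple[float, float] = (20.0, 2000.0)
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    pause: PauseSpec = PauseSpec()
    fastq: FastqSpec = FastqSpec()

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = {c.name for c in self.classes} - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class names: {sorted(unknown)}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, Var = mean + alpha mean^2); Poisson in the alpha -> 0 limit."""
    mean = np.asarray(mean, float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _assign_classes(rng: np.random.Generator, spec: SimSpec) -> np.ndarray:
    sizes = [int(round(c.proportion * spec.n_genes)) for c in spec.classes]
    sizes[0] += spec.n_genes - sum(sizes)  # remainder absorbed by first class
    labels = np.repeat([c.name for c in spec.classes], sizes)
    rng.shuffle(labels)
    return labels


def generate_counts(
    spec: SimSpec,
) -> tuple[CountMatrix, CountMatrix, SampleSheet, pd.DataFrame]:
    """Simulate the four-condition, two-assay count experiment.

    Per gene: baseline mean log-uniform over ``baseline_range`` (at
    1e6-read scale), condition/assay means scaled by 2^lfc per the
    gene's class, counts NB with the spec dispersion at each sample's
    library scale. Library sizes are jittered uniformly within
    +/- ``library_jitter`` so normalization is exercised.

    Returns (RNA CountMatrix, RPF CountMatrix, SampleSheet, truth), with
    truth columns gene_id, class, sign, true lfc per layer and contrast,
    true TE shift, and is_true_target (class == rescued).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    labels = _assign_classes(rng, spec)
    by_name = {c.name: c for c in spec.classes}
    lo, hi = spec.baseline_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    sign = rng.choice([-1.0, 1.0], n)

    lfc_ko = {
        "RNA": np.array([by_name[l].lfc_rna for l in labels]) * sign,
        "RPF": np.array([by_name[l].lfc_rpf for l in labels]) * sign,
    }
    resc = np.array([by_name[l].rescue_fraction for l in labels])
    lfc_wt_kd = np.array([by_name[l].lfc_wt_kd for l in labels]) * sign
    lfc_by_cond = {
        assay: {
            "WT": np.zeros(n),
            "KO": lfc_ko[assay],
            "KO_KD": lfc_ko[assay] * (1.0 - resc),
            "WT_KD": lfc_wt_kd,
        }
        for assay in ("RNA", "RPF")
    }

    rows = []
    matrices: dict[str, pd.DataFrame] = {}
    gene_ids = pd.Index([f"gene_{i:05d}" for i in range(n)], name="gene_id")
    for assay in ("RNA", "RPF"):
        cols = {}
        for cond in ("WT", "KO", "WT_KD", "KO_KD"):
            for rep in range(1, spec.replicates + 1):
                sample = f"{assay}_{cond}_r{rep}"
                lib = spec.library_size * rng.uniform(
                    1.0 - spec.library_jitter, 1.0 + spec.library_jitter
                )
                mu = base * np.exp2(lfc_by_cond[assay][cond]) * (lib / 1e6)
                cols[sample] = _nb_draw(rng, mu, spec.dispersion)
                rows.append(
                    {"sample_id": sample, "condition": cond, "assay": assay,
                     "replicate": rep, "library_size": int(round(lib))}
                )
        matrices[assay] = pd.DataFrame(cols, index=gene_ids)

    sheet = SampleSheet(pd.DataFrame(rows))
    truth = pd.DataFrame(
        {
            "class": labels,
            "sign": sign,
            "lfc_rna_ko": lfc_ko["RNA"],
            "lfc_rpf_ko": lfc_ko["RPF"],
            "lfc_rna_ko_kd": lfc_by_cond["RNA"]["KO_KD"],
            "lfc_rpf_ko_kd": lfc_by_cond["RPF"]["KO_KD"],
            "lfc_wt_kd": lfc_wt_kd,
            "rescue_fraction_true": resc,
            "te_shift": lfc_ko["RPF"] - lfc_ko["RNA"],
            "is_true_target": labels == "rescued",
        },
        index=gene_ids,
    )
    truth.attrs["seed"] = spec.seed
    return (
        CountMatrix(counts=matrices["RNA"], assay="RNA"),
        CountMatrix(counts=matrices["RPF"], assay="RPF"),
        sheet,
        truth,
    )


def _position_weights(ps: PauseSpec, peaked: bool) -> np.ndarray:
    w = np.ones(ps.length)
    if peaked:
        for c in ps.peak_centers:
            lo = max(0, c - 1 - ps.halfwidth)
            hi = min(ps.length, c + ps.halfwidth)
            w[lo:hi] = ps.peak_fold
    return w / w.sum()


def generate_positions(
    spec: SimSpec,
) -> tuple[ReadPositionTable, pd.DataFrame]:
    """Simulate footprint positions with planted pause peaks.

    Assigned (5') positions are drawn from a uniform background whose
    per-nucleotide intensity is multiplied by ``peak_fold`` within
    +/- halfwidth of each peak center in the peak conditions; footprint
    lengths are uniform over the 26-34-nt range. One row per read with
    unique read ids; per-sample totals equal ``n_reads``.

    Returns the combined table (sample column distinguishes samples) and
    a truth table of planted peaks per condition.
    """
    ps = spec.pause
    for c in ps.peak_centers:
        if not 1 <= c <= ps.length:
            raise ValueError(f"peak center {c} outside transcript [1, {ps.length}]")
    rng = np.random.default_rng(spec.seed)
    frames = []
    libs = {}
    truth_rows = []
    for cond in ps.conditions:
        peaked = cond in ps.peak_conditions
        weights = _position_weights(ps, peaked)
        for rep in range(1, ps.replicates + 1):
            sample = f"RPF_{cond}_r{rep}"
            starts = rng.choice(ps.length, size=ps.n_reads, p=weights)
            lens = rng.integers(ps.read_len_range[0], ps.read_len_range[1] + 1,
                                ps.n_reads)
            starts = np.minimum(starts, ps.length - lens)
            frames.append(pd.DataFrame({
                "transcript_id": ps.transcript_id,
                "start": starts,
                "end": starts + lens,
                "read_id": [f"{sample}:{i}" for i in range(ps.n_reads)],
                "weight": 1,
                "sample": sample,
            }))
            libs[sample] = ps.library_size
        for c in ps.peak_centers:
            truth_rows.append({
                "transcript_id": ps.transcript_id, "condition": cond,
                "center": c, "fold": ps.peak_fold if peaked else 1.0,
            })
    table = ReadPositionTable(
        frame=pd.concat(frames, ignore_index=True), library_sizes=libs
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["seed"] = spec.seed
    return table, truth


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_fastq(spec: SimSpec) -> tuple[list[Read], pd.DataFrame]:
    """Simulate raw footprint reads for the pre-processing pipeline.

    Each unique read is UMI(umi_len) + insert (26-34 nt) + UMI(umi_len)
    + as much adapter prefix as fits the read length. PCR duplicates
    (exact copies under fresh read ids) are appended at
    ``duplicate_rate``; a ``low_quality_fraction`` of unique reads gets
    half its bases at a failing Phred score; ``base_error_rate``
    substitutes bases uniformly at random.

    Returns the reads and a truth table with each read's true insert,
    duplicate status and planted low-quality flag.
    """
    fs = spec.fastq
    if not fs.adapter:
        raise ValueError("adapter must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n_dup = int(round(fs.duplicate_rate * fs.n_reads))
    n_unique = fs.n_reads - n_dup

    reads: list[Read] = []
    rows = []
    n_low = int(round(fs.low_quality_fraction * n_unique))
    for i in range(n_unique):
        ins_len = int(rng.integers(fs.insert_len_range[0],
                                   fs.insert_len_range[1] + 1))
        insert = _random_seq(rng, ins_len)
        umi5 = _random_seq(rng, fs.umi_len)
        umi3 = _random_seq(rng, fs.umi_len)
        core = umi5 + insert + umi3
        adapter_room = max(0, fs.read_length - len(core))
        seq = (core + fs.adapter[:adapter_room])[: fs.read_length]
        if fs.base_error_rate > 0:
            chars = np.array(list(seq))
            hit = rng.random(len(chars)) < fs.base_error_rate
            chars[hit] = rng.choice(_BASES, size=int(hit.sum()))
            seq = "".join(chars)
        low = i < n_low
        quals = [fs.high_quality_phred] * len(seq)
        if low:
            for j in range(len(seq) // 2 + 1):
                quals[j] = fs.low_quality_phred
        read_id = f"read_{i:06d}"
        reads.append(Read(read_id=read_id, sequence=seq, qualities=quals))
        rows.append({"read_id": read_id, "insert": insert,
                     "is_duplicate": False, "low_quality": low,
                     "source_id": read_id})
    # duplicates: exact copies of randomly chosen originals
    if n_unique == 0 and n_dup > 0:
        raise ValueError("duplicate_rate too high for n_reads")
    for j in range(n_dup):
        src_idx = int(rng.integers(0, n_unique))
        src = reads[src_idx]
        read_id = f"read_dup_{j:06d}"
        reads.append(Read(read_id=read_id, sequence=src.sequence,
                          qualities=list(src.qualities)))
        rows.append({"read_id": read_id, "insert": rows[src_idx]["insert"],
                     "is_duplicate": True,
                     "low_quality": rows[src_idx]["low_quality"],
                     "source_id": src.read_id})
    truth = pd.DataFrame(rows).set_index("read_id")
    truth.attrs["seed"] = spec.seed
    return reads, truth
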