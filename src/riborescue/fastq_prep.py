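"""Read pre-processing for small-RNA/ribosome-profiling libraries.

Implements the footprint-library clean-up stages in their fixed order:

1. :func:`quality_filter` — drop reads where fewer than 70% of bases reach
   99% base-call accuracy (Phred >= 20 under Phred+33).
2. :func:`collapse_duplicates` — collapse PCR duplicates by full-sequence
   identity; the embedded UMIs participate in the identity key because
   collapsing precedes any trimming.
3. :func:`trim_adapter` — remove the 3' sequencing adapter
   (semi-global suffix-vs-prefix match, Cutadapt-style).
4. :func:`extract_umi` — strip the dual 4-nt unique molecular identifiers
   from both read ends and record them on the read.
5. :func:`length_filter` — keep footprints of 26-34 nt (the gel size
   selection range), optional and intended for RPF libraries only.

:func:`run_pipeline` chains the stages and returns a per-stage report.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Illumina TruSeq small-RNA 3' adapter, 21 nt.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities.

    ``multiplicity`` counts how many original reads a collapsed
    representative stands for; ``umi`` holds the concatenated 5'+3' UMI
    after :func:`extract_umi` (empty before).
    """

    read_id: str
    sequence: str
    qualities: Sequence[int]
    multiplicity: int = 1
    umi: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if self.multiplicity < 1:
            raise ValueError(f"read {self.read_id!r}: multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrepConfig:
    """Parameters of the pre-processing pipeline.

    ``min_base_phred=20`` encodes the 99% per-base accuracy cut-off
    (P(error) <= 0.01); ``min_base_accuracy_frac=0.70`` is the fraction of
    such bases a read must reach to survive. ``min_len``/``max_len``
    mirror the 26-34-mer footprint size selection.
    """

    min_base_accuracy_frac: float = 0.70
    min_base_phred: int = 20
    adapter: str = DEFAULT_ADAPTER
    umi_len_each_end: int = 4
    min_len: int = 26
    max_len: int = 34
    adapter_min_overlap: int = 3
    adapter_max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_base_accuracy_frac <= 1.0:
            raise ValueError("min_base_accuracy_frac must lie in [0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.umi_len_each_end < 0:
            raise ValueError("umi_len_each_end must be >= 0")


def quality_filter(reads: Iterable[Read], cfg: PrepConfig) -> list[Read]:
    """Keep reads where the high-accuracy base fraction reaches the cut-off.

    A read with exactly the threshold fraction (e.g. 7 of 10 bases at
    Q>=20 with a 0.70 cut-off) is kept: the rule removes only reads with
    *less than* the required fraction. Empty reads are malformed input
    and raise rather than being silently dropped.
    """
    kept: list[Read] = []
    for read in reads:
        if len(read) == 0:
            raise ValueError(f"read {read.read_id!r} has zero length")
        n_good = sum(1 for q in read.qualities if q >= cfg.min_base_phred)
        if n_good / len(read) + 1e-12 >= cfg.min_base_accuracy_frac:
            kept.append(read)
    return kept


def collapse_duplicates(reads: Iterable[Read]) -> list[Read]:
    """Collapse reads sharing an identical full sequence.

    The first-seen read becomes the representative; its multiplicity
    accumulates the multiplicities of all collapsed copies, so total
    multiplicity is conserved. Call this on raw (untrimmed) sequences so
    the embedded UMIs take part in the identity key.
    """
    by_seq: dict[str, Read] = {}
    order: list[str] = []
    for read in reads:
        rep = by_seq.get(read.sequence)
        if rep is None:
            by_seq[read.sequence] = replace(read)
            order.append(read.sequence)
        else:
            rep.multiplicity += read.multiplicity
    return [by_seq[s] for s in order]


def trim_adapter(read: Read, cfg: PrepConfig) -> Read:
    """Trim a 3' adapter by semi-global suffix-vs-prefix matching.

    The leftmost read suffix matching a prefix of the adapter with
    mismatch rate <= ``adapter_max_error_rate`` and overlap >=
    ``adapter_min_overlap`` is removed (qualities in lockstep). ``N``
    never matches an adapter base. Reads without a match are returned
    unchanged.
    """
    adapter = cfg.adapter
    if not adapter:
        raise ValueError("adapter sequence is empty")
    if len(adapter) < cfg.adapter_min_overlap:
        raise ValueError(
            f"adapter ({len(adapter)} nt) shorter than adapter_min_overlap "
            f"({cfg.adapter_min_overlap})"
        )
    seq = read.sequence
    length = len(seq)
    # A suffix can only match an adapter *prefix* of equal length, so only
    # the last len(adapter) bases are candidates. Scan left to right.
    first = max(0, length - len(adapter))
    for i in range(first, length - cfg.adapter_min_overlap + 1):
        overlap = length - i
        allowed = math.floor(cfg.adapter_max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i:], adapter):
            if a != b or a == "N" or b == "N":
                mismatches += 1
                if mismatches > allowed:
                    break
        if mismatches <= allowed:
            return replace(read, sequence=seq[:i], qualities=list(read.qualities[:i]))
    return read


def extract_umi(read: Read, cfg: PrepConfig) -> Read | None:
    """Strip the dual end UMIs; returns ``None`` for reads with no interior.

    The UMI field becomes the 5' block followed by the 3' block
    (``umi_len_each_end`` nt each); sequence and qualities shrink to the
    interior. A read of length <= 2 x ``umi_len_each_end`` carries no
    insert and is discarded (caller counts discards).
    """
    u = cfg.umi_len_each_end
    if u == 0 or read.umi:
        return read
    if len(read) <= 2 * u:
        return None
    seq = read.sequence
    return replace(
        read,
        sequence=seq[u:-u],
        qualities=list(read.qualities[u:-u]),
        umi=seq[:u] + seq[-u:],
    )


def length_filter(reads: Iterable[Read], cfg: PrepConfig) -> list[Read]:
    """Keep reads within the footprint size range (inclusive bounds)."""
    return [r for r in reads if cfg.min_len <= len(r) <= cfg.max_len]


def run_pipeline(
    reads: Iterable[Read],
    cfg: PrepConfig | None = None,
    apply_length_filter: bool = True,
) -> tuple[list[Read], dict[str, int]]:
    """Run the full pre-processing chain in its fixed order.

    Order: quality filter -> duplicate collapse -> adapter trim -> UMI
    extraction -> length selection. ``apply_length_filter=False`` skips
    the final stage (RNA-seq libraries have no gel size selection).

    Returns the surviving reads and a report with read counts after each
    stage plus the number of reads discarded as too short at UMI removal.
    """
    if cfg is None:
        cfg = PrepConfig()
    reads = list(reads)
    report = {"input": len(reads)}
    reads = quality_filter(reads, cfg)
    report["after_quality_filter"] = len(reads)
    reads = collapse_duplicates(reads)
    report["after_collapse"] = len(reads)
    reads = [trim_adapter(r, cfg) for r in reads]
    report["after_adapter_trim"] = len(reads)
    survivors: list[Read] = []
    discarded = 0
    for r in reads:
        out = extract_umi(r, cfg)
        if out is None:
            discarded += 1
        else:
            survivors.append(out)
    reads = survivors
    report["discarded_no_insert"] = discarded
    report["after_umi_extraction"] = len(reads)
    if apply_length_filter:
        reads = length_filter(reads, cfg)
    report["after_length_filter"] = len(reads)
    if discarded:
        logger.info("discarded %d reads with no insert after UMI removal", discarded)
    return reads, report


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Phred+33; .gz transparently handled)

def _open_text(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a FASTQ file (Phred+33, optionally gzipped)."""
    from Bio import SeqIO

    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield Read(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads to a FASTQ file; returns the number written."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with _open_text(path, "w") as handle:
        return seqio_write(records, handle, "fastq")
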