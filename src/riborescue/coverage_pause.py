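"""Per-nucleotide footprint coverage and windowed ribosome-accumulation tests.

Footprints are reduced to a single assigned transcript position (their
5' end by default, or an offset P-site). Coverage profiles are reads
per nucleotide per million library reads (rpm). Local ribosome
accumulation ("pausing") at a focal nucleotide is scored by counting
distinct reads in the symmetric 25-nt window around it (halfwidth 12),
normalizing each replicate's count to its library size, and comparing
conditions with a pooled-variance two-sample Student's t test.
:func:`scan_pauses` generalizes the single-position test to a
transcript-wide scan for candidate pause sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BED_COLUMNS = ["transcript_id", "start", "end", "read_id", "weight", "sample"]


@dataclass
class ReadPositionTable:
    """Per-read transcript intervals with per-sample library sizes.

    ``frame`` columns: transcript_id, start (0-based incl.), end
    (0-based excl.), read_id, weight, sample. ``library_sizes`` maps
    sample id -> total mapped reads in that library.
    """

    frame: pd.DataFrame
    library_sizes: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(BED_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"position table missing columns: {sorted(missing)}")
        if (self.frame["start"] >= self.frame["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")

    @classmethod
    def from_tsv(cls, bed_path, library_sizes_path) -> "ReadPositionTable":
        frame = pd.read_csv(bed_path, sep="\t", names=BED_COLUMNS, header=None,
                            comment="#")
        libs = pd.read_csv(library_sizes_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(frame=frame, library_sizes=libs.to_dict())

    def to_tsv(self, bed_path, library_sizes_path) -> None:
        self.frame[BED_COLUMNS].to_csv(bed_path, sep="\t", header=False, index=False)
        pd.Series(self.library_sizes, name="library_size").rename_axis(
            "sample").to_csv(library_sizes_path, sep="\t")


@dataclass
class CoverageProfile:
    """Per-nucleotide normalized footprint coverage for one sample.

    ``values[i]`` is reads per nucleotide per million library reads at
    0-based transcript position i.
    """

    transcript_id: str
    sample_id: str
    values: np.ndarray
    library_size: float
    offset_mode: str = "five_prime"

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass
class PauseTest:
    """Windowed accumulation test at one focal nucleotide."""

    transcript_id: str
    center: int  # 1-based
    halfwidth: int
    raw_counts: dict[str, list[float]]  # condition -> per-replicate counts
    normalized: dict[str, list[float]]  # condition -> per-million counts
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero within-group variance with unequal means

    @property
    def window_width(self) -> int:
        return 2 * self.halfwidth + 1


def assign_position(
    start,
    end,
    offset_mode: str = "five_prime",
    p_site_offset: int = 12,
):
    """Reduce a footprint interval to one assigned position.

    ``five_prime`` uses the read start; ``p_site`` offsets it by
    ``p_site_offset`` nt, clipped to the last base of the read. Accepts
    scalars or arrays.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    if offset_mode == "five_prime":
        pos = start
    elif offset_mode == "p_site":
        pos = np.minimum(start + p_site_offset, end - 1)
    else:
        raise ValueError(f"unknown offset_mode {offset_mode!r}")
    return pos if pos.ndim else pos.item()


def _subset(table: ReadPositionTable, transcript_id: str, sample: str) -> pd.DataFrame:
    df = table.frame
    return df[(df["transcript_id"] == transcript_id) & (df["sample"] == sample)]


def coverage_profile(
    table: ReadPositionTable,
    transcript_id: str,
    sample: str,
    length: int,
    offset_mode: str = "five_prime",
    p_site_offset: int = 12,
) -> CoverageProfile:
    """Reads-per-nucleotide-per-million profile over one transcript.

    Each read contributes its weight at its single assigned position;
    values are scaled by 1e6 / library_size. An absent transcript gives
    an all-zero profile with a warning.
    """
    lib = float(table.library_sizes[sample])
    sub = _subset(table, transcript_id, sample)
    values = np.zeros(length, float)
    if sub.empty:
        warnings.warn(f"transcript {transcript_id!r} absent in sample {sample!r}; "
                      "returning zero profile")
    else:
        pos = assign_position(sub["start"].to_numpy(), sub["end"].to_numpy(),
                              offset_mode, p_site_offset)
        np.add.at(values, np.clip(pos, 0, length - 1),
                  sub["weight"].to_numpy(float))
        values *= 1e6 / lib
    return CoverageProfile(
        transcript_id=transcript_id, sample_id=sample, values=values,
        library_size=lib, offset_mode=offset_mode,
    )


def window_count(
    table: ReadPositionTable,
    transcript_id: str,
    sample: str,
    center_1based: int,
    halfwidth: int = 12,
    offset_mode: str = "five_prime",
    p_site_offset: int = 12,
    transcript_length: int | None = None,
) -> int:
    """Distinct reads assigned within the symmetric window around a center.

    The window is [center - halfwidth, center + halfwidth] in 1-based
    inclusive coordinates (25 nt at the default halfwidth of 12);
    windows reaching past the transcript ends are truncated with a
    warning.
    """
    if center_1based < 1:
        raise ValueError("center must be >= 1 (1-based)")
    lo = center_1based - halfwidth  # 1-based
    hi = center_1based + halfwidth
    if lo < 1 or (transcript_length is not None and hi > transcript_length):
        warnings.warn("window truncated at transcript bounds")
        lo = max(lo, 1)
        if transcript_length is not None:
            hi = min(hi, transcript_length)
    sub = _subset(table, transcript_id, sample)
    if sub.empty:
        return 0
    pos = assign_position(sub["start"].to_numpy(), sub["end"].to_numpy(),
                          offset_mode, p_site_offset)
    inside = (pos >= lo - 1) & (pos <= hi - 1)  # 0-based comparison
    return int(sub.loc[inside, "read_id"].nunique())


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, bool]:
    """Pooled-variance two-sample t of b vs a; handles degenerate variance."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = b.mean() - a.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0, False
        return float(np.sign(diff)) * np.inf, df, 0.0, True
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), df, p, False


def pause_test(
    counts_by_condition: Mapping[str, Sequence[tuple[float, float]]],
    cond_a: str,
    cond_b: str,
    transcript_id: str = "",
    center: int = 0,
    halfwidth: int = 12,
    welch: bool = False,
) -> PauseTest:
    """Student's t test on library-normalized window counts, B vs A.

    ``counts_by_condition`` maps condition -> [(raw_count, library_size),
    ...] over replicates. Counts are scaled to per-million before the
    two-sided t test: pooled variance with df = nA + nB - 2 by default,
    or Welch (unequal variances, Satterthwaite df, reported rounded
    down) with ``welch=True``. A positive t means accumulation in
    ``cond_b``. Zero variance in both groups with equal means gives
    t = 0, p = 1; with unequal means the result is flagged
    ``degenerate`` and p is reported as 0.
    """
    for cond in (cond_a, cond_b):
        if cond not in counts_by_condition:
            raise ValueError(f"condition {cond!r} missing")
        if len(counts_by_condition[cond]) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
    raw = {c: [float(cnt) for cnt, _ in counts_by_condition[c]]
           for c in (cond_a, cond_b)}
    norm = {c: [cnt / lib * 1e6 for cnt, lib in counts_by_condition[c]]
            for c in (cond_a, cond_b)}
    a = np.asarray(norm[cond_a], float)
    b = np.asarray(norm[cond_b], float)
    if welch and (a.var(ddof=1) > 0 or b.var(ddof=1) > 0):
        res = stats.ttest_ind(b, a, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df, degenerate = int(res.df), False
    else:
        t, df, p, degenerate = _pooled_t(a, b)
    return PauseTest(
        transcript_id=transcript_id, center=center, halfwidth=halfwidth,
        raw_counts=raw, normalized=norm, t=t, df=df, p=p, degenerate=degenerate,
    )


@dataclass
class PauseCandidate:
    """A candidate pause site from :func:`scan_pauses`."""

    center: int  # 1-based
    ratio: float
    test: PauseTest


def _window_sums(values: np.ndarray, halfwidth: int) -> np.ndarray:
    kernel = np.ones(2 * halfwidth + 1)
    return np.convolve(values, kernel, mode="same")


def scan_pauses(
    profiles_a: Sequence[CoverageProfile],
    profiles_b: Sequence[CoverageProfile],
    min_ratio: float = 2.0,
    halfwidth: int = 12,
    pseudocount: float = 0.1,
) -> list[PauseCandidate]:
    """Scan for positions where condition B accumulates footprints over A.

    Per replicate, per-nucleotide rpm values are summed over the sliding
    25-nt window (truncated at the ends). Candidates are positions where
    the ratio of condition-mean windowed coverage (B + pc)/(A + pc)
    reaches ``min_ratio`` and is a strict local maximum (>= both
    neighbours, > at least one). Each candidate carries the
    pooled-variance t test on the per-replicate windowed values.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both condition profile lists must be non-empty")
    lengths = {p.length for p in list(profiles_a) + list(profiles_b)}
    if len(lengths) != 1:
        raise ValueError("all profiles must share the transcript length")
    tx = profiles_a[0].transcript_id
    win_a = np.stack([_window_sums(p.values, halfwidth) for p in profiles_a])
    win_b = np.stack([_window_sums(p.values, halfwidth) for p in profiles_b])
    ratio = (win_b.mean(axis=0) + pseudocount) / (win_a.mean(axis=0) + pseudocount)
    n = len(ratio)
    candidates: list[PauseCandidate] = []
    for i in range(n):
        if ratio[i] < min_ratio:
            continue
        left = ratio[i - 1] if i > 0 else -np.inf
        right = ratio[i + 1] if i < n - 1 else -np.inf
        if ratio[i] >= left and ratio[i] >= right and (ratio[i] > left or ratio[i] > right):
            a_vals = win_a[:, i]
            b_vals = win_b[:, i]
            t, df, p, degenerate = _pooled_t(a_vals, b_vals)
            test = PauseTest(
                transcript_id=tx, center=i + 1, halfwidth=halfwidth,
                raw_counts={}, normalized={"A": a_vals.tolist(), "B": b_vals.tolist()},
                t=t, df=df, p=p, degenerate=degenerate,
            )
            candidates.append(PauseCandidate(center=i + 1, ratio=float(ratio[i]),
                                             test=test))
    return candidates
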