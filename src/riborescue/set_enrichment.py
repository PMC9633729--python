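"""Gene-set overlap and motif-instance enrichment.

Overlap between a query list (e.g. screen targets) and a reference set
(e.g. a CLIP-derived RNA-binding-protein target list, or a c-Myc
signature from a GMT file) is scored with the upper-tail hypergeometric
test over a stated gene universe. Motif enrichment counts IUPAC pattern
instances in transcript FASTA sequences and compares per-kilobase
instance densities between a query and a background group with a
two-sided rank-sum test. The default motif "TCCCW" is a poly-C-class
pattern of the KH-domain RNA-binding protein family (hnRNPK-like).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes mapped to the concrete bases they match.
#: N is deliberately the empty set: an N on either side matches nothing,
#: so ambiguous sequencing calls never create motif instances.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset(),
}

DEFAULT_MOTIF_PATTERN = "TCCCW"


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Motif:
    """An IUPAC nucleotide pattern (U and T equivalent)."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.upper().replace("U", "T")
        if not pat:
            raise ValueError("motif pattern is empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in motif: {sorted(bad)}")
        object.__setattr__(self, "pattern", pat)


@dataclass
class OverlapResult:
    """Overlap size and hypergeometric enrichment of query vs reference."""

    k: int
    n_query: int
    n_set: int
    n_universe: int
    pct_query: float
    p_hyper: float
    jaccard: float


@dataclass
class MotifEnrichmentResult:
    """Rank-sum comparison of per-kb motif instance densities."""

    motif: str
    median_query: float
    median_background: float
    u_stat: float
    p: float
    n_query: int
    n_background: int


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, members=frozenset(members), source=desc))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source or "na", *sorted(gs.members)]) + "\n")


def overlap_test(query: GeneSet, reference: GeneSet, universe: GeneSet) -> OverlapResult:
    """Upper-tail hypergeometric overlap test within a gene universe.

    Query/reference members outside the universe are dropped with a
    logged count. p = P(X >= k) for X ~ Hypergeom(N=|universe|,
    K=|reference|, n=|query|); the upper tail includes k itself, so an
    empty overlap gives p = 1.
    """
    if not universe.members:
        raise ValueError("universe is empty")
    q = query.members & universe.members
    r = reference.members & universe.members
    dropped = (len(query.members) - len(q)) + (len(reference.members) - len(r))
    if dropped:
        logger.info("dropped %d query/reference genes outside the universe", dropped)
    if not q:
        raise ValueError("no query genes inside the universe")
    k = len(q & r)
    N, K, n = len(universe.members), len(r), len(q)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(
        k=k,
        n_query=n,
        n_set=K,
        n_universe=N,
        pct_query=k / n,
        p_hyper=min(max(p, np.nextafter(0, 1)), 1.0),
        jaccard=len(q & r) / len(q | r) if (q | r) else 0.0,
    )


def motif_instances(sequence: str, motif: Motif) -> int:
    """Count (possibly overlapping) IUPAC pattern matches in a sequence."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    pat = [IUPAC[c] for c in motif.pattern]
    m = len(pat)
    count = 0
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in pat[j] for j in range(m)):
            count += 1
    return count


def motif_density_per_kb(sequence: str, motif: Motif) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    return motif_instances(sequence, motif) / len(sequence) * 1000.0


def motif_enrichment(
    query_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    motif: Motif,
    max_exact: int = 20000,
) -> MotifEnrichmentResult:
    """Compare motif densities (instances/kb) between two sequence groups.

    Two-sided Mann-Whitney rank-sum test; when the number of group
    assignments C(n1+n2, n1) is at most ``max_exact`` the permutation
    null is enumerated exactly (ties handled correctly), otherwise the
    normal approximation with tie correction is used. All-tied inputs
    yield p = 1 with a warning.
    """
    if not query_seqs or not background_seqs:
        raise ValueError("both sequence groups must be non-empty")
    dq = np.array([motif_density_per_kb(s, motif) for s in query_seqs.values()])
    db = np.array([motif_density_per_kb(s, motif) for s in background_seqs.values()])
    n1, n2 = len(dq), len(db)
    if len(set(dq.tolist()) | set(db.tolist())) == 1:
        warnings.warn("all motif densities identical; p set to 1")
        return MotifEnrichmentResult(
            motif=motif.pattern, median_query=float(np.median(dq)),
            median_background=float(np.median(db)),
            u_stat=n1 * n2 / 2.0, p=1.0, n_query=n1, n_background=n2,
        )
    if comb(n1 + n2, n1) <= max_exact:
        method = stats.PermutationMethod(n_resamples=max_exact + 1)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(dq, db, alternative="two-sided", method=method)
    return MotifEnrichmentResult(
        motif=motif.pattern,
        median_query=float(np.median(dq)),
        median_background=float(np.median(db)),
        u_stat=float(res.statistic),
        p=float(res.pvalue),
        n_query=n1,
        n_background=n2,
    )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
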