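"""Negative-binomial differential-abundance testing for RNA and RPF counts.

A deliberately simple DESeq2-style layer: median-of-ratios size factors,
method-of-moments negative-binomial dispersion, a per-gene Wald test on
log2 fold changes of normalized group means, and Benjamini-Hochberg
correction. RNA-seq and ribosome-footprint (RPF) count matrices are
tested independently with the same machinery.

The model: counts for gene g in sample j are NB with mean s_j * mu_g(cond)
and variance mu + alpha * mu^2 (alpha = overdispersion). The Wald
statistic is lfc / se with

    lfc = log2((m_test + c) / (m_ref + c)),   c = 0.5 pseudocount,
    se^2 = (1/ln 2)^2 * sum_groups [ 1 / (n * (m + c)) + alpha / n ],

a delta-method approximation to the variance of the log2 group-mean
ratio, referred to the standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: Canonical condition labels of the four-condition rescue design:
#: wild type, Fbxo4 knock-out, and each with hnRNPK knock-down.
CONDITIONS = ("WT", "KO", "WT_KD", "KO_KD")
ASSAYS = ("RNA", "RPF")


@dataclass
class SampleSheet:
    """Sample metadata: sample_id -> (condition, assay, replicate, library_size).

    ``frame`` must carry columns sample_id, condition, assay, replicate
    (and optionally library_size). (condition, assay, replicate) triples
    must be unique; testing requires >= 2 replicates per group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "assay", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.frame["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        bad = set(self.frame["assay"]) - set(ASSAYS)
        if bad:
            raise ValueError(f"unknown assay labels: {sorted(bad)}")
        triples = self.frame[["condition", "assay", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("(condition, assay, replicate) triples must be unique")

    def samples(self, condition: str | None = None, assay: str | None = None) -> list[str]:
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        if assay is not None:
            df = df[df["assay"] == assay]
        return list(df["sample_id"])

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Integer gene x sample counts for one assay.

    ``counts`` is a genes x samples DataFrame (gene ids as index);
    ``size_factors`` (geometric mean 1) is set by :func:`size_factors`.
    """

    counts: pd.DataFrame
    assay: str
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if self.size_factors is not None:
            self._check_size_factors()

    def _check_size_factors(self) -> None:
        sf = self.size_factors
        if not sf.index.equals(self.counts.columns):
            raise ValueError("size factor index does not match samples")
        if (sf <= 0).any():
            raise ValueError("size factors must be positive")
        if abs(float(np.exp(np.mean(np.log(sf)))) - 1.0) > 1e-9:
            raise ValueError("size factors must have geometric mean 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors (computed if unset)."""
        if self.size_factors is None:
            self.size_factors = size_factors(self)
        return self.counts / self.size_factors

    @classmethod
    def from_tsv(cls, path, assay: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, assay=assay)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = out.index.name or "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class DispersionModel:
    """Per-gene NB overdispersion alpha (Var = mu + alpha * mu^2).

    ``method="moments"`` keeps the raw per-gene moment estimates;
    ``method="pooled"`` replaces them with their across-gene mean, which
    stabilises Wald standard errors at the duplicate/triplicate
    replication this design uses.
    """

    dispersion: pd.Series
    method: str

    def __post_init__(self) -> None:
        d = self.dispersion.to_numpy(float)
        if not np.all(np.isfinite(d)) or (d < 0).any():
            raise ValueError("dispersions must be finite and non-negative")


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the median over all-positive genes of
    count / geometric-mean-across-samples. Genes with a zero in any
    sample are excluded from the median (standard median-of-ratios).
    """
    counts = cm.counts.to_numpy(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "use a total-count fallback normalization instead"
        )
    sub = counts[all_pos]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_gm
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - np.mean(log_sf)  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=cm.counts.columns, name="size_factor")


def estimate_dispersion(
    cm: CountMatrix,
    sheet: SampleSheet,
    method: str = "pooled",
    floor: float = 1e-8,
) -> DispersionModel:
    """Method-of-moments NB dispersion from within-condition replicates.

    Per gene and replicate group: alpha = max(0, (s^2 - mean) / mean^2)
    on normalized counts; per-group estimates are averaged with weights
    equal to group size. Groups with a single replicate are skipped;
    if every group is single-replicate this raises. With
    ``method="pooled"`` the per-gene estimates are then averaged across
    genes into one common value (see :class:`DispersionModel`).
    """
    if method not in ("moments", "pooled"):
        raise ValueError("method must be 'moments' or 'pooled'")
    norm = cm.normalized()
    estimates: list[np.ndarray] = []
    weights: list[int] = []
    for cond in CONDITIONS:
        ids = [s for s in sheet.samples(condition=cond, assay=cm.assay)
               if s in norm.columns]
        if len(ids) < 2:
            if ids:
                logger.info("skipping single-replicate group %s/%s", cond, cm.assay)
            continue
        group = norm[ids].to_numpy(float)
        mu = group.mean(axis=1)
        s2 = group.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.square(np.maximum(mu, 1e-300)), 0.0)
        estimates.append(np.maximum(a, 0.0))
        weights.append(len(ids))
    if not estimates:
        raise ValueError("no condition group has >= 2 replicates")
    per_gene = np.average(np.stack(estimates), axis=0,
                          weights=np.asarray(weights, float))
    per_gene = np.maximum(per_gene, floor)
    if method == "pooled":
        per_gene = np.full_like(per_gene, max(float(per_gene.mean()), floor))
    return DispersionModel(
        dispersion=pd.Series(per_gene, index=cm.gene_ids, name="dispersion"),
        method=method,
    )


def wald_p_value(z) -> np.ndarray | float:
    """Two-sided standard-normal tail probability of a Wald statistic."""
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, float)
    if arr.size == 0:
        return arr.copy()
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def wald_test(
    cm: CountMatrix,
    sheet: SampleSheet,
    ref_cond: str,
    test_cond: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.5,
    dispersion: DispersionModel | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``test_cond`` vs ``ref_cond``.

    Returns a DataFrame (index gene_id) with columns base_mean, lfc, se,
    wald, p, padj and direction (up/down/ns by ``padj < alpha`` and
    ``|lfc| >= lfc_threshold``, boundary included). The contrast is
    recorded in ``.attrs["contrast"]`` as (ref, test, assay). Genes with
    zero counts in every sample of the assay are dropped with a logged
    count. Dispersions default to the pooled estimate over all
    condition groups in the sheet.
    """
    for cond in (ref_cond, test_cond):
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
    ref_ids = sheet.samples(condition=ref_cond, assay=cm.assay)
    test_ids = sheet.samples(condition=test_cond, assay=cm.assay)
    if not ref_ids or not test_ids:
        raise ValueError(
            f"conditions {ref_cond}/{test_cond} missing for assay {cm.assay}"
        )
    norm = cm.normalized()
    used = sheet.samples(assay=cm.assay)
    nonzero = cm.counts[used].sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d genes with all-zero counts", n_dropped)
    norm = norm.loc[nonzero]
    if dispersion is None:
        dispersion = estimate_dispersion(cm, sheet)
    disp = dispersion.dispersion.loc[norm.index].to_numpy(float)

    c = pseudocount
    m_ref = norm[ref_ids].mean(axis=1).to_numpy(float)
    m_test = norm[test_ids].mean(axis=1).to_numpy(float)
    n_ref, n_test = len(ref_ids), len(test_ids)
    lfc = np.log2((m_test + c) / (m_ref + c))
    se2 = (1.0 / LN2) ** 2 * (
        1.0 / (n_ref * (m_ref + c)) + disp / n_ref
        + 1.0 / (n_test * (m_test + c)) + disp / n_test
    )
    se = np.sqrt(se2)
    wald = lfc / se
    p = wald_p_value(wald)
    padj = bh_adjust(p)
    direction = np.where(
        (padj < alpha) & (lfc >= lfc_threshold), "up",
        np.where((padj < alpha) & (lfc <= -lfc_threshold), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "base_mean": norm[ref_ids + test_ids].mean(axis=1).to_numpy(float),
            "lfc": lfc,
            "se": se,
            "wald": wald,
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=norm.index,
    )
    out.index.name = "gene_id"
    out.attrs["contrast"] = (ref_cond, test_cond, cm.assay)
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
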