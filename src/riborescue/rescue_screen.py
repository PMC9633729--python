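"""Three-criterion rescue-based selection of pathway target genes.

A gene is called a target of the ubiquitin-ligase/RNA-binding-protein
axis when, on at least one assay layer (RNA or RPF), all of:

I.   it responds at least 2-fold to the knock-out (|lfc_ko| >= 1 in
     log2 units on that layer), with adjusted p < 0.05 in the knock-out
     contrast on *either* layer;
II.  the response is rescued by >= 25% when the RNA-binding protein is
     additionally knocked down in the knock-out
     (rescue fraction (lfc_ko - lfc_ko_kd) / lfc_ko >= 0.25, fold-change
     only, no p-value gate);
III. the knock-down alone moves the gene in the opposite direction to
     the knock-out, or has no effect (|lfc_wt_kd| below a 1.5-fold
     "no effect" band).

All log2 fold changes are contrasts against the wild type. Criteria are
evaluated per layer; a gene qualifies through any single layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("RNA", "RPF")


@dataclass
class ScreenConfig:
    """Thresholds of the three-criterion screen.

    ``fold_threshold`` and ``null_lfc`` are in log2 units (defaults: the
    2-fold response cut-off and a 1.5-fold "no effect" band);
    ``rescue_min`` is the minimum rescued fraction of the knock-out
    response; ``rescue_scale`` chooses the scale the rescue fraction is
    computed on ("log2", default, or "linear").
    """

    fold_threshold: float = 1.0
    alpha: float = 0.05
    rescue_min: float = 0.25
    null_lfc: float = float(np.log2(1.5))
    rescue_scale: str = "log2"

    def __post_init__(self) -> None:
        if not 0 < self.rescue_min <= 1:
            raise ValueError("rescue_min must lie in (0, 1]")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if self.rescue_scale not in ("log2", "linear"):
            raise ValueError("rescue_scale must be 'log2' or 'linear'")


def rescue_fraction(lfc_ko: float, lfc_ko_kd: float) -> float:
    """Fraction of the knock-out response reverted by the double depletion.

    Computed on log2 fold changes vs wild type:
    (lfc_ko - lfc_ko_kd) / lfc_ko. May exceed 1 (over-rescue) or go
    negative (aggravation). Undefined when the knock-out response is 0.
    """
    if lfc_ko == 0:
        raise ValueError("rescue fraction undefined for lfc_ko == 0")
    return (lfc_ko - lfc_ko_kd) / lfc_ko


def _rescue_frac_vec(lko: np.ndarray, lkokd: np.ndarray, scale: str) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        if scale == "log2":
            return np.where(lko != 0, (lko - lkokd) / np.where(lko == 0, 1, lko), np.nan)
        # linear: fraction of the linear-scale departure from WT reverted
        dep_ko = np.abs(np.exp2(lko) - 1.0)
        dep_kokd = np.abs(np.exp2(lkokd) - 1.0)
        return np.where(dep_ko > 0, (dep_ko - dep_kokd) / np.where(dep_ko == 0, 1, dep_ko), np.nan)


def select_targets(
    de_ko_rna: pd.DataFrame,
    de_ko_rpf: pd.DataFrame,
    de_kokd_rna: pd.DataFrame,
    de_kokd_rpf: pd.DataFrame,
    de_wtkd_rna: pd.DataFrame,
    de_wtkd_rpf: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Evaluate criteria I-III per gene and per layer on six WT-referenced
    differential tables (KO, KO+KD, WT+KD; each on RNA and RPF).

    Returns a DataFrame indexed by gene_id with, for each layer prefix
    ``rna_``/``rpf_``: lfc_ko, lfc_ko_kd, lfc_wt_kd, padj_ko,
    rescue_frac (NaN unless criterion I holds on that layer), crit_i,
    crit_ii, crit_iii and pass columns, plus ``is_target`` and
    ``qualifying_layers``. Gene universes are restricted to the
    intersection of all six tables (logged).
    """
    if cfg is None:
        cfg = ScreenConfig()
    tables = {
        ("RNA", "ko"): de_ko_rna, ("RPF", "ko"): de_ko_rpf,
        ("RNA", "ko_kd"): de_kokd_rna, ("RPF", "ko_kd"): de_kokd_rpf,
        ("RNA", "wt_kd"): de_wtkd_rna, ("RPF", "wt_kd"): de_wtkd_rpf,
    }
    genes = None
    for t in tables.values():
        genes = t.index if genes is None else genes.intersection(t.index)
    n_union = len(pd.Index([]).union(tables[("RNA", "ko")].index).union(
        tables[("RPF", "ko")].index))
    dropped = max(t.index.size for t in tables.values()) - genes.size
    if dropped > 0:
        logger.info("restricting to %d shared genes (dropped up to %d)",
                    genes.size, dropped)

    padj_ko = {l: tables[(l, "ko")]["padj"].loc[genes].to_numpy(float) for l in LAYERS}
    sig_either = (padj_ko["RNA"] < cfg.alpha) | (padj_ko["RPF"] < cfg.alpha)

    out = pd.DataFrame(index=genes)
    out.index.name = "gene_id"
    layer_pass = {}
    for layer in LAYERS:
        pre = layer.lower()
        lko = tables[(layer, "ko")]["lfc"].loc[genes].to_numpy(float)
        lkokd = tables[(layer, "ko_kd")]["lfc"].loc[genes].to_numpy(float)
        lwtkd = tables[(layer, "wt_kd")]["lfc"].loc[genes].to_numpy(float)
        crit_i = (np.abs(lko) >= cfg.fold_threshold) & sig_either
        rf = _rescue_frac_vec(lko, lkokd, cfg.rescue_scale)
        rf = np.where(crit_i, rf, np.nan)
        crit_ii = crit_i & (rf >= cfg.rescue_min)
        crit_iii = (np.sign(lwtkd) != np.sign(lko)) | (np.abs(lwtkd) < cfg.null_lfc)
        passed = crit_i & crit_ii & crit_iii
        layer_pass[layer] = passed
        out[f"{pre}_lfc_ko"] = lko
        out[f"{pre}_lfc_ko_kd"] = lkokd
        out[f"{pre}_lfc_wt_kd"] = lwtkd
        out[f"{pre}_padj_ko"] = padj_ko[layer]
        out[f"{pre}_rescue_frac"] = rf
        out[f"{pre}_crit_i"] = crit_i
        out[f"{pre}_crit_ii"] = crit_ii
        out[f"{pre}_crit_iii"] = crit_iii
        out[f"{pre}_pass"] = passed
    out["is_target"] = layer_pass["RNA"] | layer_pass["RPF"]
    out["qualifying_layers"] = [
        ",".join(l for l in LAYERS if layer_pass[l][i])
        for i in range(len(genes))
    ]
    return out


def screen_from_counts(
    rna_cm,
    rpf_cm,
    sheet,
    cfg: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the full screen from count matrices.

    Computes the six WT-referenced Wald contrasts (KO, KO_KD, WT_KD on
    each assay layer) and applies :func:`select_targets`. Returns the
    calls and the contrast tables keyed by (condition, assay).
    """
    from .de_core import wald_test

    if cfg is None:
        cfg = ScreenConfig()
    tables = {}
    for cm in (rna_cm, rpf_cm):
        for cond in ("KO", "KO_KD", "WT_KD"):
            tables[(cond, cm.assay)] = wald_test(
                cm, sheet, "WT", cond,
                alpha=cfg.alpha, lfc_threshold=cfg.fold_threshold)
    calls = select_targets(
        tables[("KO", "RNA")], tables[("KO", "RPF")],
        tables[("KO_KD", "RNA")], tables[("KO_KD", "RPF")],
        tables[("WT_KD", "RNA")], tables[("WT_KD", "RPF")], cfg)
    return calls, tables


def screen_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Criteria funnel: gene counts surviving each criterion per layer."""
    out: dict[str, int] = {"genes": int(len(calls))}
    for pre in ("rna", "rpf"):
        out[f"{pre}_crit_i"] = int(calls[f"{pre}_crit_i"].sum())
        out[f"{pre}_crit_i_ii"] = int(calls[f"{pre}_crit_ii"].sum())
        out[f"{pre}_pass"] = int(calls[f"{pre}_pass"].sum())
    out["targets"] = int(calls["is_target"].sum())
    return out
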