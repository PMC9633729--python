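"""Translation efficiency (RPF/RNA) and per-gene regulatory event classes.

Apparent translation efficiency for a gene in one condition is the ratio
of its normalized ribosome-footprint abundance to its normalized mRNA
abundance (pseudocount-stabilised). Comparing a test condition to a
reference, each gene is assigned one of five event classes from its RNA
and RPF differential calls:

========== ==================================================
concordant both layers significant, same direction
rna_only   mRNA level changes, footprints do not (buffering)
rpf_only   footprints change, mRNA does not (translational)
discordant both significant, opposite directions
none       neither layer significant
========== ==================================================
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .de_core import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

EVENT_CLASSES = ("concordant", "rna_only", "rpf_only", "discordant", "none")


def translation_efficiency(
    rna_cm: CountMatrix,
    rpf_cm: CountMatrix,
    sheet: SampleSheet,
    condition: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene TE in one condition: (mean norm RPF + c) / (mean norm RNA + c).

    Genes present in only one matrix are excluded with a logged count.
    """
    shared = rna_cm.gene_ids.intersection(rpf_cm.gene_ids)
    n_dropped = len(rna_cm.gene_ids.union(rpf_cm.gene_ids)) - len(shared)
    if n_dropped:
        logger.info("excluding %d genes absent from one assay", n_dropped)
    rna_ids = sheet.samples(condition=condition, assay="RNA")
    rpf_ids = sheet.samples(condition=condition, assay="RPF")
    if not rna_ids or not rpf_ids:
        raise ValueError(f"condition {condition!r} missing from one assay")
    m_rna = rna_cm.normalized().loc[shared, rna_ids].mean(axis=1)
    m_rpf = rpf_cm.normalized().loc[shared, rpf_ids].mean(axis=1)
    te = (m_rpf + pseudocount) / (m_rna + pseudocount)
    te.name = f"te_{condition}"
    return te


def classify_event(rna_de: pd.DataFrame, rpf_de: pd.DataFrame) -> pd.Series:
    """Assign each gene an event class from its RNA and RPF direction calls.

    Operates on the union of the two gene universes; genes missing from
    either table fall in class ``none`` (logged).
    """
    union = rna_de.index.union(rpf_de.index)
    missing = len(union) - len(rna_de.index.intersection(rpf_de.index))
    if missing:
        logger.info("%d genes missing from one DE table -> class 'none'", missing)
    rna = rna_de["direction"].reindex(union, fill_value="ns")
    rpf = rpf_de["direction"].reindex(union, fill_value="ns")
    in_both = union.isin(rna_de.index) & union.isin(rpf_de.index)
    rna_sig = (rna != "ns") & in_both
    rpf_sig = (rpf != "ns") & in_both
    out = np.full(len(union), "none", dtype=object)
    out[rna_sig & rpf_sig & (rna == rpf)] = "concordant"
    out[rna_sig & rpf_sig & (rna != rpf)] = "discordant"
    out[rna_sig & ~rpf_sig] = "rna_only"
    out[~rna_sig & rpf_sig] = "rpf_only"
    classes = pd.Series(out, index=union, name="event_class")
    classes.index.name = "gene_id"
    return classes


def event_summary(classes: Iterable[str]) -> dict[str, int]:
    """Count genes per event class; all five classes always present."""
    counts = Counter(classes)
    unknown = set(counts) - set(EVENT_CLASSES)
    if unknown:
        raise ValueError(f"unknown event classes: {sorted(unknown)}")
    return {c: counts.get(c, 0) for c in EVENT_CLASSES}


def te_table(
    rna_cm: CountMatrix,
    rpf_cm: CountMatrix,
    sheet: SampleSheet,
    ref_cond: str,
    test_cond: str,
    rna_de: pd.DataFrame,
    rpf_de: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full per-gene TE record for one contrast.

    Columns: te_ref, te_test, delta_te (log2 te_test/te_ref),
    rna_direction, rpf_direction, event_class.
    """
    te_ref = translation_efficiency(rna_cm, rpf_cm, sheet, ref_cond, pseudocount)
    te_test = translation_efficiency(rna_cm, rpf_cm, sheet, test_cond, pseudocount)
    classes = classify_event(rna_de, rpf_de)
    genes = te_ref.index.intersection(classes.index)
    out = pd.DataFrame(
        {
            "te_ref": te_ref.loc[genes],
            "te_test": te_test.loc[genes],
            "delta_te": np.log2(te_test.loc[genes] / te_ref.loc[genes]),
            "rna_direction": rna_de["direction"].reindex(genes, fill_value="ns"),
            "rpf_direction": rpf_de["direction"].reindex(genes, fill_value="ns"),
            "event_class": classes.loc[genes],
        }
    )
    out.index.name = "gene_id"
    out.attrs["contrast"] = (ref_cond, test_cond)
    return out
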