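"""LPS-acylation and SCFA biosynthetic capacity profiling.

Taxa are classified from lipid-A pathway gene presence: the full pathway makes
a pro-inflammatory hexa-acylated LPS producer, the full pathway minus the
terminal acyltransferase LpxM a penta-acylated producer, and no lipid-A genes
a Gram-positive organism; any other pattern is left unclassified. SCFA
capacity is scored from the abundance of genes encoding the terminal enzyme
of each biosynthetic route, after a strict homology-hit filter.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import (
    DEFAULT_LIPID_A_GENES,
    RELATIVE,
    AbundanceTable,
    TaxonAnnotation,
    ValidationError,
    validate_homology_hits,
)

logger = logging.getLogger("gutmeta.capacity")

DEFAULT_EPS = 1e-6

LPS_CLASSES = ("gram_positive", "penta_producer", "hexa_producer", "unclassified")

#: fixed terminal-enzyme -> SCFA map
ENZYME_TO_SCFA = {
    "co_dehydrogenase": "acetate",
    "acetyl_coa_synthase": "acetate",
    "propionyl_coa_transferase": "propionate",
    "propionyl_succinyl_coa_transferase": "propionate",
    "butyryl_coa_transferase": "butyrate",
}

SCFAS = ("acetate", "propionate", "butyrate")


def classify_lps(annotation: TaxonAnnotation, genes=DEFAULT_LIPID_A_GENES) -> pd.Series:
    """LPS acylation class per taxon, a pure function of gene presence.

    none present -> gram_positive; all present -> hexa_producer; all except
    LpxM -> penta_producer; anything else -> unclassified.
    """
    unknown = [g for g in annotation.lipida.columns if g not in genes]
    if unknown:
        raise ValidationError(f"unknown lipid-A gene name(s): {unknown}")
    presence = pd.DataFrame(False, index=annotation.lipida.index, columns=list(genes))
    presence[annotation.lipida.columns] = annotation.lipida
    non_terminal = [g for g in genes if g != "LpxM"]
    all_present = presence.all(axis=1)
    none_present = ~presence.any(axis=1)
    penta = presence[non_terminal].all(axis=1) & ~presence["LpxM"]
    cls = pd.Series("unclassified", index=presence.index, name="lps_class")
    cls[none_present] = "gram_positive"
    cls[all_present] = "hexa_producer"
    cls[penta] = "penta_producer"
    n_uncl = int((cls == "unclassified").sum())
    if n_uncl:
        logger.info("%d taxa with partial lipid-A pathways left unclassified", n_uncl)
    return cls


def class_abundances(
    abund: AbundanceTable,
    classes: pd.Series,
    eps: float = DEFAULT_EPS,
    include_partial_in_gramneg: bool = True,
) -> pd.DataFrame:
    """Per-sample summed abundance per LPS class plus the hexa:penta log ratio.

    gram_negative sums penta + hexa producers and (by default) partial-pathway
    unclassified taxa. Samples with no Gram-negative mass report a ratio of 0
    with the ``no_mass`` flag raised.
    """
    if abund.mode != RELATIVE:
        raise ValidationError("class_abundances expects relative abundances")
    missing = [t for t in abund.feature_ids if t not in classes.index]
    if missing:
        raise ValidationError(f"classes missing for taxa: {missing[:5]}")
    cls = classes.loc[abund.feature_ids]
    vals = abund.values
    out = pd.DataFrame(index=pd.Index(abund.sample_ids, name="sample_id"))
    for c in LPS_CLASSES:
        mask = (cls == c).to_numpy()
        out[c] = vals[:, mask].sum(axis=1) if mask.any() else 0.0
    gram_neg = out["penta_producer"] + out["hexa_producer"]
    if include_partial_in_gramneg:
        gram_neg = gram_neg + out["unclassified"]
    out["gram_negative"] = gram_neg
    hexa = out["hexa_producer"].to_numpy()
    penta = out["penta_producer"].to_numpy()
    out["hexa_penta_log_ratio"] = np.log10((hexa + eps) / (penta + eps))
    out["no_mass"] = (hexa + penta) == 0
    return out


def filter_homology_hits(
    hits: pd.DataFrame,
    min_identity: float = 35.0,
    min_score: float = 60.0,
    max_evalue: float = 1e-3,
) -> dict:
    """Best-match gene -> enzyme map after the strict homology filter
    (identity > 35, score > 60, E < 1e-3; all inequalities strict)."""
    hits = validate_homology_hits(hits)
    surviving = hits[
        (hits["identity"] > min_identity)
        & (hits["score"] > min_score)
        & (hits["evalue"] < max_evalue)
    ]
    best = surviving.sort_values("score", ascending=False).drop_duplicates("gene_id")
    return dict(zip(best["gene_id"], best["enzyme_id"]))


def scfa_capacity(gene_abund, gene_map: dict, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """Per-sample summed abundance of terminal-enzyme genes per SCFA.

    ``gene_abund`` is a samples x genes table (DataFrame or AbundanceTable);
    genes absent from ``gene_map`` are ignored. Also returns log10(x + eps)
    views for reporting.
    """
    data = gene_abund.data if isinstance(gene_abund, AbundanceTable) else gene_abund
    bad = {e for e in gene_map.values() if e not in ENZYME_TO_SCFA}
    if bad:
        raise ValidationError(f"enzyme id(s) outside the fixed SCFA map: {sorted(bad)}")
    out = pd.DataFrame(
        0.0, index=pd.Index(data.index, name="sample_id"), columns=list(SCFAS)
    )
    for gene, enzyme in gene_map.items():
        if gene not in data.columns:
            logger.warning("mapped gene %s absent from the abundance table", gene)
            continue
        out[ENZYME_TO_SCFA[enzyme]] += data[gene].to_numpy(dtype=float)
    for scfa in SCFAS:
        out[f"log10_{scfa}"] = np.log10(out[scfa] + eps)
    return out
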