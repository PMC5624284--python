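"""Microbial dysbiosis index (MD-index).

Per sample: md = log10((up_mass + eps) / (down_mass + eps)) where up/down are
the summed abundances of disease-increased and disease-decreased taxon sets.
The pinned conventions are log base 10 and eps = 1e-6.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.dysbiosis")

DEFAULT_EPS = 1e-6


def md_index(abund: AbundanceTable, up_set, down_set, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """MD-index per sample from disjoint disease-increased / -decreased sets."""
    up = list(dict.fromkeys(up_set))
    down = list(dict.fromkeys(down_set))
    if not up or not down:
        raise ValidationError("up_set and down_set must both be non-empty")
    overlap = set(up) & set(down)
    if overlap:
        raise ValidationError(f"up/down sets overlap: {sorted(overlap)[:5]}")
    unknown = [t for t in up + down if t not in abund.data.columns]
    if unknown:
        raise ValidationError(f"unknown taxa in MD-index sets: {unknown[:5]}")
    up_mass = abund.data[up].sum(axis=1).to_numpy(dtype=float)
    down_mass = abund.data[down].sum(axis=1).to_numpy(dtype=float)
    md = np.log10((up_mass + eps) / (down_mass + eps))
    return pd.DataFrame(
        {"md": md, "up_mass": up_mass, "down_mass": down_mass},
        index=pd.Index(abund.sample_ids, name="sample_id"),
    )


def derive_md_sets(biomarkers: pd.DataFrame, scheme) -> tuple:
    """Split biomarkers into (disease-increased, disease-decreased) sets using
    the scheme's group polarity; biomarkers enriched in unpolarized groups are
    excluded with a warning."""
    up, down = [], []
    for feature, row in biomarkers.iterrows():
        pol = scheme.polarity.get(row["enriched_group"])
        if pol == "CD":
            up.append(feature)
        elif pol == "CT":
            down.append(feature)
        else:
            logger.warning(
                "biomarker %s enriched in unpolarized group %s; excluded",
                feature, row["enriched_group"],
            )
    if not up or not down:
        raise ValidationError("polarity mapping left one MD-index side empty")
    return up, down
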