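"""Reporter-score enrichment of pathways/modules from per-KO statistics.

Each KO gets a signed z-score from a two-group rank-sum test,
z = sign(median difference) * Phi^-1(1 - p/2). A pathway with k scored member
KOs aggregates raw_z = sum(z)/sqrt(k), which is normalized against the mean
and SD of the same statistic over random size-k KO sets drawn from the scored
universe. |score| > 1.9 is flagged, matching the conventional display cut.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import substream
from .stats import rank_sum_p
from .tables import AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.reporter")

P_CLIP = 1e-15
DISPLAY_THRESHOLD = 1.9


def ko_zscores(ko_table: AbundanceTable, group_a, group_b) -> pd.DataFrame:
    """Per-KO two-sided rank-sum p, direction (group_b - group_a) and signed z."""
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) < 3:
            raise ValidationError(f"{name} has fewer than 3 samples")
    data = ko_table.data
    A = data.loc[list(group_a)].to_numpy(dtype=float)
    B = data.loc[list(group_b)].to_numpy(dtype=float)
    present = (A.sum(axis=0) + B.sum(axis=0)) > 0
    if not present.all():
        logger.info("dropping %d KO(s) absent from all samples", int((~present).sum()))
    rows = []
    for j in np.flatnonzero(present):
        p = rank_sum_p(A[:, j], B[:, j])
        direction = float(np.sign(np.median(B[:, j]) - np.median(A[:, j])))
        p_c = float(np.clip(p, P_CLIP, 1 - P_CLIP))
        z = direction * norm.ppf(1 - p_c / 2)
        rows.append({"ko_id": data.columns[j], "p": p, "direction": direction, "z": z})
    return pd.DataFrame(rows).set_index("ko_id")


def reporter_scores(
    kostats: pd.DataFrame,
    pathway_map: dict,
    n_background: int = 1000,
    seed: int = 0,
    threshold: float = DISPLAY_THRESHOLD,
) -> pd.DataFrame:
    """Background-normalized reporter score per pathway.

    mu_k/sigma_k come from ``n_background`` random KO sets of each occurring
    size k, drawn without replacement from the scored KOs.
    """
    if n_background < 100:
        raise ValidationError("n_background must be at least 100")
    z = kostats["z"].to_numpy(dtype=float)
    scored = set(kostats.index)
    rng = substream(seed, "reporter-background")
    sizes = {}
    for pathway, members in pathway_map.items():
        k = sum(1 for m in members if m in scored)
        if k == 0:
            logger.warning("pathway %s has no scored KOs; skipped", pathway)
            continue
        sizes[pathway] = k
    mu_sigma = {}
    for k in sorted(set(sizes.values())):
        draws = np.empty(n_background)
        for b in range(n_background):
            draws[b] = z[rng.choice(z.size, size=k, replace=False)].sum() / np.sqrt(k)
        sigma = draws.std(ddof=1)
        mu_sigma[k] = (draws.mean(), sigma if sigma > 0 else 1e-12)
    rows = []
    for pathway, k in sizes.items():
        members = [m for m in pathway_map[pathway] if m in scored]
        raw = kostats.loc[members, "z"].sum() / np.sqrt(k)
        mu, sigma = mu_sigma[k]
        score = (raw - mu) / sigma
        rows.append(
            {
                "pathway_id": pathway,
                "k": k,
                "raw_z": float(raw),
                "mu_k": float(mu),
                "sigma_k": float(sigma),
                "score": float(score),
                "significant": bool(abs(score) > threshold),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["k", "raw_z", "mu_k", "sigma_k", "score", "significant"],
            index=pd.Index([], name="pathway_id"),
        )
    return pd.DataFrame(rows).set_index("pathway_id")
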