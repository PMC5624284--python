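"""Adapted LDA-effect-size (LEfSe) biomarker discovery.

The "less stringent" variant: a feature is screened in if its abundance
differs (two-sided rank-sum, unadjusted alpha) in at least one of the declared
group comparisons, then ranked by a bootstrapped log10 linear-discriminant
effect size. The pinned scoring construction per bootstrap is

    e = 1/2 (|Delta_raw| + |w_unit| * |Delta_proj|)    (abundances x 1e6)
    lda_score = log10(1 + mean_boot e)

where Delta_raw is the per-feature class-mean difference, w_unit the unit
first LDA axis and Delta_proj the class-mean difference of the projection.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._utils import substream
from .stats import rank_sum_p
from .tables import RELATIVE, AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.lefse")

ABUNDANCE_SCALE = 1e6  # relative abundances are rescaled to parts-per-million


@dataclass
class ComparisonScheme:
    """Named sample groups and the pairwise comparisons to run between them."""

    groups: dict
    comparisons: list
    #: optional group -> "CT"/"CD" polarity (drives the dysbiosis-index sets)
    polarity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.comparisons:
            for g in (a, b):
                if g not in self.groups:
                    raise ValidationError(f"comparison references undefined group {g!r}")
            if set(self.groups[a]) & set(self.groups[b]):
                raise ValidationError(f"groups {a!r} and {b!r} overlap")

    def comparison_name(self, pair) -> str:
        return f"{pair[0]}_vs_{pair[1]}"


def metacommunity_scheme(
    labels: pd.Series,
    disease: pd.Series,
    min_subgroup: int = 3,
    ct_fraction_polar: float = 0.75,
) -> ComparisonScheme:
    """Build the standard scheme from metacommunity labels and disease status.

    Metacommunities are renamed A, B, C, ... by decreasing control fraction;
    mixed communities with at least ``min_subgroup`` samples per disease side
    contribute CT/CD subgroups. Comparisons: every metacommunity pair plus the
    within-community subgroup pairs.
    """
    labels = labels.astype(str)
    frac_ct = {
        lv: float((disease[labels == lv] == "CT").mean()) for lv in labels.unique()
    }
    ordered = sorted(frac_ct, key=lambda lv: (-frac_ct[lv], lv))
    names = {lv: chr(ord("A") + i) for i, lv in enumerate(ordered)}
    groups, polarity = {}, {}
    for lv, name in names.items():
        samples = list(labels.index[labels == lv])
        groups[name] = samples
        if frac_ct[lv] >= ct_fraction_polar:
            polarity[name] = "CT"
        elif frac_ct[lv] <= 1 - ct_fraction_polar:
            polarity[name] = "CD"
    comparisons = [
        (names[a], names[b])
        for i, a in enumerate(ordered)
        for b in ordered[i + 1 :]
    ]
    for lv, name in names.items():
        ct = [s for s in groups[name] if disease[s] == "CT"]
        cd = [s for s in groups[name] if disease[s] == "CD"]
        if len(ct) >= min_subgroup and len(cd) >= min_subgroup:
            groups[f"{name}-CT"] = ct
            groups[f"{name}-CD"] = cd
            polarity[f"{name}-CT"] = "CT"
            polarity[f"{name}-CD"] = "CD"
            comparisons.append((f"{name}-CT", f"{name}-CD"))
    return ComparisonScheme(groups, comparisons, polarity)


def _require_relative(abund: AbundanceTable) -> None:
    if abund.mode != RELATIVE:
        raise ValidationError("LEfSe operates on relative abundances")


def screen_features(abund: AbundanceTable, scheme: ComparisonScheme, alpha: float = 0.05):
    """Per-feature rank-sum screen: pass iff p < alpha in >= 1 comparison.

    Returns a DataFrame with one p-value column per comparison and a
    ``passed`` flag. The alpha is deliberately unadjusted ("less stringent").
    """
    _require_relative(abund)
    for name, samples in scheme.groups.items():
        if len(samples) < 3:
            raise ValidationError(f"group {name!r} has fewer than 3 samples")
    data = abund.data
    out = pd.DataFrame(index=pd.Index(abund.feature_ids, name="feature_id"))
    for pair in scheme.comparisons:
        A = data.loc[scheme.groups[pair[0]]].to_numpy(dtype=float)
        B = data.loc[scheme.groups[pair[1]]].to_numpy(dtype=float)
        out[scheme.comparison_name(pair)] = [
            rank_sum_p(A[:, j], B[:, j]) for j in range(data.shape[1])
        ]
    pcols = [scheme.comparison_name(p) for p in scheme.comparisons]
    out["passed"] = (out[pcols] < alpha).any(axis=1)
    return out


def _lda_axis(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit vector of the first LDA axis; regularized fallback when the
    within-class scatter is singular."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            lda = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
            w = lda.scalings_[:, 0]
        except Exception:
            logger.warning("singular within-class scatter; eigen solver with shrinkage")
            try:
                lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=0.1).fit(X, y)
                w = lda.scalings_[:, 0]
            except Exception:
                diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
                sd = X.std(axis=0)
                w = diff / np.maximum(sd, 1e-12)
    norm = np.linalg.norm(w)
    return w / (norm if norm > 0 else 1.0)


def lda_effect_size(
    abund: AbundanceTable,
    group_pair,
    features,
    n_boot: int = 30,
    boot_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrapped log10 LDA effect sizes for one two-group comparison.

    Each bootstrap subsamples ``boot_fraction`` of every group without
    replacement, fits a two-class LDA on the (x 1e6) feature matrix and scores
    every feature by the pinned construction; the reported ``lda_score`` is
    log10(1 + mean over bootstraps).
    """
    _require_relative(abund)
    features = list(features)
    name_a, samples_a = group_pair[0]
    name_b, samples_b = group_pair[1]
    if not features:
        return pd.DataFrame(
            columns=["lda_score", "enriched_group"], index=pd.Index([], name="feature_id")
        )
    Xa = abund.data.loc[list(samples_a), features].to_numpy(dtype=float) * ABUNDANCE_SCALE
    Xb = abund.data.loc[list(samples_b), features].to_numpy(dtype=float) * ABUNDANCE_SCALE
    rng = substream(seed, f"lefse-{name_a}-{name_b}")
    na = max(2, int(np.ceil(boot_fraction * Xa.shape[0])))
    nb = max(2, int(np.ceil(boot_fraction * Xb.shape[0])))
    eff = np.zeros(len(features))
    for _ in range(n_boot):
        sa = Xa[rng.choice(Xa.shape[0], size=na, replace=False)]
        sb = Xb[rng.choice(Xb.shape[0], size=nb, replace=False)]
        X = np.vstack([sa, sb])
        y = np.concatenate([np.zeros(na), np.ones(nb)])
        w_unit = _lda_axis(X, y)
        proj = X @ w_unit
        d_proj = abs(proj[y == 0].mean() - proj[y == 1].mean())
        d_raw = np.abs(sa.mean(axis=0) - sb.mean(axis=0))
        eff += 0.5 * (d_raw + np.abs(w_unit) * d_proj)
    eff /= n_boot
    scores = np.log10(1.0 + eff)
    med_a = np.median(Xa, axis=0)
    med_b = np.median(Xb, axis=0)
    higher = np.where(
        med_b > med_a, name_b, np.where(med_a > med_b, name_a, None)
    )
    # median ties fall back to the mean, then to the first group
    mean_higher = np.where(Xb.mean(axis=0) > Xa.mean(axis=0), name_b, name_a)
    enriched = [h if h is not None else m for h, m in zip(higher, mean_higher)]
    return pd.DataFrame(
        {"lda_score": scores, "enriched_group": enriched},
        index=pd.Index(features, name="feature_id"),
    )


def discover_biomarkers(
    abund: AbundanceTable,
    scheme: ComparisonScheme,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_boot: int = 30,
    boot_fraction: float = 2 / 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen, score per comparison, and rank biomarkers.

    A feature's final score is the maximum over the declared comparisons;
    features with score >= ``lda_threshold`` are returned ranked descending,
    with the screen p-values attached.
    """
    screen = screen_features(abund, scheme, alpha=alpha)
    passing = list(screen.index[screen["passed"]])
    records = pd.DataFrame(
        {
            "lda_score": np.full(len(passing), -np.inf),
            "enriched_group": [None] * len(passing),
        },
        index=pd.Index(passing, name="feature_id"),
    )
    for pair in scheme.comparisons:
        if not passing:
            break
        res = lda_effect_size(
            abund,
            ((pair[0], scheme.groups[pair[0]]), (pair[1], scheme.groups[pair[1]])),
            passing,
            n_boot=n_boot,
            boot_fraction=boot_fraction,
            seed=seed,
        )
        better = res["lda_score"] > records["lda_score"]
        records.loc[better, "lda_score"] = res.loc[better, "lda_score"]
        records.loc[better, "enriched_group"] = res.loc[better, "enriched_group"]
    records["n_boot"] = n_boot
    records["passed_screen"] = True
    records = records.join(screen.drop(columns="passed"))
    if np.isfinite(lda_threshold):
        records = records[records["lda_score"] >= lda_threshold]
    else:
        records = records.iloc[0:0]
    return records.sort_values("lda_score", ascending=False)
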