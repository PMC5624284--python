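"""Diversity, ordination, association and multivariate statistics.

Conventions: natural log for the Shannon index and Jensen-Shannon divergence;
the Jensen-Shannon *distance* is the square root of the divergence (metric
form, maximum sqrt(ln 2)); rank-sum p-values are exact for combined n <= 25
without ties and use the tie/continuity-corrected normal approximation
otherwise; Benjamini-Hochberg is the plain step-up procedure.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

from .tables import COUNTS, RELATIVE, AbundanceTable, ValidationError

logger = logging.getLogger("gutmeta.stats")

METRICS = ("bray_curtis", "jensen_shannon", "gower")

#: significance tiers used in group-comparison reports
Q_TIERS = ((0.001, "****"), (0.05, "***"), (0.1, "**"), (0.2, "*"))


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------
def shannon_index(profile) -> float:
    """Shannon diversity H = -sum p ln p of one relative-abundance profile."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("shannon_index expects a profile summing to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def gene_count(counts_row) -> int:
    """Number of features with at least one mapped read."""
    return int((np.asarray(counts_row, dtype=float) >= 1).sum())


def rank_sum_p(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact for combined n <= 25 without ties; tie/continuity-corrected normal
    approximation otherwise. Constant pooled data yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 25 and no_ties) else "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def q_tier(q: float) -> str:
    """Map a q-value onto the report's star tiers."""
    for cut, stars in Q_TIERS:
        if q < cut:
            return stars
    return ""


def wilcoxon_bh(abund, group_a, group_b) -> pd.DataFrame:
    """Per-feature two-sided rank-sum test between two sample groups with
    Benjamini-Hochberg adjustment and star tiers.

    ``abund`` may be an AbundanceTable or a samples x features DataFrame.
    """
    data = abund.data if isinstance(abund, AbundanceTable) else abund
    for name, grp in (("group_a", group_a), ("group_b", group_b)):
        if len(grp) < 3:
            raise ValidationError(f"{name} has fewer than 3 samples")
    A = data.loc[list(group_a)].to_numpy(dtype=float)
    B = data.loc[list(group_b)].to_numpy(dtype=float)
    stats, ps = [], []
    for j in range(data.shape[1]):
        ps.append(rank_sum_p(A[:, j], B[:, j]))
        stats.append(float(np.median(B[:, j]) - np.median(A[:, j])))
    qs = bh_adjust(ps)
    return pd.DataFrame(
        {
            "statistic": stats,
            "p": ps,
            "q": qs,
            "tier": [q_tier(q) for q in qs],
        },
        index=pd.Index(data.columns, name="feature_id"),
    )


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValidationError("distance matrix must be non-negative")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def gower_distances(covariates: pd.DataFrame) -> np.ndarray:
    """Gower dissimilarity over mixed numeric/categorical covariates.

    Numeric columns use range-normalized absolute differences, categorical
    columns a mismatch indicator; missing pairs are ignored columnwise.
    """
    n = covariates.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            rng = np.nanmax(v) - np.nanmin(v)
            if not np.isfinite(rng) or rng == 0:
                continue
            d = np.abs(v[:, None] - v[None, :]) / rng
        else:
            v = s.to_numpy()
            d = (v[:, None] != v[None, :]).astype(float)
            d[pd.isna(v)[:, None] | pd.isna(v)[None, :]] = np.nan
        ok = ~np.isnan(d)
        num[ok] += d[ok]
        den += ok
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def distance_matrix(table, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarities.

    ``bray_curtis`` / ``jensen_shannon`` need a relative-mode AbundanceTable;
    ``gower`` takes a mixed-type covariate DataFrame.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    if metric == "gower":
        if isinstance(table, AbundanceTable):
            raise ValidationError("gower expects a covariate DataFrame")
        return DistanceMatrix(list(table.index), gower_distances(table), metric)
    if not isinstance(table, AbundanceTable) or table.mode != RELATIVE:
        raise ValidationError(f"{metric} requires a relative-mode abundance table")
    X = table.values
    if metric == "bray_curtis":
        D = squareform(pdist(X, metric="braycurtis"))
    else:  # jensen_shannon distance, natural log
        D = squareform(pdist(X, metric="jensenshannon"))
    return DistanceMatrix(table.sample_ids, D, metric)


def pcoa(D: DistanceMatrix, n_axes: int = 2):
    """Classical scaling (principal coordinate analysis).

    Returns (coordinates DataFrame, eigenvalues including negative ones).
    Axis signs follow a deterministic convention: the largest-magnitude
    loading on each axis is positive.
    """
    d = D.values
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if n_axes > n_pos:
        logger.warning("only %d positive eigenvalues; truncating axes", n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    for a in range(n_axes):
        j = np.argmax(np.abs(coords[:, a]))
        if coords[j, a] < 0:
            coords[:, a] = -coords[:, a]
    frame = pd.DataFrame(
        coords, index=D.ids, columns=[f"PCo{i + 1}" for i in range(n_axes)]
    )
    return frame, evals


# ---------------------------------------------------------------------------
# multivariate tests
# ---------------------------------------------------------------------------
@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    group_sizes: dict


def _permanova_f(D2: np.ndarray, masks, n_total: int) -> float:
    ss_total = D2.sum() / (2.0 * n_total)
    ss_within = 0.0
    for mask in masks:
        idx = np.flatnonzero(mask)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    a = len(masks)
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n_total - a))


def permanova(D: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0):
    """One-way PERMANOVA with a seeded permutation test.

    pseudo-F from total vs within-group sums of squared distances;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValidationError("permanova needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    D2 = D.values**2
    n = labels.size
    masks = [labels == lv for lv in levels]
    f_obs = _permanova_f(D2, masks, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _permanova_f(D2, [perm == lv for lv in levels], n) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, dict(zip(levels.tolist(), counts.tolist())))


@dataclass
class BioenvResult:
    best_subset: tuple
    r: float
    scores: pd.DataFrame = field(repr=False)


def bioenv(community_D: DistanceMatrix, covariates: pd.DataFrame, max_subset_size=None):
    """Exhaustive covariate-subset search maximizing the Pearson correlation
    between subset Gower distances and the community dissimilarity.

    Numeric covariates are standardized before the Gower computation. On ties
    the first subset in (size, lexicographic) order wins.
    """
    names = sorted(covariates.columns)
    if not names:
        raise ValidationError("bioenv needs at least one covariate")
    if max_subset_size is None:
        if len(names) > 20:
            raise ValidationError("more than 20 covariates: pass max_subset_size")
        max_subset_size = len(names)
    std = covariates.copy()
    for col in names:
        if pd.api.types.is_numeric_dtype(std[col]):
            v = std[col].to_numpy(dtype=float)
            sd = np.nanstd(v)
            std[col] = (v - np.nanmean(v)) / (sd if sd > 0 else 1.0)
    per_cov = {
        name: squareform(gower_distances(std[[name]]), checks=False) for name in names
    }
    target = community_D.condensed
    rows = []
    best = None
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(names, size):
            g = np.mean([per_cov[c] for c in subset], axis=0)
            if np.std(g) == 0 or np.std(target) == 0:
                r = 0.0
            else:
                r = float(pearsonr(g, target).statistic)
            rows.append({"subset": subset, "size": size, "r": r})
            if best is None or r > best[1]:
                best = (subset, r)
    scores = pd.DataFrame(rows)
    return BioenvResult(best[0], best[1], scores)


def fisher_association(membership, disease) -> pd.DataFrame:
    """Per-membership-group Fisher's exact association with disease status,
    BH-adjusted across groups.

    Each group g is tested on the 2x2 table (in g vs not) x (CD vs CT).
    """
    membership = np.asarray(membership)
    disease = np.asarray(disease)
    if membership.size != disease.size:
        raise ValidationError("membership and disease labels differ in length")
    d_levels = np.unique(disease)
    if d_levels.size != 2:
        raise ValidationError("disease labels must take exactly two values")
    case = "CD" if "CD" in d_levels else d_levels[1]
    rows = []
    for g in np.unique(membership):
        in_g = membership == g
        is_case = disease == case
        table = [
            [int((in_g & is_case).sum()), int((in_g & ~is_case).sum())],
            [int((~in_g & is_case).sum()), int((~in_g & ~is_case).sum())],
        ]
        if min(sum(table[0]), sum(table[1]), table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
            logger.warning("group %s: empty margin, p set to 1", g)
            odds, p = np.nan, 1.0
        else:
            odds, p = fisher_exact(table, alternative="two-sided")
        rows.append({"group": g, "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("group")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
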