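"""Synthetic cohort generator.

Emulates the statistical structure the pipeline assumes: a case/control stool
metagenome cohort (54 controls, 49 cases at baseline) whose taxon counts are
drawn from a small Dirichlet-multinomial mixture of metacommunities with
per-component signature taxa, group-shifted KO pathways, lipid-A / SCFA
annotations skewed so the case-exclusive component carries more hexa-acylated
LPS producers and fewer SCFA-enzyme carriers, ori->ter sloped coverage
profiles, and clinical covariates loaded on the community axis. Ground truth
is returned alongside the tables so recovery tests can score every stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import substream
from .tables import (
    COUNTS,
    DEFAULT_LIPID_A_GENES,
    RELATIVE,
    AbundanceTable,
    SampleMetadata,
    TaxonAnnotation,
    ValidationError,
)

logger = logging.getLogger("gutmeta.simulate")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class ComponentSpec:
    """One mixture component: sample allocation and signature enrichment."""

    name: str
    n_ct: int
    n_cd: int
    #: taxon id -> fold multiplier applied to this component's alpha entries
    signature: dict = field(default_factory=dict)


@dataclass
class CoverageSpec:
    """Replication-slope coverage profiles for a subset of taxa.

    ``ptr`` maps taxon id -> {component name -> true peak-to-trough ratio}.
    """

    ptr: dict = field(default_factory=dict)
    n_bins: int = 64
    depth_per_bin: float = 200.0
    rotate: bool = True


@dataclass
class CohortConfig:
    seed: int
    components: list = field(default_factory=list)
    n_taxa: int = 150
    #: per-component Dirichlet concentration (sum of alpha)
    concentration: float = 5e6
    #: mean sequencing depth (counts per sample), Poisson-distributed
    depth_mean: float = 5e6
    #: log-sd of the baseline composition across taxa
    base_log_sd: float = 1.0
    #: cap on any single taxon's baseline share
    max_base_share: float = 0.02
    #: common baseline share given to every signature taxon; equal signature
    #: base mass per component keeps the per-component concentration totals
    #: identical, so non-signature taxa are exchangeable across components
    #: (spikes do not leak into other taxa through closure)
    signature_base_share: float = 0.008
    # functional (KO) layer
    n_kos: int = 200
    pathway_size: int = 10
    #: pathway id -> log2 shift applied to member KOs in CD samples
    ko_effects: dict = field(default_factory=dict)
    ko_log_sd: float = 0.3
    # annotation layer: class probabilities for non-signature taxa
    lps_class_probs: dict = field(
        default_factory=lambda: {
            "gram_positive": 0.45,
            "penta_producer": 0.20,
            "hexa_producer": 0.15,
            "unclassified": 0.20,
        }
    )
    scfa_carriage_probs: dict = field(
        default_factory=lambda: {
            "acetate_terminal": 0.5,
            "propionate_terminal": 0.3,
            "butyrate_terminal": 0.5,
        }
    )
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    #: covariate name -> dict(mean, sd, shift={component: delta})
    covariates: dict = field(default_factory=dict)
    #: injected taxon-taxon co-variation, as dicts with keys ``taxa`` (pair),
    #: ``strength`` (log-scale sd of the shared latent factor) and
    #: ``component`` (only samples of that component are affected). Empty by
    #: default: the baseline cohort is a pure Dirichlet-multinomial mixture.
    correlations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("CohortConfig requires an explicit seed")
        if not self.components:
            raise ValidationError("CohortConfig requires at least one component")

    # -- canonical study-like defaults --------------------------------------
    @classmethod
    def default(cls, seed: int = 42) -> "CohortConfig":
        """Three metacommunities: control-dominated A, mixed B, case-exclusive C."""
        taxa = [f"MGS{i:04d}" for i in range(1, 151)]
        sig = lambda lo, hi: {taxa[i]: 6.0 for i in range(lo, hi)}
        components = [
            ComponentSpec("A", n_ct=40, n_cd=3, signature=sig(0, 6)),
            ComponentSpec("B", n_ct=14, n_cd=21, signature=sig(6, 12)),
            ComponentSpec("C", n_ct=0, n_cd=25, signature=sig(12, 18)),
        ]
        ko_effects = {"path01": 1.0, "path02": 1.0, "path03": -1.0, "path04": -1.0}
        coverage = CoverageSpec(
            ptr={
                # SCFA producers grow fastest in the control-like community
                **{taxa[i]: {"A": 1.8, "B": 1.5, "C": 1.2} for i in range(0, 3)},
                # opportunists bloom in the case-exclusive community
                **{taxa[i]: {"A": 1.2, "B": 1.4, "C": 1.8} for i in range(12, 15)},
            }
        )
        covariates = {
            "age": {"mean": 24.0, "sd": 6.0, "shift": {"B": 3.0, "C": 6.0}},
            "bmi": {"mean": 21.5, "sd": 2.5, "shift": {"B": -1.5, "C": -2.5}},
            "crp": {"mean": 5.0, "sd": 3.0, "shift": {"B": 6.0, "C": 12.0}},
            "leukocytes": {"mean": 6.0, "sd": 1.5, "shift": {"B": 1.5, "C": 3.0}},
            "albumin": {"mean": 45.0, "sd": 4.0, "shift": {}},
            "urate": {"mean": 300.0, "sd": 50.0, "shift": {}},
        }
        return cls(
            seed=seed,
            components=components,
            ko_effects=ko_effects,
            coverage=coverage,
            covariates=covariates,
        )

    @classmethod
    def null(cls, seed: int = 42) -> "CohortConfig":
        """Same sizes as :meth:`default` but zero effects everywhere: the two
        disease groups (and the component labels) are exchangeable."""
        cfg = cls.default(seed)
        for comp in cfg.components:
            comp.signature = {t: 1.0 for t in comp.signature}
        cfg.ko_effects = {p: 0.0 for p in cfg.ko_effects}
        cfg.coverage = CoverageSpec(
            ptr={t: {c: 1.5 for c in m} for t, m in cfg.coverage.ptr.items()},
            n_bins=cfg.coverage.n_bins,
            depth_per_bin=cfg.coverage.depth_per_bin,
            rotate=cfg.coverage.rotate,
        )
        for cov in cfg.covariates.values():
            cov["shift"] = {}
        return cfg


@dataclass
class SyntheticCohort:
    counts: AbundanceTable
    metadata: SampleMetadata
    annotation: TaxonAnnotation
    ko_table: AbundanceTable
    pathway_map: dict
    gene_abund: pd.DataFrame
    hits: pd.DataFrame
    coverage: dict
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.write(outdir / "counts.tsv")
        self.metadata.write(outdir / "metadata.tsv")
        self.annotation.write(outdir / "annotation.tsv")
        self.ko_table.write(outdir / "ko_abundance.tsv")
        rows = [(p, k) for p, kos in self.pathway_map.items() for k in kos]
        pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(
            outdir / "pathway_map.tsv", sep="\t", index=False
        )
        self.gene_abund.to_csv(outdir / "gene_abundance.tsv", sep="\t")
        self.hits.to_csv(outdir / "homology_hits.tsv", sep="\t", index=False)
        cov_rows = []
        for (taxon, sample), vec in self.coverage.items():
            for b, depth in enumerate(vec):
                cov_rows.append((taxon, sample, b, depth))
        pd.DataFrame(cov_rows, columns=["taxon_id", "sample_id", "bin", "depth"]).to_csv(
            outdir / "coverage.tsv", sep="\t", index=False
        )
        truth = {
            k: (v.to_dict() if isinstance(v, pd.Series) else v)
            for k, v in self.truth.items()
            if k not in ("alpha",)
        }
        truth["alpha"] = {c: list(map(float, a)) for c, a in self.truth["alpha"].items()}
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------
def simulate_dmm_counts(pi, alpha_list, n_samples, depth, seed):
    """Draw counts from a Dirichlet-multinomial mixture.

    Per sample: component z ~ pi, composition p ~ Dirichlet(alpha_z), counts
    x ~ Multinomial(d, p) with d ~ Poisson(depth) truncated at >= 1.

    Returns (counts array [n_samples x n_taxa], component labels).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValidationError("mixture weights must sum to 1")
    alphas = [np.asarray(a, dtype=float) for a in alpha_list]
    for a in alphas:
        if (a <= 0).any():
            raise ValidationError("Dirichlet parameters must be strictly positive")
    n_taxa = alphas[0].size
    labels = rng.choice(len(pi), size=n_samples, p=pi)
    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    for i, z in enumerate(labels):
        d = max(1, int(rng.poisson(depth)))
        p = rng.dirichlet(alphas[z])
        counts[i] = rng.multinomial(d, p)
    return counts, labels


def simulate_coverage(true_ptr, n_bins, mean_depth, noise, seed, ori_bin=0):
    """One circular binned coverage profile with a replication slope.

    Expected log2 coverage falls linearly from the origin (``ori_bin``) to the
    terminus half a genome away and rises back. ``noise`` draws Poisson counts
    around the expectation; with ``noise=False`` the exact expectations are
    returned, so coverage(ori)/coverage(ter) equals ``true_ptr`` exactly.
    """
    if true_ptr < 1:
        raise ValidationError("true_ptr must be >= 1")
    if n_bins < 16:
        raise ValidationError("coverage profiles need at least 16 bins")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = np.arange(n_bins)
    d = np.abs(bins - ori_bin)
    d = np.minimum(d, n_bins - d)
    frac = d / (n_bins / 2.0)  # 0 at ori, 1 at ter
    expected = true_ptr ** (1.0 - frac)
    expected *= mean_depth / expected.mean()
    if not noise:
        return expected
    return rng.poisson(expected).astype(float)


def _base_proportions(rng, n_taxa, log_sd, max_share):
    w = rng.lognormal(mean=0.0, sigma=log_sd, size=n_taxa)
    p = w / w.sum()
    p = np.minimum(p, max_share)
    return p / p.sum()


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full multi-layer cohort described by ``config``."""
    taxa = [f"MGS{i:04d}" for i in range(1, config.n_taxa + 1)]
    taxon_index = {t: i for i, t in enumerate(taxa)}
    for comp in config.components:
        missing = [t for t in comp.signature if t not in taxon_index]
        if missing:
            raise ValidationError(
                f"signature taxa absent from the table: {missing[:5]} (component {comp.name})"
            )

    rng_base = substream(config.seed, "base-composition")
    base = _base_proportions(rng_base, config.n_taxa, config.base_log_sd, config.max_base_share)
    sig_union = sorted({t for comp in config.components for t in comp.signature})
    if sig_union and config.signature_base_share:
        sig_idx = [taxon_index[t] for t in sig_union]
        sig_mass = config.signature_base_share * len(sig_idx)
        if sig_mass >= 1:
            raise ValidationError("signature_base_share leaves no mass for other taxa")
        rest = np.setdiff1d(np.arange(config.n_taxa), sig_idx)
        base[rest] *= (1.0 - sig_mass) / base[rest].sum()
        base[sig_idx] = config.signature_base_share

    # per-component alpha: multiply signature entries (keeps the Dirichlet form)
    alphas = {}
    for comp in config.components:
        a = base * config.concentration
        for taxon, fold in comp.signature.items():
            if fold <= 0:
                raise ValidationError(f"signature fold for {taxon} must be positive")
            a[taxon_index[taxon]] *= fold
        alphas[comp.name] = a

    # ---- sample allocation (shuffled so row order carries no signal) -------
    assignments = []
    for comp in config.components:
        assignments += [(comp.name, "CT")] * comp.n_ct + [(comp.name, "CD")] * comp.n_cd
    rng_alloc = substream(config.seed, "allocation")
    order = rng_alloc.permutation(len(assignments))
    assignments = [assignments[i] for i in order]
    n_ct = sum(1 for _, d in assignments if d == "CT")
    ct_ids = iter([f"CT{i:03d}" for i in range(1, n_ct + 1)])
    cd_ids = iter([f"CD{i:03d}" for i in range(1, len(assignments) - n_ct + 1)])
    sample_ids = [next(ct_ids) if d == "CT" else next(cd_ids) for _, d in assignments]

    # ---- taxon counts -------------------------------------------------------
    for spec in config.correlations:
        for t in spec["taxa"]:
            if t not in taxon_index:
                raise ValidationError(f"correlation taxon {t!r} absent from the table")
    rng_counts = substream(config.seed, "taxon-counts")
    counts = np.empty((len(assignments), config.n_taxa), dtype=np.int64)
    for i, (comp_name, _) in enumerate(assignments):
        d = max(1, int(rng_counts.poisson(config.depth_mean)))
        a = alphas[comp_name]
        injected = [s for s in config.correlations if s["component"] == comp_name]
        if injected:
            a = a.copy()
            for spec in injected:
                # one shared log-normal factor per pair: positive co-variation
                g = rng_counts.normal(0.0, 1.0)
                for t in spec["taxa"]:
                    a[taxon_index[t]] *= np.exp(spec["strength"] * g)
        p = rng_counts.dirichlet(a)
        counts[i] = rng_counts.multinomial(d, p)
    counts_table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=taxa), mode=COUNTS
    )
    rel = counts_table.to_relative()

    # ---- metadata -----------------------------------------------------------
    rng_cov = substream(config.seed, "covariates")
    comp_of = {s: c for s, (c, _) in zip(sample_ids, assignments)}
    meta = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    meta["disease_status"] = [d for _, d in assignments]
    meta["timepoint"] = "baseline"
    meta["gender"] = rng_cov.choice(["M", "F"], size=len(sample_ids), p=[0.8, 0.2])
    for name, spec in config.covariates.items():
        shift = spec.get("shift", {})
        vals = [
            spec["mean"] + shift.get(comp_of[s], 0.0) + rng_cov.normal(0.0, spec["sd"])
            for s in sample_ids
        ]
        meta[name] = np.round(vals, 3)
    metadata = SampleMetadata(meta)

    # ---- annotation ---------------------------------------------------------
    rng_annot = substream(config.seed, "annotation")
    comp_by_name = {c.name: c for c in config.components}
    order_names = [c.name for c in config.components]
    forced = {}
    if len(order_names) >= 1:
        for t in comp_by_name[order_names[0]].signature:  # control-like signatures
            forced[t] = "gram_positive"
    if len(order_names) >= 2:
        for t in comp_by_name[order_names[1]].signature:
            forced[t] = "penta_producer"
    if len(order_names) >= 3:
        for t in comp_by_name[order_names[-1]].signature:  # case-exclusive signatures
            forced[t] = "hexa_producer"
    class_names = list(config.lps_class_probs)
    class_p = np.array([config.lps_class_probs[c] for c in class_names], dtype=float)
    class_p /= class_p.sum()
    genes = list(DEFAULT_LIPID_A_GENES)
    lip = pd.DataFrame(False, index=pd.Index(taxa, name="taxon_id"), columns=genes)
    scfa = pd.DataFrame(
        False, index=lip.index, columns=["acetate_terminal", "propionate_terminal", "butyrate_terminal"]
    )
    phyla = []
    for t in taxa:
        cls = forced.get(t) or rng_annot.choice(class_names, p=class_p)
        if cls == "hexa_producer":
            lip.loc[t, :] = True
        elif cls == "penta_producer":
            lip.loc[t, [g for g in genes if g != "LpxM"]] = True
        elif cls == "unclassified":
            # partial pathway: a random proper, non-empty, non penta-pattern subset
            k = int(rng_annot.integers(1, len(genes) - 1))
            subset = rng_annot.choice(genes, size=k, replace=False)
            if set(genes) - set(subset) == {"LpxM"}:
                subset = subset[:-1]
            lip.loc[t, list(subset)] = True
        if cls == "gram_positive":
            if t in forced:
                scfa.loc[t, ["acetate_terminal", "butyrate_terminal"]] = True
                scfa.loc[t, "propionate_terminal"] = bool(rng_annot.random() < 0.5)
            else:
                for enz, p in config.scfa_carriage_probs.items():
                    scfa.loc[t, enz] = bool(rng_annot.random() < p)
        phyla.append("Firmicutes" if cls == "gram_positive" else "Bacteroidetes")
    annotation = TaxonAnnotation(lip, scfa, pd.DataFrame({"phylum": phyla}, index=lip.index))

    # ---- KO table and pathway map ------------------------------------------
    rng_ko = substream(config.seed, "ko-table")
    kos = [f"K{i:05d}" for i in range(1, config.n_kos + 1)]
    n_pathways = config.n_kos // config.pathway_size
    pathway_map = {
        f"path{p + 1:02d}": kos[p * config.pathway_size : (p + 1) * config.pathway_size]
        for p in range(n_pathways)
    }
    unknown = [p for p in config.ko_effects if p not in pathway_map]
    if unknown:
        raise ValidationError(f"ko_effects reference unknown pathway(s): {unknown}")
    ko_effect = np.zeros(config.n_kos)
    for pathway, eff in config.ko_effects.items():
        for k in pathway_map[pathway]:
            ko_effect[kos.index(k)] = eff
    ko_base = rng_ko.normal(np.log(1.0 / config.n_kos), 0.5, size=config.n_kos)
    is_cd = np.array([d == "CD" for _, d in assignments], dtype=float)
    log_ab = (
        ko_base[None, :]
        + np.log(2.0) * ko_effect[None, :] * is_cd[:, None]
        + rng_ko.normal(0.0, config.ko_log_sd, size=(len(sample_ids), config.n_kos))
    )
    ko_vals = np.exp(log_ab)
    ko_vals /= ko_vals.sum(axis=1, keepdims=True)
    ko_table = AbundanceTable(
        pd.DataFrame(ko_vals, index=sample_ids, columns=kos), mode=RELATIVE
    )

    # ---- SCFA terminal-enzyme gene layer -----------------------------------
    rng_gene = substream(config.seed, "scfa-genes")
    enzyme_of_gene = {
        "gene_codh": "co_dehydrogenase",
        "gene_acs": "acetyl_coa_synthase",
        "gene_pct": "propionyl_coa_transferase",
        "gene_psct": "propionyl_succinyl_coa_transferase",
        "gene_bcoat": "butyryl_coa_transferase",
    }
    scfa_of_enzyme = {
        "co_dehydrogenase": "acetate_terminal",
        "acetyl_coa_synthase": "acetate_terminal",
        "propionyl_coa_transferase": "propionate_terminal",
        "propionyl_succinyl_coa_transferase": "propionate_terminal",
        "butyryl_coa_transferase": "butyrate_terminal",
    }
    rel_vals = rel.values
    gene_cols = {}
    for gene, enzyme in enzyme_of_gene.items():
        carriers = scfa.index[scfa[scfa_of_enzyme[enzyme]]].tolist()
        idx = [taxon_index[t] for t in carriers]
        mass = rel_vals[:, idx].sum(axis=1) if idx else np.zeros(len(sample_ids))
        gene_cols[gene] = mass * np.exp(rng_gene.normal(0.0, 0.05, size=len(sample_ids)))
    gene_abund = pd.DataFrame(gene_cols, index=pd.Index(sample_ids, name="sample_id"))

    hit_rows = []
    for i, (gene, enzyme) in enumerate(enzyme_of_gene.items()):
        hit_rows.append((gene, enzyme, 72.0 + i, 150.0 + 10 * i, 1e-40))
        wrong = "butyryl_coa_transferase" if enzyme != "butyryl_coa_transferase" else "co_dehydrogenase"
        hit_rows.append((gene, wrong, 45.0, 90.0, 1e-10))  # worse surviving hit
    hit_rows.append(("gene_decoy", "butyryl_coa_transferase", 30.0, 50.0, 5e-2))  # fails filters
    hits = pd.DataFrame(
        hit_rows, columns=["gene_id", "enzyme_id", "identity", "score", "evalue"]
    )

    # ---- coverage profiles --------------------------------------------------
    rng_covg = substream(config.seed, "coverage")
    coverage = {}
    ptr_truth = {}
    for taxon, per_comp in config.coverage.ptr.items():
        if taxon not in taxon_index:
            raise ValidationError(f"coverage taxon {taxon!r} absent from the table")
        ori = int(rng_covg.integers(config.coverage.n_bins)) if config.coverage.rotate else 0
        for s in sample_ids:
            ptr = per_comp.get(comp_of[s], 1.0)
            coverage[(taxon, s)] = simulate_coverage(
                ptr,
                config.coverage.n_bins,
                config.coverage.depth_per_bin,
                noise=True,
                seed=rng_covg,
                ori_bin=ori,
            )
            ptr_truth[f"{taxon}|{s}"] = ptr

    truth = {
        "labels": pd.Series({s: comp_of[s] for s in sample_ids}, name="component"),
        "pi": {c.name: (c.n_ct + c.n_cd) / len(sample_ids) for c in config.components},
        "alpha": alphas,
        "signature": {c.name: dict(c.signature) for c in config.components},
        "ko_effects": dict(config.ko_effects),
        "ptr": ptr_truth,
        "covariate_shifts": {n: dict(s.get("shift", {})) for n, s in config.covariates.items()},
        "seed": config.seed,
    }
    return SyntheticCohort(
        counts=counts_table,
        metadata=metadata,
        annotation=annotation,
        ko_table=ko_table,
        pathway_map=pathway_map,
        gene_abund=gene_abund,
        hits=hits,
        coverage=coverage,
        truth=truth,
    )
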