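"""End-to-end orchestration: clustering -> biomarkers -> dysbiosis ->
enrichment -> capacity -> networks -> growth -> summary statistics.

A single global seed deterministically derives one substream per stage, so
toggling a stage never shifts another stage's randomness; re-running the same
config reproduces every output byte-identically. Each stage records its
outputs, parameters and seed in ``manifest.json`` with sha256 hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import capacity as capacity_mod
from . import dysbiosis, growth, lefse, reporter, sparcc, stats
from ._utils import derived_seed
from .dmm import assign_metacommunities, select_k
from .tables import AbundanceTable, ValidationError, load_dataset, load_homology_hits

logger = logging.getLogger("gutmeta.pipeline")

STAGES = (
    "cluster", "biomarkers", "mdindex", "reporter", "capacity", "network", "growth", "stats",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    counts: str
    metadata: str
    outdir: str
    seed: int
    annotation: str | None = None
    ko_table: str | None = None
    pathway_map: str | None = None
    gene_abundance: str | None = None
    homology_hits: str | None = None
    coverage: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # stage parameters
    occurrence_min_rate: float = 0.05
    k_min: int = 1
    k_max: int = 7
    n_restarts: int = 5
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    n_boot: int = 30
    reporter_background: int = 1000
    sparcc_iterations: int = 20
    sparcc_nulls: int = 100
    edge_threshold: float = 0.3
    p_threshold: float = 0.01
    strong_threshold: float = 0.5
    min_mean_coverage: float = 5.0
    smooth_window_frac: float = 0.1
    permanova_permutations: int = 999

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("config requires a seed")
        for name in ("counts", "metadata"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise ValidationError(f"required input {name!r} missing: {path}")
        for name in (
            "annotation", "ko_table", "pathway_map", "gene_abundance",
            "homology_hits", "coverage",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input {name!r} does not exist: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_pathway_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["pathway_id"], []).append(row["ko_id"])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage, outputs, params):
        manifest["stages"][stage] = {
            "seed": derived_seed(config.seed, stage),
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    abund, meta, annot = load_dataset(
        config.counts, config.metadata, config.annotation
    )
    if abund.mode == "counts":
        counts = abund.filter_by_occurrence(config.occurrence_min_rate)
        rel = counts.to_relative()
    else:
        counts = None
        rel = abund.filter_by_occurrence(config.occurrence_min_rate)
    disease = meta.disease_status

    scheme = None
    labels = None

    # ---- clustering --------------------------------------------------------
    if config.stages.get("cluster", True):
        stage = "cluster"
        try:
            if counts is None:
                raise ValidationError("clustering requires a counts table")
            sel = select_k(
                counts,
                k_min=config.k_min,
                k_max=config.k_max,
                n_restarts=config.n_restarts,
                seed=derived_seed(config.seed, stage),
            )
            model = sel.models[sel.best_k]
            hard = assign_metacommunities(model, counts)
            labels = pd.Series(hard.astype(str), index=counts.sample_ids, name="metacommunity")
            curve = pd.DataFrame(
                {"K": list(sel.laplace_nlp), "laplace_nlp": list(sel.laplace_nlp.values())}
            )
            curve.to_csv(outdir / "nlp_curve.tsv", sep="\t", index=False)
            labels.to_frame().to_csv(outdir / "metacommunities.tsv", sep="\t")
            with open(outdir / "dmm_model.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "best_k": sel.best_k,
                        "pi": model.pi.tolist(),
                        "nll": model.nll,
                        "laplace_nlp": model.laplace_nlp,
                        "converged": model.converged,
                    },
                    fh, indent=1, sort_keys=True,
                )
            record(stage, [outdir / "nlp_curve.tsv", outdir / "metacommunities.tsv",
                           outdir / "dmm_model.json"],
                   {"k_min": config.k_min, "k_max": config.k_max, "n_restarts": config.n_restarts})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    if labels is not None:
        scheme = lefse.metacommunity_scheme(labels, disease)

    # ---- biomarkers --------------------------------------------------------
    biomarkers = None
    if config.stages.get("biomarkers", True) and scheme is not None:
        stage = "biomarkers"
        try:
            biomarkers = lefse.discover_biomarkers(
                rel, scheme,
                alpha=config.lefse_alpha,
                lda_threshold=config.lda_threshold,
                n_boot=config.n_boot,
                seed=derived_seed(config.seed, stage),
            )
            biomarkers.to_csv(outdir / "biomarkers.tsv", sep="\t")
            record(stage, [outdir / "biomarkers.tsv"],
                   {"alpha": config.lefse_alpha, "lda_threshold": config.lda_threshold,
                    "n_boot": config.n_boot})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- dysbiosis index ---------------------------------------------------
    if (
        config.stages.get("mdindex", True)
        and biomarkers is not None
        and len(biomarkers)
    ):
        stage = "mdindex"
        try:
            up, down = dysbiosis.derive_md_sets(biomarkers, scheme)
            md = dysbiosis.md_index(rel, up, down)
            md.to_csv(outdir / "mdindex.tsv", sep="\t")
            record(stage, [outdir / "mdindex.tsv"], {"n_up": len(up), "n_down": len(down)})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- reporter enrichment ----------------------------------------------
    if (
        config.stages.get("reporter", True)
        and config.ko_table is not None
        and config.pathway_map is not None
    ):
        stage = "reporter"
        try:
            ko_table = AbundanceTable.read(config.ko_table)
            pathway_map = _read_pathway_map(config.pathway_map)
            ct = list(disease.index[disease == "CT"])
            cd = list(disease.index[disease == "CD"])
            kostats = reporter.ko_zscores(ko_table, ct, cd)
            scores = reporter.reporter_scores(
                kostats, pathway_map,
                n_background=config.reporter_background,
                seed=derived_seed(config.seed, stage),
            )
            scores.to_csv(outdir / "reporter_scores.tsv", sep="\t")
            record(stage, [outdir / "reporter_scores.tsv"],
                   {"n_background": config.reporter_background})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- capacity profiling ------------------------------------------------
    if config.stages.get("capacity", True) and annot is not None:
        stage = "capacity"
        try:
            classes = capacity_mod.classify_lps(annot)
            prof = capacity_mod.class_abundances(rel, classes)
            prof.to_csv(outdir / "capacity_lps.tsv", sep="\t")
            outputs = [outdir / "capacity_lps.tsv"]
            if config.gene_abundance is not None and config.homology_hits is not None:
                hits = load_homology_hits(config.homology_hits)
                gene_map = capacity_mod.filter_homology_hits(hits)
                gene_abund = pd.read_csv(
                    config.gene_abundance, sep="\t", comment="#", index_col=0
                )
                scfa = capacity_mod.scfa_capacity(gene_abund, gene_map)
                scfa.to_csv(outdir / "capacity_scfa.tsv", sep="\t")
                outputs.append(outdir / "capacity_scfa.tsv")
            record(stage, outputs, {})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- differential networks --------------------------------------------
    if config.stages.get("network", True) and counts is not None and scheme is not None:
        stage = "network"
        try:
            ct_groups = [g for g, pol in scheme.polarity.items()
                         if pol == "CT" and "-" not in g]
            cd_groups = [g for g, pol in scheme.polarity.items()
                         if pol == "CD" and "-" not in g]
            feats = (
                list(biomarkers.index)
                if biomarkers is not None and len(biomarkers) >= 4
                else counts.feature_ids
            )
            nets = {}
            seed = derived_seed(config.seed, stage)
            outputs = []
            for side, groups in (("CT", ct_groups), ("CD", cd_groups)):
                if not groups:
                    continue
                samples = [s for g in groups for s in scheme.groups[g]]
                sub = counts.subset(samples=samples, features=feats)
                res = sparcc.sparcc_correlations(
                    sub, n_iterations=config.sparcc_iterations, seed=seed
                )
                p = sparcc.sparcc_pvalues(sub, res, n_null=config.sparcc_nulls, seed=seed)
                net = sparcc.build_network(
                    res, p,
                    edge_threshold=config.edge_threshold,
                    p_threshold=config.p_threshold,
                )
                nets[side] = net
                rows = [
                    {"taxon_a": u, "taxon_b": v, **d} for u, v, d in net.edges(data=True)
                ]
                path = outdir / f"network_{side}_edges.tsv"
                pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"]).to_csv(
                    path, sep="\t", index=False
                )
                outputs.append(path)
            if len(nets) == 2:
                diff = sparcc.compare_networks(
                    nets["CT"], nets["CD"], strong_threshold=config.strong_threshold
                )
                summary = {
                    "edges_ct": nets["CT"].number_of_edges(),
                    "edges_cd": nets["CD"].number_of_edges(),
                    "edges_lost": len(diff.edges_lost),
                    "edges_gained": len(diff.edges_gained),
                    "edges_shared": len(diff.edges_shared),
                    "strong_lost": len(diff.strong_lost),
                    "strong_gained": len(diff.strong_gained),
                }
                path = outdir / "network_diff.tsv"
                pd.DataFrame([summary]).to_csv(path, sep="\t", index=False)
                outputs.append(path)
            record(stage, outputs,
                   {"iterations": config.sparcc_iterations, "nulls": config.sparcc_nulls})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- growth rates ------------------------------------------------------
    if config.stages.get("growth", True) and config.coverage is not None:
        stage = "growth"
        try:
            cov = growth.load_coverage_table(config.coverage)
            est = growth.estimate_ptr_table(
                cov,
                min_mean_coverage=config.min_mean_coverage,
                smooth_window_frac=config.smooth_window_frac,
            )
            est.to_csv(outdir / "growth_rates.tsv", sep="\t", index=False)
            record(stage, [outdir / "growth_rates.tsv"],
                   {"min_mean_coverage": config.min_mean_coverage,
                    "smooth_window_frac": config.smooth_window_frac})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # ---- ecology statistics -------------------------------------------------
    if config.stages.get("stats", True):
        stage = "stats"
        try:
            per_sample = pd.DataFrame(index=pd.Index(rel.sample_ids, name="sample_id"))
            per_sample["shannon"] = [stats.shannon_index(r) for r in rel.values]
            if counts is not None:
                per_sample["gene_count"] = [stats.gene_count(r) for r in counts.values]
            per_sample.to_csv(outdir / "diversity.tsv", sep="\t")
            D = stats.distance_matrix(rel, "bray_curtis")
            perm = stats.permanova(
                D, disease.loc[rel.sample_ids].to_numpy(),
                n_permutations=config.permanova_permutations,
                seed=derived_seed(config.seed, stage),
            )
            summary = {
                "permanova_pseudo_f": perm.pseudo_f,
                "permanova_p": perm.p,
            }
            if labels is not None:
                fisher = stats.fisher_association(
                    labels.loc[rel.sample_ids].to_numpy(),
                    disease.loc[rel.sample_ids].to_numpy(),
                )
                fisher.to_csv(outdir / "metacommunity_association.tsv", sep="\t")
                summary["min_fisher_q"] = float(fisher["q"].min())
            with open(outdir / "stats_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            outputs = [outdir / "diversity.tsv", outdir / "stats_summary.json"]
            if labels is not None:
                outputs.append(outdir / "metacommunity_association.tsv")
            record(stage, outputs, {"permutations": config.permanova_permutations})
        except Exception as exc:
            raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
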