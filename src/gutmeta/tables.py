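"""Typed tabular containers and TSV I/O for the analysis pipeline.

All tables are plain TSV (first column = row identifier, ``#`` comment lines
ignored, UTF-8). Abundance matrices are normalized internally to samples x
features regardless of the orientation on disk.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gutmeta.tables")

#: abundance table modes
COUNTS = "counts"
RELATIVE = "relative"

#: lipid-A (Raetz) pathway gene set; LpxM is the terminal acyltransferase that
#: distinguishes hexa- from penta-acylated producers.
DEFAULT_LIPID_A_GENES = (
    "LpxA", "LpxC", "LpxD", "LpxH", "LpxB", "LpxK", "WaaA", "LpxL", "LpxM",
)

#: terminal-enzyme classes for short-chain fatty acid biosynthesis
SCFA_ENZYME_CLASSES = ("acetate_terminal", "propionate_terminal", "butyrate_terminal")

_ROW_SUM_TOL = 1e-9


class ValidationError(ValueError):
    """A table violates its structural contract."""


def _read_tsv(path) -> pd.DataFrame:
    # float_precision="round_trip" so write -> read reproduces values bit-identically
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=0, encoding="utf-8",
        float_precision="round_trip",
    )


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique()
        raise ValidationError(f"duplicate {what} id(s): {', '.join(map(str, dup[:5]))}")


@dataclass
class AbundanceTable:
    """Samples x features matrix of counts or relative abundances."""

    data: pd.DataFrame
    mode: str = COUNTS

    def __post_init__(self) -> None:
        if self.mode not in (COUNTS, RELATIVE):
            raise ValidationError(f"unknown mode {self.mode!r}")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValidationError("negative abundance entries are not allowed")
        if np.isnan(vals).any():
            raise ValidationError("missing values in abundance table")
        if self.mode == RELATIVE and vals.size:
            sums = vals.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                sid = self.data.index[np.argmax(bad)]
                raise ValidationError(
                    f"relative abundances of sample {sid!r} sum to "
                    f"{sums[np.argmax(bad)]:.6g}, expected 1"
                )

    # -- accessors -----------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def read(cls, path, mode: str | None = None, features_as_rows: bool = False):
        """Read a TSV abundance table.

        When ``mode`` is None it is auto-detected: an all-integer matrix is
        treated as counts, anything else as relative abundances.
        """
        df = _read_tsv(path)
        if features_as_rows:
            df = df.T
        vals = df.to_numpy(dtype=float)
        if mode is None:
            integral = vals.size == 0 or np.allclose(vals, np.round(vals), atol=0)
            mode = COUNTS if integral else RELATIVE
        return cls(df, mode=mode)

    def write(self, path, features_as_rows: bool = False) -> None:
        df = self.data.T if features_as_rows else self.data
        df.to_csv(path, sep="\t", encoding="utf-8")

    # -- operations ----------------------------------------------------------
    def to_relative(self) -> "AbundanceTable":
        """Divide each row by its total; requires counts mode."""
        if self.mode != COUNTS:
            raise ValidationError("to_relative requires a counts-mode table")
        vals = self.values
        totals = vals.sum(axis=1)
        if (totals <= 0).any():
            sid = self.data.index[int(np.argmax(totals <= 0))]
            raise ValidationError(f"sample {sid!r} has zero total count")
        rel = vals / totals[:, None]
        return AbundanceTable(
            pd.DataFrame(rel, index=self.data.index, columns=self.data.columns),
            mode=RELATIVE,
        )

    def filter_by_occurrence(self, min_rate: float) -> "AbundanceTable":
        """Keep features with nonzero values in strictly more than ``min_rate``
        of samples ("over" reading of the occurrence filter)."""
        if not 0 <= min_rate <= 1:
            raise ValidationError("min_rate must lie in [0, 1]")
        occ = (self.values > 0).mean(axis=0)
        keep = occ > min_rate
        if not keep.any():
            logger.warning("occurrence filter at %.3g removed every feature", min_rate)
        out = self.data.loc[:, keep]
        return AbundanceTable(out, mode=self.mode)

    def subset(self, samples=None, features=None, renormalize: bool = True):
        """Restrict to the given samples/features (order preserved as given).

        Restricting a relative table to a feature subset breaks row closure,
        so rows are re-closed by default (``renormalize=False`` raises in that
        case); counts tables are returned as-is.
        """
        df = self.data
        if samples is not None:
            missing = [s for s in samples if s not in df.index]
            if missing:
                raise ValidationError(f"unknown sample id(s): {missing[:5]}")
            df = df.loc[list(samples)]
        if features is not None:
            missing = [f for f in features if f not in df.columns]
            if missing:
                raise ValidationError(f"unknown feature id(s): {missing[:5]}")
            df = df.loc[:, list(features)]
        if self.mode == RELATIVE and features is not None:
            if not renormalize:
                raise ValidationError(
                    "feature subsets of relative tables must be renormalized"
                )
            vals = df.to_numpy(dtype=float)
            totals = vals.sum(axis=1)
            if (totals <= 0).any():
                sid = df.index[int(np.argmax(totals <= 0))]
                raise ValidationError(f"sample {sid!r} has zero mass on the feature subset")
            df = pd.DataFrame(vals / totals[:, None], index=df.index, columns=df.columns)
            return AbundanceTable(df, mode=RELATIVE)
        return AbundanceTable(df.copy(), mode=self.mode)


@dataclass
class SampleMetadata:
    """Per-sample disease labels, timepoints and clinical covariates."""

    data: pd.DataFrame

    RESERVED = ("disease_status", "timepoint")

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        if "disease_status" not in self.data.columns:
            raise ValidationError("metadata requires a 'disease_status' column")
        bad = set(self.data["disease_status"].unique()) - {"CT", "CD"}
        if bad:
            raise ValidationError(f"disease_status must be CT or CD, got {sorted(bad)}")
        _check_unique(pd.Index(self.data.columns), "covariate")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def disease_status(self) -> pd.Series:
        return self.data["disease_status"]

    @property
    def covariates(self) -> pd.DataFrame:
        keep = [c for c in self.data.columns if c not in self.RESERVED]
        return self.data[keep]

    @classmethod
    def read(cls, path):
        return cls(_read_tsv(path))

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", encoding="utf-8")


@dataclass
class TaxonAnnotation:
    """Per-taxon phylum labels, lipid-A gene presence and SCFA enzyme carriage.

    On disk this is one TSV whose lipid-A columns are prefixed ``lipidA:`` and
    SCFA columns ``scfa:``; any other column is free-form taxonomy.
    """

    lipida: pd.DataFrame
    scfa: pd.DataFrame
    taxonomy: pd.DataFrame = field(default_factory=pd.DataFrame)
    lipida_genes: tuple = DEFAULT_LIPID_A_GENES

    def __post_init__(self) -> None:
        _check_unique(self.lipida.index, "taxon")
        unknown = [g for g in self.lipida.columns if g not in self.lipida_genes]
        if unknown:
            raise ValidationError(f"unknown lipid-A gene name(s): {unknown}")
        unknown = [c for c in self.scfa.columns if c not in SCFA_ENZYME_CLASSES]
        if unknown:
            raise ValidationError(f"unknown SCFA enzyme class(es): {unknown}")
        if not self.lipida.index.equals(self.scfa.index):
            raise ValidationError("lipid-A and SCFA tables index different taxa")
        self.lipida = self.lipida.astype(bool)
        self.scfa = self.scfa.astype(bool)

    @property
    def taxon_ids(self) -> list:
        return list(self.lipida.index)

    def scfa_carriers(self, enzyme_class: str) -> list:
        if enzyme_class not in SCFA_ENZYME_CLASSES:
            raise ValidationError(f"unknown SCFA enzyme class {enzyme_class!r}")
        col = self.scfa[enzyme_class]
        return list(col.index[col])

    @classmethod
    def read(cls, path, lipida_genes: tuple = DEFAULT_LIPID_A_GENES):
        df = _read_tsv(path)
        lip = df[[c for c in df.columns if c.startswith("lipidA:")]].copy()
        lip.columns = [c.split(":", 1)[1] for c in lip.columns]
        scfa = df[[c for c in df.columns if c.startswith("scfa:")]].copy()
        scfa.columns = [c.split(":", 1)[1] for c in scfa.columns]
        taxo = df[[c for c in df.columns if ":" not in c]].copy()
        return cls(lip.astype(bool), scfa.astype(bool), taxo, lipida_genes)

    def write(self, path) -> None:
        lip = self.lipida.astype(int).add_prefix("lipidA:")
        scfa = self.scfa.astype(int).add_prefix("scfa:")
        pd.concat([self.taxonomy, lip, scfa], axis=1).to_csv(
            path, sep="\t", encoding="utf-8", index_label="taxon_id"
        )


_HIT_COLUMNS = ("enzyme_id", "identity", "score", "evalue")


def load_homology_hits(path) -> pd.DataFrame:
    """Load a protein-homology hit table (gene_id, enzyme_id, identity, score, evalue)."""
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    return validate_homology_hits(df)


def validate_homology_hits(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("gene_id",) + _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"homology hit table missing column(s): {missing}")
    if ((df["identity"] < 0) | (df["identity"] > 100)).any():
        raise ValidationError("homology hit identity outside [0, 100]")
    if (df["evalue"] < 0).any():
        raise ValidationError("negative E-value in homology hit table")
    return df.reset_index(drop=True)


def load_dataset(
    abundance_path,
    metadata_path,
    annotation_path=None,
    mode: str | None = None,
    features_as_rows: bool = False,
):
    """Load and cross-validate an abundance table, metadata and (optionally)
    taxon annotation. Sample order follows the abundance table."""
    abund = AbundanceTable.read(abundance_path, mode=mode, features_as_rows=features_as_rows)
    meta = SampleMetadata.read(metadata_path)
    missing = [s for s in abund.sample_ids if s not in meta.data.index]
    if missing:
        raise ValidationError(f"metadata missing sample id(s): {missing[:5]}")
    meta = SampleMetadata(meta.data.loc[abund.sample_ids])
    annot = None
    if annotation_path is not None:
        annot = TaxonAnnotation.read(annotation_path)
        uncovered = [f for f in abund.feature_ids if f not in annot.lipida.index]
        if uncovered:
            logger.warning(
                "annotation lacks %d of %d abundance features (e.g. %s)",
                len(uncovered), abund.n_features, uncovered[0],
            )
    return abund, meta, annot
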