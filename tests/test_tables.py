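import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gutmeta.tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonAnnotation,
    ValidationError,
    load_dataset,
    validate_homology_hits,
)
from .conftest import make_counts, make_relative


class TestAbundanceTable:
    def test_round_trip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        tab = make_counts(rng.integers(0, 50, size=(3, 4)))
        path = tmp_path / "counts.tsv"
        tab.write(path)
        back = AbundanceTable.read(path)
        assert back.mode == "counts"
        assert back.data.equals(tab.data.astype(float).astype(np.int64).astype(float)) or np.array_equal(
            back.values, tab.values
        )
        rel = tab.to_relative()
        rel.write(path)
        back = AbundanceTable.read(path)
        assert back.mode == "relative"
        assert np.array_equal(back.values, rel.values)

    def test_orientation_flag_transposes(self, tmp_path):
        tab = make_counts([[1, 2, 3], [4, 5, 6]])
        path = tmp_path / "t.tsv"
        tab.write(path, features_as_rows=True)
        back = AbundanceTable.read(path, features_as_rows=True)
        assert np.array_equal(back.values, tab.values)
        assert back.sample_ids == tab.sample_ids

    def test_duplicate_sample_id_names_offender(self):
        df = pd.DataFrame([[1, 2], [3, 4]], index=["S1", "S1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="S1"):
            AbundanceTable(df, mode="counts")

    def test_relative_row_sum_violation_rejected(self):
        df = pd.DataFrame([[0.5, 0.3]], index=["S1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="S1"):
            AbundanceTable(df, mode="relative")

    def test_negative_entries_rejected(self):
        df = pd.DataFrame([[1, -2]], index=["S1"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="negative"):
            AbundanceTable(df, mode="counts")

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("# a comment\nid\ta\tb\nS1\t1\t2\n", encoding="utf-8")
        tab = AbundanceTable.read(path)
        assert tab.values.tolist() == [[1.0, 2.0]]


class TestToRelative:
    def test_arithmetic(self):
        tab = make_counts([[2, 2, 4]])
        assert tab.to_relative().values.tolist() == [[0.25, 0.25, 0.5]]

    def test_zero_row_names_sample(self):
        tab = make_counts([[1, 1], [0, 0]])
        with pytest.raises(ValidationError, match="S1"):
            tab.to_relative()

    def test_mode_mismatch_rejected(self):
        rel = make_relative([[1, 1]])
        with pytest.raises(ValidationError, match="counts"):
            rel.to_relative()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.int64, (4, 6), elements=st.integers(0, 1000)))
    def test_rows_close_to_one(self, X):
        X[:, 0] += 1  # ensure positive totals
        rel = make_counts(X).to_relative()
        assert np.all(np.abs(rel.values.sum(axis=1) - 1.0) < 1e-12)


class TestOccurrenceFilter:
    def test_rate_exactly_at_threshold_is_dropped(self):
        X = np.zeros((20, 2), dtype=int)
        X[:, 0] = 5
        X[0, 1] = 1  # present in 1/20 = 0.05, not > 0.05
        kept = make_counts(X).filter_by_occurrence(0.05)
        assert kept.feature_ids == ["T0"]

    def test_rate_above_threshold_is_kept(self):
        X = np.zeros((20, 2), dtype=int)
        X[:, 0] = 5
        X[:2, 1] = 1  # 2/20 = 0.10 > 0.05
        kept = make_counts(X).filter_by_occurrence(0.05)
        assert kept.feature_ids == ["T0", "T1"]

    def test_zero_rate_keeps_any_nonzero(self):
        X = np.array([[1, 0, 3], [2, 0, 0]])
        kept = make_counts(X).filter_by_occurrence(0.0)
        assert kept.feature_ids == ["T0", "T2"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(np.int64, (6, 8), elements=st.integers(0, 3)),
        st.floats(0, 1, allow_nan=False),
    )
    def test_idempotent(self, X, rate):
        X[:, 0] += 1
        once = make_counts(X).filter_by_occurrence(rate)
        twice = once.filter_by_occurrence(rate)
        assert once.feature_ids == twice.feature_ids
        assert np.array_equal(once.values, twice.values)


class TestSubset:
    def test_relative_feature_subset_renormalizes(self):
        rel = make_relative([[1, 1, 2], [1, 3, 4]])
        sub = rel.subset(features=["T0", "T2"])
        assert np.allclose(sub.values.sum(axis=1), 1.0)

    def test_unknown_ids_rejected(self):
        tab = make_counts([[1, 2]])
        with pytest.raises(ValidationError, match="nope"):
            tab.subset(samples=["nope"])


class TestAnnotationAndDataset:
    def test_annotation_round_trip(self, tmp_path, default_cohort):
        path = tmp_path / "annot.tsv"
        default_cohort.annotation.write(path)
        back = TaxonAnnotation.read(path)
        assert back.lipida.equals(default_cohort.annotation.lipida)
        assert back.scfa.equals(default_cohort.annotation.scfa)

    def test_unknown_lipida_gene_rejected(self):
        lip = pd.DataFrame({"NotAGene": [True]}, index=["t1"])
        scfa = pd.DataFrame(
            {"acetate_terminal": [False], "propionate_terminal": [False], "butyrate_terminal": [False]},
            index=["t1"],
        )
        with pytest.raises(ValidationError, match="NotAGene"):
            TaxonAnnotation(lip, scfa)

    def test_homology_hit_validation(self):
        df = pd.DataFrame(
            {"gene_id": ["g"], "enzyme_id": ["e"], "identity": [120.0], "score": [10.0], "evalue": [1e-3]}
        )
        with pytest.raises(ValidationError, match="identity"):
            validate_homology_hits(df)

    def test_load_dataset_cross_validates(self, tmp_path, default_cohort):
        default_cohort.write(tmp_path)
        abund, meta, annot = load_dataset(
            tmp_path / "counts.tsv", tmp_path / "metadata.tsv", tmp_path / "annotation.tsv"
        )
        assert abund.sample_ids == meta.sample_ids
        assert abund.mode == "counts"
        assert set(abund.feature_ids) <= set(annot.taxon_ids)

    def test_metadata_requires_disease_column(self):
        with pytest.raises(ValidationError, match="disease_status"):
            SampleMetadata(pd.DataFrame({"age": [1]}, index=["S1"]))
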