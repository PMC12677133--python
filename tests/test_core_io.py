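"""IO, QC, normalization and count-form construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trajrank.core_io import (
    CountForm,
    CountMatrix,
    compute_qc,
    exclude_genes,
    filter_cells,
    log_transform,
    make_count_forms,
    normalize_depth,
    read_counts,
    select_hvg,
    write_counts,
)

from .conftest import make_count_matrix


class TestReadWrite:
    def test_triplet_roundtrip_conserves_counts(self, small_counts, tmp_path):
        write_counts(small_counts, tmp_path / "trip", dialect="triplet")
        back = read_counts(tmp_path / "trip", dialect="triplet")
        assert back.barcodes == small_counts.barcodes
        assert back.genes == small_counts.genes
        assert (back.counts != small_counts.counts).nnz == 0
        assert back.counts.sum() == small_counts.counts.sum()

    def test_missing_features_file_is_named(self, small_counts, tmp_path):
        write_counts(small_counts, tmp_path / "trip", dialect="triplet")
        (tmp_path / "trip" / "features.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="features"):
            read_counts(tmp_path / "trip", dialect="triplet")

    def test_dense_and_triplet_dialects_agree(self, small_counts, tmp_path):
        write_counts(small_counts, tmp_path / "trip", dialect="triplet")
        write_counts(small_counts, tmp_path / "dense.tsv", dialect="dense-tsv")
        a = read_counts(tmp_path / "trip")
        b = read_counts(tmp_path / "dense.tsv")
        assert a.barcodes == b.barcodes and a.genes == b.genes
        np.testing.assert_array_equal(a.counts.toarray(), b.counts.toarray())

    def test_genes_as_rows_tsv_is_transposed(self, small_counts, tmp_path):
        df = small_counts.to_dense_df().T
        df.index.name = "gene"
        df.to_csv(tmp_path / "byrow.tsv", sep="\t")
        back = read_counts(tmp_path / "byrow.tsv")
        np.testing.assert_array_equal(
            back.counts.toarray(), small_counts.counts.toarray()
        )

    def test_duplicate_gene_symbols_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene.*GeneA"):
            make_count_matrix([[1, 2]], genes=["GeneA", "GeneA"])


class TestQC:
    def test_mito_fraction_forced_ratio(self):
        cm = make_count_matrix([[5, 5]], genes=["mt-Nd1", "GeneA"])
        qc = compute_qc(cm)
        assert qc["mito_frac"].iloc[0] == pytest.approx(0.5)

    def test_no_matching_mito_gene_gives_zero(self):
        cm = make_count_matrix([[3, 4]], genes=["GeneA", "GeneB"])
        assert (compute_qc(cm)["mito_frac"] == 0).all()

    def test_totals_match_dense_sum_oracle(self, small_counts):
        qc = compute_qc(small_counts)
        dense = small_counts.counts.toarray()
        np.testing.assert_allclose(qc["total_counts"], dense.sum(axis=1))

    def test_zero_total_cell_flagged_with_zero_mito(self):
        cm = make_count_matrix([[0, 0], [1, 1]], genes=["mt-Nd1", "GeneA"])
        qc = compute_qc(cm)
        assert bool(qc["zero_total"].iloc[0])
        assert qc["mito_frac"].iloc[0] == 0

    def test_filter_cells_thresholds(self):
        cm = make_count_matrix(
            [[5, 95], [50, 50]], genes=["mt-Nd1", "GeneA"]
        )
        meta = compute_qc(cm)
        kept, kept_meta = filter_cells(cm, meta, max_mito=0.2, min_counts=10)
        assert kept.n_cells == 1 and kept_meta.index[0] == "c0"

    def test_filter_noop_with_loose_thresholds(self, small_counts):
        meta = compute_qc(small_counts)
        kept, _ = filter_cells(small_counts, meta, max_mito=1.0, min_counts=0)
        assert kept.barcodes == small_counts.barcodes
        assert kept.genes == small_counts.genes

    def test_planted_high_mito_cells_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 20, size=(10, 4))
        counts[:, 0] = 1  # healthy cells: trace mito signal
        counts[:3, 0] = 1000  # 3 cells dominated by the mito gene
        cm = make_count_matrix(counts, genes=["mt-Nd1", "a", "b", "c"])
        meta = compute_qc(cm)
        kept, _ = filter_cells(cm, meta, max_mito=0.2, min_counts=0)
        assert kept.n_cells == 7

    def test_all_cells_removed_is_an_error(self, small_counts):
        meta = compute_qc(small_counts)
        with pytest.raises(ValueError, match="threshold"):
            filter_cells(small_counts, meta, max_mito=0.0, min_counts=10**9)


class TestExcludeGenes:
    def test_or_patterns_mask(self):
        cm = make_count_matrix(
            [[1, 1, 1]], genes=["Or1ad1", "Olfr544", "Actb"]
        )
        keep = exclude_genes(cm, ["Olfr", r"Or\d"], purpose="embedding-only")
        np.testing.assert_array_equal(keep, [False, False, True])

    def test_malat_excluded_globally(self, small_counts):
        reduced = exclude_genes(small_counts, ["Malat"], purpose="global")
        assert "Malat1" not in reduced.genes
        assert reduced.n_genes == small_counts.n_genes - 1

    def test_empty_match_warns_not_errors(self, small_counts):
        with pytest.warns(UserWarning, match="matched no genes"):
            keep = exclude_genes(small_counts, ["Xyz"], purpose="embedding-only")
        assert keep.all()

    def test_whitelist_escape(self):
        cm = make_count_matrix([[1, 1]], genes=["Olfr544", "Olfr1"])
        keep = exclude_genes(
            cm, ["Olfr"], purpose="embedding-only", whitelist=["Olfr1"]
        )
        np.testing.assert_array_equal(keep, [False, True])


class TestNormalize:
    def test_row_sums_hit_target(self):
        cm = make_count_matrix([[1000, 4000], [2, 3]])
        norm = normalize_depth(cm, target=1e4)
        np.testing.assert_allclose(
            np.asarray(norm.sum(axis=1)).ravel(), [1e4, 1e4], rtol=1e-9
        )
        np.testing.assert_allclose(norm.toarray()[0], [2000, 8000])

    def test_cell_at_target_unchanged(self):
        cm = make_count_matrix([[4000, 6000]])
        norm = normalize_depth(cm, target=1e4)
        np.testing.assert_allclose(norm.toarray()[0], [4000, 6000])

    def test_scale_invariance_of_proportions(self):
        cm = make_count_matrix([[1, 2, 3], [10, 20, 30]])
        norm = normalize_depth(cm).toarray()
        np.testing.assert_allclose(norm[0], norm[1], rtol=1e-12)

    def test_zero_total_cell_named_in_error(self):
        cm = make_count_matrix([[0, 0], [1, 1]], barcodes=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            normalize_depth(cm)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            np.int64,
            (3, 4),
            elements=st.integers(min_value=0, max_value=1000),
        ).filter(lambda a: (a.sum(axis=1) > 0).all())
    )
    def test_property_row_sums_and_rescale_invariance(self, a):
        cm = make_count_matrix(a)
        norm = normalize_depth(cm).toarray()
        np.testing.assert_allclose(norm.sum(axis=1), 1e4, rtol=1e-6)
        doubled = normalize_depth(make_count_matrix(3 * a)).toarray()
        np.testing.assert_allclose(norm, doubled, rtol=1e-9)


class TestLogTransform:
    def test_closed_forms(self):
        out = log_transform(np.array([[0.0, 9.0]]))
        np.testing.assert_allclose(out, [[0.0, np.log(10.0)]])

    def test_monotone(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 50, 100))
        y = log_transform(x)
        assert (np.diff(y) > 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([-1.0]))


class TestSelectHVG:
    def test_constant_gene_never_beats_varying(self):
        x = np.column_stack([np.full(20, 5.0), np.arange(20.0)])
        mask = select_hvg(x, ["flat", "vary"], n_top=1)
        np.testing.assert_array_equal(mask, [False, True])

    def test_planted_high_dispersion_gene_found(self):
        rng = np.random.default_rng(0)
        x = np.full((100, 51), 5.0)  # 50 flat genes ...
        x[:, 17] = rng.poisson(5.0, 100) * rng.integers(0, 8, 100)  # ... one bursty
        mask = select_hvg(x, None, n_top=1)
        # brute-force dispersion oracle on the same matrix
        with np.errstate(invalid="ignore"):
            disp = x.var(axis=0) / x.mean(axis=0)
        assert mask[np.argmax(disp)]
        assert mask.sum() == 1

    def test_n_top_equals_gene_count(self):
        x = np.random.default_rng(0).poisson(3, (10, 5)).astype(float)
        assert select_hvg(x, None, n_top=5).all()

    def test_bad_n_top(self):
        with pytest.raises(ValueError):
            select_hvg(np.ones((3, 3)), None, n_top=0)


class TestCountForms:
    def _traj(self, rows, genes):
        norm = pd.DataFrame(rows, index=genes)
        return norm, np.log1p(norm)

    def test_row_max_scaling(self):
        norm, log = self._traj([[2.0, 4.0, 8.0]], ["g"])
        forms, zero = make_count_forms(norm, log)
        np.testing.assert_allclose(
            forms[CountForm.NORM_MAX].loc["g"], [0.25, 0.5, 1.0]
        )
        assert zero == []

    def test_all_zero_row_flagged_and_absent(self):
        norm, log = self._traj([[0.0, 0.0], [1.0, 2.0]], ["dead", "live"])
        forms, zero = make_count_forms(norm, log)
        assert zero == ["dead"]
        assert "dead" not in forms[CountForm.NORM_MAX].index
        assert "dead" in forms[CountForm.NORM].index

    def test_exactly_four_forms(self):
        norm, log = self._traj([[1.0, 2.0]], ["g"])
        forms, _ = make_count_forms(norm, log)
        assert set(forms) == set(CountForm) and len(CountForm) == 4

    def test_max_scaled_rows_peak_at_one(self):
        rng = np.random.default_rng(2)
        norm = pd.DataFrame(rng.uniform(0.1, 5, (6, 10)))
        forms, _ = make_count_forms(norm, np.log1p(norm))
        for form in (CountForm.NORM_MAX, CountForm.LOG_MAX):
            np.testing.assert_allclose(forms[form].max(axis=1), 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            np.float64,
            (4, 6),
            elements=st.floats(min_value=0, max_value=100, allow_nan=False),
        )
    )
    def test_property_max_scaling_idempotent(self, a):
        norm = pd.DataFrame(a)
        forms, _ = make_count_forms(norm, np.log1p(norm))
        once = forms[CountForm.NORM_MAX]
        twice, _ = make_count_forms(once, np.log1p(once))
        np.testing.assert_allclose(
            twice[CountForm.NORM_MAX].to_numpy(), once.to_numpy(), atol=1e-12
        )
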