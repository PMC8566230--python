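"""Expression-matrix normalisation, multiple-testing utilities, and GMT IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbgf.matrix import (
    ClinicalTable,
    ExpressionMatrix,
    adjust_pvalues,
    merge_datasets,
    normalize_fold_from_mean,
    quantile_normalize,
)
from nbgf.genesets import GeneSetCollection, read_gmt, write_gmt

from conftest import toy_expression


class TestFoldFromMean:
    def test_divides_by_gene_mean(self):
        m = toy_expression(np.array([[2.0], [4.0], [6.0]]))
        out = normalize_fold_from_mean(m)
        assert np.allclose(out.data["g0"], [0.5, 1.0, 1.5])
        assert out.norm_state == "fold_from_mean"

    def test_constant_gene_maps_to_one(self):
        m = toy_expression(np.array([[5.0], [5.0], [5.0]]))
        assert np.allclose(normalize_fold_from_mean(m).data["g0"], 1.0)

    def test_zero_mean_gene_errors_naming_gene(self):
        m = toy_expression(np.array([[0.0, 1.0], [0.0, 2.0]]))
        with pytest.raises(ValueError, match="zero mean.*g0"):
            normalize_fold_from_mean(m)

    def test_idempotent_after_state_reset(self):
        rng = np.random.default_rng(0)
        m = toy_expression(rng.lognormal(1.0, 0.5, size=(8, 5)))
        once = normalize_fold_from_mean(m)
        again = normalize_fold_from_mean(
            ExpressionMatrix(once.data, norm_state="raw")
        )
        assert np.allclose(once.data, again.data)

    def test_per_dataset_when_merged(self):
        a = toy_expression(np.array([[2.0], [4.0]]))
        b = ExpressionMatrix(
            pd.DataFrame([[10.0], [30.0]], index=["t0", "t1"], columns=["g0"])
        )
        merged = merge_datasets({"A": a, "B": b})
        out = normalize_fold_from_mean(merged)
        assert np.allclose(out.data["g0"], [2 / 3, 4 / 3, 0.5, 1.5])

    def test_rejects_non_raw_input(self):
        m = toy_expression(np.ones((3, 2)), norm_state="quantile")
        with pytest.raises(ValueError, match="raw"):
            normalize_fold_from_mean(m)


def brute_force_quantile(values: np.ndarray) -> np.ndarray:
    """Rank-average quantile normalisation, written independently."""
    target = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values, dtype=float)
    for i, row in enumerate(values):
        sorted_pos = np.argsort(np.argsort(row, kind="stable"), kind="stable")
        for j, val in enumerate(row):
            tied = np.flatnonzero(row == val)
            positions = sorted(sorted_pos[t] for t in tied)
            out[i, j] = np.mean([target[p] for p in positions])
    return out


class TestQuantileNormalize:
    def test_two_samples_meet_at_mean_of_sorted(self):
        m = toy_expression(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        out = quantile_normalize(m)
        assert np.allclose(out.data.to_numpy(), [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_samples_unchanged(self):
        m = toy_expression(np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]]))
        out = quantile_normalize(m)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_ties_get_average_of_tied_targets(self):
        m = toy_expression(np.array([[1.0, 1.0, 2.0], [3.0, 4.0, 5.0]]))
        out = quantile_normalize(m)
        assert np.allclose(out.data.to_numpy(), brute_force_quantile(m.data.to_numpy()))
        # both tied entries share the average of the two lowest targets
        assert out.data.iloc[0, 0] == out.data.iloc[0, 1] == pytest.approx(2.25)

    def test_matches_brute_force_with_random_ties(self):
        rng = np.random.default_rng(42)
        values = rng.integers(0, 5, size=(6, 8)).astype(float)
        out = quantile_normalize(toy_expression(values))
        assert np.allclose(out.data.to_numpy(), brute_force_quantile(values))

    def test_row_sums_equal(self):
        rng = np.random.default_rng(1)
        values = rng.integers(0, 4, size=(7, 9)).astype(float)
        out = quantile_normalize(toy_expression(values))
        sums = out.data.sum(axis=1).to_numpy()
        assert np.allclose(sums, sums[0], atol=1e-9)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(toy_expression(np.ones((1, 4))))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH q-values straight from the definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = running_min
    return q


class TestAdjustPvalues:
    def test_bonferroni_closed_form(self):
        assert np.allclose(
            adjust_pvalues([0.01, 0.04], "bonferroni"), [0.02, 0.08]
        )

    def test_bh_equal_ratio_example(self):
        q = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty_input_passes_through(self):
        assert adjust_pvalues([], "bh_fdr").size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_bh_matches_step_up_definition(self, pvals):
        p = np.asarray(pvals)
        assert np.allclose(adjust_pvalues(p, "bh_fdr"), brute_force_bh(p))

    def test_bh_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=15)
        q = adjust_pvalues(p, "bh_fdr")
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestGMT:
    def test_round_trip_and_dedupe(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tA\tB\nS2\tother\tA\tA\tB\n")
        coll = read_gmt(path)
        assert coll["S1"].genes == ("A", "B")
        assert coll["S2"].genes == ("A", "B")  # duplicate collapsed
        out = tmp_path / "roundtrip.gmt"
        write_gmt(coll, out)
        assert read_gmt(out)["S2"].genes == ("A", "B")

    def test_short_line_errors_with_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\tA\nS2\tdesc\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gmt(path)

    def test_from_lists_preserves_order(self):
        coll = GeneSetCollection.from_lists({"S": ["C", "A", "C", "B"]})
        assert coll["S"].genes == ("C", "A", "B")


class TestContainers:
    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame(np.ones((2, 2)), index=["s", "s"], columns=["a", "b"])
        with pytest.raises(ValueError, match="duplicate sample"):
            ExpressionMatrix(df)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            toy_expression(np.array([[1.0, -1.0]]))

    def test_fold_state_enforces_unit_means(self):
        with pytest.raises(ValueError, match="means of 1"):
            toy_expression(np.array([[2.0], [4.0]]), norm_state="fold_from_mean")

    def test_clinical_roundtrip_and_alignment(self, tmp_path, small_cohort):
        expr, clinical, _ = small_cohort
        path = tmp_path / "clinical.csv"
        clinical.to_csv(path)
        back = ClinicalTable.read_csv(path)
        pd.testing.assert_frame_equal(
            back.df, clinical.df, check_dtype=False, check_names=False
        )
        aligned = back.aligned_to(expr)
        assert aligned.sample_ids == expr.sample_ids

    def test_clinical_rejects_bad_enum(self):
        df = pd.DataFrame(
            {
                "os_time": [1.0],
                "os_event": [True],
                "mycn": ["maybe"],
                "inss_stage": ["4"],
                "metastasis": ["no"],
                "response": ["good"],
            },
            index=["s0"],
        )
        with pytest.raises(ValueError, match="mycn"):
            ClinicalTable(df)

    def test_expression_tsv_roundtrip(self, tmp_path):
        m = toy_expression(np.arange(6, dtype=float).reshape(2, 3))
        path = tmp_path / "expr.tsv"
        m.to_tsv(path)
        back = ExpressionMatrix.read_tsv(path)
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_merge_requires_shared_genes(self):
        a = toy_expression(np.ones((2, 2)))
        b = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 2)), index=["t0", "t1"], columns=["x", "y"])
        )
        with pytest.raises(ValueError, match="share no genes"):
            merge_datasets({"A": a, "B": b})
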