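from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from riboselect import (
    CodonCountMatrix,
    adjust_bh,
    compute_enrichment,
    compute_tpm,
    enrichment_table,
    median_centre,
    test_enrichment,
)
from riboselect.simulate import GRP94_LIKE_ID


def _two_transcript_matrix(counts: dict[str, int]):
    rows = [
        (tid, 1, "input", 1, n) for tid, n in counts.items() if n > 0
    ]
    return CodonCountMatrix(
        pd.DataFrame(rows, columns=["transcript_id", "codon", "sample", "replicate", "count"])
    )


class TestTPM:
    def test_stated_formula_on_two_transcripts(self, tiny_annotation):
        # counts {10, 30} on CDS of 2412 and 753 nt: evaluate
        # rate = n / (cds_kb), TPM = 1e6 * rate / sum(rate) directly
        matrix = _two_transcript_matrix({"GRP94L": 10, "CYTO1": 30})
        annotation = {t: tiny_annotation[t] for t in ("GRP94L", "CYTO1")}
        tpm = compute_tpm(matrix, annotation)
        rates = {"GRP94L": 10 / 2.412, "CYTO1": 30 / 0.753}
        total = sum(rates.values())
        for tid, rate in rates.items():
            assert tpm.loc[tid, ("input", 1)] == pytest.approx(1e6 * rate / total)

    def test_equal_counts_equal_lengths_split_evenly(self, tiny_annotation):
        annotation = {"CYTO1": tiny_annotation["CYTO1"]}
        second = pd.DataFrame(
            [["CYTO1", 1, "input", 1, 20]],
            columns=["transcript_id", "codon", "sample", "replicate", "count"],
        )
        tpm = compute_tpm(CodonCountMatrix(second), annotation)
        assert tpm.loc["CYTO1", ("input", 1)] == pytest.approx(1e6)

    def test_normalization_sums_to_one_million(self, small_dataset):
        tpm = compute_tpm(small_dataset.counts, small_dataset.annotation)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_empty_library_rejected(self, tiny_annotation):
        empty = CodonCountMatrix(
            pd.DataFrame(columns=["transcript_id", "codon", "sample", "replicate", "count"])
        )
        with pytest.raises(ValueError):
            compute_tpm(empty, tiny_annotation)


class TestEnrichment:
    def test_identity_and_log_law(self):
        assert compute_enrichment(7.0, 7.0) == pytest.approx(0.0)
        assert compute_enrichment(4e6, 1e6, alpha=1e-12) == pytest.approx(2.0)

    def test_pseudocount_example(self):
        # alpha = 1 with TPMs 0 and 3: log2(1/4) = -2
        assert compute_enrichment(0.0, 3.0, alpha=1.0) == pytest.approx(-2.0)

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            compute_enrichment(-1.0, 2.0)


class TestMedianCentre:
    def test_examples(self):
        assert list(median_centre([1, 2, 3])) == [-1, 0, 1]
        assert list(median_centre([0, 0, 10])) == [0, 0, 10]

    def test_even_set_uses_midpoint(self):
        assert list(median_centre([1, 3])) == [-1, 1]

    def test_odd_output_median_exactly_zero(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=101)
        assert np.median(median_centre(values)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_centre([])


class TestChiSquared:
    def test_equal_proportions_give_zero(self):
        stat, p = test_enrichment(30, 300, 50, 500)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_against_brute_force_expected_cells(self):
        # oracle: direct sum((O - E)^2 / E) over the 2x2 table
        table = np.array([[30.0, 70.0], [10.0, 90.0]])
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        stat, p = test_enrichment(30, 100, 10, 100)
        assert stat == pytest.approx(oracle)
        assert oracle == pytest.approx(12.5)
        # independent route: scipy's contingency test without correction
        scipy_stat, scipy_p, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(scipy_stat)
        assert p == pytest.approx(scipy_p)

    def test_doubling_cells_doubles_statistic(self):
        stat1, _ = test_enrichment(30, 100, 10, 100)
        stat2, _ = test_enrichment(60, 200, 20, 200)
        assert stat2 == pytest.approx(2 * stat1)

    def test_zero_margin_flagged_untestable(self):
        stat, p = test_enrichment(0, 100, 0, 100)
        assert np.isnan(stat) and np.isnan(p)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            test_enrichment(10, 5, 0, 100)


class TestBH:
    def test_step_up_oracle(self):
        # oracle: p_adj(i) = min_{j >= i} m * p(j) / j on sorted p
        p = np.array([0.01, 0.02, 0.03, 0.04])
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        assert np.allclose(adjust_bh(p), oracle[np.argsort(order)])
        assert np.allclose(adjust_bh(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_adjusted_at_least_raw_and_monotone(self, p):
        p = np.asarray(p)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEnrichmentTable:
    def test_grp94_like_positive_control_tops_the_table(self, small_dataset):
        table = enrichment_table(small_dataset.counts, small_dataset.annotation)
        quantified = table[table["quantified"]].sort_values(
            "log2_enrichment_centred", ascending=False
        )
        assert quantified.iloc[0]["transcript_id"] == GRP94_LIKE_ID
        top = table.set_index("transcript_id").loc[GRP94_LIKE_ID]
        assert top["p_adj"] < 0.05 and top["log2_enrichment_centred"] > 1

    def test_centred_median_is_zero_over_quantified(self, small_dataset):
        table = enrichment_table(small_dataset.counts, small_dataset.annotation)
        centred = table.loc[table["quantified"], "log2_enrichment_centred"]
        assert abs(np.median(centred)) < 1e-12

    def test_low_coverage_transcripts_not_tested(self, small_dataset):
        table = enrichment_table(
            small_dataset.counts, small_dataset.annotation, min_input_reads=2000
        )
        skipped = table[~table["quantified"]]
        assert len(skipped) > 0
        assert skipped["log2_enrichment_centred"].isna().all()
        assert skipped["p_adj"].isna().all()

    def test_padj_at_least_p(self, small_dataset):
        table = enrichment_table(small_dataset.counts, small_dataset.annotation)
        tested = table[table["tested"]]
        assert (tested["p_adj"] >= tested["p_value"] - 1e-12).all()
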