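"""Variant bookkeeping, binning, and large-diameter summaries."""

import numpy as np
import pandas as pd
import pytest

from veinlaw import (
    SyntheticTruth,
    VariantFilter,
    bin_means,
    make_variant,
    simulate_dataset,
    solve_table,
    summarize_threshold_slice,
)


def solved_frame(rows):
    """Minimal solved table: (k, case) pairs with synthetic d0."""
    frame = pd.DataFrame(rows, columns=["k", "case"])
    frame["d0"] = np.linspace(10, 100, len(frame))
    return frame


FOUR_CASES = [
    (3.5, "standard"),
    (50.0, "mixed"),
    (-20.0, "both_wider"),
    (float("nan"), "uncomputable"),
]


class TestVariantRules:
    def test_v1_keeps_all_computable(self):
        vt = make_variant(solved_frame(FOUR_CASES), "V1")
        assert sorted(vt.rows["k"]) == [-20.0, 3.5, 50.0]
        assert vt.provenance["n_uncomputable_dropped"] == 1

    def test_v2_drops_mixed(self):
        vt = make_variant(solved_frame(FOUR_CASES), "V2")
        assert sorted(vt.rows["k"]) == [-20.0, 3.5]
        assert vt.provenance["n_mixed_dropped"] == 1
        assert vt.provenance["n_uncomputable_dropped"] == 1

    def test_v3_truncates_at_minus14_and_20(self):
        vt = make_variant(solved_frame(FOUR_CASES), "V3")
        assert sorted(vt.rows["k"]) == [-14.0, 3.5]
        assert vt.provenance["n_truncated"] == 1
        # deviation recomputed from the clipped k
        assert vt.rows.loc[vt.rows["k"] == -14.0, "deviation"].iloc[0] == 17.0

    def test_v4_standard_only_clipped_above(self):
        rows = FOUR_CASES + [(25.0, "standard")]
        vt = make_variant(solved_frame(rows), "V4")
        assert sorted(vt.rows["k"]) == [3.5, 20.0]
        assert vt.provenance["n_both_wider_dropped"] == 1

    def test_retained_plus_dropped_equals_input(self, ten_row_table):
        for vid in ("V1", "V2", "V3", "V4"):
            prov = make_variant(ten_row_table, vid).provenance
            dropped = (
                prov["n_uncomputable_dropped"]
                + prov["n_mixed_dropped"]
                + prov["n_both_wider_dropped"]
            )
            assert prov["n_retained"] + dropped == prov["n_input"] == 10

    def test_nesting_by_record_identity(self, ten_row_table):
        idx = {
            vid: set(make_variant(ten_row_table, vid).rows.index)
            for vid in ("V1", "V2", "V4")
        }
        assert idx["V4"] <= idx["V2"] <= idx["V1"]

    def test_truncation_is_idempotent(self, benchmark_v1):
        once = make_variant(benchmark_v1.rows, "V3").rows
        twice = make_variant(once, "V3").rows
        assert (once["k"].to_numpy() == twice["k"].to_numpy()).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            make_variant(solved_frame(FOUR_CASES), "V9")

    def test_variant_filter_estimator(self, ten_row_table):
        filt = VariantFilter(variant="V2").fit(ten_row_table)
        assert filt.provenance_["n_mixed_dropped"] == 2
        assert "deviation" in filt.transform(ten_row_table).columns


class TestBinning:
    def _variant(self, n, k_values=None, d0=None):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {
                "k": k_values if k_values is not None else rng.normal(3, 1, n),
                "case": "standard",
                "d0": d0 if d0 is not None else rng.uniform(10, 1000, n),
            }
        )
        return make_variant(frame, "V1")

    def test_remainder_policy(self):
        series = bin_means(self._variant(45), bin_size=20)
        assert len(series.table) == 2
        assert series.n_dropped_remainder == 5
        assert (series.table["n"] == 20).all()

    def test_constant_k_gives_zero_deviation_bins(self):
        series = bin_means(self._variant(60, k_values=np.full(60, 3.0)))
        assert (series.table["mean_deviation"] == 0).all()
        assert (series.table["mean_k"] == 3.0).all()

    def test_sort_determinism_under_input_reversal(self):
        vt = self._variant(80)
        fwd = bin_means(vt, sort_key="d0")
        rev_rows = vt.rows.iloc[::-1]
        rev = bin_means(type(vt)(vt.variant, rev_rows, vt.provenance), sort_key="d0")
        np.testing.assert_allclose(
            fwd.table["mean_k"].to_numpy(), rev.table["mean_k"].to_numpy()
        )

    def test_bins_are_contiguous_in_sorted_order(self):
        series = bin_means(self._variant(100), sort_key="d0")
        assert series.table["mean_d0"].is_monotonic_increasing

    def test_mean_of_bin_means_equals_grand_mean(self):
        vt = self._variant(200)
        series = bin_means(vt, sort_key="d0", bin_size=20)
        assert series.table["mean_k"].mean() == pytest.approx(vt.rows["k"].mean())

    def test_fewer_than_bin_size_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="fewer than"):
            series = bin_means(self._variant(12), bin_size=20)
        assert series.table.empty and series.n_dropped_remainder == 12


class TestThresholdSlice:
    def test_noiseless_limit_recovers_murray(self):
        records, _ = simulate_dataset(
            SyntheticTruth(
                n_bifurcations=300,
                sigma_plateau=0.0,
                sigma_slope=0.0,
                asym_frac=0.0,
                seed=5,
            )
        )
        v1 = make_variant(solve_table(records), "V1")
        out = summarize_threshold_slice(v1, d0_min=100.0, seed=0)
        assert out["mean_k"] == pytest.approx(3.0, abs=1e-9)
        assert out["ci_low"] == pytest.approx(3.0, abs=1e-9)

    def test_top_n_slice(self, benchmark_v1):
        out = summarize_threshold_slice(benchmark_v1, top_n=100, seed=0)
        assert out["n"] == 100
        assert out["ci_low"] < out["mean_k"] < out["ci_high"]
        # the slice really is the 100 largest parents
        cutoff = benchmark_v1.rows["d0"].nlargest(100).min()
        assert out["d0_range"][0] == pytest.approx(cutoff)

    def test_bootstrap_is_seeded(self, benchmark_v1):
        a = summarize_threshold_slice(benchmark_v1, d0_min=100, seed=11)
        b = summarize_threshold_slice(benchmark_v1, d0_min=100, seed=11)
        assert (a["ci_low"], a["ci_high"]) == (b["ci_low"], b["ci_high"])

    def test_empty_slice_names_threshold(self, benchmark_v1):
        with pytest.raises(ValueError, match="5000"):
            summarize_threshold_slice(benchmark_v1, d0_min=5000.0)

    def test_exactly_one_slice_spec(self, benchmark_v1):
        with pytest.raises(ValueError, match="exactly one"):
            summarize_threshold_slice(benchmark_v1, d0_min=100, top_n=10)
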