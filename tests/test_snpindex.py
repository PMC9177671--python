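"""SNP-index arithmetic, the site filters, causal flagging and windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bulkscan.snpindex import (
    apply_site_filters,
    classify_zygosity,
    compute_indices,
    delta_snp_index,
    flag_causal,
    sliding_window_means,
    snp_index,
)


def site_table(rows):
    """rows: (pos, high_ref, high_alt, low_ref, low_alt) on one chromosome."""
    return pd.DataFrame(
        [("c1", p, "A", "G", hr, ha, lr, la) for p, hr, ha, lr, la in rows],
        columns=["chrom", "pos", "ref", "alt",
                 "high_ref", "high_alt", "low_ref", "low_alt"],
    )


class TestIndexArithmetic:
    @pytest.mark.parametrize(
        "alt,depth,expected", [(0, 12, 0.0), (12, 12, 1.0), (3, 12, 0.25)]
    )
    def test_index_values(self, alt, depth, expected):
        assert snp_index(alt, depth) == expected

    def test_depth_zero_is_nan(self):
        assert np.isnan(snp_index(0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            snp_index(5, 3)

    @pytest.mark.parametrize(
        "hi,lo,expected", [(0.0, 1.0, -1.0), (1.0, 0.0, 1.0), (0.4, 0.4, 0.0)]
    )
    def test_delta_values(self, hi, lo, expected):
        assert delta_snp_index(hi, lo) == expected

    @given(
        st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
    )
    @settings(max_examples=50, deadline=None)
    def test_delta_antisymmetric_and_bounded(self, a, b):
        d = delta_snp_index(a, b)
        assert -1.0 <= d <= 1.0
        assert d == -delta_snp_index(b, a)

    def test_zygosity_thresholds(self):
        calls = classify_zygosity(np.array([0.0, 0.1, 0.11, 0.5, 0.89, 0.9, 1.0]))
        assert list(calls) == [
            "hom_ref", "hom_ref", "het", "het", "het", "hom_alt", "hom_alt"
        ]


# Six constructed sites and the hand enumeration of which filters hit them.
SIX_SITES = [
    # pos, high(ref,alt), low(ref,alt)          expected flags
    (10, 15, 0, 0, 15),   # depths 15/15, idx 0 & 1 -> PASS, causal-eligible
    (20, 6, 0, 0, 6),     # depth 6 in both bulks -> LOW_DEPTH
    (30, 16, 4, 15, 5),   # idx .2/.25 at depth 20 -> LOW_INDEX (both < .3) + not hom
    (40, 3, 3, 10, 5),    # depth 6 high only -> LOW_DEPTH (strict rule) + het
    (50, 10, 10, 0, 20),  # idx .5/1. -> NOT_HOMOZYGOUS only
    (60, 20, 0, 20, 0),   # idx 0/0 -> LOW_INDEX (both) though hom -> removed
]
EXPECTED_FLAGS = {
    10: set(),
    20: {"LOW_DEPTH"},
    30: {"LOW_INDEX", "NOT_HOMOZYGOUS"},
    40: {"LOW_DEPTH", "NOT_HOMOZYGOUS"},
    50: {"NOT_HOMOZYGOUS"},
    60: {"LOW_INDEX"},
}


class TestSiteFilters:
    def test_six_site_hand_enumeration(self):
        df = apply_site_filters(site_table(SIX_SITES))
        for row in df.itertuples(index=False):
            flags = set() if row.filters == "PASS" else set(row.filters.split(";"))
            assert flags == EXPECTED_FLAGS[row.pos], f"pos {row.pos}"
        assert list(df.loc[df["pass_filters"], "pos"]) == [10]

    def test_literal_depth_rule_keeps_one_sided_thin_sites(self):
        df = apply_site_filters(site_table(SIX_SITES), depth_rule="both")
        flagged = set(df.loc[df["flag_low_depth"], "pos"])
        assert flagged == {20}  # pos 40 (thin in one bulk) survives the literal rule

    def test_literal_index_rule_would_remove_causal_sites(self):
        df = apply_site_filters(site_table(SIX_SITES), index_rule="either")
        assert bool(df.loc[df["pos"] == 10, "flag_low_index"].iloc[0])

    def test_filtering_never_mutates_or_drops(self):
        raw = site_table(SIX_SITES)
        df = apply_site_filters(raw)
        assert len(df) == len(raw)
        pd.testing.assert_frame_equal(df[raw.columns], raw)

    def test_flags_independent_of_order(self):
        # flags computed on the full table equal flags computed on any
        # permutation, i.e. filtering is order-invariant
        raw = site_table(SIX_SITES)
        shuffled = raw.sample(frac=1.0, random_state=3)
        a = apply_site_filters(raw).set_index("pos")["filters"]
        b = apply_site_filters(shuffled).set_index("pos")["filters"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestCausalFlag:
    def test_delta_minus_one_flagged(self):
        df = flag_causal(site_table(SIX_SITES))
        assert list(df.loc[df["causal"], "pos"]) == [10]

    def test_delta_zero_not_flagged(self):
        df = flag_causal(site_table([(10, 15, 0, 15, 0)]))
        assert not df["causal"].any()

    def test_plus_one_only_under_abs_criterion(self):
        df = site_table([(10, 0, 15, 15, 0)])  # delta = +1
        assert not flag_causal(df)["causal"].any()
        assert flag_causal(df, criterion="abs")["causal"].all()

    def test_causal_count_matches_brute_force_rescan(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            hd, ld = rng.integers(5, 20, size=2)
            ha = rng.choice([0, hd, rng.integers(0, hd + 1)])
            la = rng.choice([0, ld, rng.integers(0, ld + 1)])
            rows.append((10 * (i + 1), hd - ha, ha, ld - la, la))
        df = flag_causal(site_table(rows))
        brute = (
            (df["index_high"] == 0.0)
            & (df["index_low"] == 1.0)
            & df["pass_filters"]
        )
        assert df["causal"].equals(brute)


class TestSlidingWindows:
    def test_single_snp_window_mean_is_that_value(self):
        df = site_table([(500, 10, 0, 0, 10)])
        win = sliding_window_means(df, window_size=1000, step=1000, restrict_to=None)
        row = win.iloc[0]
        assert row["n_snps"] == 1 and row["mean_delta"] == -1.0

    def test_two_snp_window_arithmetic_mean(self):
        df = site_table([(100, 10, 0, 0, 10), (200, 10, 0, 10, 0)])  # deltas -1, 0
        win = sliding_window_means(df, window_size=1000, step=1000, restrict_to=None)
        assert win.iloc[0]["mean_delta"] == pytest.approx(-0.5)

    def test_window_means_match_brute_force(self):
        rng = np.random.default_rng(5)
        pos = rng.integers(1, 300_000, size=200)
        hd = rng.integers(1, 30, size=200)
        ld = rng.integers(1, 30, size=200)
        ha = rng.integers(0, hd + 1)
        la = rng.integers(0, ld + 1)
        df = pd.DataFrame(
            {
                "chrom": "c1", "pos": pos, "ref": "A", "alt": "G",
                "high_ref": hd - ha, "high_alt": ha,
                "low_ref": ld - la, "low_alt": la,
            }
        ).sort_values("pos", kind="stable").reset_index(drop=True)
        window, step = 50_000, 7_000
        win = sliding_window_means(df, window_size=window, step=step, restrict_to=None)
        full = compute_indices(df)
        # naive O(n*w) double loop oracle
        for row in win.itertuples(index=False):
            start0 = row.start - 1
            member = full[(full["pos"] - 1 >= start0) & (full["pos"] - 1 < start0 + window)]
            assert row.n_snps == len(member)
            if len(member):
                assert row.mean_delta == pytest.approx(member["delta"].mean())
                assert row.mean_index_high == pytest.approx(member["index_high"].mean())
                assert row.median_depth_low == pytest.approx(member["low_depth"].median())
            else:
                assert np.isnan(row.mean_delta)

    def test_swapping_bulks_negates_delta_everywhere(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=80, replace=False))
        hd = rng.integers(7, 30, size=80)
        ld = rng.integers(7, 30, size=80)
        ha = rng.integers(0, hd + 1)
        la = rng.integers(0, ld + 1)
        df = pd.DataFrame(
            {"chrom": "c1", "pos": pos, "ref": "A", "alt": "G",
             "high_ref": hd - ha, "high_alt": ha, "low_ref": ld - la, "low_alt": la}
        )
        swapped = df.rename(
            columns={"high_ref": "low_ref", "high_alt": "low_alt",
                     "low_ref": "high_ref", "low_alt": "high_alt"}
        )
        a = compute_indices(df)
        b = compute_indices(swapped)
        np.testing.assert_allclose(a["delta"], -b["delta"])
        wa = sliding_window_means(a, 10_000, 2_000, restrict_to=None)
        wb = sliding_window_means(b, 10_000, 2_000, restrict_to=None)
        np.testing.assert_allclose(wa["mean_delta"], -wb["mean_delta"])

    def test_window_must_cover_step(self):
        with pytest.raises(ValueError):
            sliding_window_means(site_table([(10, 5, 0, 0, 5)]), 100, 200)
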