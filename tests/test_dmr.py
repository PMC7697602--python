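from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from bnaepi.dmr import (
    Bin,
    bh_adjust,
    call_dmrs,
    call_dmrs_from_reports,
    kruskal_wallis_bin_test,
    load_reference_dmrs,
    make_bins,
    site_differentials,
    site_fold_change,
    validate_reference_dmrs,
)


def kw_oracle(a, b):
    """Independent tie-corrected Kruskal-Wallis: explicit ranks + chi2."""
    values = np.concatenate([a, b])
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    # ranks array is aligned with `values`; split back into groups
    ra, rb = ranks[: len(a)], ranks[len(a):]
    h = 12.0 / (n * (n + 1)) * (ra.sum() ** 2 / len(a)
                                + rb.sum() ** 2 / len(b)) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if correction == 0:
        return 1.0
    return float(stats.chi2.sf(h / correction, df=1))


class TestSiteFoldChange:
    @pytest.mark.parametrize(
        "ml72,ml0,diff,direction",
        [
            (0.34, 0.10, True, "hyper"),   # Gln1;1 intron example
            (0.12, 0.43, True, "hypo"),    # NRT1.6 promoter example
            (0.30, 0.30, False, "none"),
        ],
    )
    def test_examples(self, ml72, ml0, diff, direction):
        fc, is_diff, d = site_fold_change(ml72, ml0)
        assert is_diff == diff
        assert d == direction
        if not diff:
            assert fc == pytest.approx(1.0)

    def test_two_sided_symmetry(self):
        fc_up, d_up, _ = site_fold_change(0.5, 0.1)
        fc_dn, d_dn, _ = site_fold_change(0.1, 0.5)
        assert fc_up == pytest.approx(1.0 / fc_dn)
        assert d_up and d_dn

    def test_pseudocount_handles_zero(self):
        fc, is_diff, d = site_fold_change(0.3, 0.0)
        assert np.isfinite(fc) and is_diff and d == "hyper"


class TestBins:
    def _diffs(self, positions, context="CG", chrom="A01"):
        n = len(positions)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "pos": positions,
                "strand": ["+"] * n,
                "context": [context] * n,
                "ml_0h": np.linspace(0.1, 0.9, n),
                "ml_72h": np.linspace(0.1, 0.9, n),
                "fold_change": np.ones(n),
                "is_differential": [False] * n,
                "direction": ["none"] * n,
            }
        )

    def test_fixed_tiling(self):
        d = self._diffs(list(range(1, 1001)))
        bins = make_bins(d, bin_size=100, min_sites=5)
        assert len(bins) == 10
        assert bins[0].start == 1 and bins[0].end == 100
        assert bins[-1].start == 901 and bins[-1].end == 1000

    def test_min_sites_filter(self):
        d = self._diffs([1, 2, 150, 151, 152, 153, 154])
        bins = make_bins(d, bin_size=100, min_sites=5)
        assert len(bins) == 1
        assert bins[0].start == 101

    def test_partition_of_sites(self):
        """Retained + discarded bins cover every covered site exactly once."""
        d = self._diffs(sorted(np.random.default_rng(0).choice(
            np.arange(1, 2000), size=300, replace=False)))
        all_bins = make_bins(d, bin_size=100, min_sites=1)
        assert sum(b.n_sites for b in all_bins) == len(d)
        seen = np.concatenate([b.positions for b in all_bins])
        assert sorted(seen) == sorted(d["pos"])


class TestKruskalWallis:
    def test_identical_groups(self):
        assert kruskal_wallis_bin_test(
            [0.1, 0.2, 0.3], [0.1, 0.2, 0.3]
        ) == pytest.approx(1.0, abs=1e-12)

    def test_no_variance(self):
        assert kruskal_wallis_bin_test([0.5] * 4, [0.5] * 4) == 1.0

    def test_separated_groups_match_oracle(self):
        a, b = [0.1, 0.2, 0.3, 0.4], [0.6, 0.7, 0.8, 0.9]
        assert kruskal_wallis_bin_test(a, b) == pytest.approx(
            kw_oracle(a, b), abs=1e-12
        )

    def test_observed_labeling_extreme_among_all_70(self):
        """Fully separated groups maximize H over every 8C4 labeling."""
        values = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9])

        def h_stat(idx_a):
            a = values[list(idx_a)]
            b = values[[i for i in range(8) if i not in idx_a]]
            return kw_oracle(a, b)  # smaller p <=> larger H

        p_obs = h_stat((0, 1, 2, 3))
        all_p = [h_stat(c) for c in combinations(range(8), 4)]
        assert len(all_p) == 70
        assert p_obs == min(all_p)

    def test_mann_whitney_equivalence(self):
        """For two groups KW equals the tie-corrected two-sided MW test."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = np.round(rng.random(rng.integers(3, 9)), 2)
            b = np.round(rng.random(rng.integers(3, 9)), 2)
            if np.all(a == a[0]) and np.all(b == a[0]):
                continue
            p_kw = kruskal_wallis_bin_test(a, b)
            p_mw = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert p_kw == pytest.approx(p_mw, abs=1e-9)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.choice([0.0, 0.1, 0.2, 0.5], size=rng.integers(3, 7))
            b = rng.choice([0.0, 0.1, 0.2, 0.5], size=rng.integers(3, 7))
            if len(set(a) | set(b)) == 1:
                continue
            assert kruskal_wallis_bin_test(a, b) == pytest.approx(
                kw_oracle(a, b), abs=1e-9
            )


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # q_(i) = min_{j>=i}(p_(j) * m / j): all become 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_step_up_mixed(self):
        # m=4: raw steps (0.04, 0.10, 0.08, 0.05) -> step-up mins
        assert bh_adjust([0.01, 0.05, 0.04, 0.05]) == pytest.approx(
            [0.04, 0.05, 0.05, 0.05]
        )

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_monotone_in_p_order(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) > -1e-12).all()
        assert ((q >= np.asarray(pvals) - 1e-12) & (q <= 1.0)).all()


class TestCallDmrs:
    def _bin(self, ml0, ml72, context="CG", start_pos=1):
        ml0, ml72 = np.asarray(ml0, float), np.asarray(ml72, float)
        fc = (ml72 + 0.01) / (ml0 + 0.01)
        is_diff = (fc > 1.2) | (fc < 1 / 1.2)
        direction = np.where(~is_diff, "none",
                             np.where(ml72 > ml0, "hyper", "hypo"))
        return Bin(
            chrom="A01", start=1, end=100, context=context,
            positions=np.arange(start_pos, start_pos + len(ml0)),
            ml_0h=ml0, ml_72h=ml72,
            is_differential=is_diff, direction=direction,
        )

    def test_constant_data_yields_nothing(self):
        bins = [self._bin([0.5] * 8, [0.5] * 8)]
        assert call_dmrs(bins).empty

    def test_clear_shift_called_with_trimmed_bounds(self):
        ml0 = np.linspace(0.10, 0.14, 8)
        ml72 = np.linspace(0.60, 0.64, 8)
        out = call_dmrs([self._bin(ml0, ml72, start_pos=11)])
        assert len(out) == 1
        row = out.iloc[0]
        assert row["direction"] == "hyper"
        assert (row["start"], row["end"]) == (11, 18)
        assert row["length"] == row["end"] - row["start"] + 1
        assert row["q"] < 0.05 and row["q"] >= row["p"]

    def test_label_swap_symmetry(self, demo_reports):
        """Swapping conditions flips hyper<->hypo with identical p."""
        fwd = call_dmrs_from_reports(*demo_reports)
        rev = call_dmrs_from_reports(demo_reports[1], demo_reports[0])
        assert len(fwd) == len(rev)
        key = ["chrom", "start", "end", "context"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd)
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert (merged["direction_f"].map(flip) == merged["direction_r"]).all()
        assert np.allclose(merged["p_f"], merged["p_r"])

    def test_planted_dmrs_recovered(self, demo_config, demo_reports):
        dmrs = call_dmrs_from_reports(*demo_reports)
        assert (dmrs["q"] < 0.05).all()
        for planted, expected_dir in zip(demo_config.dmr_plan,
                                         ("hyper", "hypo")):
            hit = dmrs[
                (dmrs["chrom"] == planted.chrom)
                & (dmrs["context"] == planted.context)
                & (dmrs["end"] >= planted.start)
                & (dmrs["start"] <= planted.end)
            ]
            assert not hit.empty
            assert (hit["direction"] == expected_dir).all()

    def test_direction_consistent_with_means(self, demo_reports):
        dmrs = call_dmrs_from_reports(*demo_reports)
        expect = np.where(dmrs["ml_0h"] < dmrs["ml_72h"], "hyper", "hypo")
        assert (dmrs["direction"] == expect).all()


class TestReferenceTable:
    def test_lengths_follow_inclusive_convention(self):
        t = validate_reference_dmrs()
        assert t["length_ok"].all()
        row = t[t["start"] == 18318906].iloc[0]
        assert row["end"] - row["start"] + 1 == 72

    def test_direction_rule_flags_single_inconsistency(self):
        t = validate_reference_dmrs()
        bad = t[~t["direction_consistent"]]
        assert len(bad) == 1
        assert bad.iloc[0]["start"] == 57013740
        assert bad.iloc[0]["chrom"] == "chrCnn"

    def test_table_shape(self):
        t = load_reference_dmrs()
        assert len(t) == 16
        assert set(t["context"]) <= {"CG", "CHG", "CHH"}
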