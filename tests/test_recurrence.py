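"""Cohort recurrence: density, cytobands, known/novel, MAR, overlap test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snpkaryo as sk
from snpkaryo.recurrence import CytobandMap


def lesion_table(rows):
    """rows: (sample_id, chrom, start, end) or + (category, cn)."""
    out = []
    for r in rows:
        sid, chrom, start, end = r[:4]
        category = r[4] if len(r) > 4 else "AMP_NO_LOH"
        cn = r[5] if len(r) > 5 else 4.0
        out.append(
            {"sample_id": sid, "chrom": chrom, "start": start, "end": end,
             "category": category, "cn_estimate": cn}
        )
    return pd.DataFrame(out)


def brute_force_coverage(lesions: pd.DataFrame, chrom: str, lo: int, hi: int):
    """Per-base distinct-sample counts by explicit counting (oracle)."""
    counts = np.zeros(hi - lo, dtype=int)
    for sid, sub in lesions[lesions.chrom == chrom].groupby("sample_id"):
        covered = np.zeros(hi - lo, dtype=bool)
        for _, row in sub.iterrows():
            a, b = max(int(row.start), lo), min(int(row.end), hi)
            if b > a:
                covered[a - lo:b - lo] = True
        counts += covered
    return counts


class TestChromosomeDensity:
    def test_proportional_counts_give_p_one(self):
        rows = [(f"S{i}", "1", i * 1000, i * 1000 + 100) for i in range(10)]
        rows += [(f"S{i}", "2", i * 1000, i * 1000 + 100) for i in range(5)]
        table, chi2 = sk.chromosome_density(
            lesion_table(rows), {"1": 100_000_000, "2": 50_000_000}
        )
        assert np.allclose(table["density"], 0.1)
        assert chi2["pvalue"] == pytest.approx(1.0)

    def test_all_on_one_chromosome_is_significant(self):
        rows = [(f"S{i}", "1", i * 1000 + 1, i * 1000 + 100) for i in range(20)]
        _table, chi2 = sk.chromosome_density(
            lesion_table(rows), {"1": 50_000_000, "2": 50_000_000}
        )
        assert chi2["statistic"] == pytest.approx(20.0)
        assert chi2["df"] == 1
        assert chi2["pvalue"] == pytest.approx(stats.chi2.sf(20, 1), rel=1e-9)
        assert chi2["pvalue"] < 0.001

    def test_single_chromosome_not_applicable(self):
        table, chi2 = sk.chromosome_density(
            lesion_table([("S1", "1", 100, 200)]), {"1": 1_000_000}
        )
        assert chi2["applicable"] is False and chi2["pvalue"] is None
        assert len(table) == 1

    def test_missing_size_is_coordinate_error(self):
        with pytest.raises(sk.CoordinateError):
            sk.chromosome_density(lesion_table([("S1", "9", 100, 200)]), {"1": 10})

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"S{i}", str(rng.integers(1, 4)), 1000 * i + 1, 1000 * i + 500)
            for i in range(30)
        ]
        table, _ = sk.chromosome_density(
            lesion_table(rows), {"1": 10_000_000, "2": 10_000_000, "3": 10_000_000}
        )
        assert table["count"].sum() == 30


@pytest.fixture
def bands() -> CytobandMap:
    return CytobandMap(pd.DataFrame(
        {
            "chrom": ["20", "20", "20"],
            "start": [1, 3_000_001, 6_000_001],
            "end": [3_000_001, 6_000_001, 10_000_001],
            "band": ["p13", "p12", "p11"],
            "stain": "gneg",
        }
    ))


class TestCytobands:
    def test_lesion_inside_one_band(self, bands):
        assert sk.map_to_cytobands("20", 1_000_000, 2_000_000, bands) == ["20p13"]

    def test_lesion_spanning_boundary(self, bands):
        got = sk.map_to_cytobands("20", 2_500_000, 3_500_000, bands)
        assert got == ["20p13", "20p12"]

    def test_one_bp_overlap_counts(self, bands):
        assert sk.map_to_cytobands("20", 3_000_000, 3_000_001, bands) == ["20p13"]

    def test_zero_length_query_rejected(self, bands):
        with pytest.raises(ValueError):
            sk.map_to_cytobands("20", 100, 100, bands)

    def test_unknown_chromosome(self, bands):
        with pytest.raises(sk.CoordinateError):
            sk.map_to_cytobands("21", 1, 2, bands)

    def test_every_lesion_maps_when_map_tiles(self, bands):
        rng = np.random.default_rng(5)
        for _ in range(50):
            start = int(rng.integers(1, 9_999_999))
            end = int(rng.integers(start + 1, 10_000_001))
            assert len(sk.map_to_cytobands("20", start, end, bands)) >= 1


class TestAnnotateKnown:
    def _db(self):
        return pd.DataFrame({"chrom": ["1"], "start": [1000], "end": [2000]})

    def test_contained_lesion_is_known(self):
        lesions = lesion_table([("S1", "1", 1200, 1400)])
        out, summary = sk.annotate_known(lesions, self._db())
        assert out["known"].tolist() == [True]
        assert summary["pct_known"] == 100

    def test_disjoint_lesion_is_novel(self):
        lesions = lesion_table([("S1", "1", 5000, 6000)])
        out, _ = sk.annotate_known(lesions, self._db())
        assert out["known"].tolist() == [False]

    def test_half_coverage_threshold(self):
        lesions = lesion_table([("S1", "1", 1500, 2500)])  # 50% covered
        out, _ = sk.annotate_known(lesions, self._db(), min_overlap_fraction=0.5)
        assert out["known"].tolist() == [True]
        out, _ = sk.annotate_known(lesions, self._db(), min_overlap_fraction=0.6)
        assert out["known"].tolist() == [False]

    def test_empty_db_all_novel_with_warning(self):
        lesions = lesion_table([("S1", "1", 1200, 1400)])
        with pytest.warns(UserWarning, match="empty"):
            out, summary = sk.annotate_known(lesions, pd.DataFrame())
        assert summary["n_novel"] == 1

    def test_percentages_match_reported_arithmetic(self):
        # 1,773 of 2,765 covered -> 64% known / 36% novel after rounding
        rows = []
        for i in range(2765):
            if i < 1773:
                rows.append((f"S{i}", "1", 1000, 2000))
            else:
                rows.append((f"S{i}", "1", 500_000 + i * 10, 500_005 + i * 10))
        out, summary = sk.annotate_known(lesion_table(rows), self._db())
        assert summary["n_known"] == 1773 and summary["n_novel"] == 992
        assert summary["pct_known"] == 64 and summary["pct_novel"] == 36
        assert summary["pct_known_exact"] + summary["pct_novel_exact"] == pytest.approx(100.0)


class TestRecurrenceProfile:
    def test_identical_lesion_in_all_samples(self, bands):
        rows = [(f"S{i:02d}", "20", 1_000_000, 1_500_000) for i in range(10)]
        prof = sk.recurrence_profile(lesion_table(rows), 10, unit="cytoband",
                                     cytobands=bands)
        assert prof.counts["n_samples"].tolist() == [10]
        assert prof.histogram[10] == 1

    def test_private_lesions_mass_at_one(self, bands):
        rows = [(f"S{i}", "20", 1 + i * 600_000, 500_000 + i * 600_000)
                for i in range(5)]
        prof = sk.recurrence_profile(lesion_table(rows), 5, unit="interval")
        assert set(prof.counts["n_samples"]) == {1}
        assert prof.histogram[1] == len(prof.counts)

    def test_interval_unit_matches_per_base_brute_force(self):
        rows = [("S1", "1", 100, 200), ("S2", "1", 150, 300), ("S3", "1", 250, 400)]
        lesions = lesion_table(rows)
        prof = sk.recurrence_profile(lesions, 3, unit="interval")
        oracle = brute_force_coverage(lesions, "1", 0, 500)
        for _, row in prof.counts.iterrows():
            span = oracle[int(row.start):int(row.end)]
            assert np.all(span == row.n_samples)
        # expected constant-count runs: 2 on [150,200) and [250,300)
        two = prof.counts[prof.counts.n_samples == 2]
        assert [(r.start, r.end) for r in two.itertuples()] == [(150, 200), (250, 300)]

    def test_sample_label_permutation_invariant(self, bands):
        rows = [("S1", "20", 100, 900), ("S2", "20", 500, 1200), ("S3", "20", 100, 300)]
        lesions = lesion_table(rows)
        permuted = lesions.copy()
        permuted["sample_id"] = permuted["sample_id"].map(
            {"S1": "S3", "S2": "S1", "S3": "S2"}
        )
        a = sk.recurrence_profile(lesions, 3, unit="interval")
        b = sk.recurrence_profile(permuted, 3, unit="interval")
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.histogram == b.histogram


class TestDefineMar:
    def test_printed_endpoints_give_9911_bp(self):
        rows = [(f"S{i:02d}", "20", 1_572_019, 1_581_930) for i in range(11)]
        mar, _ = sk.define_mar(lesion_table(rows), 20)
        assert (mar.start, mar.end) == (1_572_019, 1_581_930)
        assert mar.length == 9911
        assert mar.n_affected == 11
        assert mar.frequency == pytest.approx(0.55)

    def test_three_overlapping_intervals(self):
        rows = [("S1", "1", 1, 100), ("S2", "1", 50, 150), ("S3", "1", 80, 200)]
        mar, _ = sk.define_mar(lesion_table(rows), 3)
        assert (mar.start, mar.end) == (80, 100)
        assert mar.n_affected == 3

    def test_single_sample_cohort(self):
        mar, _ = sk.define_mar(lesion_table([("S1", "1", 100, 500)]), 1)
        assert (mar.start, mar.end) == (100, 500)
        assert mar.frequency == 1.0

    def test_no_majority_returns_none(self):
        rows = [("S1", "1", 100, 200), ("S2", "1", 300, 400)]
        mar, candidates = sk.define_mar(lesion_table(rows), 5)
        assert mar is None and candidates == []

    def test_tie_break_shortest_then_leftmost(self):
        rows = [
            ("S1", "1", 100, 200), ("S2", "1", 100, 200),
            ("S1", "1", 300, 350), ("S2", "1", 300, 350),
        ]
        mar, candidates = sk.define_mar(lesion_table(rows), 2)
        assert (mar.start, mar.end) == (300, 350)  # shorter of the two count-2 runs
        assert len(candidates) == 2

    def test_mean_cn_over_affected_samples(self):
        rows = [("S1", "1", 100, 200, "AMP_NO_LOH", 4.2),
                ("S2", "1", 100, 200, "AMP_NO_LOH", 3.8)]
        mar, _ = sk.define_mar(lesion_table(rows), 2)
        assert mar.mean_cn == pytest.approx(4.0)
        assert mar.dominant_category == "AMP_NO_LOH"

    @pytest.mark.parametrize("seed", range(20))
    def test_sweep_line_matches_per_base_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_samples = int(rng.integers(2, 11))
        rows = []
        for i in range(n_samples):
            for _ in range(int(rng.integers(1, 5))):
                start = int(rng.integers(0, 9_000))
                end = int(rng.integers(start + 1, 10_001))
                rows.append((f"S{i:02d}", "1", start, end))
        lesions = lesion_table(rows)
        mar, _ = sk.define_mar(lesions, n_samples)
        oracle = brute_force_coverage(lesions, "1", 0, 10_001)
        cmax = oracle.max()
        if cmax <= n_samples * 0.5:
            assert mar is None
            return
        assert mar.n_affected == cmax
        # the reported interval is a maximal run at the max count
        assert np.all(oracle[mar.start:mar.end] == cmax)
        if mar.start > 0:
            assert oracle[mar.start - 1] != cmax
        if mar.end < 10_001:
            assert oracle[mar.end] != cmax
        # and no shorter maximal run at the same count exists
        runs = []
        in_run = False
        for pos in range(10_001):
            if oracle[pos] == cmax and not in_run:
                in_run, run_start = True, pos
            elif oracle[pos] != cmax and in_run:
                in_run = False
                runs.append((run_start, pos))
        if in_run:
            runs.append((run_start, 10_001))
        assert mar.length == min(b - a for a, b in runs)


class TestOverlapSignificance:
    def test_reported_percentage_arithmetic(self):
        a = {f"A{i}" for i in range(744)}
        b = set(list(a)[:327]) | {f"B{i}" for i in range(419 - 327)}
        res = sk.overlap_significance(a, b, universe_size=862)
        assert res.n_overlap == 327
        assert res.percent_of_a == pytest.approx(100 * 327 / 744)
        assert res.percent_rounded == 44

    def test_disjoint_sets(self):
        res = sk.overlap_significance({"a", "b"}, {"c", "d"}, 100)
        assert res.percent_of_a == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_full_universe(self):
        a = {f"x{i}" for i in range(20)}
        res = sk.overlap_significance(a, a, 20)
        assert res.percent_rounded == 100
        assert res.pvalue == pytest.approx(1.0)

    def test_pvalue_matches_enumeration_oracle(self):
        # |A| = 5, |B| = 5, universe 20, overlap 3: exhaustive hypergeometric mass
        a = {f"a{i}" for i in range(5)}
        b = {"a0", "a1", "a2", "x0", "x1"}
        res = sk.overlap_significance(a, b, 20)
        expected = sum(
            math.comb(5, j) * math.comb(15, 5 - j) for j in range(3, 6)
        ) / math.comb(20, 5)
        assert res.pvalue == pytest.approx(expected, rel=1e-12)

    def test_invalid_universe(self):
        with pytest.raises(sk.InvalidUniverseError):
            sk.overlap_significance({"a", "b"}, {"c"}, 2)
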