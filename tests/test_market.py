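"""Market shares, ODD segmentation, timelines, tiers, top-asset correlation."""

import math

import numpy as np
import pandas as pd
import pytest

import rdlandscape as rd
from rdlandscape.market import TIER_CHALLENGER, TIER_LEADER, TIER_UPCOMING
from tests.conftest import rec


def frame(rows):
    return pd.DataFrame(rows, columns=["drug_name", "company", "indication", "revenue"])


class TestShares:
    def test_simple_partition(self):
        t = rd.market_shares(frame([("d1", "A", "x", 50.0), ("d2", "B", "x", 30.0),
                                    ("d3", "C", "y", 20.0)]))
        assert dict(zip(t.shares["company"], t.shares["share_percent"])) == {
            "A": 50.0, "B": 30.0, "C": 20.0}
        assert t.grand_total == 100.0

    def test_single_company_is_100(self):
        t = rd.market_shares(frame([("d", "A", "x", 7.0)]))
        assert list(t.shares["share_percent"]) == [100.0]

    def test_disease_shares_hand_computed(self):
        t = rd.market_shares(
            frame([("d1", "A", "cf", 60.0), ("d2", "B", "cf", 20.0),
                   ("d3", "A", "mm", 15.0), ("d4", "C", "mm", 5.0)]),
            key="disease",
        )
        by = dict(zip(t.shares["disease"], t.shares["share_percent"]))
        assert by["cf"] == pytest.approx(80.0) and by["mm"] == pytest.approx(20.0)

    def test_organ_system_atomic_labels_and_unmapped_bucket(self):
        t = rd.market_shares(
            frame([("d1", "A", "cf", 40.0), ("d2", "B", "mm", 40.0),
                   ("d3", "C", "mystery", 20.0)]),
            key="organ_system",
            organ_map={"cf": "liver/heart/lung", "mm": "blood/bone"},
        )
        by = dict(zip(t.shares["organ_system"], t.shares["share_percent"]))
        assert by == {"liver/heart/lung": 40.0, "blood/bone": 40.0, "unmapped": 20.0}

    def test_shares_sum_to_100_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            rows = [(f"d{i}", f"C{int(rng.integers(0, 8))}", "x",
                     float(rng.lognormal(3, 2))) for i in range(n)]
            t = rd.market_shares(frame(rows))
            assert t.shares["share_percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_scale_invariance(self):
        rows = [("d1", "A", "x", 123.0), ("d2", "B", "y", 45.0), ("d3", "C", "y", 6.0)]
        base = rd.market_shares(frame(rows))
        scaled = rd.market_shares(
            frame([(d, c, i, r * 1e3) for d, c, i, r in rows]))
        assert np.allclose(base.shares["share_percent"], scaled.shares["share_percent"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rd.market_shares(frame([]))

    def test_ground_truth_share_recovery(self):
        cfg = rd.EcosystemConfig(n_companies=12, mean_assets_per_company=6,
                                 approved_fraction=0.8, seed=14)
        records, _, truth = rd.generate_ecosystem(cfg)
        t = rd.market_shares(rd.revenue_table_from_records(records))
        grand = sum(truth.revenue_by_company.values())
        for company, share in zip(t.shares["company"], t.shares["share_percent"]):
            assert share == pytest.approx(100 * truth.revenue_by_company[company] / grand)


class TestSegmentation:
    def test_printed_headline_split(self):
        records = (
            [rec(f"o{i}", "A", "x", "m", phase="approved", odd=True, year=2010)
             for i in range(140)]
            + [rec(f"n{i}", "B", "y", "m", phase="approved", odd=False, year=2010)
               for i in range(260)]
        )
        seg = rd.odd_segmentation(records)
        assert seg["n_approved"] == 400
        assert seg["odd_percent"] == 35.0 and seg["non_odd_percent"] == 65.0

    def test_all_odd(self):
        seg = rd.odd_segmentation(
            [rec("d", "A", "x", "m", phase="approved", odd=True, year=2000)])
        assert seg["odd_percent"] == 100.0 and seg["non_odd_percent"] == 0.0

    def test_shared_indications(self):
        records = [
            rec("d1", "A", "mm", "m", phase="approved", odd=True, year=2000),
            rec("d2", "B", "mm", "m", phase="approved", odd=False, year=2001),
            rec("d3", "C", "cf", "m", phase="approved", odd=True, year=2002),
            rec("d4", "D", "cf", "m", phase="approved", odd=False, year=2003),
            rec("d5", "E", "only_odd", "m", phase="approved", odd=True, year=2004),
        ]
        assert rd.odd_segmentation(records)["shared_indications"] == ["cf", "mm"]

    def test_modality_percentages_within_group(self):
        records = [
            rec("d1", "A", "x", "m", phase="approved", odd=True, year=2000,
                modality="targeted therapy"),
            rec("d2", "B", "y", "m", phase="approved", odd=True, year=2000,
                modality="targeted therapy"),
            rec("d3", "C", "z", "m", phase="approved", odd=True, year=2000,
                modality="gene therapy"),
        ]
        seg = rd.odd_segmentation(records)
        assert seg["odd"]["modality_percent"] == {
            "targeted therapy": 66.7, "gene therapy": 33.3}

    def test_conservation(self):
        records, _, _ = rd.generate_ecosystem(
            rd.EcosystemConfig(n_companies=10, mean_assets_per_company=6, seed=3))
        seg = rd.odd_segmentation(records)
        assert seg["n_odd"] + seg["n_non_odd"] == seg["n_approved"]


class TestTimeline:
    def test_split_counts(self):
        records = [
            rec("d1", "A", "x", "m", phase="approved", odd=True, year=2019),
            rec("d2", "B", "y", "m", phase="approved", odd=True, year=2019),
            rec("d3", "C", "z", "m", phase="approved", odd=False, year=2019),
        ]
        tl = rd.approval_timeline(records).set_index("year")
        assert tl.loc[2019, "odd"] == 2 and tl.loc[2019, "non_odd"] == 1

    def test_empty(self):
        assert rd.approval_timeline([]).empty

    def test_unknown_year_bucket_and_conservation(self):
        records = [rec("d1", "A", "x", "m", phase="approved", odd=False, year=1995),
                   rec("d2", "B", "y", "m", phase="approved", odd=True, year=2021),
                   rec("d3", "C", "z", "m", phase="approved", odd=True)]
        tl = rd.approval_timeline(records)
        years = [y for y in tl["year"] if y != "unknown"]
        assert min(years) == 1995 and max(years) == 2021
        assert int(tl["odd"].sum() + tl["non_odd"].sum()) == 3
        assert "unknown" in set(tl["year"])


class TestTopAsset:
    def test_single_asset_fraction_one(self):
        table, r = rd.top_asset_profile(
            frame([("d1", "A", "x", 10.0), ("d2", "B", "x", 5.0),
                   ("d3", "C", "x", 2.0)]))
        assert (table["top_asset_fraction"] == 1.0).all()

    def test_pearson_matches_closed_form(self):
        rows = [("a1", "A", "x", 60.0), ("a2", "A", "x", 40.0),
                ("b1", "B", "x", 40.0), ("b2", "B", "x", 10.0),
                ("c1", "C", "x", 9.0), ("c2", "C", "x", 1.0)]
        table, r = rd.top_asset_profile(frame(rows))
        # closed-form Pearson r on totals (100, 50, 10) vs tops (60, 40, 9)
        x, y = [100.0, 50.0, 10.0], [60.0, 40.0, 9.0]
        n = 3
        num = n * sum(a * b for a, b in zip(x, y)) - sum(x) * sum(y)
        den = math.sqrt((n * sum(a * a for a in x) - sum(x) ** 2)
                        * (n * sum(b * b for b in y) - sum(y) ** 2))
        assert r == pytest.approx(num / den)

    def test_fewer_than_three_companies_no_correlation(self):
        table, r = rd.top_asset_profile(frame([("d1", "A", "x", 10.0),
                                               ("d2", "B", "x", 5.0)]))
        assert r is None and len(table) == 2

    def test_zero_variance_flagged(self):
        table, r = rd.top_asset_profile(
            frame([("d1", "A", "x", 10.0), ("d2", "B", "x", 10.0),
                   ("d3", "C", "x", 10.0)]))
        assert r is None

    def test_scale_invariant_correlation(self):
        rows = [("a1", "A", "x", 60.0), ("b1", "B", "x", 40.0), ("c1", "C", "x", 9.0),
                ("c2", "C", "x", 30.0)]
        _, r1 = rd.top_asset_profile(frame(rows))
        _, r2 = rd.top_asset_profile(frame([(d, c, i, v * 7.5) for d, c, i, v in rows]))
        assert r1 == pytest.approx(r2)


class TestTiers:
    @pytest.mark.parametrize("share,expected", [
        (10.8, TIER_LEADER), (5.5, TIER_UPCOMING), (2.4, TIER_CHALLENGER),
        (6.0, TIER_LEADER), (2.5, TIER_UPCOMING), (0.0, TIER_CHALLENGER),
        (100.0, TIER_LEADER),
    ])
    def test_band_assignment(self, share, expected):
        assert rd.classify_tier(share) == expected

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            rd.classify_tier(bad)

    def test_bands_partition_0_100(self):
        for share in np.linspace(0, 100, 401):
            assert rd.classify_tier(float(share)) in {
                TIER_LEADER, TIER_UPCOMING, TIER_CHALLENGER}
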