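"""Market-share analytics for the approved rare-disease therapeutic space.

Aggregates per-asset revenues (million USD, from annual financial reports)
into percentage market shares by company, disease or organ-system label;
segments EMA approvals into orphan-drug-designated (ODD) vs non-ODD groups
with modality and indication breakdowns and approval timelines; estimates
market leadership via the correlation between a company's total revenue and
its highest-grossing asset; and classifies companies into the printed share
tiers (leaders 6-12%, upcoming majors 2.5-6%, challengers <2.5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import InterventionRecord

__all__ = [
    "MarketShareTable",
    "TIER_LEADER",
    "TIER_UPCOMING",
    "TIER_CHALLENGER",
    "market_shares",
    "revenue_table_from_records",
    "odd_segmentation",
    "approval_timeline",
    "top_asset_profile",
    "classify_tier",
]

TIER_LEADER = "market_leader"
TIER_UPCOMING = "upcoming_major"
TIER_CHALLENGER = "challenger"

#: Printed tier bands; boundaries are inclusive on the lower edge
#: (share >= 6 -> leader, 2.5 <= share < 6 -> upcoming, share < 2.5 ->
#: challenger) since the source intervals carry no open/closed notation.
DEFAULT_TIER_BOUNDS = (2.5, 6.0)


@dataclass
class MarketShareTable:
    """Revenue totals and percentage shares per aggregation key.

    ``shares`` columns: key column (named after ``key_kind``),
    ``total_revenue`` (million USD), ``share_percent``.  Shares are computed
    against ``grand_total`` and sum to 100 within 1e-6; the denominator is
    always reported explicitly.
    """

    key_kind: str
    shares: pd.DataFrame
    grand_total: float


def _validate_revenue_frame(revenues: pd.DataFrame) -> pd.DataFrame:
    required = {"drug_name", "company", "revenue"}
    missing = required - set(revenues.columns)
    if missing:
        raise ValueError(f"revenue table missing columns: {sorted(missing)}")
    if revenues.empty:
        raise ValueError("revenue table is empty")
    if (revenues["revenue"] < 0).any():
        raise ValueError("negative revenue")
    return revenues


def market_shares(
    revenues: pd.DataFrame,
    key: str = "company",
    organ_map: Mapping[str, str] | None = None,
) -> MarketShareTable:
    """Percentage market shares by ``key`` ∈ {company, disease, organ_system}.

    For ``organ_system`` a mapping indication -> organ-system label is
    required; an asset's full revenue is counted once under its full
    combination label (e.g. "liver/heart/lung", treated as atomic), and
    unmapped indications fall into an "unmapped" bucket.  Per-key totals
    partition the grand total exactly.
    """
    revenues = _validate_revenue_frame(revenues)
    df = revenues.copy()
    if key == "company":
        df["_key"] = df["company"]
    elif key == "disease":
        if "indication" not in df.columns:
            raise ValueError("disease shares need an 'indication' column")
        df["_key"] = df["indication"]
    elif key == "organ_system":
        if organ_map is None:
            raise ValueError("organ_system shares need an indication->organ-system mapping")
        if "indication" not in df.columns:
            raise ValueError("organ_system shares need an 'indication' column")
        df["_key"] = df["indication"].map(lambda d: organ_map.get(d, "unmapped"))
    else:
        raise ValueError(f"unknown share key {key!r}")

    totals = df.groupby("_key")["revenue"].sum()
    grand = float(totals.sum())
    shares = pd.DataFrame(
        {
            key: totals.index,
            "total_revenue": totals.to_numpy(dtype=float),
            "share_percent": 100.0 * totals.to_numpy(dtype=float) / grand,
        }
    ).sort_values(["share_percent", key], ascending=[False, True]).reset_index(drop=True)
    return MarketShareTable(key_kind=key, shares=shares, grand_total=grand)


def revenue_table_from_records(records: Sequence[InterventionRecord]) -> pd.DataFrame:
    """Distil a revenue table from records; assets without revenue are
    excluded (absent revenue means the asset cannot enter share math)."""
    rows = [
        {"drug_name": r.drug_name, "company": r.sponsor, "indication": r.indication,
         "revenue": float(r.revenue)}
        for r in records
        if r.revenue is not None
    ]
    return pd.DataFrame(rows, columns=["drug_name", "company", "indication", "revenue"])


def odd_segmentation(records: Sequence[InterventionRecord]) -> dict:
    """Split approved assets into ODD vs non-ODD and profile each group.

    Returns counts and group percentages, per-group modality (therapy-area)
    percentage breakdowns, per-group indication frequency tables (descending),
    per-group top-company counts, and the list of indications served by both
    groups.  Group percentages are over approvals with known ODD status.
    """
    approved = [r for r in records if r.phase == "approved"]
    odd = [r for r in approved if r.odd_status is True]
    non_odd = [r for r in approved if r.odd_status is False]
    known = len(odd) + len(non_odd)

    def profile(group: list[InterventionRecord]) -> dict:
        n = len(group)
        modality = pd.Series([r.modality for r in group], dtype=str).value_counts()
        indications = pd.Series([r.indication for r in group], dtype=str).value_counts()
        companies = pd.Series([r.sponsor for r in group], dtype=str).value_counts()
        return {
            "n": n,
            "modality_percent": {k: round(100.0 * v / n, 1) for k, v in modality.items()} if n else {},
            "indication_counts": indications.to_dict(),
            "top_companies": companies.to_dict(),
        }

    shared = sorted({r.indication for r in odd} & {r.indication for r in non_odd})
    return {
        "n_approved": len(approved),
        "n_odd": len(odd),
        "n_non_odd": len(non_odd),
        "odd_percent": round(100.0 * len(odd) / known, 1) if known else 0.0,
        "non_odd_percent": round(100.0 * len(non_odd) / known, 1) if known else 0.0,
        "odd": profile(odd),
        "non_odd": profile(non_odd),
        "shared_indications": shared,
    }


def approval_timeline(records: Sequence[InterventionRecord]) -> pd.DataFrame:
    """Approvals per year split by ODD status.

    Rows: (year, odd, non_odd); approved records lacking a year are tallied in
    a final "unknown" row so the column totals always equal the approved
    count."""
    approved = [r for r in records if r.phase == "approved"]
    counts: dict[object, list[int]] = {}
    for r in approved:
        year: object = r.approval_year if r.approval_year is not None else "unknown"
        bucket = counts.setdefault(year, [0, 0])
        bucket[0 if r.odd_status is True else 1] += 1
    years = sorted((y for y in counts if y != "unknown"))
    rows = [{"year": y, "odd": counts[y][0], "non_odd": counts[y][1]} for y in years]
    if "unknown" in counts:
        rows.append({"year": "unknown", "odd": counts["unknown"][0],
                     "non_odd": counts["unknown"][1]})
    return pd.DataFrame(rows, columns=["year", "odd", "non_odd"])


def top_asset_profile(revenues: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Per-company totals vs highest-grossing asset, plus the Pearson
    correlation between the two across companies.

    The per-company table has (company, total_revenue, top_asset_revenue,
    top_asset_fraction).  The correlation is ``None`` when fewer than three
    companies are available or when either series has zero variance
    (degenerate, flagged rather than computed).
    """
    revenues = _validate_revenue_frame(revenues)
    per_drug = revenues.groupby(["company", "drug_name"])["revenue"].sum()
    totals = per_drug.groupby("company").sum()
    tops = per_drug.groupby("company").max()
    table = pd.DataFrame(
        {
            "company": totals.index,
            "total_revenue": totals.to_numpy(dtype=float),
            "top_asset_revenue": tops.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    table["top_asset_fraction"] = table["top_asset_revenue"] / table["total_revenue"]
    r: float | None = None
    if len(table) >= 3:
        x = table["total_revenue"].to_numpy()
        y = table["top_asset_revenue"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r = float(stats.pearsonr(x, y).statistic)
    return table, r


def classify_tier(
    share_percent: float, bounds: tuple[float, float] = DEFAULT_TIER_BOUNDS
) -> str:
    """Tier label for a market share: leader (>= upper bound), upcoming major
    (within [lower, upper)), challenger (< lower).  Shares must lie in
    [0, 100]."""
    if not 0 <= share_percent <= 100:
        raise ValueError(f"share {share_percent} outside [0, 100]")
    lower, upper = bounds
    if share_percent >= upper:
        return TIER_LEADER
    if share_percent >= lower:
        return TIER_UPCOMING
    return TIER_CHALLENGER
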