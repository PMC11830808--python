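"""Competitive and innovative index scoring per company.

Each asset is flagged on two axes: the disease axis (is any other company
developing against the same indication?) and the MoA axis (does any other
company use the same mechanism of action?).  A company's competitive index on
an axis is the fraction of its assets that are contested on that axis; its
innovative index is the fraction of assets whose MoA is exclusive to it.  By
construction innovative_index + competitive_index_moa = 1 for every company.

The default scope is the developmental pipeline (non-approved assets);
approved assets can be included with ``scope="all"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import InterventionRecord

__all__ = ["IndexScores", "classify_assets", "company_indexes", "index_matrix"]


@dataclass
class IndexScores:
    """Per-company index triple; every index is a fraction in [0, 1]."""

    company: str
    n_assets: int
    competitive_index_disease: float
    competitive_index_moa: float
    innovative_index: float


def _in_scope(records: Sequence[InterventionRecord], scope: str) -> list[InterventionRecord]:
    if scope == "pipeline":
        return [r for r in records if r.phase != "approved"]
    if scope == "all":
        return list(records)
    raise ValueError(f"scope must be 'pipeline' or 'all', got {scope!r}")


def classify_assets(records: Sequence[InterventionRecord], scope: str = "pipeline") -> pd.DataFrame:
    """Flag each in-scope asset on both competition axes.

    ``shared_disease`` is true iff at least one *other* company has an asset on
    the same indication; ``unique_moa`` is true iff no other company has an
    asset with the same MoA (a company re-using its own MoA stays unique).
    ``single_development`` and ``shared_moa`` are the respective complements,
    so the flags are mutually exclusive within each axis.
    """
    rows = _in_scope(records, scope)
    disease_devs: dict[str, set[str]] = {}
    moa_users: dict[str, set[str]] = {}
    for r in rows:
        disease_devs.setdefault(r.indication, set()).add(r.sponsor)
        moa_users.setdefault(r.moa, set()).add(r.sponsor)
    out = []
    for r in rows:
        shared_disease = len(disease_devs[r.indication]) > 1
        unique_moa = len(moa_users[r.moa]) == 1
        out.append(
            {
                "drug_name": r.drug_name,
                "sponsor": r.sponsor,
                "indication": r.indication,
                "moa": r.moa,
                "single_development": not shared_disease,
                "shared_disease": shared_disease,
                "unique_moa": unique_moa,
                "shared_moa": not unique_moa,
            }
        )
    return pd.DataFrame(
        out,
        columns=["drug_name", "sponsor", "indication", "moa", "single_development",
                 "shared_disease", "unique_moa", "shared_moa"],
    )


def company_indexes(records: Sequence[InterventionRecord], scope: str = "pipeline") -> list[IndexScores]:
    """Asset-weighted index fractions per company.

    competitive_index_disease = contested-disease assets / assets;
    competitive_index_moa = shared-MoA assets / assets;
    innovative_index = exclusive-MoA assets / assets.
    Companies with zero in-scope assets are simply absent.
    """
    flags = classify_assets(records, scope=scope)
    scores = []
    if flags.empty:
        return scores
    for company, block in flags.groupby("sponsor", sort=True):
        n = len(block)
        scores.append(
            IndexScores(
                company=str(company),
                n_assets=n,
                competitive_index_disease=float(block["shared_disease"].sum()) / n,
                competitive_index_moa=float(block["shared_moa"].sum()) / n,
                innovative_index=float(block["unique_moa"].sum()) / n,
            )
        )
    return scores


def index_matrix(scores: Sequence[IndexScores]) -> pd.DataFrame:
    """Heatmap-ready table: one row per company, the three indexes as columns,
    sorted descending by competitive_index_disease with alphabetical
    tie-break."""
    if not scores:
        raise ValueError("no index scores to tabulate")
    df = pd.DataFrame(
        [
            {
                "company": s.company,
                "n_assets": s.n_assets,
                "competitive_index_disease": s.competitive_index_disease,
                "competitive_index_moa": s.competitive_index_moa,
                "innovative_index": s.innovative_index,
            }
            for s in scores
        ]
    )
    df = df.sort_values(
        ["competitive_index_disease", "company"], ascending=[False, True]
    ).reset_index(drop=True)
    return df
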