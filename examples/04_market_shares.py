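"""Market shares, tiers, and the top-asset revenue correlation.

Aggregates per-asset revenues (million USD) into company shares, assigns the
leader / upcoming-major / challenger tiers (>=6%, 2.5-6%, <2.5%), and
estimates market-leader concentration via the Pearson correlation between a
company's total revenue and its highest-grossing asset.
"""

import rdlandscape as rd

records, _, _ = rd.generate_ecosystem(
    rd.EcosystemConfig(n_companies=15, mean_assets_per_company=10,
                       approved_fraction=0.5, seed=11))
revenues = rd.revenue_table_from_records(records)

shares = rd.market_shares(revenues, key="company")
top = shares.shares.head(8).copy()
top["tier"] = top["share_percent"].map(rd.classify_tier)
print(f"grand total: {shares.grand_total:,.0f} M USD")
print(top.to_string(index=False, float_format=lambda x: f"{x:,.1f}"))

profile, r = rd.top_asset_profile(revenues)
print(f"\nPearson r(total revenue, top asset) = {r:.3f}")
print("(a high correlation means market position is driven by single",
      "blockbuster assets rather than broad portfolios)")

seg = rd.odd_segmentation(records)
print(f"\nODD segmentation of approvals: {seg['n_odd']} ODD "
      f"({seg['odd_percent']}%) vs {seg['n_non_odd']} non-ODD "
      f"({seg['non_odd_percent']}%)")
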