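"""End-to-end pipeline: one validated configuration in, one report bundle out.

A run either loads real tables (portfolio / companies / aliases / revenues /
organ map / chemical links) or simulates an ecosystem, then executes the
toggled stages — summary counts, tripartite network + knockout, competition
indexes, market shares and segmentation, chemical network metrics — and
bundles every table with full provenance (config echo, version, seed) so any
number in the bundle is re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import chemnet as cn
from . import indexes as ix
from . import io as lio
from . import market as mk
from . import network as nw
from . import synth

__all__ = ["RunConfig", "InputPaths", "ReportBundle", "StageError",
           "validate_config", "run_pipeline", "write_bundle"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class InputPaths(BaseModel):
    portfolio: str
    companies: Optional[str] = None
    aliases: Optional[str] = None
    revenues: Optional[str] = None
    organ_map: Optional[str] = None
    chem_links: Optional[str] = None


class RunConfig(BaseModel):
    """Pipeline configuration; exactly one of ``inputs`` / ``simulate``."""

    inputs: Optional[InputPaths] = None
    simulate: Optional[synth.EcosystemConfig] = None
    rollup: bool = True
    scope: str = "pipeline"  # index scope: pipeline | all
    min_score: float = Field(default=cn.DEFAULT_MIN_SCORE, ge=0, le=1)
    tier_bounds: tuple[float, float] = mk.DEFAULT_TIER_BOUNDS
    seed: int = 0
    run_network: bool = True
    run_knockout: bool = True
    run_indexes: bool = True
    run_market: bool = True
    run_chemnet: bool = True


def validate_config(config: RunConfig | dict) -> list[str]:
    """All structural problems at once; empty list means OK."""
    errors: list[str] = []
    if isinstance(config, dict):
        try:
            config = RunConfig.model_validate(config)
        except ValidationError as exc:
            return [str(e["msg"]) + f" (at {'.'.join(map(str, e['loc']))})" for e in exc.errors()]
    if (config.inputs is None) == (config.simulate is None):
        errors.append("exactly one of 'inputs' or 'simulate' must be present")
    if config.scope not in ("pipeline", "all"):
        errors.append(f"scope must be pipeline|all, got {config.scope!r}")
    lo, hi = config.tier_bounds
    if not (0 <= lo < hi <= 100):
        errors.append(f"tier_bounds {config.tier_bounds} must satisfy 0 <= lower < upper <= 100")
    return errors


@dataclass
class ReportBundle:
    """Every table a run produces, plus provenance sufficient to re-derive it."""

    summary: dict
    records: list[lio.InterventionRecord]
    companies: list[lio.CompanyProfile]
    by_country: pd.DataFrame
    disease_activity: Optional[pd.DataFrame]
    knockout: Optional[pd.DataFrame]
    index_table: Optional[pd.DataFrame]
    company_shares: Optional[mk.MarketShareTable]
    disease_shares: Optional[mk.MarketShareTable]
    tiers: Optional[pd.DataFrame]
    top_asset: Optional[pd.DataFrame]
    top_asset_correlation: Optional[float]
    segmentation: Optional[dict]
    timeline: Optional[pd.DataFrame]
    chem_metrics: Optional[dict]
    provenance: dict


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the toggled stages; identical bundle for identical config+seed.

    Any stage error aborts with :class:`StageError` naming the stage.
    """
    errors = validate_config(config)
    if errors:
        raise StageError("validate", ValueError("; ".join(errors)))

    decisions: list[str] = []
    try:
        if config.simulate is not None:
            cfg = config.simulate.model_copy(update={"seed": config.seed})
            records, companies, _truth = synth.generate_ecosystem(cfg)
            aliases = lio.AliasMap()
        else:
            records, rejects = lio.read_portfolio_table(config.inputs.portfolio)
            if len(rejects):
                decisions.append(f"{len(rejects)} portfolio rows rejected")
            companies = (
                lio.read_company_table(config.inputs.companies)
                if config.inputs.companies else []
            )
            aliases = (
                lio.read_alias_table(config.inputs.aliases)
                if config.inputs.aliases else lio.AliasMap()
            )
        records = lio.normalize_entities(records, aliases, companies, rollup=config.rollup)
        decisions.append(f"rollup={'on' if config.rollup else 'off'}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    summary = lio.summarize_dataset(records)
    by_country = lio.count_companies_by_country(companies)

    activity = ko = None
    if config.run_network:
        try:
            net = nw.build_network(records)
            activity = nw.disease_activity(net)
            if config.run_knockout:
                ko = nw.knockout_all(net)
        except Exception as exc:
            raise StageError("network", exc) from exc

    index_table = None
    if config.run_indexes:
        try:
            scores = ix.company_indexes(records, scope=config.scope)
            index_table = ix.index_matrix(scores) if scores else pd.DataFrame()
            decisions.append(f"index scope={config.scope}")
        except Exception as exc:
            raise StageError("indexes", exc) from exc

    company_shares = disease_shares = tiers = top_asset = seg = timeline = None
    top_r = None
    if config.run_market:
        try:
            if config.inputs is not None and config.inputs.revenues:
                revenues = lio.read_revenue_table(config.inputs.revenues)
            else:
                revenues = mk.revenue_table_from_records(records)
            if len(revenues):
                company_shares = mk.market_shares(revenues, key="company")
                disease_shares = mk.market_shares(revenues, key="disease")
                tiers = company_shares.shares.copy()
                tiers["tier"] = tiers["share_percent"].map(
                    lambda s: mk.classify_tier(s, config.tier_bounds)
                )
                top_asset, top_r = mk.top_asset_profile(revenues)
            seg = mk.odd_segmentation(records)
            timeline = mk.approval_timeline(records)
        except Exception as exc:
            raise StageError("market", exc) from exc

    chem_metrics = None
    if config.run_chemnet:
        try:
            approved = [r for r in records if r.phase == "approved"]
            if config.inputs is not None and config.inputs.chem_links:
                links, info = cn.read_stitch_links(config.inputs.chem_links)
            else:
                frame = synth.generate_chem_links(records, seed=config.seed) if approved else None
                links = (
                    [cn.ChemProteinLink(*row) for row in frame.itertuples(index=False)]
                    if frame is not None else []
                )
                info = {"dialect": "real", "n_rejected": 0, "path": "simulated"}
            if approved:
                drugs = sorted({r.drug_name for r in approved})
                netw = cn.build_chem_network(drugs, links, min_score=config.min_score,
                                             source=info["path"])
                chem_metrics = cn.network_metrics(netw).as_dict()
        except Exception as exc:
            raise StageError("chemnet", exc) from exc

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "decisions": decisions,
    }
    return ReportBundle(
        summary=summary, records=records, companies=companies, by_country=by_country,
        disease_activity=activity, knockout=ko, index_table=index_table,
        company_shares=company_shares, disease_shares=disease_shares, tiers=tiers,
        top_asset=top_asset, top_asset_correlation=top_r, segmentation=seg,
        timeline=timeline, chem_metrics=chem_metrics, provenance=provenance,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Persist the bundle as CSV/JSON files under ``out_dir``; partial output
    from a failed write is removed."""
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        lio.write_portfolio_table(bundle.records, out / "records.csv")
        lio.write_summary(bundle.summary, out / "summary.json")
        bundle.by_country.to_csv(out / "companies_by_country.csv", index=False)
        if bundle.disease_activity is not None:
            bundle.disease_activity.to_csv(out / "disease_activity.csv", index=False)
        if bundle.knockout is not None:
            bundle.knockout.to_csv(out / "knockout.csv", index=False)
        if bundle.index_table is not None:
            bundle.index_table.to_csv(out / "indexes.csv", index=False)
        market_report: dict = {}
        if bundle.company_shares is not None:
            bundle.company_shares.shares.to_csv(out / "company_shares.csv", index=False)
            market_report["grand_total_million_usd"] = bundle.company_shares.grand_total
        if bundle.disease_shares is not None:
            bundle.disease_shares.shares.to_csv(out / "disease_shares.csv", index=False)
        if bundle.tiers is not None:
            bundle.tiers.to_csv(out / "tiers.csv", index=False)
        if bundle.top_asset is not None:
            bundle.top_asset.to_csv(out / "top_asset_profile.csv", index=False)
            market_report["top_asset_correlation"] = bundle.top_asset_correlation
        if bundle.segmentation is not None:
            market_report["segmentation"] = bundle.segmentation
        if market_report:
            (out / "market_report.json").write_text(json.dumps(market_report, indent=2) + "\n")
        if bundle.timeline is not None:
            bundle.timeline.to_csv(out / "timeline.csv", index=False)
        if bundle.chem_metrics is not None:
            (out / "chem_metrics.json").write_text(json.dumps(bundle.chem_metrics, indent=2) + "\n")
        (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2) + "\n")
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
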