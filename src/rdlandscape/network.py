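"""Tripartite sponsor-collaborator-disease network and knockout simulation.

The ecosystem graph has three role-based layers: sponsor companies (layer 1),
collaborator companies (layer 2), and diseases (layer 3).  Each drug program
contributes a path from its sponsor to its disease: through each collaborator
when the program is collaborative, or as a direct sponsor->disease edge when
the sponsor is solely responsible.  A company acting both as sponsor and as a
collaborator appears as two role-distinct nodes.

The knockout simulation removes one company — both roles, emulating market
exit — and re-measures, per disease, how many developers and how many unique
mechanisms of action (MoA) remain.  Edge multiplicity is retained (multigraph):
a company with several programs on one disease contributes one annotated edge
per program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .io import InterventionRecord

__all__ = [
    "TripartiteNetwork",
    "KnockoutImpact",
    "build_network",
    "disease_activity",
    "knockout",
    "knockout_all",
    "export_graphml",
]


def _sponsor(name: str) -> tuple[str, str]:
    return ("sponsor", name)


def _collab(name: str) -> tuple[str, str]:
    return ("collaborator", name)


def _disease(name: str) -> tuple[str, str]:
    return ("disease", name)


@dataclass
class TripartiteNetwork:
    """Three-layer multigraph plus the asset table it was built from.

    ``graph`` nodes are ``(role, name)`` pairs with a ``layer`` attribute;
    edges carry ``asset`` (originating program id), ``moa`` and ``kind``
    (``sponsor-collaborator`` | ``collaborator-disease`` | ``sponsor-disease``).
    ``assets`` is the distilled per-program table used for activity counting
    and knockout recounts.
    """

    graph: nx.MultiDiGraph
    assets: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sponsors(self) -> set[str]:
        return {n for role, n in self.graph.nodes if role == "sponsor"}

    @property
    def collaborators(self) -> set[str]:
        return {n for role, n in self.graph.nodes if role == "collaborator"}

    @property
    def diseases(self) -> set[str]:
        return {n for role, n in self.graph.nodes if role == "disease"}


@dataclass
class KnockoutImpact:
    """Per-disease consequences of removing one company from the ecosystem."""

    removed_company: str
    table: pd.DataFrame  # disease, companies_remaining, unique_moas_remaining, delta_companies, delta_moas


def build_network(records: Sequence[InterventionRecord]) -> TripartiteNetwork:
    """Build the tripartite graph from normalized records.

    A record with a blank sponsor or disease cannot be placed in the network
    and is reported in ``rejected`` rather than raising.  Every retained asset
    induces at least one sponsor->disease path; a direct sponsor->disease edge
    exists only for solo programs.
    """
    g = nx.MultiDiGraph()
    asset_rows = []
    rejected = []
    for i, r in enumerate(records):
        if not r.sponsor.strip() or not r.indication.strip():
            rejected.append({"row": i, "error": "blank sponsor or disease"})
            continue
        asset_id = f"asset_{i:05d}"
        asset_rows.append(
            {
                "asset": asset_id,
                "drug_name": r.drug_name,
                "sponsor": r.sponsor,
                "disease": r.indication,
                "moa": r.moa,
                "collaborators": tuple(r.collaborators),
            }
        )
        g.add_node(_sponsor(r.sponsor), layer=1, name=r.sponsor)
        g.add_node(_disease(r.indication), layer=3, name=r.indication)
        if r.collaborators:
            for c in r.collaborators:
                g.add_node(_collab(c), layer=2, name=c)
                g.add_edge(_sponsor(r.sponsor), _collab(c), asset=asset_id, moa=r.moa,
                           kind="sponsor-collaborator")
                g.add_edge(_collab(c), _disease(r.indication), asset=asset_id, moa=r.moa,
                           kind="collaborator-disease")
        else:
            g.add_edge(_sponsor(r.sponsor), _disease(r.indication), asset=asset_id,
                       moa=r.moa, kind="sponsor-disease")
    assets = pd.DataFrame(
        asset_rows, columns=["asset", "drug_name", "sponsor", "disease", "moa", "collaborators"]
    )
    return TripartiteNetwork(graph=g, assets=assets,
                             rejected=pd.DataFrame(rejected, columns=["row", "error"]))


def disease_activity(network: TripartiteNetwork) -> pd.DataFrame:
    """Per-disease developer count and unique-MoA count.

    A company is active on a disease if one of its programs reaches it; the
    MoA count deduplicates the MoA annotations of the programs targeting the
    disease.  Diseases with no assets are absent.
    """
    return _activity_from_assets(network.assets)


def _activity_from_assets(assets: pd.DataFrame) -> pd.DataFrame:
    if assets.empty:
        return pd.DataFrame(columns=["disease", "n_companies", "n_unique_moas"])
    grouped = assets.groupby("disease").agg(
        n_companies=("sponsor", "nunique"), n_unique_moas=("moa", "nunique")
    )
    return grouped.reset_index().sort_values("disease").reset_index(drop=True)


def knockout(network: TripartiteNetwork, company: str) -> KnockoutImpact:
    """Remove ``company`` (sponsor role and collaborator role) and recount.

    Equivalent to rebuilding the network from the records minus the company's
    sponsored programs: its assets vanish, it is scrubbed from surviving
    collaborator lists, and collaborator nodes left without any sponsor edge
    disappear.  Returns the per-disease impact for every disease the full
    network contains (untouched diseases show zero deltas).
    """
    if company not in network.sponsors:
        raise KeyError(f"company {company!r} is not a layer-1 sponsor in this network")
    before = _activity_from_assets(network.assets).set_index("disease")
    surviving = network.assets[network.assets["sponsor"] != company]
    after = _activity_from_assets(surviving).set_index("disease")
    after = after.reindex(before.index, fill_value=0)
    table = pd.DataFrame(
        {
            "disease": before.index,
            "companies_remaining": after["n_companies"].to_numpy(),
            "unique_moas_remaining": after["n_unique_moas"].to_numpy(),
            "delta_companies": (before["n_companies"] - after["n_companies"]).to_numpy(),
            "delta_moas": (before["n_unique_moas"] - after["n_unique_moas"]).to_numpy(),
        }
    ).reset_index(drop=True)
    return KnockoutImpact(removed_company=company, table=table)


def knockout_all(network: TripartiteNetwork) -> pd.DataFrame:
    """One knockout per sponsor; long table identical to per-company calls."""
    blocks = []
    for company in sorted(network.sponsors):
        impact = knockout(network, company)
        block = impact.table.copy()
        block.insert(0, "company", company)
        blocks.append(block)
    if not blocks:
        return pd.DataFrame(
            columns=["company", "disease", "companies_remaining", "unique_moas_remaining",
                     "delta_companies", "delta_moas"]
        )
    return pd.concat(blocks, ignore_index=True)


def removed_subgraph(network: TripartiteNetwork, company: str) -> nx.MultiDiGraph:
    """The graph after market exit of ``company``: both role nodes gone, its
    assets' edges gone, and collaborator nodes with no remaining sponsor edge
    pruned."""
    g = network.graph.copy()
    dead_assets = set(network.assets.loc[network.assets["sponsor"] == company, "asset"])
    g.remove_edges_from(
        [(u, v, k) for u, v, k, d in g.edges(keys=True, data=True) if d["asset"] in dead_assets]
    )
    for node in (_sponsor(company), _collab(company)):
        if g.has_node(node):
            g.remove_node(node)
    orphans = [n for n in g.nodes if n[0] == "collaborator" and g.degree(n) == 0]
    g.remove_nodes_from(orphans)
    g.remove_nodes_from([n for n in g.nodes if g.degree(n) == 0 and n[0] != "disease"])
    return g


def export_graphml(network: TripartiteNetwork, path: str | Path) -> None:
    """Write the graph as GraphML with layer and MoA attributes preserved."""
    g = nx.MultiDiGraph()
    for node, data in network.graph.nodes(data=True):
        g.add_node(f"{node[0]}:{node[1]}", **data)
    for u, v, data in network.graph.edges(data=True):
        g.add_edge(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}", **data)
    nx.write_graphml(g, str(path))
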