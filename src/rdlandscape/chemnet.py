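"""Confidence-scored drug-drug / drug-protein networks (STITCH dialect).

STITCH-style link tables quantify each chemical-protein (or chemical-chemical)
association with a combined confidence score — 0-1 in the real dialect, 0-1000
integers in the file-download dialect.  This module parses either dialect,
builds confidence-thresholded networks for a drug set, computes the
sparsity/connectivity metrics used to contrast first-in-class (ODD) drug sets
against repurposed (non-ODD) ones, and tallies the top mechanisms of action
per group.

Drug-drug edges come only from explicit chemical-chemical links; drug pairs
connected through a shared protein target are counted separately
(``shared_protein_pairs``) rather than materialized as edges, preserving the
red (drug-drug) vs green (drug-protein) edge semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import InterventionRecord

__all__ = [
    "ChemProteinLink",
    "ChemNetwork",
    "NetworkMetrics",
    "read_stitch_links",
    "write_stitch_links",
    "build_chem_network",
    "network_metrics",
    "compare_groups",
    "top_moa_counts",
    "pathway_membership",
    "DEFAULT_MIN_SCORE",
]

#: STITCH "medium confidence" convention; always recorded in provenance.
DEFAULT_MIN_SCORE = 0.4


@dataclass
class ChemProteinLink:
    """One scored association between a chemical and a partner (protein or
    chemical); scores live on [0, 1]."""

    chemical: str
    partner: str
    partner_kind: str  # "protein" | "chemical"
    score: float

    def __post_init__(self) -> None:
        if self.partner_kind not in ("protein", "chemical"):
            raise ValueError(f"partner_kind must be protein|chemical, got {self.partner_kind!r}")
        if not 0 <= self.score <= 1:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class ChemNetwork:
    """Typed drug/protein network at a recorded confidence threshold."""

    graph: nx.Graph
    min_score: float
    shared_protein_pairs: int
    source: str = ""
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def drugs(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "drug"}

    @property
    def proteins(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "protein"}


@dataclass
class NetworkMetrics:
    n_drugs: int
    n_proteins: int
    n_edges: int
    density: float
    n_components: int
    mean_degree: float
    isolated_drug_fraction: float
    shared_protein_pairs: int
    min_score: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _infer_kind(partner: str) -> str:
    # STITCH protein ids look like "9606.ENSP000..."; chemicals like "CIDm91758680".
    p = partner.upper()
    if "ENSP" in p or partner.startswith(("PROT", "prot")):
        return "protein"
    if p.startswith("CID") or p.startswith("DRUG"):
        return "chemical"
    return "protein"


def read_stitch_links(path: str | Path) -> tuple[list[ChemProteinLink], dict]:
    """Parse a STITCH-dialect TSV of (chemical, partner, combined score).

    The score dialect is detected per file — integers on 0-1000 are divided by
    1000, reals on 0-1 pass through — and recorded in the returned info dict;
    a file mixing dialects is an error.  Scores outside both ranges reject the
    row (counted in ``info["n_rejected"]``).  An optional ``partner_kind``
    column overrides kind inference from identifier shape.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower().strip(): c for c in df.columns}
    chem_col = next((cols[c] for c in ("chemical", "item_id_a", "drug") if c in cols), None)
    part_col = next((cols[c] for c in ("partner", "protein", "item_id_b") if c in cols), None)
    score_col = next((cols[c] for c in ("combined_score", "score", "combined score") if c in cols), None)
    if chem_col is None or part_col is None or score_col is None:
        raise ValueError(
            "STITCH table needs chemical, partner and combined_score columns; "
            f"got {list(df.columns)}"
        )
    kind_col = cols.get("partner_kind")

    scores = pd.to_numeric(df[score_col], errors="coerce")
    valid = scores.notna()
    integral = (scores[valid] % 1 == 0) & (scores[valid] > 1)
    fractional = (scores[valid] >= 0) & (scores[valid] <= 1)
    if integral.any() and (~integral & ~fractional).any():
        pass  # handled per-row below as rejects
    has_int = bool((scores[valid] > 1).any())
    has_real = bool(((scores[valid] <= 1) & (scores[valid] % 1 != 0)).any())
    if has_int and has_real:
        raise ValueError("mixed score dialects (0-1000 integers and 0-1 reals) in one file")
    dialect = "integer" if has_int else "real"

    links: list[ChemProteinLink] = []
    n_rejected = 0
    for raw, chem, part, kind_raw in zip(
        scores, df[chem_col], df[part_col],
        df[kind_col] if kind_col else [""] * len(df),
    ):
        if pd.isna(raw):
            n_rejected += 1
            continue
        if dialect == "integer":
            if not (0 <= raw <= 1000 and raw % 1 == 0):
                n_rejected += 1
                continue
            score = float(raw) / 1000.0
        else:
            if not 0 <= raw <= 1:
                n_rejected += 1
                continue
            score = float(raw)
        kind = str(kind_raw).strip().lower() or _infer_kind(str(part))
        links.append(ChemProteinLink(str(chem).strip(), str(part).strip(), kind, score))
    return links, {"dialect": dialect, "n_rejected": n_rejected, "path": str(path)}


def write_stitch_links(
    links: Sequence[ChemProteinLink] | pd.DataFrame, path: str | Path, dialect: str = "real"
) -> None:
    """Write links as TSV in either score dialect (round-trip partner of the
    reader)."""
    if isinstance(links, pd.DataFrame):
        df = links.rename(columns={"score": "combined_score"}).copy()
    else:
        df = pd.DataFrame(
            [{"chemical": l.chemical, "partner": l.partner, "partner_kind": l.partner_kind,
              "combined_score": l.score} for l in links]
        )
    if dialect == "integer":
        df["combined_score"] = (df["combined_score"] * 1000).round().astype(int)
    elif dialect != "real":
        raise ValueError(f"dialect must be real|integer, got {dialect!r}")
    df.to_csv(path, sep="\t", index=False)


def build_chem_network(
    drugs: Sequence[str],
    links: Sequence[ChemProteinLink],
    min_score: float = DEFAULT_MIN_SCORE,
    source: str = "",
) -> ChemNetwork:
    """Confidence-filtered network for a drug set.

    Keeps edges for links with score >= ``min_score`` that touch a listed
    drug: chemical-protein links become drug-protein edges; chemical-chemical
    links become drug-drug edges when both endpoints are listed.  The node set
    is threshold-independent — every listed drug and every protein partnered
    with a listed drug in the link table appears as a node even when all its
    links fall below the threshold — so density and mean degree shrink
    monotonically as the threshold rises.  Proteins linked to two or more
    listed drugs induce the shared-protein pair count.
    """
    if not 0 <= min_score <= 1:
        raise ValueError("min_score must be in [0, 1]")
    drug_set = set(drugs)
    if not drug_set:
        raise ValueError("drug list is empty")
    g = nx.Graph()
    for d in sorted(drug_set):
        g.add_node(d, kind="drug")
    for link in links:
        if link.partner_kind == "protein" and link.chemical in drug_set:
            g.add_node(link.partner, kind="protein")
    for link in links:
        if link.score < min_score:
            continue
        if link.partner_kind == "protein":
            if link.chemical in drug_set:
                _add_scored_edge(g, link.chemical, link.partner, "drug-protein", link.score)
        else:
            if link.chemical in drug_set and link.partner in drug_set:
                _add_scored_edge(g, link.chemical, link.partner, "drug-drug", link.score)
    pairs = set()
    for p in [n for n, d in g.nodes(data=True) if d["kind"] == "protein"]:
        touching = sorted(n for n in g.neighbors(p) if g.nodes[n]["kind"] == "drug")
        for i, a in enumerate(touching):
            for b in touching[i + 1:]:
                pairs.add((a, b))
    return ChemNetwork(graph=g, min_score=min_score, shared_protein_pairs=len(pairs),
                       source=source)


def _add_scored_edge(g: nx.Graph, u: str, v: str, kind: str, score: float) -> None:
    if u == v:
        return
    if g.has_edge(u, v):
        if score > g.edges[u, v]["score"]:
            g.edges[u, v]["score"] = score
    else:
        g.add_edge(u, v, kind=kind, score=score)


def network_metrics(network: ChemNetwork) -> NetworkMetrics:
    """Sparsity/connectivity summary: density = 2E / (N(N-1)) over all typed
    nodes, connected-component count, mean degree, and the fraction of drugs
    with no edge at all."""
    g = network.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    drugs = network.drugs
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    return NetworkMetrics(
        n_drugs=len(drugs),
        n_proteins=len(network.proteins),
        n_edges=e,
        density=density,
        n_components=nx.number_connected_components(g) if n else 0,
        mean_degree=2.0 * e / n if n else 0.0,
        isolated_drug_fraction=(
            sum(1 for d in drugs if g.degree(d) == 0) / len(drugs) if drugs else 0.0
        ),
        shared_protein_pairs=network.shared_protein_pairs,
        min_score=network.min_score,
    )


def compare_groups(metrics_a: NetworkMetrics, metrics_b: NetworkMetrics) -> dict:
    """Signed per-metric differences (a minus b) plus a denser/more-connected
    verdict per connectivity metric; both inputs must share a threshold.  No
    statistical test is attached."""
    if metrics_a.min_score != metrics_b.min_score:
        raise ValueError(
            f"threshold mismatch: {metrics_a.min_score} vs {metrics_b.min_score}"
        )
    a, b = metrics_a.as_dict(), metrics_b.as_dict()
    diffs = {k: a[k] - b[k] for k in a if k != "min_score"}
    # Connectivity read-out: higher density/mean degree/shared pairs and lower
    # isolation mean "denser and more connected".
    verdict = {
        "density": "a" if diffs["density"] > 0 else ("b" if diffs["density"] < 0 else "tie"),
        "mean_degree": "a" if diffs["mean_degree"] > 0 else ("b" if diffs["mean_degree"] < 0 else "tie"),
        "shared_protein_pairs": "a" if diffs["shared_protein_pairs"] > 0
        else ("b" if diffs["shared_protein_pairs"] < 0 else "tie"),
        "isolated_drug_fraction": "a" if diffs["isolated_drug_fraction"] < 0
        else ("b" if diffs["isolated_drug_fraction"] > 0 else "tie"),
    }
    return {"differences": diffs, "denser": verdict, "min_score": metrics_a.min_score}


def top_moa_counts(
    records: Sequence[InterventionRecord], odd: bool | None = None, n: int = 30
) -> pd.DataFrame:
    """The ``n`` most frequent mechanisms of action, optionally restricted to
    one ODD group; descending by count with alphabetical tie-break (ties at
    rank ``n`` resolve alphabetically)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = records if odd is None else [r for r in records if r.odd_status is odd]
    counts: dict[str, int] = {}
    for r in pool:
        counts[r.moa] = counts.get(r.moa, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return pd.DataFrame(ranked, columns=["moa", "count"])


def pathway_membership(
    network: ChemNetwork, protein_pathways: Mapping[str, Sequence[str]] | pd.DataFrame
) -> pd.DataFrame:
    """Join network proteins against a user-supplied protein -> pathway table
    and count members per pathway (no enrichment statistic)."""
    if isinstance(protein_pathways, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for _, row in protein_pathways.iterrows():
            mapping.setdefault(str(row["protein"]), []).append(str(row["pathway"]))
    else:
        mapping = {k: list(v) for k, v in protein_pathways.items()}
    counts: dict[str, int] = {}
    for p in network.proteins:
        for pw in mapping.get(p, []):
            counts[pw] = counts.get(pw, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(ranked, columns=["pathway", "n_proteins"])
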