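"""Reading, validation and normalization of portfolio and financial tables.

The tables this module handles describe one drug program per row: the drug,
its sponsoring company, any collaborators, the targeted rare indication, the
mechanism of action (MoA), the therapy modality, the development phase, and —
for EMA-approved assets — orphan drug designation (ODD) status, approval year
and annual revenue in million USD.

Entity names in real portfolio listings are messy ("Hoffmann-La Roche AG" vs
"Roche"; "Celgene" post-acquisition vs "Bristol-Myers Squibb"), so the module
supports an alias table per entity kind and a company table carrying parent
(merger/acquisition) relationships; :func:`normalize_entities` canonicalizes
names and can roll subsidiaries up into their parents while retaining the
original sponsor in an annotation field.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "InterventionRecord",
    "CompanyProfile",
    "AliasMap",
    "SchemaError",
    "AliasError",
    "PHASES",
    "read_portfolio_table",
    "write_portfolio_table",
    "read_company_table",
    "read_alias_table",
    "read_revenue_table",
    "normalize_entities",
    "summarize_dataset",
    "count_companies_by_country",
]

PHASES = ("early_clinical", "late_clinical", "approved")

#: Values treated as "absent" when parsing optional fields.
_MISSING = {"", "n/a", "na", "none", "null", "nan", "-", "."}

_LIST_SEP = ";"

PORTFOLIO_COLUMNS = (
    "drug_name",
    "sponsor",
    "collaborators",
    "indication",
    "moa",
    "modality",
    "phase",
    "odd_status",
    "approval_year",
    "revenue",
    "organ_systems",
)

COMPANY_COLUMNS = ("name", "hq_country", "parent")
ALIAS_COLUMNS = ("kind", "raw", "canonical")
REVENUE_COLUMNS = ("drug_name", "company", "indication", "revenue", "fiscal_year")


class SchemaError(ValueError):
    """A table is structurally unusable (missing required columns)."""


class AliasError(ValueError):
    """An alias table is not idempotent (a target is itself aliased away)."""


def fold_name(name: str) -> str:
    """Fold an entity name for matching: casefold, strip accents, collapse
    whitespace and punctuation.  "Hoffmann-La Roche AG" and
    "hoffmann la roche ag" fold identically."""
    s = unicodedata.normalize("NFKD", name)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = re.sub(r"[^\w\s]", " ", s.casefold())
    return re.sub(r"\s+", " ", s).strip()


@dataclass
class InterventionRecord:
    """One drug program: a (drug, sponsor, indication) row of a portfolio table.

    ``odd_status`` is only meaningful for approved assets and is ``None`` for
    pipeline-only ones.  ``revenue`` is annual product revenue in million USD;
    records without revenue are excluded from market-share aggregations.
    ``sponsor_original`` is set by merger roll-up so portfolios can still be
    reported including/excluding a subsidiary.
    """

    drug_name: str
    sponsor: str
    indication: str
    moa: str
    modality: str
    phase: str
    collaborators: list[str] = field(default_factory=list)
    odd_status: bool | None = None
    approval_year: int | None = None
    revenue: float | None = None
    organ_systems: list[str] = field(default_factory=list)
    sponsor_original: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if not self.sponsor.strip():
            raise ValueError("blank sponsor")
        if not self.indication.strip():
            raise ValueError("blank indication")
        if self.sponsor in self.collaborators:
            raise ValueError(f"sponsor {self.sponsor!r} listed among its own collaborators")
        if self.approval_year is not None and self.phase != "approved":
            raise ValueError("approval_year set on a non-approved record")
        if self.revenue is not None and self.revenue < 0:
            raise ValueError("negative revenue")


@dataclass
class CompanyProfile:
    """A pharmaceutical entity: canonical name, HQ country, optional parent
    (the acquiring company after a merger, e.g. Celgene -> Bristol-Myers Squibb)."""

    name: str
    hq_country: str = ""
    parent: str | None = None


@dataclass
class AliasMap:
    """Raw-name -> canonical-name mappings, scoped by entity kind
    (``company`` | ``disease`` | ``moa``).  Lookup keys are folded via
    :func:`fold_name`; the map must be idempotent (canonical values map to
    themselves)."""

    entries: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, kind: str, raw: str, canonical: str) -> None:
        self.entries.setdefault(kind, {})[fold_name(raw)] = canonical

    def resolve(self, kind: str, raw: str) -> str:
        return self.entries.get(kind, {}).get(fold_name(raw), raw)

    def check_idempotent(self) -> None:
        offenders = []
        for kind, table in self.entries.items():
            for raw, canonical in table.items():
                target = table.get(fold_name(canonical), canonical)
                if target != canonical:
                    offenders.append((kind, raw, canonical, target))
        if offenders:
            detail = "; ".join(
                f"{k}: {r!r} -> {c!r} but {c!r} -> {t!r}" for k, r, c, t in offenders
            )
            raise AliasError(f"alias map not idempotent: {detail}")


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_optional(raw: object) -> str | None:
    s = str(raw).strip()
    return None if s.lower() in _MISSING else s


def _parse_list(raw: object) -> list[str]:
    s = _parse_optional(raw)
    if s is None:
        return []
    return [part.strip() for part in s.split(_LIST_SEP) if part.strip()]


def _parse_bool(raw: object) -> bool | None:
    s = _parse_optional(raw)
    if s is None:
        return None
    low = s.lower()
    if low in {"true", "yes", "1", "odd"}:
        return True
    if low in {"false", "no", "0", "non-odd", "non_odd"}:
        return False
    raise ValueError(f"unparseable boolean {raw!r}")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {', '.join(missing)}")


def read_portfolio_table(
    path: str | Path,
) -> tuple[list[InterventionRecord], pd.DataFrame]:
    """Read a portfolio CSV/TSV into records.

    Returns ``(records, rejects)`` where ``rejects`` is a table of
    ``(row, error)`` for rows that failed row-level parsing.  Malformed rows
    never abort the read; a missing required column does (:class:`SchemaError`).
    Row numbers are 1-based data rows (header excluded).
    """
    df = _read_table(path)
    required = [c for c in PORTFOLIO_COLUMNS if c not in
                ("odd_status", "approval_year", "revenue", "organ_systems", "collaborators")]
    _require_columns(df, required, "portfolio")

    records: list[InterventionRecord] = []
    rejects: list[dict] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            year_s = _parse_optional(row.get("approval_year", ""))
            rev_s = _parse_optional(row.get("revenue", ""))
            records.append(
                InterventionRecord(
                    drug_name=str(row["drug_name"]).strip(),
                    sponsor=str(row["sponsor"]).strip(),
                    indication=str(row["indication"]).strip(),
                    moa=str(row["moa"]).strip(),
                    modality=str(row["modality"]).strip(),
                    phase=str(row["phase"]).strip(),
                    collaborators=_parse_list(row.get("collaborators", "")),
                    odd_status=_parse_bool(row.get("odd_status", "")),
                    approval_year=int(year_s) if year_s is not None else None,
                    revenue=float(rev_s) if rev_s is not None else None,
                    organ_systems=_parse_list(row.get("organ_systems", "")),
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append({"row": i, "error": str(exc)})
    return records, pd.DataFrame(rejects, columns=["row", "error"])


def records_to_frame(records: Iterable[InterventionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["collaborators"] = _LIST_SEP.join(r.collaborators)
        d["organ_systems"] = _LIST_SEP.join(r.organ_systems)
        d["odd_status"] = "" if r.odd_status is None else str(r.odd_status).lower()
        d["approval_year"] = "" if r.approval_year is None else str(r.approval_year)
        d["revenue"] = "" if r.revenue is None else repr(r.revenue)
        d["sponsor_original"] = r.sponsor_original or ""
        rows.append(d)
    cols = list(PORTFOLIO_COLUMNS) + ["sponsor_original"]
    return pd.DataFrame(rows, columns=cols)


def write_portfolio_table(records: Iterable[InterventionRecord], path: str | Path) -> None:
    """Write records as CSV/TSV (extension decides the delimiter); lossless
    round-trip partner of :func:`read_portfolio_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_company_table(path: str | Path) -> list[CompanyProfile]:
    df = _read_table(path)
    _require_columns(df, ("name", "hq_country"), "company")
    out = []
    for row in df.to_dict("records"):
        out.append(
            CompanyProfile(
                name=str(row["name"]).strip(),
                hq_country=(_parse_optional(row.get("hq_country", "")) or ""),
                parent=_parse_optional(row.get("parent", "")),
            )
        )
    _check_parent_chains(out)
    return out


def _check_parent_chains(companies: Sequence[CompanyProfile]) -> None:
    by_name = {c.name: c for c in companies}
    for c in companies:
        seen = {c.name}
        cur = c
        while cur.parent is not None:
            if cur.parent not in by_name:
                raise ValueError(f"parent {cur.parent!r} of {cur.name!r} is not a known company")
            if cur.parent in seen:
                raise ValueError(f"cycle in parent chain at {cur.parent!r}")
            seen.add(cur.parent)
            cur = by_name[cur.parent]


def read_alias_table(path: str | Path) -> AliasMap:
    df = _read_table(path)
    _require_columns(df, ALIAS_COLUMNS, "alias")
    amap = AliasMap()
    for row in df.to_dict("records"):
        amap.add(str(row["kind"]).strip(), str(row["raw"]).strip(), str(row["canonical"]).strip())
    amap.check_idempotent()
    return amap


def read_revenue_table(path: str | Path) -> pd.DataFrame:
    """Read a financial-report extract: one row per (drug, company, indication)
    with product-specific revenue in million USD."""
    df = _read_table(path)
    _require_columns(df, ("drug_name", "company", "revenue"), "revenue")
    df = df.copy()
    df["revenue"] = pd.to_numeric(df["revenue"], errors="coerce")
    df = df.dropna(subset=["revenue"])
    if (df["revenue"] < 0).any():
        raise ValueError("negative revenue in financial table")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# normalization


def resolve_parent(name: str, companies: Sequence[CompanyProfile]) -> str:
    """Follow the parent chain of ``name`` to its ultimate owner."""
    by_name = {c.name: c for c in companies}
    cur = name
    while cur in by_name and by_name[cur].parent is not None:
        cur = by_name[cur].parent
    return cur


def normalize_entities(
    records: Sequence[InterventionRecord],
    aliases: AliasMap | None = None,
    companies: Sequence[CompanyProfile] | None = None,
    rollup: bool = False,
) -> list[InterventionRecord]:
    """Canonicalize company/disease/MoA strings and optionally roll subsidiaries
    up into their parents.

    With ``rollup=True`` a sponsor with a parent company is replaced by the
    ultimate parent; the pre-rollup canonical name is kept in
    ``sponsor_original`` so portfolios can be reported including or excluding
    the subsidiary.  Idempotent: applying twice equals applying once.
    """
    aliases = aliases or AliasMap()
    aliases.check_idempotent()
    companies = companies or []

    out: list[InterventionRecord] = []
    for r in records:
        sponsor = aliases.resolve("company", r.sponsor)
        collab = [aliases.resolve("company", c) for c in r.collaborators]
        original = r.sponsor_original
        if rollup:
            parent = resolve_parent(sponsor, companies)
            if parent != sponsor:
                original = original or sponsor
                sponsor = parent
            collab = [resolve_parent(c, companies) for c in collab]
        collab = [c for c in dict.fromkeys(collab) if c != sponsor]
        out.append(
            InterventionRecord(
                drug_name=r.drug_name,
                sponsor=sponsor,
                indication=aliases.resolve("disease", r.indication),
                moa=aliases.resolve("moa", r.moa),
                modality=r.modality,
                phase=r.phase,
                collaborators=collab,
                odd_status=r.odd_status,
                approval_year=r.approval_year,
                revenue=r.revenue,
                organ_systems=list(r.organ_systems),
                sponsor_original=original,
            )
        )
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize_dataset(records: Sequence[InterventionRecord]) -> dict:
    """Dataset-level counts: unique drugs / diseases / MoAs / companies, phase
    tallies, and ODD vs non-ODD approved counts with the ODD percentage of
    approved assets with known status."""
    drugs = {r.drug_name for r in records}
    diseases = {r.indication for r in records}
    moas = {r.moa for r in records}
    companies = {r.sponsor for r in records}
    approved = [r for r in records if r.phase == "approved"]
    odd = sum(1 for r in approved if r.odd_status is True)
    non_odd = sum(1 for r in approved if r.odd_status is False)
    known = odd + non_odd
    return {
        "n_records": len(records),
        "n_unique_drugs": len(drugs),
        "n_diseases": len(diseases),
        "n_moas": len(moas),
        "n_companies": len(companies),
        "n_approved": len(approved),
        "n_early_clinical": sum(1 for r in records if r.phase == "early_clinical"),
        "n_late_clinical": sum(1 for r in records if r.phase == "late_clinical"),
        "n_odd_approved": odd,
        "n_non_odd_approved": non_odd,
        "odd_share_percent": round(100.0 * odd / known, 10) if known else 0.0,
    }


def count_companies_by_country(companies: Sequence[CompanyProfile]) -> pd.DataFrame:
    """Companies headquartered per country, descending; blank/unknown HQ falls
    into an "unspecified" bucket.  Counts partition the company list."""
    buckets: dict[str, int] = {}
    for c in companies:
        country = c.hq_country.strip() or "unspecified"
        buckets[country] = buckets.get(country, 0) + 1
    df = pd.DataFrame(
        sorted(buckets.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["country", "n_companies"],
    )
    return df


def write_summary(summary: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(summary), indent=2) + "\n")
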