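"""Synthetic rare-disease ecosystem generator.

Emulates the statistical structure of a sponsor/portfolio landscape: a skewed
(power-law) distribution of developers per indication so a few diseases are
crowded, collaboration edges between sponsors, an ODD fraction near 0.35 among
approved assets, a controllable rate of company-exclusive mechanisms of action,
and heavy-tailed (log-normal) per-asset revenues.  Ground truth is planted for
parameter-recovery tests downstream (index recovery, share recovery, knockout
recounts).

Defaults mirror the study conditions: 43 companies, 295 diseases, a shared
pool of 283 MoA labels, ~14 assets per company, about a third of assets
approved, 35% of approvals carrying orphan drug designation (ODD), approvals
spanning 1995-2021, and log-normal revenues in million USD whose sum across
~200 approved assets lands near the 1.7e5 million (~170 B) scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io import CompanyProfile, InterventionRecord

__all__ = ["EcosystemConfig", "GroundTruth", "generate_ecosystem", "generate_chem_links"]

# Rough HQ-country weights for company generation (US-heavy, then EU/JP/AU),
# matching the geography of rare-disease sponsors.
_COUNTRIES = [
    ("United States", 0.40), ("Germany", 0.08), ("France", 0.08),
    ("Switzerland", 0.07), ("United Kingdom", 0.07), ("Netherlands", 0.05),
    ("Ireland", 0.05), ("Sweden", 0.04), ("Italy", 0.04), ("Spain", 0.03),
    ("Belgium", 0.03), ("Japan", 0.04), ("Australia", 0.02),
]

_MODALITIES = [
    ("targeted therapy", 0.55), ("enzyme replacement therapy", 0.12),
    ("gene therapy", 0.10), ("chemotherapy", 0.07), ("CAR-T", 0.05),
    ("antisense RNA", 0.06), ("siRNA", 0.05),
]


class EcosystemConfig(BaseModel):
    """Parameters of the synthetic landscape; validated before any generation."""

    n_companies: int = Field(default=43, ge=1)
    n_diseases: int = Field(default=295, ge=1)
    n_moas: int = Field(default=283, ge=1)
    mean_assets_per_company: float = Field(default=14.0, gt=0)
    disease_popularity_exponent: float = Field(default=1.0, gt=0)
    collaboration_prob: float = Field(default=0.3, ge=0, le=1)
    odd_fraction: float = Field(default=0.35, ge=0, le=1)
    unique_moa_fraction: float = Field(default=0.5, ge=0, le=1)
    revenue_log_mean: float = 5.5
    revenue_log_sd: float = Field(default=1.5, ge=0)
    approved_fraction: float = Field(default=0.345, ge=0, le=1)
    year_range: tuple[int, int] = (1995, 2021)
    seed: int = 0

    @model_validator(mode="after")
    def _check_years(self) -> "EcosystemConfig":
        lo, hi = self.year_range
        if lo > hi:
            raise ValueError(f"year_range {self.year_range} has start > end")
        return self


@dataclass
class GroundTruth:
    """Planted quantities, recountable from the emitted record table."""

    unique_moa_fraction_by_company: dict[str, float]
    developer_count_by_disease: dict[str, int]
    revenue_by_company: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def _weighted_choice(rng: np.random.Generator, items: Sequence[tuple[str, float]], size: int):
    labels = [x for x, _ in items]
    w = np.array([p for _, p in items], dtype=float)
    return rng.choice(labels, size=size, p=w / w.sum())


def generate_ecosystem(
    config: EcosystemConfig,
) -> tuple[list[InterventionRecord], list[CompanyProfile], GroundTruth]:
    """Generate a portfolio landscape with planted ground truth.

    Deterministic for a fixed ``config.seed``.  Independent pseudo-random
    streams are spawned per table (companies / assets / financials) so adding
    one table never perturbs another.

    Per asset: the disease is sampled with probability proportional to
    ``rank^(-disease_popularity_exponent)``; with probability
    ``unique_moa_fraction`` the asset gets a fresh company-exclusive MoA label,
    otherwise it draws from the shared pool; with probability
    ``collaboration_prob`` one collaborator is drawn uniformly from the other
    companies.  Approved assets (probability ``approved_fraction``) carry an
    ODD flag (probability ``odd_fraction``), a uniform approval year and a
    log-normal revenue; pipeline assets carry none of these.

    Shared-pool draws that end up used by a single company are deterministically
    reassigned to the most-used shared label, so "shared" is shared in fact and
    the downstream innovative index is an unbiased estimate of
    ``unique_moa_fraction``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_companies, rng_assets, rng_fin = (np.random.default_rng(s) for s in ss.spawn(3))

    width = max(3, len(str(config.n_companies)))
    companies = [
        CompanyProfile(
            name=f"Company_{i + 1:0{width}d}",
            hq_country=str(_weighted_choice(rng_companies, _COUNTRIES, 1)[0]),
        )
        for i in range(config.n_companies)
    ]
    names = [c.name for c in companies]

    diseases = [f"disease_{i + 1:04d}" for i in range(config.n_diseases)]
    ranks = np.arange(1, config.n_diseases + 1, dtype=float)
    disease_p = ranks ** (-config.disease_popularity_exponent)
    disease_p /= disease_p.sum()

    shared_pool = [f"moa_shared_{i + 1:04d}" for i in range(config.n_moas)]
    lo, hi = config.year_range

    records: list[InterventionRecord] = []
    exclusive_flag: list[bool] = []  # parallel to records; planted uniqueness
    drug_counter = 0
    for ci, company in enumerate(names):
        n_assets = max(1, int(rng_assets.poisson(config.mean_assets_per_company)))
        n_excl = 0
        for k in range(n_assets):
            drug_counter += 1
            disease = str(rng_assets.choice(diseases, p=disease_p))
            is_exclusive = bool(rng_assets.random() < config.unique_moa_fraction)
            if is_exclusive:
                n_excl += 1
                moa = f"moa_excl_{company}_{n_excl:03d}"
            else:
                moa = str(rng_assets.choice(shared_pool))
            collaborators: list[str] = []
            if config.n_companies > 1 and rng_assets.random() < config.collaboration_prob:
                others = [n for n in names if n != company]
                collaborators = [str(rng_assets.choice(others))]
            approved = bool(rng_assets.random() < config.approved_fraction)
            if approved:
                phase = "approved"
                odd: bool | None = bool(rng_fin.random() < config.odd_fraction)
                year: int | None = int(rng_fin.integers(lo, hi + 1))
                revenue: float | None = float(
                    np.exp(rng_fin.normal(config.revenue_log_mean, config.revenue_log_sd))
                )
            else:
                phase = "early_clinical" if rng_assets.random() < 0.5 else "late_clinical"
                odd, year, revenue = None, None, None
            records.append(
                InterventionRecord(
                    drug_name=f"drug_{drug_counter:05d}",
                    sponsor=company,
                    indication=disease,
                    moa=moa,
                    modality=str(_weighted_choice(rng_assets, _MODALITIES, 1)[0]),
                    phase=phase,
                    collaborators=collaborators,
                    odd_status=odd,
                    approval_year=year,
                    revenue=revenue,
                    organ_systems=[],
                )
            )
            exclusive_flag.append(is_exclusive)

    _enforce_shared_moas(records, exclusive_flag)

    truth = GroundTruth(
        unique_moa_fraction_by_company={
            name: _planted_fraction(records, exclusive_flag, name) for name in names
        },
        developer_count_by_disease=_developer_counts(records),
        revenue_by_company={
            name: float(sum(r.revenue or 0.0 for r in records if r.sponsor == name))
            for name in names
        },
    )
    return records, companies, truth


def _planted_fraction(records, flags, company) -> float:
    mine = [f for r, f in zip(records, flags) if r.sponsor == company]
    return float(sum(mine)) / len(mine) if mine else 0.0


def _developer_counts(records: Sequence[InterventionRecord]) -> dict[str, int]:
    devs: dict[str, set[str]] = {}
    for r in records:
        devs.setdefault(r.indication, set()).add(r.sponsor)
    return {d: len(s) for d, s in sorted(devs.items())}


def _enforce_shared_moas(records: list[InterventionRecord], flags: Sequence[bool]) -> None:
    """Reassign shared-pool labels used by exactly one company to the most-used
    shared label, so planted "shared" assets are shared across companies.

    Degenerate case: if every shared draw sits with one company (tiny
    ecosystems), no cross-company label exists and the draws are left as-is.
    """
    users: dict[str, set[str]] = {}
    uses: dict[str, int] = {}
    for r, excl in zip(records, flags):
        if not excl:
            users.setdefault(r.moa, set()).add(r.sponsor)
            uses[r.moa] = uses.get(r.moa, 0) + 1
    multi = {m for m, s in users.items() if len(s) > 1}
    if not multi:
        return
    anchor = max(multi, key=lambda m: (uses[m], m))
    lonely = {m for m, s in users.items() if len(s) == 1}
    for r, excl in zip(records, flags):
        if not excl and r.moa in lonely:
            r.moa = anchor


def generate_chem_links(
    records: Sequence[InterventionRecord],
    targets_per_drug: int = 5,
    shared_target_prob: float = 0.3,
    seed: int = 0,
    score_range: tuple[float, float] = (0.15, 0.999),
) -> pd.DataFrame:
    """Emit a STITCH-dialect chemical-protein link table for the approved drugs.

    Each approved drug receives ``targets_per_drug`` protein links with
    confidence scores uniform on ``score_range``; with probability
    ``shared_target_prob`` a link reuses a protein already linked to another
    drug, creating drug-drug connectivity through shared targets.  Drug
    repurposing is emulated by generating the non-ODD subset with a higher
    ``shared_target_prob`` than the ODD subset (two calls on the two subsets).

    Returns a frame with columns (chemical, partner, partner_kind,
    combined_score), real-score dialect.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    if not 0 <= shared_target_prob <= 1:
        raise ValueError("shared_target_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    drugs = sorted({r.drug_name for r in records if r.phase == "approved"})
    rows = []
    protein_counter = 0
    protein_owner: dict[str, str] = {}  # protein -> first drug linked
    for drug in drugs:
        for _ in range(targets_per_drug):
            reusable = [p for p, owner in protein_owner.items() if owner != drug]
            if reusable and rng.random() < shared_target_prob:
                protein = str(rng.choice(reusable))
            else:
                protein_counter += 1
                protein = f"PROT_{protein_counter:05d}"
                protein_owner[protein] = drug
            score = float(rng.uniform(*score_range))
            rows.append((drug, protein, "protein", round(score, 3)))
    return pd.DataFrame(rows, columns=["chemical", "partner", "partner_kind", "combined_score"])
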