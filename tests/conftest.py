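import pytest

from rdlandscape import AliasMap, CompanyProfile, InterventionRecord


def rec(drug, sponsor, disease, moa, phase="early_clinical", collaborators=(),
        odd=None, year=None, revenue=None, modality="targeted therapy", organs=()):
    return InterventionRecord(
        drug_name=drug, sponsor=sponsor, indication=disease, moa=moa,
        modality=modality, phase=phase, collaborators=list(collaborators),
        odd_status=odd, approval_year=year, revenue=revenue,
        organ_systems=list(organs),
    )


@pytest.fixture
def toy_records():
    """Five programs, two sponsors (plus one collaborator), three diseases.

    Alpha has three pipeline programs (two on the contested disease d1);
    Beta has one pipeline program on d1 and one approved asset on d3.
    """
    return [
        rec("drug_a1", "Alpha", "d1", "m_shared"),
        rec("drug_a2", "Alpha", "d1", "m_alpha_only", collaborators=["Gamma"]),
        rec("drug_a3", "Alpha", "d2", "m_alpha2"),
        rec("drug_b1", "Beta", "d1", "m_shared"),
        rec("drug_b2", "Beta", "d3", "m_beta", phase="approved", odd=True,
            year=2019, revenue=120.0),
    ]


@pytest.fixture
def toy_companies():
    return [
        CompanyProfile("Bristol-Myers Squibb", "United States"),
        CompanyProfile("Celgene", "United States", parent="Bristol-Myers Squibb"),
        CompanyProfile("AstraZeneca", "United Kingdom"),
        CompanyProfile("Alexion", "United States", parent="AstraZeneca"),
        CompanyProfile("Alpha", "France"),
        CompanyProfile("Beta", "France"),
    ]


@pytest.fixture
def toy_aliases():
    amap = AliasMap()
    amap.add("company", "Roche", "Hoffmann-La Roche AG")
    amap.add("company", "Hoffmann-La Roche AG", "Hoffmann-La Roche AG")
    amap.add("disease", "CF", "cystic fibrosis")
    amap.add("moa", "CFTR act.", "CFTR activator")
    return amap
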