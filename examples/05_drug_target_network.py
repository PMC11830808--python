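"""Drug-target network contrast: first-in-class vs repurposed drug sets.

Drugs developed specifically for rare diseases tend to hit unique targets
(sparse networks); repurposed drugs share targets with their original
indications (dense networks).  The generator emulates this with a low vs
high shared-target probability, and the metrics quantify the contrast.
"""

import rdlandscape as rd

records, _, _ = rd.generate_ecosystem(
    rd.EcosystemConfig(n_companies=10, mean_assets_per_company=6,
                       approved_fraction=1.0, seed=5))
drugs = sorted({r.drug_name for r in records})


def metrics(shared_target_prob):
    frame = rd.generate_chem_links(records, shared_target_prob=shared_target_prob,
                                   seed=5)
    links = [rd.ChemProteinLink(*row) for row in frame.itertuples(index=False)]
    net = rd.build_chem_network(drugs, links, min_score=0.15)
    return rd.network_metrics(net)


sparse = metrics(0.05)   # first-in-class-like: almost all targets private
dense = metrics(0.60)    # repurposed-like: targets widely shared

for label, m in (("first-in-class-like", sparse), ("repurposed-like", dense)):
    print(f"{label}: density={m.density:.4f}  mean_degree={m.mean_degree:.2f}  "
          f"components={m.n_components}  shared_protein_pairs={m.shared_protein_pairs}")

report = rd.compare_groups(dense, sparse)
wins = sum(v == "a" for v in report["denser"].values())
print(f"\nrepurposed-like network denser/more connected in {wins} of 4 metrics")
print("(this is the operational signature of drug repositioning: shared",
      "targets knit the chemical network together)")
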