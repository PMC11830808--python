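"""STITCH-dialect parsing and drug-target network metrics."""

import itertools

import pandas as pd
import pytest

import rdlandscape as rd
from rdlandscape.chemnet import pathway_membership
from tests.conftest import rec


def links_from(rows):
    return [rd.ChemProteinLink(*row) for row in rows]


def write_tsv(path, rows, cols=("chemical", "partner", "combined_score")):
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep="\t", index=False)


class TestStitchParsing:
    def test_integer_dialect_normalized(self, tmp_path):
        p = tmp_path / "links.tsv"
        write_tsv(p, [("CID1", "9606.ENSP1", 900), ("CID2", "9606.ENSP2", 150)])
        links, info = rd.read_stitch_links(p)
        assert info["dialect"] == "integer"
        assert [l.score for l in links] == [0.9, 0.15]
        assert all(l.partner_kind == "protein" for l in links)

    def test_real_dialect_identity(self, tmp_path):
        p = tmp_path / "links.tsv"
        write_tsv(p, [("CID1", "9606.ENSP1", 0.73)])
        links, info = rd.read_stitch_links(p)
        assert info["dialect"] == "real" and links[0].score == 0.73

    def test_out_of_range_score_rejected(self, tmp_path):
        p = tmp_path / "links.tsv"
        write_tsv(p, [("CID1", "9606.ENSP1", 900), ("CID2", "9606.ENSP2", 1500)])
        links, info = rd.read_stitch_links(p)
        assert len(links) == 1 and info["n_rejected"] == 1

    def test_mixed_dialects_error(self, tmp_path):
        p = tmp_path / "links.tsv"
        write_tsv(p, [("CID1", "9606.ENSP1", 900), ("CID2", "9606.ENSP2", 0.73)])
        with pytest.raises(ValueError, match="dialect"):
            rd.read_stitch_links(p)

    def test_chemical_partner_inferred(self, tmp_path):
        p = tmp_path / "links.tsv"
        write_tsv(p, [("CID1", "CID2", 0.8)])
        links, _ = rd.read_stitch_links(p)
        assert links[0].partner_kind == "chemical"

    def test_dialect_round_trip(self, tmp_path):
        original = links_from([("CID1", "9606.ENSP1", "protein", 0.9),
                               ("CID1", "CID2", "chemical", 0.415)])
        int_path = tmp_path / "int.tsv"
        rd.write_stitch_links(original, int_path, dialect="integer")
        reread, info = rd.read_stitch_links(int_path)
        assert info["dialect"] == "integer"
        assert [(l.chemical, l.partner, l.partner_kind, l.score) for l in reread] == [
            (l.chemical, l.partner, l.partner_kind, l.score) for l in original]


class TestBuild:
    def test_shared_protein_counted_not_edged(self):
        links = links_from([("dA", "P1", "protein", 0.8), ("dB", "P1", "protein", 0.8)])
        net = rd.build_chem_network(["dA", "dB"], links, min_score=0.4)
        m = rd.network_metrics(net)
        assert m.n_edges == 2 and m.shared_protein_pairs == 1
        kinds = {d["kind"] for _, _, d in net.graph.edges(data=True)}
        assert kinds == {"drug-protein"}

    def test_threshold_one_gives_edgeless_isolated_network(self):
        links = links_from([("dA", "P1", "protein", 0.8)])
        net = rd.build_chem_network(["dA", "dB"], links, min_score=1.0)
        m = rd.network_metrics(net)
        assert m.n_edges == 0 and m.isolated_drug_fraction == 1.0

    def test_threshold_zero_keeps_everything(self):
        links = links_from([("dA", "P1", "protein", 0.01), ("dA", "dB", "chemical", 0.2)])
        net = rd.build_chem_network(["dA", "dB"], links, min_score=0.0)
        assert net.graph.number_of_edges() == 2

    def test_drug_drug_edges_from_explicit_chemical_links(self):
        links = links_from([("dA", "dB", "chemical", 0.9)])
        net = rd.build_chem_network(["dA", "dB"], links)
        assert net.graph.edges["dA", "dB"]["kind"] == "drug-drug"

    def test_unlisted_drugs_ignored(self):
        links = links_from([("ghost", "P1", "protein", 0.9)])
        net = rd.build_chem_network(["dA"], links)
        assert net.graph.number_of_nodes() == 1

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError):
            rd.build_chem_network([], [])


class TestMetrics:
    def test_density_formula(self):
        links = links_from([("dA", "P1", "protein", 0.9), ("dB", "P1", "protein", 0.9),
                            ("dA", "dB", "chemical", 0.9)])
        net = rd.build_chem_network(["dA", "dB", "dC"], links)
        m = rd.network_metrics(net)
        assert m.density == pytest.approx(2 * 3 / (4 * 3))

    def test_edgeless_network(self):
        net = rd.build_chem_network(list("abcde"), [])
        m = rd.network_metrics(net)
        assert m.n_components == 5 and m.mean_degree == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_small_networks(self, seed):
        import numpy as np
        rng = np.random.default_rng(seed)
        drugs = [f"d{i}" for i in range(6)]
        proteins = [f"P{i}" for i in range(10)]
        rows = [(str(rng.choice(drugs)), str(rng.choice(proteins)), "protein",
                 float(rng.uniform(0.2, 1.0))) for _ in range(25)]
        net = rd.build_chem_network(drugs, links_from(rows), min_score=0.4)
        m = rd.network_metrics(net)
        # brute-force adjacency recount
        nodes = sorted(net.graph.nodes)
        adj = {n: set(net.graph.neighbors(n)) for n in nodes}
        edges = sum(len(v) for v in adj.values()) // 2
        assert m.n_edges == edges
        assert m.mean_degree == pytest.approx(2 * edges / len(nodes))
        assert m.density == pytest.approx(
            2 * edges / (len(nodes) * (len(nodes) - 1)))
        # component count by traversal
        seen, comps = set(), 0
        for n in nodes:
            if n not in seen:
                comps += 1
                stack = [n]
                while stack:
                    cur = stack.pop()
                    if cur in seen:
                        continue
                    seen.add(cur)
                    stack.extend(adj[cur])
        assert m.n_components == comps
        # shared-protein pairs by brute force over drug pairs
        drug_nodes = [n for n in nodes if net.graph.nodes[n]["kind"] == "drug"]
        pairs = sum(
            1 for a, b in itertools.combinations(drug_nodes, 2)
            if any(net.graph.nodes[p]["kind"] == "protein" for p in adj[a] & adj[b])
        )
        assert m.shared_protein_pairs == pairs

    def test_threshold_monotonicity(self):
        import numpy as np
        rng = np.random.default_rng(1)
        drugs = [f"d{i}" for i in range(8)]
        rows = [(str(rng.choice(drugs)), f"P{int(rng.integers(0, 12))}", "protein",
                 float(rng.uniform(0, 1))) for _ in range(60)]
        links = links_from(rows)
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            m = rd.network_metrics(rd.build_chem_network(drugs, links, min_score=thr))
            if prev is not None:
                assert m.n_edges <= prev.n_edges
                assert m.density <= prev.density
                assert m.mean_degree <= prev.mean_degree
            prev = m


class TestCompare:
    def _metrics(self, shared_prob, seed):
        records, _, _ = rd.generate_ecosystem(
            rd.EcosystemConfig(n_companies=8, mean_assets_per_company=5,
                               approved_fraction=1.0, seed=seed))
        frame = rd.generate_chem_links(records, shared_target_prob=shared_prob,
                                       seed=seed)
        links = links_from(list(frame.itertuples(index=False)))
        drugs = sorted({r.drug_name for r in records})
        return rd.network_metrics(rd.build_chem_network(drugs, links, min_score=0.15))

    def test_identical_inputs_zero_difference(self):
        m = self._metrics(0.3, 0)
        report = rd.compare_groups(m, m)
        assert all(v == 0 for v in report["differences"].values())

    def test_antisymmetry(self):
        a, b = self._metrics(0.5, 1), self._metrics(0.05, 1)
        ab = rd.compare_groups(a, b)["differences"]
        ba = rd.compare_groups(b, a)["differences"]
        assert all(ab[k] == -ba[k] for k in ab)

    def test_threshold_mismatch_error(self):
        a = self._metrics(0.3, 2)
        b = rd.NetworkMetrics(**{**a.as_dict(), "min_score": 0.7})
        with pytest.raises(ValueError, match="threshold"):
            rd.compare_groups(a, b)

    def test_repurposed_like_group_denser(self):
        # high shared-target probability (repurposing) vs low (first-in-class)
        wins = 0
        for seed in range(5):
            dense, sparse = self._metrics(0.6, seed), self._metrics(0.05, seed)
            verdict = rd.compare_groups(dense, sparse)["denser"]
            wins += sum(v == "a" for v in verdict.values()) >= 3
        assert wins == 5


class TestTopMoa:
    def approved(self, moa_counts, odd):
        out = []
        for moa, k in moa_counts.items():
            for i in range(k):
                out.append(rec(f"{moa}_{i}", "A", "x", moa, phase="approved",
                               odd=odd, year=2000))
        return out

    def test_ranked_with_counts(self):
        records = self.approved({"m1": 3, "m2": 1}, odd=True)
        df = rd.top_moa_counts(records, odd=True, n=30)
        assert list(map(tuple, df.itertuples(index=False))) == [("m1", 3), ("m2", 1)]

    def test_n_one(self):
        records = self.approved({"m1": 3, "m2": 1}, odd=True)
        assert list(rd.top_moa_counts(records, odd=True, n=1)["moa"]) == ["m1"]

    def test_tie_at_cutoff_resolves_alphabetically(self):
        records = self.approved({"a_moa": 2, "b_moa": 1, "c_moa": 1}, odd=False)
        df = rd.top_moa_counts(records, odd=False, n=2)
        assert list(df["moa"]) == ["a_moa", "b_moa"]

    def test_group_filter(self):
        records = (self.approved({"odd_moa": 2}, odd=True)
                   + self.approved({"non_moa": 5}, odd=False))
        assert list(rd.top_moa_counts(records, odd=True)["moa"]) == ["odd_moa"]


class TestPathways:
    def test_membership_counts(self):
        links = links_from([("dA", "P1", "protein", 0.9), ("dA", "P2", "protein", 0.9)])
        net = rd.build_chem_network(["dA"], links)
        df = pathway_membership(net, {"P1": ["glycolysis"], "P2": ["glycolysis", "tca"]})
        assert dict(zip(df["pathway"], df["n_proteins"])) == {"glycolysis": 2, "tca": 1}
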