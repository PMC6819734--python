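"""Per-host networks, rank merging, host aggregation, comparison, IO."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microgame.interaction_scores import build_pair_table
from microgame.network_builder import (
    MUTUALISM,
    PARASITISM,
    InteractionNetwork,
    aggregate_from_values,
    aggregate_over_hosts,
    merge_to_rank,
    merged_element_values,
    network_correlation,
    per_host_network,
    read_network,
    write_network,
)
from microgame.taxa_io import AbundanceMatrix, TaxonomyTable, ValidationError


def community(n_genera, phyla, seed=0, n_samples=4):
    """Random lognormal community with genera assigned to given phyla."""
    rng = np.random.default_rng(seed)
    taxa = [f"g{i:02d}" for i in range(n_genera)]
    assign = [phyla[i % len(phyla)] for i in range(n_genera)]
    ab = AbundanceMatrix(pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(n_genera, n_samples)),
        index=taxa, columns=[f"s{j}" for j in range(n_samples)],
    ))
    tax = TaxonomyTable(pd.DataFrame({"genus": taxa, "phylum": assign}, index=taxa))
    return ab, tax


class TestPerHostNetwork:
    def test_two_taxa_single_edge_weight_is_two(self):
        ab = AbundanceMatrix(pd.DataFrame(
            [[math.e], [math.e]], index=["a", "b"], columns=["s1"]
        ))
        tax = TaxonomyTable(pd.DataFrame({"genus": ["a", "b"], "phylum": ["P", "P"]},
                                         index=["a", "b"]))
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        net = per_host_network(pt, "s1", MUTUALISM)
        assert net.edges == {("a", "b"): pytest.approx(2.0)}
        assert net.nodes == {}

    def test_equal_abundances_give_zero_signed_parasitism(self):
        ab, tax = community(6, ["P1", "P2"])
        ab.df["s0"] = 3.7
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        net = per_host_network(pt, "s0", PARASITISM)
        assert all(w == pytest.approx(0.0) for w in net.edges.values())

    def test_complete_graph_size(self):
        ab, tax = community(10, ["P1", "P2", "P3"])
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        net = per_host_network(pt, "s1", MUTUALISM)
        assert len(net.node_set) == 10 and len(net.edges) == 45

    def test_unknown_sample_rejected(self):
        ab, tax = community(4, ["P1"])
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        with pytest.raises(ValidationError, match="nope"):
            per_host_network(pt, "nope", MUTUALISM)


def brute_force_merge(net, mapping, interaction):
    """Independent re-derivation: plain means over qualifying genus pairs."""
    clades = sorted(set(mapping.values()))
    nodes, edges = {}, {}
    for c in clades:
        vals = [w for (a, b), w in net.edges.items() if mapping[a] == c and mapping[b] == c]
        if vals:
            nodes[c] = sum(vals) / len(vals)
    for c, d in itertools.combinations(clades, 2):
        vals = []
        for (a, b), w in net.edges.items():
            ca, cb = mapping[a], mapping[b]
            if {ca, cb} == {c, d}:
                if interaction == PARASITISM and (ca, cb) != (c, d):
                    w = -w
                vals.append(w)
        if vals:
            edges[(c, d)] = sum(vals) / len(vals)
    return nodes, edges


class TestMergeToRank:
    def test_one_genus_per_phylum_is_identity_relabeling(self):
        ab, tax = community(4, ["P1", "P2", "P3", "P4"])
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        for interaction in (MUTUALISM, PARASITISM):
            net = per_host_network(pt, "s0", interaction)
            merged = merge_to_rank(net, tax, "phylum")
            mapping = tax.clade_of("phylum")
            assert merged.nodes == {}
            for (a, b), w in net.edges.items():
                ca, cb = sorted((mapping[a], mapping[b]))
                expect = w
                if interaction == PARASITISM and (mapping[a], mapping[b]) != (ca, cb):
                    expect = -w
                assert merged.edges[(ca, cb)] == pytest.approx(expect)

    def test_two_genus_phylum_node_weight_is_its_single_pair_edge(self):
        ab, tax = community(4, ["P1", "P1", "P2", "P2"][:2] * 2, seed=3)
        # g00,g02 -> P1; g01,g03 -> P2 per round-robin; rebuild explicitly:
        tax = TaxonomyTable(pd.DataFrame(
            {"genus": ["g00", "g01", "g02", "g03"],
             "phylum": ["P1", "P1", "P2", "P2"]},
            index=["g00", "g01", "g02", "g03"]))
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        net = per_host_network(pt, "s0", MUTUALISM)
        merged = merge_to_rank(net, tax, "phylum")
        assert merged.nodes["P1"] == pytest.approx(net.edges[("g00", "g01")])
        assert merged.nodes["P2"] == pytest.approx(net.edges[("g02", "g03")])

    @pytest.mark.parametrize("interaction", [MUTUALISM, PARASITISM])
    def test_against_brute_force_oracle(self, interaction):
        ab, tax = community(10, ["P1", "P2", "P3"], seed=42)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        mapping = tax.clade_of("phylum").to_dict()
        for sample in pt.samples:
            net = per_host_network(pt, sample, interaction)
            merged = merge_to_rank(net, tax, "phylum")
            nodes, edges = brute_force_merge(net, mapping, interaction)
            assert set(merged.nodes) == set(nodes) and set(merged.edges) == set(edges)
            for k in nodes:
                assert merged.nodes[k] == pytest.approx(nodes[k], abs=1e-12)
            for k in edges:
                assert merged.edges[k] == pytest.approx(edges[k], abs=1e-12)

    def test_merge_is_mean_preserving_over_cross_pairs(self):
        """Pair-count-weighted mean of merged between-clade edges equals the
        mean of the underlying cross-clade genus-pair weights."""
        ab, tax = community(9, ["P1", "P2", "P3"], seed=1)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        mapping = tax.clade_of("phylum").to_dict()
        net = per_host_network(pt, "s0", MUTUALISM)
        merged = merge_to_rank(net, tax, "phylum")
        cross = [w for (a, b), w in net.edges.items() if mapping[a] != mapping[b]]
        counts = {}
        for (a, b) in net.edges:
            ca, cb = sorted((mapping[a], mapping[b]))
            if ca != cb:
                counts[(ca, cb)] = counts.get((ca, cb), 0) + 1
        weighted = sum(merged.edges[k] * counts[k] for k in merged.edges) / sum(counts.values())
        assert weighted == pytest.approx(np.mean(cross), abs=1e-12)

    def test_rank_not_above_rejected(self):
        ab, tax = community(4, ["P1", "P2"])
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        net = per_host_network(pt, "s0", MUTUALISM)
        with pytest.raises(ValidationError):
            merge_to_rank(net, tax, "genus")

    @pytest.mark.parametrize("interaction", [MUTUALISM, PARASITISM])
    def test_fast_path_matches_per_network_merge(self, interaction):
        ab, tax = community(8, ["P1", "P2", "P3"], seed=9)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        node_vals, edge_vals = merged_element_values(pt, "phylum", interaction)
        for sample in pt.samples:
            merged = merge_to_rank(per_host_network(pt, sample, interaction), tax, "phylum")
            for k, w in merged.nodes.items():
                assert node_vals.loc[k, sample] == pytest.approx(w, abs=1e-12)
            for k, w in merged.edges.items():
                assert edge_vals.loc[[k], sample].iloc[0] == pytest.approx(w, abs=1e-12)


class TestAggregateOverHosts:
    def test_single_host_equals_itself_with_flagged_variance(self):
        net = InteractionNetwork("phylum", MUTUALISM, nodes={"P1": 2.0},
                                 edges={("P1", "P2"): 1.0})
        agg = aggregate_over_hosts([net], group="winter")
        assert agg.nodes == net.nodes and agg.edges == net.edges
        assert math.isnan(agg.edge_var[("P1", "P2")])
        assert agg.edge_n[("P1", "P2")] == 1

    def test_two_hosts_mean_and_unbiased_variance(self):
        nets = [
            InteractionNetwork("phylum", MUTUALISM, edges={("A", "B"): w})
            for w in (1.0, 3.0)
        ]
        agg = aggregate_over_hosts(nets)
        assert agg.edges[("A", "B")] == pytest.approx(2.0)
        assert agg.edge_var[("A", "B")] == pytest.approx(2.0)

    def test_thirty_hosts_match_brute_force_means(self):
        rng = np.random.default_rng(8)
        weights = rng.normal(0, 1, size=(30, 3))
        keys = [("A", "B"), ("A", "C"), ("B", "C")]
        nets = [
            InteractionNetwork("phylum", PARASITISM,
                               edges=dict(zip(keys, row)))
            for row in weights
        ]
        agg = aggregate_over_hosts(nets, group="g")
        for j, k in enumerate(keys):
            assert agg.edges[k] == pytest.approx(weights[:, j].mean())
            assert agg.edge_var[k] == pytest.approx(weights[:, j].var(ddof=1))
            assert agg.edge_n[k] == 30

    def test_direction_disagreement_fraction(self):
        nets = [
            InteractionNetwork("phylum", PARASITISM, edges={("A", "B"): w})
            for w in (1.0, 2.0, -0.5, 3.0)
        ]
        agg = aggregate_over_hosts(nets)
        assert agg.direction_disagreement[("A", "B")] == pytest.approx(0.25)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_over_hosts([])

    def test_merge_then_aggregate_commutes_with_aggregate_then_merge(self):
        """Both orders are means over the same multiset of pair values."""
        ab, tax = community(8, ["P1", "P2", "P3"], seed=4, n_samples=6)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        for interaction in (MUTUALISM, PARASITISM):
            per_host = [per_host_network(pt, s, interaction) for s in pt.samples]
            merged_first = aggregate_over_hosts(
                [merge_to_rank(n, tax, "phylum") for n in per_host]
            )
            aggregated_first = merge_to_rank(aggregate_over_hosts(per_host), tax, "phylum")
            for k in merged_first.edges:
                assert merged_first.edges[k] == pytest.approx(aggregated_first.edges[k], abs=1e-12)
            for k in merged_first.nodes:
                assert merged_first.nodes[k] == pytest.approx(aggregated_first.nodes[k], abs=1e-12)

    def test_fast_aggregate_matches_network_route(self):
        ab, tax = community(8, ["P1", "P2", "P3"], seed=5, n_samples=6)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        for interaction in (MUTUALISM, PARASITISM):
            node_vals, edge_vals = merged_element_values(pt, "phylum", interaction)
            fast = aggregate_from_values(node_vals, edge_vals, "phylum", interaction,
                                         samples=pt.samples)
            slow = aggregate_over_hosts(
                [merge_to_rank(per_host_network(pt, s, interaction), tax, "phylum")
                 for s in pt.samples]
            )
            for k in slow.edges:
                assert fast.edges[k] == pytest.approx(slow.edges[k], abs=1e-12)
                assert fast.edge_var[k] == pytest.approx(slow.edge_var[k], abs=1e-12)
            for k in slow.nodes:
                assert fast.nodes[k] == pytest.approx(slow.nodes[k], abs=1e-12)


class TestNetworkCorrelation:
    def fixture_pair(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        keys = list(itertools.combinations([f"P{i}" for i in range(n)], 2))
        a = InteractionNetwork("phylum", MUTUALISM,
                               nodes={f"P{i}": rng.normal() for i in range(n)},
                               edges={k: rng.normal() for k in keys})
        b = InteractionNetwork("phylum", MUTUALISM,
                               nodes={f"P{i}": rng.normal() for i in range(n)},
                               edges={k: rng.normal() for k in keys})
        return a, b

    def test_self_correlation_is_one(self):
        a, _ = self.fixture_pair()
        r, _, n = network_correlation(a, a)
        assert r == pytest.approx(1.0) and n == 28

    def test_negation_gives_minus_one(self):
        a, _ = self.fixture_pair()
        neg = InteractionNetwork("phylum", MUTUALISM,
                                 edges={k: -w for k, w in a.edges.items()})
        r, _, _ = network_correlation(a, neg)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        a, b = self.fixture_pair(seed=3)
        for elements, m in (("edges", 28), ("both", 36), ("nodes", 8)):
            r, ci, n = network_correlation(a, b, elements=elements)
            xs, ys = [], []
            if elements in ("edges", "both"):
                xs += [a.edges[k] for k in sorted(a.edges)]
                ys += [b.edges[k] for k in sorted(b.edges)]
            if elements in ("nodes", "both"):
                xs += [a.nodes[k] for k in sorted(a.nodes)]
                ys += [b.nodes[k] for k in sorted(b.nodes)]
            assert n == m
            assert r == pytest.approx(np.corrcoef(xs, ys)[0, 1], abs=1e-12)
            assert ci[0] < r < ci[1]

    def test_symmetric_in_arguments(self):
        a, b = self.fixture_pair(seed=5)
        assert network_correlation(a, b)[0] == pytest.approx(network_correlation(b, a)[0])

    def test_too_few_shared_elements_rejected(self):
        a = InteractionNetwork("phylum", MUTUALISM, edges={("A", "B"): 1.0})
        with pytest.raises(ValidationError):
            network_correlation(a, a)


class TestSerialization:
    def agg(self):
        ab, tax = community(8, ["P1", "P2", "P3"], seed=6, n_samples=5)
        pt = build_pair_table(ab, tax, pseudocount=0.0)
        out = {}
        for interaction in (MUTUALISM, PARASITISM):
            node_vals, edge_vals = merged_element_values(pt, "phylum", interaction)
            out[interaction] = aggregate_from_values(
                node_vals, edge_vals, "phylum", interaction, group="winter",
                samples=pt.samples,
            )
        return out

    def test_graphml_round_trip_preserves_weights_and_provenance(self, tmp_path):
        for interaction, net in self.agg().items():
            p = tmp_path / f"{interaction}.graphml"
            write_network(net, p, "graphml")
            back = read_network(p)
            assert back.rank == net.rank and back.interaction == net.interaction
            assert back.group == "winter" and back.n_hosts == net.n_hosts
            for k, w in net.edges.items():
                assert back.edges[k] == pytest.approx(w, abs=1e-12)
                assert back.edge_var[k] == pytest.approx(net.edge_var[k], abs=1e-12)
                assert back.edge_n[k] == net.edge_n[k]
            for k, w in net.nodes.items():
                assert back.nodes[k] == pytest.approx(w, abs=1e-12)

    def test_directed_parasitism_edge_source_matches_sign(self, tmp_path):
        net = self.agg()[PARASITISM]
        g = net.to_networkx()
        assert g.is_directed()
        for u, v, attrs in g.edges(data=True):
            assert attrs["signed_weight"] >= 0 or (u, v) == (attrs["clade_2"], attrs["clade_1"])
            key = tuple(sorted((u, v)))
            if net.edges[key] > 0:
                assert u == key[0]
            elif net.edges[key] < 0:
                assert u == key[1]

    def test_eight_node_edge_tsv_has_28_edge_rows(self, tmp_path):
        rng = np.random.default_rng(1)
        keys = list(itertools.combinations([f"P{i}" for i in range(8)], 2))
        net = InteractionNetwork("phylum", MUTUALISM,
                                 edges={k: rng.normal() for k in keys})
        p = tmp_path / "net.tsv"
        write_network(net, p, "edge_tsv")
        df = pd.read_csv(p, sep="\t")
        assert (df["element_type"] == "edge").sum() == 28
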