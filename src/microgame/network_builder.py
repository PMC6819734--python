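"""Interaction networks: per-host construction, rank merging, aggregation.

A per-host network at the lowest rank is the complete graph on the taxa of
one sample, with the pairwise mutualism value (undirected) or signed
parasitism value (directed by sign) as edge weights. Networks are merged to
a coarser rank by averaging: the node weight of a clade is the mean of the
lower-rank edge weights over pairs inside the clade, and the edge weight
between two clades is the mean over the cross pairs (signed parasitism
values oriented consistently, clade-1 side minus clade-2 side under the
sorted clade-pair key). Host-level networks are aggregated within a group
(e.g. season) by element-wise means, keeping the across-host variance and n
per element for the significance machinery.

Merging and host aggregation are both plain means over the same multiset of
underlying pair values, so they commute; this is exploited for a fast
vectorised path (`merged_element_values`) and checked in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .interaction_scores import PairTable
from .taxa_io import TaxonomyTable, ValidationError, rank_is_above

logger = logging.getLogger("microgame")

MUTUALISM = "mutualism"
PARASITISM = "parasitism"


def _canon(a, b) -> tuple:
    """Canonical unordered edge key (lexicographic)."""
    return (a, b) if str(a) <= str(b) else (b, a)


@dataclass
class InteractionNetwork:
    """Weighted interaction network on clades at one taxonomic rank.

    Edge keys are canonical sorted clade pairs. For parasitism the edge
    weight is signed, read as (first clade) minus (second clade); the
    implied direction is the sign of the weight. Aggregated networks carry
    per-element across-host variance and count, plus (parasitism) the
    fraction of hosts whose per-host direction disagrees with the aggregate.
    """

    rank: str
    interaction: str
    nodes: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)
    group: str | None = None
    sample: str | None = None
    n_hosts: int = 1
    node_var: dict = field(default_factory=dict)
    edge_var: dict = field(default_factory=dict)
    node_n: dict = field(default_factory=dict)
    edge_n: dict = field(default_factory=dict)
    direction_disagreement: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interaction not in (MUTUALISM, PARASITISM):
            raise ValidationError(
                f"interaction must be {MUTUALISM!r} or {PARASITISM!r}, got {self.interaction!r}"
            )

    @property
    def node_set(self) -> set:
        s = set(self.nodes)
        for a, b in self.edges:
            s.add(a)
            s.add(b)
        return s

    def edge_direction(self, key) -> str:
        """Parasitism direction of a canonical edge: who exploits whom."""
        w = self.edges[key]
        if self.interaction != PARASITISM or w == 0:
            return "none"
        a, b = key
        return f"{a}->{b}" if w > 0 else f"{b}->{a}"

    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        """GraphML-ready graph; parasitism edges run exploiter -> exploited."""
        g: nx.Graph | nx.DiGraph
        g = nx.DiGraph() if self.interaction == PARASITISM else nx.Graph()
        g.graph.update(
            rank=self.rank,
            interaction=self.interaction,
            group="" if self.group is None else str(self.group),
            sample="" if self.sample is None else str(self.sample),
            n_hosts=int(self.n_hosts),
        )
        for node in sorted(self.node_set, key=str):
            attrs = {}
            if node in self.nodes:
                attrs["weight"] = float(self.nodes[node])
            if node in self.node_var and not math.isnan(self.node_var.get(node, float("nan"))):
                attrs["variance"] = float(self.node_var[node])
            if node in self.node_n:
                attrs["n"] = int(self.node_n[node])
            g.add_node(node, **attrs)
        for (a, b), w in sorted(self.edges.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
            src, dst = ((a, b) if w >= 0 else (b, a)) if self.interaction == PARASITISM else (a, b)
            attrs = {"weight": abs(float(w)) if self.interaction == PARASITISM else float(w),
                     "signed_weight": float(w), "clade_1": str(a), "clade_2": str(b)}
            if (a, b) in self.edge_var and not math.isnan(self.edge_var.get((a, b), float("nan"))):
                attrs["variance"] = float(self.edge_var[(a, b)])
            if (a, b) in self.edge_n:
                attrs["n"] = int(self.edge_n[(a, b)])
            if (a, b) in self.direction_disagreement:
                attrs["direction_disagreement"] = float(self.direction_disagreement[(a, b)])
            g.add_edge(src, dst, **attrs)
        return g


def per_host_network(pair_table: PairTable, sample, interaction: str) -> InteractionNetwork:
    """Complete lowest-rank network of one host/sample.

    Nodes are the taxa (no node weights at the lowest rank); edge weights are
    the per-pair mutualism values or signed parasitism values of `sample`.
    """
    if sample not in pair_table.samples:
        raise ValidationError(f"unknown sample {sample!r}")
    values = (pair_table.y_plus if interaction == MUTUALISM else pair_table.y_minus)[sample]
    edges = {
        _canon(a, b): float(v)
        for a, b, v in zip(
            pair_table.pairs["taxon_a"], pair_table.pairs["taxon_b"], values
        )
    }
    net = InteractionNetwork(
        rank=pair_table.lowest_rank, interaction=interaction, edges=edges, sample=str(sample)
    )
    return net


def _node_mapping(network: InteractionNetwork, taxonomy: TaxonomyTable, rank: str) -> dict:
    nodes = network.node_set
    tax_index = set(map(str, taxonomy.table.index))
    if all(str(n) in tax_index for n in nodes):
        clade = taxonomy.clade_of(rank)
        return {n: clade.loc[str(n)] for n in nodes}
    mapping = taxonomy.map_between(network.rank, rank)
    missing = [n for n in nodes if n not in mapping]
    if missing:
        raise ValidationError(f"nodes not mappable to rank {rank!r}: {missing[:10]}")
    return {n: mapping[n] for n in nodes}


def merge_to_rank(
    network: InteractionNetwork, taxonomy: TaxonomyTable, rank: str
) -> InteractionNetwork:
    """Average a network up to a strictly higher rank.

    Node weight of clade C = mean edge weight over lower-rank pairs inside C
    (absent for singleton clades); edge weight (C, D) = mean over cross pairs,
    parasitism values oriented C-side minus D-side under the sorted key.
    """
    if not rank_is_above(rank, network.rank):
        raise ValidationError(
            f"target rank {rank!r} is not above network rank {network.rank!r}"
        )
    mapping = _node_mapping(network, taxonomy, rank)
    node_acc: dict = {}
    edge_acc: dict = {}
    for (a, b), w in network.edges.items():
        ca, cb = mapping[a], mapping[b]
        if ca == cb:
            node_acc.setdefault(ca, []).append(w)
        else:
            key = _canon(ca, cb)
            if network.interaction == PARASITISM and (ca, cb) != key:
                w = -w
            edge_acc.setdefault(key, []).append(w)
    clades = set(mapping.values())
    for c in clades:
        members = sum(1 for n in mapping.values() if n == c)
        if members >= 2 and c not in node_acc:
            logger.info("clade %r has no within-clade pairs in the network", c)
    expected_edges = {(c, d) for c in clades for d in clades if str(c) < str(d)}
    for key in expected_edges - set(edge_acc):
        logger.info("clade pair %r has no cross pairs; edge absent", key)
    return InteractionNetwork(
        rank=rank,
        interaction=network.interaction,
        nodes={c: float(np.mean(v)) for c, v in node_acc.items()},
        edges={k: float(np.mean(v)) for k, v in edge_acc.items()},
        group=network.group,
        sample=network.sample,
        n_hosts=network.n_hosts,
    )


def merged_element_values(
    pair_table: PairTable, rank: str, interaction: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised per-host merged values at `rank` for every sample at once.

    Returns ``(node_values, edge_values)``: frames indexed by clade label /
    canonical clade-pair tuple, one column per sample. Equivalent to running
    `per_host_network` + `merge_to_rank` per sample (tested), but in one
    groupby.
    """
    cp = pair_table.clade_pair(rank)
    # oriented_minus flips nothing within a clade (equal labels), so
    # within-clade parasitism keeps the stored lexicographic taxon orientation
    y = pair_table.y_plus if interaction == MUTUALISM else pair_table.oriented_minus(rank)
    within = cp["clade_1"] == cp["clade_2"]
    node_values = y[within].groupby(cp.loc[within, "clade_1"]).mean()
    node_values.index.name = "clade"
    cross = ~within
    edge_values = y[cross].groupby(
        [cp.loc[cross, "clade_1"], cp.loc[cross, "clade_2"]]
    ).mean()
    edge_values.index = pd.Index(
        [tuple(t) for t in edge_values.index], name="clade_pair", tupleize_cols=False
    )
    return node_values, edge_values


def aggregate_over_hosts(
    networks, group: str | None = None
) -> InteractionNetwork:
    """Element-wise mean across per-host networks of one group.

    Each node/edge weight of the aggregate is the available-case mean across
    hosts possessing that element; the unbiased across-host variance and n
    are stored per element for inference. Parasitism is aggregated on signed
    weights; the implied direction is the sign of the mean, and the fraction
    of hosts whose per-host sign disagrees with it is kept as a diagnostic.
    """
    networks = list(networks)
    if not networks:
        raise ValidationError("cannot aggregate an empty collection of networks")
    rank = networks[0].rank
    interaction = networks[0].interaction
    for net in networks:
        if net.rank != rank or net.interaction != interaction:
            raise ValidationError("all networks must share rank and interaction type")
    node_acc: dict = {}
    edge_acc: dict = {}
    for net in networks:
        for k, w in net.nodes.items():
            node_acc.setdefault(k, []).append(w)
        for k, w in net.edges.items():
            edge_acc.setdefault(k, []).append(w)

    def summarise(acc):
        mean, var, n = {}, {}, {}
        for k, vals in acc.items():
            arr = np.asarray(vals, dtype=float)
            mean[k] = float(arr.mean())
            n[k] = int(arr.size)
            var[k] = float(arr.var(ddof=1)) if arr.size >= 2 else float("nan")
        return mean, var, n

    nodes, node_var, node_n = summarise(node_acc)
    edges, edge_var, edge_n = summarise(edge_acc)
    disagreement = {}
    if interaction == PARASITISM:
        for k, vals in edge_acc.items():
            arr = np.asarray(vals, dtype=float)
            s = np.sign(arr.mean())
            disagreement[k] = float(np.mean(np.sign(arr) != s)) if s != 0 else float("nan")
    return InteractionNetwork(
        rank=rank,
        interaction=interaction,
        nodes=nodes,
        edges=edges,
        group=group,
        n_hosts=len(networks),
        node_var=node_var,
        edge_var=edge_var,
        node_n=node_n,
        edge_n=edge_n,
        direction_disagreement=disagreement,
    )


def aggregate_from_values(
    node_values: pd.DataFrame,
    edge_values: pd.DataFrame,
    rank: str,
    interaction: str,
    group: str | None = None,
    samples=None,
) -> InteractionNetwork:
    """Aggregate the output of `merged_element_values` over (a subset of) samples."""
    if samples is not None:
        node_values = node_values[list(samples)]
        edge_values = edge_values[list(samples)]
    if node_values.shape[1] == 0 and edge_values.shape[1] == 0:
        raise ValidationError("no samples to aggregate")

    def summarise(frame):
        mean = frame.mean(axis=1)
        var = frame.var(axis=1, ddof=1)
        n = frame.notna().sum(axis=1)
        return (
            {k: float(v) for k, v in mean.items()},
            {k: float(v) for k, v in var.items()},
            {k: int(v) for k, v in n.items()},
        )

    nodes, node_var, node_n = summarise(node_values)
    edges, edge_var, edge_n = summarise(edge_values)
    disagreement = {}
    if interaction == PARASITISM:
        arr = edge_values.to_numpy()
        means = arr.mean(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.mean(np.sign(arr) != np.sign(means)[:, None], axis=1)
        for k, s, f in zip(edge_values.index, means, frac):
            disagreement[k] = float(f) if s != 0 else float("nan")
    return InteractionNetwork(
        rank=rank,
        interaction=interaction,
        nodes=nodes,
        edges=edges,
        group=group,
        n_hosts=int(node_values.shape[1] or edge_values.shape[1]),
        node_var=node_var,
        edge_var=edge_var,
        node_n=node_n,
        edge_n=edge_n,
        direction_disagreement=disagreement,
    )


def network_correlation(
    a: InteractionNetwork,
    b: InteractionNetwork,
    elements: str = "edges",
    method: str = "pearson",
):
    """Correlation of shared element weights between two networks.

    Used to compare, e.g., the winter and summer aggregate networks. Returns
    ``(r, (lo, hi), n)`` with a 95% CI from the Fisher z transform.
    Parasitism correlations use the signed weights under the common canonical
    orientation. ``elements`` selects edges (default), nodes, or both.
    """
    if a.rank != b.rank or a.interaction != b.interaction:
        raise ValidationError("networks must share rank and interaction type")
    if elements not in ("edges", "nodes", "both"):
        raise ValidationError(f"elements must be edges|nodes|both, got {elements!r}")
    xs, ys = [], []
    if elements in ("edges", "both"):
        for k in sorted(set(a.edges) & set(b.edges), key=str):
            xs.append(a.edges[k])
            ys.append(b.edges[k])
    if elements in ("nodes", "both"):
        for k in sorted(set(a.nodes) & set(b.nodes), key=str):
            xs.append(a.nodes[k])
            ys.append(b.nodes[k])
    n = len(xs)
    if n < 3:
        raise ValidationError(f"need >= 3 shared elements, have {n}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance on one side; correlation undefined")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValidationError(f"method must be pearson|spearman, got {method!r}")
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (float("nan"), float("nan"))
    return r, ci, n


# ---------------------------------------------------------------------------
# serialization

EDGE_TSV_COLUMNS = [
    "element_type", "clade_1", "clade_2", "weight", "signed_weight",
    "direction", "variance", "n",
]


def write_network(network: InteractionNetwork, path, format: str = "graphml") -> None:
    """Serialize a network losslessly (weights, direction, provenance).

    GraphML keeps the full attribute set (directed graph for parasitism,
    exploiter -> exploited). The edge TSV has the fixed columns
    ``element_type clade_1 clade_2 weight signed_weight direction variance n``
    with one row per node (clade_2 empty) and per edge.
    """
    if format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
        return
    if format != "edge_tsv":
        raise ValidationError(f"format must be graphml|edge_tsv, got {format!r}")
    rows = []
    for node in sorted(network.node_set, key=str):
        if node in network.nodes:
            rows.append({
                "element_type": "node", "clade_1": node, "clade_2": "",
                "weight": network.nodes[node], "signed_weight": network.nodes[node],
                "direction": "",
                "variance": network.node_var.get(node, float("nan")),
                "n": network.node_n.get(node, ""),
            })
    for (a, b), w in sorted(network.edges.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        rows.append({
            "element_type": "edge", "clade_1": a, "clade_2": b,
            "weight": abs(w) if network.interaction == PARASITISM else w,
            "signed_weight": w,
            "direction": network.edge_direction((a, b)) if network.interaction == PARASITISM else "",
            "variance": network.edge_var.get((a, b), float("nan")),
            "n": network.edge_n.get((a, b), ""),
        })
    pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network(path) -> InteractionNetwork:
    """Read back a GraphML file written by `write_network`."""
    g = nx.read_graphml(path)
    meta = g.graph
    interaction = meta.get("interaction", MUTUALISM)
    net = InteractionNetwork(
        rank=meta.get("rank", "unknown"),
        interaction=interaction,
        group=meta.get("group") or None,
        sample=meta.get("sample") or None,
        n_hosts=int(meta.get("n_hosts", 1)),
    )
    for node, attrs in g.nodes(data=True):
        if "weight" in attrs:
            net.nodes[node] = float(attrs["weight"])
        if "variance" in attrs:
            net.node_var[node] = float(attrs["variance"])
        if "n" in attrs:
            net.node_n[node] = int(attrs["n"])
    for u, v, attrs in g.edges(data=True):
        a, b = attrs.get("clade_1", u), attrs.get("clade_2", v)
        key = _canon(a, b)
        net.edges[key] = float(attrs.get("signed_weight", attrs.get("weight", 0.0)))
        if "variance" in attrs:
            net.edge_var[key] = float(attrs["variance"])
        if "n" in attrs:
            net.edge_n[key] = int(attrs["n"])
        if "direction_disagreement" in attrs:
            net.direction_disagreement[key] = float(attrs["direction_disagreement"])
    return net
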