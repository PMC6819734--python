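"""Synthetic communities with known, planted interaction structure.

The generator draws per-host log abundances from a multivariate normal with
a clade-structured correlation matrix, so that every framework statistic
(all of which are linear in log abundance) has a tractable planted
expectation:

* cooperation within a clade c (a value in [0, 1]) acts twice, consistent
  with the fixed-resource argument behind the mutualism score: it is the
  equicorrelation of the member log abundances across hosts (a shared
  host-level clade factor), and it sets the evenness of the members' mean
  abundances - members split a common clade total, with mean offsets
  ``log(p_i * m)`` for proportions p_i that flatten to 1/m as cooperation
  approaches 1. Flatter proportions raise the clade's mean log abundance
  for a fixed clade total (concavity of the log), hence its within-clade
  mutualism strength.
* a parasitism shift delta planted on a clade pair (A, B) moves the member
  mean log abundances by +delta/2 (A side) and -delta/2 (B side), so the
  merged signed clade-level parasitism weight A-minus-B has expectation
  delta exactly (mean-based merging; pair-count factor 1).
* traits are linear combinations of realized per-host merged interaction
  values plus Gaussian noise, so trait-association recovery is checkable
  against the implied correlation.

Abundances are exponentiated log-normals: a modelling convenience (it makes
planted effects analytic), not a claim about real 16S count distributions.
A single RNG stream derived from the spec seed drives everything; the same
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction_scores import FitnessModel, build_pair_table
from .network_builder import merged_element_values
from .taxa_io import (
    RANKS,
    AbundanceMatrix,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
    _rank_index,
)


@dataclass(frozen=True)
class TraitElement:
    """One interaction element a trait is coupled to."""

    interaction: str  # "mutualism" | "parasitism"
    rank: str
    element: object  # clade label (node) or (clade, clade) tuple (edge)
    coefficient: float


@dataclass(frozen=True)
class TraitSpec:
    elements: tuple[TraitElement, ...]
    noise_sd: float = 1.0
    intercept: float = 0.0


@dataclass
class CommunitySpec:
    """Parameters of one synthetic community draw.

    ``rank_sizes`` maps rank names to clade counts, e.g. ``{"phylum": 8,
    "genus": 101}``; the lowest declared rank defines the taxa.
    ``cooperation_strength`` is a global float in [0, 1] or a dict keyed by
    clade label (within-clade) and/or (clade, clade) tuple (between-clade
    correlation) at the rank just above the taxa. ``parasitism_shift`` maps
    (clade, clade) tuples at that rank to a signed log-scale mean shift
    (first clade up, second down). ``group_clade_shift`` optionally moves
    clade mean log abundances per group (e.g. a seasonal effect).
    """

    rank_sizes: dict
    n_hosts_per_group: dict
    n_shared_hosts: int = 0
    log_abundance_base_mean: float = 3.0
    base_sd: float = 1.0
    member_spread_sd: float = 1.0
    cooperation_strength: float | dict = 0.3
    parasitism_shift: dict = field(default_factory=dict)
    group_clade_shift: dict = field(default_factory=dict)
    trait_spec: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rank_sizes:
            raise ValidationError("rank_sizes must name at least one rank")
        for r, n in self.rank_sizes.items():
            _rank_index(r)
            if n < 1:
                raise ValidationError(f"rank {r!r} needs >= 1 clades, got {n}")
        if not self.n_hosts_per_group:
            raise ValidationError("need at least one host group")
        coop = self.cooperation_strength
        vals = coop.values() if isinstance(coop, dict) else [coop]
        for c in vals:
            if not (0.0 <= c <= 1.0):
                raise ValidationError(f"cooperation_strength must be in [0, 1], got {c}")

    @property
    def ordered_ranks(self) -> list[str]:
        """Declared ranks, lowest to highest."""
        return sorted(self.rank_sizes, key=_rank_index)


def _label(rank: str, i: int, width: int) -> str:
    return f"{rank[0].upper()}{i + 1:0{width}d}"


def _build_taxonomy(spec: CommunitySpec, rng: np.random.Generator) -> TaxonomyTable:
    ranks = spec.ordered_ranks
    sizes = [spec.rank_sizes[r] for r in ranks]
    for lower, upper in zip(sizes[:-1], sizes[1:]):
        if upper > lower:
            raise ValidationError(
                "higher ranks cannot have more clades than lower ranks"
            )
    cols: dict[str, np.ndarray] = {}
    width = {r: len(str(spec.rank_sizes[r])) for r in ranks}
    # assign each child clade a parent, every parent non-empty
    child_labels = np.array([_label(ranks[0], i, width[ranks[0]]) for i in range(sizes[0])], dtype=object)
    cols[ranks[0]] = child_labels
    assignment = np.arange(sizes[0])  # child index at previous rank
    prev_labels = child_labels
    for rank, n_parents in zip(ranks[1:], sizes[1:]):
        n_children = len(prev_labels)
        parents = np.concatenate([
            np.arange(n_parents),
            rng.integers(0, n_parents, size=n_children - n_parents),
        ])
        rng.shuffle(parents)
        parent_labels = np.array(
            [_label(rank, i, width[rank]) for i in range(n_parents)], dtype=object
        )
        cols[rank] = parent_labels[parents]
        prev_labels = parent_labels
    table = pd.DataFrame(cols, index=pd.Index(child_labels, name="taxon_id"))
    return TaxonomyTable(table)


def _coop(spec: CommunitySpec, key) -> float:
    c = spec.cooperation_strength
    if isinstance(c, dict):
        if key in c:
            return float(c[key])
        if isinstance(key, tuple):
            return float(c.get((key[1], key[0]), 0.0))
        return float(c.get("default", 0.0))
    return float(c) if not isinstance(key, tuple) else 0.0


def _correlation_matrix(spec: CommunitySpec, clade: pd.Series) -> np.ndarray:
    taxa = clade.index
    labels = clade.to_numpy()
    n = len(taxa)
    rmat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                r = _coop(spec, labels[i])
            else:
                r = _coop(spec, (labels[i], labels[j]))
            rmat[i, j] = rmat[j, i] = r
    return rmat


def _mean_offsets(spec: CommunitySpec, clade: pd.Series, rng: np.random.Generator) -> pd.Series:
    offsets = pd.Series(0.0, index=clade.index)
    for label, members in clade.groupby(clade).groups.items():
        m = len(members)
        c = _coop(spec, label)
        u = rng.normal(0.0, spec.member_spread_sd, size=m)
        w = (1.0 - c) * u
        p = np.exp(w - w.max())
        p /= p.sum()
        offsets.loc[members] += np.log(p * m)  # 0 at perfect evenness
    for (a, b), delta in spec.parasitism_shift.items():
        offsets.loc[clade.index[clade == a]] += delta / 2.0
        offsets.loc[clade.index[clade == b]] -= delta / 2.0
    return offsets


def _hosts_and_samples(spec: CommunitySpec):
    groups = list(spec.n_hosts_per_group)
    counts = [int(spec.n_hosts_per_group[g]) for g in groups]
    shared = int(spec.n_shared_hosts)
    if shared and len(groups) != 2:
        raise ValidationError("n_shared_hosts requires exactly two groups")
    if shared > min(counts, default=0) and shared:
        raise ValidationError("n_shared_hosts exceeds a group size")
    n_hosts = sum(counts) - shared if shared else sum(counts)
    width = max(3, len(str(n_hosts)))
    hosts = [f"H{i + 1:0{width}d}" for i in range(n_hosts)]
    records = []  # (sample_id, host_id, group)
    if shared:
        g1, g2 = groups
        n1, n2 = counts
        for h in hosts[:n1]:
            records.append((f"{h}.{g1}", h, g1))
        for h in hosts[n1 - shared:]:
            records.append((f"{h}.{g2}", h, g2))
    else:
        start = 0
        for g, c in zip(groups, counts):
            for h in hosts[start:start + c]:
                records.append((f"{h}.{g}", h, g))
            start += c
    return records


def simulate_community(
    spec: CommunitySpec,
) -> tuple[AbundanceMatrix, TaxonomyTable, SampleMetadata]:
    """Draw one community: abundances, taxonomy, and metadata with traits."""
    rng = np.random.default_rng(spec.seed)
    taxonomy = _build_taxonomy(spec, rng)
    ranks = taxonomy.ranks
    parent_rank = ranks[1] if len(ranks) > 1 else ranks[0]
    clade = taxonomy.clade_of(parent_rank)
    rmat = _correlation_matrix(spec, clade)
    try:
        chol = np.linalg.cholesky(rmat)
    except np.linalg.LinAlgError:
        # boundary cases (e.g. cooperation exactly 1) are singular but valid;
        # genuinely indefinite matrices are a spec error
        eigval, eigvec = np.linalg.eigh(rmat)
        if eigval.min() < -1e-8:
            raise ValidationError(
                "implied log-abundance correlation matrix is not positive "
                f"definite (min eigenvalue {eigval.min():.4g}); check "
                "between-clade cooperation_strength entries"
            ) from None
        chol = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    offsets = _mean_offsets(spec, clade, rng)
    records = _hosts_and_samples(spec)
    n_taxa = len(taxonomy.taxa)
    cols = {}
    for sample_id, _host, group in records:
        mu = spec.log_abundance_base_mean + offsets.to_numpy()
        shift = spec.group_clade_shift.get(group, {})
        if shift:
            mu = mu + np.array([shift.get(c, 0.0) for c in clade.to_numpy()])
        z = mu + spec.base_sd * (chol @ rng.standard_normal(n_taxa))
        cols[sample_id] = np.exp(z)
    abundance = AbundanceMatrix(
        pd.DataFrame(cols, index=pd.Index(taxonomy.taxa, name="taxon_id"))
    )
    meta = pd.DataFrame(
        {"host_id": [h for _, h, _ in records], "group": [g for _, _, g in records]},
        index=pd.Index([s for s, _, _ in records], name="sample_id"),
    )
    trait_names = []
    if spec.trait_spec:
        pt = build_pair_table(abundance, taxonomy, FitnessModel("e"), pseudocount=0.0)
        cache: dict = {}
        for name, tspec in spec.trait_spec.items():
            values = np.full(len(records), float(tspec.intercept))
            for el in tspec.elements:
                key = (el.interaction, el.rank)
                if key not in cache:
                    cache[key] = merged_element_values(pt, el.rank, el.interaction)
                node_vals, edge_vals = cache[key]
                if isinstance(el.element, tuple):
                    k = el.element if str(el.element[0]) <= str(el.element[1]) else el.element[::-1]
                    series = edge_vals.loc[[k]].iloc[0]
                else:
                    series = node_vals.loc[el.element]
                values = values + el.coefficient * series[meta.index].to_numpy()
            values = values + rng.normal(0.0, tspec.noise_sd, size=len(records))
            meta[name] = values
            trait_names.append(name)
    metadata = SampleMetadata(meta, trait_names=trait_names)
    return abundance, taxonomy, metadata


def davenport_shaped_fixture(
    seed: int = 0,
) -> tuple[AbundanceMatrix, TaxonomyTable, SampleMetadata]:
    """A community shaped like the published gut-microbiota survey.

    101 genera across 8 phyla; 93 winter and 91 summer samples with 57 host
    ids appearing in both seasons (127 hosts in total); a BMI trait coupled
    to the within-phylum mutualism of the two largest phyla plus noise.
    Abundance structure (cooperation, parasitism shifts, seasonal clade
    shifts) is planted, not fitted to the real survey.
    """
    spec = CommunitySpec(
        rank_sizes={"genus": 101, "phylum": 8},
        n_hosts_per_group={"winter": 93, "summer": 91},
        n_shared_hosts=57,
        log_abundance_base_mean=3.0,
        base_sd=1.0,
        cooperation_strength={
            "P1": 0.6, "P2": 0.5, "P3": 0.3, "P4": 0.3,
            "P5": 0.2, "P6": 0.2, "P7": 0.1, "P8": 0.1,
            "default": 0.2,
        },
        parasitism_shift={("P1", "P2"): 0.8, ("P3", "P4"): -0.5},
        group_clade_shift={"summer": {"P1": -0.3, "P2": 0.3}},
        trait_spec={
            "BMI": TraitSpec(
                elements=(
                    TraitElement("mutualism", "phylum", "P1", 0.8),
                    TraitElement("mutualism", "phylum", "P2", 0.5),
                ),
                noise_sd=2.0,
                intercept=25.0,
            )
        },
        seed=seed,
    )
    return simulate_community(spec)
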