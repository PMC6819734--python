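"""Correlating abundance and interactions with numeric host traits.

Two analyses across hosts of one group (e.g. one season), mirroring each
other so they can be reported side by side:

* abundance-trait: per clade at a rank, Pearson correlation between the
  clade-summed log abundance and the trait (e.g. BMI);
* interaction-trait: per network element (node = within-clade, edge =
  between-clade), Pearson correlation between the per-host merged
  interaction weight and the trait (signed weights for parasitism).

Hosts with a missing trait value are excluded pairwise, never imputed.
Raw p-values come from the exact two-sided t test of Pearson's r;
Benjamini-Hochberg q-values are computed across the elements of each call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interaction_scores import FitnessModel
from .network_builder import InteractionNetwork
from .taxa_io import AbundanceMatrix, SampleMetadata, TaxonomyTable, ValidationError

logger = logging.getLogger("microgame")


def _corr(x: np.ndarray, t: np.ndarray, method: str):
    if method == "pearson":
        res = stats.pearsonr(x, t)
    elif method == "spearman":
        res = stats.spearmanr(x, t)
    else:
        raise ValidationError(f"method must be pearson|spearman, got {method!r}")
    return float(res.statistic), float(res.pvalue)


def _finalize(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["q"] = float("nan")
    mask = df["p"].notna()
    if mask.any():
        df.loc[mask, "q"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def abundance_trait_correlation(
    abundance: AbundanceMatrix,
    taxonomy: TaxonomyTable,
    rank: str,
    metadata: SampleMetadata,
    trait: str,
    group: str | None = None,
    model: FitnessModel = FitnessModel(),
    pseudocount: float = 0.0,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate clade-level log abundance with a host trait.

    Clade abundance at `rank` is the SUM of member-taxon abundances (taken
    before the log: abundance aggregates additively), then log-transformed.
    Returns a tidy frame with element_type, element, trait, group, n, r, p, q.
    """
    abundance, taxonomy = abundance.align_taxonomy(taxonomy)
    samples = [s for s in metadata.samples_in_group(group) if s in abundance.samples]
    tvals = metadata.trait(trait).reindex(samples)
    if tvals.notna().sum() == 0:
        raise ValidationError(f"trait {trait!r} is missing for every host in group {group!r}")
    keep = tvals.notna()
    samples = [s for s, k in zip(samples, keep) if k]
    if len(samples) < 3:
        raise ValidationError(f"need >= 3 hosts with trait {trait!r}, have {len(samples)}")
    t = tvals[keep].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValidationError(f"trait {trait!r} is constant; correlation undefined")
    clade_sums = abundance.df[samples].groupby(taxonomy.clade_of(rank)).sum()
    vals = clade_sums.to_numpy(dtype=float) + pseudocount
    if (vals <= 0).any():
        bad = clade_sums.index[(vals <= 0).any(axis=1)].tolist()
        raise ValidationError(
            f"non-positive clade abundance for {bad[:5]}; use a pseudocount"
        )
    logs = model.log(vals)
    rows = []
    for clade, x in zip(clade_sums.index, logs):
        if np.ptp(x) == 0:
            logger.info("clade %r has constant abundance; correlation undefined", clade)
            r = p = float("nan")
        else:
            r, p = _corr(x, t, method)
        rows.append({
            "element_type": "abundance", "clade_1": str(clade), "clade_2": "",
            "trait": trait, "group": "all" if group is None else str(group),
            "n": len(samples), "r": r, "p": p,
        })
    return _finalize(rows)


def interaction_trait_correlation(
    per_host_values,
    metadata: SampleMetadata,
    trait: str,
    group: str | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate per-host interaction weights with a host trait.

    ``per_host_values`` is either a pair of frames ``(node_values,
    edge_values)`` from :func:`microgame.network_builder.merged_element_values`
    (elements x samples) or a collection of per-host
    :class:`InteractionNetwork` objects carrying their sample ids. One
    correlation per element; elements observed in < 3 trait-bearing hosts
    are skipped and logged.
    """
    if isinstance(per_host_values, tuple):
        node_values, edge_values = per_host_values
    else:
        networks = list(per_host_values)
        if not networks:
            raise ValidationError("no per-host networks given")
        node_values = pd.DataFrame(
            {n.sample: pd.Series(n.nodes) for n in networks}
        )
        edge_values = pd.DataFrame(
            {n.sample: pd.Series(n.edges) for n in networks}
        )
    frames = [("node", node_values), ("edge", edge_values)]
    samples = set()
    for _, f in frames:
        samples.update(map(str, f.columns))
    in_group = [s for s in metadata.samples_in_group(group) if s in samples]
    tvals = metadata.trait(trait).reindex(in_group)
    hosts = [s for s in in_group if not pd.isna(tvals[s])]
    if len(hosts) < 3:
        raise ValidationError(f"need >= 3 hosts with trait {trait!r}, have {len(hosts)}")
    t = tvals[hosts].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValidationError(f"trait {trait!r} is constant; correlation undefined")
    rows = []
    for etype, frame in frames:
        if frame.empty:
            continue
        sub = frame[hosts]
        for key, series in sub.iterrows():
            x = series.to_numpy(dtype=float)
            ok = ~np.isnan(x)
            if ok.sum() < 3:
                logger.info("element %r present in < 3 hosts; skipped", key)
                continue
            if np.ptp(x[ok]) == 0:
                logger.info("element %r constant across hosts; skipped", key)
                continue
            r, p = _corr(x[ok], t[ok], method)
            c1, c2 = (str(key[0]), str(key[1])) if etype == "edge" else (str(key), "")
            rows.append({
                "element_type": etype, "clade_1": c1, "clade_2": c2,
                "trait": trait, "group": "all" if group is None else str(group),
                "n": int(ok.sum()), "r": r, "p": p,
            })
    if not rows:
        raise ValidationError("no testable elements")
    return _finalize(rows)
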