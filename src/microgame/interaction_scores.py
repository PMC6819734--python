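"""Fitness indices and pairwise mutualism / parasitism scores.

The fitness of a microbe is modelled as a metabolic power law of its
abundance, F = N0 * N^b, so the fitness index G = log(F/N0)/b = log N:
abundance on a log scale is a proxy of fitness, and the normalisation N0 and
scaling exponent b cancel identically (they are documentation, never numbers).

For a pair of microbes with abundances N1, N2:

* mutualism (inclusive fitness): ``log N1 + log N2 = log(N1*N2)``. For a
  fixed resource total N1 + N2 this is maximal exactly at N1 = N2, so its
  magnitude proxies the strength of cooperation.
* parasitism (exclusive fitness): ``log N1 - log N2 = log(N1/N2)``. The
  magnitude (larger abundance over smaller) proxies the strength of
  asymmetric exploitation; the sign gives its direction.

`build_pair_table` reorganises an I-taxon abundance matrix into all
W = I(I-1)/2 unordered pairs, carrying per-sample mutualism and signed
parasitism values together with the clade-pair annotation of each pair at
every available taxonomic rank. The signed parasitism value is stored under
a fixed lexicographic taxon order (taxon_a < taxon_b) so that averaging
across samples and pairs is well defined; the larger-over-smaller reporting
convention (magnitude + direction) is applied only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .taxa_io import AbundanceMatrix, TaxonomyTable, ValidationError


class DomainError(ValueError):
    """A score was requested outside its mathematical domain."""


@dataclass(frozen=True)
class FitnessModel:
    """Log base used for all scores; fixed for a whole analysis.

    The power-law constants N0 (normalisation) and b (scaling exponent)
    cancel in the fitness index and are carried for documentation only.
    Network correlations downstream are invariant to the base, which only
    rescales every score by a common positive constant.
    """

    base: str = "e"  # "e" (natural) or "10"
    N0: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.base not in ("e", "10"):
            raise ValidationError(f"log base must be 'e' or '10', got {self.base!r}")

    def log(self, x):
        return np.log(x) if self.base == "e" else np.log10(x)


def fitness_index(abundance, model: FitnessModel = FitnessModel()):
    """Fitness index G = log N of a positive abundance (scalar or array)."""
    arr = np.asarray(abundance, dtype=float)
    if (arr <= 0).any():
        raise DomainError(f"fitness index requires abundance > 0, got {arr[arr <= 0][:5]}")
    out = model.log(arr)
    return float(out) if np.isscalar(abundance) else out


def mutualism_score(n1, n2, model: FitnessModel = FitnessModel()):
    """Inclusive fitness log n1 + log n2; symmetric in its arguments."""
    return fitness_index(n1, model) + fitness_index(n2, model)


def parasitism_score(n_a, n_b, model: FitnessModel = FitnessModel()):
    """Exclusive fitness under the caller's fixed order.

    Returns ``(signed, magnitude, direction)`` where signed = log n_a - log n_b,
    magnitude = |signed| (log of larger over smaller), and direction is
    "a_over_b", "b_over_a", or "none" when the abundances tie (no epsilon
    jitter on ties).
    """
    signed = fitness_index(n_a, model) - fitness_index(n_b, model)
    magnitude = abs(signed)
    if signed > 0:
        direction = "a_over_b"
    elif signed < 0:
        direction = "b_over_a"
    else:
        direction = "none"
    return signed, magnitude, direction


def pair_count(n_taxa: int) -> int:
    """Number of unordered pairs W = n(n-1)/2."""
    if n_taxa < 1:
        raise ValidationError(f"n_taxa must be >= 1, got {n_taxa}")
    return n_taxa * (n_taxa - 1) // 2


def resolve_pseudocount(matrix: AbundanceMatrix, pseudocount) -> float:
    """Resolve the zero-handling pseudocount policy.

    "auto": 1.0 for declared counts; half the smallest nonzero value for
    declared relative abundances; 0.0 when the kind is undeclared (zeros then
    raise). A float is taken as-is.
    """
    if pseudocount == "auto":
        if matrix.kind == "counts":
            return 1.0
        if matrix.kind == "relative":
            vals = matrix.df.to_numpy()
            nz = vals[vals > 0]
            if nz.size == 0:
                raise DomainError("all-zero abundance matrix")
            return float(nz.min() / 2.0)
        return 0.0
    return float(pseudocount)


@dataclass
class PairTable:
    """All unordered taxon pairs with per-sample interaction values.

    ``pairs`` is indexed by pair id (0..W-1) with columns ``taxon_a``,
    ``taxon_b`` (taxon_a < taxon_b lexicographically) and, for every rank the
    taxonomy declares, ``<rank>_a`` / ``<rank>_b`` clade annotations.
    ``y_plus`` and ``y_minus`` are W x n_samples frames: the mutualism value
    log Na + log Nb and the signed parasitism value log Na - log Nb.
    """

    pairs: pd.DataFrame
    y_plus: pd.DataFrame
    y_minus: pd.DataFrame
    n_taxa: int
    lowest_rank: str
    model: FitnessModel = FitnessModel()
    pseudocount: float = 0.0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def samples(self) -> list:
        return list(self.y_plus.columns)

    @property
    def ranks(self) -> list[str]:
        return [c[:-2] for c in self.pairs.columns if c.endswith("_a") and c != "taxon_a"]

    def clade_pair(self, rank: str) -> pd.DataFrame:
        """Canonical (sorted) clade pair per pair plus an orientation flag.

        ``flipped`` is True where the stored (taxon_a, taxon_b) orientation
        runs opposite to the sorted clade order, i.e. the stored signed
        parasitism value must be negated to read clade_1-side minus
        clade_2-side.
        """
        if rank not in self.ranks:
            raise ValidationError(f"rank {rank!r} not annotated (have {self.ranks})")
        a = self.pairs[f"{rank}_a"].astype(str)
        b = self.pairs[f"{rank}_b"].astype(str)
        flipped = a > b
        lo = a.where(~flipped, b)
        hi = b.where(~flipped, a)
        return pd.DataFrame({"clade_1": lo, "clade_2": hi, "flipped": flipped})

    def group_labels(self, rank: str) -> pd.Series:
        """Unordered clade-pair annotation per pair, e.g. ``"C1 x C2"``."""
        cp = self.clade_pair(rank)
        return cp["clade_1"].str.cat(cp["clade_2"], sep=" x ").rename("pair_group")

    def oriented_minus(self, rank: str) -> pd.DataFrame:
        """Signed parasitism values re-oriented to the sorted clade pair."""
        cp = self.clade_pair(rank)
        sign = np.where(cp["flipped"].to_numpy(), -1.0, 1.0)
        return self.y_minus.mul(sign, axis=0)

    def to_long(self) -> pd.DataFrame:
        """Long-format export: one row per (pair, sample)."""
        meta = self.pairs.reset_index(names="pair_id")
        plus = self.y_plus.stack().rename("y_plus")
        minus = self.y_minus.stack().rename("y_minus_signed")
        long = pd.concat([plus, minus], axis=1).reset_index(names=["pair_id", "sample_id"])
        return long.merge(meta, on="pair_id")[
            ["pair_id", "taxon_a", "taxon_b"]
            + [c for c in meta.columns if c.endswith(("_a", "_b")) and c not in ("taxon_a", "taxon_b")]
            + ["sample_id", "y_plus", "y_minus_signed"]
        ]

    def write(self, path, format: str = "tsv") -> None:
        sep = "\t" if format == "tsv" else ","
        self.to_long().to_csv(path, sep=sep, index=False)


def total_sum_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Per-sample total-sum scaling (columns sum to 1)."""
    totals = matrix.df.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DomainError(f"cannot total-sum scale all-zero sample(s): {bad}")
    return AbundanceMatrix(matrix.df / totals, kind="relative")


def build_pair_table(
    abundance: AbundanceMatrix,
    taxonomy: TaxonomyTable,
    model: FitnessModel = FitnessModel(),
    pseudocount: float | str = "auto",
    normalize: bool = False,
) -> PairTable:
    """Reorganise an abundance matrix into the all-pairs interaction table.

    Taxa are sorted lexicographically so that taxon_a < taxon_b in every
    pair; the signed parasitism value is stored under that fixed order.
    ``normalize=True`` applies per-sample total-sum scaling first (off by
    default; it leaves parasitism untouched and shifts each sample's
    mutualism values by a constant).
    """
    if abundance.n_taxa < 2:
        raise ValidationError("need at least 2 taxa to build a pair table")
    abundance, taxonomy = abundance.align_taxonomy(taxonomy)
    if normalize:
        abundance = total_sum_scale(abundance)
    pc = resolve_pseudocount(abundance, pseudocount)
    order = sorted(abundance.taxa, key=str)
    df = abundance.df.loc[order]
    vals = df.to_numpy(dtype=float) + pc
    if (vals <= 0).any():
        rr, cc = np.argwhere(vals <= 0).T
        cells = [(df.index[r], df.columns[c]) for r, c in zip(rr[:10], cc[:10])]
        raise DomainError(
            f"non-positive abundance with pseudocount={pc}; offending "
            f"(taxon, sample) cells include {cells}"
        )
    logs = model.log(vals)  # I x S
    ia, ib = np.triu_indices(len(order), k=1)
    y_plus = logs[ia] + logs[ib]
    y_minus = logs[ia] - logs[ib]
    taxa = np.asarray(order, dtype=object)
    pairs = pd.DataFrame({"taxon_a": taxa[ia], "taxon_b": taxa[ib]})
    for rank in taxonomy.ranks:
        clade = taxonomy.clade_of(rank).loc[order].to_numpy(dtype=object)
        pairs[f"{rank}_a"] = clade[ia]
        pairs[f"{rank}_b"] = clade[ib]
    pairs.index.name = "pair_id"
    cols = list(df.columns)
    return PairTable(
        pairs=pairs,
        y_plus=pd.DataFrame(y_plus, columns=cols),
        y_minus=pd.DataFrame(y_minus, columns=cols),
        n_taxa=len(order),
        lowest_rank=taxonomy.lowest_rank,
        model=model,
        pseudocount=pc,
    )
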