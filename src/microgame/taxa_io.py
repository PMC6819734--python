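"""Input tables: abundance matrices, taxonomy lineages, sample metadata.

The framework works on three plain-text tables:

* an abundance matrix (rows = lowest-rank taxa, columns = samples/hosts,
  non-negative reals: counts or relative abundances),
* a taxonomy table (one row per taxon, columns a contiguous suffix of the
  rank ladder strain < species < genus < family < order < class < phylum),
* sample metadata (sample id, optional group label such as season, zero or
  more numeric host traits such as BMI; blanks are missing, never zero).

All three are validated on read; validation failures name the offending
rows/cells so problems in real tables are actionable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("microgame")

#: Taxonomic rank ladder, lowest (finest) to highest (coarsest).
RANKS: tuple[str, ...] = (
    "strain",
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
)


class ValidationError(ValueError):
    """An input table violates the format contract."""


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank.lower())
    except ValueError:
        raise ValidationError(
            f"unknown rank {rank!r}; expected one of {list(RANKS)}"
        ) from None


def rank_is_above(rank: str, other: str) -> bool:
    """True if `rank` is strictly coarser (higher) than `other`."""
    return _rank_index(rank) > _rank_index(other)


@dataclass
class TaxonomyTable:
    """Per-taxon lineage across a contiguous suffix of the rank ladder.

    `table` is indexed by taxon id with one column per declared rank, ordered
    lowest to highest. The lineage must form a tree: a clade label at rank r
    has exactly one parent label at rank r+1. Because 16S taxonomies reuse
    labels under different parents, `read_taxonomy(disambiguate=True)` can
    rewrite colliding child labels as "parent/child" instead of rejecting.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        ranks = [c for c in self.table.columns]
        if not ranks:
            raise ValidationError("taxonomy has no rank columns")
        idx = [_rank_index(r) for r in ranks]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValidationError(f"rank columns out of ladder order: {ranks}")
        # any ladder-ordered subset is accepted (e.g. genus + phylum only, the
        # resolution of typical 16S genus tables); the tree property is then
        # checked between consecutive *declared* ranks
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        empty = self.table.isna() | (self.table.astype(str).apply(lambda s: s.str.strip()) == "")
        if empty.to_numpy().any():
            bad = [
                (t, r)
                for t, row in empty.iterrows()
                for r, is_empty in row.items()
                if is_empty
            ]
            raise ValidationError(f"empty clade labels at (taxon, rank): {bad[:10]}")
        self._validate_tree()

    def _validate_tree(self) -> None:
        ranks = self.ranks
        for lower, upper in zip(ranks[:-1], ranks[1:]):
            parents = self.table.groupby(lower, sort=False)[upper].nunique()
            bad = parents[parents > 1]
            if not bad.empty:
                raise ValidationError(
                    f"clade label(s) at rank {lower!r} with multiple parents at "
                    f"rank {upper!r}: {bad.index.tolist()}"
                )

    @property
    def ranks(self) -> list[str]:
        """Declared ranks, lowest to highest."""
        return list(self.table.columns)

    @property
    def lowest_rank(self) -> str:
        return self.ranks[0]

    @property
    def taxa(self) -> list:
        return list(self.table.index)

    def clade_of(self, rank: str) -> pd.Series:
        """taxon id -> clade label at `rank`."""
        if rank not in self.table.columns:
            raise ValidationError(f"rank {rank!r} not in taxonomy ({self.ranks})")
        return self.table[rank]

    def clades(self, rank: str) -> list:
        return sorted(self.clade_of(rank).unique().tolist())

    def n_clades(self, rank: str) -> int:
        return self.clade_of(rank).nunique()

    def map_between(self, from_rank: str, to_rank: str) -> dict:
        """clade label at `from_rank` -> unique parent label at `to_rank`."""
        if not rank_is_above(to_rank, from_rank):
            raise ValidationError(
                f"target rank {to_rank!r} must be above {from_rank!r}"
            )
        pairs = self.table[[from_rank, to_rank]].drop_duplicates()
        return dict(zip(pairs[from_rank], pairs[to_rank]))

    def subset(self, taxa) -> "TaxonomyTable":
        return TaxonomyTable(self.table.loc[list(taxa)].copy())


@dataclass
class AbundanceMatrix:
    """Lowest-rank taxa x samples matrix of non-negative abundances."""

    df: pd.DataFrame
    kind: str | None = None  #: declared data kind: "counts", "relative" or None

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.df.columns.duplicated().any():
            dups = self.df.columns[self.df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("abundance body must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing abundance at taxon {self.df.index[r]!r}, "
                f"sample {self.df.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[r, c]} at taxon "
                f"{self.df.index[r]!r}, sample {self.df.columns[c]!r}"
            )

    @property
    def taxa(self) -> list:
        return list(self.df.index)

    @property
    def samples(self) -> list:
        return list(self.df.columns)

    @property
    def n_taxa(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]

    def align_taxonomy(self, taxonomy: TaxonomyTable) -> tuple["AbundanceMatrix", TaxonomyTable]:
        """Drop (and log) taxa absent from the taxonomy; subset taxonomy to the rest."""
        known = [t for t in self.taxa if t in taxonomy.table.index]
        orphans = [t for t in self.taxa if t not in taxonomy.table.index]
        if orphans:
            logger.warning(
                "dropping %d abundance taxa absent from taxonomy: %s",
                len(orphans), orphans[:10],
            )
        if not known:
            raise ValidationError("no abundance taxa present in taxonomy")
        return AbundanceMatrix(self.df.loc[known].copy(), kind=self.kind), taxonomy.subset(known)


@dataclass
class SampleMetadata:
    """Per-sample group label and numeric host traits.

    Missing traits are NaN and are excluded pairwise from correlations,
    never imputed as zero.
    """

    df: pd.DataFrame  # index sample_id; column "group"; remaining columns traits
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if "group" not in self.df.columns:
            self.df = self.df.copy()
            self.df["group"] = "all"
        for t in self.trait_names:
            if t not in self.df.columns:
                raise ValidationError(f"trait column {t!r} missing from metadata")
            self.df[t] = pd.to_numeric(self.df[t], errors="raise")

    @property
    def samples(self) -> list:
        return list(self.df.index)

    @property
    def groups(self) -> list:
        return sorted(self.df["group"].astype(str).unique().tolist())

    def samples_in_group(self, group: str | None) -> list:
        if group is None:
            return self.samples
        sel = self.df.index[self.df["group"].astype(str) == str(group)]
        return list(sel)

    def trait(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise ValidationError(
                f"trait column {name!r} missing from metadata "
                f"(have {self.trait_names})"
            )
        return pd.to_numeric(self.df[name], errors="coerce")


# ---------------------------------------------------------------------------
# readers / writers


def _sep(fmt: str) -> str:
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_abundance_table(path, format: str = "tsv", kind: str | None = None) -> AbundanceMatrix:
    """Read a taxon x sample abundance table (first column taxon ids)."""
    raw = pd.read_csv(path, sep=_sep(format), index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        body = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric abundance body in {path}: {exc}") from None
    return AbundanceMatrix(body, kind=kind)


def write_abundance_table(matrix: AbundanceMatrix, path, format: str = "tsv") -> None:
    matrix.df.to_csv(path, sep=_sep(format), index_label="taxon_id")


def read_taxonomy(path, format: str = "tsv", disambiguate: bool = False) -> TaxonomyTable:
    """Read a lineage table: taxon_id column plus a contiguous suffix of ranks.

    Rank column names are case-insensitive. With ``disambiguate=True`` a child
    clade label that appears under two parents is rewritten as
    ``"parent/child"`` instead of raising.
    """
    raw = pd.read_csv(path, sep=_sep(format), dtype=str)
    cols = {c.lower().strip(): c for c in raw.columns}
    if "taxon_id" not in cols:
        raise ValidationError(f"taxonomy {path} lacks a 'taxon_id' column")
    rank_cols = [r for r in RANKS if r in cols]
    if not rank_cols:
        raise ValidationError(f"taxonomy {path} has no rank columns from {list(RANKS)}")
    extra = [c for c in raw.columns if c.lower().strip() not in ("taxon_id", *RANKS)]
    if extra:
        raise ValidationError(f"unknown rank/column name(s) in taxonomy: {extra}")
    table = raw.set_index(cols["taxon_id"])[[cols[r] for r in rank_cols]]
    table.columns = rank_cols
    table.index = table.index.astype(str)
    table.index.name = "taxon_id"
    if disambiguate:
        for lower, upper in zip(rank_cols[:-1], rank_cols[1:]):
            parents = table.groupby(lower, sort=False)[upper].nunique()
            for label in parents[parents > 1].index:
                mask = table[lower] == label
                table.loc[mask, lower] = table.loc[mask, upper] + "/" + label
    return TaxonomyTable(table)


def write_taxonomy(taxonomy: TaxonomyTable, path, format: str = "tsv") -> None:
    taxonomy.table.to_csv(path, sep=_sep(format), index_label="taxon_id")


def read_metadata(path, format: str = "tsv") -> SampleMetadata:
    """Read sample metadata; blank trait cells become missing (NaN), not 0."""
    raw = pd.read_csv(path, sep=_sep(format), dtype=str)
    cols = {c.lower().strip(): c for c in raw.columns}
    if "sample_id" not in cols:
        raise ValidationError(f"metadata {path} lacks a 'sample_id' column")
    df = raw.set_index(cols["sample_id"])
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    rename = {}
    if "group" in cols:
        rename[cols["group"]] = "group"
    df = df.rename(columns=rename)
    traits = []
    for c in df.columns:
        if c in ("group", "host_id"):
            continue
        df[c] = pd.to_numeric(df[c], errors="raise")
        traits.append(c)
    return SampleMetadata(df, trait_names=traits)


def write_metadata(metadata: SampleMetadata, path, format: str = "tsv") -> None:
    metadata.df.to_csv(path, sep=_sep(format), index_label="sample_id")
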