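"""Abundance tables: derivation, aggregation, filtering and TSV I/O.

The metagenomic convention implemented here:

* *gene abundance* — reads mapped to a gene divided by the gene length (bp);
* *relative abundance* — each sample's gene (or taxon) abundances divided by
  their per-sample total, so columns sum to one ("closure");
* *taxon abundance* — the sum of the abundances of all genes annotated to the
  same taxon, at species or genus rank.

Tables are stored feature-by-sample (rows are genes or taxa, columns are
samples), matching the TSV layout used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    AnnotationError,
    DuplicateIdError,
    EmptySampleError,
    GeneLengthError,
    GroupError,
    TableFormatError,
)

UNASSIGNED = "unassigned"

CLOSURE_TOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GeneAbundanceTable:
    """Read counts per gene per sample plus gene lengths in base pairs."""

    counts: pd.DataFrame  # genes x samples, non-negative
    gene_lengths: pd.Series  # indexed by gene id, positive integers

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise DuplicateIdError("duplicate gene ids in counts table")
        if self.counts.columns.has_duplicates:
            raise DuplicateIdError("duplicate sample ids in counts table")
        if (self.counts.to_numpy() < 0).any():
            raise TableFormatError("negative read counts")
        lengths = self.gene_lengths.reindex(self.counts.index)
        missing = lengths.index[lengths.isna()]
        if len(missing):
            raise GeneLengthError(f"missing gene lengths for: {list(missing[:5])}")
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0]
            raise GeneLengthError(f"non-positive gene lengths for: {list(bad[:5])}")
        self.gene_lengths = lengths

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class GeneAnnotation:
    """Maps gene ids to species/genus labels and functional categories.

    ``table`` is indexed by gene id with columns ``species``, ``genus`` and
    ``categories`` (a semicolon-free list of category labels, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise DuplicateIdError("duplicate gene ids in annotation")
        for col in ("species", "genus"):
            if col not in self.table.columns:
                raise AnnotationError(f"annotation missing column {col!r}")
            labels = self.table[col].astype(str)
            if (labels.str.len() == 0).any():
                raise AnnotationError(f"empty {col} label in annotation")
        if "categories" not in self.table.columns:
            self.table = self.table.assign(categories=[[] for _ in range(len(self.table))])

    def taxon_of(self, rank: str) -> pd.Series:
        if rank not in ("species", "genus"):
            raise AnnotationError(f"rank must be 'species' or 'genus', got {rank!r}")
        return self.table[rank]

    def category_members(self) -> dict[str, list[str]]:
        """Category label -> list of member gene ids."""
        members: dict[str, list[str]] = {}
        for gene, cats in self.table["categories"].items():
            for cat in cats:
                members.setdefault(cat, []).append(gene)
        return members

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 3:
            raise TableFormatError("annotation TSV needs gene_id, species, genus columns")
        df = df.set_index(df.columns[0])
        if "categories" in df.columns:
            cats = df["categories"]
        else:
            cats = pd.Series([""] * len(df), index=df.index)
        parsed = [c.split(";") if isinstance(c, str) and c else [] for c in cats]
        out = df[["species", "genus"]].copy()
        out["categories"] = parsed
        return cls(out)

    def to_tsv(self, path) -> None:
        out = self.table[["species", "genus"]].copy()
        out["categories"] = [";".join(c) for c in self.table["categories"]]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class AbundanceTable:
    """Taxon-by-sample relative abundances at a stated rank.

    ``closed`` records whether every sample column sums to one; operations
    that assume compositional closure check this flag.
    """

    data: pd.DataFrame  # taxa x samples
    rank: str = "species"
    closed: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateIdError(f"duplicate taxon id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DuplicateIdError(f"duplicate sample id: {dup!r}")
        if (self.data.to_numpy() < 0).any():
            raise TableFormatError("negative abundance values")
        if self.closed:
            sums = self.data.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=CLOSURE_TOL, rtol=0):
                raise TableFormatError(
                    "columns do not sum to 1 within tolerance; "
                    "construct with closed=False for unclosed tables"
                )

    @property
    def taxon_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def to_samples_matrix(self) -> pd.DataFrame:
        """Samples-by-taxa view, the orientation estimators consume."""
        return self.data.T

    # -- TSV round trip ----------------------------------------------------

    @classmethod
    def read_tsv(cls, path, rank: str = "species", closed: bool | None = None) -> "AbundanceTable":
        return read_abundance(path, rank=rank, closed=closed)

    def to_tsv(self, path) -> None:
        write_abundance(self, path)


@dataclass
class SampleDesign:
    """Sample-to-group assignment with a designated reference group."""

    groups: pd.Series  # sample id -> group label
    reference: str

    def __post_init__(self) -> None:
        self.groups = self.groups.astype(str)
        if not self.reference:
            raise GroupError("reference group label is empty")
        if self.reference not in set(self.groups):
            raise GroupError(f"reference group {self.reference!r} has no samples")

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise GroupError(f"group {group!r} absent from design")
        return list(self.groups.index[self.groups == group])

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups))

    @property
    def disease_groups(self) -> list[str]:
        return [g for g in self.group_labels if g != self.reference]

    def require_cover(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise GroupError(f"samples without group labels: {missing[:5]}")

    @classmethod
    def read_tsv(cls, path, reference: str) -> "SampleDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df.set_index(df.columns[0])[df.columns[1]], reference)


# ---------------------------------------------------------------------------
# derivation operations
# ---------------------------------------------------------------------------


def compute_gene_abundance(table: GeneAbundanceTable) -> pd.DataFrame:
    """Length-normalized gene abundance: reads mapped / gene length (bp)."""
    lengths = table.gene_lengths.to_numpy(dtype=float)
    return table.counts.div(lengths, axis=0)


def compute_relative_abundance(
    abundances: pd.DataFrame, rank: str = "species"
) -> AbundanceTable:
    """Close each sample column to sum one (relative abundance as fraction)."""
    sums = abundances.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise EmptySampleError(f"all-zero sample(s) cannot be closed: {list(zero[:5])}")
    return AbundanceTable(abundances.div(sums, axis=1), rank=rank, closed=True)


def aggregate_to_taxa(
    gene_table: pd.DataFrame,
    annotation: GeneAnnotation,
    rank: str = "species",
) -> AbundanceTable:
    """Sum gene abundances per annotated taxon.

    Genes missing from the annotation are collected under the reserved
    ``"unassigned"`` label so that per-sample mass is conserved; the bucket is
    reported but should be excluded (and the table re-closed) before network
    analysis.
    """
    if annotation.table.empty:
        raise AnnotationError("empty annotation map")
    taxa = annotation.taxon_of(rank).reindex(gene_table.index)
    taxa = taxa.fillna(UNASSIGNED)
    agg = gene_table.groupby(taxa.to_numpy()).sum()
    agg.index.name = "taxon_id"
    closed = bool(np.allclose(agg.sum(axis=0).to_numpy(), 1.0, atol=CLOSURE_TOL, rtol=0))
    return AbundanceTable(agg, rank=rank, closed=closed)


def drop_unassigned(table: AbundanceTable, reclose: bool = True) -> AbundanceTable:
    """Remove the ``unassigned`` bucket, re-closing columns by default."""
    data = table.data.drop(index=UNASSIGNED, errors="ignore")
    if reclose:
        return compute_relative_abundance(data, rank=table.rank)
    return AbundanceTable(data, rank=table.rank, closed=False)


def prevalence_filter(
    table: AbundanceTable, min_samples: int
) -> tuple[AbundanceTable, list[str]]:
    """Drop features detected (value > 0) in fewer than ``min_samples`` samples.

    Returns the filtered table (row order preserved) and the removed ids.
    Filtering breaks closure, so the result is flagged unclosed unless
    nothing was removed.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    detected = (table.data > 0).sum(axis=1)
    keep = detected >= min_samples
    removed = list(table.data.index[~keep])
    filtered = table.data.loc[keep]
    closed = table.closed and not removed
    return AbundanceTable(filtered, rank=table.rank, closed=closed), removed


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_abundance(path, rank: str = "species", closed: bool | None = None) -> AbundanceTable:
    """Read a feature-by-sample TSV (header = sample ids, first column = ids).

    CRLF and LF files parse identically. Duplicate ids, ragged rows and
    non-numeric cells raise named errors with context.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows
        raise TableFormatError(f"malformed TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DuplicateIdError(f"duplicate taxon id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise DuplicateIdError(f"duplicate sample id {dup!r} in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna()][0]
                raise TableFormatError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from exc
        raise TableFormatError(f"non-numeric data in {path}") from exc
    if values.isna().any().any():
        raise TableFormatError(f"missing values in {path}")
    if closed is None:
        closed = bool(
            np.allclose(values.sum(axis=0).to_numpy(), 1.0, atol=1e-6, rtol=0)
        )
    return AbundanceTable(values, rank=rank, closed=closed)


def write_abundance(table: AbundanceTable, path) -> None:
    """Write the feature-by-sample TSV; round-trips to 1e-12."""
    out = table.data.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format="%.17g", lineterminator="\n")


def read_gene_table(counts_path, lengths_path) -> GeneAbundanceTable:
    counts = read_abundance(counts_path, closed=False).data
    lengths_df = pd.read_csv(lengths_path, sep="\t", index_col=0)
    return GeneAbundanceTable(counts, lengths_df.iloc[:, 0])


def write_gene_table(table: GeneAbundanceTable, counts_path, lengths_path) -> None:
    out = table.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t", lineterminator="\n")
    lengths = table.gene_lengths.to_frame("length")
    lengths.index.name = "gene_id"
    lengths.to_csv(lengths_path, sep="\t", lineterminator="\n")
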