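"""Data containers, normalization, pseudobulk aggregation and ortholog alignment.

The containers here are deliberately thin wrappers around numpy / pandas /
scipy.sparse objects so that every downstream operation (specificity scores,
expressolog / accessolog AUROCs, axis divergence) works on plain arrays with
an explicit gene and cell-type bookkeeping layer.

Conventions
-----------
* Count and expression matrices are gene-major: shape ``(n_genes, n_cells)``
  or ``(n_genes, n_cell_types)``.
* Cell metadata is a DataFrame indexed by cell id with columns
  ``species``, ``donor_id`` and ``cell_type``.
* Cross-species pseudobulk matrices are harmonized over the *union* of
  observed cell types; a cell type missing from a species contributes an
  exactly-zero column flagged absent in ``presence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AnnotatedCounts",
    "PseudobulkSet",
    "OrthologMap",
    "AlignedProfiles",
    "normalize_log1p",
    "pseudobulk_mean",
    "filter_expressed",
    "align_orthologs",
]

REQUIRED_META_COLUMNS = ("species", "donor_id", "cell_type")


class EmptyResultError(ValueError):
    """Raised when a filter removes every gene (or region)."""


def _as_dense(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.todense())
    return np.asarray(matrix)


@dataclass
class AnnotatedCounts:
    """Gene x cell integer counts for one or more species plus cell metadata.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` non-negative integer matrix (dense or sparse).
    gene_ids
        Ordered, unique gene identifiers (length ``n_genes``).
    cell_meta
        DataFrame indexed by cell id, one row per column of ``counts``, with
        at least the columns ``species``, ``donor_id``, ``cell_type``.
    """

    counts: sp.spmatrix | np.ndarray
    gene_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        if self.gene_ids.has_duplicates:
            dupes = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise ValueError("counts rows do not match gene_ids")
        if n_cells != len(self.cell_meta):
            raise ValueError("counts columns do not match cell_meta rows")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.tocsr().min()
        if mn < 0:
            raise ValueError("counts must be non-negative")
        for species, grp in self.cell_meta.groupby("species", observed=True):
            if grp["donor_id"].nunique() < 1 or grp["cell_type"].nunique() < 1:
                raise ValueError(f"species {species!r} lacks donors or cell types")

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def species(self) -> list[str]:
        return list(pd.unique(self.cell_meta["species"]))

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedCounts":
        counts = self.counts.tocsc()[:, mask] if sp.issparse(self.counts) else self.counts[:, mask]
        return AnnotatedCounts(counts, self.gene_ids, self.cell_meta.iloc[np.flatnonzero(mask)])

    def for_species(self, species: str) -> "AnnotatedCounts":
        return self.subset_cells((self.cell_meta["species"] == species).to_numpy())

    # -- I/O ---------------------------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        """cells x genes AnnData view (the single-cell ecosystem convention)."""
        x = self.counts.T.tocsr() if sp.issparse(self.counts) else self.counts.T
        return ad.AnnData(X=sp.csr_matrix(x), obs=self.cell_meta.copy(),
                          var=pd.DataFrame(index=self.gene_ids))

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "AnnotatedCounts":
        x = adata.X.T if not sp.issparse(adata.X) else adata.X.T.tocsr()
        return cls(x, adata.var_names, adata.obs)

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, meta_path) -> "AnnotatedCounts":
        """Read Matrix Market counts (genes x cells) with sidecar TSVs.

        ``genes_path`` is a one-column TSV of gene ids; ``meta_path`` must
        have columns cell_id, species, donor_id, cell_type (cells in matrix
        column order).
        """
        import scipy.io as sio

        counts = sp.csr_matrix(sio.mmread(str(mtx_path)))
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        return cls(counts, pd.Index(genes), meta)

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "AnnotatedCounts":
        """Dense TSV with genes as rows (first column = gene id) plus metadata TSV."""
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        return cls(df.to_numpy(), pd.Index(df.index), meta.loc[df.columns])

    def write_mtx(self, mtx_path, genes_path, meta_path) -> None:
        import scipy.io as sio

        sio.mmwrite(str(mtx_path), sp.coo_matrix(self.counts))
        pd.Series(self.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
        self.cell_meta.rename_axis("cell_id").reset_index().to_csv(meta_path, sep="\t", index=False)


@dataclass
class PseudobulkSet:
    """Per-species gene x cell-type mean-expression matrices on a shared grid.

    ``matrices[s]`` has shape ``(n_genes, n_cell_types)`` over the union of
    cell types; ``presence.loc[s, t]`` is False (and the column exactly zero)
    when species ``s`` has no cell of type ``t``.
    """

    species_list: list[str]
    cell_types: list[str]
    gene_ids: pd.Index
    matrices: dict[str, np.ndarray]
    cells_per_type: pd.DataFrame  # species x cell_type integer counts
    presence: pd.DataFrame  # species x cell_type booleans

    def __post_init__(self) -> None:
        k = len(self.cell_types)
        for s in self.species_list:
            m = self.matrices[s]
            if m.shape != (len(self.gene_ids), k):
                raise ValueError(f"matrix for {s!r} has wrong shape {m.shape}")
            absent = ~self.presence.loc[s].to_numpy()
            if absent.any() and not np.all(m[:, absent] == 0):
                raise ValueError(f"absent cell types of {s!r} must be zero-filled")

    def frame(self, species: str) -> pd.DataFrame:
        return pd.DataFrame(self.matrices[species], index=self.gene_ids, columns=self.cell_types)

    def subset_genes(self, gene_mask: np.ndarray) -> "PseudobulkSet":
        return PseudobulkSet(
            self.species_list,
            self.cell_types,
            self.gene_ids[gene_mask],
            {s: m[gene_mask] for s, m in self.matrices.items()},
            self.cells_per_type,
            self.presence,
        )


@dataclass
class OrthologMap:
    """Strict 1:1 gene correspondences; one column per species."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in self.table.columns:
            dup = self.table[col][self.table[col].duplicated()]
            if len(dup):
                raise ValueError(
                    f"gene id(s) {dup.unique()[:5].tolist()} appear more than once in "
                    f"species {col!r}: map is not 1:1"
                )

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class AlignedProfiles:
    """Ortholog x cell-type x species expression tensor, identically ordered.

    Materializes the harmonized per-species pseudobulk matrices restricted
    and re-ordered to the rows of an :class:`OrthologMap`.
    """

    ortholog_index: pd.Index
    cell_types: list[str]
    species_list: list[str]
    tensor: np.ndarray  # (n_orthologs, n_cell_types, n_species)
    presence_mask: np.ndarray = field(default=None)  # (n_cell_types, n_species) bool

    def __post_init__(self) -> None:
        n, k, s = self.tensor.shape
        if (n, k, s) != (len(self.ortholog_index), len(self.cell_types), len(self.species_list)):
            raise ValueError("tensor shape inconsistent with labels")
        if np.any(self.tensor < 0):
            raise ValueError("tensor must be non-negative")
        if self.presence_mask is not None:
            absent = ~self.presence_mask
            if np.any(self.tensor[:, absent] != 0):
                raise ValueError("tensor must be zero where presence_mask is False")

    def slice(self, species: str) -> np.ndarray:
        return self.tensor[:, :, self.species_list.index(species)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_log1p(counts: AnnotatedCounts | np.ndarray | sp.spmatrix,
                    scale: float = 1e4) -> np.ndarray:
    """Depth-normalize each cell to ``scale`` total counts, then ln(1 + x).

    Zero-depth cells cannot be rescaled; they come back as all-zero columns
    with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    x = counts.counts if isinstance(counts, AnnotatedCounts) else counts
    x = _as_dense(x).astype(float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    depth = x.sum(axis=0)
    zero = depth == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero depth; left all-zero")
    safe = np.where(zero, 1.0, depth)
    return np.log1p(x * (scale / safe))


def pseudobulk_mean(expr: np.ndarray, cell_meta: pd.DataFrame, level: str = "cell_type",
                    gene_ids: pd.Index | None = None) -> PseudobulkSet:
    """Per-species mean expression for each gene in each ``level`` group.

    Cell types are harmonized across species by taking the union; a type
    absent from a species yields an exactly-zero, flagged column. Types with
    zero cells in every species are dropped with a warning.
    """
    if level not in cell_meta.columns:
        raise ValueError(f"annotation level {level!r} not in cell metadata")
    expr = np.asarray(expr)
    if expr.shape[1] != len(cell_meta):
        raise ValueError("expr columns do not match cell_meta rows")
    gene_ids = pd.Index(gene_ids if gene_ids is not None else range(expr.shape[0]))

    species_list = list(pd.unique(cell_meta["species"]))
    cell_types = sorted(pd.unique(cell_meta[level].astype(str)))
    counts = pd.DataFrame(0, index=species_list, columns=cell_types, dtype=int)
    matrices: dict[str, np.ndarray] = {}
    for s in species_list:
        s_mask = (cell_meta["species"] == s).to_numpy()
        labels = cell_meta.loc[s_mask, level].astype(str).to_numpy()
        mat = np.zeros((expr.shape[0], len(cell_types)))
        sub = expr[:, s_mask]
        for j, t in enumerate(cell_types):
            sel = labels == t
            counts.loc[s, t] = int(sel.sum())
            if sel.any():
                mat[:, j] = sub[:, sel].mean(axis=1)
        matrices[s] = mat
    empty = counts.sum(axis=0) == 0
    if empty.any():
        dropped = counts.columns[empty].tolist()
        warnings.warn(f"cell type(s) with zero cells in all species dropped: {dropped}")
        keep = ~empty.to_numpy()
        cell_types = [t for t, k in zip(cell_types, keep) if k]
        counts = counts.loc[:, cell_types]
        matrices = {s: m[:, keep] for s, m in matrices.items()}
    return PseudobulkSet(species_list, cell_types, gene_ids, matrices, counts, counts > 0)


def filter_expressed(pb: PseudobulkSet, min_mean: float = 1.0, how: str = "any") -> PseudobulkSet:
    """Retain genes whose max-over-cell-types mean expression exceeds ``min_mean``.

    ``how='any'`` keeps a gene if it passes in at least one species,
    ``how='all'`` requires every species. The comparison is strict (``>``).
    """
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    per_species = np.stack([pb.matrices[s].max(axis=1) > min_mean for s in pb.species_list])
    if how == "any":
        keep = per_species.any(axis=0)
    elif how == "all":
        keep = per_species.all(axis=0)
    else:
        raise ValueError("how must be 'any' or 'all'")
    if not keep.any():
        raise EmptyResultError(f"no gene has mean expression > {min_mean} in any cell type")
    return pb.subset_genes(keep)


def align_orthologs(pbs: "dict[str, PseudobulkSet] | PseudobulkSet", ortho: OrthologMap,
                    allow_missing: bool = False) -> AlignedProfiles:
    """Build the ortholog x cell-type x species tensor in map row order.

    ``pbs`` is either one PseudobulkSet covering all map species or a dict
    of per-species PseudobulkSets (each with its own gene universe). Cell
    types are harmonized over the union of types observed in any species;
    types absent from a species are zero-filled and flagged in the presence
    mask. Every map entry must resolve to a gene in its species' matrix
    unless ``allow_missing``, in which case unresolvable rows are dropped
    and counted in a warning.
    """
    if isinstance(pbs, PseudobulkSet):
        pbs = {s: pbs for s in pbs.species_list}
    missing_species = [s for s in ortho.species if s not in pbs]
    if missing_species:
        raise ValueError(f"ortholog map lacks pseudobulk for species: {missing_species}")

    union_types = sorted({t for s in ortho.species
                          for t in pbs[s].cell_types
                          if pbs[s].presence.loc[s, t]})
    table = ortho.table
    gene_pos = {s: {g: i for i, g in enumerate(pbs[s].gene_ids)} for s in ortho.species}
    row_ok = np.ones(len(table), dtype=bool)
    for col in ortho.species:
        resolvable = table[col].map(gene_pos[col]).notna().to_numpy()
        if not resolvable.all() and not allow_missing:
            bad = table[col][~resolvable].iloc[0]
            raise KeyError(f"gene id {bad!r} (species {col!r}) not found in pseudobulk")
        row_ok &= resolvable
    if not row_ok.all():
        warnings.warn(f"{int((~row_ok).sum())} ortholog row(s) dropped: unresolvable gene ids")
        table = table.loc[row_ok]

    n, k, ns = len(table), len(union_types), len(ortho.species)
    tensor = np.zeros((n, k, ns))
    presence = np.zeros((k, ns), dtype=bool)
    for j, s in enumerate(ortho.species):
        pb = pbs[s]
        idx = table[s].map(gene_pos[s]).to_numpy(dtype=int)
        col_of = {t: c for c, t in enumerate(pb.cell_types)}
        for c, t in enumerate(union_types):
            if t in col_of and pb.presence.loc[s, t]:
                tensor[:, c, j] = pb.matrices[s][idx, col_of[t]]
                presence[c, j] = True
    return AlignedProfiles(
        ortholog_index=pd.Index(table.index),
        cell_types=union_types,
        species_list=list(ortho.species),
        tensor=tensor,
        presence_mask=presence,
    )
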