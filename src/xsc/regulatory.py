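"""cCRE orthology, phylogeny-weighted evolutionary distance, and annotation.

Orthology of candidate cis-regulatory elements (cCREs) is called from
liftover-style alignment tables: a source region counts as matched in a
target species when at least ``min_frac`` of its bases align there (the
classical rule is >= 250 bp of a ~500-bp element, i.e. 50%). Regions matched
in every target are *orthologous*, in none *species_specific*, otherwise
*partial*.

The evolutionary distance of a region integrates breadth and depth of
conservation over a phylogeny: branch lengths (all non-root nodes) are
normalized to sum to one, the region x node alignment-fraction matrix is
binarized at >= 90% aligned bases, and the distance is the sum of normalized
branch lengths over passing nodes — 0 for a species-specific region, 1 for
one aligned to every species and ancestor.

Interval arithmetic is 0-based half-open throughout and delegated to
pyranges.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "regions_from_bed",
    "region_ids",
    "classify_region_orthology",
    "evolutionary_distance",
    "promoter_windows",
    "annotate_min_overlap",
    "group_jaccard",
    "ORTHOLOGY_CLASSES",
]

ORTHOLOGY_CLASSES = ("orthologous", "species_specific", "partial")
NO_HIT_FEATURE = "False"
NO_HIT_OVERLAP = -1


def region_ids(df: pd.DataFrame) -> pd.Series:
    """Canonical 'chrom:start-end' ids for a Chromosome/Start/End table."""
    return (df["Chromosome"].astype(str) + ":" + df["Start"].astype(str)
            + "-" + df["End"].astype(str))


def regions_from_bed(path, alias: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a BED3+ file into a Chromosome/Start/End/region_id frame.

    ``alias`` optionally maps chromosome names (e.g. RefSeq -> UCSC) before
    ids are formed.
    """
    df = pr.read_bed(str(path)).df
    if alias:
        df["Chromosome"] = df["Chromosome"].astype(str).map(lambda c: alias.get(c, c))
    df = df[["Chromosome", "Start", "End"]].copy()
    if (df["Start"] >= df["End"]).any():
        raise ValueError("regions must satisfy start < end")
    df["region_id"] = region_ids(df)
    return df


def classify_region_orthology(regions: pd.DataFrame,
                              liftover: dict[str, pd.DataFrame],
                              min_frac: float = 0.5) -> pd.DataFrame:
    """Classify each region by its alignment status across target species.

    Parameters
    ----------
    regions
        Frame with Chromosome/Start/End/region_id.
    liftover
        Per target species, a frame with at least ``region_id`` and
        ``aligned_bp`` (best record per region is used if several).
    min_frac
        A target counts as matched iff aligned_bp >= min_frac * region
        length. Default 0.5 (the >=250 bp of a 500-bp element rule).

    Returns a frame indexed by region_id with one boolean ``matched_<sp>``
    column per target and an ``orthology_class`` column: ``orthologous``
    (matched in all targets), ``species_specific`` (in none), ``partial``.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    lengths = (regions["End"] - regions["Start"]).to_numpy()
    idx = pd.Index(regions["region_id"], name="region_id")
    out = pd.DataFrame(index=idx)
    for sp, lift in liftover.items():
        unknown = ~lift["region_id"].isin(idx)
        if unknown.any():
            bad = lift.loc[unknown, "region_id"].iloc[0]
            raise KeyError(f"liftover for {sp!r} references unknown region {bad!r}")
        if (lift["aligned_bp"] < 0).any():
            raise ValueError("aligned_bp must be >= 0")
        best = lift.groupby("region_id")["aligned_bp"].max()
        aligned = best.reindex(idx, fill_value=0).to_numpy()
        over = aligned > lengths
        if over.any():
            raise ValueError("aligned_bp exceeds region length")
        out[f"matched_{sp}"] = aligned >= min_frac * lengths
    match_cols = [c for c in out.columns if c.startswith("matched_")]
    n_matched = out[match_cols].sum(axis=1)
    out["orthology_class"] = np.where(
        n_matched == len(match_cols), "orthologous",
        np.where(n_matched == 0, "species_specific", "partial"))
    return out


def _load_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def node_branch_lengths(tree, mode: str = "all") -> pd.Series:
    """Branch length per named non-root node, normalized to sum to one.

    ``mode='all'`` uses every non-root node (leaves + ancestral nodes, the
    default); ``mode='leaves'`` restricts to leaves. The root carries no
    branch and never contributes.
    """
    t = _load_tree(tree)
    rows = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue  # root: no branch
        if mode == "leaves" and not nd.is_leaf():
            continue
        name = nd.taxon.label if nd.taxon is not None else nd.label
        if name is None:
            raise ValueError("all non-root tree nodes must be named")
        if nd.edge.length is None:
            raise ValueError(f"node {name!r} lacks a branch length")
        rows[name] = float(nd.edge.length)
    s = pd.Series(rows, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("tree has no positive branch length")
    return s / total


def evolutionary_distance(tree, fractions: pd.DataFrame, align_thr: float = 0.9,
                          mode: str = "all") -> pd.Series:
    """Phylogeny-weighted conservation score per region.

    ``fractions`` is a (regions x nodes) matrix of aligned-base fractions in
    [0, 1]; columns must name nodes of ``tree`` (Newick string, path
    contents, or dendropy Tree). A node counts as aligned when its fraction
    is >= ``align_thr`` (default 0.9); the score sums the normalized branch
    lengths of aligned nodes, so it lies in [0, 1].
    """
    if not 0 < align_thr <= 1:
        raise ValueError("align_thr must be in (0, 1]")
    weights = node_branch_lengths(tree, mode=mode)
    unknown = [c for c in fractions.columns if c not in weights.index]
    if mode == "all" and unknown:
        raise KeyError(f"fraction matrix column(s) not in tree: {unknown[:5]}")
    cols = [c for c in fractions.columns if c in weights.index]
    F = fractions[cols].to_numpy(dtype=float)
    if np.any((F < 0) | (F > 1)):
        raise ValueError("alignment fractions must lie in [0, 1]")
    w = weights.reindex(cols).to_numpy()
    score = (F >= align_thr) @ w
    return pd.Series(score, index=fractions.index, name="evolutionary_distance")


def promoter_windows(gene_models: pd.DataFrame, upstream: int = 1000,
                     downstream: int = 500) -> pd.DataFrame:
    """Strand-aware promoter windows around transcription start sites.

    ``gene_models`` needs columns gene_id, Chromosome, Strand ('+'/'-') and
    tss (0-based). '+' strand gives [tss-upstream, tss+downstream), '-'
    strand [tss-downstream, tss+upstream), clipped at 0. Overlapping windows
    of the same gene are merged.
    """
    gm = gene_models
    bad = ~gm["Strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand value(s): {gm.loc[bad, 'Strand'].unique()[:3]}")
    tss = gm["tss"].to_numpy(dtype=int)
    plus = (gm["Strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    df = pd.DataFrame({
        "Chromosome": gm["Chromosome"].to_numpy(),
        "Start": np.maximum(start, 0),
        "End": end,
        "gene_id": gm["gene_id"].to_numpy(),
    })
    merged = pr.PyRanges(df).merge(by="gene_id").df
    return merged.sort_values(["Chromosome", "Start", "gene_id"]).reset_index(drop=True)


def annotate_min_overlap(regions: pd.DataFrame, features: pd.DataFrame,
                         min_bp: int = 250,
                         feature_col: str = "name") -> pd.DataFrame:
    """Annotate regions with features they overlap by at least ``min_bp``.

    ``min_bp=0`` means any overlap (>= 1 bp; intervals are half-open, so
    abutting intervals never qualify). All qualifying features are reported.
    Regions without a qualifying feature carry the no-hit sentinel
    (feature 'False', overlap_bp -1, hit False).
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    need = max(min_bp, 1)
    a = pr.PyRanges(regions[["Chromosome", "Start", "End", "region_id"]].copy())
    feat = features.rename(columns={feature_col: "feature"})
    b = pr.PyRanges(feat[["Chromosome", "Start", "End", "feature"]].copy())
    joined = a.join(b).df
    rows = []
    if len(joined):
        ov = (np.minimum(joined["End"], joined["End_b"])
              - np.maximum(joined["Start"], joined["Start_b"]))
        joined = joined.assign(overlap_bp=ov)
        hits = joined[joined["overlap_bp"] >= need]
        rows = hits[["region_id", "feature", "overlap_bp"]].to_dict("records")
    hit_df = pd.DataFrame(rows, columns=["region_id", "feature", "overlap_bp"])
    no_hit = regions.loc[~regions["region_id"].isin(hit_df["region_id"]), "region_id"]
    sentinel = pd.DataFrame({
        "region_id": no_hit,
        "feature": NO_HIT_FEATURE,
        "overlap_bp": NO_HIT_OVERLAP,
    })
    out = pd.concat([hit_df, sentinel], ignore_index=True)
    out["hit"] = out["overlap_bp"] >= need
    order = {r: i for i, r in enumerate(regions["region_id"])}
    return (out.sort_values(["region_id", "overlap_bp"],
                            key=lambda s: s.map(order) if s.name == "region_id" else s,
                            ascending=[True, False])
               .reset_index(drop=True))


def group_jaccard(binary_peaks: pd.DataFrame, distance: bool = False) -> pd.DataFrame:
    """Pairwise Jaccard similarity (or distance) between binarized peak sets.

    ``binary_peaks`` is a (regions x groups) 0/1 matrix; J(a, b) =
    |a AND b| / |a OR b|. Empty groups produce NaN with a warning.
    """
    X = binary_peaks.to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValueError("peak matrix must be binary")
    X = X.astype(float)
    sizes = X.sum(axis=0)
    empty = sizes == 0
    if empty.any():
        warnings.warn(
            f"empty group(s): {binary_peaks.columns[empty].tolist()}; Jaccard set to NaN")
    inter = X.T @ X
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = inter / union
    J[empty, :] = np.nan
    J[:, empty] = np.nan
    np.fill_diagonal(J, np.where(empty, np.nan, 1.0))
    out = pd.DataFrame(1.0 - J if distance else J,
                       index=binary_peaks.columns, columns=binary_peaks.columns)
    return out
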