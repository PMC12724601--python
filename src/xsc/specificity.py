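"""Cell-type specificity indices: tau for genes, Gini for regulatory regions.

Tau is the classical 0-1 tissue-specificity index applied to per-cell-type
pseudobulk profiles; 0 means uniform expression, 1 means expression confined
to a single type. To keep the estimate robust to donor composition, the
pipeline recomputes tau on repeated random donor subsamples (size
``max(2, ceil(D / 3))`` of D donors, 10 iterations by default) and reports
the per-gene mean across subsamples.

Gini plays the same role for chromatin accessibility: it is 0 for a region
equally accessible in every cell type and approaches (k-1)/k as the signal
concentrates in one of k types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AnnotatedCounts, _as_dense

__all__ = [
    "tau",
    "tau_matrix",
    "tau_donor_subsampled",
    "donor_subsample_size",
    "gini",
    "gini_specificity",
]


def tau(profile) -> float:
    """Tau specificity of one per-cell-type expression profile.

    tau = sum_i (1 - x_i / x_max) / (k - 1), with tau = 0 for an all-zero
    profile. Requires k >= 2 non-negative values.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector over k >= 2 cell types")
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    xmax = x.max()
    if xmax == 0:
        return 0.0
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def tau_matrix(X: np.ndarray) -> np.ndarray:
    """Vectorized tau over the rows of a (genes x cell-types) matrix."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need k >= 2 cell types")
    if np.any(X < 0):
        raise ValueError("expression values must be non-negative")
    xmax = X.max(axis=1)
    out = np.zeros(X.shape[0])
    nz = xmax > 0
    out[nz] = (1.0 - X[nz] / xmax[nz, None]).sum(axis=1) / (X.shape[1] - 1)
    return out


def donor_subsample_size(n_donors: int) -> int:
    """Subsample ``max(2, ceil(D / 3))`` donors out of D."""
    return max(2, math.ceil(n_donors / 3))


def tau_donor_subsampled(
    counts: AnnotatedCounts,
    level: str = "cell_type",
    n_iter: int = 10,
    seed: int = 0,
    min_mean: float = 1.0,
    min_iters: int = 5,
    scale: float = 1e4,
    log: bool = False,
) -> pd.DataFrame:
    """Donor-subsampled tau for every gene of a single-species count matrix.

    Each iteration draws ``max(2, ceil(D/3))`` of the D donors without
    replacement (counter-based RNG keyed on ``(seed, iteration)`` so
    iterations are order-independent), restricts to their cells, aggregates
    depth-normalized expression per ``level`` group, keeps genes with mean
    expression > ``min_mean`` in at least one group, and computes tau on the
    resulting profile. Genes failing the expression filter in an iteration
    get a missing value for that iteration.

    Returns a DataFrame indexed by gene id with one ``tau_<i>`` column per
    iteration, ``n_iters_used``, and ``mean_tau`` (NaN when fewer than
    ``min_iters`` iterations produced a value).

    Aggregation is the linear-scale mean of depth-normalized counts by
    default (matching the mean-expression > 1 retention rule); pass
    ``log=True`` to aggregate ln(1+x) values instead.
    """
    if counts.cell_meta["species"].nunique() != 1:
        raise ValueError("tau_donor_subsampled operates on one species at a time")
    donors = np.asarray(sorted(counts.cell_meta["donor_id"].unique()))
    if len(donors) < 2:
        raise ValueError("need at least 2 donors for donor subsampling")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_take = donor_subsample_size(len(donors))

    x = _as_dense(counts.counts).astype(float)
    depth = x.sum(axis=0)
    safe = np.where(depth == 0, 1.0, depth)
    norm = x * (scale / safe)
    if log:
        norm = np.log1p(norm)

    taus = np.full((counts.n_genes, n_iter), np.nan)
    donor_col = counts.cell_meta["donor_id"].to_numpy()
    level_col = counts.cell_meta[level].astype(str).to_numpy()
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), it]))
        chosen = rng.choice(donors, size=n_take, replace=False)
        cell_mask = np.isin(donor_col, chosen)
        labels = level_col[cell_mask]
        types = np.unique(labels)
        if len(types) < 2:
            continue
        sub = norm[:, cell_mask]
        prof = np.stack([sub[:, labels == t].mean(axis=1) for t in types], axis=1)
        keep = prof.max(axis=1) > min_mean
        if keep.any():
            taus[keep, it] = tau_matrix(prof[keep])

    n_used = (~np.isnan(taus)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_tau = np.nanmean(taus, axis=1)
    mean_tau[n_used < min(min_iters, n_iter)] = np.nan
    out = pd.DataFrame(taus, index=counts.gene_ids,
                       columns=[f"tau_{i}" for i in range(n_iter)])
    out["n_iters_used"] = n_used
    out["mean_tau"] = mean_tau
    out.index.name = "gene_id"
    return out


def gini(profile) -> float:
    """Gini inequality of one non-negative accessibility profile.

    Computed on ascending-sorted values x_(1..k):
    gini = sum_i (2i - k - 1) x_(i) / (k * sum_i x_i).
    Returns NaN for an all-zero profile.
    """
    x = np.sort(np.asarray(profile, dtype=float))
    if x.size < 2:
        raise ValueError("profile must cover k >= 2 cell types")
    if np.any(x < 0):
        raise ValueError("accessibility values must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    i = np.arange(1, x.size + 1)
    return float(np.sum((2 * i - x.size - 1) * x) / (x.size * total))


@dataclass
class GiniResult:
    region_id: str
    gini: float
    top_cell_type: str


def gini_specificity(access: pd.DataFrame) -> pd.DataFrame:
    """Per-region Gini specificity of a (regions x cell-types) matrix.

    The single Gini value of each region is assigned to its most accessible
    cell type (``top_cell_type``; lowest-index type wins ties). All-zero
    regions get a missing Gini with a warning.
    """
    X = access.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need k >= 2 cell types")
    if np.any(X < 0):
        raise ValueError("accessibility values must be non-negative")
    total = X.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero region(s): Gini set to NaN")
    Xs = np.sort(X, axis=1)
    k = X.shape[1]
    i = np.arange(1, k + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = ((2 * i - k - 1) * Xs).sum(axis=1) / (k * total)
    g[zero] = np.nan
    top = access.columns.to_numpy()[X.argmax(axis=1)]
    out = pd.DataFrame({"gini": g, "top_cell_type": top}, index=access.index)
    out.loc[zero, "top_cell_type"] = pd.NA
    out.index.name = "region_id"
    return out
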