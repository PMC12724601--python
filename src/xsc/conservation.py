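"""Expressolog / accessolog rank-AUROC conservation scores and regime labels.

For a 1:1 ortholog pair (gene i in a reference species, gene j in a query
species), the expressolog score asks: among all query genes, how highly does
j's cell-type expression profile rank in similarity (Pearson correlation) to
i's profile? Ranks are converted to an AUROC,

    AUROC = (r_ij - 1) / (N - 1),

where r_ij is the (average-tie) ascending rank of the ortholog's correlation
among the N query profiles. 1.0 means the ortholog is the single best match,
0.5 is chance, and the per-gene conservation score is the median AUROC over
all ordered species pairs. Accessologs apply the identical machinery to
orthologous cCRE accessibility profiles, optionally ranking against a random
candidate subset because the all-pairs comparison is quadratic in region
count.

Genes are then placed into four evolutionary regimes by thresholding the
median AUROC (conservation) against tau (cell-type specificity), and cCREs
into epi-conservation classes by accessolog score and per-species tau.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .core_data import AlignedProfiles

__all__ = [
    "pair_correlations",
    "expressolog_auroc",
    "rank_auroc",
    "expressolog_scores",
    "classify_regimes",
    "accessolog_scores",
    "classify_epi",
    "REGIME_LABELS",
]

REGIME_LABELS = ("conserved_marker", "conserved_broad", "divergent_marker", "divergent_broad")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center/scale rows to unit norm; constant rows become all-NaN."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    Z = X - mu
    sd = np.sqrt((Z ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Z / sd
    Z[np.broadcast_to(sd == 0, Z.shape)] = np.nan
    return Z


def pair_correlations(ap: AlignedProfiles, ref: str, qry: str) -> np.ndarray:
    """All-vs-all Pearson correlations between ref and query gene profiles.

    Returns an (n_ref_genes, n_qry_genes) matrix; entry (i, g) is the
    correlation of reference gene i's profile across cell types with query
    gene g's profile. Constant (zero-variance) profiles yield NaN rows or
    columns. Requires at least 3 cell types.
    """
    if len(ap.cell_types) < 3:
        raise ValueError("need at least 3 shared cell types for profile correlations")
    zr = _standardize_rows(ap.slice(ref))
    zq = _standardize_rows(ap.slice(qry))
    return zr @ zq.T


def rank_auroc(values: np.ndarray, index: int) -> float:
    """AUROC of ``values[index]`` within ``values`` by average ascending rank.

    NaN entries are excluded from the ranking; a NaN at ``index`` (or fewer
    than 2 usable values) yields NaN.
    """
    v = np.asarray(values, dtype=float)
    v0 = v[index]
    if np.isnan(v0):
        return float("nan")
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 2:
        return float("nan")
    less = int((v[ok] < v0).sum())
    equal = int((v[ok] == v0).sum())  # includes the ortholog itself
    rank = less + (equal + 1) / 2.0
    return (rank - 1.0) / (n - 1.0)


def expressolog_auroc(correlations: np.ndarray, ortholog_index: int) -> float:
    """Rank-AUROC of the true ortholog's correlation among all N candidates."""
    return rank_auroc(correlations, ortholog_index)


def _auroc_rows(C: np.ndarray) -> np.ndarray:
    """Vectorized diagonal rank-AUROC: for each row i of (n x n) matrix C,
    the AUROC of C[i, i] among the non-NaN entries of row i."""
    n = C.shape[0]
    diag = np.diagonal(C).copy()
    ok = ~np.isnan(C)
    with np.errstate(invalid="ignore"):
        less = np.where(ok & (C < diag[:, None]), 1, 0).sum(axis=1)
        equal = np.where(ok & (C == diag[:, None]), 1, 0).sum(axis=1)
    n_ok = ok.sum(axis=1)
    rank = less + (equal + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rank - 1.0) / (n_ok - 1.0)
    out[np.isnan(diag) | (n_ok < 2)] = np.nan
    return out


def expressolog_scores(ap: AlignedProfiles) -> pd.DataFrame:
    """Expressolog AUROC for every ordered species pair plus the median score.

    The aligned tensor's rows are the 1:1 ortholog set, so the true ortholog
    of reference row i is query row i. Output columns: one
    ``auroc_<ref>__<qry>`` per ordered pair, ``median_score`` over available
    pair-directions (missing directions excluded, not imputed), and the
    per-species profile standard deviation ``sd_<species>``.
    """
    if len(ap.species_list) < 2:
        raise ValueError("need at least 2 species")
    out = pd.DataFrame(index=ap.ortholog_index)
    out.index.name = "ortholog_id"
    pair_cols = []
    for ref, qry in permutations(ap.species_list, 2):
        C = pair_correlations(ap, ref, qry)
        col = f"auroc_{ref}__{qry}"
        out[col] = _auroc_rows(C)
        pair_cols.append(col)
    out["median_score"] = out[pair_cols].median(axis=1, skipna=True)
    for s in ap.species_list:
        out[f"sd_{s}"] = ap.slice(s).std(axis=1, ddof=0)
    return out


def classify_regimes(median_auroc, tau_summary, auroc_thr: float = 0.75,
                     tau_thr: float = 0.75) -> pd.Series | str:
    """Four-regime label from conservation (AUROC) x specificity (tau).

    conserved_marker (AUROC >= thr, tau >= thr), conserved_broad (>=, <),
    divergent_marker (<, >=), divergent_broad (<, <). Values exactly at a
    threshold fall on the conserved / marker side. Missing inputs give
    'unclassified'.
    """
    a = np.atleast_1d(np.asarray(median_auroc, dtype=float))
    t = np.atleast_1d(np.asarray(tau_summary, dtype=float))
    if a.shape != t.shape:
        raise ValueError("median_auroc and tau_summary must align")
    cons = a >= auroc_thr
    mark = t >= tau_thr
    lab = np.where(cons & mark, "conserved_marker",
          np.where(cons & ~mark, "conserved_broad",
          np.where(~cons & mark, "divergent_marker", "divergent_broad")))
    lab = np.where(np.isnan(a) | np.isnan(t), "unclassified", lab)
    if np.isscalar(median_auroc) or np.ndim(median_auroc) == 0:
        return str(lab[0])
    idx = median_auroc.index if isinstance(median_auroc, pd.Series) else None
    return pd.Series(lab, index=idx, name="regime")


def accessolog_scores(access: dict[str, pd.DataFrame], region_map: pd.DataFrame,
                      n_candidates: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Accessolog AUROC for orthologous regions over every ordered species pair.

    ``access[s]`` is a (regions x cell-types) accessibility matrix for
    species ``s`` (shared cell-type columns); ``region_map`` has one column
    per species giving the orthologous region ids. The true ortholog's
    profile correlation is ranked against correlations with ``n_candidates``
    other mapped regions sampled uniformly without replacement
    (``n_candidates=0`` ranks against all mapped regions). Map rows whose
    region id is absent from a species matrix are skipped; the count is
    reported in ``df.attrs['n_skipped']``.
    """
    species = list(region_map.columns)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    ok = np.ones(len(region_map), dtype=bool)
    for s in species:
        ok &= region_map[s].isin(access[s].index).to_numpy()
    n_skipped = int((~ok).sum())
    rmap = region_map.loc[ok].reset_index(drop=True)
    n = len(rmap)
    if n < 2:
        raise ValueError("fewer than 2 resolvable orthologous regions")
    if n_candidates < 0:
        raise ValueError("n_candidates must be >= 0 (0 = rank against all regions)")

    # profiles in map order, standardized once per species
    Z = {s: _standardize_rows(access[s].loc[rmap[s]].to_numpy(dtype=float)) for s in species}

    out = pd.DataFrame(index=pd.Index(rmap[species[0]], name="region_id"))
    pair_cols = []
    for p, (ref, qry) in enumerate(permutations(species, 2)):
        zr, zq = Z[ref], Z[qry]
        col = f"auroc_{ref}__{qry}"
        if n_candidates == 0 or n_candidates >= n - 1:
            C = zr @ zq.T
            out[col] = _auroc_rows(C)
        else:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), p]))
            scores = np.full(n, np.nan)
            true_corr = (zr * zq).sum(axis=1)
            for i in range(n):
                if np.isnan(true_corr[i]):
                    continue
                cand = rng.choice(n - 1, size=n_candidates, replace=False)
                cand[cand >= i] += 1  # sample from regions other than i
                corrs = zq[cand] @ zr[i]
                pool = np.concatenate([corrs, [true_corr[i]]])
                scores[i] = rank_auroc(pool, len(pool) - 1)
            out[col] = scores
        pair_cols.append(col)
    out["median_score"] = out[pair_cols].median(axis=1, skipna=True)
    out["n_candidates"] = n_candidates if n_candidates else n - 1
    out.attrs["n_skipped"] = n_skipped
    return out


def classify_epi(accessolog, tau_per_species: pd.DataFrame,
                 access_thr: float = 0.75, tau_thr: float = 0.75) -> pd.Series:
    """Epi-conservation class per region.

    ``epi_conserved`` when the accessolog score clears ``access_thr``;
    otherwise ``species_biased:<s>`` when tau is elevated (>= tau_thr) in
    exactly one species ``s``; otherwise ``other``.
    """
    a = np.asarray(accessolog, dtype=float)
    T = tau_per_species.to_numpy(dtype=float)
    if len(a) != len(T):
        raise ValueError("accessolog and tau_per_species must align")
    elevated = T >= tau_thr
    n_elev = elevated.sum(axis=1)
    biased_sp = tau_per_species.columns.to_numpy()[elevated.argmax(axis=1)]
    lab = np.where(a >= access_thr, "epi_conserved",
          np.where(n_elev == 1, np.char.add("species_biased:", biased_sp.astype(str)), "other"))
    return pd.Series(lab, index=tau_per_species.index, name="epi_class")
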