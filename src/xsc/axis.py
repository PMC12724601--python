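"""MSN axis gene sets and cross-species divergence of expression programs.

The striatal medium spiny neuron (MSN) population varies along three roughly
orthogonal axes — direct/indirect pathway (D1 vs D2), striosome vs matrix
compartment, and the dorsoventral spatial gradient. Each axis is represented
as a gene program: per-species Wilcoxon differential expression for the two
categorical contrasts, and Spearman co-variation with an anchor gradient
gene (CNR1-like) for the dorsoventral axis. Programs are then compared for
evolutionary lability: per-gene cross-species divergence is the mean
absolute deviation of log-expression from the cross-species mean profile
over shared MSN groups, and each program is tested against a
highly-variable-gene background with a two-sided Mann-Whitney U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_bh",
    "exact_rank_sum_p",
    "axis_de_sets",
    "gradient_gene_set",
    "select_hvgs",
    "divergence",
    "compare_set_divergence",
    "AxisGeneSets",
    "SetDivergenceReport",
]

LOG2FC_EPS = 1e-9


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the
    first group and counts assignments whose U statistic deviates from its
    mean n1*n2/2 at least as much as the observed one (ties contribute
    through average ranks). Intended for small groups (n1, n2 <= ~10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def _log2fc(log_in: np.ndarray, log_out: np.ndarray) -> np.ndarray:
    """scanpy-style fold change from mean ln(1+x) values per group."""
    a = np.maximum(np.expm1(log_in), 0.0)
    b = np.maximum(np.expm1(log_out), 0.0)
    return np.log2((a + LOG2FC_EPS) / (b + LOG2FC_EPS))


def wilcoxon_bh(expr: np.ndarray, groups, target=None, gene_ids=None,
                exact_max: int = 10) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test with BH correction.

    ``expr`` is (genes x cells) log-normalized expression; ``groups`` a
    two-level label per cell; ``target`` the level treated as the in-group
    (defaults to the first level in sorted order). P-values come from the
    tie-corrected normal approximation, or from exact enumeration when both
    groups have at most ``exact_max`` cells. Genes constant across all cells
    get p = 1 and constant=True. Columns: log2_fold_change (in vs out group,
    computed on back-transformed means with a pseudocount), p_value,
    adjusted_p (BH), frac_in / frac_out (fraction of cells expressing).
    """
    expr = np.asarray(expr, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly 2 levels, got {levels}")
    target = levels[0] if target is None else target
    other = levels[1] if target == levels[0] else levels[0]
    in_mask = groups == target
    out_mask = ~in_mask
    n1, n2 = int(in_mask.sum()), int(out_mask.sum())
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 cells per group")

    xin, xout = expr[:, in_mask], expr[:, out_mask]
    constant = expr.std(axis=1) == 0
    if max(n1, n2) <= exact_max:
        p = np.array([exact_rank_sum_p(a, b) for a, b in zip(xin, xout)])
    else:
        res = stats.mannwhitneyu(xin, xout, axis=1, method="asymptotic")
        p = np.asarray(res.pvalue)
    p = np.where(constant, 1.0, p)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "log2_fold_change": _log2fc(xin.mean(axis=1), xout.mean(axis=1)),
        "p_value": p,
        "adjusted_p": adj,
        "frac_in": (xin > 0).mean(axis=1),
        "frac_out": (xout > 0).mean(axis=1),
        "constant": constant,
    }, index=pd.Index(gene_ids if gene_ids is not None else range(expr.shape[0]),
                      name="gene_id"))
    out.attrs["target"] = target
    out.attrs["other"] = other
    return out


def axis_de_sets(expr_by_species: dict[str, tuple[np.ndarray, np.ndarray]],
                 gene_ids, contrast: tuple[str, str],
                 adj_p_thr: float = 0.01, lfc_thr: float = 1.0,
                 min_frac: float = 0.2, combine: str = "union"
                 ) -> tuple[set, dict[str, pd.DataFrame]]:
    """Differentially expressed gene set for one categorical MSN axis.

    For each species, ``expr_by_species[s]`` is ``(expr, labels)`` with expr
    (genes x cells) log-normalized and labels per cell; cells are restricted
    to the two ``contrast`` levels (species missing a level are skipped with
    a warning). A gene enters a species' call set when adjusted_p <
    ``adj_p_thr``, \\|log2FC\\| > ``lfc_thr`` and the expressing fraction in
    the enriched group exceeds ``min_frac``. Species call sets are combined
    by ``'union'`` (default) or ``'intersection'``.

    Returns (gene set, per-species DE tables).
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    gene_ids = pd.Index(gene_ids)
    tables: dict[str, pd.DataFrame] = {}
    per_species_sets = []
    for s, (expr, labels) in expr_by_species.items():
        labels = np.asarray(labels)
        present = set(pd.unique(labels))
        if not set(contrast) <= present:
            warnings.warn(f"species {s!r} lacks contrast level(s) "
                          f"{sorted(set(contrast) - present)}; skipped")
            continue
        keep = np.isin(labels, contrast)
        tab = wilcoxon_bh(np.asarray(expr)[:, keep], labels[keep],
                          target=contrast[0], gene_ids=gene_ids)
        enriched_frac = np.where(tab["log2_fold_change"] > 0, tab["frac_in"], tab["frac_out"])
        called = ((tab["adjusted_p"] < adj_p_thr)
                  & (tab["log2_fold_change"].abs() > lfc_thr)
                  & (enriched_frac > min_frac))
        tab["called"] = called
        tables[s] = tab
        per_species_sets.append(set(gene_ids[called.to_numpy()]))
    if not per_species_sets:
        raise ValueError("no species had both contrast levels")
    out = set.union(*per_species_sets) if combine == "union" else set.intersection(*per_species_sets)
    return out, tables


def gradient_gene_set(pb_by_species: dict[str, pd.DataFrame], anchor_gene: str,
                      rho_thr: float = 0.3) -> tuple[set, pd.DataFrame]:
    """Genes co-varying with an anchor gradient gene across MSN groups.

    ``pb_by_species[s]`` is a (genes x MSN groups) log-pseudobulk frame. A
    gene is included when the absolute Spearman correlation of its group
    profile with the anchor's exceeds ``rho_thr`` in ANY species; the anchor
    itself is excluded. A species in which the anchor is constant
    contributes no inclusions.

    Returns (gene set, per-species rho table).
    """
    rho_cols = {}
    for s, pb in pb_by_species.items():
        if anchor_gene not in pb.index:
            raise KeyError(f"anchor gene {anchor_gene!r} missing from species {s!r}")
        if pb.shape[1] < 4:
            raise ValueError("need at least 4 MSN groups for the gradient correlation")
        anchor = pb.loc[anchor_gene].to_numpy(dtype=float)
        if np.ptp(anchor) == 0:
            warnings.warn(f"anchor constant in species {s!r}; contributes no inclusions")
            rho_cols[s] = pd.Series(np.nan, index=pb.index)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant gene rows -> NaN rho
            rho, _ = stats.spearmanr(pb.to_numpy(dtype=float), anchor, axis=1)
        rho_cols[s] = pd.Series(np.asarray(rho)[:-1, -1] if np.ndim(rho) == 2
                                else np.atleast_1d(rho), index=pb.index)
    rho_df = pd.DataFrame(rho_cols)
    hit = (rho_df.abs() > rho_thr).any(axis=1)
    hit[rho_df.index == anchor_gene] = False
    return set(rho_df.index[hit]), rho_df


def select_hvgs(pb_by_species: dict[str, pd.DataFrame], n: int) -> tuple[set, pd.Series]:
    """Top-n highly variable genes by mean per-species log-pseudobulk variance.

    Variance is taken across MSN groups within each species and averaged
    over species; ties break on input gene order.
    """
    scores = []
    for s, pb in pb_by_species.items():
        scores.append(pb.var(axis=1, ddof=0))
    score = pd.concat(scores, axis=1).mean(axis=1)
    if n > len(score):
        raise ValueError(f"n={n} exceeds the {len(score)}-gene universe")
    order = np.argsort(-score.to_numpy(), kind="stable")[:n]
    return set(score.index[order]), score.rename("hvg_score")


@dataclass
class AxisGeneSets:
    """The gene programs compared in the axis-divergence analysis."""

    d1_vs_d2: set = field(default_factory=set)
    striosome_vs_matrix: set = field(default_factory=set)
    dv_gradient: set = field(default_factory=set)
    hvg_background: set = field(default_factory=set)

    def as_dict(self) -> dict[str, set]:
        return {
            "d1_vs_d2": self.d1_vs_d2,
            "striosome_vs_matrix": self.striosome_vs_matrix,
            "dv_gradient": self.dv_gradient,
            "hvg_background": self.hvg_background,
        }


def divergence(tensor: np.ndarray, gene_ids, species_list,
               group_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Cross-species divergence of log-expression profiles.

    ``tensor`` is (genes x groups x species) log-pseudobulk over MSN groups;
    ``group_mask`` optionally restricts to groups present in all species
    (required when some groups are zero-filled placeholders). For gene g and
    species s, D(g, s) is the mean over shared groups t of
    \\|x(g, s, t) - mean_species x(g, ., t)\\|; the pooled divergence is the
    mean of D over species.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3 or tensor.shape[2] < 2:
        raise ValueError("tensor must be (genes x groups x >=2 species)")
    if group_mask is not None:
        tensor = tensor[:, np.asarray(group_mask, dtype=bool), :]
    if tensor.shape[1] == 0:
        raise ValueError("no shared groups across species")
    center = tensor.mean(axis=2, keepdims=True)
    D = np.abs(tensor - center).mean(axis=1)  # (genes x species)
    out = pd.DataFrame(D, index=pd.Index(gene_ids, name="gene_id"),
                       columns=[f"D_{s}" for s in species_list])
    out["pooled_divergence"] = D.mean(axis=1)
    return out


@dataclass
class SetDivergenceReport:
    set_name: str
    n_set: int
    n_background: int
    n_overlap_removed: int
    p_value: float
    median_set: float
    median_background: float
    median_difference: float
    rank_biserial: float
    direction: str  # 'more diverged' | 'less diverged'
    test: str = "mann-whitney-u-two-sided"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_set_divergence(div: pd.DataFrame, gene_set, background,
                           set_name: str = "set") -> SetDivergenceReport:
    """Mann-Whitney comparison of a gene program's divergence vs background.

    Genes shared between set and background are removed from the background
    (count reported). Uses the ``pooled_divergence`` column; two-sided
    p-value, median difference, rank-biserial effect (2*AUC - 1, positive =
    set more diverged) and a direction verdict are returned.
    """
    gene_set = set(gene_set) & set(div.index)
    background = (set(background) & set(div.index))
    overlap = gene_set & background
    background = background - overlap
    if not gene_set or not background:
        raise ValueError("set and background must be non-empty after intersection "
                         "with the divergence table")
    a = div.loc[sorted(gene_set), "pooled_divergence"].to_numpy()
    b = div.loc[sorted(background), "pooled_divergence"].to_numpy()
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    auc = u / (len(a) * len(b))
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return SetDivergenceReport(
        set_name=set_name,
        n_set=len(a),
        n_background=len(b),
        n_overlap_removed=len(overlap),
        p_value=float(p),
        median_set=med_a,
        median_background=med_b,
        median_difference=med_a - med_b,
        rank_biserial=float(2 * auc - 1),
        direction="more diverged" if med_a >= med_b else "less diverged",
    )
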