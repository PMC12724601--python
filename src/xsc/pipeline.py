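"""High-level pipeline stages: simulate -> score -> classify -> report.

Each function here is a thin composition of the library operations with the
file-format glue needed by the command-line interface; calling a stage
through the CLI and calling the underlying functions directly produce the
same outputs. ``run_pipeline`` executes the full synthetic study and writes
TSV outputs plus a JSON run manifest (config snapshot, package version,
seeds, file digests, per-stage timings).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axis import (
    AxisGeneSets,
    axis_de_sets,
    compare_set_divergence,
    divergence,
    gradient_gene_set,
    select_hvgs,
)
from .conservation import (
    accessolog_scores,
    classify_epi,
    classify_regimes,
    expressolog_scores,
)
from .core_data import AnnotatedCounts, OrthologMap, align_orthologs, normalize_log1p, pseudobulk_mean
from .regulatory import classify_region_orthology, evolutionary_distance, group_jaccard, region_ids
from .simulate import (
    MSN_GROUPS,
    SimConfig,
    simulate_accessibility,
    simulate_expression,
    simulate_phylogeny_alignment,
    write_accessibility,
    write_expression,
    write_phylogeny_alignment,
)
from .specificity import gini_specificity, tau_donor_subsampled, tau_matrix

STAGES = ("simulate", "expression", "accessibility", "phylogeny", "axis")


def pseudobulk_all(counts: dict[str, AnnotatedCounts], level: str = "cell_type",
                   scale: float = 1e4):
    """Log-normalized pseudobulk per species (the expressolog default)."""
    return {
        s: pseudobulk_mean(normalize_log1p(ac, scale), ac.cell_meta, level,
                           gene_ids=ac.gene_ids)
        for s, ac in counts.items()
    }


def score_expression(counts: dict[str, AnnotatedCounts], omap: OrthologMap,
                     level: str = "cell_type", tau_iters: int = 10, tau_seed: int = 0,
                     auroc_thr: float = 0.75, tau_thr: float = 0.75) -> pd.DataFrame:
    """Full gene conservation table: expressolog AUROCs, tau, regime label.

    Per-species mean_tau comes from donor-subsampled tau; the regime tau
    summary is the median of per-species mean_tau over species.
    """
    pbs = pseudobulk_all(counts, level)
    ap = align_orthologs(pbs, omap)
    table = expressolog_scores(ap)
    tau_cols = {}
    for s, ac in counts.items():
        mt = tau_donor_subsampled(ac, level, n_iter=tau_iters, seed=tau_seed)["mean_tau"]
        # ortholog rows follow the map order; translate species gene ids
        idx = pd.Series(mt.to_numpy(), index=mt.index)
        tau_cols[f"mean_tau_{s}"] = idx.loc[omap.table[s]].to_numpy()
    for c, v in tau_cols.items():
        table[c] = v
    table["tau_summary"] = np.nanmedian(np.column_stack(list(tau_cols.values())), axis=1)
    table["regime"] = classify_regimes(table["median_score"].to_numpy(),
                                       table["tau_summary"].to_numpy(),
                                       auroc_thr, tau_thr).to_numpy()
    return table


def score_accessibility(access: dict[str, pd.DataFrame], region_map: pd.DataFrame,
                        n_candidates: int = 1000, seed: int = 0,
                        access_thr: float = 0.75, tau_thr: float = 0.75) -> pd.DataFrame:
    """Accessolog scores, per-species tau, Gini and epi class for mapped regions."""
    species = [c for c in region_map.columns if c != "anchor_region_id"]
    table = accessolog_scores(access, region_map[species], n_candidates=n_candidates, seed=seed)
    taus = pd.DataFrame(
        {s: tau_matrix(access[s].loc[region_map[s]].to_numpy(dtype=float)) for s in species},
        index=table.index)
    table[[f"tau_{s}" for s in species]] = taus.to_numpy()
    anchor = species[0]
    g = gini_specificity(access[anchor].loc[region_map[anchor]])
    table["gini"] = g["gini"].to_numpy()
    table["top_cell_type"] = g["top_cell_type"].to_numpy()
    table["epi_class"] = classify_epi(table["median_score"].to_numpy(), taus,
                                      access_thr, tau_thr).to_numpy()
    return table


def axis_divergence_analysis(counts: dict[str, AnnotatedCounts], omap: OrthologMap,
                             msn_groups: pd.DataFrame = MSN_GROUPS,
                             anchor_gene: str | None = None,
                             adj_p_thr: float = 0.01, lfc_thr: float = 1.5,
                             min_frac: float = 0.2, rho_thr: float = 0.3,
                             hvg_n: int | None = None, combine: str = "union",
                             use_planted_sets: dict | None = None):
    """The MSN axis-divergence procedure.

    Builds the D1-vs-D2 and striosome-vs-matrix DE sets, the anchor-gene
    dorsoventral gradient set and the highly-variable background; computes
    per-gene cross-species divergence over shared MSN groups; and tests each
    axis set against the background. ``hvg_n`` defaults to a third of the
    ortholog universe. ``use_planted_sets`` (mapping set name -> gene set)
    overrides the data-derived axis sets, for planted-truth studies.

    Returns ``(AxisGeneSets, divergence table, list of reports)``.
    """
    pbs = pseudobulk_all(counts)
    ap = align_orthologs(pbs, omap)
    ogids = ap.ortholog_index
    msn_types = [t for t in ap.cell_types if t in msn_groups.index]
    if len(msn_types) < 4:
        raise ValueError("need at least 4 MSN groups present in the data")
    msn_mask = np.isin(ap.cell_types, msn_types)
    shared = ap.presence_mask[msn_mask].all(axis=1) if ap.presence_mask is not None else None

    # ortholog-universe ids: use the map row position as the shared key
    def per_species_cells(attr: str):
        out = {}
        for s, ac in counts.items():
            expr = normalize_log1p(ac)
            ct = ac.cell_meta["cell_type"].astype(str)
            lab = ct.map(msn_groups[attr].to_dict()).fillna("other").to_numpy()
            is_msn = ct.isin(msn_types).to_numpy()
            gene_order = omap.table[s].map(
                {g: i for i, g in enumerate(ac.gene_ids)}).to_numpy(dtype=int)
            out[s] = (expr[gene_order][:, is_msn], lab[is_msn])
        return out

    row_ids = ogids
    sets = AxisGeneSets()
    d1d2, de_tables_p = axis_de_sets(per_species_cells("pathway"), row_ids, ("D1", "D2"),
                                     adj_p_thr, lfc_thr, min_frac, combine)
    sm, de_tables_c = axis_de_sets(per_species_cells("compartment"), row_ids,
                                   ("striosome", "matrix"), adj_p_thr, lfc_thr,
                                   min_frac, combine)
    pb_msn = {s: pd.DataFrame(ap.slice(s)[:, msn_mask], index=row_ids,
                              columns=np.asarray(ap.cell_types)[msn_mask])
              for s in ap.species_list}
    hvg_n = hvg_n if hvg_n is not None else max(1, len(row_ids) // 3)
    hvg, hvg_score = select_hvgs(pb_msn, hvg_n)
    sets.d1_vs_d2, sets.striosome_vs_matrix, sets.hvg_background = d1d2, sm, hvg
    if anchor_gene is not None:
        grad, _ = gradient_gene_set(pb_msn, anchor_gene, rho_thr)
        sets.dv_gradient = grad
    if use_planted_sets:
        for name, genes in use_planted_sets.items():
            setattr(sets, name, set(genes))
    tensor = ap.tensor[:, msn_mask, :]
    if shared is not None:
        tensor = tensor[:, shared, :]
    div = divergence(tensor, row_ids, ap.species_list)
    reports = []
    for name in ("d1_vs_d2", "striosome_vs_matrix", "dv_gradient"):
        genes = getattr(sets, name)
        if genes:
            reports.append(compare_set_divergence(div, genes, sets.hvg_background, name))
    return sets, div, reports


# ---------------------------------------------------------------------------
# end-to-end run with manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: SimConfig, out_dir, stages=STAGES, n_candidates: int = 1000) -> dict:
    """Run the synthetic study end to end and write outputs plus a manifest.

    Unknown stage names raise before anything is written. Returns the
    manifest dict (also written to ``<out_dir>/manifest.json``).
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown}; valid stages are {list(STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": json.loads(cfg.to_json()),
        "seed": cfg.seed,
        "stages": list(stages),
        "timings_s": {},
        "outputs": {},
        "errors": {},
    }

    sim_expr = sim_access = sim_phylo = None
    for stage in stages:
        t0 = time.time()
        try:
            if stage == "simulate":
                sim_expr = simulate_expression(cfg)
                sim_access = simulate_accessibility(cfg)
                sim_phylo = simulate_phylogeny_alignment(cfg)
                write_expression(out / "sim", *sim_expr)
                write_accessibility(out / "sim", *sim_access)
                write_phylogeny_alignment(out / "sim", *sim_phylo)
            elif stage == "expression":
                if sim_expr is None:
                    sim_expr = simulate_expression(cfg)
                counts, omap, _ = sim_expr
                tab = score_expression(counts, omap, tau_seed=cfg.seed)
                tab.to_csv(out / "gene_conservation.tsv", sep="\t")
            elif stage == "accessibility":
                if sim_access is None:
                    sim_access = simulate_accessibility(cfg)
                access, region_map, liftover, _ = sim_access
                tab = score_accessibility(access, region_map,
                                          n_candidates=n_candidates, seed=cfg.seed)
                tab.to_csv(out / "region_conservation.tsv", sep="\t")
                regions = pd.DataFrame({
                    "Chromosome": "chr1",
                    "Start": np.arange(cfg.n_regions) * (2 * cfg.region_length)})
                regions["End"] = regions["Start"] + cfg.region_length
                regions["region_id"] = region_ids(regions)
                oc = classify_region_orthology(regions, liftover, min_frac=0.5)
                oc.to_csv(out / "region_orthology.tsv", sep="\t")
                anchor = list(access)[0]
                med = access[anchor].to_numpy().mean()
                jac = group_jaccard((access[anchor] > med).astype(int))
                jac.to_csv(out / "group_jaccard.tsv", sep="\t")
            elif stage == "phylogeny":
                if sim_phylo is None:
                    sim_phylo = simulate_phylogeny_alignment(cfg)
                newick, fractions, _ = sim_phylo
                dist = evolutionary_distance(newick, fractions, align_thr=0.9)
                dist.to_frame().to_csv(out / "evolutionary_distance.tsv", sep="\t")
            elif stage == "axis":
                if sim_expr is None:
                    sim_expr = simulate_expression(cfg)
                counts, omap, truth = sim_expr
                sets, div, reports = axis_divergence_analysis(
                    counts, omap, anchor_gene=truth.anchor_gene)
                div.to_csv(out / "axis_divergence.tsv", sep="\t")
                rows = [r.as_dict() for r in reports]
                (out / "axis_reports.json").write_text(json.dumps(rows, indent=2))
                pd.DataFrame([(k, g) for k, genes in sets.as_dict().items() for g in sorted(genes)],
                             columns=["set_name", "gene_id"]
                             ).to_csv(out / "axis_gene_sets.tsv", sep="\t", index=False)
        except Exception as exc:  # record and re-raise: partial outputs stay on disk
            manifest["errors"][stage] = repr(exc)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["timings_s"][stage] = round(time.time() - t0, 3)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
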