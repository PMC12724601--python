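"""Synthetic multi-species data with planted ground truth for every stage.

The generator emulates, at desk scale, the statistical structure that the
cross-species conservation pipeline assumes in real data:

* per-species single-nucleus counts with donor random effects and
  log-normal library sizes, drawn gamma-Poisson (negative binomial) around
  per-cell-type rate profiles;
* four planted gene evolutionary regimes — conserved markers (shared
  near-one-hot profiles), conserved broadly-expressed genes (shared
  low-amplitude profiles), divergent markers (marker cell type reassigned
  per species at the shuffle rate) and divergent broad genes (structured
  low-amplitude profiles that decorrelate across species, with per-species
  magnitude shifts);
* MSN axis modules layered on the conserved-broad genes: D1/D2 pathway and
  striosome/matrix compartment effects with *large* cross-species noise, and
  a dorsoventral gradient module anchored on a CNR1-like gene with *small*
  cross-species noise, so that axis programs differ in evolutionary
  lability by construction;
* cCRE accessibility matrices with planted epi-conservation classes and
  liftover tables whose aligned-bp values make planted orthologous regions
  pass (and species-specific regions fail) the 50% alignment rule;
* a pure-birth phylogeny with region origin nodes and alignment fractions
  drawn high (Beta(20, 1)) inside the origin clade and low (Beta(1, 20))
  outside.

All generators are pure functions of :class:`SimConfig`: randomness flows
from ``SeedSequence([seed, stage])`` streams, so reruns are byte-identical
and stages are independent of execution order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import AnnotatedCounts, OrthologMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "MSN_GROUPS",
    "simulate_expression",
    "simulate_accessibility",
    "simulate_phylogeny_alignment",
    "write_expression",
    "write_accessibility",
    "write_phylogeny_alignment",
]

# 8 MSN groups in a 2 (pathway) x 2 (compartment) factorial with a
# dorsoventral position per group, plus two non-MSN types.
MSN_GROUPS = pd.DataFrame(
    {
        "group": ["D1_strio_d", "D1_strio_v", "D1_matrix_d", "D1_matrix_v",
                   "D2_strio_d", "D2_strio_v", "D2_matrix_d", "D2_matrix_v"],
        "pathway": ["D1", "D1", "D1", "D1", "D2", "D2", "D2", "D2"],
        "compartment": ["striosome", "striosome", "matrix", "matrix",
                         "striosome", "striosome", "matrix", "matrix"],
        "dv_position": [0.0, 1.0, 1 / 3, 2 / 3, 2 / 3, 1 / 3, 1.0, 0.0],
    }
).set_index("group")

NON_MSN_TYPES = ["interneuron", "astrocyte"]

REGIMES = ("conserved_marker", "conserved_broad", "divergent_marker", "divergent_broad")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, fully serializable.

    Defaults define the desk-scale study: 3 species, 10 cell types (8 MSN
    groups + 2 non-MSN), 6 donors per species, 50 cells per (type, donor),
    2,000 genes, 5,000 regions, a 24-leaf tree.
    """

    seed: int = 0
    species: tuple = ("speciesA", "speciesB", "speciesC")
    n_donors: int = 6
    cells_per_type_donor: int = 50
    n_genes: int = 2000
    regime_proportions: dict = field(default_factory=lambda: {
        "conserved_marker": 0.08, "conserved_broad": 0.24,
        "divergent_marker": 0.07, "divergent_broad": 0.61})
    marker_fold: float = 50.0            # marker cell-type enrichment over baseline
    broad_profile_sigma: float = 0.5     # lognormal sd of shared broad profiles
    divergent_profile_sigma: float = 0.3  # lognormal sd of divergent_broad profiles
    divergence_shuffle_rate: float = 1.0  # 0 = divergent genes degenerate to conserved
    species_shift_sigma: float = 0.4     # per-species magnitude shift of divergent_broad
    noise_base_sigma: float = 0.15       # cross-species lognormal rate noise, all genes
    axis_module_size: int = 80
    axis_fold: float = 6.0               # pathway / compartment group enrichment
    gradient_slope: float = 2.0          # ln-scale dv gradient amplitude
    axis_noise_sigma: float = 0.5        # pathway & compartment cross-species noise
    gradient_noise_sigma: float = 0.05   # gradient cross-species noise
    abundance_sigma: float = 0.4         # lognormal spread of per-gene abundance
    nb_dispersion: float = 10.0          # gamma-Poisson shape (larger = less overdispersed)
    donor_sigma: float = 0.2             # per (gene, donor) lognormal effect
    library_log_mean: float = np.log(5000.0)
    library_log_sigma: float = 0.3
    n_regions: int = 5000
    region_length: int = 500
    orthology_proportions: dict = field(default_factory=lambda: {
        "orthologous": 0.7, "species_specific": 0.2, "partial": 0.1})
    epi_proportions: dict = field(default_factory=lambda: {
        "epi_conserved": 0.5, "species_biased": 0.25, "other": 0.25})
    access_profile_sigma: float = 1.0
    access_noise_sigma: float = 0.1
    access_biased_fold: float = 20.0
    n_leaves: int = 24

    def __post_init__(self) -> None:
        for name, props in (("regime_proportions", self.regime_proportions),
                            ("orthology_proportions", self.orthology_proportions),
                            ("epi_proportions", self.epi_proportions)):
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} must be non-negative")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("n_donors", "cells_per_type_donor", "n_genes", "n_regions",
                     "region_length", "axis_module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_leaves < 3:
            raise ValueError("tree needs at least 3 leaves")
        if len(self.species) < 2:
            raise ValueError("need at least 2 species")
        if 3 * self.axis_module_size > self.regime_proportions["conserved_broad"] * self.n_genes:
            raise ValueError("axis modules exceed the conserved_broad gene pool")

    @property
    def cell_types(self) -> list[str]:
        return list(MSN_GROUPS.index) + NON_MSN_TYPES

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["species"] = list(d["species"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["species"] = tuple(d["species"])
        return cls(**d)


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    genes: pd.DataFrame | None = None       # ortholog_id, regime, axis_module, marker types
    regions: pd.DataFrame | None = None     # region_id, orthology_class, epi_class, ...
    tree_newick: str | None = None
    anchor_gene: str | None = None


def _counts_partition(n: int, proportions: dict) -> list[str]:
    """Deterministic label vector honoring proportions (largest remainder)."""
    keys = list(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for j in order[:rem]:
        base[j] += 1
    labels = []
    for k, c in zip(keys, base):
        labels.extend([k] * c)
    return labels


def simulate_expression(cfg: SimConfig) -> tuple[dict[str, AnnotatedCounts], OrthologMap, SimTruth]:
    """Per-species counts with planted regimes and MSN axis modules."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    S, G = len(cfg.species), cfg.n_genes
    types = cfg.cell_types
    K = len(types)
    msn_idx = np.arange(len(MSN_GROUPS))
    dv = MSN_GROUPS["dv_position"].to_numpy()
    is_d1 = (MSN_GROUPS["pathway"] == "D1").to_numpy()
    is_strio = (MSN_GROUPS["compartment"] == "striosome").to_numpy()

    regimes = np.array(_counts_partition(G, cfg.regime_proportions))
    genes = pd.DataFrame({"ortholog_id": [f"OG{i:05d}" for i in range(G)],
                          "regime": regimes})
    genes["axis_module"] = "none"
    broad_pool = np.flatnonzero(regimes == "conserved_broad")
    mod_genes = broad_pool[: 3 * cfg.axis_module_size]
    for m, name in enumerate(("pathway", "compartment", "gradient")):
        genes.loc[mod_genes[m * cfg.axis_module_size:(m + 1) * cfg.axis_module_size],
                  "axis_module"] = name
    anchor_pos = int(mod_genes[2 * cfg.axis_module_size])  # first gradient gene

    # --- base linear-rate profiles per species: (S, G, K) -----------------
    B = np.ones((S, G, K))
    marker_type = np.full((S, G), -1)
    for g in np.flatnonzero(regimes == "conserved_marker"):
        t = rng.integers(K)
        marker_type[:, g] = t
        B[:, g, t] = cfg.marker_fold
    in_module = (genes["axis_module"] != "none").to_numpy()
    for g in np.flatnonzero(regimes == "conserved_broad"):
        prof = np.exp(rng.normal(0, cfg.broad_profile_sigma, K))
        # axis-module genes keep a flat base: their cross-cell-type structure
        # comes from the planted module effect, not from random profile noise
        # (random structure would inflate their tau into the marker band)
        B[:, g, :] = 1.0 if in_module[g] else prof[None, :]
    rate = float(cfg.divergence_shuffle_rate)
    if not 0 <= rate <= 1:
        raise ValueError("divergence_shuffle_rate must be in [0, 1]")
    for g in np.flatnonzero(regimes == "divergent_marker"):
        t0 = int(rng.integers(K))
        marker_type[:, g] = t0
        for s in range(S):
            # with prob `rate`, this species' marker cell type is reassigned
            if rng.random() < rate:
                marker_type[s, g] = (t0 + 1 + int(rng.integers(K - 1))) % K
            B[s, g, marker_type[s, g]] = cfg.marker_fold
    # divergent_broad: structured log-profiles that decorrelate across species.
    # Each species' profile is a rotation-mixture of two shared latent
    # profiles, so at shuffle rate 1 the pairwise cross-species correlation
    # is cos(2*pi/S) (= -1/2 for 3 species) and the planted divergence is a
    # stable property rather than a sampling accident; at rate 0 the profile
    # is shared and the gene degenerates to conserved_broad.
    theta = 2 * np.pi * np.arange(S) / S
    for g in np.flatnonzero(regimes == "divergent_broad"):
        a = rng.normal(0, cfg.divergent_profile_sigma, K)
        b = rng.normal(0, cfg.divergent_profile_sigma, K)
        shared = rng.normal(0, cfg.divergent_profile_sigma, K)
        shifts = rng.normal(0, cfg.species_shift_sigma, S)
        for s in range(S):
            anti = np.cos(theta[s]) * a + np.sin(theta[s]) * b
            B[s, g, :] = np.exp((1 - rate) * shared + rate * anti + shifts[s])

    # --- axis-module group effects on MSN groups --------------------------
    axis_sign = np.zeros(G)
    for g in np.flatnonzero((genes["axis_module"] == "pathway").to_numpy()):
        sign = rng.choice([-1.0, 1.0])
        axis_sign[g] = sign
        eff = np.where(is_d1, sign, -sign) * np.log(cfg.axis_fold) / 2.0
        B[:, g, msn_idx] *= np.exp(eff)[None, :]
    for g in np.flatnonzero((genes["axis_module"] == "compartment").to_numpy()):
        sign = rng.choice([-1.0, 1.0])
        axis_sign[g] = sign
        eff = np.where(is_strio, sign, -sign) * np.log(cfg.axis_fold) / 2.0
        B[:, g, msn_idx] *= np.exp(eff)[None, :]
    for g in np.flatnonzero((genes["axis_module"] == "gradient").to_numpy()):
        sign = 1.0 if g == anchor_pos else rng.choice([-1.0, 1.0])
        axis_sign[g] = sign
        B[:, g, msn_idx] *= np.exp(sign * cfg.gradient_slope * (dv - 0.5))[None, :]
    genes["axis_sign"] = axis_sign

    # --- cross-species rate noise, module-specific scale ------------------
    sigma_g = np.full(G, cfg.noise_base_sigma)
    sigma_g[(genes["axis_module"] == "pathway").to_numpy()] = cfg.axis_noise_sigma
    sigma_g[(genes["axis_module"] == "compartment").to_numpy()] = cfg.axis_noise_sigma
    sigma_g[(genes["axis_module"] == "gradient").to_numpy()] = cfg.gradient_noise_sigma
    genes["cross_species_sigma"] = sigma_g
    B *= np.exp(rng.normal(0, 1, B.shape) * sigma_g[None, :, None])

    abundance = np.exp(rng.normal(0, cfg.abundance_sigma, G))
    B *= abundance[None, :, None]

    # --- counts -----------------------------------------------------------
    out: dict[str, AnnotatedCounts] = {}
    n_cells = K * cfg.n_donors * cfg.cells_per_type_donor
    for s, sp_name in enumerate(cfg.species):
        donor_eff = np.exp(rng.normal(0, cfg.donor_sigma, (G, cfg.n_donors)))
        blocks, meta_rows = [], []
        for ti, t in enumerate(types):
            for d in range(cfg.n_donors):
                rate = B[s, :, ti] * donor_eff[:, d]
                p = rate / rate.sum()
                depths = np.exp(rng.normal(cfg.library_log_mean, cfg.library_log_sigma,
                                           cfg.cells_per_type_donor))
                mu = p[:, None] * depths[None, :]
                lam = rng.gamma(cfg.nb_dispersion, mu / cfg.nb_dispersion)
                blocks.append(sp.csc_matrix(rng.poisson(lam)))
                for c in range(cfg.cells_per_type_donor):
                    meta_rows.append((f"{sp_name}_{t}_d{d}_c{c}", sp_name, f"{sp_name}_donor{d}", t))
        counts = sp.hstack(blocks, format="csr")
        meta = pd.DataFrame(meta_rows, columns=["cell_id", "species", "donor_id", "cell_type"]
                            ).set_index("cell_id")
        gene_ids = pd.Index([f"{sp_name}_G{i:05d}" for i in range(G)])
        out[sp_name] = AnnotatedCounts(counts, gene_ids, meta)
        assert out[sp_name].n_cells == n_cells

    omap = OrthologMap(pd.DataFrame(
        {sp_name: [f"{sp_name}_G{i:05d}" for i in range(G)] for sp_name in cfg.species},
        index=pd.Index(genes["ortholog_id"], name="ortholog_id")))
    for s, sp_name in enumerate(cfg.species):
        genes[f"marker_type_{sp_name}"] = [types[t] if t >= 0 else "" for t in marker_type[s]]
    truth = SimTruth(genes=genes.set_index("ortholog_id"),
                     anchor_gene=f"OG{anchor_pos:05d}")
    return out, omap, truth


def simulate_accessibility(cfg: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame,
                                                    dict[str, pd.DataFrame], SimTruth]:
    """cCRE accessibility with planted epi classes plus liftover tables.

    Returns ``(access, region_map, liftover, truth)``: per-species
    (regions x cell-types) accessibility frames, the orthologous-region map
    (anchor-species ids, one column per species), per-target-species
    liftover tables, and the planted truth table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    R, K, S = cfg.n_regions, len(cfg.cell_types), len(cfg.species)
    anchor = cfg.species[0]
    length = cfg.region_length
    starts = np.arange(R) * (2 * length)
    regions = pd.DataFrame({"Chromosome": "chr1", "Start": starts, "End": starts + length})
    regions["region_id"] = (regions["Chromosome"].astype(str) + ":"
                            + regions["Start"].astype(str) + "-" + regions["End"].astype(str))

    ortho_class = np.array(_counts_partition(R, cfg.orthology_proportions))
    rng.shuffle(ortho_class)
    epi_class = np.array(["na"] * R, dtype=object)
    ortho_idx = np.flatnonzero(ortho_class == "orthologous")
    planted = _counts_partition(len(ortho_idx), cfg.epi_proportions)
    epi_class[ortho_idx] = planted
    biased_species = np.array([""] * R, dtype=object)
    biased = np.flatnonzero(epi_class == "species_biased")
    biased_species[biased] = rng.choice(list(cfg.species), size=len(biased))

    # accessibility profiles
    access: dict[str, pd.DataFrame] = {}
    shared = np.exp(rng.normal(0, cfg.access_profile_sigma, (R, K)))
    per_species_ids = {s: [f"{s}_R{i:05d}" for i in range(R)] for s in cfg.species}
    for s in cfg.species:
        X = np.exp(rng.normal(0, cfg.access_profile_sigma, (R, K)))  # default: independent
        cons = epi_class == "epi_conserved"
        X[cons] = shared[cons] * np.exp(rng.normal(0, cfg.access_noise_sigma,
                                                   (int(cons.sum()), K)))
        for r in biased:
            if biased_species[r] == s:
                prof = np.ones(K)
                prof[rng.integers(K)] = cfg.access_biased_fold
                X[r] = prof
            else:
                X[r] = np.exp(rng.normal(0, 0.2, K))  # flat-ish, low specificity
        access[s] = pd.DataFrame(X, index=per_species_ids[s], columns=cfg.cell_types)

    region_map = pd.DataFrame({s: np.asarray(per_species_ids[s])[ortho_idx]
                               for s in cfg.species})
    region_map.insert(0, "anchor_region_id", regions["region_id"].to_numpy()[ortho_idx])

    # liftover tables: aligned_bp passes the 50% rule iff planted to match
    targets = list(cfg.species[1:])
    liftover: dict[str, pd.DataFrame] = {}
    partial_pass = {r: rng.integers(len(targets)) for r in np.flatnonzero(ortho_class == "partial")}
    for j, tgt in enumerate(targets):
        pass_mask = (ortho_class == "orthologous") | np.array(
            [partial_pass.get(r, -1) == j for r in range(R)])
        frac = np.where(pass_mask, rng.uniform(0.7, 1.0, R), rng.uniform(0.0, 0.3, R))
        liftover[tgt] = pd.DataFrame({
            "region_id": regions["region_id"],
            "target_species": tgt,
            "aligned_bp": np.round(frac * length).astype(int),
            "target_chrom": "chr1",
            "target_start": starts,
            "target_end": starts + length,
        })

    truth_df = pd.DataFrame({
        "region_id": regions["region_id"],
        "orthology_class": ortho_class,
        "epi_class": epi_class,
        "biased_species": biased_species,
    }).set_index("region_id")
    truth_df["anchor_species_region"] = per_species_ids[anchor]
    truth = SimTruth(regions=truth_df)
    return access, region_map, liftover, truth


def _pure_birth_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Yule-style topology by random leaf splitting; Exp(1) branch lengths."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.label = "root"
    leaves = []
    for _ in range(2):
        ch = tree.seed_node.new_child()
        leaves.append(ch)
    next_internal = 0
    while len(leaves) < n_leaves:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        node.label = f"N{next_internal}"
        next_internal += 1
        for _ in range(2):
            leaves.append(node.new_child())
    for i, lf in enumerate(leaves):
        lf.taxon = taxa.new_taxon(label=f"L{i}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(np.round(rng.exponential(1.0), 6))
    return tree


def simulate_phylogeny_alignment(cfg: SimConfig) -> tuple[str, pd.DataFrame, SimTruth]:
    """Pure-birth tree plus region x node alignment fractions.

    Each region gets an origin node; fractions are Beta(20, 1) for nodes in
    the origin's clade (origin + descendants) and Beta(1, 20) outside.
    Returns ``(newick, fraction_matrix, truth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))
    tree = _pure_birth_tree(cfg.n_leaves, rng)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()

    def node_name(nd):
        return nd.taxon.label if nd.taxon is not None else nd.label

    nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    names = [node_name(nd) for nd in nodes]
    clade = {}
    for nd in nodes:
        clade[node_name(nd)] = {node_name(x) for x in nd.preorder_iter()
                                if x.parent_node is not None}
    origin_pool = ["root"] + names
    origins = rng.choice(origin_pool, size=cfg.n_regions)
    F = np.empty((cfg.n_regions, len(names)))
    all_names = set(names)
    for i, og in enumerate(origins):
        inside = all_names if og == "root" else clade[og]
        in_mask = np.array([n in inside for n in names])
        F[i, in_mask] = rng.beta(20, 1, int(in_mask.sum()))
        F[i, ~in_mask] = rng.beta(1, 20, int((~in_mask).sum()))
    region_ids = [f"chr1:{i * 1000}-{i * 1000 + cfg.region_length}" for i in range(cfg.n_regions)]
    fractions = pd.DataFrame(F, index=pd.Index(region_ids, name="region_id"), columns=names)
    truth = SimTruth(regions=pd.DataFrame({"region_id": region_ids, "origin_node": origins}
                                          ).set_index("region_id"),
                     tree_newick=newick)
    return newick, fractions, truth


# ---------------------------------------------------------------------------
# text-format writers (round-trip through the core_data readers)
# ---------------------------------------------------------------------------

def write_expression(out_dir, counts: dict[str, AnnotatedCounts], omap: OrthologMap,
                     truth: SimTruth) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, ac in counts.items():
        ac.write_mtx(out / f"{s}_counts.mtx", out / f"{s}_genes.tsv", out / f"{s}_meta.tsv")
    omap.to_tsv(out / "orthologs.tsv")
    truth.genes.to_csv(out / "gene_truth.tsv", sep="\t")


def write_accessibility(out_dir, access: dict[str, pd.DataFrame], region_map: pd.DataFrame,
                        liftover: dict[str, pd.DataFrame], truth: SimTruth) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, df in access.items():
        df.rename_axis("region_id").to_csv(out / f"{s}_access.tsv", sep="\t")
    region_map.to_csv(out / "region_map.tsv", sep="\t", index=False)
    for s, df in liftover.items():
        df.to_csv(out / f"liftover_{s}.tsv", sep="\t", index=False)
    truth.regions.to_csv(out / "region_truth.tsv", sep="\t")


def write_phylogeny_alignment(out_dir, newick: str, fractions: pd.DataFrame,
                              truth: SimTruth) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(newick + "\n")
    fractions.to_csv(out / "alignment_fractions.tsv", sep="\t")
    truth.regions.to_csv(out / "phylo_region_truth.tsv", sep="\t")
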