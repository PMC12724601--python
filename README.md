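# xsc — cross-species cell-type conservation analysis

`xsc` quantifies how well cell-type–resolved molecular programs are conserved
across species, for labs comparing single-nucleus RNA and ATAC atlases of
homologous tissues (the motivating system is the primate basal ganglia and
its medium spiny neurons, MSNs). It implements:

* **Expressologs / accessologs** — for each 1:1 ortholog pair (gene *i* in a
  reference species, gene *j* in a query species), the Pearson correlation of
  their cell-type pseudobulk profiles is ranked against *i*'s correlation
  with every other query gene and converted to an AUROC,

  `AUROC = (r_ij − 1) / (N − 1)`,

  where `r_ij` is the ascending average-tie rank among `N` query genes. 1.0
  means the ortholog is the single best profile match, 0.5 is chance. The
  per-gene conservation score is the median AUROC over all ordered species
  pairs. Accessologs apply the same statistic to orthologous cCRE
  (candidate cis-regulatory element) accessibility profiles.
* **Cell-type specificity** — tau for genes,
  `τ = Σᵢ (1 − xᵢ/x_max) / (k − 1)`, estimated over repeated random donor
  subsamples (`max(2, ⌈D/3⌉)` of `D` donors, 10 draws), and the Gini
  coefficient for cCREs, computed on ascending-sorted accessibility.
* **Evolutionary regimes** — genes classified by conservation × specificity
  at 0.75/0.75 thresholds into conserved/divergent markers and
  broadly-expressed genes; cCREs into epi-conserved vs species-biased
  classes.
* **Regulatory evolution** — cCRE orthology from liftover tables (matched
  when ≥50% of bases align), phylogeny-weighted evolutionary distance
  (normalized branch lengths summed over nodes with ≥90% of bases aligned),
  strand-aware promoter windows (−1 kb/+500 bp), minimum-overlap feature
  annotation (≥250 bp), and Jaccard similarity of binarized peak sets.
* **MSN axis divergence** — gene programs for the D1/D2 pathway,
  striosome/matrix compartment (per-species Wilcoxon + BH differential
  expression) and the dorsoventral gradient (Spearman co-variation with an
  anchor gene), compared against a highly-variable-gene background by
  per-gene cross-species divergence: the mean absolute deviation of
  log-expression from the cross-species mean profile over shared MSN groups.
* **A synthetic multi-species generator** with planted regimes, axis
  modules, epi-conservation classes and phylogenetic origins, used by the
  test suite to verify that every stage recovers its planted truth.

## Worked example

```python
import xsc
from xsc.pipeline import score_expression

cfg = xsc.SimConfig(seed=1)                      # 3 species, 2,000 genes
counts, orthologs, truth = xsc.simulate_expression(cfg)
table = score_expression(counts, orthologs, tau_seed=7)
print(table["regime"].value_counts())
print("recovery:", (table["regime"] == truth.genes["regime"]).mean())
```

prints

```
regime
divergent_broad     1221
conserved_broad      442
conserved_marker     200
divergent_marker     137
Name: count, dtype: int64
recovery: 0.9785
```

i.e. the four planted evolutionary regimes are recovered for 97.9% of genes
at this tau seed (the per-gene table also carries the six pairwise AUROCs,
the median expressolog score, and per-species donor-subsampled mean tau).
The same stages are exposed as a CLI:

```bash
xsc simulate --out-dir sim/ --seed 1
xsc expressolog --data-dir sim/ --out expr.tsv
xsc tau --counts sim/speciesA_counts.mtx --genes sim/speciesA_genes.tsv \
        --meta sim/speciesA_meta.tsv --out tau_A.tsv
xsc run --out results/        # end-to-end with a JSON run manifest
```

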