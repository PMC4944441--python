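# dysbiome

Longitudinal analysis of gut-microbiome dysbiosis in pediatric
inflammatory bowel disease (IBD) cohorts: per-sample dysbiosis and
diversity metrics, cluster-robust association models against
inflammation markers, phylogenetic beta-diversity variance
partitioning, and prediction of treatment response from pretreatment
stool samples.

The package is written for microbiome researchers who have genus- or
OTU-level 16S count tables (QIIME-1 `summarize_taxa`-style lineage
strings), per-sample clinical metadata (subject, group, collection
day, fecal calprotectin, PCDAI/PUCAI), and optionally a rooted
phylogeny — and who want the full analysis reproducible from a single
seed. A synthetic cohort generator with known ground truth makes
every stage testable without patient data.

## What it computes

**Microbial dysbiosis (MD) index.** Per sample,

MD = log10 [ (Σ increased-in-CD abundance + ε) / (Σ decreased-in-CD abundance + ε) ]

where the increased set is the families Enterobacteriaceae,
Pasteurellaceae, Fusobacteriaceae, Neisseriaceae, Veillonellaceae and
Gemellaceae, and the decreased set is the orders Bacteroidales and
Clostridiales (excluding Veillonellaceae) plus Erysipelotrichaceae and
Bifidobacteriaceae; ε = 1e-5 guards the log. Shannon diversity
H = −Σ pᵢ log₂ pᵢ is computed alongside, and both metrics have a
repeated-rarefaction variant (median over 10,000 subsamples without
replacement to 3,155 reads).

**Weighted GEE.** Markers (calprotectin, MD index, Shannon) and genus
abundances are modeled by linear generalized estimating equations
with an independence working correlation: β solves
Σᵢ Xᵢ′Wᵢ(yᵢ − Xᵢβ) = 0 over subjects i, with observation weights
1/(visits of that subject), robust covariance B⁻¹(Σᵢ gᵢgᵢ′)B⁻¹
(B = Σᵢ Xᵢ′WᵢXᵢ, gᵢ the cluster score), and two-sided Wald χ²₁ tests.
The genus-by-genus screen applies a Bonferroni threshold 0.05/G over
the G genera that exceed 0.15 % relative abundance in some sample.

**Beta diversity.** Weighted UniFrac distances
d(A,B) = Σ_branches l_b·|A_b − B_b| from a rooted tree, partitioned by
sequential (Type-I) PERMANOVA with permutation p-values — responder
status entered before IBD subtype, as when checking whether subtypes
may be pooled.

**Treatment-response forest.** A 25,001-tree random forest predicts
responder vs non-responder from each subject's first pretreatment
sample, with inverse-class-size weights inside the Gini criterion and
leaf votes (or a balanced per-class subsample per tree), out-of-bag
confusion/accuracy, rank-based AUC, Gini importances, and
significance from refitting under 10,000 label permutations.

## Worked example

```python
from dysbiome.synth import CohortSimConfig, simulate_cohort
from dysbiome.diversity import sample_metrics
from dysbiome.gee import GEEModelSpec, model_suite

table, metadata, truth, tree = simulate_cohort(CohortSimConfig(seed=7))
metrics = sample_metrics(table)           # Shannon + MD index per sample
suite = model_suite(metrics, metadata, specs=(
    GEEModelSpec("md_baseline", "md_index",
                 ("diagnosis", "time", "diagnosis:time")),
    GEEModelSpec("cal_on_md", "calprotectin", ("md_index",)),
))
```

This simulates the default 29-subject cohort (10 controls, 15 Crohn's
disease, 4 ulcerative colitis; 186 stool samples at seed 7) and prints:

```
      model     term  beta      se          p
md_baseline       CD 1.162 0.05898  2.138e-86
md_baseline       UC 2.065 0.04132          0
  cal_on_md md_index 245.3   7.886 2.194e-212
```

Reading: at baseline the CD group's MD index sits ≈1.2 log10 units
above controls and the UC group ≈2.1 units above (the generator's
configured group offsets of +0.86/+1.75 plus the non-responder
signature that overlaps the increased-in-CD families), and each MD
unit carries ≈245 µg/g more fecal calprotectin (true simulated slope
260, within the robust CI).

The same pipeline runs from the shell:

```
dysbiome simulate --seed 7 --out cohort/
dysbiome all --table cohort/genus_counts.tsv --metadata cohort/metadata.tsv \
    --tree cohort/tree.nwk --out results/ --seed 7
```

writing per-sample metrics, GEE tables, genus screens, the PERMANOVA
partition, the forest report (confusion, ROC/PR points, importances,
permutation p-values) and a manifest echoing the config and seed.
Reruns with the same inputs and seed are byte-identical.

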