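# seagea

Seascape genomics in Python: detect SNP loci putatively under selection
along marine environmental gradients and characterize the putatively
adaptive population structure they imply.

Marine populations often show very weak neutral differentiation
(F<sub>ST</sub> ~ 0.001–0.1) across large, environmentally heterogeneous
coastlines, yet strong local adaptation to gradients in temperature,
salinity, current velocity or productivity.  `seagea` implements the
genotype–environment association (GEA) workflow used to detect such
adaptation from reduced-representation SNP panels:

1. **QC** — minor-allele dosage coding from VCF, missingness and minor
   allele count (MAC ≥ 3) filters, and removal of duplicates/close kin by a
   pairwise relatedness screen (|R| ≥ 0.5).
2. **Spatial covariates** — least-cost oceanic distances over a water-mask
   raster, transformed to distance-based Moran's eigenvector maps (dbMEM)
   and forward-selected against the genotype response.
3. **Environmental selection** — z-scoring, pairwise-correlation (|r| > 0.7)
   and VIF (≥ 3) pruning, then permutation forward selection.
4. **Partial RDA** — the core model.  With Y the centered dosage matrix,
   X the retained environmental predictors and Z the selected MEMs, a
   partial redundancy analysis Y ~ X | Z partitions total genotype variance
   into conditioned (spatial), constrained (environmental) and residual
   fractions; permutation ANOVA (1000 permutations) tests the model, each
   term and each axis; loci whose loadings lie beyond ±3 SD on significant
   constrained axes are candidate adaptive markers, each assigned its best
   predictor by Spearman rank correlation.
5. **Structure** — per-site H<sub>O</sub>/H<sub>E</sub>, pairwise
   Weir–Cockerham F<sub>ST</sub> with 10,000 permutations and
   Benjamini–Yekutieli control (FDR < 10%), PCA, and EM ancestry clustering
   with AIC and cross-validation choice of K (1–9).
6. **Enrichment** — SNP genomic context (exonic/intronic/promoter/
   intergenic) from GFF3 gene models and GO-term over-representation among
   candidates by Fisher's exact test (FDR ≤ 5%).

A synthetic seascape generator (`seagea.simgen`) with a planted truth table
— stepping-stone neutral drift calibrated to a target F<sub>ST</sub>, plus
logistic environmental clines at known loci — makes every stage testable
without external data.  See `docs/methods.md` for the models, defaults and
limitations.

## Worked example

```python
from seagea.simgen import SimConfig, generate_fixture
from seagea.pipeline import PipelineConfig, run_pipeline

fx = generate_fixture(SimConfig(seed=3), outdir="fixture")   # writes VCF, CSVs, mask, GFF3
cfg = PipelineConfig(
    vcf=fx.paths["vcf"], samples=fx.paths["samples"], env=fx.paths["env"],
    mask=fx.paths["mask"], gff=fx.paths["gff"], go_map=fx.paths["go_map"],
    truth=fx.paths["truth"], seed=3,
)
result = run_pipeline(cfg, "out")
print(open("out/report.txt").read())
```

prints

```
seagea pipeline report
========================
QC: 203 -> 200 individuals, 2050 -> 2050 loci
MEMs selected: ['MEM1', 'MEM2', 'MEM3', 'MEM5', 'MEM4']
Environmental variables retained: ['sst_min', 'pp_max', 'salinity_max']
Variance partition: conditioned=0.0722 constrained=0.0215 residual=0.9064
Overall p=0.000999001; significant axes: [1, 2, 3]; candidates: 35
Best K (AIC): 8; best K (CV): 6; significant FST pairs: 36
GO terms significant: 0 of 31
Truth recovery: sensitivity=0.22, FDR=0.6857142857
```

Reading the report: the three planted duplicates were pruned (203 → 200
individuals); all five positive spatial eigenvectors were selected; one
environmental variable was aliased by the spatial conditioners and three
were retained; space explains 7.2% and environment a further 2.2% of
genotype variance; 35 loci exceed ±3 SD on the three significant axes.  The
low sensitivity (0.22) against the planted truth is the documented
space–environment confounding of 1-D site-level designs: conditioning on
the selected MEMs absorbs most of the true environmental signal (the
unconditioned detector recovers ~99% of planted loci at ~16–19% false
discovery; see `docs/methods.md`, "Confounding of space and environment").
Candidate F<sub>ST</sub> far exceeds non-candidate F<sub>ST</sub> between
sites, the expected signature of spatially varying selection.  The same run
writes `candidates.csv`, `fst.csv`, `diversity.csv`, `q_matrix.csv`,
`k_table.csv`, `enrichment.csv` and a machine-readable `report.json`.

The pipeline is also exposed as a CLI (`seagea run --config config.yaml
--outdir out/`, with `seagea qc/spatial/envsel/simulate` subcommands), and
reruns with the same configuration and seed are byte-identical.

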