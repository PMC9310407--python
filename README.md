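# rejuvseq

Tools for asking, from bulk RNA-seq of aging tissue, two questions that come up
in geroscience intervention studies:

1. **Does a treatment push an old transcriptome back toward a young one?**
   Given young, old-vehicle and old-treated groups, which age-altered genes are
   *reverted* — significantly changed with age, significantly shifted back by
   the treatment, and no longer distinguishable from young expression?
2. **Does the treatment act through a specific gene product?**  Given a
   wild-type × tissue-specific-knockout factorial (each vehicle- or
   compound-treated), which treatment-responsive genes lose their response in
   the knockout (*dependent*) and which retain it (*independent*)?

The package also computes the lifespan side of such studies (Kaplan–Meier
medians, maximum lifespan, absolute/percent gains, log-rank tests), and ships
a negative-binomial simulator with planted ground truth so the whole pipeline
can be validated by parameter recovery.

## The method

Counts are normalised to RPKM (reads per kilobase of exon model per million
mapped reads), `RPKM_gs = 1e9 · c_gs / (L_g · N_s)` with `L_g` the exon-model
length and `N_s` the library size.  Genes are kept when RPKM > 4 in at least
50% of samples.  Each two-group contrast is a two-sided Welch *t*-test on
`log2(RPKM + 1)`; per-contrast *p*-values are adjusted over the gene universe
by the Benjamini–Hochberg step-up, `q_(i) = min_{j≥i} p_(j)·m/j`.

**Reversal calls** use three contrasts over one universe —
set 1: old-vehicle vs young; set 2: old-treated vs old-vehicle;
set 3: old-treated vs young — and the rule

* aging DEG: `q₁ < 0.1`;
* reverted: additionally `p₂ < 0.05` with `sign(lfc₂) = −sign(lfc₁)`
  and `p₃ > 0.05`.

**Dependence calls** use the wild-type and knockout treatment contrasts:
DEG when `q_WT < 0.2`; a DEG is *dependent* when `p_KO > 0.05` and
*independent* when `p_KO < 0.05`.

All estimator classes follow the scikit-learn `fit`/`transform` conventions
(`RPKMNormalizer`, `ExpressionFilter`, `GeneStandardizer`, `TwoGroupContrast`,
`ReversalClassifier`, `DependenceClassifier`) and compose with sklearn
pipelines; module-level functions (`compute_rpkm`, `filter_expressed`,
`classify_reversal`, …) wrap them for genes-as-rows DataFrames.

## Worked example

```python
from rejuvseq import DesignSpec, simulate_experiment, lifespan_change
from rejuvseq.pipeline import run_reversal_pipeline

spec = DesignSpec.aging_reversal(n_per_group=5, n_genes=2000,
                                 frac_aging=0.1, frac_reverted=0.5,
                                 effect_size=2.0, dispersion=0.05, seed=11)
counts, annotation, sheet, truth = simulate_experiment(spec)
res = run_reversal_pipeline(counts, annotation, sheet)
print(res["summary"]["counts"])
print(lifespan_change(25.95, 28.2))
```

prints

```
{'aging_not_reverted': 126, 'not_aging_deg': 1767, 'reverted': 104}
(2.25, 8.670520231213873)
```

i.e. of 2000 simulated genes (200 planted aging DEGs, 100 of them reverted by
treatment) the pipeline calls 230 aging DEGs of which 104 are reverted — 97 of
the 100 planted reversals plus 7 false calls — and a cohort whose median
lifespan moves from 25.95 to 28.2 months gained 2.25 months (8.7%).

The same flows are available from a shell:

```sh
rejuvseq simulate --config design.yaml --seed 11 --outdir data/
rejuvseq run-reversal --counts data/counts.tsv --annotation data/annotation.tsv \
    --sample-sheet data/sample_sheet.tsv --outdir out/
rejuvseq survival --data data/survival.csv --ref Veh --cmp Hes --outdir out/
```

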