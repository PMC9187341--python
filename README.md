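# bimix — controlled mixture modeling for bimodal expression in cancer

Many tumorigenic genes and miRNA are not shifted in mean between tumors and
healthy tissue — they are *bimodal*, switched on in one patient subgroup and
off in another (the classic example is *ESR1* in breast cancer). Mean-based
differential expression misses them, and naive bimodality detection flags
features that are just as bimodal in the general population
(immunoglobulins, copy-number-variable genes) and therefore say nothing
about the tumor.

`bimix` implements **controlled mixture modeling (CM)** for bulk expression
cohorts: bimodality is scored in the tumor cohort and *penalized by the
matched control cohort*, so only features whose two-mode structure is
tumor-specific survive. Downstream stages group the survivors into
concurrently expressed modules, stratify patients by module expression for
survival analysis, and rank drugs by the correlation of cell-line
expression with potency. A synthetic-cohort generator with planted ground
truth makes every stage testable without any data download.

## Method

For each feature, the log2-expression vector in the tumor cohort is fit
with a one-component Gaussian and a two-component Gaussian mixture
π₁G(μ₁,σ₁) + π₂G(μ₂,σ₂) (EM, deterministic multi-start). BIC decides
between them; two-component winners need both mixing proportions above 0.1
(spike components hugging a few outliers are not bimodality). Surviving
features are re-clustered with exact 1-D k-means (k = 2) and scored by the
bimodality index

    BI = sqrt(π₁ π₂) · (μ₂ − μ₁) / sqrt(π₂ σ₁² + π₁ σ₂²),

which reduces to the classical sqrt(π(1−π))·Δμ/σ when σ₁ = σ₂. The same
selection is run on the control cohort; if the control is itself bimodal,
two penalties are computed,

    BI_μ = BI − 1 / (|μ₁C − μ₁T| + |μ₂C − μ₂T|)
    BI_π = BI − 1 / (|π₁C − π₁T| + |π₂C − π₂T|),

and the larger (clamped at 0) is the final score: a feature with the same
two modes in tumor and control scores 0. Features with final BI > 1.4 are
candidates; groups of ≥ 3 candidates with all pairwise Pearson r > 0.5
form co-expression modules; patients are stratified by hierarchical
clustering of module expression (Manhattan distance, complete linkage, two
groups) and compared with a Cox proportional-hazards fit (hazard ratio,
Wald test, Kaplan–Meier medians) and a chi-square test against TNM stage;
drugs are ranked by Pearson correlation of cell-line expression with
log(IC50), the most negative correlations marking candidates for the
high-expressing subgroup.

## Worked example

```python
from bimix import ControlledMixtureModel, standard_config, generate_cohort

cfg = standard_config(seed=42, n_tumor=200, n_control=50,
                      n_unimodal=6, n_tumor_bimodal=2, n_shared_bimodal=2)
tumor, control, truth = generate_cohort(cfg)
res = ControlledMixtureModel(tumor, control).fit()
print(res.summary())
print(res.ranked().head(5)[["rank", "feature_id", "bi_raw", "bi_final",
                            "penalized"]].to_string(index=False))
```

```
CM bimodality scan: 10 features, 200 tumor samples, 50 control samples

BI > 0      3
BI > 1      2
BI > 1.2    2
BI > 1.3    2
BI > 1.4    2
BI > 1.5    2

features with BI > 1.4: 2

 rank feature_id   bi_raw  bi_final  penalized
    1     tb-001 3.256096  3.256096      False
    2     tb-000 2.979606  2.979606      False
    3     sb-000 2.886357  0.458800       True
    4     sb-001 3.177642  0.000000       True
    5    uni-000 0.000000  0.000000      False
```

The two planted tumor-only bimodal features (`tb-*`) are called with BI ≈ 3
and no penalty (their controls are unimodal). The two features planted
bimodal in *both* cohorts (`sb-*`) have comparable raw BI but are penalized
to ≈ 0 — the control cohort reveals their bimodality is population-level,
not tumor-specific. Unimodal features score 0.

The same workflow is available from the shell:

```sh
bimix simulate --out study/ --seed 7
bimix detect --tumor study/tumor_expression.tsv \
             --control study/control_expression.tsv --mode cm --out calls.tsv
bimix modules --calls calls.tsv --expr study/tumor_expression.tsv --out modules.tsv
bimix run --data study/ --out results/            # full pipeline + manifest
```

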