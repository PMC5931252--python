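# ccmirnet

Integrated miRNA–mRNA analysis of paired tumor/normal expression data,
built around the cell-cycle pathway in colorectal cancer. Given RNA-seq
counts for paired carcinoma / normal-mucosa samples, miRNA total-gene-signal
for the same pairs, subject metadata, and mature-miRNA / 3'-UTR sequences,
the pipeline answers four questions:

1. **Which genes change?** Paired negative-binomial differential expression
   with a protein-coding exposure offset:
   `log E[count] = log(pc_total) + a_subject + b·1[carcinoma]`, fold change
   `FC = exp(b)`, BH-FDR, and a band filter keeping genes with
   descriptive FC > 1.50 or < 0.67. Expression is reported in RPMPCG
   (reads per million protein-coding genes).
2. **Which miRNAs track those changes?** On per-subject *differential
   profiles* (carcinoma − normal), least squares
   `mrna_diff ~ mirna_diff + age + sex` with the nested-model F statistic
   and a residual-bootstrap p-value: resample the null model's residuals
   10,000 times, `p = (1 + #{F* ≥ F_obs})/(B + 1)`, then BH within each
   gene.
3. **Is either prognostic?** Cox proportional hazards for
   colorectal-cancer-specific death, adjusted for age, sex, and AJCC stage,
   with hazard ratios per interquartile range (`HR = exp(β·IQR)`) and
   p-values from 10,000 permutations of the likelihood-ratio test.
4. **Which associations could be direct?** 6/7/8-nt seeds (miRNA positions
   2–7/2–8/2–9) are reverse-complemented and scanned against 3'-UTR
   sequences across genome builds; a significant association with a seed
   match is classified `direct_negative` (repression-consistent) or
   `direct_positive` (feedback / feed-forward candidate), otherwise
   `indirect`.

A synthetic-data module generates full datasets with *planted* fold
changes, regression slopes, hazard ratios, and seed sites, so every stage
can be tested against known ground truth. See `docs/methods.md` for the
models, assumptions, and design decisions.

## Worked example

Simulate a 60-subject cohort with three planted differentially expressed
genes, one planted gene–miRNA association (β = 2.0) whose pair also carries
a planted 7-mer seed site, and a planted protective hazard ratio, then run
the whole pipeline:

```python
import numpy as np
from ccmirnet.simulate import SimConfig, AssocEffect, SeedSite, write_dataset
from ccmirnet.pipeline import PipelineConfig, run_pipeline

sim = SimConfig(
    n_subjects=60, n_genes=10, n_mirnas=8,
    planted_log_fc=(("G0001", np.log(2.5)), ("G0002", np.log(2.0)),
                    ("G0003", -np.log(2.0))),
    assoc_effects=(AssocEffect("G0001", "miR-0001", beta=2.0, noise_sd=2.0),),
    planted_log_hr_per_iqr=(("G0001", np.log(0.5)),),
    seed_sites=(SeedSite("G0001", "miR-0001", 7),),
    utr_length=300, base_rpm_range=(5.0, 50.0), rng_seed=7,
)
write_dataset(sim, "demo/data")
cfg = PipelineConfig(
    counts="demo/data/counts.tsv", pc_totals="demo/data/pc_totals.tsv",
    samples="demo/data/samples.tsv", subjects="demo/data/subjects.tsv",
    mirna_signal="demo/data/mirna_signal.tsv",
    mirna_fasta="demo/data/mirna.fa", utr_fasta="demo/data/utrs.fa",
    n_boot=2000, n_perm=2000, rng_seed=7,
)
run_pipeline(cfg, "demo/run")
```

The run directory then contains per-stage TSVs and a manifest whose summary
reads:

```
genes_tested 10        genes_banded_significant 3
pairs_tested 24        pairs_significant 1
significant_with_seed_match_positive_beta 1
survival_features_tested 4
```

The DE table recovers the planted genes (`de.tsv`, FC rounded to 2 d.p.):

```
 gene  mean_carcinoma  mean_normal  fc_ratio     p_adj        band
G0001           74.42        31.08      2.39   1.0e-05   up_strong
G0002           17.86         9.23      1.93   6.2e-13   up_strong
G0003           23.24        45.13      0.52   3.7e-18 down_strong
G0004           15.40        14.09      1.09   2.5e-01      within
```

`fc_ratio` is the ratio of mean RPMPCG values: 74.42 / 31.08 = 2.39, i.e.
G0001 is 2.4-fold up-regulated in carcinoma tissue. The planted association
is the one significant pair, and because its UTR carries the planted seed
site and its slope is positive it is classified as a feedback candidate:

```
 gene    mirna   beta  f_obs  p_boot  fdr_gene   interaction_class
G0001 miR-0001  1.752  81.19  0.0005    0.0040     direct_positive
```

(The fitted slope 1.75 sits below the planted 2.0 because the count-level
round trip adds negative-binomial noise to the gene profile; the slope is
recovered within ±0.03 at 500 subjects in the acceptance checks.) The
planted protective effect shows up in `survival.tsv` as a hazard ratio per
IQR well below 1:

```
feature  hr_per_iqr  ci_low  ci_high  p_perm    fdr
  G0001       0.240   0.085    0.680  0.0055  0.016
```

i.e. a subject whose differential expression of G0001 is one interquartile
range higher has 0.24 times the hazard of colorectal-cancer death,
permutation p = 0.0055.

The same stages are available from the shell:

```sh
ccmirnet simulate --out demo/data --seed 7
ccmirnet de --counts demo/data/counts.tsv --totals demo/data/pc_totals.tsv \
            --samples demo/data/samples.tsv --out de.tsv
ccmirnet run --config pipeline.yaml --out demo/run --seed 7
```

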