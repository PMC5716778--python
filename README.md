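# cdscore

A reusable, tested implementation of a **CD-antigen gene-expression risk
score** for outcome prediction in multiple myeloma (MM), of the kind built
from the four genes *CD24*, *CD27*, *CD36* and *CD302*.

Multiple myeloma is a plasma-cell malignancy with highly heterogeneous
outcomes. Cluster-of-differentiation (CD) surface antigens are routinely
used to immunophenotype plasma cells, and the expression of the genes that
encode them carries prognostic information. This package implements the
full statistical pipeline that turns a candidate list of CD probesets and
normalized (MAS5-style, linear-scale) microarray cohorts into a validated
two-class risk model:

1. **Differential screen** (`cdscore.sam`) — a two-class unpaired SAM
   screen between normal bone-marrow plasma cells (BMPC) and malignant
   plasma cells (MMC): moderated statistic
   `d_i = (x̄_i2 − x̄_i1) / (s_i + s0)` with a permutation FDR in percent,
   called at *FDR < 5% and fold change ≥ 2* in either direction.
2. **Prognostic cutpoint screen** (`cdscore.maxstat`) — per probeset, the
   maximally selected log-rank statistic
   `M = max_c |S(c)| / sqrt(Var S(c))` over all expression cutpoints `c`
   whose above-cutpoint group proportion lies in a band (default
   0.10–0.90), with a finite-sample-corrected Lausen–Schumacher p-value,
   Benjamini–Hochberg adjustment across the candidate list, and a
   cross-cohort replication filter (significant with consistent direction
   in *every* cohort).
3. **Risk score construction** (`cdscore.score`) — each patient is staged
   by the count of retained genes expressed above their cutpoints
   (stage = count + 1); adjacent stages that do not differ by log-rank
   test are merged, yielding a binary low/high-risk model that is frozen,
   serialized to JSON and applicable to new cohorts (cutpoints either
   recalibrated per cohort or frozen).
4. **Survival evaluation** (`cdscore.survival`) — Kaplan–Meier curves with
   "not reached" medians, k-sample log-rank tests, and Cox
   proportional-hazards reporting (univariate, pairwise "2 by 2", and full
   multivariate designs) against clinical covariates such as ISS, β2M,
   t(4;14) and del17p.

A synthetic-data module (`cdscore.simulate`) generates cohorts with known
ground truth — planted fold changes, planted prognostic genes with
dichotomized hazard effects, calibrated censoring — so every stage is
testable without any data download.

## Worked example

```python
import numpy as np
from cdscore import CdGeneRiskScore
from cdscore.simulate import (PlantedGene, SyntheticTruth,
                              generate_survival_cohort, probeset_names)

# two synthetic MM cohorts, 4 protective genes among 266 candidates
planted = {ps: PlantedGene(cut_quantile=0.5, beta=-np.log(3.5))
           for ps in probeset_names(266)[:4]}
cohorts = []
for seed, name in [(11, "training"), (12, "validation")]:
    truth = SyntheticTruth(planted_prognostic=planted, censor_rate=0.25,
                           baseline_hazard=0.05, seed=seed)
    cohort, _ = generate_survival_cohort(350, 266, truth, name=name)
    cohorts.append(cohort)

est = CdGeneRiskScore(cohorts[0], validation=[cohorts[1]],
                      candidates=probeset_names(266))
results = est.fit(seed=11)
print(results.summary())
```

prints

```
CD gene risk score
============================================================
training cohort : training (n=350)
validation      : validation (n=350)
endpoint        : os
candidates      : 266 probesets
replicated genes: 4

gene        probeset            cutpoint   direction
ps00000_at  ps00000_at             54.37   high_good
ps00001_at  ps00001_at             263.2   high_good
ps00002_at  ps00002_at             374.4   high_good
ps00003_at  ps00003_at             36.27   high_good

stage -> risk: 1:high, 2:high, 3:low, 4:low, 5:low

risk         n       %  events   median OS
low        239    68.3     158       252.8
high       111    31.7     105        35.5
log-rank chi2=156.774, p=5.73e-36
Cox HR (high vs low)=5.073; (low vs high)=0.197; p=2.82e-30
```

The screen recovered exactly the four planted protective genes
(`direction high_good`: high expressors live longer). Counting how many
of the four genes each patient expresses above its cutpoint yields five
stages; the log-rank merge collapsed them into the familiar two-group
structure — patients with none or only one gene high (stages 1–2, here
31.7% of the cohort) form the high-risk class with a 35.5-month median
overall survival, while patients with at least two genes high form the
low-risk class. Applying the frozen model to the independent validation
cohort (`results.evaluate(cohorts[1])`) reproduces the separation
(log-rank p = 2.2e-41, hazard ratio high-vs-low = 6.31).

## Command line

Every stage is also a subcommand of the `cdscore` console script:

```bash
cdscore simulate --n-patients 300 --n-probesets 266 --seed 17 --out-prefix sim
cdscore sam --expression expr.tsv --clinical clin.csv --class1 BMPC --class2 MMC \
            --n-perm 1000 --fdr 5 --fold 2 --seed 17 --out sam_results.tsv
cdscore screen --train expr.tsv clin.csv --validate v_expr.tsv v_clin.csv \
               --candidates cd_probesets.txt --out screen.tsv
cdscore build-score --train expr.tsv clin.csv --validate v_expr.tsv v_clin.csv \
                    --out model.json
cdscore apply-score --expression v_expr.tsv --clinical v_clin.csv \
                    --model model.json --cutpoint-mode recalibrate --out eval.tsv
cdscore cox-report --clinical clin.csv --design pairwise \
                   --covariates cd_risk_high,ISS,B2m --out table.tsv
cdscore run --config run.yaml --out run_dir/   # full pipeline
```

Expression matrices are read as TSV or GCT v1.2; clinical tables as
CSV/TSV with `sample_id`, `os_time` (months), `os_event` (0/1), optional
`efs_time`/`efs_event` and arbitrary covariate columns.

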