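# mdscore

Metabolic dysbiosis scoring for ICU metabolomics cohorts: per-metabolite
Youden-optimal cutpoints binarize fecal metabolite concentrations into a
patient × metabolite point matrix, ridge-regression importance orders the
metabolites, and a composite dysbiosis score is assembled iteratively and
evaluated with classification metrics and survival statistics (Kaplan-Meier,
log-rank, restricted mean survival time, Cox proportional hazards with
Schoenfeld diagnostics). A synthetic-cohort generator stands in for raw
per-patient data so every stage is testable offline.

## Layout

| Module | Purpose |
| --- | --- |
| `mdscore.synthetic` | seeded synthetic cohorts: outcomes with CCI/SOFA confounders, log-normal metabolites with a planted discriminative subset, Dirichlet taxa profiles with optional pathobiont domination |
| `mdscore.prep` | stratified splitting, sparsity filtering, predictive-mean-matching imputation, 2×2 chi-square / rank-sum / BH statistics, volcano fold changes |
| `mdscore.cutpoints` | ROC curves, Youden cutpoints with stratified bootstrap stability, point-matrix binarization |
| `mdscore.score` | ridge importance ranking, iterative score building, parsimony model selection, fitted/predefined score application |
| `mdscore.survival` | KM, log-rank, RMST (+ Greenwood variance), Cox PH (Efron/Breslow ties, likelihood-ratio p-values), Schoenfeld PH test |
| `mdscore.taxa` | MetaPhlAn-style profile parsing, rank aggregation, Shannon, Bray-Curtis, domination flags, Youden survival stratification |
| `mdscore.pipeline` / `mdscore.cli` | end-to-end orchestration with a reproducibility manifest; `mds` command-line interface |

## CLI

```sh
mds simulate --out data/ --seed 7                      # synthetic cohort TSVs + truth JSON
mds run --cohort data/cohort.tsv \
        --metabolites data/metabolites.tsv \
        --out run/ --seed 7                            # full pipeline, report bundle in run/
mds score --model run/model.json --metabolites data/metabolites.tsv
mds survival --model run/model.json --cohort data/cohort.tsv \
             --metabolites data/metabolites.tsv --covars cci,sofa
mds taxa --profiles data/taxa.tsv --rank genus
```

`mds run` writes `cutpoints.tsv`, `iterations.tsv`, `model.json`,
`performance.json`, per-cohort KM and Cox tables, and `manifest.json`
(config hash, seeds, stage timings). All model decisions are made on the
training cohort only.

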