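# gsemkit

Multivariate genetic analysis of GWAS summary statistics: estimate a
multi-trait genetic covariance matrix **S** and its sampling covariance
**V** by LD-score regression with a joint block jackknife, then fit
latent-variable structural equation models to (S, V) by diagonally
weighted least squares (DWLS) with sandwich standard errors, model
chi-square, CFI, SRMR and AIC.

The package ships the two prebuilt study models for the
impulsivity / substance-use / anorexia analysis — a correlated-factor
model (common impulsivity, an orthogonal urgency-specific factor, a
substance-use-disorder factor, plus delay discounting, sensation seeking,
lack of perseverance and anorexia nervosa as single indicators) and a
multiple-regression model in which the outcome is regressed on all six
predictors — together with a synthetic-data module that generates summary
statistics under a known factor-structured architecture so the whole
stack is testable offline.

## Layout

| module                | contents |
|-----------------------|----------|
| `gsemkit.sumstats`    | reading, allele harmonization and QC of per-trait summary statistics |
| `gsemkit.ldsc`        | LD scores, h²/genetic-covariance regression, joint jackknife S and V, correlation standardization, PSD smoothing |
| `gsemkit.model`       | model-syntax parser (`F =~ a + b`, `x ~~ y`, `y ~ x`, `0*` fixed constants, shared labels for equality constraints) and RAM-form implied covariance |
| `gsemkit.fit`         | DWLS estimation, sandwich SEs, chi-square (mean-corrected / Browne / naive), CFI, SRMR, AIC, standardized solutions |
| `gsemkit.models`      | the two prebuilt study models and the replication runner |
| `gsemkit.simulate`    | direct (moment-exact) and forward (individual-level) summary-statistics simulators plus reference panels |
| `gsemkit.cli`         | `gsemkit munge / ldscore / sv / fit / simulate / replicate` |

## CLI quick start

```bash
# synthesize a small dataset (forward mode writes a reference panel too)
gsemkit simulate --preset small --mode forward --m 2000 --n 20000 \
    --seed 1 --out work/sim

# harmonize + QC, LD scores, S and V
gsemkit munge --sumstats work/sim/A.sumstats --sumstats work/sim/B.sumstats \
    --sumstats work/sim/C.sumstats --sumstats work/sim/D.sumstats \
    --out work/panel
gsemkit ldscore --panel work/sim/reference --window 100 --out work/ld
gsemkit sv --panel work/panel --ld work/ld.ldscore.tsv --out work/sv

# fit a model written in the plain-text syntax
gsemkit fit --matrices work/sv --model-file my_model.txt --out work/fit
```

`--config cfg.yaml` supplies defaults for any stage; flags override.
Every stage writes a JSON provenance record (seed, thresholds, config
hash) and refuses to overwrite outputs without `--force`.

## Replicating the published fits

The deposited genetic covariance and sampling covariance matrices are
published as R data files on the study's public repository.  Convert them
once:

```bash
Rscript scripts/convert_deposited.R LDSCoutput.RData data/deposited/matrices \
    rename.json   # optional label map onto NU, PU, ..., AN
gsemkit replicate --matrices data/deposited/matrices --out results/replication
```

The replication report contains both models' standardized estimates, SEs,
p-values, chi-square/df, CFI, SRMR and AIC, and a side-by-side table
against the published values.

## Conventions worth knowing

- vech ordering of V is column-major over the lower triangle of S, fixed
  and tested.
- The model chi-square defaults to the weighted-residual statistic with a
  V-based mean correction (`chisq_kind="mean_corrected"`); Browne's
  residual-based statistic and the uncorrected statistic are available.
- SRMR is computed on the correlation-standardized scale over all unique
  moments, diagonal included.  AIC = chi-square + 2q.
- Latents are identified by unit variance with free loadings by default
  (`identification="marker_loading"` is available).  A two-indicator
  orthogonal factor needs its loadings constrained equal — use a shared
  label, as the prebuilt models do.
- QC defaults (`maf_min 0.01`, `chisq_max = max(80, 0.001 * median N)`)
  are package choices and are logged with every run.
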