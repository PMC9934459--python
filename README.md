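# chronotx

Day-night and seasonal variation in gene expression from single-snapshot
postmortem transcriptomes.

Postmortem cohorts such as GTEx record one transcriptome per donor, taken at
the time of death, with only the clock time and the season of death as
temporal metadata. `chronotx` implements the analysis chain that turns those
scattered snapshots into temporal biology: it discretizes death times into
day / night / twilight, runs covariate-adjusted moderated differential
expression per tissue, scans sliding 6-hour window pairs for "circadian-like"
genes, detects rhythmicity with the Lomb–Scargle periodogram, aggregates
per-tissue calls into high-confidence gene sets with exact binomial tests,
builds permutation and constrained-randomization null distributions, and
compares day/night directions across species. A synthetic cohort generator
with planted cosine, seasonal, and covariate effects makes every stage
testable without controlled-access data.

## The statistics at the core

**Temporal labels.** A donor is *day* if the time of death t ∈ [08:00, 17:00),
*night* if t ∈ [21:00, 05:00) (wrapping midnight), *twilight* otherwise.
Twilight donors are excluded from day-night contrasts but kept as a third
factor level in seasonal models.

**Moderated differential expression.** For each tissue, genes with median
TPM ≥ 1 over the contrast samples are kept; TMM factors correct library
composition; log-CPM values y_gs get precision weights w_gs from a lowess
mean–variance trend (span 0.5); per gene, weighted least squares fit

  y_g = Xβ_g + ε_g,  Var(ε_gs) = σ_g² / w_gs

with X containing the contrast indicator (day vs night, or one season vs the
rest) plus season (or day/night/twilight), sex, age, BMI and postmortem
interval. Residual variances are shrunk with an empirical-Bayes
scaled-inverse-χ² prior (d₀, s₀² estimated by moment matching) and the
moderated t-statistic

  t_g = ĉ'β_g / (s̃_g · sd(ĉ'β_g)),  s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g)

gives two-sided p-values, BH-adjusted within the tissue. Calls:
*sensitive* = raw p ≤ 0.05 and |log2FC| ≥ 0.1; *strict* = FDR ≤ 0.1.

**Aggregation.** Per gene, the signed per-tissue call pattern
(+1 day/up, −1 night/down) is tested with an exact two-sided binomial test
(p₀ = 0.5) over all tissues, brain regions only, and non-brain tissues only;
membership in the high-confidence set requires p ≤ 0.05 in any scope, which
a fully consistent pattern first reaches at **6 tissues**.

**Nulls.** Label permutations (counts preserved, filtering re-applied per
permutation) calibrate the per-tissue DE counts; a rejection-sampled
randomization of cell-type marker up/down instances over region × season
cells — never mixing signs within a cell — gives empirical p-values with
Bonferroni correction.

## Worked example

```python
from chronotx import (SimConfig, simulate_tissue, run_daynight,
                      min_tissues_for_significance, binomial_concordance)
from chronotx.simulate import cohort_to_frame
from chronotx.labels import label_cohort

config = SimConfig(n_donors=932, n_genes=2000, seed=42)
cohort, truth, matrix = simulate_tissue(config)
labels, counts = label_cohort(cohort)
print(counts)
res = run_daynight(matrix, cohort_to_frame(cohort))
print(int(res.table.call_sensitive.sum()), int(res.table.call_strict.sum()))
print(min_tissues_for_significance(0.05))
print(binomial_concordance(59, 15, "excess_similar"))
```

prints

```
{'day': 330, 'night': 322, 'twilight': 280}
109 94
6
1.2767110037205522e-07
```

A 932-donor cohort with uniform death times lands 330/322/280 donors in the
day/night/twilight bins. Of 2,000 simulated genes (100 carrying planted
cosine day-night effects), 109 are called at the sensitive threshold and 94
at the strict one — 94% of the planted genes are recovered
(`res.table.loc[planted, "call_sensitive"].mean()` → 0.94). Six fully
consistent tissues are the minimum for a high-confidence call, and 59
similar vs 15 opposite cross-species core-clock pairs give a one-sided
binomial p of 1.277 × 10⁻⁷.

The same stages are available from the shell:

```bash
chronotx simulate --out sim --seed 42
chronotx label --metadata sim/metadata.tsv --out sim/labelled.tsv
chronotx de daynight --counts sim/tissue.counts.tsv \
    --lengths sim/tissue.lengths.tsv --metadata sim/metadata.tsv --out de.tsv
```

## Layout

| module | role |
| --- | --- |
| `chronotx.simulate` | synthetic cohort + negative-binomial counts with planted effects |
| `chronotx.labels` | day/night/twilight and season labelling |
| `chronotx.expression` | expression container, TPM, median-TPM filter |
| `chronotx.io` | TSV / GCT / MTX / GMT readers and writers |
| `chronotx.diffexp` | TMM, precision weights, moderated fits, both contrast schemes |
| `chronotx.windows` | sliding 6-h window-pair scan |
| `chronotx.rhythm` | Lomb–Scargle scan and phase reconciliation |
| `chronotx.aggregate` | direction profiles, binomial high-confidence sets, consistency tests |
| `chronotx.resampling` | label permutations and the marker randomization test |
| `chronotx.concordance` | cross-species classification, Simpson index, Fisher overlap |
| `chronotx.cli` | `chronotx` command-line entry point |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
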