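# cryptomics

Reusable, tested implementations of the computational procedures used to
study diet-induced maladaptation of the small-intestinal crypt: how a
high-fat/high-sugar diet shifts stem-cell lineage allocation, regional
identity, proliferation, villus zonation, gene expression and the tissue
metabolome. The package is aimed at computational biologists who want these
bespoke statistics as ordinary, scriptable Python objects — exercised
end-to-end on a synthetic-data generator, so every stage is testable without
any data download.

## What it computes

* **Cell-type composition** (`cryptomics.composition`) — a Bayesian
  Dirichlet-multinomial model of sample × cell-type counts. For condition
  *c* with per-sample counts *x\_s*:

  *x\_s* | *p\_c*, γ ~ DirMult(*n\_s*, γ·*p\_c*),  *p\_c* ~ Dir(1,…,1),
  log γ ~ N(log 100, 1²).

  `DirichletMultinomialModel(table, condition).fit()` samples the posterior
  by adaptive Metropolis-within-Gibbs on ALR simplex coordinates and
  returns a `CompositionResults` whose `shift_report()` gives, per cell
  type, the frequency shift Δ\_k = *p*\_{c2,k} − *p*\_{c1,k}, its 95%
  highest-posterior-density (HPD) interval, and a *credible* flag
  (0 outside the HPD).
* **Signature scoring and classification** (`cryptomics.scoring`) —
  expression-bin-controlled signature scores; cell-cycle calls
  (G1 unless max(S, G2M) > 0, larger score wins, ties → G2M);
  proximal/distal regional calls; score-correlated gene discovery
  (Pearson r > 0.7).
* **Villus zonation** (`cryptomics.zonation`) — pseudospatial ordering
  ζ ∈ [0, 1] from tip-minus-bottom landmark scores, five equal-frequency
  zones, per-zone expression profiles and condition contrasts.
* **Markers and differential expression** (`cryptomics.markers`) —
  tie-corrected Wilcoxon rank-sum z; state markers (z > 5 and rank ≤ 1,200
  in *every* pairwise test); lineage markers with later-stage exclusion;
  limma-trend-style moderated t (empirical-Bayes variance shrinkage toward
  a mean-expression trend, flags at FDR < 0.01 and |logFC| > 0.1); bulk
  regulated sets (raw P < 0.01, FC > 1.3, group mean > 32); Fisher-exact
  gene-set enrichment with logFC weighting summaries.
* **MALDI-MSI metabolomics** (`cryptomics.metabolome`) — LIMPIC-style peak
  picking (minimal width m/z 0.0005, SNR ≥ 4, intensity ≥ 0.01% of the
  maximum), automatic isotope exclusion (+1.00335 Da), discriminative
  masses (FC ≥ 2 and two-tailed t-test P ≤ 0.05), ≤ 4 ppm database
  annotation, hypergeometric pathway enrichment with relative-betweenness
  topology impact, and Ward/Euclidean clustering.
* **Cross-omics integration** (`cryptomics.crossomics`) — a reaction is
  *affected* when ≥ 1 of its genes and ≥ 1 of its metabolites are
  significant; pathways roll up from affected reactions. Plus the HOMA
  indices: HOMA-IR = glucose·insulin/405, HOMA-β = insulin·360/(glucose − 63).
* **Synthetic data** (`cryptomics.simulate`) — seeded generators for the
  whole design: 2 conditions × 3 replicate samples, ~10 crypt cell
  clusters with Dirichlet-multinomial composition (optionally with planted
  shifts), gamma-Poisson counts with marker/regional/cell-cycle programs
  and a latent villus axis, Gaussian-peak mass spectra with isotope
  satellites, and toy gene→reaction→metabolite networks — each with a
  ground-truth manifest.

## Worked example

Simulate a 3 vs 3 composition experiment (3,000 cells per sample) in which
the goblet-cell frequency is doubled under the high-fat/high-sugar diet,
then fit the Dirichlet-multinomial model:

```python
from cryptomics.simulate import SimConfig, simulate_composition_table
from cryptomics.composition import fit_dirichlet_multinomial

cfg = SimConfig(cells_per_sample=3000, shift_map={"Goblet": 2.0}, seed=42)
table, condition = simulate_composition_table(cfg)
results = fit_dirichlet_multinomial(table, condition, seed=0)
print(results.summary())
```

```
Dirichlet-multinomial composition model
  conditions: CD -> HFHSD   cell types: 10
  draws: 4 chains x 5000   max split-R-hat: 1.015

                      delta_mean  hpd_lower  hpd_upper  credible  mean_CD  sem_CD  mean_HFHSD  sem_HFHSD
ISC                      -0.0046    -0.0582     0.0482     False   0.2220  0.0066      0.2173     0.0219
EnterocyteProgenitor     -0.0278    -0.0751     0.0209     False   0.1853  0.0179      0.1544     0.0109
Enterocyte               -0.0168    -0.0591     0.0263     False   0.1421  0.0245      0.1194     0.0084
GobletProgenitor         -0.0175    -0.0519     0.0180     False   0.0912  0.0051      0.0727     0.0062
Goblet                    0.0568     0.0114     0.1001      True   0.1118  0.0055      0.1710     0.0187
EEP_Sox4                  0.0022    -0.0237     0.0288     False   0.0457  0.0089      0.0459     0.0041
...
```

Only the planted goblet shift is flagged: its posterior mean shift is
+5.7 percentage points (raw proportions 11.2% → 17.1%) with a 95% HPD of
[+0.011, +0.100] that excludes zero; every unshifted type stays
non-credible. `Goblet`'s true simulated shift is 0.112·2/1.112 − 0.112 ≈
+0.09 at the composition level before replicate noise.

The same stages run from the shell:

```bash
cryptomics simulate --out sim --seed 3
cryptomics composition --table comp.csv --out shifts.csv --seed 0
cryptomics homa --glucose 100 --insulin 10
cryptomics run --config pipeline.yaml --out results/
```

`cryptomics run` executes a YAML-configured multi-stage pipeline
(simulate → composition → score → zonation → markers → de → maldi →
integrate → homa), writing CSV/JSON outputs, a manifest and a log;
identical config + seed gives byte-identical results.

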