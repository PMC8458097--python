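# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `cryptomics`. It
states nothing the test suite or `scripts/acceptance.py` does not itself
compute.

## Dirichlet-multinomial composition model

Per condition *c*, sample cell-type count vectors *x_s* (totals *n_s*) are
modelled as DirichletMultinomial(*n_s*, γ·*p_c*) with a flat Dirichlet
prior on the composition *p_c* and log γ ~ Normal(log 100, 1²). The
concentration γ captures replicate (mouse-to-mouse) overdispersion beyond
multinomial counting noise; it is shared between the two conditions by
default (a per-condition γ was considered and rejected as
under-identified with three replicates per condition; the shared-γ model
is the minimal one consistent with replicate overdispersion).

**Sampling.** Metropolis-within-Gibbs: coordinate-wise random-walk scans
on additive-log-ratio (ALR) simplex coordinates (the last cell type is
the reference; the flat Dirichlet prior is carried through the transform
with its Jacobian ∏ p_k) and a scalar walk on log γ. Step sizes adapt in
windows of 50 warm-up iterations toward ~35% acceptance. Defaults:
4 chains × 5,000 post-warm-up iterations after 2,000 warm-up; split-R̂ is
reported per scalar and a value above 1.05 raises a warning (never a
silent failure). At these defaults split-R̂ is ≈ 1.01 on the designs used
in the tests. Reduced-iteration mode (2 chains × 1,000 after 400) is used
in the 200-dataset calibration study; the whole study runs as one
vectorized batch across datasets and chains.

**Shift report.** Δ_k = p_{c2,k} − p_{c1,k} per pooled draw; the 95% HPD
interval is the shortest contiguous window containing ⌈0.95·N⌉ sorted
draws, ties between equal-width windows broken toward the smallest lower
bound; *credible* ⇔ 0 outside the interval. Cell types absent from all
samples are dropped with a warning; types with zero counts in one
condition are retained (the prior regularizes) and flagged in the report.
In the γ→∞ limit (`fixed_gamma` large) the posterior reduces to the
conjugate Dirichlet(1 + Σ x) update, which the tests verify.

**Degenerate cases.** K = 1 gives p ≡ 1 and Δ ≡ 0 without sampling.
Exact label-permutation equivariance does not hold for a finite chain
(the ALR reference coordinate and the random-number stream break it);
the tests assert statistical equivalence within Monte-Carlo error instead.

## Signature scoring and classification

The score of a signature in a cell is the mean log-normalized expression
of its genes minus the mean over a control pool: genes are ranked by
dataset-average expression into `n_bins` (default 25) equal-size bins and
`n_controls` (default 50) controls are drawn without replacement from the
bin of each signature gene. A signature's own genes are excluded from its
control pools (with a fallback to all non-signature genes if a bin is
exhausted); this keeps the score exactly zero-centred on background-like
signatures even when bins are small. Scores are deterministic given the
seed. The score is exactly invariant under adding a per-cell constant to
all genes, and equivariant under signature-only shifts as long as the
shift does not re-bin the genes.

Phase rule: G1 unless max(S, G2M) > 0, otherwise the larger score, ties
to G2M (arbitrary but documented and tested). Regional rule: proximal iff
prox − dist > 0, tie to distal. Classification is done per cell and
aggregated to per-(cluster × condition × sample) proportions reported as
mean ± s.e.m.; a subcluster-level majority vote can be built from the
per-cell calls if wanted.

## Villus zonation

Raw pseudospace score = tip-signature score − bottom-signature score
(shared seed so the control machinery cancels); ζ = rank/(n−1) ∈ [0, 1]
with ties broken by stable cell order, so ζ is invariant under any
monotone transform of the raw score and landmark swap maps ζ → 1 − ζ
exactly. Cells are partitioned into five contiguous equal-frequency zones
(sizes differ by ≤ 1; remainder goes to the bottom zones). Zones are
assigned within condition so compositional differences cannot move zone
boundaries; cross-condition comparisons use the zone index. This
two-signature rank estimator was chosen over probabilistic landmark
reconstruction as the simplest monotone estimator whose recovery can be
validated against the generator's latent axis (Spearman ≈ 0.96 at the
default simulation depth).

## Marker rules and moderated differential expression

`wilcoxon_z` is the tie-corrected normal approximation of the rank-sum
statistic: mid-ranks, σ²_W = nm/12·[(N+1) − Σ(t³−t)/(N(N−1))], no
continuity correction, positive when the first group is stochastically
larger; all-tied data give z = 0. The "test-score" of the marker rules is
this z (the convention of the single-cell ecosystem); a gene is a state
marker if z > 5 *and* its descending-z rank is ≤ 1,200 in every pairwise
test against the other states; ties at the rank boundary are kept. The
lineage variant excludes the transitive descendants of each progenitor
(cyclic stage orders are rejected). States with fewer than 3 cells are
excluded with a warning.

`moderated_de` implements the limma-trend scheme: per gene, two-group
means on log expression, pooled residual variance s²_g with d_g degrees
of freedom; the prior variance s₀²(A) is a lowess fit (span 0.5) of
log s²_g on average log expression; the prior degrees of freedom d₀ come
from moment-matching the scaled-F distribution of s²/s₀² (trigamma
inversion by Newton iteration; a non-positive moment estimate maps to
d₀ = ∞, i.e. full shrinkage). Posterior variance
s̃² = (d₀s₀² + d_g s²)/(d₀ + d_g); t = logFC/(s̃·√(1/n₁+1/n₂)) on
d₀ + d_g df; BH adjustment within stratum; flag at FDR < 0.01 and
|logFC| > 0.1 (natural-log scale, also reported as log₂). With a constant
prior (`trend=False`) the implementation reproduces Bioconductor limma's
`eBayes(trend=FALSE)` to 1e−14 on a frozen fixture; with the trend the
smoother differs from limma's internal one, so agreement is close but not
bit-for-bit (max |Δt| ≈ 0.25 on the fixture) — a documented divergence.
`d0_override=0` reduces exactly to the ordinary pooled t. Cell-level
testing is the default; a pseudobulk mode (mean per sample, then test) is
available for replicate-level inference. Bulk regulated sets test log₂
values (no trend by default) and apply the printed rule: raw P < 0.01,
linear FC > 1.3, and the larger group mean > 32.

Gene-set enrichment is an unweighted two-sided Fisher exact test on the
in-set × in-query 2×2 table against the supplied background; "weighting
by logFC" is reported as the mean |logFC| of in-set query genes rather
than folded into the P value, since the weighting scheme of the original
web tool is not reproducible from its description.

## Spectrum processing

Peak picking operates on the baseline-subtracted mean spectrum: the
baseline is a running median (default window 501 grid points — wider than
any peak), noise σ is 1.4826 × MAD of the residual, and a local maximum
is a peak when its above-half-height support spans ≥ 0.0005 m/z, its
height ≥ 4σ, and its height ≥ 0.01% of the spectrum maximum (referenced
to the detrended global maximum; all thresholds are relative, so constant
rescaling leaves the peak set unchanged). Per-sample intensities are the
maxima within the peak support. Isotope exclusion removes any peak lying
+1.00335 Da (±20 ppm) above another peak with at most equal mean
intensity, cascading along M, M+1, M+2 chains. Discriminative masses use
a pooled two-tailed t (Welch behind a flag) with the joint rule
FC ≥ 2 and P ≤ 0.05; enriched/depleted counts decompose the passes.
Annotation keeps every database entry within 4 ppm, sorted by error.
These are operational substitutes for the unpublished details of the
original adapted LIMPIC pre-processing; the recovery study (20 planted
peaks ≥ 8σ, satellites excluded, designed pass counts) is the contract.

Pathway topology impact is the summed relative betweenness centrality of
hit metabolites within the pathway graph (singleton pathways: 1 if hit,
else 0; a pathway with all-zero betweenness falls back to the hit
fraction). Ward clustering is implemented with Lance–Williams updates on
squared Euclidean distances, deterministic smallest-index tie-breaking,
and matches the scipy reference implementation's merge heights to 1e−9.

## Cross-omics integration and HOMA

A reaction is affected iff ≥ 1 of its genes and ≥ 1 of its metabolites
appear in the significant sets supplied by the upstream analyses (no
re-thresholding); pathways are affected iff they contain an affected
reaction — the report is monotone in both input sets. The HOMA-β
denominator is grouped as (glucose − 63), the standard form of the index;
glucose ≤ 63 mg per 100 ml raises an explicit domain error.

## The synthetic-data generator

The generator emulates the data structure the analyses assume, not any
particular dataset: 2 diets × 3 replicate mice; per sample, cluster
counts are Dirichlet-multinomial around the condition composition
(concentration 200 — replicate s.e.m. of a few percentage points on
double-digit proportions, as for inbred mice on controlled diets; planted
shifts multiply a cluster's frequency before renormalization); gene
counts are gamma-Poisson (dispersion 0.3) with log-normal library sizes
and log-normal baseline means. Program structure mirrors what the
procedures rely on in real data: cluster markers (10 genes × fold 4 by
default), regional programs (20 + 20 genes, fold 4, present in both
identities in every cluster, 70/30 in the focus lineages), cell-cycle
programs (50 + 50 genes, near-silent baseline 0.05, fold 80 in cycling
cells — canonical cycle genes are essentially off outside cyclers at
scRNA-seq depth, which is what makes the threshold-zero phase rule work),
and a latent villus axis u ~ Uniform(0, 1) in enterocytes with log-linear
landmark gradients (slope 3, high-abundance baselines, as for the
strongly zonated apolipoprotein/fatty-acid-binding transcripts).
Program-gene baselines keep a log-normal spread so they occupy many
expression bins and cannot become their own score controls.

Spectra are sums of Gaussians on a strictly increasing m/z grid with
white noise clipped at zero and +1.00335 Da satellites at ratio 0.3.
Reaction networks are random bipartite gene↔reaction↔metabolite maps with
a pathway partition and a mass-carrying metabolite table.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, cluster-specific library sizes, MALDI baseline drift, adducts,
or correlated gene programs beyond the planted ones. Passing recovery
tests therefore demonstrates correctness of the procedures under the
assumed structure, not robustness to those artefacts.

## Problem sizes and determinism

Simulation studies use desk-scale sizes chosen as the package's own
defaults: 200 null datasets (reduced draws) and 100 power datasets for
the composition studies; 3 states × ~300 cells × 2,000 genes for marker
recovery; 100 all-null runs of 1,000 genes × 200 cells for the moderated
DE calibration; 6 × 600-cell samples × 1,000 genes for the scoring and
zonation recoveries; 10 noise seeds × 20 peaks on a 150,001-point grid
for the spectrum study. All generators and samplers are deterministic
given their seeds; the pipeline runner writes no timestamps, so identical
config + seed reproduces outputs byte-for-byte.

## Package shape

Where a model is genuinely fitted the package exposes statsmodels-style
objects (`DirichletMultinomialModel.fit()` → `CompositionResults` with
draws, diagnostics and `summary()`); rule-based stages (peak picking,
marker selection, integration, HOMA) are plain functions returning
DataFrames, which is the natural shape for a multi-stage pipeline. The
`cryptomics` CLI is a thin layer over these functions.

## Known limitations

* The moderated-t trend smoother is not bit-identical to limma's; only
  the constant-prior mode is exact.
* The MCMC is a random-walk sampler: posterior tails for very small
  proportions mix more slowly than gradient-based samplers would; the
  split-R̂ warning is the guard.
* Regional classification assumes two identities; mixed or graded
  regional states are forced to the nearer pole.
* Equal-frequency zonation quintiles are a convention; biological zone
  boundaries need not contain equal cell numbers.
* The pathway impact score replicates the published topology idea
  (relative betweenness) but not any specific web-tool internals.
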