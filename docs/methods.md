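# Methods

This note documents the models, estimators and numerical choices behind
`gliarev`, and what the synthetic-data experiments do and do not establish.

## Study design and data model

The pipeline targets a 2 age (young / aged) × 2 treatment (control vector
GFP / IL2 vector) × 3 replicate design with targeted capture of three glial
populations (microglia, astrocytes, oligodendrocytes/OPCs), roughly 300
cells per sample at desk scale (the generator default; real cohorts of
~5,000 cells/sample run through the same code, only slower).  Counts are
modelled as negative binomial: for gene *g* in cell *c*,

    y_gc ~ NB(mean = s_c · m_g(c),  var = mean + φ · mean²)

with `s_c` the cell's total-count offset and φ the dispersion
(inverse-size parameterization, generator default 0.05 — a typical UMI
value; larger φ inflates all noise floors proportionally).

## Synthetic cohort generator

Per-cell expected expression is `libsize × softmax(log-scale effects)`,
with the mitochondrial gene mass re-weighted to the cell's drawn
mitochondrial fraction.  The log-scale effects are additive:

* **baseline** gene abundance: N(0, 1.25) log2, giving a realistic
  abundance spread over 2,000 genes (~1–2 counts/gene/cell at depth 2,500);
* **cell-type programs**: +1.5 log2 on 40 marker genes per glial type;
* **age effect**: 500 genes in 5 pathway blocks; one sign per block,
  |N(0, 0.5)| log2 magnitudes, applied to all aged cells.  The sd is a
  module choice (age effects in glia are mostly sub-twofold); block
  coherence is what makes pathway-level direction calls meaningful;
* **treatment effect**: −ρ\* × age effect, applied to aged-IL2 cells only
  (ρ\* ∈ [0, 1] is the planted reversal fraction); young-IL2 effects are
  off by default and switchable for the treatment-in-young contrast;
* **DAM program**: a fraction (2 % aged, 0 % young) of microglia get a
  +1.5 log2 boost on the canonical marker panel (Trem2, Cst7, Lpl, Itgax,
  Apoe, Clec7a, Tyrobp, Axl, Cd9, Spp1).  Marker baselines sit +1.5 log2
  above the genome average because these are robustly detected microglial
  genes — lowly expressed markers would make any 10-gene score mostly shot
  noise;
* **maturation axis**: latent t ∈ [0, 1] on a trunk (t < 0.5) splitting
  into two arms (geometry "branch", the default) or a plain path.  Sixty
  shared gradient genes change linearly in t (span 2 log2, including an
  S100b-like marker that rises monotonically); 30 arm-specific genes per
  arm switch on past the branch point.  Group occupancy over
  (trunk, mature arm, immature arm) is (0.5, 0.25, 0.25) for young;
  aged-GFP occupancy is shifted by total variation δ toward the mature arm,
  `p_aged = (1−δ)·p_young + δ·e_mature` (default δ = 0.3, so the expected
  young-vs-aged L1 deviance is 1.5·δ = 0.45 before sampling noise);
  aged-IL2 uses δ·(1−ρ\*) so full reversal restores young occupancy;
* **mitochondrial fraction**: truncated normal (mean 0.04, sd 0.02) with a
  3 % tail redrawn from U(0.12, 0.30), so the 10 % QC rule has work to do.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects beyond sample identity, UMI-level sequencing noise, and — most
importantly — age effects that are *confounded with* the maturation
manifold.  Age effects here displace cells orthogonally to the trajectory
genes; real aged cells move partly along the manifold.  Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every real-data pathology.

## QC and normalization

Cells with mitochondrial fraction strictly greater than 0.10 or fewer than
200 total counts are removed, then genes detected in fewer than 3 cells.
The count/gene floors are module defaults (only the mitochondrial rule is a
hard contract); the removal report logs counts per criterion.  Two layers:

* `lognorm = log1p(count × 1e4 / cell total)`;
* `pearson`: analytic NB Pearson residuals `(y − μ)/√(μ + φμ²)` with
  `μ_gc = p_g · s_c` under the pooled per-gene rate, fixed φ = 0.05
  (configurable), clipped at ±√n_cells.  This replaces a fitted
  variance-stabilizing GLM with a closed-form residual of the same intent;
  under the generator's NB null its per-gene variance is ~1, which the
  suite checks by simulation.

Covariate adjustment for depth and mitochondrial load is applied by
residualizing principal-component scores against (total counts, mito
fraction), keeping the count layers interpretable.

## Embeddings and clustering

PCA uses the `pearson` layer restricted to the 500 most variable genes
(fewer when the panel is smaller); selection is essential at panel sizes
where full-matrix noise would swamp the leading axes.  Subclustering is
Leiden (RB-configuration, resolution 0.5, 15-NN graph, seeded) with a
k-means fallback; cluster counts are data-driven, labels are
size-ordered (`Micro1` is the largest microglial cluster).

Composition statistics: per-sample cluster proportions (rows sum to 1
within the analyzed cell type), column-centered PCA with the sign fixed by
making each component's largest loading positive, and Welch t-tests for
three families — treatment within young, treatment within aged, age pooled
over treatments — Holm-corrected within each family across clusters.
Welch is used because replicate groups are tiny (n = 3) and homoscedasticity
is not worth assuming; Holm is the named post-hoc correction for these
family-wise tests.

## DAM score and threshold

Score = mean `lognorm` expression of the marker panel − mean of a control
pool built by sampling, per marker, 50 genes from the marker's
mean-expression bin (25 bins, seeded, markers excluded).  Bin matching
removes the depth/abundance component, so the score is ~0-centered for
cells without the program and library-size invariant in expectation.
Classification is strict: `is_dam = score > τ`.  The default τ = 0.07 is
the published operating point *on the published score scale*; score scales
differ across formulas, so `dam_prevalence(..., auto_threshold=True)`
instead places τ at the antimode of a two-component Gaussian mixture over
the scores (components initialized at the median and the 99.9th percentile
so a ~2 % minor mode is found; threshold at the weighted-density crossing
between the component means).  The synthetic experiments use the
auto-calibrated mode.

## Principal-tree pseudotime and the deviance statistic

The tree is a deliberately simple principal graph: k-means (20 nodes) on
the top PCA scores (3 components by default — the latent geometry of one
axis plus one branch point spans at most three dimensions), followed by 8
rounds of elastic relaxation (each node pulled halfway toward the mean of
its MST neighbours, MST rebuilt) and a final MST.  Branches are maximal
segments between nodes of degree ≠ 2; leaf branches carrying < 10 % of
cells are pruned iteratively as noise spurs.  Cells project to the nearest
edge segment.  A full alternating-optimization tree embedding would be out
of proportion to the statistic computed on it; a hook (`principal_tree` on
arbitrary coordinates) lets an external tree be plugged in.

Rooting: the branch with the highest occupancy share among young control
cells wins (ties → lower branch id); the root is its outer (degree-1)
terminus, and when both or neither endpoint is a leaf the endpoint closer
on average (geodesic) to the young control cells is taken (exact ties →
lower node id).  Pseudotime is geodesic arc length from the root to the
cell's projection.

Sum of deviance: for sample *s* and young-control replicate *r* (r ≠ s),
`D(s, r) = Σ_b |p_s(b) − p_r(b)|` over branch-occupancy proportions —
the L1 distance on the branch simplex, in [0, 2].  One data point per
pairing; self-pairings are excluded so the young baseline is not deflated;
group summaries are means ± sd over points.  The statistic needs a
branching tree to be informative — on a pure path it collapses to a single
branch and D ≡ 0, which is why the generator's default geometry branches.

## Negative-binomial differential expression

Contrasts: AGE (agedGFP vs youngGFP), TREAT_YOUNG (youngIL2 vs youngGFP),
TREAT_AGED (agedIL2 vs agedGFP), AGE_TREATED (agedIL2 vs youngIL2); the
second group is the baseline.  Genes detected in < 1 % of cells on both
sides are skipped.  Per gene, the two group log-means are profiled by
Newton steps on the NB score equation with `log s_c` offsets (steps clipped
at ±4; a group with zero counts keeps its continuity-corrected start value,
`(Σy + 0.5)/Σs`, which also stabilizes the reported log2 fold change);
dispersion is pooled method-of-moments with a 1e-4 floor, re-estimated once
around the refitted means.  The Wald z is the log-mean difference over
`√(1/I₁ + 1/I₀)` with `I = Σ μ/(1 + φμ)`; BH adjustment within each
contrast.  The whole fit is vectorized across genes (a 2,000-gene contrast
takes well under a second), and its null calibration (KS distance, type-I
error) is checked by simulation.  A pseudobulk mode (summing counts per
sample) exists for robustness comparisons.

## Reversal fraction

Genes with BH-adjusted age p < 0.05 are paired as (LFC_age, LFC_treat).
The primary estimator is the intercept-free least-squares slope of
LFC_treat on LFC_age, negated and clipped to [0, 1]: under the generative
model LFC_treat = −ρ\*·LFC_age on affected genes, so −β estimates ρ\*
directly, and restricting to age-significant genes keeps regression
attenuation from noisy LFC_age negligible.  The sign-discordance fraction
(genes moved opposite to aging) and the Pearson correlation are reported
alongside because a percentage of "countered" change can be read either
way.  Known edge behavior: at ρ\* = 0 the clip at 0 gives a small positive
bias (~0.05), and at ρ\* = 1 selection/attenuation gives ~0.95; both well
inside the ±0.10 recovery band the suite enforces.

## Gene-set tests and directionality

The set-level test keeps the GAGE idea (a set-mean two-group statistic) but
uses the per-gene NB Wald z: set statistic = mean z over matched members
(case-insensitive symbol matching; sets with < 10 matches skipped).  The
null is built from shared global permutations of the z vector — each of
1,000 permutations contributes its prefix means, giving the null mean for
every set size at once, without replacement — and
`p = min(2·min(P_up, P_down), 1)` with add-one permutation tails, so the
smallest attainable two-sided p is 2/(n_perm + 1).  BH across sets within a
contrast.

Directionality per (pathway, contrast), relative to the aging axis:

* concordance `C = Σ w_g · sign(LFC_c · LFC_AGE) / Σ w_g` with
  `w_g = |LFC_AGE|`, zero-age-LFC genes excluded; C(AGE vs AGE) = +1 by
  construction (a standing self-consistency check);
* magnitude ratio `R = |Σ LFC_c · LFC_AGE| / Σ LFC_AGE²` — the set-level
  projection coefficient of the contrast onto the aging axis.  R = 1 when
  the contrast reproduces the age change exactly and R ≈ 1 − ρ\* under the
  generator.  A per-gene ratio would be ill-defined in one dimension; the
  projection form is the magnitude comparison that "closer to young"
  implies, kept nonnegative so over-reversal does not masquerade as
  amplification.

Calls: `same_direction_as_aging` ⇔ C(AGE_TREATED) > 0;
`reverted_toward_young` ⇔ R(AGE_TREATED) < 1.  Pathway curation is a
declarative include/exclude rule file over sets significant at q < 0.1 in
any contrast — never hard-coded judgment.

## Determinism and problem sizes

Every stochastic step (generator, k-means, Leiden, control-gene sampling,
permutations) is driven by an explicit seed; pipeline runs with the same
config and seed are byte-identical (floats are written at 10 significant
digits).  The test suite and the acceptance script run the synthetic
experiments at the design scale of 3 samples/group × 300 cells/sample ×
2,000 genes (500 affected) for estimator recovery, 1,000 cells/sample for
DAM prevalence (so per-sample binomial noise at 2 % prevalence stays below
the effect), and 800-gene cohorts for the deviance power sweep — sizes
chosen so each experiment is a few minutes of CPU while keeping Monte-Carlo
error well inside the asserted bands.

## Known limitations

* The NB Wald test treats cells as independent within groups; with strong
  replicate-level variation a pseudobulk or mixed-model analysis is more
  conservative (the pseudobulk mode is provided, not default).
* The centroid-MST tree recovers one-axis/one-branch-point geometries
  reliably; densely looped or high-dimensional trajectories need an
  external tree via the plug-in hook.
* The mixture-antimode DAM calibration assumes the score is bimodal; in
  cohorts with no DAM component it will place τ in the upper tail and call
  ~0 % prevalence, which is the desired failure mode but should be checked
  against the score histogram.
* Symbol-based gene-set matching reports a match rate but does not resolve
  aliases.
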