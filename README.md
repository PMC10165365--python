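# gliarev

**Quantifying treatment reversal of the glial aging signature in
multi-sample single-cell RNA-seq.**

`gliarev` is a Python library (plus a thin CLI) for a recurring question in
brain-aging intervention studies: given a 2 age × 2 treatment × replicate
scRNA-seq design over glial cells (microglia, astrocytes,
oligodendrocytes/OPCs), *how much of the age-induced transcriptomic change
does the treatment undo?*  It implements the full analysis chain:

1. **QC & normalization** — cells with > 10 % mitochondrial reads removed
   (strict rule), log-normalized counts and clipped analytic NB Pearson
   residuals as layers.
2. **Subclustering & composition statistics** — Leiden communities per glial
   type; per-sample cluster proportions; PCA of the proportion table; Welch
   t-tests with Holm correction for treatment-within-age and pooled-age
   contrasts.
3. **DAM scoring** — per-cell disease-associated-microglia score (marker
   panel mean minus expression-bin-matched control mean), threshold
   classification, and prevalence tests.
4. **Trajectory & branch deviance** — principal-tree pseudotime
   (k-means centroids + elastic MST), rooted at the branch richest in young
   control cells; the **sum of deviance**
   `D(s, r) = Σ_b |p_s(b) − p_r(b)|` compares each sample's
   branch-occupancy vector with every young-control replicate.
5. **NB differential expression** — per-gene negative-binomial Wald test
   with library-size offsets over four contrasts: age, treatment-in-young,
   treatment-in-aged, and age-in-treated.
6. **Reversal fraction** — for age-significant genes, pair
   `(LFC_age, LFC_treat)`; the estimator is
   `ρ̂ = clip(−β, 0, 1)` with `β` the intercept-free slope of `LFC_treat` on
   `LFC_age` (sign-discordance reported as a secondary readout).
7. **Gene-set directionality** — GAGE-style set-mean permutation enrichment
   per contrast, and per-pathway directionality relative to the aging axis:
   concordance `C ∈ [−1, 1]` and magnitude ratio `R ≥ 0`, with calls
   *same-direction-as-aging* (`C > 0`) and *reverted-toward-young*
   (`R < 1`).

A first-class **synthetic cohort generator** reproduces the statistical
structure this design assumes — NB counts with per-cell depth and
mitochondrial fraction, pathway-block age effects, a tunable reversal
fraction ρ\*, a rare (~2 %) DAM-like state in aged microglia, and a
branching maturation axis with a per-group occupancy shift — with all
ground truth recorded, so every estimator is tested for parameter recovery.

## Worked example

```python
import gliarev as g

cohort, truth = g.simulate_cohort(g.SimParams(seed=4, reversal_fraction_true=0.5))
g.compute_qc_metrics(cohort)
cohort, _ = g.filter_cells(cohort)

de_age   = g.nb_de(cohort, "microglia", "AGE")
de_treat = g.nb_de(cohort, "microglia", "TREAT_AGED")
result   = g.reversal_fraction(g.two_dim_de(de_age, de_treat), celltype="microglia")
```

Running this as `python examples/04_reversal_fraction.py` prints

```
age-significant genes paired: 257
reversal fraction rho_hat:   0.510  (planted 0.5)
sign discordance:            1.000
2-D DE slope / correlation:  -0.510 / -0.961
```

(from `examples/04_reversal_fraction.py`): the pipeline recovers the
planted ρ\* = 0.5 — the treatment countered ~51 % of the age-induced
changes — and every age-moved significant gene moves back toward young
(discordance 1.0, strongly negative 2-D DE correlation).  The other
`examples/*.py` scripts walk through each capability (simulation, QC + DAM,
trajectory deviance, gene-set directionality, full pipeline) and print a
short interpretation with their numbers.

## Command line

```bash
gliarev simulate --out cohort_dir --seed 1          # synthetic cohort + truth
gliarev run --config cfg.yaml                       # staged pipeline
gliarev run --config cfg.yaml --stages de,reversal  # re-run stages from disk
```

The config names the input (a 10x-convention Matrix-Market directory +
`metadata.tsv`, or generator parameters), the stages, per-stage parameters
and a global seed; each stage writes CSV tables and a JSON parameter log,
and reruns with the same config and seed are byte-identical.

## Scope notes

Doublet detection, atlas label transfer, and UMAP visualization are out of
scope (subtype labels come from metadata or synthetic truth).  Published
headline percentages from real cohorts depend on the deposited accession
and pathway-database versions; this package verifies the *method* by
parameter recovery on synthetic data at desk scale.
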