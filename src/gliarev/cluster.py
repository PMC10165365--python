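"""Subclustering within glial types and sample-composition statistics.

Cells of one type are embedded by PCA on the Pearson-residual layer, the
principal-component scores are residualized against total counts and the
mitochondrial fraction (the covariate "regression" applied in embedding
space), and communities are found by Leiden on a k-nearest-neighbour graph
(k-means fallback).  Composition statistics follow the multi-sample design:
per-sample cluster proportions, a centered PCA over the proportion table,
and Welch t-tests over three contrast families with Holm correction within
each family across clusters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .cohort import CellCohort, CohortDesign, ParameterError

log = logging.getLogger(__name__)

_PREFIX = {"microglia": "Micro", "astrocyte": "Astro", "oligodendrocyte": "Oligo"}

#: Contrast families of the composition tests: name -> (group A, group B) or
#: ("age", None) meaning aged vs young pooled over treatments.
COMPOSITION_CONTRASTS = {
    "treatment|young": ("youngIL2", "youngGFP"),
    "treatment|aged": ("agedIL2", "agedGFP"),
    "age": (None, None),
}


def pca_scores(
    cohort: CellCohort,
    celltype: str | None = None,
    n_components: int = 30,
    layer: str = "pearson",
    residualize: bool = True,
    n_hvg: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA embedding of cells (optionally one cell type), covariate-residualized.

    The ``n_hvg`` most variable genes (by layer variance within the selected
    cells) enter the PCA; set 0 to use all genes.  Returns (scores cells x k,
    integer cell indices into the cohort).
    """
    if layer not in cohort.layers:
        raise ParameterError(f"layer {layer!r} missing; run qc.normalize first")
    idx = cohort.cells_of_type(celltype) if celltype else np.arange(cohort.n_cells)
    X = cohort.layers[layer][:, idx].T  # cells x genes
    if n_hvg and n_hvg < X.shape[1]:
        var = X.var(axis=0)
        top = np.sort(np.argsort(var)[::-1][:n_hvg])
        X = X[:, top]
    k = int(min(n_components, X.shape[0] - 1, X.shape[1]))
    if k < 1:
        raise ParameterError(f"too few cells ({X.shape[0]}) for PCA")
    scores = PCA(n_components=k, svd_solver="full", random_state=seed).fit_transform(X)
    if residualize:
        cov = np.column_stack(
            [
                np.ones(idx.size),
                cohort.cell_table["total_counts"].iloc[idx].to_numpy(dtype=float),
                cohort.cell_table["mito_fraction"].iloc[idx].to_numpy(dtype=float),
            ]
        )
        beta, *_ = np.linalg.lstsq(cov, scores, rcond=None)
        scores = scores - cov @ beta
    return scores, idx


def subcluster(
    cohort: CellCohort,
    celltype: str,
    resolution: float = 0.5,
    n_neighbors: int = 15,
    n_components: int = 30,
    method: str = "leiden",
    k: int | None = None,
    seed: int = 0,
) -> CellCohort:
    """Assign cluster labels (e.g. Micro1..k) to cells of one type, in place.

    method "leiden": community detection on a k-NN graph of the residualized
    PCA scores; method "kmeans": k-means with ``k`` clusters.  Deterministic
    under a fixed seed.
    """
    scores, idx = pca_scores(cohort, celltype, n_components=n_components, seed=seed)
    if method == "leiden":
        if idx.size <= n_neighbors:
            raise ParameterError(
                f"{idx.size} {celltype} cells but n_neighbors={n_neighbors}"
            )
        import igraph
        import leidenalg

        nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(scores)
        _, nbrs = nn.kneighbors(scores)
        edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbrs) for j in row[1:]}
        graph = igraph.Graph(n=idx.size, edges=sorted(edges))
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
    elif method == "kmeans":
        if k is None:
            raise ParameterError("kmeans clustering requires k")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(scores)
    else:
        raise ParameterError(f"unknown clustering method {method!r}")

    # Stable label order: clusters numbered by decreasing size.
    order = pd.Series(labels).value_counts().index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    prefix = _PREFIX.get(celltype, celltype.capitalize())
    named = np.array([f"{prefix}{remap[l] + 1}" for l in labels], dtype=object)
    if "cluster" not in cohort.cell_table.columns:
        cohort.cell_table["cluster"] = pd.array([None] * cohort.n_cells, dtype=object)
    cohort.cell_table.loc[cohort.cell_table.index[idx], "cluster"] = named
    return cohort


def composition_table(
    cohort: CellCohort,
    celltype: str | None = None,
    grouping: str = "cluster",
    design: CohortDesign | None = None,
) -> pd.DataFrame:
    """Per-sample proportions over clusters (or any cell_table column).

    Rows sum to 1 over the analyzed cell type; samples contributing no cells
    of the type get a zero row with a warning.  Design columns are attached.
    """
    design = design or CohortDesign.from_cell_table(cohort.cell_table)
    ct = cohort.cell_table
    mask = (ct["celltype"] == celltype) if celltype else pd.Series(True, index=ct.index)
    sub = ct[mask]
    tab = pd.crosstab(sub["sample"], sub[grouping])
    tab = tab.reindex(design.samples.index, fill_value=0)
    totals = tab.sum(axis=1)
    empty = totals == 0
    if empty.any():
        log.warning("samples with 0 %s cells: %s", celltype, list(tab.index[empty]))
    props = tab.div(totals.replace(0, 1), axis=0)
    props.columns = [str(c) for c in props.columns]
    return props.join(design.samples)


def composition_pca(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA of a sample x cluster proportion table.

    Sign convention: each component's largest-magnitude loading is positive.
    Returns (scores with design columns, explained variance ratios).
    """
    design_cols = [c for c in ("age", "treatment", "replicate") if c in table.columns]
    X = table.drop(columns=design_cols).to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ParameterError("composition PCA needs >=3 samples")
    k = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    out = pd.DataFrame(scores, index=table.index, columns=[f"PC{j + 1}" for j in range(k)])
    return out.join(table[design_cols]), pca.explained_variance_ratio_


def holm_within(pvals: pd.Series) -> pd.Series:
    adj = multipletests(pvals.to_numpy(), method="holm")[1]
    return pd.Series(adj, index=pvals.index)


def composition_tests(table: pd.DataFrame, design: CohortDesign) -> pd.DataFrame:
    """Welch t-tests per cluster for the three contrast families, Holm-corrected
    within each family across clusters.

    Families: treatment within young, treatment within aged, and age pooled
    over treatments.  Groups with fewer than two samples are skipped with a flag.
    """
    design_cols = [c for c in ("age", "treatment", "replicate") if c in table.columns]
    clusters = [c for c in table.columns if c not in design_cols]
    group = design.group_of_sample.reindex(table.index)
    age = design.samples["age"].reindex(table.index)
    rows = []
    for fam, (ga, gb) in COMPOSITION_CONTRASTS.items():
        if fam == "age":
            a_mask, b_mask = (age == "aged").to_numpy(), (age == "young").to_numpy()
        else:
            a_mask, b_mask = (group == ga).to_numpy(), (group == gb).to_numpy()
        for cl in clusters:
            a = table.loc[a_mask, cl].to_numpy(dtype=float)
            b = table.loc[b_mask, cl].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                rows.append(
                    {"cluster": cl, "contrast": fam, "t": np.nan, "pvalue": np.nan,
                     "mean_a": np.nan, "mean_b": np.nan, "skipped": True}
                )
                continue
            if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
                t, p = 0.0, 1.0  # identical constant groups
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {"cluster": cl, "contrast": fam, "t": float(t), "pvalue": float(p),
                 "mean_a": a.mean(), "mean_b": b.mean(), "skipped": False}
            )
    res = pd.DataFrame(rows)
    res["padj"] = np.nan
    for fam in COMPOSITION_CONTRASTS:
        m = (res["contrast"] == fam) & ~res["skipped"] & res["pvalue"].notna()
        if m.any():
            res.loc[m, "padj"] = holm_within(res.loc[m, "pvalue"])
    return res
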