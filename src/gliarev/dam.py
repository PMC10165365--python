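"""Disease-associated microglia (DAM) scoring, classification and prevalence.

The per-cell DAM score is the mean log-normalized expression of a marker
panel minus the mean of an expression-bin-matched random control gene set
(genes binned by mean expression; controls drawn per marker from the
marker's bin, seeded).  Cells are classified DAM when the score exceeds a
threshold tau (default 0.07, strict greater-than); prevalence per sample is
tested across the same contrast families as the composition statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import composition_tests
from .cohort import CellCohort, CohortDesign, ParameterError


def default_markers() -> list[str]:
    """The packaged DAM marker panel."""
    text = resources.files("gliarev.data").joinpath("dam_markers.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class DAMParams:
    markers: list[str] = field(default_factory=default_markers)
    n_control_bins: int = 25
    n_control_genes_per_marker: int = 50
    threshold: float = 0.07
    seed: int = 0


def dam_score(cohort: CellCohort, params: DAMParams | None = None, celltype: str = "microglia") -> pd.Series:
    """Bin-matched aggregate marker score for cells of one type.

    Returns a float Series indexed like cell_table, NaN outside the cell type;
    also stored as cell_table["dam_score"].
    """
    params = params or DAMParams()
    if "lognorm" not in cohort.layers:
        raise ParameterError("lognorm layer missing; run qc.normalize first")
    idx = cohort.cells_of_type(celltype)
    if idx.size == 0:
        raise ParameterError(f"no {celltype!r} cells")
    X = cohort.layers["lognorm"][:, idx]  # genes x microglia
    symbols = cohort.gene_table["symbol"].astype(str)
    lookup = {s.lower(): i for i, s in enumerate(symbols)}
    marker_idx = np.array(sorted({lookup[m.lower()] for m in params.markers if m.lower() in lookup}),
                          dtype=int)
    if marker_idx.size < 3:
        raise ParameterError(
            f"only {marker_idx.size} of {len(params.markers)} DAM markers matched; need >=3"
        )

    # Expression bins over mean lognorm expression of all genes.
    mean_expr = X.mean(axis=1)
    order = np.argsort(mean_expr, kind="stable")
    bin_of = np.empty(len(mean_expr), dtype=int)
    bin_of[order] = np.minimum(
        np.arange(len(order)) * params.n_control_bins // len(order), params.n_control_bins - 1
    )
    rng = np.random.default_rng(params.seed)
    controls: list[np.ndarray] = []
    marker_set = set(marker_idx.tolist())
    for g in marker_idx:
        pool = np.flatnonzero(bin_of == bin_of[g])
        pool = pool[~np.isin(pool, marker_idx)]
        if pool.size == 0:
            pool = np.setdiff1d(np.arange(len(mean_expr)), marker_idx)
        take = min(params.n_control_genes_per_marker, pool.size)
        controls.append(rng.choice(pool, size=take, replace=False))
    control_idx = np.concatenate(controls)

    score = X[marker_idx].mean(axis=0) - X[control_idx].mean(axis=0)
    out = pd.Series(np.nan, index=cohort.cell_table.index, name="dam_score")
    out.iloc[idx] = score
    cohort.cell_table["dam_score"] = out
    return out


def calibrate_threshold(scores: pd.Series, seed: int = 0) -> float:
    """Antimode of a two-component Gaussian mixture over the scores.

    The marker score of a cohort containing a distinct DAM state is bimodal:
    a null mode near 0 and a boosted mode.  The components are initialized at
    the median and the extreme upper tail so the minor component captures the
    boosted state even at ~2% prevalence; the threshold is the point between
    the component means where the weighted densities cross.
    """
    from scipy.stats import norm
    from sklearn.mixture import GaussianMixture

    x = scores.dropna().to_numpy().reshape(-1, 1)
    lo, hi = float(np.median(x)), float(np.quantile(x, 0.999))
    gm = GaussianMixture(
        n_components=2,
        means_init=[[lo], [hi]],
        weights_init=[0.98, 0.02],
        random_state=seed,
    ).fit(x)
    m = gm.means_.ravel()
    s = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(m)
    m, s, w = m[order], s[order], w[order]
    grid = np.linspace(m[0], m[1], 512)
    dens = np.vstack(
        [w[k] * norm.pdf(grid, m[k], s[k]) for k in range(2)]
    )
    return float(grid[np.argmin(np.abs(dens[0] - dens[1]))])


def classify_dam(scores: pd.Series, threshold: float = 0.07) -> pd.Series:
    """Strict-threshold DAM flag: is_dam = score > tau (NaN scores -> False)."""
    return (scores > threshold).fillna(False).astype(bool)


def dam_prevalence(
    cohort: CellCohort,
    design: CohortDesign | None = None,
    params: DAMParams | None = None,
    celltype: str = "microglia",
    auto_threshold: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample DAM proportion among cells of one type, plus contrast tests.

    Scores are computed if absent.  ``auto_threshold`` replaces the fixed
    threshold with the mixture-antimode calibration (the fixed default lives
    on the published score scale, which need not match other score scales).
    Returns (prevalence table with design columns, composition-style
    Welch/Holm test rows over the DAM proportion).
    """
    params = params or DAMParams()
    design = design or CohortDesign.from_cell_table(cohort.cell_table)
    if "dam_score" not in cohort.cell_table.columns:
        dam_score(cohort, params, celltype=celltype)
    tau = (
        calibrate_threshold(cohort.cell_table["dam_score"], seed=params.seed)
        if auto_threshold
        else params.threshold
    )
    flags = classify_dam(cohort.cell_table["dam_score"], tau)
    cohort.cell_table["is_dam"] = flags
    ct = cohort.cell_table
    sub = ct[ct["celltype"] == celltype]
    prev = sub.groupby("sample")["is_dam"].mean().reindex(design.samples.index).fillna(0.0)
    n = sub.groupby("sample").size().reindex(design.samples.index).fillna(0).astype(int)
    table = pd.DataFrame({"DAM": prev, "n_cells": n}).join(design.samples)
    tests = composition_tests(table.drop(columns=["n_cells"]), design)
    return table, tests
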