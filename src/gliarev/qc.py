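"""Cell/gene quality-control filtering and normalization layers.

Cells with a mitochondrial read fraction strictly above the threshold
(default 10%) or too few total counts are removed; genes expressed in too
few cells are dropped afterwards.  Two normalized layers feed downstream
stages: "lognorm" (log1p of counts-per-10k) and "pearson" (clipped analytic
Pearson residuals under a per-gene NB null with mean proportional to
library size and a fixed dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CellCohort, ParameterError


@dataclass
class QCParams:
    mito_threshold: float = 0.10  # strict greater-than removal
    min_counts_per_cell: int = 200
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_threshold <= 1.0:
            raise ParameterError("mito_threshold must lie in [0, 1]")
        if self.min_counts_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ParameterError("QC floors must be nonnegative")


def compute_qc_metrics(cohort: CellCohort) -> CellCohort:
    """Append per-cell total_counts, n_genes and mito_fraction in place."""
    counts = cohort.counts
    totals = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = cohort.gene_table["is_mitochondrial"].to_numpy()
    mito_counts = np.asarray(counts[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    cohort.cell_table["total_counts"] = totals
    cohort.cell_table["n_genes"] = n_genes
    cohort.cell_table["mito_fraction"] = frac
    return cohort


def filter_cells(cohort: CellCohort, params: QCParams | None = None) -> tuple[CellCohort, pd.DataFrame]:
    """Remove low-quality cells, then lowly-detected genes.

    Returns the filtered cohort and a per-sample removal report
    (retained / removed_mito / removed_low_counts counts).
    """
    params = params or QCParams()
    if "mito_fraction" not in cohort.cell_table.columns:
        compute_qc_metrics(cohort)
    ct = cohort.cell_table
    high_mito = ct["mito_fraction"].to_numpy() > params.mito_threshold
    low_counts = ct["total_counts"].to_numpy() < params.min_counts_per_cell
    keep = ~(high_mito | low_counts)
    if not keep.any():
        raise ParameterError("QC filter removed every cell")
    report = (
        pd.DataFrame(
            {
                "sample": ct["sample"],
                "retained": keep,
                "removed_high_mito": high_mito,
                "removed_low_counts": low_counts,
            }
        )
        .groupby("sample", sort=True)
        .sum()
        .reset_index()
    )
    out = cohort.subset_cells(np.flatnonzero(keep))
    detected = np.asarray((out.counts > 0).sum(axis=1)).ravel()
    out = out.subset_genes(np.flatnonzero(detected >= params.min_cells_per_gene))
    return out, report


def normalize(cohort: CellCohort, method: str = "both", dispersion: float = 0.05) -> CellCohort:
    """Attach normalized layers.

    method "lognorm": log1p(count x 1e4 / cell total).  method "pearson":
    clipped Pearson residuals (x - mu)/sqrt(mu + phi mu^2) with
    mu_gc = p_g x total_c under the pooled per-gene rate p_g, clipped at
    +/- sqrt(n_cells).  "both" computes the two.
    """
    if method not in ("lognorm", "pearson", "both"):
        raise ParameterError(f"unknown normalization method {method!r}")
    dense = np.asarray(cohort.counts.todense(), dtype=float)
    totals = dense.sum(axis=0)
    safe = np.maximum(totals, 1.0)
    if method in ("lognorm", "both"):
        cohort.layers["lognorm"] = np.log1p(dense * 1e4 / safe)
    if method in ("pearson", "both"):
        grand = max(dense.sum(), 1.0)
        p_g = dense.sum(axis=1) / grand
        mu = np.outer(p_g, totals)
        resid = (dense - mu) / np.sqrt(mu + dispersion * mu**2 + 1e-12)
        clip = np.sqrt(cohort.n_cells)
        cohort.layers["pearson"] = np.clip(resid, -clip, clip)
    return cohort
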