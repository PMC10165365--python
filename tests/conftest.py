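import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gliarev as g


def small_params(seed: int = 0, **over) -> g.SimParams:
    """A reduced cohort that keeps every structured gene set but runs fast."""
    base = dict(
        n_cells_per_sample=100,
        n_genes=700,
        n_affected_genes=120,
        n_pathways=3,
        seed=seed,
    )
    base.update(over)
    dam_over = base.pop("dam", {})
    traj_over = base.pop("trajectory", {})
    p = g.SimParams(**base)
    if dam_over:
        p.dam = dataclasses.replace(p.dam, **dam_over)
    if traj_over:
        p.trajectory = dataclasses.replace(p.trajectory, **traj_over)
    return p


def prepared(params: g.SimParams):
    """simulate -> qc -> normalize; returns (cohort, truth, design)."""
    cohort, truth = g.simulate_cohort(params)
    g.compute_qc_metrics(cohort)
    cohort, _ = g.filter_cells(cohort)
    g.normalize(cohort)
    design = g.CohortDesign.from_cell_table(cohort.cell_table)
    return cohort, truth, design


@pytest.fixture(scope="session")
def default_run():
    """One shared default-parameter cohort (rho*=0.5) after QC/normalization."""
    return prepared(g.SimParams(seed=11))


@pytest.fixture(scope="session")
def small_run():
    return prepared(small_params(seed=7))


def manual_cohort(counts: np.ndarray, mito_rows=(), samples=None, ages=None,
                  treatments=None, celltype="microglia") -> g.CellCohort:
    """Build a CellCohort from a dense genes x cells array."""
    counts = np.asarray(counts)
    ng, nc = counts.shape
    symbols = [f"mt-G{i}" if i in set(mito_rows) else f"G{i}" for i in range(ng)]
    gene_table = pd.DataFrame(
        {"gene_id": [f"id{i}" for i in range(ng)], "symbol": symbols,
         "is_mitochondrial": [i in set(mito_rows) for i in range(ng)]}
    )
    samples = list(samples) if samples is not None else ["youngGFP_1"] * nc
    ages = list(ages) if ages is not None else ["young"] * nc
    treatments = list(treatments) if treatments is not None else ["GFP"] * nc
    reps = [s.rsplit("_", 1)[-1] for s in samples]
    cell_table = pd.DataFrame(
        {"barcode": [f"bc{i}" for i in range(nc)], "sample": samples,
         "age": ages, "treatment": treatments, "replicate": reps,
         "celltype": [celltype] * nc}
    )
    return g.CellCohort(counts=sp.csr_matrix(counts), gene_table=gene_table,
                        cell_table=cell_table)
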