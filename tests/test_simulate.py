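"""Generator contracts: determinism, planted-structure bookkeeping, NB marginals."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gliarev as g
from conftest import small_params


def test_same_seed_bit_identical():
    p = small_params(seed=42)
    c1, t1 = g.simulate_cohort(p)
    c2, t2 = g.simulate_cohort(small_params(seed=42))
    assert (c1.counts != c2.counts).nnz == 0
    pd.testing.assert_frame_equal(t1.cells, t2.cells)
    assert (c1.counts != g.simulate_cohort(small_params(seed=43))[0].counts).nnz > 0


def test_metadata_and_flags():
    cohort, truth = g.simulate_cohort(small_params(seed=1))
    assert cohort.counts.min() >= 0
    for col in ("sample", "age", "treatment", "celltype", "replicate"):
        assert col in cohort.cell_table.columns
    assert cohort.gene_table["is_mitochondrial"].sum() > 0
    assert set(truth.cells["segment"]) <= {"trunk", "armA", "armB"}
    # DAM flags appear only in aged microglia when dam_fraction_young = 0
    flagged = truth.cells[truth.cells["is_dam"]]
    ages = cohort.cell_table.set_index("barcode")["age"]
    assert (ages.loc[flagged["barcode"]] == "aged").all()


def test_null_construction_groups_identical():
    """rho*=0, no DAM, no occupancy shift: young and aged means agree to noise."""
    p = small_params(
        seed=2, n_affected_genes=0, n_pathways=1, reversal_fraction_true=0.0,
        dam={"dam_fraction_aged": 0.0}, trajectory={"delta_aged": 0.0},
    )
    cohort, truth = g.simulate_cohort(p)
    assert truth.genes["true_age_lfc"].abs().sum() == 0
    X = np.asarray(cohort.counts.todense(), dtype=float)
    tot = X.sum(axis=0)
    cpm = X / tot * 1e4
    aged = (cohort.cell_table["age"] == "aged").to_numpy()
    diff = cpm[:, aged].mean(axis=1) - cpm[:, ~aged].mean(axis=1)
    se = np.sqrt(cpm[:, aged].var(axis=1) / aged.sum() + cpm[:, ~aged].var(axis=1) / (~aged).sum())
    z = diff / np.maximum(se, 1e-9)
    # genome-wide z should look standard normal; allow generous MC slack
    assert abs(np.mean(z)) < 0.2
    assert (np.abs(z) > 4).mean() < 0.01


def test_dam_flag_count_binomial():
    p = small_params(seed=3, n_cells_per_sample=500, dam={"dam_fraction_aged": 0.02})
    cohort, truth = g.simulate_cohort(p)
    aged_micro = cohort.cell_table.merge(truth.cells[["barcode", "is_dam"]], on="barcode")
    aged_micro = aged_micro[(aged_micro["age"] == "aged") & (aged_micro["celltype"] == "microglia")]
    n = len(aged_micro)
    k = aged_micro["is_dam"].sum()
    sd = np.sqrt(n * 0.02 * 0.98)
    assert abs(k - 0.02 * n) <= 3 * sd


def test_parameter_errors():
    p = small_params()
    p.celltype_mixture = {"microglia": 0.5, "astrocyte": 0.2}
    with pytest.raises(g.ParameterError):
        g.simulate_cohort(p)
    with pytest.raises(g.ParameterError):
        g.simulate_cohort(small_params(n_genes=100))  # smaller than structured sets
    with pytest.raises(g.ParameterError):
        g.simulate_cohort(small_params(reversal_fraction_true=1.5))


def test_nb_marginal_moments():
    """Marginal variance of a planted-null gene tracks NB(mean, dispersion)."""
    p = small_params(
        seed=4, n_cells_per_sample=250, n_affected_genes=0, n_pathways=1,
        dam={"dam_fraction_aged": 0.0},
        trajectory={"delta_aged": 0.0, "gradient_log2_span": 0.0, "arm_log2_boost": 0.0},
        libsize_lognormal=(np.log(2500.0), 1e-6),  # fixed depth isolates NB noise
    )
    cohort, truth = g.simulate_cohort(p)
    X = np.asarray(cohort.counts.todense(), dtype=float)
    null_rows = (truth.genes["role"] == "null").to_numpy()
    mu = X[null_rows].mean(axis=1)
    v = X[null_rows].var(axis=1)
    keep = mu > 1.0
    phi_hat = np.median((v[keep] - mu[keep]) / mu[keep] ** 2)
    assert 0.5 * p.nb_dispersion < phi_hat < 2.0 * p.nb_dispersion


def test_full_reversal_restores_young_profile():
    """rho*=1: aged-IL2 mean expression matches young-GFP on affected genes."""
    p = small_params(seed=5, n_cells_per_sample=400, reversal_fraction_true=1.0)
    cohort, truth = g.simulate_cohort(p)
    X = np.asarray(cohort.counts.todense(), dtype=float)
    cpm = X / X.sum(axis=0) * 1e4
    grp = cohort.group.to_numpy()
    aff = (truth.genes["true_age_lfc"].abs() > 0.3).to_numpy()
    with np.errstate(divide="ignore"):
        lfc = np.log2(cpm[aff][:, grp == "agedIL2"].mean(axis=1)
                      / cpm[aff][:, grp == "youngGFP"].mean(axis=1))
    assert np.nanmedian(np.abs(lfc)) < 0.15
    # while aged-GFP stays shifted
    lfc_gfp = np.log2(cpm[aff][:, grp == "agedGFP"].mean(axis=1)
                      / cpm[aff][:, grp == "youngGFP"].mean(axis=1))
    assert np.nanmedian(np.abs(lfc_gfp)) > 0.3


def test_write_cohort_roundtrip(tmp_path):
    cohort, _ = g.simulate_cohort(small_params(seed=6))
    g.write_cohort(cohort, tmp_path / "c")
    back = g.read_cohort(tmp_path / "c")
    assert (back.counts != cohort.counts).nnz == 0
    assert list(back.cell_table["sample"]) == list(cohort.cell_table["sample"])
    assert back.gene_table["is_mitochondrial"].sum() == cohort.gene_table["is_mitochondrial"].sum()


def test_write_empty_cohort_roundtrip(tmp_path):
    from conftest import manual_cohort

    cohort = manual_cohort(np.zeros((3, 0), dtype=int))
    g.write_cohort(cohort, tmp_path / "empty")
    back = g.read_cohort(tmp_path / "empty")
    assert back.n_cells == 0 and back.n_genes == 3


def test_toy_matrix_nonzero_triplets(tmp_path):
    from conftest import manual_cohort

    cohort = manual_cohort(np.array([[1, 0], [0, 2], [3, 3]]))
    g.write_cohort(cohort, tmp_path / "toy")
    header_and_data = [
        ln for ln in (tmp_path / "toy" / "matrix.mtx").read_text().splitlines()
        if not ln.startswith("%")
    ]
    n_entries = int(header_and_data[0].split()[2])
    assert n_entries == 4
    assert len(header_and_data) == 1 + 4


def test_truth_gmt_contains_pathway_blocks(tmp_path):
    cohort, truth = g.simulate_cohort(small_params(seed=7))
    path = g.write_truth_gmt(truth, tmp_path / "p.gmt", n_null_sets=4)
    sets = g.read_gmt(path)
    names = set(sets.sets)
    assert {"AgePath1", "AgePath2", "AgePath3"} <= names
    assert sum(n.startswith("NullSet") for n in names) == 4
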