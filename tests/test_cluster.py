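"""Subclustering recovery and the composition statistics (proportions,
PCA of proportions, Welch/Holm contrast tests)."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import gliarev as g
from conftest import prepared, small_params


def _null_traj():
    return {"delta_aged": 0.0, "gradient_log2_span": 0.0, "arm_log2_boost": 0.0}


def test_planted_programs_recovered():
    p = small_params(seed=1, n_subclusters=3, n_cells_per_sample=150)
    cohort, truth, _ = prepared(p)
    g.subcluster(cohort, "microglia", seed=1)
    idx = cohort.cells_of_type("microglia")
    labels = cohort.cell_table["cluster"].iloc[idx]
    planted = truth.cells.set_index("barcode").loc[
        cohort.cell_table["barcode"].iloc[idx], "subcluster"
    ]
    assert adjusted_rand_score(planted, labels) >= 0.9
    assert labels.str.startswith("Micro").all()


def test_single_program_stays_one_cluster():
    p = small_params(
        seed=2, n_affected_genes=0, n_pathways=1,
        dam={"dam_fraction_aged": 0.0}, trajectory=_null_traj(),
    )
    cohort, _, _ = prepared(p)
    g.subcluster(cohort, "microglia", seed=2)
    idx = cohort.cells_of_type("microglia")
    labels = cohort.cell_table["cluster"].iloc[idx]
    assert labels.value_counts(normalize=True).iloc[0] >= 0.95


def test_subcluster_deterministic(small_run):
    cohort, _, _ = small_run
    a = cohort.copy()
    b = cohort.copy()
    g.subcluster(a, "astrocyte", seed=9)
    g.subcluster(b, "astrocyte", seed=9)
    ia = a.cells_of_type("astrocyte")
    assert list(a.cell_table["cluster"].iloc[ia]) == list(b.cell_table["cluster"].iloc[ia])


def test_composition_table_arithmetic():
    from conftest import manual_cohort

    cohort = manual_cohort(np.ones((2, 6), dtype=int),
                           samples=["youngGFP_1"] * 6)
    cohort.cell_table["cluster"] = ["A", "A", "B", "B", "B", "C"]
    design = g.CohortDesign.from_cell_table(cohort.cell_table)
    tab = g.composition_table(cohort, "microglia", design=design)
    assert tab.loc["youngGFP_1", ["A", "B", "C"]].tolist() == pytest.approx([1 / 3, 1 / 2, 1 / 6])
    assert tab[["A", "B", "C"]].sum(axis=1).iloc[0] == pytest.approx(1.0)


def test_planted_composition_shift_recovered():
    """Aged-enriched subcluster (30% vs 10%) shows up in proportions and tests."""
    p = small_params(
        seed=3, n_subclusters=3, n_cells_per_sample=200,
        subcluster_props_young=[0.45, 0.45, 0.10],
        subcluster_props_aged=[0.35, 0.35, 0.30],
    )
    cohort, truth, design = prepared(p)
    # use planted labels: composition machinery is under test, not Leiden
    planted = truth.cells.set_index("barcode")["subcluster"]
    cohort.cell_table["cluster"] = (
        "P" + planted.loc[cohort.cell_table["barcode"]].astype(str).to_numpy()
    )
    tab = g.composition_table(cohort, "microglia", design=design)
    aged = tab[tab["age"] == "aged"]["P2"].mean()
    young = tab[tab["age"] == "young"]["P2"].mean()
    n_per = 200 * 0.4
    sd = np.sqrt(0.3 * 0.7 / n_per / 6) + np.sqrt(0.1 * 0.9 / n_per / 6)
    assert abs((aged - young) - 0.20) <= 3 * (sd + 0.02)
    tests = g.composition_tests(tab, design)
    age_row = tests[(tests["contrast"] == "age") & (tests["cluster"] == "P2")]
    assert age_row["padj"].iloc[0] < 0.05


def test_composition_pca_basics():
    idxs = [f"youngGFP_{i}" for i in (1, 2)] + [f"agedGFP_{i}" for i in (1, 2)]
    tab = pd.DataFrame(
        {"A": [0.2, 0.2, 0.8, 0.8], "B": [0.8, 0.8, 0.2, 0.2]}, index=idxs
    )
    tab["age"] = ["young", "young", "aged", "aged"]
    tab["treatment"] = "GFP"
    tab["replicate"] = [1, 2, 1, 2]
    scores, evr = g.composition_pca(tab)
    # duplicated samples land on identical scores; rank-1 table -> PC1 = 100%
    assert scores.loc[idxs[0], "PC1"] == pytest.approx(scores.loc[idxs[1], "PC1"])
    assert evr[0] == pytest.approx(1.0)
    with pytest.raises(g.ParameterError):
        g.composition_pca(tab.iloc[:2])


def test_composition_pca_age_separates_not_treatment():
    """Age-driven composition shift: age groups separate on PC1-2, treatments don't."""
    p = small_params(
        seed=4, n_subclusters=3, n_cells_per_sample=200,
        subcluster_props_young=[0.5, 0.4, 0.1],
        subcluster_props_aged=[0.25, 0.35, 0.40],
    )
    cohort, truth, design = prepared(p)
    planted = truth.cells.set_index("barcode")["subcluster"]
    cohort.cell_table["cluster"] = planted.loc[cohort.cell_table["barcode"]].to_numpy()
    tab = g.composition_table(cohort, "microglia", design=design)
    scores, _ = g.composition_pca(tab)
    X = scores[["PC1", "PC2"]].to_numpy()
    sil_age = silhouette_score(X, scores["age"])
    sil_trt = silhouette_score(X, scores["treatment"])
    assert sil_age > sil_trt


def test_composition_tests_degenerate_and_separated():
    idxs = ([f"youngGFP_{i}" for i in (1, 2, 3)] + [f"youngIL2_{i}" for i in (1, 2, 3)]
            + [f"agedGFP_{i}" for i in (1, 2, 3)] + [f"agedIL2_{i}" for i in (1, 2, 3)])
    rng = np.random.default_rng(0)
    base = np.array([0.1] * 6 + [0.3] * 6)
    tab = pd.DataFrame({"A": base + rng.normal(0, 1e-3, 12)}, index=idxs)
    tab["B"] = 1 - tab["A"]
    tab["age"] = ["young"] * 6 + ["aged"] * 6
    tab["treatment"] = (["GFP"] * 3 + ["IL2"] * 3) * 2
    tab["replicate"] = [1, 2, 3] * 4
    design = g.CohortDesign(tab[["age", "treatment", "replicate"]])
    res = g.composition_tests(tab, design)
    age = res[res["contrast"] == "age"].set_index("cluster")
    assert age.loc["A", "padj"] < 0.05
    # identical groups: treatment within young on near-constant equal values
    tab2 = tab.copy()
    tab2["A"] = 0.5
    tab2["B"] = 0.5
    res2 = g.composition_tests(tab2, design)
    row = res2[(res2["contrast"] == "treatment|young") & (res2["cluster"] == "A")]
    assert row["t"].iloc[0] == 0.0 and row["pvalue"].iloc[0] == 1.0


def test_holm_adjustment_monotone():
    rng = np.random.default_rng(1)
    idxs = [f"{grp}_{i}" for grp in g.GROUPS for i in (1, 2, 3)]
    props = rng.dirichlet(np.ones(6), 12)
    tab = pd.DataFrame(props, index=idxs, columns=[f"C{j}" for j in range(6)])
    tab["age"] = ["young"] * 6 + ["aged"] * 6
    tab["treatment"] = (["GFP"] * 3 + ["IL2"] * 3) * 2
    tab["replicate"] = [1, 2, 3] * 4
    design = g.CohortDesign(tab[["age", "treatment", "replicate"]])
    res = g.composition_tests(tab, design)
    for fam, sub in res.groupby("contrast"):
        s = sub.sort_values("pvalue")
        assert (s["padj"] >= s["pvalue"] - 1e-12).all()
        assert s["padj"].is_monotonic_increasing


def test_holm_familywise_error_calibrated():
    """Null Dirichlet compositions: FWER of the age family stays near 0.05."""
    rng = np.random.default_rng(2)
    idxs = [f"{grp}_{i}" for grp in g.GROUPS for i in (1, 2, 3)]
    meta = {"age": ["young"] * 6 + ["aged"] * 6,
            "treatment": (["GFP"] * 3 + ["IL2"] * 3) * 2,
            "replicate": [1, 2, 3] * 4}
    n_rep, hits = 400, 0
    for _ in range(n_rep):
        tab = pd.DataFrame(rng.dirichlet(np.ones(6) * 20, 12), index=idxs,
                           columns=[f"C{j}" for j in range(6)])
        for k, v in meta.items():
            tab[k] = v
        design = g.CohortDesign(tab[["age", "treatment", "replicate"]])
        res = g.composition_tests(tab, design)
        fam = res[res["contrast"] == "age"]
        hits += int((fam["padj"] < 0.05).any())
    fwer = hits / n_rep
    assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
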