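"""Principal-tree geometry, the young-control rooting rule, pseudotime
fidelity, and the branch-occupancy deviance statistic."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import gliarev as g
from conftest import prepared, small_params


def _line(n=600, noise=0.2, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, n)
    X = np.column_stack([t * 10, rng.normal(0, noise, n)])
    return t, X


def _y_shape(n=900, noise=0.15, seed=0):
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 3, n)
    u = rng.uniform(0, 1, n)
    X = np.zeros((n, 2))
    X[arm == 0] = np.column_stack([u[arm == 0] * 5, np.zeros((arm == 0).sum())])
    X[arm == 1] = np.column_stack([5 + u[arm == 1] * 5, u[arm == 1] * 5])
    X[arm == 2] = np.column_stack([5 + u[arm == 2] * 5, -u[arm == 2] * 5])
    X += rng.normal(0, noise, X.shape)
    return arm, u, X


def test_line_recovers_path_and_order():
    t, X = _line()
    tree = g.principal_tree(X, seed=0)
    assert tree.n_branches == 1  # a path: 2 leaves, no internal branch points
    g.root_tree_from_mask(tree, t < 0.4)
    rho = spearmanr(tree.cell_pseudotime, t).statistic
    assert rho >= 0.95
    assert tree.cell_pseudotime.min() >= 0


def test_y_shape_branches_recovered():
    arm, _, X = _y_shape()
    tree = g.principal_tree(X, seed=0)
    assert tree.n_branches == 3
    hits = sum(
        collections.Counter(tree.cell_branch[arm == a]).most_common(1)[0][1]
        for a in range(3)
    )
    assert hits / len(arm) >= 0.9


def test_tree_deterministic():
    _, X = _line(seed=4)
    t1 = g.principal_tree(X, seed=7)
    t2 = g.principal_tree(X, seed=7)
    assert t1.edges == t2.edges
    assert np.array_equal(t1.cell_branch, t2.cell_branch)


def test_rooting_rule_constructed_cases():
    arm, u, X = _y_shape(seed=1)
    tree = g.principal_tree(X, seed=1)
    # reference cells exclusively on one arm -> root at that arm's terminus
    target = collections.Counter(tree.cell_branch[arm == 1]).most_common(1)[0][0]
    g.root_tree_from_mask(tree, arm == 1)
    a, b = tree.branch_endpoints(target)
    assert tree.root in (a, b)
    # reference cells at the arm's tip end up with small pseudotime
    tip = (arm == 1) & (u > 0.9)
    assert tree.cell_pseudotime[tip].mean() < np.median(tree.cell_pseudotime)


def test_rooting_tie_breaks_to_lower_branch_id():
    arm, _, X = _y_shape(seed=2)
    tree = g.principal_tree(X, seed=2)
    # force an exact tie by giving every branch equal reference mass
    ref = np.zeros(len(arm), dtype=bool)
    per = min(np.bincount(tree.cell_branch, minlength=3))
    for b in range(tree.n_branches):
        ref[np.flatnonzero(tree.cell_branch == b)[:per]] = True
    g.root_tree_from_mask(tree, ref)
    a, b = tree.branch_endpoints(0)
    assert tree.root in (a, b)


def test_rooting_requires_reference_cells():
    _, X = _line()
    tree = g.principal_tree(X, seed=0)
    with pytest.raises(g.ParameterError):
        g.root_tree_from_mask(tree, np.zeros(X.shape[0], dtype=bool))


def test_simulated_maturation_axis_recovered():
    """Full generator: pseudotime tracks latent t and the S100b-like marker
    rises along it."""
    p = g.SimParams(seed=5)
    cohort, truth, design = prepared(p)
    tree = g.fit_tree(cohort, "oligodendrocyte", seed=5)
    g.root_tree(tree, cohort, design)
    barcodes = cohort.cell_table["barcode"].iloc[tree.cell_index]
    latent = truth.cells.set_index("barcode").loc[barcodes, "latent_t"].to_numpy()
    assert spearmanr(tree.cell_pseudotime, latent).statistic >= 0.8
    marker_row = int(np.flatnonzero(cohort.gene_table["symbol"] == "S100b")[0])
    marker = cohort.layers["lognorm"][marker_row, tree.cell_index]
    # sparse counts attenuate rank correlation; the contract is a clearly
    # positive trend of the maturation marker along pseudotime
    trend = spearmanr(marker, tree.cell_pseudotime)
    assert trend.statistic > 0 and trend.pvalue < 1e-6
    early = marker[tree.cell_pseudotime < np.quantile(tree.cell_pseudotime, 1 / 3)]
    late = marker[tree.cell_pseudotime > np.quantile(tree.cell_pseudotime, 2 / 3)]
    assert late.mean() > early.mean()


def test_deviance_analytic_cases():
    assert g.l1_deviance([0.5, 0.5, 0.0], [0.5, 0.5, 0.0]) == 0.0
    assert g.l1_deviance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)
    assert g.l1_deviance([0.5, 0.5, 0.0], [0.25, 0.25, 0.5]) == pytest.approx(1.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
       st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
       st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
def test_deviance_is_a_metric(a, b, c):
    p, q, r = (np.array(v) / np.sum(v) for v in (a, b, c))
    assert g.l1_deviance(p, q) == pytest.approx(g.l1_deviance(q, p))
    assert g.l1_deviance(p, q) <= 2.0 + 1e-9
    assert g.l1_deviance(p, r) <= g.l1_deviance(p, q) + g.l1_deviance(q, r) + 1e-9


def test_sum_of_deviance_pairing_scheme(small_run):
    cohort, _, design = small_run
    tree = g.fit_tree(cohort, "oligodendrocyte", seed=3)
    dev = g.sum_of_deviance(tree, cohort, design)
    refs = design.samples_in_group("youngGFP")
    # every sample paired with every reference except itself
    for s in design.samples.index:
        expect = len(refs) - (1 if s in refs else 0)
        assert (dev["sample"] == s).sum() == expect
    assert not ((dev["sample"] == dev["reference"])).any()
    assert dev.loc[~dev["skipped"], "D"].between(0, 2).all()


def test_deviance_ordering_partial_reversal():
    """agedIL2 deviance sits between youngGFP baseline and agedGFP."""
    p = small_params(seed=6, n_cells_per_sample=200, reversal_fraction_true=0.5)
    cohort, _, design = prepared(p)
    tree = g.fit_tree(cohort, "oligodendrocyte", seed=6)
    dev = g.deviance_summary(g.sum_of_deviance(tree, cohort, design)).set_index("group")
    assert dev.loc["youngGFP", "mean"] < dev.loc["agedIL2", "mean"] < dev.loc["agedGFP", "mean"]
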