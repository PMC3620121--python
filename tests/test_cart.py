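"""CART recursive partitioning: splits, conservation, node odds ratios."""

import numpy as np
import pandas as pd
import pytest

import stonegene as sg
from stonegene.cart import (CartParams, best_split, cart_grow,
                            cart_node_ors, cart_terminal_summary)

from conftest import make_cohort


def _gini(nc, n):
    p = nc / n
    return 2 * p * (1 - p)


def test_pure_node_is_terminal():
    g = np.array([[0], [1], [2], [0]], dtype=np.int8)
    cohort = make_cohort(g, [1, 1, 1, 1] and [1, 1, 1, 1])
    tree = cart_grow(cohort, params=CartParams(min_parent=2, min_child=1))
    assert tree.root.is_terminal
    assert tree.root.case_rate == 1.0


def test_perfect_dominant_split_gini_oracle():
    """40-individual fixture where the dominant split of one SNP separates
    status perfectly; the gain equals the hand-computed impurity decrease."""
    g = np.array([[0]] * 20 + [[1]] * 10 + [[2]] * 10, dtype=np.int8)
    status = [0] * 20 + [1] * 20
    cohort = make_cohort(g, status)
    params = CartParams(min_parent=5, min_child=2)
    tree = cart_grow(cohort, params=params)
    assert tree.root.split_snp == "s1"
    assert set(tree.root.left_levels) in ({0}, {1, 2})
    # parent gini 0.5, children pure -> gain = 0.5
    assert tree.root.gini_gain == pytest.approx(0.5)
    assert len(tree.terminal_nodes) == 2


def test_root_split_matches_brute_force_oracle():
    """On small fixtures the chosen root split maximises Gini decrease over
    every (SNP, level-partition) pair."""
    rng = np.random.default_rng(8)
    for rep in range(5):
        g = rng.integers(0, 3, size=(60, 3)).astype(np.int8)
        status = rng.integers(0, 2, size=60)
        cohort = make_cohort(g, status)
        n = len(status)
        n_case = status.sum()
        parent = _gini(n_case, n)
        best_gain = -1.0
        for j in range(3):
            for left in ([0], [1], [2]):
                lm = np.isin(g[:, j], left)
                nl, nr = lm.sum(), n - lm.sum()
                if min(nl, nr) < 2:
                    continue
                gain = parent - (
                    nl * _gini(status[lm].sum(), nl)
                    + nr * _gini(status[~lm].sum(), nr)) / n
                best_gain = max(best_gain, gain)
        found = best_split(g, np.asarray(status), [0, 1, 2], min_child=2)
        if found is None:
            assert best_gain <= 0 or best_gain < 1e-12
        else:
            assert found[0] == pytest.approx(best_gain, abs=1e-12)


def test_gini_gain_nonnegative_everywhere(synthetic_study_cohort):
    tree = cart_grow(synthetic_study_cohort)
    for node in tree.nodes:
        if node.split_snp is not None:
            assert node.gini_gain >= 0


def test_duplicated_uninformative_predictor_invariance():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(200, 2)).astype(np.int8)
    status = (g[:, 0] > 0).astype(int) ^ (rng.random(200) < 0.1).astype(int)
    base = make_cohort(g, status)
    dup = make_cohort(np.column_stack([g, np.ones(200, dtype=np.int8)]), status)
    t1 = cart_grow(base)
    t2 = cart_grow(dup)
    assert t1.root.split_snp == t2.root.split_snp
    assert len(t1.terminal_nodes) == len(t2.terminal_nodes)


def test_terminal_case_rates_conserve_root_rate(synthetic_study_cohort):
    tree = cart_grow(synthetic_study_cohort)
    ts = cart_terminal_summary(tree)
    weighted = (ts.case_rate_pct / 100 * ts.n).sum() / ts.n.sum()
    assert weighted == pytest.approx(tree.root.case_rate, abs=1e-3)
    assert (ts.case_rate_pct.diff().dropna() >= 0).all()  # ascending order


def test_single_node_tree_case_rate(study_cohort):
    tree = cart_grow(study_cohort, params=CartParams(min_parent=10_000,
                                                     min_child=7))
    assert len(tree.terminal_nodes) == 1
    assert tree.root.case_rate == pytest.approx(230 / 450)


def test_two_node_rates():
    g = np.array([[0]] * 40 + [[2]] * 60, dtype=np.int8)
    status = [1] * 10 + [0] * 30 + [1] * 40 + [0] * 20
    cohort = make_cohort(g, status)
    tree = cart_grow(cohort, params=CartParams(min_parent=5, min_child=2))
    ts = cart_terminal_summary(tree)
    assert sorted(ts.case_rate_pct) == [25.0, pytest.approx(66.7, abs=0.05)]


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        cart_grow(make_cohort(np.zeros((0, 1), dtype=np.int8), []))


# -- node odds ratios -----------------------------------------------------------

def test_reference_node_or_is_one(synthetic_study_cohort):
    tree = cart_grow(synthetic_study_cohort)
    ors = cart_node_ors(synthetic_study_cohort, tree)
    assert ors[0].is_reference and ors[0].odds_ratio == 1.0
    rates = [r.case_rate for r in ors]
    assert rates == sorted(rates)


def test_node_ors_equal_contingency_oracle():
    """Without covariates the node ORs equal the crude cross-products
    against the reference node (3-node fixture)."""
    g = np.concatenate([np.zeros(40), np.ones(40), np.full(40, 2)]
                       ).astype(np.int8)[:, None]
    status = ([1] * 8 + [0] * 32) + ([1] * 20 + [0] * 20) + ([1] * 30 + [0] * 10)
    cohort = make_cohort(g, status)
    tree = cart_grow(cohort, params=CartParams(min_parent=5, min_child=5,
                                               min_gini_gain=1e-9))
    ors = cart_node_ors(cohort, tree)
    assert len(ors) == 3
    ref = ors[0]
    for r in ors[1:]:
        node = next(n for n in tree.terminal_nodes if n.node_id == r.node_id)
        ref_node = next(n for n in tree.terminal_nodes
                        if n.node_id == ref.node_id)
        oracle = (node.n_case * ref_node.n_control) / \
                 (node.n_control * ref_node.n_case)
        assert r.odds_ratio == pytest.approx(oracle, rel=1e-4)


def test_degenerate_node_haldane_flagged():
    g = np.concatenate([np.zeros(30), np.full(30, 2)]).astype(np.int8)[:, None]
    status = [0] * 25 + [1] * 5 + [1] * 30  # right node: zero controls
    cohort = make_cohort(g, status)
    tree = cart_grow(cohort, params=CartParams(min_parent=5, min_child=2))
    ors = cart_node_ors(cohort, tree)
    flagged = [r for r in ors if r.haldane]
    assert len(flagged) == 1 and np.isfinite(flagged[0].odds_ratio)


def test_covariate_adjusted_node_ors_run(synthetic_study_cohort):
    tree = cart_grow(synthetic_study_cohort)
    ors = cart_node_ors(synthetic_study_cohort, tree,
                        covariates=("age", "sex"))
    assert sum(r.is_reference for r in ors) == 1
    finite = [r for r in ors if not r.is_reference and not r.haldane]
    assert all(np.isfinite(r.odds_ratio) for r in finite)


def test_interaction_snps_appear_in_tree():
    """Embedded two-locus interaction: both causal SNPs appear among the
    split variables in most replicates."""
    model = sg.PenetranceModel.xor_two_locus(("a", "b"), high=0.5, low=0.05)
    hits = 0
    for seed in range(10):
        cohort = sg.simulate_epistasis(model, [0.3, 0.3], 400, 400,
                                       seed=seed, noise_snps=8)
        tree = cart_grow(cohort)
        hits += {"a", "b"} <= tree.split_snps()
    assert hits >= 8


def test_summary_report_layout(synthetic_study_cohort):
    res = sg.GenotypeTree(synthetic_study_cohort).fit()
    df = res.summary()
    assert list(df.columns) == ["node_id", "path", "case_rate_pct",
                                "p_value", "or_ci"]
    assert df.iloc[0]["or_ci"] == "Reference"
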