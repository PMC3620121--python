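"""Classification tree over categorical genotype predictors (CART-style).

Binary recursive partitioning with the Gini impurity criterion.  At each
node every binary partition of every SNP's *present* genotype levels is
evaluated (a 3-level genotype yields three partitions: {0}|{1,2},
{1}|{0,2}, {2}|{0,1}), and the split with the largest impurity decrease is
accepted, subject to minimum node sizes, a maximum depth and a minimum
gain.  Ties are broken by manifest order of the SNP, then by the partition
isolating the rarer level set, so growth is fully deterministic.

Terminal nodes are summarised by their case rate (fraction of cases among
the node's individuals); the size-weighted mean of terminal case rates
always equals the root case rate.  Node-level odds ratios come from a
logistic regression of status on terminal-node membership indicators
(reference: the lowest-case-rate node), optionally adjusted for covariates;
a terminal node with zero cases or zero controls falls back to a
Haldane-corrected crude OR and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, MISSING, Cohort
from .single_locus import Z975, crude_or


@dataclass
class CartParams:
    """Stopping rules for tree growth.

    Defaults are sized for a few-hundred-individual candidate-gene cohort
    (they allow on the order of seven terminal nodes at n = 450) and are
    fully configurable.
    """

    min_parent: int = 20     # smallest node that may be split
    min_child: int = 7       # smallest allowed child
    max_depth: int = 5
    min_gini_gain: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.min_parent, self.min_child, self.max_depth) <= 0:
            raise ValueError("tree parameters must be positive")
        if self.min_gini_gain < 0:
            raise ValueError("min_gini_gain must be non-negative")


@dataclass
class CartNode:
    node_id: int
    n_case: int
    n_control: int
    depth: int
    split_snp: str | None = None
    left_levels: tuple[int, ...] = ()
    right_levels: tuple[int, ...] = ()
    children: tuple["CartNode", "CartNode"] | None = None
    gini_gain: float = 0.0
    path: tuple[tuple[str, tuple[int, ...]], ...] = ()  # (snp, levels) from root

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_rate(self) -> float:
        return self.n_case / self.n if self.n else float("nan")

    @property
    def is_terminal(self) -> bool:
        return self.children is None


def _gini(n_case: float, n_control: float) -> float:
    n = n_case + n_control
    if n == 0:
        return 0.0
    p = n_case / n
    return 2.0 * p * (1.0 - p)


def _partitions(levels: Sequence[int]):
    """Non-trivial binary partitions of a set of genotype levels (each
    unordered partition enumerated once, smaller side first)."""
    levels = tuple(sorted(levels))
    if len(levels) < 2:
        return
    if len(levels) == 2:
        yield (levels[:1], levels[1:])
        return
    for lv in levels:  # |levels| == 3: isolate each level in turn
        rest = tuple(x for x in levels if x != lv)
        yield ((lv,), rest)


def best_split(geno: np.ndarray, status: np.ndarray,
               predictors: Sequence[int], min_child: int,
               snp_order: Sequence[int] | None = None):
    """Best Gini split at one node.

    Returns (gain, predictor column, left_levels, right_levels, left_mask)
    or None if no admissible split exists.  Ties are broken by predictor
    order, then by the partition whose smaller side is rarer.
    """
    n_case = float((status == CASE).sum())
    n_ctrl = float((status == CONTROL).sum())
    n = n_case + n_ctrl
    parent_gini = _gini(n_case, n_ctrl)
    best = None
    for j in predictors:
        g = geno[:, j]
        present = sorted(int(v) for v in np.unique(g[g != MISSING]))
        for left, right in _partitions(present):
            lmask = np.isin(g, left)
            rmask = np.isin(g, right)
            nl, nr = int(lmask.sum()), int(rmask.sum())
            if nl < min_child or nr < min_child:
                continue
            lc = float((status[lmask] == CASE).sum())
            rc = float((status[rmask] == CASE).sum())
            child = (nl * _gini(lc, nl - lc) + nr * _gini(rc, nr - rc)) / n
            gain = parent_gini - child
            rarer = min(nl, nr)
            key = (-gain, predictors.index(j) if isinstance(predictors, list) else j,
                   rarer)
            if best is None or key < best[0]:
                best = (key, gain, j, tuple(left), tuple(right), lmask)
    if best is None:
        return None
    _, gain, j, left, right, lmask = best
    return gain, j, left, right, lmask


def cart_grow(cohort: Cohort, predictors: Sequence[str] | None = None,
              params: CartParams | None = None) -> "CartTree":
    """Grow a binary classification tree on genotype predictors."""
    if cohort.n == 0:
        raise ValueError("cannot grow a tree on an empty cohort")
    params = params or CartParams()
    pred_ids = list(predictors) if predictors is not None else cohort.snp_ids
    pred_cols = [cohort.snp_index(s) for s in pred_ids]
    geno = cohort.genotypes
    status = cohort.status
    counter = [0]
    nodes: list[CartNode] = []

    def grow(mask: np.ndarray, depth: int,
             path: tuple) -> CartNode:
        idx = np.flatnonzero(mask)
        st = status[idx]
        node = CartNode(
            node_id=counter[0],
            n_case=int((st == CASE).sum()),
            n_control=int((st == CONTROL).sum()),
            depth=depth,
            path=path,
        )
        counter[0] += 1
        nodes.append(node)
        if (depth >= params.max_depth or node.n < params.min_parent
                or node.n_case == 0 or node.n_control == 0):
            return node
        found = best_split(geno[idx], st, pred_cols, params.min_child)
        if found is None:
            return node
        gain, j, left, right, lmask = found
        if gain < params.min_gini_gain:
            return node
        snp_id = cohort.snps[j].snp_id
        node.split_snp = snp_id
        node.left_levels, node.right_levels = left, right
        node.gini_gain = float(gain)
        lsel = np.zeros_like(mask)
        lsel[idx[lmask]] = True
        rsel = mask & ~lsel
        # individuals with a missing call at the split SNP follow the right
        # (majority-convention) branch only if their genotype matched; here
        # they are excluded from the left mask and retained on the right.
        node.children = (
            grow(lsel, depth + 1, path + ((snp_id, left),)),
            grow(rsel, depth + 1, path + ((snp_id, right),)),
        )
        return node

    root = grow(np.ones(cohort.n, dtype=bool), 0, ())
    return CartTree(root=root, nodes=nodes, cohort=cohort, params=params)


@dataclass
class CartTree:
    root: CartNode
    nodes: list[CartNode]
    cohort: Cohort
    params: CartParams

    @property
    def terminal_nodes(self) -> list[CartNode]:
        return [n for n in self.nodes if n.is_terminal]

    def split_snps(self) -> set[str]:
        return {n.split_snp for n in self.nodes if n.split_snp is not None}

    def assign(self, cohort: Cohort | None = None) -> np.ndarray:
        """Terminal node id per individual."""
        cohort = cohort or self.cohort
        out = np.empty(cohort.n, dtype=np.int64)
        for i in range(cohort.n):
            node = self.root
            while not node.is_terminal:
                g = cohort.genotypes[i, cohort.snp_index(node.split_snp)]
                node = node.children[0] if g in node.left_levels else node.children[1]
            out[i] = node.node_id
        return out


def cart_terminal_summary(tree: CartTree) -> pd.DataFrame:
    """Terminal nodes sorted by ascending case rate, with a genotype-path
    description per node."""
    labels = {s.snp_id: s.label for s in tree.cohort.snps}
    rows = []
    for n in sorted(tree.terminal_nodes, key=lambda x: (x.case_rate, x.node_id)):
        desc = " & ".join(
            f"{labels[s]}∈{{{','.join(map(str, lv))}}}" for s, lv in n.path) or "(root)"
        rows.append({"node_id": n.node_id, "path": desc, "n_case": n.n_case,
                     "n_control": n.n_control, "n": n.n,
                     "case_rate_pct": round(100 * n.case_rate, 1)})
    return pd.DataFrame(rows, columns=["node_id", "path", "n_case", "n_control",
                                       "n", "case_rate_pct"])


@dataclass(frozen=True)
class NodeOrResult:
    node_id: int
    path: str
    case_rate: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    is_reference: bool
    haldane: bool = False


def cart_node_ors(cohort: Cohort, tree: CartTree,
                  covariates: Sequence[str] = ()) -> list[NodeOrResult]:
    """Odds ratio of each terminal node versus the lowest-case-rate node.

    Fitted jointly by logistic regression of status on node-membership
    indicators plus covariates (Wald CIs).  Nodes with zero cases or
    controls get a Haldane-corrected crude OR instead, flagged.
    """
    import statsmodels.api as sm

    terminals = sorted(tree.terminal_nodes, key=lambda x: (x.case_rate, x.node_id))
    if len(terminals) < 2:
        raise ValueError("node odds ratios require at least two terminal nodes")
    ref = terminals[0]
    assign = tree.assign(cohort)
    status = (cohort.status == CASE).astype(float)

    degenerate = {n.node_id for n in terminals
                  if n.n_case == 0 or n.n_control == 0}
    fit_nodes = [n for n in terminals[1:] if n.node_id not in degenerate]
    X = pd.DataFrame({f"node_{n.node_id}": (assign == n.node_id).astype(float)
                      for n in fit_nodes}, index=np.arange(len(assign)))
    for cov in covariates:
        v = cohort.covariates[cov]
        X[cov] = v.map({"female": 1.0, "male": 0.0}).values if cov == "sex" \
            else pd.to_numeric(v, errors="coerce").values
    X = sm.add_constant(X, has_constant="add")
    keep = (~X.isna().any(axis=1).values) & np.isin(assign,
                                                    [ref.node_id] + [n.node_id for n in fit_nodes])
    fit = None
    if fit_nodes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(status[keep], X.loc[keep]).fit(disp=0, maxiter=200)

    labels = {s.snp_id: s.label for s in cohort.snps}

    def path_str(n: CartNode) -> str:
        return " & ".join(
            f"{labels[s]}∈{{{','.join(map(str, lv))}}}" for s, lv in n.path) or "(root)"

    results = [NodeOrResult(
        node_id=ref.node_id, path=path_str(ref), case_rate=ref.case_rate,
        odds_ratio=1.0, ci_low=float("nan"), ci_high=float("nan"),
        p_value=float("nan"), is_reference=True)]
    for n in terminals[1:]:
        if n.node_id in degenerate:
            table = np.array([[ref.n_control, n.n_control],
                              [ref.n_case, n.n_case]], dtype=float)
            orr = crude_or(table) if (table.sum(axis=0) > 0).all() and \
                (table.sum(axis=1) > 0).all() else None
            results.append(NodeOrResult(
                node_id=n.node_id, path=path_str(n), case_rate=n.case_rate,
                odds_ratio=orr.odds_ratio if orr else float("nan"),
                ci_low=orr.ci_low if orr else float("nan"),
                ci_high=orr.ci_high if orr else float("nan"),
                p_value=float("nan"), is_reference=False, haldane=True))
            continue
        b = float(fit.params[f"node_{n.node_id}"])
        se = float(fit.bse[f"node_{n.node_id}"])
        results.append(NodeOrResult(
            node_id=n.node_id, path=path_str(n), case_rate=n.case_rate,
            odds_ratio=float(np.exp(min(b, 700.0))),
            ci_low=float(np.exp(max(b - Z975 * se, -700.0))),
            ci_high=float(np.exp(min(b + Z975 * se, 700.0))),
            p_value=float(fit.pvalues[f"node_{n.node_id}"]),
            is_reference=False))
    return results


# -- model/results facade -------------------------------------------------------

class GenotypeTree:
    """Model facade: CART recursive partitioning of a cohort."""

    def __init__(self, cohort: Cohort, predictors: Sequence[str] | None = None,
                 params: CartParams | None = None,
                 covariates: Sequence[str] = ()):
        cohort.require_both_groups()
        self.cohort = cohort
        self.predictors = list(predictors) if predictors is not None else None
        self.params = params or CartParams()
        self.covariates = tuple(covariates)

    def fit(self) -> "CartResults":
        tree = cart_grow(self.cohort, self.predictors, self.params)
        return CartResults(self, tree)


class CartResults:
    def __init__(self, model: GenotypeTree, tree: CartTree):
        self.model = model
        self.tree = tree

    def terminal_summary(self) -> pd.DataFrame:
        return cart_terminal_summary(self.tree)

    def node_ors(self) -> list[NodeOrResult]:
        return cart_node_ors(self.model.cohort, self.tree,
                             covariates=self.model.covariates)

    def summary(self) -> pd.DataFrame:
        """Terminal-node report: path, case rate, OR (95% CI) vs the
        lowest-case-rate (reference) node, ordered by ascending case rate."""
        rows = []
        for r in self.node_ors():
            rows.append({
                "node_id": r.node_id,
                "path": r.path,
                "case_rate_pct": round(100 * r.case_rate, 1),
                "p_value": "-" if r.is_reference or not np.isfinite(r.p_value)
                           else f"{r.p_value:.3f}",
                "or_ci": "Reference" if r.is_reference else
                         f"{r.odds_ratio:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})",
            })
        return pd.DataFrame(rows, columns=["node_id", "path", "case_rate_pct",
                                           "p_value", "or_ci"])
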