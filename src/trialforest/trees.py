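"""Bayesian regression-tree machinery: the sum-of-trees engine.

This module implements the building blocks shared by the prognostic and the
treatment-moderation surfaces of a Bayesian causal forest: binary regression
trees with numeric and categorical split rules, the regularization prior on
tree depth, Metropolis–Hastings structure moves (grow / prune / change) with
leaf parameters integrated out, conjugate leaf resampling, Bayesian
backfitting over a forest, and the conjugate inverse-gamma draw for the error
variance.

Leaf parameters are either scalars (an ordinary sum-of-trees fit) or
coefficient vectors on a supplied row basis (used for targeted smoothing over
time, where every leaf holds a smooth function rather than a constant).  Each
row may additionally carry a multiplier, which is how the causal-forest layer
implements centred treatment coding: the contribution of a tree to row ``i``
is ``mult[i] * basis[i] @ eta(leaf(i))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats


# --------------------------------------------------------------------------
# priors and hyperparameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DepthPrior:
    """Node-splitting prior p(split at depth d) = base * (1 + d) ** -power."""

    base: float = 0.95
    power: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.base < 1.0):
            raise ValueError("depth prior base must lie in (0, 1)")
        if self.power <= 0:
            raise ValueError("depth prior power must be positive")

    def p_split(self, depth: int) -> float:
        return self.base * (1.0 + depth) ** (-self.power)


@dataclass(frozen=True)
class ProposalProbs:
    grow: float = 0.28
    prune: float = 0.28
    change: float = 0.44

    def __post_init__(self) -> None:
        tot = self.grow + self.prune + self.change
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("proposal probabilities must sum to 1")


@dataclass(frozen=True)
class VariancePrior:
    """Inverse-gamma prior on the error variance, sigma^2 ~ IG(nu/2, nu*lam/2)."""

    nu: float = 3.0
    lam: float = 1.0

    @classmethod
    def from_data(cls, y: np.ndarray, nu: float = 3.0, q: float = 0.90) -> "VariancePrior":
        """Calibrate lam so that P(sigma < sd(y)) = q a priori (BART default)."""
        s2 = float(np.var(np.asarray(y, dtype=float), ddof=1)) if len(y) > 1 else 1.0
        if s2 <= 0:
            s2 = 1.0
        lam = s2 * _stats.chi2.ppf(1.0 - q, nu) / nu
        return cls(nu=nu, lam=lam)


def sample_error_variance(residuals, prior: VariancePrior, rng: np.random.Generator) -> float:
    """One draw of sigma^2 from its conjugate inverse-gamma full conditional.

    Posterior: IG((nu + n) / 2, (nu * lam + sum r^2) / 2).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("sample_error_variance requires at least one residual")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite")
    shape = 0.5 * (prior.nu + r.size)
    scale = 0.5 * (prior.nu * prior.lam + float(r @ r))
    return float(scale / rng.gamma(shape))


# --------------------------------------------------------------------------
# covariates and split rules
# --------------------------------------------------------------------------

_MAX_CATEGORIES = 63  # categorical subsets stored as int64 bitmasks


class CovariateSet:
    """Numeric design matrix with per-variable split-candidate information.

    Numeric columns keep their values; categorical (object / category / bool)
    columns are integer-coded.  Continuous split candidates come from a
    quantile grid of the observed values (deterministic given the data), with
    the convention that a row routes left iff value < threshold.
    """

    def __init__(self, frame: pd.DataFrame, n_cutpoints: int = 100):
        self.columns: list[str] = list(frame.columns)
        n = len(frame)
        p = len(self.columns)
        self.values = np.empty((n, p), dtype=float)
        self.is_categorical = np.zeros(p, dtype=bool)
        self.categories: list[list | None] = []
        self.cutpoints: list[np.ndarray | None] = []
        self.n_rules = np.zeros(p, dtype=np.int64)
        for j, name in enumerate(self.columns):
            col = frame[name]
            if (
                isinstance(col.dtype, pd.CategoricalDtype)
                or col.dtype == object
                or col.dtype == bool
            ):
                codes, cats = pd.factorize(col, sort=True)
                if (codes < 0).any():
                    raise ValueError(f"column {name!r} contains missing values")
                cats = list(cats)
                if len(cats) > _MAX_CATEGORIES:
                    raise ValueError(
                        f"column {name!r} has more than {_MAX_CATEGORIES} categories"
                    )
                self.values[:, j] = codes
                self.is_categorical[j] = True
                self.categories.append(cats)
                self.cutpoints.append(None)
                c = len(cats)
                # subsets counted with their complements; >= 2 categories split
                self.n_rules[j] = (2**c - 2) if c >= 2 else 0
            else:
                v = col.to_numpy(dtype=float)
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"column {name!r} contains missing values")
                self.values[:, j] = v
                self.is_categorical[j] = False
                self.categories.append(None)
                qs = np.linspace(0.0, 1.0, n_cutpoints + 1)[1:-1]
                grid = np.unique(np.quantile(v, qs)) if n > 1 else np.array([])
                grid = grid[grid > v.min()]  # threshold == min would empty the left child
                self.cutpoints.append(grid)
                self.n_rules[j] = len(grid)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def encode_like(self, frame: pd.DataFrame):
        """Encode new rows with this set's columns; returns (matrix, unseen mask)."""
        missing = [c for c in self.columns if c not in frame.columns]
        if missing:
            raise ValueError(f"new data is missing columns: {missing}")
        n = len(frame)
        out = np.empty((n, self.n_vars), dtype=float)
        unseen = np.zeros((n, self.n_vars), dtype=bool)
        for j, name in enumerate(self.columns):
            col = frame[name]
            if self.is_categorical[j]:
                lookup = {c: i for i, c in enumerate(self.categories[j])}
                codes = np.array([lookup.get(v, -1) for v in col], dtype=float)
                unseen[:, j] = codes < 0
                out[:, j] = codes
            else:
                out[:, j] = col.to_numpy(dtype=float)
        return out, unseen


@dataclass(frozen=True)
class SplitRule:
    """Decision rule at an internal node.

    Numeric: route left iff value < threshold.  Categorical: route left iff
    the category code is in ``category_subset`` (stored as an int64 bitmask).
    """

    variable_index: int
    threshold: float = math.nan
    category_mask: int = 0

    @property
    def is_categorical(self) -> bool:
        return self.category_mask != 0

    def goes_left(self, values: np.ndarray) -> np.ndarray:
        if self.is_categorical:
            codes = values.astype(np.int64)
            return (self.category_mask >> codes) & 1 == 1
        return values < self.threshold


class Tree:
    """A binary regression tree stored as parallel node lists.

    Node 0 is the root.  Pruned nodes are left as tombstones (never reused),
    which keeps row→leaf membership ids stable across updates; compact()
    produces a dense array snapshot for storage and out-of-sample prediction.
    """

    def __init__(self, basis_dim: int = 1):
        self.basis_dim = basis_dim
        self.rule: list[SplitRule | None] = [None]
        self.left: list[int] = [-1]
        self.right: list[int] = [-1]
        self.depth: list[int] = [0]
        self.is_leaf: list[bool] = [True]
        self.parent: list[int] = [-1]
        # leaf parameters, one row per node id (only leaf rows meaningful)
        self.eta = np.zeros((1, basis_dim))

    # -- structure queries ---------------------------------------------------

    @property
    def n_ids(self) -> int:
        return len(self.is_leaf)

    def leaf_ids(self) -> list[int]:
        return self._leaves

    @property
    def _leaves(self) -> list[int]:
        return [i for i in self._alive() if self.is_leaf[i]]

    def _alive(self) -> list[int]:
        out = [0]
        stack = [0]
        while stack:
            i = stack.pop()
            if not self.is_leaf[i]:
                for c in (self.left[i], self.right[i]):
                    out.append(c)
                    stack.append(c)
        return out

    def prunable_ids(self) -> list[int]:
        return [
            i
            for i in self._alive()
            if not self.is_leaf[i]
            and self.is_leaf[self.left[i]]
            and self.is_leaf[self.right[i]]
        ]

    def n_leaves(self) -> int:
        return len(self._leaves)

    # -- structure edits -----------------------------------------------------

    def add_children(self, node: int, rule: SplitRule) -> tuple[int, int]:
        lid, rid = self.n_ids, self.n_ids + 1
        d = self.depth[node] + 1
        for _ in range(2):
            self.rule.append(None)
            self.left.append(-1)
            self.right.append(-1)
            self.depth.append(d)
            self.is_leaf.append(True)
            self.parent.append(node)
        self.eta = np.vstack([self.eta, np.zeros((2, self.basis_dim))])
        self.rule[node] = rule
        self.left[node], self.right[node] = lid, rid
        self.is_leaf[node] = False
        return lid, rid

    def prune_at(self, node: int) -> None:
        self.is_leaf[node] = True
        self.rule[node] = None
        self.left[node] = self.right[node] = -1

    # -- evaluation ----------------------------------------------------------

    def assign(self, values: np.ndarray, unseen: np.ndarray | None = None,
               counts: np.ndarray | None = None) -> np.ndarray:
        """Map each row of a coded covariate matrix to its leaf id.

        ``unseen`` marks categorical cells whose level was not observed in
        fitting; such rows follow the larger child (by training row count,
        from ``counts``) at any node splitting on that variable.
        """
        n = values.shape[0]
        mem = np.zeros(n, dtype=np.int64)
        stack = [0]
        while stack:
            node = stack.pop()
            if self.is_leaf[node]:
                continue
            rule = self.rule[node]
            idx = np.flatnonzero(mem == node)
            gl = rule.goes_left(values[idx, rule.variable_index])
            if unseen is not None:
                un = unseen[idx, rule.variable_index]
                if un.any():
                    lid, rid = self.left[node], self.right[node]
                    bigger_left = True
                    if counts is not None and counts[rid] > counts[lid]:
                        bigger_left = False
                    gl = np.where(un, bigger_left, gl)
            mem[idx[gl]] = self.left[node]
            mem[idx[~gl]] = self.right[node]
            stack.extend([self.left[node], self.right[node]])
        return mem


def predict_tree(tree: Tree, row, cov: CovariateSet | None = None) -> float:
    """Evaluate one tree at a single covariate row (scalar leaves only).

    ``row`` is a mapping/Series of variable name → value when ``cov`` is
    given, or an already-coded numeric vector otherwise.
    """
    if tree.basis_dim != 1:
        raise ValueError("predict_tree evaluates scalar-leaf trees; use a basis-aware path")
    if cov is not None:
        vec = np.empty(cov.n_vars)
        for j, name in enumerate(cov.columns):
            try:
                v = row[name]
            except (KeyError, IndexError):
                raise ValueError(f"row is missing variable {name!r}") from None
            if cov.is_categorical[j]:
                cats = cov.categories[j]
                if v not in cats:
                    raise ValueError(f"unseen level {v!r} for variable {name!r}")
                vec[j] = cats.index(v)
            else:
                vec[j] = float(v)
    else:
        vec = np.asarray(row, dtype=float)
    node = 0
    while not tree.is_leaf[node]:
        rule = tree.rule[node]
        if rule.variable_index >= vec.size:
            raise ValueError(f"row is missing variable index {rule.variable_index}")
        goes_left = bool(rule.goes_left(np.array([vec[rule.variable_index]]))[0])
        node = tree.left[node] if goes_left else tree.right[node]
    return float(tree.eta[node, 0])


# --------------------------------------------------------------------------
# collapsed leaf scores (leaf parameters integrated out)
# --------------------------------------------------------------------------


def _leaf_score_scalar(A: float, S: float, sigma2: float, s2: float) -> float:
    """log marginal-likelihood contribution of one scalar leaf, up to terms
    that cancel between competing structures on the same rows.

    A = sum of squared multipliers, S = sum of multiplier * residual.
    """
    if A <= 0.0:
        return 0.0
    denom = sigma2 + A * s2
    return 0.5 * math.log(sigma2 / denom) + 0.5 * s2 * S * S / (sigma2 * denom)


def _leaf_score_vector(Amat: np.ndarray, S: np.ndarray, sigma2: float,
                       Vinv: np.ndarray, logdetV: float) -> float:
    """Vector-leaf analogue of :func:`_leaf_score_scalar` for basis leaves."""
    P = Vinv + Amat / sigma2
    sign, logdetP = np.linalg.slogdet(P)
    m = np.linalg.solve(P, S / sigma2)
    return -0.5 * (logdetP + logdetV) + 0.5 * float((S / sigma2) @ m)


@dataclass
class ForestPrior:
    """Prior and proposal settings shared by all trees of one forest."""

    leaf_scale: float = 1.0
    depth_prior: DepthPrior = field(default_factory=DepthPrior)
    proposals: ProposalProbs = field(default_factory=ProposalProbs)
    min_leaf: int = 5
    # vector-leaf (targeted smoothing) prior covariance; None for scalar leaves
    leaf_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.leaf_scale <= 0:
            raise ValueError("leaf_scale must be positive")
        if self.leaf_cov is not None:
            self.leaf_cov = np.asarray(self.leaf_cov, dtype=float)
            self._Vinv = np.linalg.inv(self.leaf_cov)
            self._logdetV = float(np.linalg.slogdet(self.leaf_cov)[1])
            self._chol = np.linalg.cholesky(self.leaf_cov)

    @property
    def basis_dim(self) -> int:
        return 1 if self.leaf_cov is None else self.leaf_cov.shape[0]


def _sample_rule(cov: CovariateSet, rng: np.random.Generator) -> SplitRule | None:
    """Draw (variable, rule) uniformly over variables and their rule grids."""
    j = int(rng.integers(cov.n_vars))
    if cov.n_rules[j] == 0:
        return None
    if cov.is_categorical[j]:
        c = len(cov.categories[j])
        mask = int(rng.integers(1, 2**c - 1))  # non-trivial proper subset
        return SplitRule(j, category_mask=mask)
    grid = cov.cutpoints[j]
    thr = float(grid[int(rng.integers(len(grid)))])
    return SplitRule(j, threshold=thr)


class TreeState:
    """One tree plus its cached row membership and fit within a sampler."""

    __slots__ = ("tree", "mem", "raw")

    def __init__(self, n_rows: int, basis_dim: int):
        self.tree = Tree(basis_dim)
        self.mem = np.zeros(n_rows, dtype=np.int64)
        self.raw = np.zeros(n_rows)  # basis @ eta at each row (no multiplier)


def _update_tree_structure(
    state: TreeState,
    cov: CovariateSet,
    resid: np.ndarray,
    mult2: np.ndarray,
    mult_resid: np.ndarray,
    sigma2: float,
    prior: ForestPrior,
    rng: np.random.Generator,
    basis: np.ndarray | None,
) -> bool:
    """One Metropolis–Hastings grow / prune / change step. Returns acceptance."""
    tree, mem = state.tree, state.mem
    s2 = prior.leaf_scale**2
    scalar = basis is None

    def score_idx(idx: np.ndarray) -> float:
        if scalar:
            return _leaf_score_scalar(
                float(mult2[idx].sum()), float(mult_resid[idx].sum()), sigma2, s2
            )
        X = basis[idx] * np.sqrt(mult2[idx])[:, None]
        # S uses signed multiplier * residual against the basis
        S = basis[idx].T @ mult_resid[idx]
        return _leaf_score_vector(X.T @ X, S, sigma2, prior._Vinv, prior._logdetV)

    u = rng.random()
    p = prior.proposals
    move = "grow" if u < p.grow else ("prune" if u < p.grow + p.prune else "change")

    if move == "grow":
        leaves = tree.leaf_ids()
        node = leaves[int(rng.integers(len(leaves)))]
        rule = _sample_rule(cov, rng)
        if rule is None:
            return False
        idx = np.flatnonzero(mem == node)
        if idx.size < 2 * prior.min_leaf:
            return False
        gl = rule.goes_left(cov.values[idx, rule.variable_index])
        nl = int(gl.sum())
        if nl < prior.min_leaf or idx.size - nl < prior.min_leaf:
            return False
        li, ri = idx[gl], idx[~gl]
        log_ml = score_idx(li) + score_idx(ri) - score_idx(idx)
        d = tree.depth[node]
        ps_d = prior.depth_prior.p_split(d)
        ps_child = prior.depth_prior.p_split(d + 1)
        log_prior = math.log(ps_d) + 2.0 * math.log1p(-ps_child) - math.log1p(-ps_d)
        # prunable count if this grow is accepted
        parent = tree.parent[node]
        n_prunable_new = len(tree.prunable_ids()) + 1
        if parent >= 0:
            sib = tree.right[parent] if tree.left[parent] == node else tree.left[parent]
            if tree.is_leaf[sib]:
                n_prunable_new -= 1
        log_trans = (
            math.log(p.prune)
            - math.log(n_prunable_new)
            - math.log(p.grow)
            + math.log(len(leaves))
        )
        if math.log(rng.random() + 1e-300) < log_trans + log_prior + log_ml:
            lid, rid = tree.add_children(node, rule)
            mem[li] = lid
            mem[ri] = rid
            return True
        return False

    if move == "prune":
        prunable = tree.prunable_ids()
        if not prunable:
            return False
        node = prunable[int(rng.integers(len(prunable)))]
        lid, rid = tree.left[node], tree.right[node]
        li = np.flatnonzero(mem == lid)
        ri = np.flatnonzero(mem == rid)
        idx = np.concatenate([li, ri])
        log_ml = score_idx(idx) - score_idx(li) - score_idx(ri)
        d = tree.depth[node]
        ps_d = prior.depth_prior.p_split(d)
        ps_child = prior.depth_prior.p_split(d + 1)
        log_prior = -(math.log(ps_d) + 2.0 * math.log1p(-ps_child) - math.log1p(-ps_d))
        n_leaves_new = tree.n_leaves() - 1
        log_trans = (
            math.log(p.grow)
            - math.log(n_leaves_new)
            - math.log(p.prune)
            + math.log(len(prunable))
        )
        if math.log(rng.random() + 1e-300) < log_trans + log_prior + log_ml:
            tree.prune_at(node)
            mem[idx] = node
            return True
        return False

    # change: redraw the rule at an internal node whose children are leaves
    prunable = tree.prunable_ids()
    if not prunable:
        return False
    node = prunable[int(rng.integers(len(prunable)))]
    rule = _sample_rule(cov, rng)
    if rule is None:
        return False
    lid, rid = tree.left[node], tree.right[node]
    li0 = np.flatnonzero(mem == lid)
    ri0 = np.flatnonzero(mem == rid)
    idx = np.concatenate([li0, ri0])
    gl = rule.goes_left(cov.values[idx, rule.variable_index])
    nl = int(gl.sum())
    if nl < prior.min_leaf or idx.size - nl < prior.min_leaf:
        return False
    li1, ri1 = idx[gl], idx[~gl]
    log_ml = score_idx(li1) + score_idx(ri1) - score_idx(li0) - score_idx(ri0)
    if math.log(rng.random() + 1e-300) < log_ml:
        tree.rule[node] = rule
        mem[li1] = lid
        mem[ri1] = rid
        return True
    return False


def _resample_leaves(
    state: TreeState,
    resid: np.ndarray,
    mult: np.ndarray,
    mult2: np.ndarray,
    sigma2: float,
    prior: ForestPrior,
    rng: np.random.Generator,
    basis: np.ndarray | None,
) -> None:
    """Draw leaf parameters from their conjugate normal full conditionals and
    refresh the tree's cached raw fit (basis @ eta per row)."""
    tree, mem = state.tree, state.mem
    n_ids = tree.n_ids
    if basis is None:
        s2 = prior.leaf_scale**2
        A = np.bincount(mem, weights=mult2, minlength=n_ids)
        S = np.bincount(mem, weights=mult * resid, minlength=n_ids)
        leaves = np.array(tree.leaf_ids(), dtype=np.int64)
        post_var = 1.0 / (1.0 / s2 + A[leaves] / sigma2)
        post_mean = post_var * S[leaves] / sigma2
        draws = post_mean + np.sqrt(post_var) * rng.standard_normal(leaves.size)
        tree.eta[leaves, 0] = draws
        state.raw = tree.eta[mem, 0].copy()
    else:
        mr = mult * resid
        for leaf in tree.leaf_ids():
            idx = np.flatnonzero(mem == leaf)
            if idx.size == 0:
                # prior draw for an empty leaf
                z = rng.standard_normal(prior.basis_dim)
                tree.eta[leaf] = prior._chol @ z
                continue
            X = basis[idx] * np.sqrt(mult2[idx])[:, None]
            P = prior._Vinv + (X.T @ X) / sigma2
            S = basis[idx].T @ mr[idx]
            L = np.linalg.cholesky(P)
            m = np.linalg.solve(P, S / sigma2)
            z = rng.standard_normal(prior.basis_dim)
            tree.eta[leaf] = m + np.linalg.solve(L.T, z)
        state.raw = np.einsum("ij,ij->i", basis, tree.eta[mem])


def mh_tree_update(
    tree: Tree,
    cov: CovariateSet,
    partial_residuals,
    sigma: float,
    prior: ForestPrior,
    rng: np.random.Generator,
    resample_leaf_values: bool = True,
) -> Tree:
    """One MH structure step (and optional leaf redraw) on a scalar-leaf tree.

    Mutates and returns ``tree``; an invalid or rejected proposal returns the
    tree unchanged.
    """
    r = np.asarray(partial_residuals, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if r.shape[0] != cov.n_rows:
        raise ValueError("residuals are not aligned with the design rows")
    state = TreeState(cov.n_rows, tree.basis_dim)
    state.tree = tree
    state.mem = tree.assign(cov.values)
    ones = np.ones(cov.n_rows)
    _update_tree_structure(state, cov, r, ones, r, sigma**2, prior, rng, None)
    if resample_leaf_values:
        _resample_leaves(state, r, ones, ones, sigma**2, prior, rng, None)
    return tree


# --------------------------------------------------------------------------
# forests
# --------------------------------------------------------------------------


class Forest:
    """An ordered collection of trees updated by Bayesian backfitting.

    The forest's prediction is exactly the sum of its trees' contributions:
    ``fit(i) = mult[i] * sum_t basis[i] @ eta_t(leaf_t(i))``.
    """

    def __init__(
        self,
        cov: CovariateSet,
        n_trees: int,
        prior: ForestPrior,
        mult: np.ndarray | None = None,
        basis: np.ndarray | None = None,
    ):
        if n_trees < 1:
            raise ValueError("a forest needs at least one tree")
        self.cov = cov
        self.prior = prior
        self.basis = None if basis is None else np.asarray(basis, dtype=float)
        bdim = prior.basis_dim
        if self.basis is not None and self.basis.shape[1] != bdim:
            raise ValueError("basis width does not match the leaf prior")
        n = cov.n_rows
        self.mult = np.ones(n) if mult is None else np.asarray(mult, dtype=float)
        self._mult2 = self.mult**2
        self.states = [TreeState(n, bdim) for _ in range(n_trees)]

    @property
    def n_trees(self) -> int:
        return len(self.states)

    def raw_prediction(self) -> np.ndarray:
        """Sum-of-trees output before the row multiplier (tau or beta scale)."""
        out = np.zeros(self.cov.n_rows)
        for st in self.states:
            out += st.raw
        return out

    def prediction(self) -> np.ndarray:
        return self.mult * self.raw_prediction()

    def backfit_sweep(self, resid: np.ndarray, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
        """One Bayesian-backfitting sweep over all trees.

        ``resid`` is the full residual (y minus every model component
        including this forest); it is updated in place tree by tree and the
        new full residual is returned.
        """
        if not np.all(np.isfinite(resid)):
            raise ValueError("non-finite residuals in backfit sweep")
        sigma2 = sigma**2
        for st in self.states:
            fit_t = self.mult * st.raw
            r = resid + fit_t  # partial residual for this tree
            mr = self.mult * r
            _update_tree_structure(
                st, self.cov, r, self._mult2, mr, sigma2, self.prior, rng, self.basis
            )
            _resample_leaves(
                st, r, self.mult, self._mult2, sigma2, self.prior, rng, self.basis
            )
            resid = r - self.mult * st.raw
        return resid

    # -- storage / out-of-sample evaluation ----------------------------------

    def snapshot(self) -> list[dict]:
        """Compact alive-node arrays for every tree (for draw storage)."""
        out = []
        for st in self.states:
            tree = st.tree
            alive = []
            stack = [0]
            while stack:  # preorder
                i = stack.pop()
                alive.append(i)
                if not tree.is_leaf[i]:
                    stack.append(tree.right[i])
                    stack.append(tree.left[i])
            remap = {old: new for new, old in enumerate(alive)}
            k = len(alive)
            var = np.full(k, -1, dtype=np.int64)
            thr = np.full(k, np.nan)
            cmask = np.zeros(k, dtype=np.int64)
            left = np.full(k, -1, dtype=np.int64)
            right = np.full(k, -1, dtype=np.int64)
            counts = np.bincount(st.mem, minlength=tree.n_ids)
            cnt = np.zeros(k, dtype=np.int64)
            eta = np.empty((k, tree.basis_dim))
            for old in alive:
                new = remap[old]
                eta[new] = tree.eta[old]
                cnt[new] = counts[old] if old < counts.size else 0
                if not tree.is_leaf[old]:
                    rule = tree.rule[old]
                    var[new] = rule.variable_index
                    thr[new] = rule.threshold
                    cmask[new] = rule.category_mask
                    left[new] = remap[tree.left[old]]
                    right[new] = remap[tree.right[old]]
            # internal counts accumulate bottom-up so unseen-level routing can
            # compare child sizes
            for new in range(k - 1, -1, -1):
                if left[new] >= 0:
                    cnt[new] = cnt[left[new]] + cnt[right[new]]
            out.append(
                {"var": var, "thr": thr, "cmask": cmask, "left": left,
                 "right": right, "count": cnt, "eta": eta}
            )
        return out


def snapshot_raw_prediction(
    snapshot: list[dict],
    values: np.ndarray,
    unseen: np.ndarray | None = None,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate a stored forest snapshot at coded covariate rows.

    Returns the raw sum-of-trees output (no row multiplier).  Rows with
    categorical levels unseen in fitting follow the larger child.
    """
    n = values.shape[0]
    out = np.zeros(n)
    for tr in snapshot:
        mem = np.zeros(n, dtype=np.int64)
        stack = [0]
        while stack:
            node = stack.pop()
            if tr["left"][node] < 0:
                continue
            j = int(tr["var"][node])
            idx = np.flatnonzero(mem == node)
            if idx.size == 0:
                continue
            if tr["cmask"][node] != 0:
                codes = values[idx, j]
                ok = codes >= 0
                gl = np.zeros(idx.size, dtype=bool)
                gl[ok] = (tr["cmask"][node] >> codes[ok].astype(np.int64)) & 1 == 1
                un = ~ok
                if unseen is not None:
                    un = un | unseen[idx, j]
                if un.any():
                    bigger_left = tr["count"][tr["left"][node]] >= tr["count"][tr["right"][node]]
                    gl = np.where(un, bigger_left, gl)
            else:
                gl = values[idx, j] < tr["thr"][node]
            mem[idx[gl]] = tr["left"][node]
            mem[idx[~gl]] = tr["right"][node]
            stack.extend([int(tr["left"][node]), int(tr["right"][node])])
        if basis is None:
            out += tr["eta"][mem, 0]
        else:
            out += np.einsum("ij,ij->i", basis, tr["eta"][mem])
    return out
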