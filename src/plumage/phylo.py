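"""Tree-based comparative statistics.

Under a Brownian-motion (BM) model of trait evolution the expected trait
covariance between two species equals the shared root-to-ancestor path
length, giving the phylogenetic covariance matrix C.  Pagel's lambda scales
the off-diagonals of C: lambda = 0 is a star phylogeny (independent
species), lambda = 1 full BM.  On top of C this module implements

* ``phylo_paired_ttest`` — the mean of paired species differences modelled
  as MVN(mu * 1, sigma^2 * C(lambda)), with lambda estimated by ML;
* ``pgls`` — generalized least squares regression with BM or
  Ornstein-Uhlenbeck error covariance;
* ``pca`` / ``phylo_pca`` — standard SVD-based PCA and the
  evolutionary-covariance PCA with ML lambda;
* ``ancestral_states`` — ML (= GLS/BM) continuous ancestral states with
  linear along-branch interpolation.

Trees are dendropy objects; trait vectors are pandas Series keyed by tip
label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import InsufficientDataError, RankError, TreeError

__all__ = [
    "read_tree", "write_tree", "brownian_cov", "phylo_paired_ttest",
    "PairedTTestResult", "pgls", "pca", "phylo_pca", "ancestral_states",
]


def read_tree(path_or_string: str, *, schema: str = "newick") -> dendropy.Tree:
    if "(" in str(path_or_string):
        tree = dendropy.Tree.get(data=str(path_or_string), schema=schema)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema)
    _validate(tree)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def _validate(tree: dendropy.Tree) -> None:
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def brownian_cov(tree: dendropy.Tree, lam: float = 1.0,
                 labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Brownian trait covariance: C_ij = root-to-MRCA path length.

    ``lam`` (Pagel's lambda) multiplies the off-diagonal entries.
    """
    _validate(tree)
    if labels is None:
        labels = tip_labels(tree)
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + \
            (edge if parent is not None else 0.0)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    n = len(labels)
    C = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    for i, a in enumerate(labels):
        C[i, i] = depth[leaves[a]]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[leaves[a]] + depth[leaves[b]] - d)
    off = ~np.eye(n, dtype=bool)
    C[off] *= lam
    return pd.DataFrame(C, index=list(labels), columns=list(labels))


def _align(values, labels) -> np.ndarray:
    s = pd.Series(values)
    missing = [l for l in labels if l not in s.index]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing}")
    return s.loc[list(labels)].to_numpy(dtype=float)


@dataclass
class PairedTTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    ci: tuple
    lam: float
    sigma2: float

    def __repr__(self):
        return (f"PairedTTestResult(t={self.t:.4g}, df={self.df}, p={self.p:.4g}, "
                f"mean={self.mean_difference:.4g}, ci=({self.ci[0]:.4g}, "
                f"{self.ci[1]:.4g}), lambda={self.lam:.3g})")


def _gls_mean(d: np.ndarray, C: np.ndarray):
    Ci = linalg.inv(C)
    one = np.ones(len(d))
    w = one @ Ci @ one
    mu = (one @ Ci @ d) / w
    resid = d - mu
    rss = resid @ Ci @ resid
    return mu, rss, w


def phylo_paired_ttest(x, y, tree: dendropy.Tree,
                       fix_lambda: Optional[float] = None) -> PairedTTestResult:
    """Phylogenetic paired t-test of condition A minus condition B.

    The species differences d = x - y are modelled as multivariate normal
    with mean mu and covariance sigma^2 C(lambda); mu, sigma^2 and lambda
    are estimated by maximum likelihood (lambda profiled on [0, 1] unless
    fixed), and mu = 0 is tested with n - 1 degrees of freedom.
    """
    labels = tip_labels(tree)
    if len(labels) < 3:
        raise InsufficientDataError("need at least 3 species")
    d = _align(x, labels) - _align(y, labels)
    n = len(d)
    C1 = brownian_cov(tree, 1.0, labels).to_numpy()

    def neg_profile_loglik(lam):
        C = C1.copy()
        off = ~np.eye(n, dtype=bool)
        C[off] *= lam
        try:
            mu, rss, _ = _gls_mean(d, C)
        except linalg.LinAlgError:
            return np.inf
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return np.inf
        s2 = max(rss / n, 1e-300)
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    if fix_lambda is not None:
        lam = float(fix_lambda)
    else:
        res = optimize.minimize_scalar(neg_profile_loglik, bounds=(0.0, 1.0),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        lam = float(res.x)
        # the ML lambda may sit at a boundary; keep whichever is best
        for cand in (0.0, 1.0):
            if neg_profile_loglik(cand) < neg_profile_loglik(lam):
                lam = cand
    C = C1.copy()
    C[~np.eye(n, dtype=bool)] *= lam
    mu, rss, w = _gls_mean(d, C)
    dfree = n - 1
    s2 = rss / dfree
    se = np.sqrt(s2 / w)
    t = mu / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), dfree) if se > 0 else 1.0
    tcrit = stats.t.ppf(0.975, dfree)
    return PairedTTestResult(float(t), dfree, float(p), float(mu),
                             (float(mu - tcrit * se), float(mu + tcrit * se)),
                             lam, float(s2))


def _ou_cov(tree: dendropy.Tree, alpha: float, labels) -> np.ndarray:
    """OU stationary covariance on an (approximately) ultrametric tree."""
    Cbm = brownian_cov(tree, 1.0, labels).to_numpy()
    T = np.diag(Cbm).max()
    ts = Cbm  # shared path length to MRCA
    ti = np.diag(Cbm)[:, None]
    tj = np.diag(Cbm)[None, :]
    dij = ti + tj - 2 * ts
    return np.exp(-alpha * dij) * (1 - np.exp(-2 * alpha * ts)) / (2 * alpha)


def pgls(y, X, tree: dendropy.Tree, *, model: str = "BM",
         lam: float = 1.0, add_intercept: bool = True) -> dict:
    """Phylogenetic generalized least squares regression.

    ``X`` is a DataFrame (rows keyed by tip label) or array aligned to the
    tree's tips; with ``model='OU'`` a single attraction strength alpha is
    fitted by ML.  Coefficient tests use a t distribution with n - k df.
    """
    labels = tip_labels(tree)
    yv = _align(y, labels)
    if isinstance(X, pd.DataFrame):
        Xm = X.loc[list(labels)].to_numpy(dtype=float)
        names = list(X.columns)
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[0] != len(labels):
            Xm = Xm.T
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(yv)), Xm])
        names = ["intercept"] + names
    n, k = Xm.shape
    if np.linalg.matrix_rank(Xm) < k:
        raise RankError("design matrix is rank deficient")

    def fit_with(C):
        Ci = linalg.inv(C)
        XtCi = Xm.T @ Ci
        beta = linalg.solve(XtCi @ Xm, XtCi @ yv)
        resid = yv - Xm @ beta
        rss = resid @ Ci @ resid
        return beta, rss, XtCi

    if model == "BM":
        C = brownian_cov(tree, lam, labels).to_numpy()
    elif model == "OU":
        def nll(log_alpha):
            Ca = _ou_cov(tree, np.exp(log_alpha), labels)
            try:
                _, rss, _ = fit_with(Ca)
                sign, logdet = np.linalg.slogdet(Ca)
            except linalg.LinAlgError:
                return np.inf
            if sign <= 0:
                return np.inf
            s2 = max(rss / n, 1e-300)
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        res = optimize.minimize_scalar(nll, bounds=(np.log(1e-3), np.log(50.0)),
                                       method="bounded")
        C = _ou_cov(tree, np.exp(res.x), labels)
    else:
        raise ValueError(f"unknown model {model!r}")
    beta, rss, XtCi = fit_with(C)
    dfree = n - k
    s2 = rss / dfree
    cov_beta = s2 * linalg.inv(XtCi @ Xm)
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfree)
    return {
        "coefficients": pd.Series(beta, index=names),
        "se": pd.Series(se, index=names),
        "t": pd.Series(tvals, index=names),
        "p": pd.Series(pvals, index=names),
        "df": dfree, "sigma2": float(s2), "model": model,
        "residuals": pd.Series(yv - Xm @ beta, index=list(labels)),
    }


def pca(table, *, center: bool = True, scale: bool = True,
        log: bool = False) -> dict:
    """SVD principal component analysis with optional log10 transform.

    Rows with missing values are dropped (listwise deletion, reported in
    the ``dropped`` entry).  Variance fractions sum to 1.
    """
    df = pd.DataFrame(table)
    numeric = df.select_dtypes(include=[np.number])
    keep = numeric.dropna()
    dropped = sorted(set(df.index) - set(keep.index))
    M = keep.to_numpy(dtype=float)
    if log:
        if (M <= 0).any():
            raise RankError("log transform requires positive values")
        M = np.log10(M)
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        zero = np.isclose(sd, 0)
        if zero.any():
            raise RankError(
                f"constant column(s) with scale=True: {list(numeric.columns[zero])}")
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # sign convention: largest-magnitude loading of each component positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    var = S ** 2 / max(len(keep) - 1, 1)
    frac = var / var.sum()
    pcs = [f"PC{i+1}" for i in range(len(S))]
    return {
        "scores": pd.DataFrame(U * S, index=keep.index, columns=pcs),
        "loadings": pd.DataFrame(Vt.T, index=numeric.columns, columns=pcs),
        "variance_fraction": pd.Series(frac, index=pcs),
        "transformed": pd.DataFrame(M, index=keep.index, columns=numeric.columns),
        "dropped": dropped,
    }


def phylo_pca(table, tree: dendropy.Tree, *, method: str = "lambda",
              mode: str = "cov") -> dict:
    """Phylogenetic PCA: eigen-decomposition of the evolutionary covariance.

    The evolutionary rate matrix R is estimated by GLS against C(lambda)
    with lambda fitted by ML over all traits jointly (``method='lambda'``;
    ``method='BM'`` fixes lambda = 1).  Scores are the (phylogenetically)
    mean-centered data projected on R's eigenvectors.
    """
    labels = tip_labels(tree)
    X = pd.DataFrame(table).loc[list(labels)]
    M = X.to_numpy(dtype=float)
    n, p = M.shape
    if n < p + 1:
        import warnings
        warnings.warn(f"only {n} species for {p} traits: rank-deficient "
                      "evolutionary covariance", stacklevel=2)
    C1 = brownian_cov(tree, 1.0, labels).to_numpy()

    def evo_cov(lam):
        C = C1.copy()
        C[~np.eye(n, dtype=bool)] *= lam
        Ci = linalg.inv(C)
        one = np.ones(n)
        a = (one @ Ci @ M) / (one @ Ci @ one)
        D = M - a
        R = D.T @ Ci @ D / (n - 1)
        return C, Ci, a, D, R

    def nll(lam):
        try:
            C, Ci, a, D, R = evo_cov(lam)
        except linalg.LinAlgError:
            return np.inf
        sC, ldC = np.linalg.slogdet(C)
        Rn = R * (n - 1) / n
        sR, ldR = np.linalg.slogdet(Rn + 1e-12 * np.eye(p))
        if sC <= 0 or sR <= 0:
            return np.inf
        return 0.5 * (n * p * np.log(2 * np.pi) + p * ldC + n * ldR + n * p)

    if method == "lambda":
        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        lam = float(res.x)
        for cand in (0.0, 1.0):
            if nll(cand) < nll(lam):
                lam = cand
    elif method == "BM":
        lam = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    C, Ci, a, D, R = evo_cov(lam)
    if mode == "corr":
        dvec = np.sqrt(np.diag(R))
        R = R / np.outer(dvec, dvec)
        D = D / dvec
    elif mode != "cov":
        raise ValueError(f"unknown mode {mode!r}")
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    signs = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(p)])
    evecs = evecs * signs[None, :]
    pcs = [f"PC{i+1}" for i in range(p)]
    return {
        "scores": pd.DataFrame(D @ evecs, index=list(labels), columns=pcs),
        "loadings": pd.DataFrame(evecs, index=X.columns, columns=pcs),
        "eigenvalues": pd.Series(np.maximum(evals, 0), index=pcs),
        "lambda": lam,
        "anc_mean": pd.Series(a, index=X.columns),
    }


def ancestral_states(tree: dendropy.Tree, trait) -> dict:
    """ML (Brownian-motion GLS) ancestral states plus along-branch interpolation.

    Internal-node states minimize the sum of squared changes weighted by
    inverse branch lengths — the maximum-likelihood solution under BM with
    the root state free.  Zero-length branches are collapsed (their nodes
    share a state).  Returns node states keyed by dendropy node (tips keyed
    by label in ``tip_states``) and an ``interpolate(child, fraction)``
    function, linear along each branch.
    """
    _validate(tree)
    labels = tip_labels(tree)
    x = _align(trait, labels)
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    leaf_idx = {leaf.taxon.label: index[id(leaf)] for leaf in tree.leaf_node_iter()}
    n = len(nodes)
    known = np.full(n, np.nan)
    for lab, xi in zip(labels, x):
        known[leaf_idx[lab]] = xi
    free = np.isnan(known)
    tiny = max(tree.length() or 1.0, 1.0) * 1e-9
    W = np.zeros((n, n))
    for nd in nodes:
        parent = nd.parent_node
        if parent is None:
            continue
        v = nd.edge.length if nd.edge.length else tiny  # collapse zero branches
        i, j = index[id(parent)], index[id(nd)]
        w = 1.0 / v
        W[i, j] += w
        W[j, i] += w
    L = np.diag(W.sum(axis=1)) - W
    fidx = np.where(free)[0]
    kidx = np.where(~free)[0]
    A = L[np.ix_(fidx, fidx)]
    b = -L[np.ix_(fidx, kidx)] @ known[kidx]
    states = known.copy()
    states[fidx] = linalg.solve(A, b, assume_a="pos")

    node_states = {nd: float(states[index[id(nd)]]) for nd in nodes}

    def interpolate(child_node, fraction: float) -> float:
        """State a ``fraction`` of the way down the branch above ``child_node``."""
        if isinstance(child_node, str):
            child = next(l for l in tree.leaf_node_iter()
                         if l.taxon.label == child_node)
        else:
            child = child_node
        parent = child.parent_node
        if parent is None:
            return node_states[child]
        a, bb = node_states[parent], node_states[child]
        return float(a + (bb - a) * fraction)

    return {
        "node_states": node_states,
        "tip_states": {lab: float(states[leaf_idx[lab]]) for lab in labels},
        "root_state": float(states[index[id(tree.seed_node)]]),
        "interpolate": interpolate,
    }
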