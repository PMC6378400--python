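"""Tree handling and phylogenetic generalized least squares with Pagel's λ.

The phylogenetic covariance matrix C has C[i, j] equal to the shared branch
length from the root to the most recent common ancestor of tips i and j (the
variance of a Brownian trait shared by both lineages); Pagel's λ multiplies the
off-diagonal entries, interpolating between phylogenetic independence (λ=0)
and pure Brownian motion (λ=1).

PGLS fits a linear model whose error covariance is σ²·C_λ.  λ may be fixed
(the Brownian robustness re-run uses λ=1) or profiled out by maximum
likelihood over [0, 1] with a bounded scalar search.  Estimation is ML
throughout (σ̂² = r'C_λ⁻¹r / n), matching the comparative-methods packages this
module is interchangeable with; per-term F statistics come from GLS-whitened
residual sums of squares of nested fits evaluated at the same λ.

Trees are represented as :class:`dendropy.Tree` objects; Newick round-trips,
pure-birth simulation and traversal are delegated to dendropy.  Non-ultrametric
trees are accepted as-is (genetic-distance branch lengths are fine);
zero-length terminal branches are floored at 1e-8 of tree depth with a warning.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .errors import (
    CovarianceError,
    InvalidArgumentError,
    NewickParseError,
    RankDeficiencyError,
    TreeMismatchError,
)

__all__ = [
    "read_newick",
    "write_newick",
    "tip_labels",
    "node_support",
    "collapse_low_support",
    "phylo_covariance",
    "lambda_transform",
    "PGLSFit",
    "pgls_fit",
    "pgls_ftest",
    "simulate_bm",
    "simulate_tree",
]


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Internal node labels, when numeric, are interpreted as support values
    (bootstrap percentages).  Malformed input raises :class:`NewickParseError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickParseError("duplicate tip labels in Newick input")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to Newick, preserving branch lengths and support labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in tree traversal order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_support(node: dendropy.Node) -> float | None:
    """Support value of an internal node (its numeric label), or None."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Support-based collapsing
# ---------------------------------------------------------------------------

def collapse_low_support(tree: dendropy.Tree, threshold: float = 70.0) -> dendropy.Tree:
    """Collapse internal nodes with bootstrap support below ``threshold`` into polytomies.

    The subtended edge is removed and its length added to each child branch, so
    every root-to-tip distance is preserved exactly.  Nodes without a support
    value are treated as fully supported and kept.  The input tree is not
    modified.
    """
    out = tree.clone(depth=1)
    to_collapse = [
        nd
        for nd in out.postorder_node_iter()
        if nd.parent_node is not None
        and not nd.is_leaf()
        and node_support(nd) is not None
        and node_support(nd) < threshold
    ]
    for nd in to_collapse:
        parent = nd.parent_node
        elen = nd.edge.length or 0.0
        for child in list(nd.child_nodes()):
            child.edge.length = (child.edge.length or 0.0) + elen
            nd.remove_child(child)
            parent.add_child(child)
        parent.remove_child(nd)
    return out


# ---------------------------------------------------------------------------
# Covariance construction and the λ transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloCovariance:
    """Covariance matrix C with its tip ordering and the λ applied to it."""

    matrix: np.ndarray
    labels: tuple
    lam: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _root_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depths[nd] = 0.0
        else:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def phylo_covariance(tree: dendropy.Tree, taxa: list[str] | None = None) -> PhyloCovariance:
    """Brownian covariance matrix of a tree: C[i, j] = root-to-MRCA(i, j) depth.

    ``taxa`` selects and orders the rows; species absent from the tree raise
    :class:`TreeMismatchError` listing every offender.
    """
    labels = tip_labels(tree)
    if taxa is not None:
        missing = set(taxa) - set(labels)
        if missing:
            raise TreeMismatchError(missing)
        labels = list(taxa)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depths = _root_depths(tree)
    below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label
            below[nd] = [idx[lab]] if lab in idx else []
            if lab in idx:
                C[idx[lab], idx[lab]] = depths[nd]
        else:
            groups = [below[ch] for ch in nd.child_nodes()]
            d = depths[nd]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            C[i, j] = C[j, i] = d
            below[nd] = [t for g in groups for t in g]
    # Floor degenerate zero-length terminal branches (diagonal must dominate).
    depth = C.diagonal().max()
    floor = 1e-8 * depth if depth > 0 else 0.0
    for i in range(n):
        off = np.delete(C[i, :], i)
        off_max = off.max() if off.size else 0.0
        if C[i, i] < off_max + floor:
            warnings.warn(
                f"terminal branch of {labels[i]} has (near-)zero length; "
                f"floored at {floor:g}",
                stacklevel=2,
            )
            C[i, i] = off_max + floor
    return PhyloCovariance(matrix=C, labels=tuple(labels), lam=1.0)


def lambda_transform(C: PhyloCovariance | np.ndarray, lam: float) -> PhyloCovariance | np.ndarray:
    """Pagel's λ transform: off-diagonal entries × λ, diagonal untouched."""
    if not 0.0 <= lam <= 1.0:
        raise InvalidArgumentError(f"lambda must lie in [0, 1], got {lam}")
    if isinstance(C, PhyloCovariance):
        M = C.matrix
    else:
        M = np.asarray(C, dtype=float)
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    if isinstance(C, PhyloCovariance):
        return PhyloCovariance(matrix=out, labels=C.labels, lam=lam)
    return out


def _chol(Clam: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(Clam)
    except np.linalg.LinAlgError as exc:
        raise CovarianceError("phylogenetic covariance is not positive definite") from exc


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """One PGLS model fit: coefficients, λ, ML variance and log-likelihood."""

    coef: pd.Series
    se: pd.Series
    lam: float
    sigma2: float
    loglik: float
    n: int
    rss_whitened: float
    lam_mode: str
    labels: tuple
    _y: np.ndarray
    _X: np.ndarray
    _C: np.ndarray
    term_names: tuple

    @property
    def df_resid(self) -> int:
        return self.n - len(self.coef)


def _gls_at_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float):
    """Closed-form ML GLS at fixed λ.  Returns (beta, se, sigma2, loglik, rss_w)."""
    Clam = lambda_transform(C, lam)
    L = _chol(Clam)
    # whiten both sides: solve L a = v
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise RankDeficiencyError("X'V^-1X is singular; drop collinear predictors")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    n = len(y)
    rss = float(r @ r)
    sigma2 = rss / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + n)
    cov_beta = sigma2 * n / max(n - X.shape[1], 1) * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    return beta, se, sigma2, loglik, rss


def _profile_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    """Maximise the PGLS log-likelihood over λ ∈ [0, 1]."""

    def negll(lam: float) -> float:
        try:
            return -_gls_at_lambda(y, X, C, float(lam))[3]
        except CovarianceError:
            return np.inf

    candidates = [0.0, 1.0]
    for lo, hi in ((0.0, 0.5), (0.5, 1.0), (0.0, 1.0)):
        res = optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        candidates.append(float(np.clip(res.x, 0.0, 1.0)))
    return min(candidates, key=negll)


def pgls_fit(
    y,
    X,
    tree: dendropy.Tree | None = None,
    C: PhyloCovariance | None = None,
    mode: str = "ml",
    lam: float | None = None,
    add_intercept: bool = True,
) -> PGLSFit:
    """Fit a PGLS model of species-level response ``y`` on design ``X``.

    Parameters
    ----------
    y, X
        Species-indexed :class:`pandas.Series` / :class:`pandas.DataFrame`
        (or plain arrays when ``C`` carries the ordering).
    tree, C
        Either a tree (covariance built and aligned to ``y``'s index) or a
        ready :class:`PhyloCovariance`.
    mode
        ``"ml"`` profiles λ over [0, 1] by bounded search; ``"fixed"`` uses the
        supplied ``lam``.
    """
    if isinstance(y, pd.Series):
        labels = list(y.index)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        labels = list(C.labels) if C is not None else [f"t{i}" for i in range(len(yv))]

    if isinstance(X, pd.DataFrame):
        X = X.loc[labels]
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    elif isinstance(X, pd.Series):
        names = [X.name or "x"]
        Xv = X.loc[labels].to_numpy(dtype=float)[:, None]
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]

    if add_intercept:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        names = ["intercept"] + names

    if C is None:
        if tree is None:
            raise InvalidArgumentError("provide either a tree or a covariance")
        C = phylo_covariance(tree, taxa=labels)
    elif list(C.labels) != labels:
        order = [list(C.labels).index(lab) for lab in labels]
        C = PhyloCovariance(C.matrix[np.ix_(order, order)], tuple(labels), C.lam)

    n, p = Xv.shape
    if n < p + 1:
        raise InvalidArgumentError(f"need at least {p + 1} species for {p} parameters, have {n}")

    Cm = C.matrix
    if mode == "ml":
        lam_hat = _profile_lambda(yv, Xv, Cm)
        lam_mode = "ml"
    elif mode == "fixed":
        if lam is None:
            raise InvalidArgumentError("mode='fixed' requires lam")
        if not 0.0 <= lam <= 1.0:
            raise InvalidArgumentError("lambda must lie in [0, 1]")
        lam_hat = float(lam)
        lam_mode = "fixed"
    else:
        raise InvalidArgumentError("mode must be 'ml' or 'fixed'")

    beta, se, sigma2, loglik, rss = _gls_at_lambda(yv, Xv, Cm, lam_hat)
    return PGLSFit(
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        lam=lam_hat,
        sigma2=sigma2,
        loglik=loglik,
        n=n,
        rss_whitened=rss,
        lam_mode=lam_mode,
        labels=tuple(labels),
        _y=yv,
        _X=Xv,
        _C=Cm,
        term_names=tuple(names),
    )


def pgls_ftest(full: PGLSFit, drop: list[str] | str) -> tuple[float, int, int, float]:
    """Nested F test for dropping term(s) from a fitted PGLS model.

    The reduced model is refit at the full model's λ̂ so both residual sums of
    squares live under the same whitening.  Returns (F, df1, df2, p).
    """
    if isinstance(drop, str):
        drop = [drop]
    keep = [i for i, nm in enumerate(full.term_names) if nm not in drop]
    if len(keep) == len(full.term_names):
        raise InvalidArgumentError(f"terms {drop} not in model {full.term_names}")
    Xr = full._X[:, keep]
    _, _, _, _, rss_r = _gls_at_lambda(full._y, Xr, full._C, full.lam)
    df1 = len(full.term_names) - len(keep)
    df2 = full.n - len(full.term_names)
    if df2 <= 0:
        raise InvalidArgumentError("no residual degrees of freedom")
    F = ((rss_r - full.rss_whitened) / df1) / (full.rss_whitened / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_bm(
    tree: dendropy.Tree,
    sigma2: float,
    lam: float = 1.0,
    mu: float = 0.0,
    seed: int | np.random.Generator = 0,
    taxa: list[str] | None = None,
) -> pd.Series:
    """Draw tip values of a λ-transformed Brownian trait: MVN(μ1, σ²·C_λ)."""
    if sigma2 <= 0:
        raise InvalidArgumentError("sigma2 must be > 0")
    C = phylo_covariance(tree, taxa=taxa)
    Clam = lambda_transform(C, lam)
    L = _chol(sigma2 * Clam.matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(len(C.labels))
    return pd.Series(mu + L @ z, index=list(C.labels))


def simulate_tree(n_species: int, seed: int = 0) -> dendropy.Tree:
    """Simulate a rooted pure-birth (Yule) tree rescaled to unit root-to-tip depth.

    Tips are relabelled ``sp01..spNN`` in traversal order; the result is
    ultrametric and deterministic for a given seed.
    """
    if n_species < 2:
        raise InvalidArgumentError("need at least 2 species")
    rng = random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_species)])
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    # The simulator stops at the n-th speciation, leaving the youngest pair
    # with zero-length terminals; extend every tip by the waiting time to the
    # next (uncounted) birth, Exp(n·birth_rate), which keeps the process exact.
    extra = rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depths = _root_depths(tree)
    depth = max(depths[lf] for lf in tree.leaf_node_iter())
    if depth <= 0:
        raise CovarianceError("degenerate simulated tree (zero depth)")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    ns = dendropy.TaxonNamespace()
    width = max(2, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"sp{i:0{width}d}")
    tree.taxon_namespace = ns
    return tree
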