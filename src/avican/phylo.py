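"""Weighted phylogenetic generalized least squares with Pagel's lambda.

Species trait values are not independent observations: under a Brownian-motion
model of evolution their covariance is proportional to shared branch length.
PGLS fits a linear model whose error covariance is

    V(λ) = D · C_λ · D,       C_λ = λ·C off-diagonal, diag(C) on-diagonal,

where C[i,j] is the root-to-MRCA branch length shared by tips i and j,
λ ∈ [0, 1] is Pagel's branch-length multiplier (0 = star phylogeny,
1 = pure Brownian motion), and D = diag(w_i) carries per-species weights
(here w_i = n_i^{-1/2}, the binomial sampling scale of a prevalence estimated
from n_i necropsies). λ is estimated by maximizing the profile Gaussian
log-likelihood over [1e-6, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats


class PhyloError(ValueError):
    pass


@dataclass
class PhyloCovariance:
    """Species-by-species shared branch-length matrix, in fixed species order."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.matrix, dtype=float)
        if C.shape != (len(self.species), len(self.species)):
            raise PhyloError("matrix shape does not match species list")
        if not np.allclose(C, C.T):
            raise PhyloError("covariance matrix must be symmetric")
        if np.any(np.diag(C)[:, None] < C - 1e-12):
            raise PhyloError("diagonal must dominate each row")
        self.matrix = C

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(idx, idx)])

    def scaled(self, lam: float) -> np.ndarray:
        return lambda_scale(self, lam).matrix


def normalize_name(name: str) -> str:
    """Join key for species names: case-folded, underscores as spaces."""
    return " ".join(name.replace("_", " ").split()).casefold()


def read_tree(source, schema: str = "newick") -> dendropy.Tree:
    if isinstance(source, dendropy.Tree):
        return source
    if isinstance(source, str) and ("(" in source and ";" in source):
        return dendropy.Tree.get(data=source, schema=schema)
    return dendropy.Tree.get(path=str(source), schema=schema)


def vcv_from_tree(
    tree,
    tips: list[str] | None = None,
    branch_length_rule: str = "one",
    normalize: bool = True,
) -> PhyloCovariance:
    """Phylogenetic variance–covariance matrix from a rooted tree.

    C[i,j] is the summed branch length from the root to the most recent
    common ancestor of tips i and j; C[i,i] is the root-to-tip depth. The
    tree is pruned to *tips* (matched after underscore/case normalization)
    when given; a missing tip is an error.

    Trees without branch lengths (e.g. NCBI common-tree topologies) get
    lengths assigned by *branch_length_rule*: ``"one"`` sets every edge to 1,
    ``"grafen"`` sets node heights to the number of descendant tips minus one.
    With *normalize*, an ultrametric result is rescaled to unit depth.
    """
    tree = read_tree(source=tree)
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    label_of = {lf: (lf.taxon.label if lf.taxon else lf.label) for lf in leaves}

    if tips is not None:
        by_norm = {}
        for lf, lab in label_of.items():
            by_norm.setdefault(normalize_name(lab), lf)
        missing = [t for t in tips if normalize_name(t) not in by_norm]
        if missing:
            raise PhyloError(f"tips absent from tree: {missing}")
        keep = [by_norm[normalize_name(t)].taxon for t in tips]
        tree.retain_taxa(keep)
        leaves = list(tree.leaf_node_iter())
        label_of = {lf: (lf.taxon.label if lf.taxon else lf.label) for lf in leaves}
        order = {normalize_name(t): i for i, t in enumerate(tips)}
        leaves.sort(key=lambda lf: order[normalize_name(label_of[lf])])
        names = list(tips)
    else:
        names = [label_of[lf] for lf in leaves]

    has_lengths = all(e.length is not None for e in tree.preorder_edge_iter()
                      if e.head_node is not tree.seed_node)
    if not has_lengths:
        if branch_length_rule == "one":
            for e in tree.preorder_edge_iter():
                e.length = 1.0
        elif branch_length_rule == "grafen":
            n_desc = {}
            for nd in tree.postorder_node_iter():
                n_desc[nd] = 1 if nd.is_leaf() else sum(
                    n_desc[c] for c in nd.child_nodes())
            for nd in tree.preorder_node_iter():
                if nd.parent_node is not None:
                    nd.edge.length = float(
                        (n_desc[nd.parent_node] - 1) - (n_desc[nd] - 1))
        else:
            raise PhyloError(f"unknown branch_length_rule {branch_length_rule!r}")

    # node depths from the root
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)

    pos = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for lf in leaves:
        C[pos[lf], pos[lf]] = depth[lf]
    # C[i,j] = depth of MRCA: for each internal node, tip pairs split across
    # its children coalesce exactly there
    tip_sets = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tip_sets[nd] = [pos[nd]]
            continue
        children = [tip_sets[c] for c in nd.child_nodes()]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    C[i, children[b]] = depth[nd]
                    C[np.array(children[b]), i] = depth[nd]
        tip_sets[nd] = [i for ch in children for i in ch]

    if normalize:
        d = np.diag(C)
        if d.max() > 0 and np.allclose(d, d.max(), rtol=1e-8):
            C = C / d.max()
    return PhyloCovariance(names, C)


def lambda_scale(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: multiply off-diagonal covariances by λ."""
    if not 0.0 <= lam <= 1.0:
        raise PhyloError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    return PhyloCovariance(list(C.species), out)


@dataclass
class PGLSFit:
    """One fitted phylogenetic regression."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_hat: float
    sigma2_hat: float
    r_squared: float            # V-metric (generalized) R^2
    r_squared_ordinary: float   # 1 - RSS/TSS on the raw response scale
    f_statistic: float
    f_p_value: float
    df_num: int
    df_den: int
    log_likelihood: float
    n: int
    term_names: list[str] = field(default_factory=list)

    @property
    def association_signs(self) -> list[str]:
        return ["+" if b >= 0 else "-" for b in self.coefficients[1:]]


def _prepare(y, X, C: PhyloCovariance, weights):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n or C.matrix.shape[0] != n:
        raise PhyloError("dimension mismatch between y, X and C")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != n or np.any(w <= 0):
            raise PhyloError("weights must be positive, one per species")
    return y, X, w, n


def _fit_at_lambda(y, X, C: PhyloCovariance, w, lam):
    n, p = X.shape
    V = lambda_scale(C, lam).matrix * np.outer(w, w)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # nearly coincident tips can make V numerically semidefinite at
        # lambda ~ 1; a ridge at relative machine scale restores PD-ness
        ridge = 1e-10 * float(np.mean(np.diag(V)))
        try:
            L = np.linalg.cholesky(V + ridge * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise PhyloError(f"V(lambda={lam}) is not positive definite") from exc
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise PhyloError("X'V^-1X is singular (collinear design?)")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
    # V-metric total SS about the V-weighted mean
    ones_w = np.linalg.solve(L, np.ones(n))
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    return beta, XtX_inv, rss, tss, logdet_v, L


def profile_loglik(y, X, C: PhyloCovariance, weights, lam: float) -> float:
    """Profile log-likelihood of λ with β and σ² at their ML values."""
    y, X, w, n = _prepare(y, X, C, weights)
    _, _, rss, _, logdet_v, _ = _fit_at_lambda(y, X, C, w, lam)
    sigma2_ml = rss / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_v + n)


def weighted_gls(y, X, C: PhyloCovariance, weights=None, lam: float = 1.0,
                 term_names: list[str] | None = None) -> PGLSFit:
    """GLS fit with error covariance diag(w)·C_λ·diag(w), λ held fixed.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y; σ̂² = residᵀV⁻¹resid/(n−p); t and two-sided p on
    n−p df; F compares the model with the V-weighted intercept-only model on
    (p−1, n−p) df; R² is reported both in the V metric and on the ordinary
    response scale. X must include the intercept column.
    """
    y, X, w, n = _prepare(y, X, C, weights)
    p = X.shape[1]
    if n <= p:
        raise PhyloError(f"need n > p (n={n}, p={p})")
    beta, XtX_inv, rss, tss, logdet_v, _ = _fit_at_lambda(y, X, C, w, lam)
    df_den = n - p
    sigma2 = rss / df_den
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_den)
    df_num = max(p - 1, 1)
    if p > 1 and tss > 0:
        f = ((tss - rss) / (p - 1)) / (rss / df_den)
        f_p = float(stats.f.sf(f, p - 1, df_den))
        r2_v = 1.0 - rss / tss
    else:
        f, f_p, r2_v = np.nan, np.nan, np.nan
    fitted = X @ beta
    tss_ord = float(np.sum((y - y.mean()) ** 2))
    r2_ord = 1.0 - float(np.sum((y - fitted) ** 2)) / tss_ord if tss_ord > 0 else np.nan
    sigma2_ml = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_v + n)
    return PGLSFit(
        coefficients=beta, std_errors=se, t_values=tvals,
        p_values=np.clip(pvals, np.finfo(float).tiny, 1.0),
        lambda_hat=float(lam), sigma2_hat=float(sigma2),
        r_squared=float(r2_v), r_squared_ordinary=float(r2_ord),
        f_statistic=float(f), f_p_value=f_p,
        df_num=df_num, df_den=df_den, log_likelihood=float(ll), n=n,
        term_names=list(term_names or []),
    )


def ml_lambda(y, X, C: PhyloCovariance, weights=None,
              bounds: tuple[float, float] = (1e-6, 1.0), tol: float = 1e-6,
              term_names: list[str] | None = None) -> PGLSFit:
    """PGLS with Pagel's λ estimated by bounded ML on the profile likelihood."""
    y_, X_, w, n = _prepare(y, X, C, weights)

    def neg_ll(lam):
        _, _, rss, _, logdet_v, _ = _fit_at_lambda(y_, X_, C, w, lam)
        return 0.5 * (n * np.log(2 * np.pi * rss / n) + logdet_v + n)

    res = optimize.minimize_scalar(neg_ll, bounds=bounds, method="bounded",
                                   options={"xatol": tol})
    if not np.isfinite(res.fun):
        raise PhyloError("non-finite likelihood during lambda optimization")
    # bounded Brent can stall short of an endpoint; compare explicitly
    candidates = [(res.fun, float(res.x))] + [(neg_ll(b), b) for b in bounds]
    _, lam_hat = min(candidates, key=lambda t: t[0])
    return weighted_gls(y, X, C, weights=weights, lam=lam_hat,
                        term_names=term_names)


def design_matrix(df, covariates: list[str]) -> np.ndarray:
    """Intercept + named covariate columns, in order."""
    cols = [np.ones(len(df))] + [np.asarray(df[c], dtype=float) for c in covariates]
    return np.column_stack(cols)
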