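"""Phylogenetic comparative statistics.

Two methods are implemented from first principles:

* **Felsenstein's independent contrasts** (PICs).  Under Brownian
  evolution the standardized differences at the nodes of the tree are
  independent and identically distributed, so cross-species correlations
  computed on contrasts (through the origin) are free of phylogenetic
  pseudoreplication.

* **Phylogenetic generalized least squares** (PGLS) with either a
  stationary Ornstein-Uhlenbeck correlation, ``corr(i, j) =
  exp(-alpha * d_ij)`` with ``d_ij`` the patristic distance, or Pagel's
  lambda transform of the Brownian covariance (off-diagonals scaled by
  ``lambda``; 0 = star phylogeny / OLS, 1 = Brownian).  The structure
  parameter is estimated by maximising the restricted likelihood over a
  grid followed by golden-section refinement.  Per-term F tests are
  sequential (type I) in the order the terms are written.

lambda is allowed below zero down to the tree-specific bound at which the
transformed covariance loses positive definiteness; negative maximum
likelihood estimates do occur in practice on real comparative data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .design import build_design, check_full_rank, complete_cases
from .errors import DomainError, TreeError, ValidationError
from .tree import Node, PhyloTree

__all__ = [
    "ContrastSet", "GLSFit", "compute_contrasts", "pic_correlation",
    "ou_correlation", "lambda_covariance", "lambda_bounds", "pgls_fit",
]


# --------------------------------------------------------------------------
# independent contrasts
# --------------------------------------------------------------------------

@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node of the resolved tree."""

    contrasts: List[Tuple[str, float]]  # (node id, contrast)

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)

    @property
    def values(self) -> np.ndarray:
        return np.array([c for _, c in self.contrasts])


def compute_contrasts(tree: PhyloTree, trait: Mapping[str, float],
                      allow_zero_length: bool = False) -> ContrastSet:
    """Felsenstein's pruning recursion.

    At an internal node joining (x_i, v_i) and (x_j, v_j) the contrast is
    ``(x_i - x_j) / sqrt(v_i + v_j)``; the node is assigned the
    1/v-weighted mean of its children and its parent branch is lengthened
    by ``v_i * v_j / (v_i + v_j)``.  Polytomies are resolved
    deterministically (children ordered by smallest tip label, folded with
    zero-length branches) before the recursion.
    """
    if hasattr(trait, "to_dict"):  # accept a pandas Series keyed by tip
        trait = trait.to_dict()
    tips = set(tree.tip_labels)
    missing = tips - set(trait)
    if missing:
        raise ValidationError(f"trait missing for tips: {sorted(missing)}")
    bt = tree.resolve_binary()
    floor = 1e-8 * max(bt.total_depth(), 1.0)
    contrasts: List[Tuple[str, float]] = []
    counter = [0]

    def rec(node: Node) -> Tuple[float, float]:
        if node.is_leaf:
            return float(trait[node.label]), node.length
        (x1, v1), (x2, v2) = (rec(c) for c in node.children)
        vsum = v1 + v2
        if vsum <= 0:
            if not allow_zero_length:
                raise TreeError(
                    "zero branch-length variance at a junction; pass "
                    "allow_zero_length=True to substitute a small floor")
            vsum = floor
            v1 = v2 = vsum / 2.0
        counter[0] += 1
        node_id = node.label or f"node{counter[0]}"
        contrasts.append((node_id, (x1 - x2) / math.sqrt(vsum)))
        if v1 == 0.0:
            xa, extra = x1, 0.0
        elif v2 == 0.0:
            xa, extra = x2, 0.0
        else:
            xa = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
            extra = v1 * v2 / vsum
        return xa, node.length + extra

    rec(bt.root)
    return ContrastSet(contrasts=contrasts)


def pic_correlation(tree: PhyloTree, x: Mapping[str, float],
                    y: Mapping[str, float],
                    allow_zero_length: bool = False
                    ) -> Tuple[float, float, float]:
    """Through-origin correlation of independent contrasts.

    Returns ``(r, F, p)`` with F on (1, n_contrasts - 1) degrees of
    freedom.  Contrasts for both traits are taken with the same
    deterministic child ordering, so r keeps its sign (report |r| when
    comparing against unsigned tabulations).
    """
    cx = compute_contrasts(tree, x, allow_zero_length).values
    cy = compute_contrasts(tree, y, allow_zero_length).values
    n = len(cx)
    if n < 3:
        raise ValidationError(f"need >= 3 contrasts, got {n}")
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    sxy = float(cx @ cy)
    if sxx <= 0 or syy <= 0:
        raise ValidationError("a trait has zero contrast variance")
    r = sxy / math.sqrt(sxx * syy)
    df2 = n - 1
    if abs(r) >= 1.0:
        return r, math.inf, 0.0
    F = r * r * df2 / (1.0 - r * r)
    p = float(stats.f.sf(F, 1, df2))
    return r, F, p


# --------------------------------------------------------------------------
# correlation structures
# --------------------------------------------------------------------------

def ou_correlation(tree: PhyloTree, alpha: float,
                   order: Optional[Sequence[str]] = None
                   ) -> Tuple[List[str], np.ndarray]:
    """Stationary Ornstein-Uhlenbeck correlation: exp(-alpha * d_ij)."""
    if alpha <= 0:
        raise DomainError(f"alpha must be positive, got {alpha}")
    labels, D = tree.patristic_matrix(order=order)
    M = np.exp(-alpha * D)
    np.fill_diagonal(M, 1.0)
    return labels, M


def lambda_bounds(tree: PhyloTree) -> Tuple[float, float]:
    """Admissible (open) interval of lambda keeping the covariance PD.

    With C the Brownian covariance and D its diagonal, the transform is
    ``V(lam) = (1 - lam) * D + lam * C``; positive definiteness holds iff
    every eigenvalue mu of D^{-1/2} C D^{-1/2} satisfies
    ``1 + lam * (mu - 1) > 0``.  The lower bound is negative on any tree
    with shared history; the upper bound exceeds 1.
    """
    _, C = tree.shared_path_matrix()
    d = np.diag(C)
    if np.any(d <= 0):
        raise TreeError("zero root-to-tip depth; lambda transform undefined")
    s = 1.0 / np.sqrt(d)
    M = C * np.outer(s, s)
    mu = np.linalg.eigvalsh(M)
    mu_min, mu_max = float(mu[0]), float(mu[-1])
    lo = -1.0 / (mu_max - 1.0) if mu_max > 1.0 else -math.inf
    hi = 1.0 / (1.0 - mu_min) if mu_min < 1.0 else math.inf
    return lo, hi


def lambda_covariance(tree: PhyloTree, lam: float,
                      order: Optional[Sequence[str]] = None
                      ) -> Tuple[List[str], np.ndarray]:
    """Pagel's lambda transform of the Brownian covariance.

    Off-diagonal entries are multiplied by ``lam``; the diagonal is
    unchanged.  ``lam`` outside the tree's positive-definiteness interval
    raises a :class:`DomainError` reporting the admissible interval.
    """
    lo, hi = lambda_bounds(tree)
    if not (lo < lam < hi):
        raise DomainError(
            f"lambda={lam} outside the admissible interval ({lo:.6g}, {hi:.6g})")
    labels, C = tree.shared_path_matrix(order=order)
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return labels, V


# --------------------------------------------------------------------------
# PGLS
# --------------------------------------------------------------------------

@dataclass
class GLSFit:
    """A fitted (phylogenetic) generalized least squares model."""

    coefficients: Dict[str, float]
    term_F: Dict[str, float]       # sequential (type I) F per term
    term_p: Dict[str, float]
    structure: str                 # "ou" | "lambda" | "identity"
    structure_param: Optional[float]
    log_likelihood: float          # restricted (or full) log-likelihood
    sigma2: float
    n: int
    n_params: int
    terms: Tuple[str, ...]
    reml: bool = True


def _gls_rss(ys: np.ndarray, Xs: np.ndarray) -> Tuple[np.ndarray, float]:
    if Xs.shape[1] == 0:
        return np.empty(0), float(ys @ ys)
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    return beta, float(resid @ resid)


def _neg2_restricted_ll(ys, Xs, logdetV, reml: bool) -> Tuple[float, float]:
    """(criterion, sigma2). Criterion is -2 * (restricted) log-likelihood."""
    n, p = Xs.shape
    _, rss = _gls_rss(ys, Xs)
    if reml:
        dof = n - p
        if dof <= 0:
            raise ValidationError("not enough cases for REML")
        sigma2 = rss / dof
        _, logdet_xtx = np.linalg.slogdet(Xs.T @ Xs)
        crit = (dof * math.log(2 * math.pi * sigma2) + logdetV
                + logdet_xtx + dof)
    else:
        sigma2 = rss / n
        crit = n * math.log(2 * math.pi * sigma2) + logdetV + n
    return crit, sigma2


class _LambdaWhitener:
    """Fast whitening across lambda via one eigendecomposition.

    V(lam) = D^{1/2} [(1 - lam) I + lam M] D^{1/2} with
    M = D^{-1/2} C D^{-1/2} = Q diag(mu) Q'.  Rotating the (D^{-1/2}
    scaled) data by Q' turns every V(lam) into a diagonal weight matrix.
    """

    def __init__(self, C: np.ndarray, y: np.ndarray, X: np.ndarray):
        d = np.diag(C)
        s = 1.0 / np.sqrt(d)
        M = C * np.outer(s, s)
        self.mu, Q = np.linalg.eigh(M)
        self.logdet_d = float(np.sum(np.log(d)))
        self.yr = Q.T @ (y * s)
        self.Xr = Q.T @ (X * s[:, None])

    def whiten(self, lam: float) -> Tuple[np.ndarray, np.ndarray, float]:
        w = (1.0 - lam) + lam * self.mu
        if np.any(w <= 0):
            raise DomainError(f"lambda={lam} not positive definite")
        sw = 1.0 / np.sqrt(w)
        logdetV = self.logdet_d + float(np.sum(np.log(w)))
        return self.yr * sw, self.Xr * sw[:, None], logdetV


def _chol_whiten(V: np.ndarray, y: np.ndarray, X: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray, float]:
    L = linalg.cholesky(V, lower=True)
    ys = linalg.solve_triangular(L, y, lower=True)
    Xs = linalg.solve_triangular(L, X, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    return ys, Xs, logdetV


def _golden_refine(fun, grid: np.ndarray, scores: np.ndarray,
                   tol: float) -> float:
    i = int(np.argmin(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi - lo < tol:
        return float(grid[i])
    res = optimize.minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    return float(res.x) if res.fun <= scores[i] else float(grid[i])


def pgls_fit(tree: PhyloTree, response: Mapping[str, float],
             data: pd.DataFrame, terms: Sequence[str],
             structure: str = "lambda",
             estimate_structure: bool = True,
             structure_param: Optional[float] = None,
             reml: bool = True,
             grid_size: int = 64,
             tol: float = 1e-6,
             allow_lambda_above_one: bool = False,
             ocean1_as_continuous: bool = False) -> GLSFit:
    """Fit a PGLS model of a per-species response on a term list.

    Only species with the response, all terms, and a tip in the tree are
    used; the tree is pruned to them.  ``structure`` selects the error
    correlation ("ou", "lambda", or "identity" for ordinary least
    squares); when ``estimate_structure`` the OU rate or lambda is chosen
    by maximising the (restricted) likelihood over a ``grid_size``-point
    grid with golden-section refinement to ``tol``.
    """
    resp = pd.Series(response, dtype=float)
    species = [s for s in complete_cases(data, terms, resp)
               if s in set(tree.tip_labels)]
    species = sorted(species)
    if len(species) < len(terms) + 2:
        raise ValidationError(
            f"only {len(species)} complete-case species in the tree for "
            f"{len(terms)} terms")
    sub = data.loc[species]
    X, names, term_cols = build_design(sub, terms, intercept=True,
                                       ocean1_as_continuous=ocean1_as_continuous)
    y = resp.loc[species].to_numpy()
    ptree = tree.prune(species)

    # --- whitening machinery per structure ---------------------------------
    if structure == "identity":
        def whiten(_=None):
            return y, X, 0.0
        param = None

        def crit_at(_):
            ys, Xs, ld = whiten()
            return _neg2_restricted_ll(ys, Xs, ld, reml)[0]
    elif structure == "lambda":
        _, C = ptree.shared_path_matrix(order=species)
        lw = _LambdaWhitener(C, y, X)
        lo, hi = lambda_bounds(ptree)
        upper = (hi - tol) if allow_lambda_above_one else (1.0 - tol)
        lower = lo + tol if math.isfinite(lo) else -1.0

        def whiten(lam):
            return lw.whiten(lam)

        def crit_at(lam):
            ys, Xs, ld = lw.whiten(lam)
            return _neg2_restricted_ll(ys, Xs, ld, reml)[0]

        if estimate_structure:
            grid = np.linspace(lower, upper, grid_size)
            scores = np.array([crit_at(g) for g in grid])
            param = _golden_refine(crit_at, grid, scores, tol)
        else:
            if structure_param is None:
                raise ValueError("structure_param required when not estimating")
            param = float(structure_param)
    elif structure == "ou":
        _, D = ptree.patristic_matrix(order=species)
        dbar = float(np.mean(D[np.triu_indices_from(D, k=1)]))
        if dbar <= 0:
            raise TreeError("degenerate tree: all patristic distances zero")

        def whiten(alpha):
            M = np.exp(-alpha * D)
            np.fill_diagonal(M, 1.0)
            return _chol_whiten(M, y, X)

        def crit_at(log_alpha):
            ys, Xs, ld = whiten(math.exp(log_alpha))
            return _neg2_restricted_ll(ys, Xs, ld, reml)[0]

        if estimate_structure:
            grid = np.linspace(math.log(1e-3 / dbar), math.log(50.0 / dbar),
                               grid_size)
            scores = np.array([crit_at(g) for g in grid])
            param = math.exp(_golden_refine(crit_at, grid, scores, tol))
        else:
            if structure_param is None or structure_param <= 0:
                raise DomainError("a positive OU alpha is required")
            param = float(structure_param)
    else:
        raise ValueError(f"unknown structure {structure!r}")

    # --- final fit at the chosen structure parameter -----------------------
    if structure == "identity":
        ys, Xs, logdetV = whiten()
    else:
        ys, Xs, logdetV = whiten(param)
    check_full_rank(Xs, names)
    beta, rss_full = _gls_rss(ys, Xs)
    crit, sigma2 = _neg2_restricted_ll(ys, Xs, logdetV, reml)
    n, p = Xs.shape

    # sequential (type I) F tests in formula order, intercept first
    mse = rss_full / (n - p)
    order = ["Intercept"] + list(terms)
    term_F: Dict[str, float] = {}
    term_p: Dict[str, float] = {}
    prev_rss = float(ys @ ys)
    used_cols: List[int] = []
    for term in order:
        used_cols.extend(term_cols[term])
        _, rss_k = _gls_rss(ys, Xs[:, used_cols])
        df_term = len(term_cols[term])
        F = max((prev_rss - rss_k) / df_term / mse, 0.0)
        term_F[term] = F
        term_p[term] = float(stats.f.sf(F, df_term, n - p))
        prev_rss = rss_k

    return GLSFit(
        coefficients=dict(zip(names, map(float, beta))),
        term_F=term_F, term_p=term_p,
        structure=structure, structure_param=param,
        log_likelihood=-0.5 * crit, sigma2=sigma2,
        n=n, n_params=p, terms=tuple(terms), reml=reml)
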