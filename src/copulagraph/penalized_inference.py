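"""Penalized EM: graphical-lasso M-step and the outer EM loop over a
penalty grid.

Each EM iteration alternates an E-step (conditional latent second
moments given the observed mixed data) with an l1-penalized precision
estimation on that moment matrix.  The penalty applies to the
off-diagonal elements only, so zeros of the fitted precision matrix are
exact and encode missing edges in the conditional-independence graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .copula_latent import CutpointSet, e_step, latent_bounds
from .data_io import MixedDataset


@dataclass
class PrecisionEstimate:
    """A fitted sparse precision matrix at one penalty value.

    ``loglik`` is the latent-scale Gaussian log-likelihood
    l = (n/2)(log det O - trace(R_bar O)), up to an additive constant
    that cancels across penalties, evaluated at the unpenalized MLE
    restricted to the fitted support (see :func:`constrained_mle`) so
    that model scores are free of l1 shrinkage bias;
    ``objective_trace`` records the per-iteration penalized objective
    for convergence monitoring.
    """

    omega: np.ndarray
    lam: float
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = False
    r_bar: np.ndarray | None = field(default=None, repr=False)
    objective_trace: list = field(default_factory=list, repr=False)

    @property
    def support(self) -> np.ndarray:
        """Boolean adjacency (off-diagonal nonzero pattern)."""
        s = self.omega != 0.0
        np.fill_diagonal(s, False)
        return s

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.support, 1)))


@dataclass
class PenaltyPath:
    """Estimates over a strictly decreasing penalty grid, with eBIC scores."""

    grid: np.ndarray
    estimates: list[PrecisionEstimate]
    ebic: np.ndarray | None = None
    selected: int | None = None
    n: int = 0
    var_names: list[str] | None = None
    node_groups: dict | None = None

    def __len__(self):
        return len(self.grid)


@dataclass
class FitConfig:
    """All knobs of the fit-and-select pipeline (shared by the bootstrap)."""

    n_lambda: int = 30
    min_ratio: float = 0.05
    gamma: float = 0.5
    estep_method: str = "approx"
    tol: float = 1e-4
    max_iter: int = 100
    penalize_diagonal: bool = False
    seed: int | None = None


def glasso_mstep(S: np.ndarray, lam: float,
                 penalize_diagonal: bool = False) -> np.ndarray:
    """l1-penalized precision estimate: argmax log det(O) - tr(SO) - lam*|O|_1,off.

    ``S`` must be symmetric with unit diagonal (the E-step moment matrix).
    Solved by coordinate descent, so bound penalties give exact zeros.
    By default only off-diagonal entries are penalized; with
    ``penalize_diagonal`` the diagonal penalty is absorbed by shifting the
    diagonal of ``S`` by ``lam`` (exact for a positive-definite solution).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    S = 0.5 * (S + S.T)
    if penalize_diagonal:
        S = S + lam * np.eye(S.shape[0])
    if lam == 0:
        omega = np.linalg.inv(S)
        return 0.5 * (omega + omega.T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # lars mode solves each lasso subproblem exactly (piecewise-linear
        # path), which matters for the closed-form small-p solutions;
        # coordinate descent is the fallback for numerical corners
        try:
            _, omega = graphical_lasso(S, alpha=lam, mode="lars",
                                       max_iter=300, tol=1e-7)
        except (FloatingPointError, np.linalg.LinAlgError):
            _, omega = graphical_lasso(S + 1e-6 * np.eye(S.shape[0]),
                                       alpha=lam, mode="cd",
                                       max_iter=300, tol=1e-7)
    omega = 0.5 * (omega + omega.T)
    # enforce an exactly symmetric support
    off_zero = (omega == 0.0) | (omega.T == 0.0)
    np.fill_diagonal(off_zero, False)
    omega[off_zero] = 0.0
    return omega


def constrained_mle(S: np.ndarray, support: np.ndarray, max_iter: int = 200,
                    tol: float = 1e-8) -> np.ndarray:
    """Unpenalized Gaussian MLE of the precision matrix under a fixed
    zero pattern (covariance selection).

    Solves max log det(O) - tr(SO) subject to O_ij = 0 off the given
    support, by the classic column-wise regression algorithm: the fitted
    covariance W matches S on the diagonal and the support, and the
    precision is exactly zero elsewhere.  Used to score each graph on the
    penalty path free of l1 shrinkage bias.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    support = np.asarray(support, dtype=bool)
    W = S.copy()
    betas = [None] * p
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.r_[0:j, j + 1:p]
            nb = np.flatnonzero(support[idx, j])
            beta = np.zeros(p - 1)
            if nb.size:
                W11 = W[np.ix_(idx, idx)]
                beta[nb] = np.linalg.solve(W11[np.ix_(nb, nb)], S[idx[nb], j])
                W[idx, j] = W11 @ beta
                W[j, idx] = W[idx, j]
            else:
                W[idx, j] = 0.0
                W[j, idx] = 0.0
            betas[j] = beta
        if np.abs(W - W_old).max() < tol:
            break
    omega = np.zeros((p, p))
    for j in range(p):
        idx = np.r_[0:j, j + 1:p]
        beta = betas[j]
        theta_jj = 1.0 / max(S[j, j] - W[idx, j] @ beta, 1e-12)
        omega[j, j] = theta_jj
        omega[idx, j] = -beta * theta_jj
    omega = 0.5 * (omega + omega.T)
    omega[~support & ~np.eye(p, dtype=bool)] = 0.0
    return omega


def _penalized_objective(omega: np.ndarray, R: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    l1_off = np.abs(omega).sum() - np.trace(np.abs(omega))
    return logdet - float(np.sum(R * omega)) - lam * l1_off


def em_fit(data: MixedDataset, cutpoints: CutpointSet, lam: float,
           estep_method: str = "approx", init: np.ndarray | None = None,
           max_iter: int = 100, tol: float = 1e-4,
           seed: int | None = None, *, penalize_diagonal: bool = False,
           bounds=None, estep_kwargs: dict | None = None) -> PrecisionEstimate:
    """Penalized EM at a single penalty value.

    Alternates the E-step and the glasso M-step from ``init`` (identity by
    default, or a warm start along a penalty path) until the relative
    Frobenius change of the precision matrix drops below ``tol`` or
    ``max_iter`` is reached.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    p = data.p
    omega = np.eye(p) if init is None else np.asarray(init, dtype=float)
    if bounds is None:
        bounds = latent_bounds(data, cutpoints)
    kw = dict(estep_kwargs or {})
    rng = np.random.default_rng(seed) if estep_method == "gibbs" else None
    converged = False
    trace = []
    mom = None
    means = None
    it = 0
    support_stable = 0
    prev_support = None
    for it in range(1, max_iter + 1):
        mom = e_step(data, cutpoints, omega, method=estep_method,
                     seed=rng, bounds=bounds, init_means=means, **kw)
        means = mom.means
        new_omega = glasso_mstep(mom.R_bar, lam,
                                 penalize_diagonal=penalize_diagonal)
        trace.append(_penalized_objective(new_omega, mom.R_bar, lam))
        denom = max(np.linalg.norm(omega), 1.0)
        rel = np.linalg.norm(new_omega - omega) / denom
        support = new_omega != 0.0
        support_stable = (support_stable + 1
                          if prev_support is not None
                          and np.array_equal(support, prev_support) else 0)
        prev_support = support
        omega = new_omega
        if rel < tol:
            converged = True
            break
        # the approximate E-step leaves a small limit cycle around the
        # fixed point; once the graph stops changing and the values move
        # by < sqrt(tol) the iteration has effectively converged
        if support_stable >= 5 and rel < np.sqrt(tol):
            converged = True
            break
    if estep_method == "gibbs" and len(trace) > 2:
        drops = np.diff(trace)
        if np.any(drops < -1e-3):
            warnings.warn("penalized objective decreased beyond Monte-Carlo "
                          "noise during EM", stacklevel=2)
    # score the selected support free of l1 shrinkage: refit the
    # unpenalized MLE restricted to the support and evaluate
    # l = (n/2)(log det O - tr(R_bar O)) there
    support = omega != 0.0
    np.fill_diagonal(support, True)
    omega_mle = constrained_mle(mom.R_bar, support)
    sign, logdet = np.linalg.slogdet(omega_mle)
    loglik = 0.5 * data.n * (logdet - float(np.sum(mom.R_bar * omega_mle)))
    return PrecisionEstimate(omega=omega, lam=float(lam), loglik=loglik,
                             n_iter=it, converged=converged,
                             r_bar=mom.R_bar, objective_trace=trace)


def penalty_grid(data: MixedDataset, cutpoints: CutpointSet,
                 n_lambda: int = 30, min_ratio: float = 0.05, *,
                 bounds=None) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to min_ratio*lambda_max.

    lambda_max is the largest absolute off-diagonal entry of the initial
    E-step moment matrix (at Omega = I), the smallest penalty whose
    glasso fit on that matrix has no edges.
    """
    if n_lambda < 2:
        raise ValueError("grid needs at least 2 penalty values")
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must lie in (0, 1)")
    if bounds is None:
        bounds = latent_bounds(data, cutpoints)
    mom = e_step(data, cutpoints, np.eye(data.p), method="approx",
                 bounds=bounds)
    off = np.abs(mom.R_bar - np.diag(np.diag(mom.R_bar)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("degenerate moment matrix: no off-diagonal signal")
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def fit_path(data: MixedDataset, cutpoints: CutpointSet, grid: np.ndarray,
             estep_method: str = "approx", seed: int | None = None, *,
             gamma: float = 0.5, tol: float = 1e-4, max_iter: int = 100,
             penalize_diagonal: bool = False, warm_start: bool = True,
             estep_kwargs: dict | None = None) -> PenaltyPath:
    """Fit the penalized EM at every grid value, largest penalty first,
    warm-starting each fit from the previous solution, and attach per-
    penalty eBIC scores (selection happens in :func:`select_model`)."""
    from .selection_stability import ebic_score

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    if grid.size > 1 and not np.all(np.diff(grid) < 0):
        raise ValueError("penalty grid must be strictly decreasing")
    bounds = latent_bounds(data, cutpoints)
    ss = np.random.SeedSequence(seed) if seed is not None else None
    estimates = []
    init = None
    for k, lam in enumerate(grid):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)) \
            if ss is not None else None
        est = em_fit(data, cutpoints, lam, estep_method=estep_method,
                     init=init, max_iter=max_iter, tol=tol, seed=sub_seed,
                     penalize_diagonal=penalize_diagonal, bounds=bounds,
                     estep_kwargs=estep_kwargs)
        estimates.append(est)
        if warm_start:
            init = est.omega
    # Score every support on a common moment matrix — the converged R_bar
    # of the densest (smallest-penalty) fit, the latent analog of the
    # sample covariance.  Per-penalty moment matrices adapt to their own
    # precision estimate, which would make likelihoods incomparable
    # across the path.
    R_ref = estimates[-1].r_bar
    eye = np.eye(data.p, dtype=bool)
    for est in estimates:
        support = (est.omega != 0.0) | eye
        omega_mle = constrained_mle(R_ref, support)
        _, logdet = np.linalg.slogdet(omega_mle)
        est.loglik = 0.5 * data.n * (logdet - float(np.sum(R_ref * omega_mle)))
    ebic = np.array([ebic_score(e.loglik, e.n_edges, data.n, data.p, gamma)
                     for e in estimates])
    groups = {s.name: s.group for s in data.specs}
    return PenaltyPath(grid=grid, estimates=estimates, ebic=ebic,
                       n=data.n, var_names=data.names, node_groups=groups)
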