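"""Latent-Gaussian representation of the copula model and its E-step.

Each observed variable X_v is tied to a latent standard-normal Z_v by
X_v = F_v^{-1}(Phi(Z_v)) with the marginal F_v treated as a nuisance
parameter.  A discrete level k therefore pins Z_v into an interval
(c_k, c_{k+1}] between cutpoints obtained from empirical cumulative
proportions; a continuous observation pins Z_v to its rank-based
normal score; a missing cell leaves Z_v free on (-inf, +inf).

The E-step approximates E[Z | X] and E[ZZ^T | X] under Z ~ N(0, Omega^{-1})
restricted to the per-subject rectangle, either by a mean-field pass with
a Gaussian covariance correction (``approx``, fast, deterministic) or by
a truncated-normal Gibbs sampler (``gibbs``, the Monte-Carlo reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

from .data_io import MixedDataset, VariableSpec

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# cutpoints


@dataclass
class CutpointSet:
    """Per-discrete-variable thresholds on the latent N(0,1) scale.

    For a K-level variable the interior thresholds c_1 < ... < c_{K-1}
    delimit the latent intervals; c_0 = -inf and c_K = +inf are implicit.
    """

    thresholds: dict[str, np.ndarray] = field(default_factory=dict)

    def interval(self, name: str, level_code: int) -> tuple[float, float]:
        c = self.thresholds[name]
        k = int(level_code)
        lo = -np.inf if k == 0 else c[k - 1]
        hi = np.inf if k == len(c) else c[k]
        return lo, hi


def estimate_cutpoints(column: np.ndarray, n_levels: int) -> np.ndarray:
    """Thresholds c_k = Phi^{-1}(cumulative fraction at or below level k).

    ``column`` holds level codes 0..K-1 (NaN = missing, excluded).  A level
    unobserved at either extreme yields a +/-inf threshold there, which is
    harmless (no observation uses that interval); a fully constant column
    is rejected because every interior threshold would be infinite.
    """
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError("cutpoints need at least one observed value")
    if np.unique(col).size < 2:
        raise ValueError("constant discrete column: cutpoints undefined")
    counts = np.bincount(col.astype(int), minlength=n_levels)
    cumfrac = np.cumsum(counts)[:-1] / col.size
    return ndtri(cumfrac)


def estimate_all_cutpoints(data: MixedDataset) -> CutpointSet:
    cps = CutpointSet()
    for j, spec in enumerate(data.specs):
        if spec.is_discrete:
            cps.thresholds[spec.name] = estimate_cutpoints(
                data.values[:, j], spec.n_levels)
    return cps


def latent_interval(x, variable: VariableSpec, cutpoints: CutpointSet
                    ) -> tuple[float, float]:
    """Latent interval implied by one observed cell (level code or NaN)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return -np.inf, np.inf
    return cutpoints.interval(variable.name, int(x))


def continuous_to_latent(column: np.ndarray) -> np.ndarray:
    """Rank-based normal scores z_i = Phi^{-1}(r_i / (m + 1)).

    Ties receive average ranks; missing entries stay NaN (they are handled
    through an unbounded latent interval in the E-step).  Invariant under
    any strictly monotone transform of the data.
    """
    col = np.asarray(column, dtype=float)
    out = np.full(col.shape, np.nan)
    obs = ~np.isnan(col)
    m = int(obs.sum())
    if np.unique(col[obs]).size < 2:
        raise ValueError("constant continuous column")
    ranks = stats.rankdata(col[obs], method="average")
    out[obs] = ndtri(ranks / (m + 1))
    return out


# ---------------------------------------------------------------------------
# truncated-normal moments


def _std_trunc_moments(alpha: np.ndarray, beta: np.ndarray):
    """First two moments of N(0,1) truncated to (alpha, beta), vectorized.

    Computed on the log scale so that intervals far in a tail stay stable;
    symmetry maps every interval onto one whose midpoint is <= 0 so the
    lower tail is always the dominant one.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        mid = np.where(np.isinf(alpha) & np.isinf(beta), 0.0,
                       np.where(np.isinf(beta), 1.0,
                                np.where(np.isinf(alpha), -1.0,
                                         alpha + beta)))
    flip = mid > 0
    a = np.where(flip, -beta, alpha)
    b = np.where(flip, -alpha, beta)

    log_b = log_ndtr(b)
    log_a = np.where(np.isinf(a), -np.inf, log_ndtr(np.where(np.isinf(a), 0.0, a)))
    # log Z = log(Phi(b) - Phi(a)), stable because Phi(b) dominates
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.exp(np.clip(log_a - log_b, None, 0.0))
        log_z = log_b + np.log1p(-ratio)

    def _logphi(x):
        return -0.5 * x * x - _LOG_SQRT_2PI

    fin_a = np.isfinite(a)
    fin_b = np.isfinite(b)
    with np.errstate(over="ignore", invalid="ignore"):
        pa = np.where(fin_a, np.exp(_logphi(np.where(fin_a, a, 0.0)) - log_z), 0.0)
        pb = np.where(fin_b, np.exp(_logphi(np.where(fin_b, b, 0.0)) - log_z), 0.0)
        m1 = pa - pb
        m2 = 1.0 + np.where(fin_a, a * pa, 0.0) - np.where(fin_b, b * pb, 0.0)

    # Far-tail fallback: the mass concentrates at the endpoint nearer zero.
    bad = ~np.isfinite(log_z) | (log_z < -700) | ~np.isfinite(m1) | ~np.isfinite(m2)
    if np.any(bad):
        near = np.where(fin_b, b, a)
        m1 = np.where(bad, near, m1)
        m2 = np.where(bad, near * near, m2)

    m1 = np.clip(m1, np.where(fin_a, a, -np.inf), np.where(fin_b, b, np.inf))
    m1 = np.where(flip, -m1, m1)
    m2 = np.maximum(m2, m1 * m1 + 1e-12)
    return m1, m2


def truncnorm_moments(a, b, mu=0.0, sigma=1.0):
    """First and second moments of N(mu, sigma^2) restricted to (a, b).

    All arguments broadcast; ``a``/``b`` may be +/-inf.  Raises if any
    interval is empty or any sigma is nonpositive.
    """
    a, b, mu, sigma = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a, b, mu, sigma)))
    if np.any(a >= b):
        raise ValueError("empty truncation interval (requires a < b)")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    with np.errstate(invalid="ignore"):
        alpha = np.where(np.isinf(a), -np.inf, (a - mu) / sigma)
        beta = np.where(np.isinf(b), np.inf, (b - mu) / sigma)
    m1s, m2s = _std_trunc_moments(alpha, beta)
    mean = mu + sigma * m1s
    second = mu * mu + 2.0 * mu * sigma * m1s + sigma * sigma * m2s
    if mean.ndim == 0:
        return float(mean), float(second)
    return mean, second


def _trunc_mean_var(a, b, mu, sigma):
    alpha = np.where(np.isinf(a), -np.inf, (a - mu) / sigma)
    beta = np.where(np.isinf(b), np.inf, (b - mu) / sigma)
    m1s, m2s = _std_trunc_moments(alpha, beta)
    return mu + sigma * m1s, sigma * sigma * np.maximum(m2s - m1s * m1s, 1e-12)


# ---------------------------------------------------------------------------
# E-step


@dataclass
class LatentMoments:
    """Averaged conditional second moments of the latent vector.

    ``R_bar`` is the p x p matrix (1/n) sum_i E[Z_i Z_i^T | X_i], rescaled to
    unit diagonal after a PSD repair; ``means`` holds the per-cell
    conditional means E[Z_iv | X_i].
    """

    R_bar: np.ndarray
    means: np.ndarray
    min_eig_raw: float = np.nan
    n_sweeps: int = 0


def latent_bounds(data: MixedDataset, cutpoints: CutpointSet):
    """Per-cell latent constraints: interval bounds for discrete/missing
    cells, fixed rank-based scores for observed continuous cells."""
    n, p = data.values.shape
    lo = np.full((n, p), -np.inf)
    hi = np.full((n, p), np.inf)
    fixed = np.zeros((n, p), dtype=bool)
    zfix = np.zeros((n, p))
    for j, spec in enumerate(data.specs):
        miss = data.missing_mask[:, j]
        if spec.is_discrete:
            c = cutpoints.thresholds[spec.name]
            edges_lo = np.concatenate(([-np.inf], c))
            edges_hi = np.concatenate((c, [np.inf]))
            codes = np.where(miss, 0, data.values[:, j]).astype(int)
            lo[:, j] = np.where(miss, -np.inf, edges_lo[codes])
            hi[:, j] = np.where(miss, np.inf, edges_hi[codes])
        else:
            z = continuous_to_latent(data.values[:, j])
            fixed[:, j] = ~miss
            zfix[~miss, j] = z[~miss]
    return lo, hi, fixed, zfix


def _check_pd(omega: np.ndarray) -> None:
    omega = np.asarray(omega)
    if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
        raise ValueError("omega must be square")
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("omega must be symmetric")
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("omega must be positive definite") from exc


def _psd_rescale(S: np.ndarray, floor: float = 1e-6):
    """Eigenvalue-floor a symmetric matrix and rescale to unit diagonal."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    min_eig = float(w.min())
    if min_eig < floor:
        S = (V * np.maximum(w, floor)) @ V.T
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T), min_eig


def _meanfield_pass(omega, lo, hi, fixed, M, V, free_cols, max_sweeps, tol):
    d = np.diag(omega)
    sd = 1.0 / np.sqrt(d)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        delta = 0.0
        for v in free_cols:
            rows = ~fixed[:, v]
            if not rows.any():
                continue
            cond = -(M @ omega[:, v] - d[v] * M[:, v]) / d[v]
            mean, var = _trunc_mean_var(lo[rows, v], hi[rows, v],
                                        cond[rows], sd[v])
            delta = max(delta, float(np.max(np.abs(M[rows, v] - mean))))
            M[rows, v] = mean
            V[rows, v] = var
        if delta < tol:
            break
    return sweeps


def _covariance_correction(omega, fixed, V):
    """Per-subject Gaussian approximation to the free-block posterior
    covariance: inv(Omega_FF + diag(s)) with site precisions s matched to
    the truncated conditional variances, then rescaled so the diagonal
    equals the truncated marginal variances exactly."""
    n, p = fixed.shape
    d = np.diag(omega)
    Csum = np.zeros((p, p))
    all_free = not fixed.any()
    if all_free:
        # common pattern: every coordinate free for every subject -> batch
        s = np.maximum(1.0 / np.maximum(V, 1e-10) - d[None, :], 0.0)
        A = np.broadcast_to(omega, (n, p, p)).copy()
        idx = np.arange(p)
        A[:, idx, idx] += s
        C = np.linalg.inv(A)
        diagC = np.maximum(C[:, idx, idx], 1e-12)
        scale = np.sqrt(V / diagC)
        C *= scale[:, :, None] * scale[:, None, :]
        return C.sum(axis=0)
    for i in range(n):
        F = np.flatnonzero(~fixed[i])
        if F.size == 0:
            continue
        vi = np.maximum(V[i, F], 1e-10)
        s = np.maximum(1.0 / vi - d[F], 0.0)
        A = omega[np.ix_(F, F)] + np.diag(s)
        C = np.linalg.inv(A)
        scale = np.sqrt(vi / np.maximum(np.diag(C), 1e-12))
        C = C * np.outer(scale, scale)
        Csum[np.ix_(F, F)] += C
    return Csum


def _estep_approx(omega, lo, hi, fixed, zfix, max_sweeps, tol, init_means=None):
    n, p = fixed.shape
    d = np.diag(omega)
    M = zfix.copy()
    V = np.zeros((n, p))
    free = ~fixed
    # initialize free cells at their unconditional truncated moments
    if free.any():
        m0, v0 = _trunc_mean_var(lo[free], hi[free], 0.0, 1.0)
        M[free] = m0
        V[free] = v0
    if init_means is not None:
        M[free] = init_means[free]
    free_cols = [v for v in range(p) if free[:, v].any()]
    sweeps = _meanfield_pass(omega, lo, hi, fixed, M, V, free_cols,
                             max_sweeps, tol)
    Csum = _covariance_correction(omega, fixed, V)
    R = (M.T @ M + Csum) / n
    R_bar, min_eig = _psd_rescale(R)
    return LatentMoments(R_bar, M, min_eig, sweeps)


def _sample_truncnorm(rng, lo, hi, mu, sd):
    """Vectorized truncated-normal draws by log-scale inverse CDF.

    The interval is reflected so its dominant tail is the lower one, and
    the uniform is mapped through log Phi so draws stay accurate even for
    intervals far in a tail.
    """
    with np.errstate(invalid="ignore"):
        alpha = np.where(np.isinf(lo), -np.inf, (lo - mu) / sd)
        beta = np.where(np.isinf(hi), np.inf, (hi - mu) / sd)
        mid = np.where(np.isinf(alpha) & np.isinf(beta), 0.0,
                       np.where(np.isinf(beta), 1.0,
                                np.where(np.isinf(alpha), -1.0,
                                         alpha + beta)))
    flip = mid > 0
    a = np.where(flip, -beta, alpha)
    b = np.where(flip, -alpha, beta)
    log_b = log_ndtr(b)
    log_a = np.where(np.isinf(a), -np.inf,
                     log_ndtr(np.where(np.isinf(a), 0.0, a)))
    ratio = np.exp(np.clip(log_a - log_b, None, 0.0))
    u = rng.random(np.broadcast(a, b).shape)
    with np.errstate(divide="ignore"):
        z = ndtri_exp(log_b + np.log(u + (1.0 - u) * ratio))
    z = np.clip(z, np.where(np.isfinite(a), a, -38.0), b)
    z = np.where(flip, -z, z)
    return mu + sd * z


def _estep_gibbs(omega, lo, hi, fixed, zfix, rng, burn_in, n_sweeps):
    if n_sweeps < 1:
        raise ValueError("gibbs E-step needs at least one retained sweep")
    n, p = fixed.shape
    d = np.diag(omega)
    sd = 1.0 / np.sqrt(d)
    Z = zfix.copy()
    free = ~fixed
    if free.any():
        m0, _ = _trunc_mean_var(lo[free], hi[free], 0.0, 1.0)
        Z[free] = m0
    free_cols = [v for v in range(p) if free[:, v].any()]
    S = np.zeros((p, p))
    Msum = np.zeros((n, p))
    for t in range(burn_in + n_sweeps):
        for v in free_cols:
            rows = free[:, v]
            cond = -(Z @ omega[:, v] - d[v] * Z[:, v]) / d[v]
            Z[rows, v] = _sample_truncnorm(rng, lo[rows, v], hi[rows, v],
                                           cond[rows], sd[v])
        if t >= burn_in:
            S += Z.T @ Z
            Msum += Z
    R = S / (n * n_sweeps)
    R_bar, min_eig = _psd_rescale(R)
    return LatentMoments(R_bar, Msum / n_sweeps, min_eig, n_sweeps)


def e_step(data: MixedDataset, cutpoints: CutpointSet, omega: np.ndarray,
           method: str = "approx", seed: int | None = None, *,
           max_sweeps: int = 50, tol: float = 1e-4,
           gibbs_burn_in: int = 500, gibbs_sweeps: int = 1000,
           bounds=None, init_means=None) -> LatentMoments:
    """Conditional latent second moments E[ZZ^T | X] averaged over subjects.

    ``method="approx"`` runs the deterministic mean-field fixed point
    (at most ``max_sweeps`` passes, stopping when conditional means move
    < ``tol``) with a Gaussian covariance correction; ``method="gibbs"``
    runs a truncated-normal Gibbs sampler and requires a seed (or an
    ``np.random.Generator``) for reproducibility.
    """
    omega = np.asarray(omega, dtype=float)
    _check_pd(omega)
    if bounds is None:
        bounds = latent_bounds(data, cutpoints)
    lo, hi, fixed, zfix = bounds
    if method == "approx":
        return _estep_approx(omega, lo, hi, fixed, zfix, max_sweeps, tol,
                             init_means)
    if method == "gibbs":
        if seed is None:
            raise ValueError("gibbs E-step requires a seed")
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        return _estep_gibbs(omega, lo, hi, fixed, zfix, rng,
                            gibbs_burn_in, gibbs_sweeps)
    raise ValueError(f"unknown E-step method {method!r}")
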