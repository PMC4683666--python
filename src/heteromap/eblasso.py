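"""Fast empirical Bayesian LASSO by greedy marginal-likelihood basis selection.

The model is ``y = U c + X beta + e`` with a three-level hierarchy on each
penalized coefficient: ``beta_j ~ N(0, sigma2_j)``, ``sigma2_j ~
Exponential(lambda)`` and ``lambda ~ Gamma(a, b)``.  Maximizing the
lambda-penalized marginal likelihood over one ``sigma2_j`` at a time gives a
closed form: with ``s_j = x_j' C_{-j}^{-1} x_j`` and
``q_j = x_j' C_{-j}^{-1} y`` (``C_{-j}`` excludes effect j), effect j is
retained iff ``q_j^2 > s_j + 2*lambda``, in which case

    sigma2_j = (u - 1) / s_j,   u = (-s_j + sqrt(s_j^2 + 8*lambda*q_j^2)) / (4*lambda)

(the ``lambda -> 0`` limit ``sigma2_j = (q_j^2 - s_j)/s_j^2`` is the fast
relevance-vector-machine update).  The inner iteration repeatedly applies
the single add / re-estimate / delete action with the largest likelihood
gain; the outer iteration re-estimates the noise variance ``sigma0^2`` and
the posterior mode of ``lambda``.  Unpenalized covariates are handled by
projecting them out of ``y`` and ``X`` up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .model import EffectDesign, EffectLabel

DEFAULT_HYPER_GRID = tuple(product((0.01, 0.1, 0.5, 1.0), (1.0, 3.0, 10.0, 30.0, 100.0)))
DEFAULT_HYPER = (0.1, 30.0)

_EPS = 1e-12


class EBLassoError(RuntimeError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class EBLassoFit:
    """Retained effects with posterior summaries and hyperparameters."""

    labels: list[EffectLabel]
    indices: np.ndarray              # retained column indices into design.X
    beta: np.ndarray                 # posterior means
    Sigma: np.ndarray                # posterior covariance of retained beta
    sigma2: np.ndarray               # prior variances of retained effects
    sigma0_sq: float
    lam: float
    hyper: tuple | None
    n: int
    df: int
    n_unpenalized: int
    unpenalized_coef: np.ndarray
    converged: bool
    n_outer: int
    ml_trace: list = field(default_factory=list)  # per-outer arrays of the penalized marginal log-lik
    # final leave-one-out statistics for every candidate column (diagnostics)
    s_: np.ndarray | None = None
    q_: np.ndarray | None = None
    candidates_: np.ndarray | None = None

    @property
    def n_retained(self) -> int:
        return len(self.indices)

    def predict(self, X: np.ndarray, U: np.ndarray) -> np.ndarray:
        return U @ self.unpenalized_coef + X[:, self.indices] @ self.beta


def _sigma2_new(s, q, lam):
    """Per-candidate maximizer of the penalized marginal likelihood (0 = exclude)."""
    s = np.maximum(s, _EPS)
    theta = q * q - s - 2.0 * lam
    out = np.zeros_like(s)
    pos = theta > 0
    if lam > 0:
        u = (-s[pos] + np.sqrt(s[pos] ** 2 + 8.0 * lam * q[pos] ** 2)) / (4.0 * lam)
        out[pos] = (u - 1.0) / s[pos]
    else:
        out[pos] = theta[pos] / s[pos] ** 2  # (q^2 - s) / s^2
    return out


def _ell(v, s, q, lam):
    """Likelihood contribution of one effect with prior variance v (vs v = 0)."""
    sv = 1.0 + v * s
    return 0.5 * (-np.log(sv) + q * q * v / sv) - lam * v


class _GreedyState:
    """Active-set bookkeeping for one (projected) problem.

    The per-candidate statistics ``S_j = x_j' C^-1 x_j`` and
    ``Q_j = x_j' C^-1 y`` (full covariance C) are kept up to date with exact
    Sherman-Morrison rank-1 updates after every add / re-estimate / delete
    action, and recomputed from scratch at the start of every sweep to
    avoid numerical drift.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        self.xty = X.T @ y
        self.cn2 = np.einsum("ij,ij->j", X, X)
        self.yty = float(y @ y)
        self.active: list[int] = []
        self.sig2: list[float] = []
        self.B = np.empty((self.p, 0))   # X' X_active
        self.G = np.empty((0, 0))        # X_active' X_active
        self.Sigma = np.empty((0, 0))
        self.mu = np.empty(0)
        self.S = np.empty(0)
        self.Q = np.empty(0)
        self.logdet_prec = 0.0  # log det of (A + G / sigma0), maintained incrementally

    @property
    def M(self) -> int:
        return len(self.active)

    def _refresh_mu(self, sigma0: float) -> None:
        self.mu = self.Sigma @ self.xty[self.active] / sigma0 if self.active else np.empty(0)

    def refresh_posterior(self, sigma0: float) -> None:
        """Exact posterior covariance, mean and precision log-determinant."""
        if not self.active:
            self.Sigma = np.empty((0, 0))
            self.mu = np.empty(0)
            self.logdet_prec = 0.0
            return
        A = np.diag(1.0 / np.asarray(self.sig2))
        prec = A + self.G / sigma0
        try:
            self.Sigma = np.linalg.inv(prec)
        except np.linalg.LinAlgError as exc:
            raise EBLassoError("singular posterior covariance") from exc
        sign, self.logdet_prec = np.linalg.slogdet(prec)
        if sign <= 0:
            raise EBLassoError("posterior precision not positive definite")
        self._refresh_mu(sigma0)

    def refresh_sq(self, sigma0: float) -> None:
        """Exact S, Q for every candidate with the full current covariance."""
        if not self.active:
            self.S = self.cn2 / sigma0
            self.Q = self.xty / sigma0
            return
        T = self.B @ self.Sigma
        self.S = self.cn2 / sigma0 - np.einsum("ij,ij->i", T, self.B) / sigma0**2
        self.Q = self.xty / sigma0 - (self.B @ self.mu) / sigma0

    def loo_sq(self):
        """Leave-one-out s, q (effect j excluded from C for active j)."""
        s, q = self.S.copy(), self.Q.copy()
        if self.active:
            act = np.asarray(self.active)
            denom = 1.0 - np.asarray(self.sig2) * self.S[act]
            denom = np.where(np.abs(denom) < _EPS, _EPS, denom)
            s[act] = self.S[act] / denom
            q[act] = self.Q[act] / denom
        return s, q

    def log_marginal(self, sigma0: float, lam: float) -> float:
        """Penalized marginal log-likelihood at the current state."""
        if not self.active:
            return -0.5 * (self.n * np.log(2 * np.pi * sigma0) + self.yty / sigma0)
        sig2 = np.asarray(self.sig2)
        quad = (self.yty - self.xty[self.active] @ self.mu) / sigma0
        return -0.5 * (
            self.n * np.log(2 * np.pi * sigma0)
            + np.sum(np.log(sig2))
            + self.logdet_prec
            + quad
        ) - lam * float(np.sum(sig2))

    def _rank1_sq_update(self, j: int, delta: float, gram_j: np.ndarray, sigma0: float) -> None:
        """Exact S/Q update for C -> C + delta * x_j x_j' (Sherman-Morrison)."""
        denom = 1.0 + delta * self.S[j]
        if abs(denom) < _EPS:
            denom = _EPS
        if self.active:
            bj = self.B[j]  # x_j' X_active
            e = gram_j / sigma0 - (self.B @ (self.Sigma @ bj)) / sigma0**2
        else:
            e = gram_j / sigma0
        kappa = delta / denom
        qj = self.Q[j]
        self.S = self.S - kappa * e * e
        self.Q = self.Q - kappa * e * qj

    def apply(self, j: int, new_v: float, sigma0: float) -> None:
        """One add / re-estimate / delete action with O(M^2 + p) updates.

        The posterior covariance, its log-determinant and the candidate
        S/Q statistics are updated incrementally (Schur complement /
        Sherman-Morrison); exact refreshes at sweep starts bound drift.
        """
        old_v = 0.0
        if j in self.active:
            old_v = self.sig2[self.active.index(j)]
            gram_j = self.B[:, self.active.index(j)]
        else:
            gram_j = self.X.T @ self.X[:, j]
        self._rank1_sq_update(j, new_v - old_v, gram_j, sigma0)
        if j in self.active:
            k = self.active.index(j)
            if new_v > 0:  # re-estimate: diagonal precision perturbation
                dalpha = 1.0 / new_v - 1.0 / old_v
                skk = self.Sigma[k, k]
                denom = 1.0 + dalpha * skk
                if denom <= _EPS:
                    self.sig2[k] = new_v
                    self.refresh_posterior(sigma0)
                    self._refresh_mu(sigma0)
                    return
                col = self.Sigma[:, k].copy()
                self.Sigma = self.Sigma - (dalpha / denom) * np.outer(col, col)
                self.logdet_prec += np.log(denom)
                self.sig2[k] = new_v
            else:  # delete: Schur downdate
                skk = self.Sigma[k, k]
                keep = np.arange(self.M) != k
                col = self.Sigma[keep, k]
                self.Sigma = self.Sigma[np.ix_(keep, keep)] - np.outer(col, col) / skk
                self.logdet_prec += np.log(skk)
                del self.active[k]
                del self.sig2[k]
                self.B = np.delete(self.B, k, axis=1)
                self.G = np.delete(np.delete(self.G, k, axis=0), k, axis=1)
        else:
            if new_v <= 0:
                return
            g = gram_j[self.active] if self.active else np.empty(0)
            M = self.M
            c = g / sigma0
            d = 1.0 / new_v + self.cn2[j] / sigma0
            w = self.Sigma @ c if M else np.empty(0)
            chi = d - float(c @ w) if M else d
            if chi <= _EPS:  # numerically collinear with the active set
                self._grow_bg(j, gram_j, g)
                self.active.append(j)
                self.sig2.append(new_v)
                self.refresh_posterior(sigma0)
                return
            Sn = np.empty((M + 1, M + 1))
            if M:
                Sn[:M, :M] = self.Sigma + np.outer(w, w) / chi
                Sn[:M, M] = -w / chi
                Sn[M, :M] = -w / chi
            Sn[M, M] = 1.0 / chi
            self.Sigma = Sn
            self.logdet_prec += np.log(chi)
            self._grow_bg(j, gram_j, g)
            self.active.append(j)
            self.sig2.append(new_v)
        self._refresh_mu(sigma0)

    def _grow_bg(self, j: int, gram_j: np.ndarray, g: np.ndarray) -> None:
        M = self.G.shape[0]
        Gn = np.empty((M + 1, M + 1))
        Gn[:M, :M] = self.G
        Gn[:M, M] = g
        Gn[M, :M] = g
        Gn[M, M] = self.cn2[j]
        self.G = Gn
        self.B = np.concatenate([self.B, gram_j[:, None]], axis=1)


def fit(
    design: EffectDesign,
    hyper: tuple[float, float] | None = DEFAULT_HYPER,
    lam: float | None = None,
    tol: float = 1e-4,
    inner_tol: float = 1e-8,
    max_iter: int = 500,
    max_actions: int = 500,
    max_basis: int | None = None,
    noise_var: float | None = None,
    seed=None,
    _trace_hook=None,
) -> EBLassoFit:
    """Fit the joint effect model by fast empirical Bayesian LASSO.

    Parameters
    ----------
    design : EffectDesign
        Response, penalized columns and unpenalized block.
    hyper : (a, b)
        Gamma hyperprior on lambda.  The exponential prior sits on the
        variance of every candidate effect (excluded effects at the
        boundary sigma2_j = 0), so the posterior mode re-estimated in the
        outer iteration is ``max(0, (p - 1 + a) / (sum sigma2_j + b))``
        with p the number of candidate columns.
    lam : float, optional
        Fix lambda at this value instead (``lam=0`` reduces to the fast
        relevance-vector-machine schedule).
    noise_var : float, optional
        Fix the noise variance sigma0^2 instead of re-estimating it in the
        outer iteration.
    tol : float
        Outer convergence: relative change of both sigma0^2 and lambda.
    seed : unused
        The algorithm is deterministic; accepted for interface symmetry.

    Notes
    -----
    The response and candidate columns are residualized on the unpenalized
    block once up front, so the greedy machinery only ever sees penalized
    effects.  Unpenalized coefficients are recovered afterwards by least
    squares on the original scale.
    """
    y0 = design.y
    if y0.size < 3:
        raise EBLassoError("need at least 3 observations")
    if not (np.isfinite(design.X).all() and np.isfinite(y0).all()):
        raise EBLassoError("non-finite values in the design")

    U = design.U
    rank_u = np.linalg.matrix_rank(U)
    Qu, _ = np.linalg.qr(U)
    y = y0 - Qu @ (Qu.T @ y0)

    cand0 = np.flatnonzero(design.active)
    Xc = design.X[:, cand0]
    Xc = Xc - Qu @ (Qu.T @ Xc)
    keep = np.einsum("ij,ij->j", Xc, Xc) / max(len(y), 1) > 1e-12
    candidates = cand0[keep]
    X = np.ascontiguousarray(Xc[:, keep])
    n, p = X.shape

    var_y = float(np.var(y))
    if var_y <= 0:
        raise EBLassoError("response has no variance after residualization")
    fixed_sigma0 = noise_var is not None
    sigma0 = float(noise_var) if fixed_sigma0 else var_y
    fixed_lam = lam is not None
    if fixed_lam:
        lam_cur = float(lam)
        a_g = b_g = None
    else:
        if hyper is None:
            raise EBLassoError("provide hyper=(a, b) or a fixed lam")
        a_g, b_g = hyper
        # Start lambda at its null-state posterior mode; as effects enter,
        # sigma0 anneals downward from var(y) and progressively weaker
        # effects become visible at this nearly constant lambda.
        lam_cur = (p - 1.0 + a_g) / b_g if b_g > 0 else 1.0

    if max_basis is None:
        max_basis = max(min(p, int(0.8 * n)), 1)
    state = _GreedyState(X, y)
    ml_trace: list[np.ndarray] = []
    converged = False
    n_outer = 0

    def inner_sweep() -> np.ndarray:
        seg = []
        state.refresh_sq(sigma0)
        for _ in range(max_actions):
            s, q = state.loo_sq()
            v_new = _sigma2_new(s, q, lam_cur)
            gain = np.full(p, -np.inf)
            act = np.asarray(state.active, dtype=int)
            inactive = np.ones(p, dtype=bool)
            if act.size:
                inactive[act] = False
            add = inactive & (v_new > 0) if state.M < max_basis else np.zeros(p, dtype=bool)
            gain[add] = _ell(v_new[add], s[add], q[add], lam_cur)
            if act.size:
                v_old = np.asarray(state.sig2)
                ell_old = _ell(v_old, s[act], q[act], lam_cur)
                re = v_new[act] > 0
                gain[act[re]] = _ell(v_new[act[re]], s[act[re]], q[act[re]], lam_cur) - ell_old[re]
                gain[act[~re]] = -ell_old[~re]
            j = int(np.argmax(gain))
            if not np.isfinite(gain[j]) or gain[j] <= inner_tol:
                break
            state.apply(j, float(v_new[j]), sigma0)
            seg.append(state.log_marginal(sigma0, lam_cur))
        else:
            warnings.warn("inner iteration hit the action cap", ConvergenceWarning)
        return np.asarray(seg)

    state.refresh_posterior(sigma0)
    for n_outer in range(1, max_iter + 1):
        state.refresh_posterior(sigma0)
        ml_trace.append(inner_sweep())
        # outer updates: noise variance and lambda posterior mode
        M = state.M
        sum_sig2 = float(np.sum(state.sig2)) if M else 0.0
        if fixed_sigma0:
            sigma0_new = sigma0
        elif M:
            resid = y - X[:, state.active] @ state.mu
            gamma = 1.0 - np.diag(state.Sigma) / np.asarray(state.sig2)
            denom = n - float(np.sum(gamma))
            denom = denom if denom > 1 else float(n)
            sigma0_new = max(float(resid @ resid) / denom, 1e-12 * var_y)
        else:
            sigma0_new = max(state.yty / n, 1e-12 * var_y)
        if fixed_lam:
            lam_new = lam_cur
        else:
            lam_new = max(0.0, (p - 1.0 + a_g) / (sum_sig2 + b_g))
        if _trace_hook is not None:
            _trace_hook(n_outer, M, sigma0, lam_cur, sigma0_new, lam_new)
        d_sig = abs(sigma0_new - sigma0) / max(sigma0, _EPS)
        d_lam = abs(lam_new - lam_cur) / max(lam_cur, _EPS) if not fixed_lam else 0.0
        sigma0, lam_cur = sigma0_new, lam_new
        if d_sig < tol and d_lam < tol:
            converged = True
            state.refresh_posterior(sigma0)
            ml_trace.append(inner_sweep())  # final polish at converged hyperparameters
            break
    if not converged:
        warnings.warn("EBLASSO did not converge; returning the final iterate",
                      ConvergenceWarning)
    state.refresh_posterior(sigma0)
    state.refresh_sq(sigma0)
    s_fin, q_fin = state.loo_sq()

    act = np.asarray(state.active, dtype=int)
    indices = candidates[act] if act.size else np.empty(0, dtype=int)
    beta = state.mu.copy()
    Sigma = state.Sigma.copy()
    sig2 = np.asarray(state.sig2, dtype=float)
    # unpenalized coefficients on the original (unprojected) scale
    resid0 = y0 - (design.X[:, indices] @ beta if act.size else 0.0)
    coef_u, *_ = np.linalg.lstsq(U, resid0, rcond=None)

    return EBLassoFit(
        labels=[design.labels[i] for i in indices],
        indices=indices,
        beta=beta,
        Sigma=Sigma,
        sigma2=sig2,
        sigma0_sq=float(sigma0),
        lam=float(lam_cur),
        hyper=None if fixed_lam else (a_g, b_g),
        n=n,
        df=int(n - act.size - rank_u),
        n_unpenalized=int(rank_u),
        unpenalized_coef=coef_u,
        converged=converged,
        n_outer=n_outer,
        ml_trace=ml_trace,
        s_=s_fin,
        q_=q_fin,
        candidates_=candidates,
    )


def test_effects(fit_result: EBLassoFit, alpha: float = 0.05) -> pd.DataFrame:
    """t-tests for the retained effects.

    ``t_j = beta_j / sqrt(Sigma_jj)`` with df = n - retained - unpenalized;
    two-sided P; significant iff P < alpha (default 0.05, unadjusted).
    """
    if fit_result.n_retained == 0:
        return pd.DataFrame(
            {
                "label": pd.Series(dtype=str),
                "type": pd.Series(dtype=str),
                "markers": pd.Series(dtype=str),
                "estimate": pd.Series(dtype=float),
                "t": pd.Series(dtype=float),
                "P": pd.Series(dtype=float),
                "significant": pd.Series(dtype=bool),
            }
        )
    se = np.sqrt(np.diag(fit_result.Sigma))
    if np.any(se <= 0):
        raise EBLassoError("non-positive posterior variance")
    t = fit_result.beta / se
    df = max(fit_result.df, 1)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "label": [l.name for l in fit_result.labels],
            "type": [l.type + ("xE" if l.env else "") for l in fit_result.labels],
            "markers": [":".join(l.markers) for l in fit_result.labels],
            "estimate": fit_result.beta,
            "t": t,
            "P": pvals,
            "significant": pvals < alpha,
        }
    )
    return out.sort_values("P", kind="stable").reset_index(drop=True)


def select_hyper(
    design: EffectDesign,
    folds: int = 3,
    grid=None,
    seed=0,
    **fit_kwargs,
) -> tuple[float, float]:
    """Choose (a, b) by k-fold cross-validated prediction error.

    Ties are broken toward stronger shrinkage (the larger null-state
    lambda posterior mode).
    """
    if folds not in (3, 5, 10):
        raise EBLassoError("folds must be 3, 5 or 10")
    n = design.n
    if n < folds:
        raise EBLassoError("need at least `folds` observations")
    grid = list(grid) if grid is not None else list(DEFAULT_HYPER_GRID)
    if not grid:
        raise EBLassoError("empty hyperparameter grid")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    splits = np.array_split(order, folds)
    scores = []
    for a_g, b_g in grid:
        sse, cnt = 0.0, 0
        for k in range(folds):
            test_idx = splits[k]
            train_idx = np.concatenate([splits[i] for i in range(folds) if i != k])
            sub = design.subset(train_idx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                f = fit(sub, hyper=(a_g, b_g), **fit_kwargs)
            yhat = f.predict(design.X[test_idx], design.U[test_idx])
            sse += float(np.sum((design.y[test_idx] - yhat) ** 2))
            cnt += len(test_idx)
        scores.append(sse / cnt)
    p = int(np.sum(design.active))
    def null_lam(point):
        a_g, b_g = point
        return (p - 1.0 + a_g) / b_g if b_g > 0 else np.inf
    best = min(range(len(grid)), key=lambda i: (scores[i], -null_lam(grid[i])))
    return tuple(grid[best])
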