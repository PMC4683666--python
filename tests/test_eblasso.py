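import numpy as np
import pytest
from scipy import optimize, stats

from heteromap.eblasso import (
    ConvergenceWarning,
    EBLassoError,
    EBLassoFit,
    _ell,
    _sigma2_new,
    fit,
    select_hyper,
)
from heteromap.eblasso import test_effects as effect_table  # avoid pytest collection
from heteromap.model import EffectDesign


def _signal_design(n=80, p=30, k=2, beta=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    coef = np.zeros(p)
    coef[:k] = beta
    y = X @ coef + rng.standard_normal(n)
    return EffectDesign.from_arrays(y, X)


# ---------------------------------------------------------------------------
# closed-form variance update
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_sigma2_update_maximizes_penalized_likelihood(seed):
    """The closed-form sigma2_j matches a numerical maximizer of the
    one-effect penalized marginal likelihood."""
    rng = np.random.default_rng(seed)
    s = float(rng.uniform(0.5, 50))
    lam = float(rng.uniform(0.01, 20))
    q2 = (s + 2 * lam) * float(rng.uniform(1.05, 10))  # retention region
    q = np.sqrt(q2)
    v_hat = _sigma2_new(np.array([s]), np.array([q]), lam)[0]
    res = optimize.minimize_scalar(
        lambda v: -_ell(v, s, q, lam), bounds=(1e-10, 100.0), method="bounded",
        options={"xatol": 1e-12},
    )
    assert v_hat > 0
    assert v_hat == pytest.approx(res.x, rel=1e-4)
    # below the retention boundary the maximizer is the origin
    q_low = np.sqrt(s + 2 * lam) * 0.99
    assert _sigma2_new(np.array([s]), np.array([q_low]), lam)[0] == 0.0


def test_sigma2_update_lambda_zero_limit():
    s, q = np.array([4.0]), np.array([6.0])
    exact = (q**2 - s) / s**2
    assert _sigma2_new(s, q, 0.0)[0] == pytest.approx(exact[0])
    assert _sigma2_new(s, q, 1e-10)[0] == pytest.approx(exact[0], rel=1e-6)


# ---------------------------------------------------------------------------
# fitting behaviour
# ---------------------------------------------------------------------------

def test_pure_noise_with_large_lambda_retains_nothing():
    rng = np.random.default_rng(1)
    des = EffectDesign.from_arrays(rng.standard_normal(50), rng.standard_normal((50, 20)))
    f = fit(des, lam=1e8)
    assert f.n_retained == 0
    assert f.sigma0_sq == pytest.approx(np.var(des.y), rel=0.1)


def test_single_column_sigma2_matches_rvm_stationarity():
    """With one candidate and lambda = 0, sigma2 = (q^2 - s)/s^2 at the optimum."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal(200)
    y = 0.8 * x + rng.standard_normal(200)
    des = EffectDesign.from_arrays(y, x[:, None])
    f = fit(des, lam=0.0)
    assert f.n_retained == 1
    s, q = f.s_[0], f.q_[0]
    assert f.sigma2[0] == pytest.approx((q**2 - s) / s**2, rel=1e-3)


def test_retention_criterion_partitions_candidates():
    """At convergence q^2 > s + 2 lambda holds exactly for retained effects
    and fails for excluded ones."""
    for seed in (0, 3):
        f = fit(_signal_design(seed=seed), hyper=(0.1, 30.0))
        assert f.converged
        crit = f.q_**2 - f.s_ - 2 * f.lam
        retained = np.isin(f.candidates_, f.indices)
        assert np.all(crit[retained] > 0)
        # any candidate still above the boundary must sit below the greedy
        # gain tolerance (the convergence criterion restated)
        over = ~retained & (crit > 0)
        if over.any():
            v_star = _sigma2_new(f.s_[over], f.q_[over], f.lam)
            gains = _ell(v_star, f.s_[over], f.q_[over], f.lam)
            assert np.all(gains <= 1e-6)


def test_marginal_likelihood_monotone_within_sweeps():
    f = fit(_signal_design(seed=4), hyper=(0.1, 30.0))
    assert any(len(seg) for seg in f.ml_trace)
    for seg in f.ml_trace:
        if len(seg) > 1:
            assert np.all(np.diff(seg) > -1e-8)


def test_fit_invariant_to_candidate_order():
    des = _signal_design(seed=5)
    f1 = fit(des, hyper=(0.1, 30.0))
    perm = np.random.default_rng(0).permutation(des.X.shape[1])
    des2 = EffectDesign.from_arrays(des.y, des.X[:, perm])
    f2 = fit(des2, hyper=(0.1, 30.0))
    assert sorted(perm[f2.indices]) == sorted(f1.indices)
    order1 = np.argsort(f1.indices)
    order2 = np.argsort(perm[f2.indices])
    assert np.allclose(f1.beta[order1], f2.beta[order2], atol=1e-8)


def test_relabelling_markers_permutes_but_preserves_fit():
    """Fitting a marker design with markers relabelled/reordered gives the
    same retained effects under the name mapping."""
    from heteromap.model import build_design

    rng = np.random.default_rng(6)
    codes = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
    beta_col = (codes[:, 1] - 1).astype(float)
    y = 1.2 * beta_col + rng.standard_normal(60)
    des = build_design(codes, y, markers=["M1", "M2", "M3", "M4"])
    perm = [2, 0, 3, 1]
    des_p = build_design(codes[:, perm], y, markers=[f"M{i+1}" for i in perm])
    fa = fit(des, hyper=(0.1, 10.0))
    fb = fit(des_p, hyper=(0.1, 10.0))

    def canonical(label):
        # pair columns are products; orientation follows column order, so
        # aa/dd are symmetric and a reversed ad is a da (and vice versa)
        if len(label.markers) != 2:
            return label.name
        k, s_ = label.markers
        if int(k[1:]) <= int(s_[1:]):
            return label.name
        flipped = {"aa": "aa", "dd": "dd", "ad": "da", "da": "ad"}[label.type]
        return f"{flipped}@{s_}:{k}"

    assert {canonical(l) for l in fa.labels} == {canonical(l) for l in fb.labels}


def test_unpenalized_covariates_absorb_confounder():
    rng = np.random.default_rng(7)
    n = 100
    conf = rng.standard_normal(n)
    X = rng.standard_normal((n, 10))
    y = 5.0 * conf + rng.standard_normal(n)
    U = np.column_stack([np.ones(n), conf])
    des = EffectDesign.from_arrays(y, X, U=U)
    f = fit(des, lam=1e4)
    assert f.n_retained == 0
    assert f.unpenalized_coef[1] == pytest.approx(5.0, abs=0.5)


def test_nonconvergence_warns():
    with pytest.warns(ConvergenceWarning):
        fit(_signal_design(seed=8), hyper=(0.1, 30.0), max_iter=1)


def test_input_validation():
    with pytest.raises(EBLassoError):
        fit(EffectDesign.from_arrays(np.zeros(2), np.zeros((2, 1))))
    bad = EffectDesign.from_arrays(np.array([1.0, np.nan, 0.0, 2.0]), np.ones((4, 1)))
    bad.active[:] = True
    with pytest.raises(EBLassoError):
        fit(bad)


# ---------------------------------------------------------------------------
# lambda -> 0 equivalence with the fast RVM schedule (independent oracle)
# ---------------------------------------------------------------------------

def _slow_rvm_oracle(X, y, max_steps=400, tol=1e-10):
    """Direct greedy relevance-vector machine on 5 columns: explicit C
    inversion, sigma2 = (q^2-s)/s^2 update, largest-gain action."""
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sigma0 = float(np.var(yc))
    sig2 = np.zeros(p)
    for _ in range(max_steps):
        C = sigma0 * np.eye(n) + (Xc * sig2) @ Xc.T
        Ci = np.linalg.inv(C)
        best, best_gain = None, tol
        for j in range(p):
            if sig2[j] > 0:  # leave-one-out covariance
                Cj = C - sig2[j] * np.outer(Xc[:, j], Xc[:, j])
                Cji = np.linalg.inv(Cj)
            else:
                Cji = Ci
            s = Xc[:, j] @ Cji @ Xc[:, j]
            q = Xc[:, j] @ Cji @ yc
            new = (q * q - s) / s**2 if q * q > s else 0.0
            def L(v):
                return 0.5 * (-np.log1p(v * s) + q * q * v / (1 + v * s))
            gain = L(new) - L(sig2[j])
            if gain > best_gain:
                best, best_gain, best_new = j, gain, new
        if best is None:
            break
        sig2[best] = best_new
    active = np.flatnonzero(sig2 > 0)
    A = np.diag(1.0 / sig2[active])
    Sigma = np.linalg.inv(A + Xc[:, active].T @ Xc[:, active] / sigma0)
    mu = Sigma @ Xc[:, active].T @ yc / sigma0
    return active, sig2[active], mu, sigma0


def test_lambda_zero_matches_slow_rvm_oracle():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((40, 5))
    y = 1.5 * X[:, 1] - 1.0 * X[:, 3] + 0.3 * rng.standard_normal(40)
    des = EffectDesign.from_arrays(y, X)
    sigma0 = float(np.var(y - y.mean()))
    f = fit(des, lam=0.0, noise_var=sigma0)  # fixed noise, pure RVM schedule
    active, sig2, mu, _ = _slow_rvm_oracle(X, y)
    assert sorted(f.indices.tolist()) == sorted(active.tolist())
    order_f = np.argsort(f.indices)
    order_o = np.argsort(active)
    assert np.allclose(np.asarray(f.sigma2)[order_f], sig2[order_o], rtol=1e-6)
    assert np.allclose(f.beta[order_f], mu[order_o], rtol=1e-6)


# ---------------------------------------------------------------------------
# hypothesis tests on retained effects
# ---------------------------------------------------------------------------

def _fake_fit(beta, Sigma, n, n_unpen=1):
    from heteromap.model import EffectLabel

    beta = np.asarray(beta, dtype=float)
    labels = [EffectLabel("a", (f"M{i + 1}",)) for i in range(beta.size)]
    return EBLassoFit(
        labels=labels, indices=np.arange(beta.size), beta=beta,
        Sigma=np.asarray(Sigma, dtype=float), sigma2=np.ones(beta.size),
        sigma0_sq=1.0, lam=0.0, hyper=None, n=n,
        df=n - beta.size - n_unpen, n_unpenalized=n_unpen,
        unpenalized_coef=np.zeros(1), converged=True, n_outer=1,
    )


def test_t_statistic_and_p_value_oracle():
    """t = 2.0 with 30 df gives the textbook two-sided P of about 0.0547."""
    table = effect_table(_fake_fit([2.0], [[1.0]], n=32))
    assert table["t"].iloc[0] == pytest.approx(2.0)
    assert table["P"].iloc[0] == pytest.approx(2 * stats.t.sf(2.0, 30), rel=1e-12)
    assert table["P"].iloc[0] == pytest.approx(0.0547, abs=1e-3)
    assert not table["significant"].iloc[0]


def test_zero_effect_and_p_monotone_in_t():
    table = effect_table(_fake_fit([0.0, 1.0, 2.0, 4.0], np.eye(4), n=40))
    by_label = table.set_index("label")
    assert by_label.loc["a@M1", "t"] == 0 and by_label.loc["a@M1", "P"] == pytest.approx(1.0)
    ordered = table.sort_values("t")["P"].to_numpy()
    assert np.all(np.diff(ordered) <= 0)  # larger |t| -> smaller P


def test_empty_fit_gives_empty_typed_table():
    rng = np.random.default_rng(10)
    des = EffectDesign.from_arrays(rng.standard_normal(30), rng.standard_normal((30, 5)))
    table = effect_table(fit(des, lam=1e8))
    assert len(table) == 0
    assert table["significant"].dtype == bool


# ---------------------------------------------------------------------------
# hyperparameter selection
# ---------------------------------------------------------------------------

def test_select_hyper_single_point_grid():
    des = _signal_design(n=30, p=8, seed=11)
    assert select_hyper(des, folds=3, grid=[(0.5, 2.0)], seed=0) == (0.5, 2.0)


def test_select_hyper_deterministic_and_duplicate_points():
    des = _signal_design(n=30, p=8, seed=12)
    grid = [(0.1, 1.0), (0.1, 1.0), (0.1, 50.0)]
    first = select_hyper(des, folds=3, grid=grid, seed=7)
    second = select_hyper(des, folds=3, grid=grid, seed=7)
    assert first == second


def test_select_hyper_prefers_weaker_shrinkage_for_signal():
    """Data with real effects select a weaker-shrinkage grid point than noise."""
    grid = [(0.1, 0.5), (0.1, 200.0)]  # strong vs nearly-unpenalized
    chosen_signal, chosen_noise = [], []
    for seed in range(4):
        rng = np.random.default_rng(100 + seed)
        n, p = 60, 20
        X = rng.standard_normal((n, p))
        coef = np.zeros(p)
        coef[:5] = 1.2
        signal = EffectDesign.from_arrays(X @ coef + rng.standard_normal(n), X)
        noise = EffectDesign.from_arrays(rng.standard_normal(n), X)
        chosen_signal.append(select_hyper(signal, folds=3, grid=grid, seed=seed)[1])
        chosen_noise.append(select_hyper(noise, folds=3, grid=grid, seed=seed)[1])
    assert np.mean(chosen_signal) > np.mean(chosen_noise)


def test_select_hyper_validation():
    des = _signal_design(n=30, p=5, seed=13)
    with pytest.raises(EBLassoError):
        select_hyper(des, folds=4)
    with pytest.raises(EBLassoError):
        select_hyper(des, folds=3, grid=[])
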