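"""Richness drivers: nutrient index, climate proxy joins, trend and mixed models.

The catchment nutrient index summarizes bedrock-derived nutrient
availability:

    NI = (P + K + ln(Ca)) / H_min

with P, K, Ca in ppm and H_min the extended Mohs hardness of the most
easily weathered principal mineral, so softer (more weatherable) bedrock
yields a higher index.  ln(Ca) is used because Ca content tracks pH,
which controls nutrient (especially P) availability.

Temporal richness trends are fitted as penalized B-spline Poisson
regressions (GAMs) of Hill richness on sample age, optionally with a
continuous-time first-order autoregressive (CAR1) residual process
estimated in a two-stage scheme.  The regional trend adds lake-level
random intercepts (ridge-penalized lake effects) to a shared smooth.
The driver model is a linear mixed-effects model of log richness on
delta-18-O and NI interacted with Holocene period, with a random
intercept and random age slope per lake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.gam.api import BSplines

HOLOCENE_MAX = 11_700
EARLY_MIDDLE = 8_300
MIDDLE_LATE = 4_250
PERIODS = ("Early", "Middle", "Late")


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def nutrient_index(P: float, K: float, Ca: float, H_min: float, mode: str = "divide") -> float:
    """Catchment nutrient index NI = (P + K + ln Ca) / H_min.

    ``mode='multiply'`` gives the alternative reading (P + K + ln Ca) * H_min,
    kept behind a flag; division is the default because nutrient release
    should fall as mineral hardness rises.
    """
    if Ca <= 0:
        raise ValueError("Ca must be positive (ln-transformed)")
    if H_min <= 0:
        raise ValueError("H_min must be positive")
    base = P + K + np.log(Ca)
    return float(base / H_min if mode == "divide" else base * H_min)


def assign_proxy(
    ages,
    series: pd.DataFrame,
    exclude_below: float | None = None,
) -> pd.DataFrame:
    """Nearest-age join of a climate proxy series onto sample ages.

    ``series`` has columns ``age`` (cal yr BP, 50-year grid) and ``d18o``.
    Exact midpoints tie to the older (larger BP) grid point.  Ages outside
    the series range take the nearest endpoint with a warning.  With
    ``exclude_below`` set, values below it are flagged ``excluded``
    (colder-than-threshold outliers dropped from driver models).
    """
    if len(series) == 0:
        raise ValueError("empty proxy series")
    s = series.sort_values("age").reset_index(drop=True)
    grid = s["age"].to_numpy(dtype=float)
    vals = s["d18o"].to_numpy(dtype=float)
    ages = np.asarray(ages, dtype=float)
    if (ages < grid[0]).any() or (ages > grid[-1]).any():
        warnings.warn("sample ages outside proxy range; using nearest endpoint")
    pos = np.searchsorted(grid, ages)
    lo = np.clip(pos - 1, 0, len(grid) - 1)
    hi = np.clip(pos, 0, len(grid) - 1)
    # ties (equidistant) resolve to the older = larger-age grid point, hi
    pick_hi = (grid[hi] - ages) <= (ages - grid[lo])
    idx = np.where(pick_hi, hi, lo)
    out = pd.DataFrame({"age": ages, "d18o": vals[idx], "proxy_age": grid[idx]})
    out["excluded"] = (out["d18o"] < exclude_below) if exclude_below is not None else False
    return out


def split_periods(ages) -> np.ndarray:
    """Holocene period label per age; boundary ages go to the older period.

    Early: 11 700 down to (and including) 8 300 yr BP; Middle: below
    8 300 down to (and including) 4 250; Late: below 4 250 to 0.
    Pre-Holocene ages (> 11 700) are rejected.
    """
    ages = np.asarray(ages, dtype=float)
    if (ages > HOLOCENE_MAX).any() or (ages < 0).any():
        raise ValueError("ages must lie within the Holocene (0 to 11700 yr BP)")
    out = np.where(ages >= EARLY_MIDDLE, "Early",
                   np.where(ages >= MIDDLE_LATE, "Middle", "Late"))
    return out


def build_driver_table(
    diversity: pd.DataFrame,
    lakes: pd.DataFrame,
    proxy: pd.DataFrame,
    exclude_d18o_below: float | None = -39.0,
) -> pd.DataFrame:
    """Assemble the per-sample driver table for the mixed model.

    Joins nearest-age delta-18-O and per-lake NI onto the per-sample
    diversity summary, drops pre-Holocene samples and (by default)
    samples with proxy values below -39.  ``lakes`` needs ``lake_id``
    and ``ni`` columns.
    """
    work = diversity[diversity["age"] <= HOLOCENE_MAX].copy()
    prox = assign_proxy(work["age"].to_numpy(), proxy, exclude_below=exclude_d18o_below)
    work["d18o"] = prox["d18o"].to_numpy()
    work["period"] = split_periods(work["age"].to_numpy())
    work = work.merge(lakes[["lake_id", "ni"]], on="lake_id", how="left")
    work["log_richness"] = np.log(work["n0"].astype(float))
    work["age_ka"] = work["age"] / 1000.0
    if exclude_d18o_below is not None:
        work = work[~prox["excluded"].to_numpy()]
    cols = ["lake_id", "sample_id", "age", "age_ka", "period", "d18o", "ni",
            "n0", "log_richness"]
    return work[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# penalized Poisson GAM engine
# ---------------------------------------------------------------------------

@dataclass
class GamFit:
    """A fitted smooth trend with pointwise confidence band."""

    pred_age: np.ndarray
    fit: np.ndarray          # response scale (expected richness)
    lower: np.ndarray
    upper: np.ndarray
    edf: float
    adj_r2: float
    alpha: float
    phi: float = 0.0         # continuous-time AR1 coefficient per ka
    converged: bool = True
    random_intercept_var: float = float("nan")
    extra: dict = field(default_factory=dict)


def _pirls(y, X, S, R_chol=None, max_iter=100, tol=1e-8):
    """Penalized IRLS for a Poisson log-link model with penalty matrix S.

    ``R_chol`` is the lower Cholesky factor of a working-residual
    correlation matrix; when given, the working model is whitened with it
    (generalized least squares inner step).
    """
    y = np.asarray(y, dtype=float)
    eta = np.log(y + 0.5)
    beta = None
    dev = np.inf
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        w = np.sqrt(mu)
        A = X * w[:, None]
        b = z * w
        if R_chol is not None:
            A = linalg.solve_triangular(R_chol, A, lower=True)
            b = linalg.solve_triangular(R_chol, b, lower=True)
        H = A.T @ A
        beta = linalg.solve(H + S, A.T @ b, assume_a="pos")
        eta_new = X @ beta
        mu_new = np.exp(np.clip(eta_new, -30, 30))
        dev_new = 2 * np.sum(np.where(y > 0, y * np.log(y / mu_new), 0.0) - (y - mu_new))
        if abs(dev - dev_new) < tol * (abs(dev_new) + 0.1):
            eta, dev = eta_new, dev_new
            break
        eta, dev = eta_new, dev_new
    cov = linalg.inv(H + S)
    edf = float(np.trace(cov @ H))
    return {"beta": beta, "cov": cov, "eta": eta, "dev": dev, "edf": edf}


def _null_deviance(y):
    mu0 = np.mean(y)
    return 2 * np.sum(np.where(y > 0, y * np.log(y / mu0), 0.0) - (y - mu0))


def _estimate_phi(resid, times_ka):
    """Continuous-time AR1 coefficient from age-ordered residuals.

    Minimizes the one-step prediction error sum((r[i+1] - phi**dt * r[i])^2)
    over phi in [0, 0.99]; dt in millennia.
    """
    order = np.argsort(times_ka)
    r = np.asarray(resid, dtype=float)[order]
    t = np.asarray(times_ka, dtype=float)[order]
    dt = np.diff(t)
    ok = dt > 0
    if ok.sum() < 3:
        return 0.0

    def loss(phi):
        w = phi ** dt[ok]
        return np.sum((r[1:][ok] - w * r[:-1][ok]) ** 2)

    res = optimize.minimize_scalar(loss, bounds=(0.0, 0.99), method="bounded")
    phi = float(res.x) if res.fun < loss(0.0) else 0.0
    # keep the AR term only when the implied one-step correlation is
    # detectable at this series length; otherwise whitening just adds noise
    if phi > 0 and phi ** np.median(dt[ok]) < 2.0 / np.sqrt(ok.sum()):
        phi = 0.0
    return phi


def _ar1_chol(times_ka, phi):
    if phi <= 0:
        return None
    t = np.asarray(times_ka, dtype=float)
    R = phi ** np.abs(t[:, None] - t[None, :])
    return linalg.cholesky(R, lower=True)


_DEFAULT_ALPHAS = np.logspace(-5, 5, 11)


def fit_trend_gam(
    ages,
    counts,
    use_ar1: bool = False,
    basis_df: int = 10,
    n_pred: int = 300,
    alphas=None,
) -> GamFit:
    """Penalized-spline Poisson smooth of richness on sample age.

    The penalty weight is chosen by AIC (deviance + 2 edf) on a log grid.
    ``use_ar1`` adds the two-stage CAR1 correction: the AR1 coefficient
    phi (per millennium) is estimated on age-ordered Pearson residuals of
    the plain fit, then the model is refitted with whitened working
    equations at the same penalty.  Fitted values are reported at
    ``n_pred`` evenly spaced ages with a pointwise 95% confidence band
    from the t distribution.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(counts, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("need >=8 samples for a smooth trend fit")
    k = int(min(basis_df, max(4, n // 2)))
    # basis on age normalized to [0, 1] so the penalty has O(1) scale
    a0, a1 = ages.min(), ages.max()
    xn = (ages - a0) / (a1 - a0)
    bs = BSplines(xn, df=[k], degree=[3], include_intercept=False)
    X = np.column_stack([np.ones(n), bs.basis])
    P = np.zeros((X.shape[1], X.shape[1]))
    P[1:, 1:] = bs.penalty_matrices[0]

    if alphas is None:
        alphas = _DEFAULT_ALPHAS
    best, best_aic = None, np.inf
    for a in alphas:
        try:
            fit = _pirls(y, X, a * P)
        except linalg.LinAlgError:
            continue
        aic = fit["dev"] + 2 * fit["edf"]
        if aic < best_aic:
            best, best_aic, best_alpha = fit, aic, a
    if best is None:
        raise RuntimeError("smooth fit failed at every penalty weight")

    phi = 0.0
    t_ka = ages / 1000.0
    if use_ar1:
        mu = np.exp(best["eta"])
        pearson = (y - mu) / np.sqrt(mu)
        phi = _estimate_phi(pearson, t_ka)
        if phi > 0:
            L = _ar1_chol(t_ka, phi)
            try:
                best = _pirls(y, X, best_alpha * P, R_chol=L)
            except linalg.LinAlgError:
                warnings.warn("CAR1 refit failed; falling back to the plain smooth")
                phi = 0.0

    grid = np.linspace(a0, a1, n_pred)
    Xp = np.column_stack([np.ones(n_pred),
                          bs.transform(((grid - a0) / (a1 - a0))[:, None])])
    eta_p = Xp @ best["beta"]
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xp, best["cov"], Xp))
    crit = stats.t.ppf(0.975, max(n - best["edf"], 1.0))
    dev0 = _null_deviance(y)
    adj_r2 = 1.0 - (best["dev"] / max(n - best["edf"], 1.0)) / (dev0 / (n - 1))
    return GamFit(
        pred_age=grid,
        fit=np.exp(eta_p),
        lower=np.exp(eta_p - crit * se),
        upper=np.exp(eta_p + crit * se),
        edf=max(best["edf"] - 1.0, 1.0),   # smooth edf, intercept excluded
        adj_r2=float(adj_r2),
        alpha=float(best_alpha),
        phi=phi,
        extra={"dev": best["dev"], "n": n, "beta": best["beta"]},
    )


def fit_regional_gamm(
    df: pd.DataFrame,
    response: str = "n0",
    use_ar1: bool = False,
    basis_df: int = 10,
    n_pred: int = 300,
    alphas=None,
) -> GamFit:
    """Shared Poisson smooth of age with lake-level random intercepts.

    Lake effects enter as ridge-penalized indicator columns (the
    standard random-effects-as-smooths construction), so the reported
    curve is the population-level trend.  With one lake this reduces to
    :func:`fit_trend_gam`.  ``use_ar1`` whitens within-lake blocks with
    the two-stage CAR1 estimate.
    """
    lakes = df["lake_id"].unique()
    if len(lakes) < 2:
        return fit_trend_gam(df["age"].to_numpy(), df[response].to_numpy(),
                             use_ar1=use_ar1, basis_df=basis_df, n_pred=n_pred,
                             alphas=alphas)
    work = df.sort_values(["lake_id", "age"], kind="mergesort").reset_index(drop=True)
    ages = work["age"].to_numpy(dtype=float)
    y = work[response].to_numpy(dtype=float)
    n = len(y)
    k = int(min(basis_df, max(4, n // 4)))
    a0, a1 = ages.min(), ages.max()
    xn = (ages - a0) / (a1 - a0)
    bs = BSplines(xn, df=[k], degree=[3], include_intercept=False)
    D = pd.get_dummies(work["lake_id"]).to_numpy(dtype=float)
    p_s, p_b = bs.basis.shape[1], D.shape[1]
    X = np.column_stack([np.ones(n), bs.basis, D])

    def penalty(a_s, a_b):
        S = np.zeros((X.shape[1], X.shape[1]))
        S[1:1 + p_s, 1:1 + p_s] = a_s * bs.penalty_matrices[0]
        S[1 + p_s:, 1 + p_s:] = a_b * np.eye(p_b)
        return S

    if alphas is None:
        alphas = np.logspace(-4, 4, 7)
    ridge_grid = np.logspace(-1, 3, 5)
    best, best_aic = None, np.inf
    for a_s in alphas:
        for a_b in ridge_grid:
            try:
                fit = _pirls(y, X, penalty(a_s, a_b))
            except linalg.LinAlgError:
                continue
            aic = fit["dev"] + 2 * fit["edf"]
            if aic < best_aic:
                best, best_aic = fit, aic
                best_as, best_ab = a_s, a_b
    if best is None:
        raise RuntimeError("regional smooth failed at every penalty weight")

    phi = 0.0
    if use_ar1:
        mu = np.exp(best["eta"])
        pearson = (y - mu) / np.sqrt(mu)
        t_ka = ages / 1000.0
        phis = []
        for lk in lakes:
            m = (work["lake_id"] == lk).to_numpy()
            if m.sum() >= 6:
                phis.append(_estimate_phi(pearson[m], t_ka[m]))
        phi = float(np.mean(phis)) if phis else 0.0
        if phi > 0:
            blocks = [
                _ar1_chol(t_ka[(work["lake_id"] == lk).to_numpy()], phi)
                if (work["lake_id"] == lk).sum() > 1
                else np.ones((1, 1))
                for lk in lakes
            ]
            L = linalg.block_diag(*[b if b is not None else np.ones((1, 1)) for b in blocks])
            try:
                best = _pirls(y, X, penalty(best_as, best_ab), R_chol=L)
            except linalg.LinAlgError:
                warnings.warn("CAR1 refit failed; falling back to the plain smooth")
                phi = 0.0

    grid = np.linspace(a0, a1, n_pred)
    Xp = np.column_stack([np.ones(n_pred),
                          bs.transform(((grid - a0) / (a1 - a0))[:, None]),
                          np.zeros((n_pred, p_b))])
    eta_p = Xp @ best["beta"]
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xp, best["cov"], Xp))
    crit = stats.t.ppf(0.975, max(n - best["edf"], 1.0))
    dev0 = _null_deviance(y)
    adj_r2 = 1.0 - (best["dev"] / max(n - best["edf"], 1.0)) / (dev0 / (n - 1))
    b_lake = best["beta"][1 + p_s:]
    return GamFit(
        pred_age=grid,
        fit=np.exp(eta_p),
        lower=np.exp(eta_p - crit * se),
        upper=np.exp(eta_p + crit * se),
        edf=max(best["edf"] - 1.0, 1.0),
        adj_r2=float(adj_r2),
        alpha=float(best_as),
        phi=phi,
        random_intercept_var=float(np.var(b_lake, ddof=1)),
        extra={"dev": best["dev"], "n": n, "ridge_alpha": float(best_ab),
               "lake_effects": dict(zip(lakes, b_lake))},
    )


# ---------------------------------------------------------------------------
# richness-driver mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmeFit:
    """Fitted richness-driver mixed model."""

    slopes: pd.DataFrame           # term, period, beta, se, p
    f_tests: dict                  # term -> (F, df_num, df_den, p)
    var_fixed_pct: float
    var_random_pct: float
    random_effect_var: dict
    singular: bool
    converged: bool
    result: object = None


def fit_driver_lme(driver: pd.DataFrame, random_slope: bool = True) -> LmeFit:
    """Mixed model of log richness on climate and nutrient drivers.

    Fixed effects: per-period delta-18-O and NI slopes (equivalently the
    driver x Holocene-period interactions); random intercept and random
    age slope per lake.  A singular random-effects fit triggers a flagged
    refit without the random slope.  Variance explained is decomposed
    marginally (fixed effects) and conditionally (plus random effects).
    """
    if driver["lake_id"].nunique() < 3:
        raise ValueError("need >=3 lakes")
    if set(driver["period"].unique()) != set(PERIODS):
        raise ValueError("all three Holocene periods must be represented")
    data = driver.copy()
    data["period"] = pd.Categorical(data["period"], categories=PERIODS)
    if data.groupby("lake_id")["ni"].first().nunique() < 2:
        raise ValueError("NI constant across lakes; nutrient terms inestimable")

    formula = "log_richness ~ 0 + C(period) + C(period):d18o + C(period):ni"
    re_formula = "~age_ka" if random_slope else "1"
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["lake_id"], re_formula=re_formula)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        bad = res is None or not np.isfinite(res.params).all() or (
            random_slope and np.min(np.linalg.eigvalsh(res.cov_re)) < 1e-8
        )
        if bad and random_slope:
            singular = True
            return _refit_flagged(driver)
        if res is None:
            raise RuntimeError("mixed model failed to converge")

    fe = res.fe_params
    slopes = []
    for term, col in (("d18o", "d18o"), ("ni", "ni")):
        for per in PERIODS:
            name = f"C(period)[{per}]:{col}"
            slopes.append({
                "term": term, "period": per,
                "beta": float(fe[name]),
                "se": float(res.bse_fe[name]),
                "p": float(res.pvalues[name]),
            })
    slopes = pd.DataFrame(slopes)

    # interaction tests: equality of the three period-specific slopes
    f_tests = {}
    names = list(fe.index)
    k_total = len(res.params)
    for term in ("d18o", "ni"):
        L = np.zeros((2, k_total))
        base = names.index(f"C(period)[Early]:{term}")
        for i, per in enumerate(("Middle", "Late")):
            L[i, base] = 1.0
            L[i, names.index(f"C(period)[{per}]:{term}")] = -1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(L, scalar=False)
        stat = float(np.squeeze(wt.statistic)) / 2.0  # chi2 -> F scale
        df_den = int(res.nobs - len(fe))
        f_tests[term] = {"F": stat, "df_num": 2, "df_den": df_den,
                         "p": float(stats.f.sf(stat, 2, df_den))}

    # Nakagawa-style marginal/conditional variance decomposition
    X = model.exog
    var_f = float(np.var(X @ fe.to_numpy()))
    cov_re = np.atleast_2d(res.cov_re.to_numpy())
    Z = np.column_stack([np.ones(len(data)), data["age_ka"].to_numpy()]) \
        if random_slope else np.ones((len(data), 1))
    var_re = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
    total = var_f + var_re + float(res.scale)
    return LmeFit(
        slopes=slopes,
        f_tests=f_tests,
        var_fixed_pct=100.0 * var_f / total,
        var_random_pct=100.0 * var_re / total,
        random_effect_var={"names": list(res.cov_re.columns),
                           "cov": cov_re.tolist(), "resid": float(res.scale)},
        singular=singular,
        converged=bool(res.converged),
        result=res,
    )


def _refit_flagged(driver: pd.DataFrame) -> LmeFit:
    out = fit_driver_lme(driver, random_slope=False)
    out.singular = True
    return out
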