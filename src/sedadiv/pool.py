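"""Regional species-pool estimation.

The regional pool is estimated two ways:

1. Whole-period accumulation: the cumulative count of distinct taxa over
   all retained samples from every lake, ordered oldest to youngest,
   with piecewise growth rates fitted on the curve (log-log slope, plus
   the linear taxa-per-millennium rate within an age window).
2. Time-binned co-occurrence completion: samples are binned to the
   nearest 500 years; within each bin, Beals smoothing gives each taxon
   an occurrence probability per sample from its co-occurrence pattern,
   thresholded at the minimum probability among the samples where the
   taxon was actually observed.  The completed bin pools are then
   standardized by repeated subsampling to a fixed number of samples
   (default 5, the smallest bin) and summarized as mean +/- SD.

Beals smoothing, pinned explicitly: for sample i and focal taxon j,

    b(i, j) = (1 / S_i') * sum_{k present in i, k != j} M_jk / N_k,

where M_jk counts joint occurrences of taxa j and k across samples,
N_k the occurrences of k, and S_i' the taxa present in i excluding j.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

BIN_WIDTH = 500
STANDARD_SIZE = 5
N_RESAMPLES = 1000


# ---------------------------------------------------------------------------
# accumulation and growth rates
# ---------------------------------------------------------------------------

def accumulate_regional(
    table: pd.DataFrame,
    ages: pd.Series,
    min_occurrences: int | None = None,
    exclude_lakes: tuple = (),
) -> pd.DataFrame:
    """Regional cumulative distinct-taxon curve over all lakes combined.

    Optional variants drop taxa with at most ``min_occurrences``
    sample occurrences across the dataset, or whole lakes (e.g. short
    records); both variants are pointwise below the full curve.
    """
    work = table[~table["lake_id"].isin(exclude_lakes)]
    if min_occurrences is not None:
        occ = work.groupby("taxon")["sample_id"].count()
        work = work[work["taxon"].isin(occ[occ > min_occurrences].index)]
    from sedadiv.diversity import accumulated_richness

    return accumulated_richness(work, ages)


def pool_growth_rate(curve: pd.DataFrame, age_window: tuple) -> dict:
    """Taxon-accumulation rate within an age window of the regional curve.

    Reports the OLS slope of log(cumulative count) on log(years since the
    first sample) — the standard accumulation-scaling exponent — and the
    linear-scale rate in taxa per millennium over the window.
    Ages in cal yr BP; ``age_window = (old, young)``.
    """
    old, young = age_window
    t0 = float(curve["age"].max())
    sel = curve[(curve["age"] <= old) & (curve["age"] >= young)]
    if len(sel) < 3:
        raise ValueError("need >=3 curve points inside the age window")
    elapsed = t0 - sel["age"].to_numpy(dtype=float)  # years since first sample
    count = sel["cumulative_taxa"].to_numpy(dtype=float)
    if (elapsed <= 0).any() or (count <= 0).any():
        # log axes undefined at the very first sample; drop it
        ok = (elapsed > 0) & (count > 0)
        elapsed, count = elapsed[ok], count[ok]
        if elapsed.size < 3:
            raise ValueError("window too close to the start of the record")
    loglog = sm.OLS(np.log(count), sm.add_constant(np.log(elapsed))).fit()
    linear = sm.OLS(count, sm.add_constant(elapsed / 1000.0)).fit()
    return {
        "loglog_slope": float(loglog.params[1]),
        "loglog_slope_se": float(loglog.bse[1]),
        "taxa_per_millennium": float(linear.params[1]),
        "taxa_per_millennium_se": float(linear.bse[1]),
        "n_points": int(elapsed.size),
    }


# ---------------------------------------------------------------------------
# 500-year binning and Beals completion
# ---------------------------------------------------------------------------

def assign_bins(ages, width: int = BIN_WIDTH):
    """Nearest-multiple-of-``width`` bin for each age; ties round older."""
    ages = np.asarray(ages, dtype=float)
    return (np.floor(ages / width + 0.5) * width).astype(int)


def presence_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Sample x taxon boolean presence matrix from a harmonized table."""
    m = (
        table.assign(_one=1)
        .pivot_table(index=["lake_id", "sample_id"], columns="taxon",
                     values="_one", aggfunc="max", fill_value=0)
        .astype(bool)
    )
    m.columns.name = None
    return m


def beals_probabilities(presence: pd.DataFrame) -> pd.DataFrame:
    """Beals-smoothed occurrence probability for every (sample, taxon).

    The focal taxon is excluded from its own conditioning set.  Samples
    with no taxa (or only the focal taxon) get probability 0.
    """
    X = presence.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 taxa")
    N = X.sum(axis=0)                      # occurrences per taxon
    M = X.T @ X                            # joint occurrences
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.where(N > 0, M / N, 0.0)    # Q[j, k] = M_jk / N_k
    S = X.sum(axis=1)                      # taxa per sample
    raw = X @ Q.T                          # sum over present k of M_jk/N_k
    # subtract the focal taxon's own contribution (M_jj/N_j = 1 when present)
    num = raw - X
    denom = S[:, None] - X
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(denom > 0, num / denom, 0.0)
    B = np.clip(B, 0.0, 1.0)
    return pd.DataFrame(B, index=presence.index, columns=presence.columns)


def threshold_beal_pool(
    presence: pd.DataFrame, beals: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, set]:
    """Complete a bin's presence matrix by probability thresholding.

    Per taxon, the threshold is the minimum Beals probability over the
    samples where the taxon was observed; the taxon is marked present in
    any sample where it was observed or its probability reaches the
    threshold.  Taxa never observed in the bin are never added.  Returns
    the completed matrix and the bin pool (union over samples).
    """
    if beals is None:
        beals = beals_probabilities(presence)
    X = presence.to_numpy(dtype=bool)
    B = beals.to_numpy(dtype=float)
    completed = X.copy()
    for j in range(X.shape[1]):
        obs = X[:, j]
        if not obs.any():
            continue
        thr = B[obs, j].min()
        completed[:, j] = obs | (B[:, j] >= thr)
    comp = pd.DataFrame(completed, index=presence.index, columns=presence.columns)
    pool = set(comp.columns[comp.any(axis=0)])
    return comp, pool


def standardized_pool(
    presence: pd.DataFrame,
    size: int = STANDARD_SIZE,
    n_resamples: int = N_RESAMPLES,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mean and SD of distinct-taxon count over random sample subsets.

    Draws ``n_resamples`` subsets of ``size`` samples without
    replacement.  With ``size`` equal to the bin's sample count the mean
    is the observed pool size and the SD is 0.
    """
    n = len(presence)
    if n < size:
        raise ValueError(f"bin has {n} samples, fewer than subsample size {size}")
    X = presence.to_numpy(dtype=bool)
    if size == n:
        return float(X.any(axis=0).sum()), 0.0
    if rng is None:
        rng = np.random.default_rng()
    counts = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.choice(n, size=size, replace=False)
        counts[i] = X[idx].any(axis=0).sum()
    return float(counts.mean()), float(counts.std(ddof=1))


def binned_pools(
    table: pd.DataFrame,
    diversity: pd.DataFrame,
    width: int = BIN_WIDTH,
    size: int = STANDARD_SIZE,
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin pool estimates over the whole dataset.

    ``diversity`` supplies sample ages and Hill-N0 (for the bin's mean
    richness).  Bins with fewer than ``size`` samples are excluded from
    standardized estimates (reported with NaN mean/SD).  Each bin gets an
    independent RNG substream derived from ``seed``.
    """
    ages = diversity.set_index(["lake_id", "sample_id"])["age"]
    n0 = diversity.set_index(["lake_id", "sample_id"])["n0"]
    pres = presence_matrix(table)
    bins = pd.Series(assign_bins(ages.reindex(pres.index), width), index=pres.index)

    root = np.random.SeedSequence(seed)
    rows = []
    for b, streams in zip(sorted(bins.unique(), reverse=True),
                          root.spawn(len(bins.unique()))):
        sub = pres[bins == b]
        sub = sub.loc[:, sub.any(axis=0)]
        observed = int(sub.shape[1])
        if len(sub) >= 2 and sub.shape[1] >= 2:
            comp, poolset = threshold_beal_pool(sub)
        else:
            comp, poolset = sub, set(sub.columns[sub.any(axis=0)])
        if len(comp) >= size:
            mean, sd = standardized_pool(comp, size, n_resamples,
                                         np.random.default_rng(streams))
        else:
            mean, sd = float("nan"), float("nan")
        rows.append({
            "bin_age": int(b),
            "n_samples": int(len(sub)),
            "observed_pool": observed,
            "completed_pool": len(poolset),
            "standardized_mean": mean,
            "standardized_sd": sd,
            "mean_richness": float(n0.reindex(sub.index).mean()),
        })
    return pd.DataFrame(rows)


def fit_pool_models(bins: pd.DataFrame) -> dict:
    """Temporal trend of the standardized pool and its link to richness.

    Fits (a) standardized pool size on bin age with and without a
    second-order polynomial term, and (b) mean richness per bin on the
    standardized pool.  Reports adjusted R^2, F and p for each.
    """
    ok = bins.dropna(subset=["standardized_mean"])
    if len(ok) < 4:
        raise ValueError("need >=4 usable bins")
    age_ka = ok["bin_age"].to_numpy(dtype=float) / 1000.0
    pool = ok["standardized_mean"].to_numpy(dtype=float)
    rich = ok["mean_richness"].to_numpy(dtype=float)

    X1 = sm.add_constant(age_ka)
    X2 = sm.add_constant(np.column_stack([age_ka, age_ka**2]))
    if np.linalg.matrix_rank(X2) < X2.shape[1]:
        raise ValueError("degenerate design (collinear bin ages)")
    lin = sm.OLS(pool, X1).fit()
    quad = sm.OLS(pool, X2).fit()
    rp = sm.OLS(rich, sm.add_constant(pool)).fit()

    def _summ(res):
        return {
            "params": [float(v) for v in res.params],
            "adj_r2": float(res.rsquared_adj),
            "f": float(res.fvalue),
            "p": float(res.f_pvalue),
            "df": (int(res.df_model), int(res.df_resid)),
        }

    return {"pool_vs_age_linear": _summ(lin),
            "pool_vs_age_poly2": _summ(quad),
            "richness_vs_pool": _summ(rp)}
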