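"""Detectability-weighted Hill diversity and taxon accumulation.

Taxon detectability within a sample is measured by wtRep: the share of
the sample's retained reads carried by the PCR replicates in which the
taxon was detected,

    wtRep = sum of replicate read totals where detected
            / grand total over all replicates,

so detections in deep replicates count for more than detections in
shallow ones.  Replicates with zero retained reads contribute to
neither numerator nor denominator.  Because wtRep overstates
detectability in sparse samples, it is only applied when the sample has
>=10 barcode sequences and a mean detection proportion >=0.33; otherwise
the plain proportion of positive replicates is used (e.g. 2 of 8 = 0.25).

Hill numbers are computed on the normalized detectability profile:
N0 is the taxon count and N1 = exp(-sum p_i log p_i), the exponent of
the Shannon index (effective number of common taxa).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from sedadiv.filtering import rep_cols

WTREP_MIN_MEAN_PROP = 0.33
WTREP_MIN_BARCODES = 10


def wt_rep(detected: np.ndarray, rep_totals: np.ndarray) -> float:
    """Detectability weight for one taxon (read-weighted replicate share)."""
    detected = np.asarray(detected, dtype=bool)
    rep_totals = np.asarray(rep_totals, dtype=float)
    grand = rep_totals.sum()
    if grand <= 0:
        raise ValueError("no retained reads in any replicate")
    return float(rep_totals[detected].sum() / grand)


def replicate_weights(rep_totals: np.ndarray) -> np.ndarray:
    """Per-replicate weights (read shares); zero-read replicates get 0."""
    rep_totals = np.asarray(rep_totals, dtype=float)
    grand = rep_totals.sum()
    if grand <= 0:
        raise ValueError("no retained reads in any replicate")
    return rep_totals / grand


def detectability_row(
    sample_table: pd.DataFrame,
    n_replicates: int | None = None,
    min_mean_prop: float = WTREP_MIN_MEAN_PROP,
    min_barcodes: int = WTREP_MIN_BARCODES,
) -> tuple[pd.Series, str]:
    """Per-taxon detectability values for one sample, plus the mode used.

    ``sample_table`` is the harmonized taxon table restricted to one
    sample (per-replicate read columns present).  Mode is ``"weighted"``
    (wtRep) when the sample has at least ``min_barcodes`` taxa and the
    mean over taxa of (positive replicates / n_replicates) is at least
    ``min_mean_prop``; otherwise ``"plain-proportion"``.
    """
    cols = rep_cols(sample_table)
    if n_replicates is None:
        n_replicates = len(cols)
    reads = sample_table[cols].to_numpy(dtype=float)
    detected = reads > 0
    n_det = detected.sum(axis=1)
    mean_prop = float(n_det.mean() / n_replicates) if len(sample_table) else 0.0

    if len(sample_table) >= min_barcodes and mean_prop >= min_mean_prop:
        rep_totals = reads.sum(axis=0)
        vals = np.array([wt_rep(d, rep_totals) for d in detected])
        mode = "weighted"
    else:
        vals = n_det / n_replicates
        mode = "plain-proportion"
    return pd.Series(vals, index=sample_table["taxon"].to_numpy()), mode


def detectability_matrix(
    table: pd.DataFrame,
    n_replicates: int | None = None,
    min_mean_prop: float = WTREP_MIN_MEAN_PROP,
    min_barcodes: int = WTREP_MIN_BARCODES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Long-format sample x taxon detectability values with per-sample mode."""
    rows, modes = [], {}
    for (lake, sid), sub in table.groupby(["lake_id", "sample_id"], sort=False):
        vals, mode = detectability_row(sub, n_replicates, min_mean_prop, min_barcodes)
        modes[(lake, sid)] = mode
        for taxon, v in vals.items():
            rows.append({"lake_id": lake, "sample_id": sid, "taxon": taxon, "value": v})
    out = pd.DataFrame(rows, columns=["lake_id", "sample_id", "taxon", "value"])
    return out, pd.Series(modes, name="mode")


def hill_n0(values) -> int:
    """Taxon count (Hill number of order 0)."""
    values = np.asarray(values, dtype=float)
    return int((values > 0).sum())


def hill_n1(values) -> float:
    """Exponent of the Shannon index on the normalized profile."""
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        return float("nan")
    p = values / values.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def rarefied_richness(
    counts,
    depth: int,
    n_resamples: int | None = None,
    seed: int | None = None,
) -> float:
    """Expected distinct-taxon count in a random subsample of ``depth`` reads.

    Analytic by default (hypergeometric expectation, no randomness):
    E[S] = sum_i 1 - C(T - x_i, d) / C(T, d).  Passing ``n_resamples``
    switches to Monte-Carlo subsampling without replacement, which
    requires a seed.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth <= 0:
        return 0.0
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if n_resamples is None:
        # log-space binomial ratio, robust for large totals
        logdenom = gammaln(total + 1) - gammaln(total - depth + 1)
        rest = total - counts
        with np.errstate(invalid="ignore"):
            lognum = gammaln(rest + 1) - gammaln(np.maximum(rest - depth, 0) + 1)
        p_absent = np.where(rest >= depth, np.exp(lognum - logdenom), 0.0)
        return float((1.0 - p_absent).sum())
    if seed is None:
        raise ValueError("Monte-Carlo rarefaction requires a seed")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(counts.size), counts)
    vals = [np.unique(rng.choice(pool, size=depth, replace=False)).size
            for _ in range(n_resamples)]
    return float(np.mean(vals))


def correlate_rarefied(lake_diversity: pd.DataFrame) -> float:
    """Pearson r between rarefied richness and Hill-N0 across a lake's samples."""
    if len(lake_diversity) < 3:
        raise ValueError("need >=3 samples to correlate")
    x = lake_diversity["rarefied"].to_numpy(dtype=float)
    y = lake_diversity["n0"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def accumulated_richness(table: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Cumulative distinct-taxon curve, samples ordered oldest to youngest.

    ``table`` is a harmonized taxon table; ``ages`` maps
    (lake_id, sample_id) -> age in cal yr BP.  Ties in age are broken by
    sample id for determinism.  Returns one row per sample with its age
    and the cumulative taxon count.
    """
    key = pd.MultiIndex.from_frame(table[["lake_id", "sample_id"]])
    work = table.assign(_age=ages.reindex(key).to_numpy())
    order = (
        work[["lake_id", "sample_id", "_age"]]
        .drop_duplicates()
        .sort_values(["_age", "lake_id", "sample_id"], ascending=[False, True, True],
                     kind="mergesort")
    )
    seen: set = set()
    rows = []
    taxa_by_sample = work.groupby(["lake_id", "sample_id"])["taxon"].agg(set)
    for _, r in order.iterrows():
        seen |= taxa_by_sample[(r["lake_id"], r["sample_id"])]
        rows.append({"lake_id": r["lake_id"], "sample_id": r["sample_id"],
                     "age": r["_age"], "cumulative_taxa": len(seen)})
    return pd.DataFrame(rows)


def sample_diversity_table(
    table: pd.DataFrame,
    ages: pd.Series,
    n_replicates: int | None = None,
    rarefy: bool = True,
) -> pd.DataFrame:
    """Per-sample diversity summary (N0, N1, rarefied richness, mode).

    Rarefaction depth is the lowest total read count of any sample within
    the same lake, per the within-lake standardization convention.
    """
    det, modes = detectability_matrix(table, n_replicates)
    reads = table.groupby(["lake_id", "sample_id"])["reads"].sum()
    depth_by_lake = reads.groupby("lake_id").min()

    rows = []
    for (lake, sid), sub in det.groupby(["lake_id", "sample_id"], sort=False):
        vals = sub["value"].to_numpy()
        row = {
            "lake_id": lake,
            "sample_id": sid,
            "age": float(ages.get((lake, sid), np.nan)),
            "n0": hill_n0(vals),
            "n1": hill_n1(vals),
            "mode": modes[(lake, sid)],
        }
        if rarefy:
            cnts = table[(table["lake_id"] == lake) & (table["sample_id"] == sid)]["reads"]
            row["rarefied"] = rarefied_richness(cnts.to_numpy(), int(depth_by_lake[lake]))
        rows.append(row)
    return pd.DataFrame(rows)
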