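"""Per-sample replication quality scores (MTQ/MAQ), gating and diagnostics.

Both scores summarize how reliably a sample's 10 most read-abundant
amplicon sequences replicate across its PCR replicates (out of a possible
10 x n_replicates detections, i.e. 80 for 8 replicates):

* MTQ (metabarcoding technical quality) is computed before any taxonomic
  identification, over all sequences surviving the per-replicate
  low-count filter.
* MAQ (metabarcoding analytical quality) is the same statistic over the
  taxonomically identified, blacklist-cleaned sequences only.

A sample passes QC iff MTQ >= 0.75 (>=60 detections of 80) and
MAQ >= 0.2 (>=16 detections).  Divergence between the two scores flags
co-amplification of unidentified or contaminant sequences.  Samples with
fewer than 10 sequences keep the full 10 x n_replicates denominator, so
low-richness samples are penalized by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sedadiv.filtering import rep_cols

MTQ_THRESHOLD = 0.75
MAQ_THRESHOLD = 0.2
TOP_N = 10


def _top_n_detections(sample: pd.DataFrame, n_replicates: int, top_n: int = TOP_N) -> int:
    """Positive replicate cells among the ``top_n`` most read-abundant sequences.

    Ties at the read-count boundary are broken by lexicographic
    ``sequence_id`` so the score is independent of row order.
    """
    if len(sample) == 0:
        return 0
    cols = rep_cols(sample)
    work = sample.assign(_total=sample[cols].sum(axis=1))
    work = work.sort_values(["_total", "sequence_id"], ascending=[False, True], kind="mergesort")
    top = work.head(top_n)
    return int((top[cols] > 0).to_numpy().sum())


def mtq_score(sample: pd.DataFrame, n_replicates: int = 8) -> tuple[float, int]:
    """MTQ score and its detection count for one sample.

    ``sample`` holds the sample's sequences after per-replicate filtering,
    before identification.  Missing top-10 slots contribute zero
    detections; an empty sample scores 0.
    """
    det = _top_n_detections(sample, n_replicates)
    return det / (TOP_N * n_replicates), det


def maq_score(sample_identified: pd.DataFrame, n_replicates: int = 8) -> tuple[float, int]:
    """MAQ score over the identified, blacklist-cleaned sequences."""
    det = _top_n_detections(sample_identified, n_replicates)
    return det / (TOP_N * n_replicates), det


def gate_samples(
    qc: pd.DataFrame,
    mtq_threshold: float = MTQ_THRESHOLD,
    maq_threshold: float = MAQ_THRESHOLD,
) -> pd.DataFrame:
    """Add the boolean ``passed`` column (both thresholds met, inclusive)."""
    out = qc.copy()
    out["passed"] = (out["mtq"] >= mtq_threshold) & (out["maq"] >= maq_threshold)
    return out


def select_extraction_replicate(extract_qc: pd.DataFrame) -> pd.DataFrame:
    """Pick one DNA extract per sample: greatest MAQ, ties to extract 1.

    ``extract_qc`` needs columns ``sample_id``, ``extract`` (1-based
    extraction replicate number) and ``maq``; returns the chosen rows.
    """
    if len(extract_qc) == 0:
        return extract_qc.copy()
    work = extract_qc.sort_values(["sample_id", "maq", "extract"], ascending=[True, False, True],
                                  kind="mergesort")
    return work.groupby("sample_id", sort=False).head(1).reset_index(drop=True)


def quality_diagnostics(
    raw_sample: pd.DataFrame,
    retained_sample: pd.DataFrame,
    terrestrial_reads: float,
    read_weighted_length: bool = False,
) -> dict:
    """Per-sample data-quality diagnostics.

    Returns total raw reads (summed across replicates, pre-filter), mean
    barcode length over distinct retained barcodes (optionally
    read-weighted) and the proportion of raw reads assigned to
    terrestrial taxa.  With zero raw reads the proportions are missing.
    """
    raw_total = int(raw_sample[rep_cols(raw_sample)].to_numpy().sum()) if len(raw_sample) else 0
    if len(retained_sample):
        lengths = retained_sample["dna"].str.len().to_numpy(dtype=float)
        if read_weighted_length:
            w = retained_sample[rep_cols(retained_sample)].sum(axis=1).to_numpy(dtype=float)
            mean_len = float(np.average(lengths, weights=w)) if w.sum() > 0 else float("nan")
        else:
            # unweighted over distinct barcodes
            mean_len = float(retained_sample.drop_duplicates("dna")["dna"].str.len().mean())
    else:
        mean_len = float("nan")
    prop_terr = terrestrial_reads / raw_total if raw_total > 0 else float("nan")
    return {
        "total_raw_reads": raw_total,
        "mean_barcode_length": mean_len,
        "prop_terrestrial_reads": prop_terr,
    }


def sample_qc_table(
    raw: pd.DataFrame,
    postfilter: pd.DataFrame,
    clean_identified: pd.DataFrame,
    n_replicates: int = 8,
    mtq_threshold: float = MTQ_THRESHOLD,
    maq_threshold: float = MAQ_THRESHOLD,
) -> pd.DataFrame:
    """Score every sample (and control) in the dataset.

    ``raw`` is the unfiltered counts table, ``postfilter`` the output of
    the per-replicate filter (MTQ candidate pool) and ``clean_identified``
    the identified, blacklist-cleaned records (MAQ candidate pool).
    """
    keys = ["lake_id", "sample_id", "sample_type"]
    samples = raw[keys].drop_duplicates().reset_index(drop=True)

    terr = clean_identified[clean_identified["group"] == "terrestrial"]
    terr_reads = terr.groupby(["lake_id", "sample_id"])[rep_cols(raw)].sum().sum(axis=1)

    rows = []
    for _, key in samples.iterrows():
        sel = lambda df: df[(df["lake_id"] == key["lake_id"]) & (df["sample_id"] == key["sample_id"])]
        mtq, n_mtq = mtq_score(sel(postfilter), n_replicates)
        maq, n_maq = maq_score(sel(clean_identified), n_replicates)
        diag = quality_diagnostics(
            sel(raw), sel(postfilter),
            float(terr_reads.get((key["lake_id"], key["sample_id"]), 0.0)),
        )
        rows.append({**key.to_dict(), "mtq": mtq, "n_detections_mtq": n_mtq,
                     "maq": maq, "n_detections_maq": n_maq, **diag})
    return gate_samples(pd.DataFrame(rows), mtq_threshold, maq_threshold)
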