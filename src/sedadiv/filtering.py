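"""Sequence filtering and taxonomic harmonization.

Transforms raw per-replicate amplicon counts into a harmonized taxon table.
The stages run in a pinned order:

1. per-replicate low-count removal (cells with <3 reads zeroed),
2. exact-match taxonomic assignment against the reference database,
3. blacklist removal (synthetic controls, curated false positives),
4. dataset-wide low-frequency removal (<10 reads or <3 positive replicate
   cells summed over the whole dataset),
5. merging of co-occurring barcodes assigned to the same taxon,
6. exclusion of non-target taxa (above-family ranks, aquatic plants, algae).

Input tables are long-format pandas DataFrames with one row per
(sample, barcode sequence) and one integer column per PCR replicate
(``rep_1`` ... ``rep_n``); ``dna`` holds the barcode sequence and is the
identity key used across samples and lakes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from sedadiv.reference import ReferenceDatabase

REP_PREFIX = "rep_"

#: identity/grouping columns expected on a counts table
KEY_COLUMNS = ("lake_id", "sample_id", "sample_type", "sequence_id", "dna")


def rep_cols(df: pd.DataFrame) -> list:
    """Replicate count columns, in replicate order."""
    cols = [c for c in df.columns if c.startswith(REP_PREFIX)]
    return sorted(cols, key=lambda c: int(c[len(REP_PREFIX):]))


def filter_per_replicate_low_count(records: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Zero out replicate cells with fewer than ``min_reads`` reads.

    Sequences whose counts become all-zero within a sample are dropped.
    The default retains cells with >=3 reads, i.e. removes sequences
    represented by <=2 reads in a replicate.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    cols = rep_cols(records)
    out = records.copy()
    vals = out[cols].to_numpy()
    vals[vals < min_reads] = 0
    out[cols] = vals
    return out[vals.sum(axis=1) > 0].reset_index(drop=True)


def resolve_vaccinium(
    dna: str,
    short_taxon: str = "Vaccinium myrtillus",
    long_taxon: str = "Vaccinium vitis-idaea",
    genus_taxon: str = "Vaccinium",
) -> str:
    """Resolve a poly-A-group barcode by its 3' poly-A run length.

    Two congeners differ only in the terminal homopolymer: a run of <=5
    A's identifies *V. myrtillus* and a run of >8 A's *V. vitis-idaea*.
    Intermediate lengths (6-8) are only resolvable to genus level.  A
    barcode with no terminal A counts as run length 0.
    """
    n = len(dna) - len(dna.rstrip("A"))
    if n <= 5:
        return short_taxon
    if n > 8:
        return long_taxon
    return genus_taxon


def assign_taxonomy_exact(
    records: pd.DataFrame, refdb: ReferenceDatabase
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into identified and unidentified by exact matching.

    A record is identified iff its ``dna`` string is byte-identical to a
    reference barcode, or its 3'-A-stripped stem matches a poly-A-group
    stem (then the taxon is resolved by :func:`resolve_vaccinium`).
    Identified records gain ``taxon``, ``rank`` and ``group`` columns;
    unidentified records are returned separately because they still feed
    the MTQ score and read-proportion diagnostics.
    """
    if len(refdb.taxonomy) == 0:
        raise ValueError("reference database is empty")
    tax = refdb.taxonomy
    stems = refdb.polya_stems()

    dna = records["dna"]
    exact = dna.isin(tax.index)
    polya = ~exact & dna.str.rstrip("A").isin(stems) & dna.str.rstrip("A").ne("")
    ident = records[exact | polya].copy()
    unident = records[~(exact | polya)].copy()

    is_exact = ident["dna"].isin(tax.index)
    ident["taxon"] = ""
    ident["rank"] = ""
    ident["group"] = ""
    ident.loc[is_exact, "taxon"] = tax.loc[ident.loc[is_exact, "dna"], "taxon"].to_numpy()
    ident.loc[is_exact, "rank"] = tax.loc[ident.loc[is_exact, "dna"], "rank"].to_numpy()
    ident.loc[is_exact, "group"] = tax.loc[ident.loc[is_exact, "dna"], "group"].to_numpy()

    # poly-A group (including the exact-matching members): rule overrides lookup
    in_group = ident["dna"].str.rstrip("A").isin(stems)
    if in_group.any():
        resolved = ident.loc[in_group, "dna"].map(resolve_vaccinium)
        ident.loc[in_group, "taxon"] = resolved.to_numpy()
        ident.loc[in_group, "rank"] = np.where(resolved.str.contains(" "), "species", "genus")
        ident.loc[in_group, "group"] = "terrestrial"
    return ident.reset_index(drop=True), unident.reset_index(drop=True)


def apply_blacklists(records: pd.DataFrame, refdb: ReferenceDatabase) -> pd.DataFrame:
    """Remove records whose sequence exactly matches any blacklist entry."""
    bl = refdb.blacklist
    if not bl:
        return records.reset_index(drop=True)
    return records[~records["dna"].isin(bl)].reset_index(drop=True)


def filter_dataset_wide(
    records: pd.DataFrame,
    min_total_reads: int = 10,
    min_total_replicates: int = 3,
    scope: str = "dataset",
) -> pd.DataFrame:
    """Drop sequences that are rare over the whole dataset.

    A sequence survives iff, summed over every sample (and lake), it has
    at least ``min_total_reads`` reads AND at least ``min_total_replicates``
    positive replicate cells.  ``scope='lake'`` applies the same rule
    within each lake instead (sensitivity analysis; strictly more
    aggressive).
    """
    cols = rep_cols(records)
    work = records.assign(
        _reads=records[cols].sum(axis=1),
        _cells=(records[cols] > 0).sum(axis=1),
    )
    keys = ["dna"] if scope == "dataset" else ["lake_id", "dna"]
    agg = work.groupby(keys)[["_reads", "_cells"]].sum()
    ok = agg[(agg["_reads"] >= min_total_reads) & (agg["_cells"] >= min_total_replicates)].index
    if scope == "dataset":
        keep = work["dna"].isin(ok)
    else:
        keep = pd.MultiIndex.from_frame(work[keys]).isin(ok)
    return records[np.asarray(keep)].reset_index(drop=True)


def merge_cooccurring_barcodes(identified: pd.DataFrame) -> pd.DataFrame:
    """Merge same-taxon barcodes that co-occur within samples.

    Barcodes assigned to the same taxon name are assumed to represent the
    same taxon when they co-occur in at least one sample (directly or
    through a chain of co-occurrences); their reads are summed per
    replicate, so the per-replicate detection set is the union of the
    inputs.  Same-name barcodes that never co-occur remain separate taxa
    and receive sequential numeric suffixes (e.g. ``Asteraceae1``,
    ``Asteraceae2``).

    Returns a harmonized taxon table: one row per (sample, taxon) with
    per-replicate summed reads, total ``reads`` and ``n_replicates``
    (count of positive replicate cells).
    """
    cols = rep_cols(identified)
    work = identified.copy()
    work["_mtaxon"] = work["taxon"]

    for taxon, sub in identified.groupby("taxon", sort=False):
        barcodes = sub["dna"].unique()
        if len(barcodes) < 2:
            continue
        bidx = {b: i for i, b in enumerate(barcodes)}
        skey = sub["lake_id"].astype(str) + "\t" + sub["sample_id"].astype(str)
        sidx = {s: i for i, s in enumerate(skey.unique())}
        inc = np.zeros((len(bidx), len(sidx)), dtype=np.int64)
        inc[sub["dna"].map(bidx), skey.map(sidx)] = 1
        adj = csr_matrix(inc @ inc.T > 0)
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            continue
        # deterministic suffix order: by lexicographically smallest member barcode
        order = sorted(range(n_comp), key=lambda c: min(barcodes[labels == c]))
        suffix = {comp: rank + 1 for rank, comp in enumerate(order)}
        name_of = {b: f"{taxon}{suffix[labels[bidx[b]]]}" for b in barcodes}
        mask = work["taxon"] == taxon
        work.loc[mask, "_mtaxon"] = work.loc[mask, "dna"].map(name_of)

    keys = ["lake_id", "sample_id", "sample_type", "_mtaxon"]
    merged = (
        work.groupby(keys, sort=False)
        .agg(**{c: (c, "sum") for c in cols}, rank=("rank", "first"), group=("group", "first"))
        .reset_index()
        .rename(columns={"_mtaxon": "taxon"})
    )
    merged["reads"] = merged[cols].sum(axis=1)
    merged["n_replicates"] = (merged[cols] > 0).sum(axis=1)
    return merged


def exclude_nontarget(table: pd.DataFrame, refdb: ReferenceDatabase | None = None) -> pd.DataFrame:
    """Retain only terrestrial taxa identified at family level or below.

    Drops algae, aquatic/wetland plants and any barcode only identifiable
    above the family level; the survivors are the terrestrial vascular
    plants and bryophytes on which all diversity analyses run.
    """
    keep = (table["group"] == "terrestrial") & (table["rank"] != "above-family")
    return table[keep].reset_index(drop=True)


def harmonize(
    records: pd.DataFrame,
    refdb: ReferenceDatabase,
    min_reads: int = 3,
    min_total_reads: int = 10,
    min_total_replicates: int = 3,
    scope: str = "dataset",
) -> dict:
    """Run the full filtering chain in the pinned order.

    Returns a dict with every intermediate needed downstream:
    ``postfilter`` (after per-replicate filter), ``identified`` /
    ``unidentified`` (after taxonomy), ``clean`` (after blacklists),
    ``retained`` (after dataset-wide filter), ``taxon_table`` (merged) and
    ``final`` (after non-target exclusion).
    """
    postfilter = filter_per_replicate_low_count(records, min_reads=min_reads)
    identified, unidentified = assign_taxonomy_exact(postfilter, refdb)
    clean = apply_blacklists(identified, refdb)
    retained = filter_dataset_wide(
        clean, min_total_reads=min_total_reads,
        min_total_replicates=min_total_replicates, scope=scope,
    )
    taxon_table = merge_cooccurring_barcodes(retained)
    final = exclude_nontarget(taxon_table, refdb)
    return {
        "postfilter": postfilter,
        "identified": identified,
        "unidentified": unidentified,
        "clean": clean,
        "retained": retained,
        "taxon_table": taxon_table,
        "final": final,
    }
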