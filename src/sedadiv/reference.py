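"""Barcode reference database: sequence -> taxonomy lookup plus blacklists.

The database maps exact barcode sequences (trnL p6-loop style short
amplicons) to a taxon name, a taxonomic rank and an ecological group, and
carries two blacklists of known false-positive sequences (synthetic
control sequences and curated false positives such as homopolymer variants
of dominant barcodes).  A blacklisted sequence may also be present in the
database; the blacklist wins.

Two congeneric dwarf-shrub species (*Vaccinium myrtillus* and
*V. vitis-idaea*) share a barcode that differs only in the length of a
3' poly-A run; such barcodes are resolved by a poly-A length rule rather
than by exact lookup (see :func:`sedadiv.filtering.resolve_vaccinium`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RANKS = ("species", "genus", "family", "above-family")
GROUPS = ("terrestrial", "aquatic", "alga")

#: taxonomy table columns, in file order
TAXONOMY_COLUMNS = ("barcode_id", "taxon", "rank", "group", "polya_group")


@dataclass(frozen=True)
class ReferenceDatabase:
    """Exact-match barcode reference with blacklists.

    Parameters
    ----------
    taxonomy
        One row per barcode, indexed by the barcode DNA string, with
        columns ``barcode_id``, ``taxon``, ``rank``, ``group`` and the
        boolean ``polya_group`` marking barcodes resolved by the
        3' poly-A rule.
    blacklist_synthetic, blacklist_false_positive
        Sets of DNA strings removed wherever they occur.
    """

    taxonomy: pd.DataFrame
    blacklist_synthetic: frozenset = frozenset()
    blacklist_false_positive: frozenset = frozenset()

    def __post_init__(self):
        missing = [c for c in ("barcode_id", "taxon", "rank", "group") if c not in self.taxonomy.columns]
        if missing:
            raise ValueError(f"taxonomy table missing columns: {missing}")
        if "polya_group" not in self.taxonomy.columns:
            self.taxonomy["polya_group"] = False
        bad_rank = set(self.taxonomy["rank"]) - set(RANKS)
        if bad_rank:
            raise ValueError(f"unknown ranks: {sorted(bad_rank)}")
        bad_group = set(self.taxonomy["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown ecological groups: {sorted(bad_group)}")

    # -- lookups ---------------------------------------------------------
    @property
    def barcodes(self) -> frozenset:
        return frozenset(self.taxonomy.index)

    @property
    def blacklist(self) -> frozenset:
        return self.blacklist_synthetic | self.blacklist_false_positive

    def polya_stems(self) -> frozenset:
        """3'-A-stripped stems of the poly-A-resolved barcode group."""
        grp = self.taxonomy.index[self.taxonomy["polya_group"].astype(bool)]
        return frozenset(s.rstrip("A") for s in grp)

    def __contains__(self, dna: str) -> bool:
        return dna in self.taxonomy.index

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_files(
        cls,
        fasta_path: str | Path,
        taxonomy_path: str | Path,
        blacklist_synthetic_path: str | Path | None = None,
        blacklist_false_positive_path: str | Path | None = None,
    ) -> "ReferenceDatabase":
        """Load from a FASTA of barcode sequences plus a taxonomy TSV.

        FASTA record ids must match the taxonomy ``barcode_id`` column
        exactly; an orphan id on either side is an error.
        """
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype={"barcode_id": str})
        if "polya_group" in tax.columns:
            tax["polya_group"] = tax["polya_group"].astype(bool)
        orphans = set(seqs) ^ set(tax["barcode_id"])
        if orphans:
            raise ValueError(f"FASTA ids and taxonomy rows disagree: {sorted(orphans)[:5]}")
        tax = tax.set_index(tax["barcode_id"].map(seqs))
        tax.index.name = "dna"
        return cls(
            taxonomy=tax,
            blacklist_synthetic=_read_seq_list(blacklist_synthetic_path),
            blacklist_false_positive=_read_seq_list(blacklist_false_positive_path),
        )

    def to_files(
        self,
        fasta_path: str | Path,
        taxonomy_path: str | Path,
        blacklist_synthetic_path: str | Path | None = None,
        blacklist_false_positive_path: str | Path | None = None,
    ) -> None:
        records = [
            SeqRecord(Seq(dna), id=row["barcode_id"], description=row["taxon"].replace(" ", "_"))
            for dna, row in self.taxonomy.iterrows()
        ]
        SeqIO.write(records, str(fasta_path), "fasta")
        out = self.taxonomy.reset_index(drop=True)[list(TAXONOMY_COLUMNS)]
        out.to_csv(taxonomy_path, sep="\t", index=False)
        if blacklist_synthetic_path is not None:
            _write_seq_list(blacklist_synthetic_path, self.blacklist_synthetic)
        if blacklist_false_positive_path is not None:
            _write_seq_list(blacklist_false_positive_path, self.blacklist_false_positive)


def _read_seq_list(path) -> frozenset:
    if path is None:
        return frozenset()
    lines = Path(path).read_text().split()
    return frozenset(s.strip().upper() for s in lines if s.strip())


def _write_seq_list(path, seqs) -> None:
    Path(path).write_text("\n".join(sorted(seqs)) + "\n")
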