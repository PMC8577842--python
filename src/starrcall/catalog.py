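"""Amplicon catalog: library membership, coordinates, GC content, in-silico PCR.

The unit of analysis is the *amplicon*, a ~900 bp PCR-cloned candidate
regulatory sequence.  Amplicons carry a group label (how the candidate was
selected: GWAS lead-SNP interval, LD expansion of a lead SNP, fetal-brain DNase
hypersensitive site, previously tested putative enhancer) and an ascertainment
flag marking candidates selected with prior open-chromatin evidence.
Coordinates are 0-based half-open throughout (BED convention); 1-based
coordinates appear only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

GROUPS = ("GWAS", "LD", "FBDHS", "PutEnh", "other")

CATALOG_COLUMNS = [
    "amplicon_id",
    "chrom",
    "start",
    "end",
    "group",
    "gc",
    "ascertained_enhancer",
]


class CatalogError(ValueError):
    """Raised when a catalog violates its invariants."""


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide sequence.

    Case-insensitive; ambiguity codes (anything not A/C/G/T) are excluded from
    both numerator and denominator, so the estimate is unbiased on masked
    sequence.

    Raises
    ------
    ValueError
        If the sequence contains no A/C/G/T characters.
    """
    s = sequence.upper()
    a = s.count("A")
    c = s.count("C")
    g = s.count("G")
    t = s.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T characters")
    return (g + c) / denom


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """Genomic-priming portions of a primer pair (homology tails stripped).

    Cloning primers carry vector-homology tails that do not prime the genome;
    only the genomic 3' portions belong here.
    """

    amplicon_id: str
    forward: str
    reverse: str
    min_product: int
    max_product: int

    def __post_init__(self) -> None:
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primer lengths must be >= 10 nt")
        if self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


@dataclass(frozen=True)
class PcrProduct:
    start: int
    end: int  # half-open
    strand: str  # '+' if the forward primer primes the plus strand

    @property
    def length(self) -> int:
        return self.end - self.start


def _mismatches(text: str, pos: int, pattern: str, limit: int) -> int:
    mm = 0
    for i, ch in enumerate(pattern):
        if text[pos + i] != ch:
            mm += 1
            if mm > limit:
                break
    return mm


def _match_sites(text: str, pattern: str, max_mismatches: int) -> list[int]:
    k = len(pattern)
    return [
        i
        for i in range(len(text) - k + 1)
        if _mismatches(text, i, pattern, max_mismatches) <= max_mismatches
    ]


def in_silico_pcr(
    reference: str, primers: PrimerPair, max_mismatches: int = 0
) -> list[PcrProduct]:
    """Predict PCR products of a primer pair on a reference sequence.

    A product requires a forward-primer match at its 5' end and a
    reverse-complemented reverse-primer match at its 3' end (each with at most
    ``max_mismatches`` mismatches) with total length inside
    ``[min_product, max_product]``.  Both priming orientations are scanned;
    ``strand`` records which strand the forward primer primes.  Products are
    returned in ascending (start, end) order; no match yields an empty list.
    """
    ref = reference.upper()
    fwd = primers.forward.upper()
    rev = primers.reverse.upper()
    lo, hi = primers.min_product, primers.max_product

    products: set[PcrProduct] = set()
    for five, three, strand in (
        (fwd, reverse_complement(rev), "+"),
        (rev, reverse_complement(fwd), "-"),
    ):
        starts = _match_sites(ref, five, max_mismatches)
        ends = _match_sites(ref, three, max_mismatches)
        for s in starts:
            for e in ends:
                end = e + len(three)
                length = end - s
                if e >= s + len(five) and lo <= length <= hi:
                    products.add(PcrProduct(s, end, strand))
    return sorted(products, key=lambda p: (p.start, p.end, p.strand))


@dataclass
class AmpliconCatalog:
    """The amplicon library: one row per amplicon, optional sequences.

    Invariants: unique ``amplicon_id``; ``end > start``; ``gc`` in [0, 1];
    where a sequence is attached its GC content must equal the ``gc`` column.
    """

    table: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.table.columns]
        if missing:
            raise CatalogError(f"catalog missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if t["amplicon_id"].duplicated().any():
            raise CatalogError("amplicon_id values must be unique")
        if (t["end"] <= t["start"]).any():
            raise CatalogError("every amplicon must satisfy end > start")
        if ((t["gc"] < 0) | (t["gc"] > 1)).any():
            raise CatalogError("gc must lie in [0, 1]")
        bad_groups = set(t["group"]) - set(GROUPS)
        if bad_groups:
            raise CatalogError(f"unknown group labels: {sorted(bad_groups)}")
        for aid, seq in self.sequences.items():
            row = t.loc[t["amplicon_id"] == aid]
            if len(row) and abs(gc_content(seq) - float(row["gc"].iloc[0])) > 1e-9:
                raise CatalogError(f"sequence GC does not match gc column for {aid}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.table["amplicon_id"])

    def gc(self) -> pd.Series:
        return self.table.set_index("amplicon_id")["gc"]

    def groups(self) -> pd.Series:
        return self.table.set_index("amplicon_id")["group"]

    def ascertained(self) -> pd.Series:
        return self.table.set_index("amplicon_id")["ascertained_enhancer"].astype(bool)

    def intervals(self) -> Iterable[tuple[str, str, int, int]]:
        for row in self.table.itertuples(index=False):
            yield row.amplicon_id, row.chrom, int(row.start), int(row.end)

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, path: str | Path, fasta: str | Path | None = None
    ) -> "AmpliconCatalog":
        table = pd.read_csv(path, sep="\t", comment="#")
        table["ascertained_enhancer"] = table["ascertained_enhancer"].astype(bool)
        sequences: dict[str, str] = {}
        if fasta is not None:
            sequences = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
            }
        return cls(table, sequences)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_bed(self, path: str | Path) -> None:
        bed = self.table[["chrom", "start", "end", "amplicon_id"]]
        bed.to_csv(path, sep="\t", index=False, header=False)


def attach_sequences(
    catalog: AmpliconCatalog, records: Sequence[tuple[str, str]]
) -> AmpliconCatalog:
    """Return a catalog with sequences attached and GC recomputed from them."""
    seqs = dict(records)
    table = catalog.table.copy()
    gc = table["amplicon_id"].map(
        lambda a: gc_content(seqs[a]) if a in seqs else None
    )
    table["gc"] = gc.where(gc.notna(), table["gc"])
    return AmpliconCatalog(table, seqs)
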