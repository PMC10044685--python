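"""Readers and writers for the pipeline's file dialects.

FASTA is read through Biopython.  The reference library is a FASTA plus a
tab-separated metadata table joined on accession.  The sample table mirrors
the verification-report layout: one row per barcoded individual with its
field identification, best database match with annotation marker, percent
identity, tree match, and consensus identification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .taxonomy import Lineage, Taxonomy

VALID_MARKERS = {"", "DS", "LS", "MM", "MU", "R"}
IUPAC = set("ACGTRYSWKMBDHVN-")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class BarcodeSequence:
    """One aligned CO1 barcode fragment."""

    id: str
    seq: str
    location: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.id:
            raise FormatError("empty sequence id")
        if not self.seq:
            raise FormatError(f"{self.id}: empty sequence")
        bad = set(self.seq) - IUPAC
        if bad:
            raise FormatError(
                f"{self.id}: non-IUPAC symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceRecord:
    """A curated reference barcode with its deposited label and lineage."""

    accession: str
    label: str
    lineage: Lineage
    seq: BarcodeSequence
    trusted: bool = True


@dataclass
class TabulatedMatchRecord:
    """One row of the per-sample verification table."""

    sample: str
    location: str
    accession: str
    field_id: str
    best_match: str
    marker: str  # "", DS, LS, MM, MU or R
    ncbi_pct: float
    bold_match: str = ""
    bold_pct: float | None = None
    tree_match: str = ""
    consensus: str = ""
    inconclusive: bool = False

    def __post_init__(self):
        if self.marker not in VALID_MARKERS:
            raise FormatError(
                f"{self.sample}: unknown marker {self.marker!r}")
        if not 0.0 <= self.ncbi_pct <= 100.0:
            raise FormatError(
                f"{self.sample}: percent identity out of range")


def read_sequences(path: str | Path) -> list[BarcodeSequence]:
    """Read a FASTA file into a list of barcode sequences, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(BarcodeSequence(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_sequences(seqs: list[BarcodeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.seq}\n")


def read_reference_library(
    fasta: str | Path,
    meta: str | Path,
    trusted_only: bool = False,
) -> list[ReferenceRecord]:
    """Join a reference FASTA with its taxonomy metadata TSV on accession.

    Metadata columns: accession, label, species, genus, subfamily, family,
    order, infraclass, class, trusted.  Every FASTA id must appear in the
    metadata; the reverse is not required (metadata may cover more).
    """
    seqs = read_sequences(fasta)
    rows = {}
    with open(meta, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows[row["accession"]] = row
    missing = [s.id for s in seqs if s.id not in rows]
    if missing:
        raise FormatError(
            f"FASTA ids missing from metadata: {', '.join(missing)}")
    records = []
    for s in seqs:
        row = rows[s.id]
        lin = Lineage(
            species=row["species"],
            genus=row["genus"],
            subfamily=row.get("subfamily", "") or "",
            family=row["family"],
            order=row["order"],
            infraclass=row.get("infraclass", "") or "",
            class_=row["class"],
        )
        trusted = row.get("trusted", "1").strip().lower() not in (
            "0", "false", "no")
        if trusted_only and not trusted:
            continue
        records.append(ReferenceRecord(
            accession=s.id, label=row.get("label", lin.species) or
            lin.species, lineage=lin, seq=s, trusted=trusted))
    return records


_SAMPLE_COLUMNS = [
    "sample", "location", "accession", "field_id", "best_match", "marker",
    "ncbi_pct", "bold_match", "bold_pct", "tree_match", "consensus",
    "inconclusive",
]


def read_sample_table(path: str | Path) -> list[TabulatedMatchRecord]:
    """Read a verification-table TSV into records."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(
                ("sample", "field_id", "best_match", "ncbi_pct")
        ).issubset(reader.fieldnames):
            raise FormatError(f"{path}: not a sample-table TSV")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(TabulatedMatchRecord(
                    sample=row["sample"],
                    location=row.get("location", ""),
                    accession=row.get("accession", ""),
                    field_id=row["field_id"],
                    best_match=row["best_match"],
                    marker=row.get("marker", "") or "",
                    ncbi_pct=float(row["ncbi_pct"]),
                    bold_match=row.get("bold_match", ""),
                    bold_pct=float(row["bold_pct"])
                    if row.get("bold_pct") else None,
                    tree_match=row.get("tree_match", "") or "",
                    consensus=row.get("consensus", ""),
                    inconclusive=row.get("inconclusive", "0").strip()
                    in ("1", "true", "True"),
                ))
            except (FormatError, ValueError) as err:
                raise FormatError(f"{path} line {i}: {err}") from err
    return out


def write_sample_table(
    records: list[TabulatedMatchRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SAMPLE_COLUMNS)
        for r in records:
            w.writerow([
                r.sample, r.location, r.accession, r.field_id, r.best_match,
                r.marker, _fmt_pct(r.ncbi_pct), r.bold_match,
                _fmt_pct(r.bold_pct) if r.bold_pct is not None else "",
                r.tree_match, r.consensus, int(r.inconclusive),
            ])


def _fmt_pct(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s


def packaged_sample_table() -> list[TabulatedMatchRecord]:
    """The study's per-sample verification table shipped with the package."""
    ref = resources.files("elasmobarcode.data") / "sample_table.tsv"
    with resources.as_file(ref) as path:
        return read_sample_table(path)


def packaged_taxonomy() -> Taxonomy:
    return Taxonomy.packaged()
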