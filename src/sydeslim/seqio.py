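"""Sequence and interval-annotation I/O.

All residue coordinates in this package are 1-based and inclusive at both
ends, matching the superscript convention used when motif instances are
written as, e.g., ``^177^RRRLSLR^183^``.  Conversion to 0-based half-open
indices happens only at the boundary with Python slicing, inside this
module and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: letters tolerated in stored sequences; X never matches any motif class
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")

REGION_LABELS = ("C2", "RhoGAP", "disorder", "NES", "palmitoylation-site", "custom")

_TSV_COLUMNS = ["protein_id", "label", "start", "end", "source"]


class SeqIOError(ValueError):
    """Malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id : str
        Short label (for UniProt-style headers, the entry name).
    accession : str
        UniProt-style accession, or ``""`` when the header carries none.
    species : str
        Free-text species tag.
    sequence : str
        Residues over the 20 amino-acid letters plus X; stored upper-case.
    """

    id: str
    accession: str = ""
    species: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for pos, letter in enumerate(seq, start=1):
            if letter not in ALLOWED_LETTERS:
                raise SeqIOError(
                    f"record {self.id!r}: illegal character {letter!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled interval on a protein, 1-based inclusive.

    A point annotation (e.g. a palmitoylation site) has ``start == end``.
    """

    protein_id: str
    label: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SeqIOError(
                f"annotation {self.protein_id}/{self.label}: bad interval "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA header into (id, accession, species).

    UniProt dialects ``sp|ACC|NAME`` and ``tr|ACC|NAME`` are recognized;
    any other header keeps its first whitespace token as the id with an
    empty accession.  An ``OS=...`` field, when present, becomes the
    species tag.
    """
    token = header.split()[0]
    species = ""
    if " OS=" in header:
        species = header.split(" OS=", 1)[1].split(" OX=")[0].split(" GN=")[0].strip()
    parts = token.split("|")
    if len(parts) == 3 and parts[0] in ("sp", "tr"):
        return parts[2], parts[1], species
    return token, "", species


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved.  Raises :class:`SeqIOError` on an empty file or on
    residues outside the 20 amino acids + X (the offending record and
    position are named).
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, accession, species = _parse_header(rec.description)
        records.append(
            ProteinRecord(id=rid, accession=accession, species=species,
                          sequence=str(rec.seq))
        )
    if not records:
        raise SeqIOError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 columns per line.

    UniProt-style headers (``sp|ACC|ID``) are emitted when an accession is
    present so that ``read_fasta`` round-trips records losslessly.
    """
    seqrecords = []
    for r in records:
        if r.accession:
            name = f"sp|{r.accession}|{r.id}"
        else:
            name = r.id
        desc = f"OS={r.species}" if r.species else ""
        seqrecords.append(SeqRecord(Seq(r.sequence), id=name, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def extract_region(record: ProteinRecord, region: RegionAnnotation) -> str:
    """Residues ``region.start .. region.end`` inclusive."""
    if region.end > record.length:
        raise SeqIOError(
            f"region {region.start}..{region.end} out of bounds for "
            f"{record.id!r} (valid 1..{record.length})"
        )
    return record.sequence[region.start - 1 : region.end]


def locate_peptide(record: ProteinRecord, peptide: str) -> list[int]:
    """All 1-based start positions of exact, possibly overlapping occurrences."""
    if not peptide:
        raise SeqIOError("empty peptide")
    peptide = peptide.upper()
    hits: list[int] = []
    start = record.sequence.find(peptide)
    while start != -1:
        hits.append(start + 1)
        start = record.sequence.find(peptide, start + 1)
    return hits


def read_region_table(path: str | Path) -> list[RegionAnnotation]:
    """Read an annotation TSV with columns protein_id, label, start, end, source."""
    text = Path(path).read_text()
    return parse_region_table(text, origin=str(path))


def parse_region_table(text: str, origin: str = "<string>") -> list[RegionAnnotation]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in _TSV_COLUMNS if c not in header]
    if missing:
        raise SeqIOError(f"{origin}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in _TSV_COLUMNS}
    out: list[RegionAnnotation] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        try:
            start = int(cells[idx["start"]])
            end = int(cells[idx["end"]])
        except (ValueError, IndexError) as exc:
            raise SeqIOError(f"{origin} row {row_no}: non-integer coordinate") from exc
        try:
            out.append(
                RegionAnnotation(
                    protein_id=cells[idx["protein_id"]],
                    label=cells[idx["label"]],
                    start=start,
                    end=end,
                    source=cells[idx["source"]] if idx["source"] < len(cells) else "",
                )
            )
        except SeqIOError as exc:
            raise SeqIOError(f"{origin} row {row_no}: {exc}") from exc
    return out


def write_region_table(annotations: Sequence[RegionAnnotation], path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("\t".join(_TSV_COLUMNS) + "\n")
    for a in annotations:
        buf.write(f"{a.protein_id}\t{a.label}\t{a.start}\t{a.end}\t{a.source}\n")
    Path(path).write_text(buf.getvalue())
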