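"""Pairwise identity, multiple-alignment column mapping, motif conservation.

"Domain homology" figures are operationalized as global-alignment percent
identity: the two domain sequences are aligned end-to-end (Needleman–
Wunsch, affine gaps, BLOSUM62, open 10 / extend 0.5) and identity is the
fraction of alignment columns with identical residues, reported to 0.1%.

Ortholog motif conservation maps a reference motif match through a multiple
alignment: the match's residue span is converted to alignment columns,
widened by a slack of ±5 columns, and the motif class pattern is searched
in each ortholog's ungapped residues under that column window.  The
conserved fraction is the share of assessed orthologs retaining a match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .catalog import MotifClass
from .patterns import match_at
from .seqio import ProteinRecord

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped strings differ in length")


@dataclass(frozen=True)
class MultipleAlignment:
    """id -> gapped string; all rows equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gap penalties.

    Ties between co-optimal tracebacks are broken deterministically by
    taking the aligner's first reported optimum.  Residues absent from the
    substitution matrix raise a warning and score as 0 mismatches.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    mat = substitution_matrices.load(matrix)
    alphabet = set(str(mat.alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        warnings.warn(f"residues {sorted(bad)} not in {matrix}; scored as 0", stacklevel=2)
        trans = {ch: "X" if "X" in alphabet else next(iter(alphabet)) for ch in bad}
        a = "".join(trans.get(ch, ch) for ch in a)
        b = "".join(trans.get(ch, ch) for ch in b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(ga, gb, float(aln.score), matrix, gap_open, gap_extend)


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x identical columns / total alignment columns, to 0.1."""
    same = sum(
        1 for x, y in zip(aln.gapped_a, aln.gapped_b)
        if x == y and x != GAP
    )
    return round(100.0 * same / len(aln.gapped_a), 1)


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Aligned FASTA -> MultipleAlignment (gap character '-')."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id.split("|")[-1] if rec.id.count("|") == 2 else rec.id] = (
            str(rec.seq).upper()
        )
    if not rows:
        raise ValueError(f"{path}: no aligned sequences")
    return MultipleAlignment(rows)


def write_alignment(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, gapped in msa.rows.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(gapped), 60):
                fh.write(gapped[i : i + 60] + "\n")


def map_position(msa: MultipleAlignment, seq_id: str, residue_pos: int) -> int:
    """1-based residue position -> 1-based alignment column."""
    gapped = msa.rows[seq_id]
    count = 0
    for col, ch in enumerate(gapped, start=1):
        if ch != GAP:
            count += 1
            if count == residue_pos:
                return col
    raise IndexError(
        f"{seq_id}: residue {residue_pos} beyond ungapped length {count}"
    )


def unmap_column(msa: MultipleAlignment, seq_id: str, column: int) -> int | None:
    """1-based alignment column -> 1-based residue position (None on a gap)."""
    gapped = msa.rows[seq_id]
    if not (1 <= column <= len(gapped)):
        raise IndexError(f"column {column} outside alignment 1..{len(gapped)}")
    if gapped[column - 1] == GAP:
        return None
    return sum(1 for ch in gapped[:column] if ch != GAP)


@dataclass(frozen=True)
class OrthologVerdict:
    seq_id: str
    conserved: bool
    matched_peptide: str  # "" when absent


@dataclass(frozen=True)
class ConservationReport:
    motif_id: str
    reference_id: str
    start: int
    end: int
    verdicts: tuple[OrthologVerdict, ...]

    @property
    def conserved_fraction(self) -> float:
        if not self.verdicts:
            return float("nan")
        return sum(v.conserved for v in self.verdicts) / len(self.verdicts)


def motif_conservation(
    msa: MultipleAlignment,
    reference_id: str,
    start: int,
    end: int,
    motif: MotifClass,
    slack: int = 5,
) -> ConservationReport:
    """Is the reference match retained in each other aligned sequence?

    The reference residue interval is mapped to alignment columns, widened
    by ±``slack`` columns (clipped to the alignment), and each ortholog is
    scored conserved iff the class pattern matches within its ungapped
    residues under that window.
    """
    col_lo = max(1, map_position(msa, reference_id, start) - slack)
    col_hi = min(msa.n_columns, map_position(msa, reference_id, end) + slack)
    verdicts = []
    for sid, gapped in msa.rows.items():
        if sid == reference_id:
            continue
        window = gapped[col_lo - 1 : col_hi].replace(GAP, "")
        matched = ""
        for pos0 in range(len(window)):
            lengths = match_at(motif.compiled, window, pos0)
            if lengths:
                matched = window[pos0 : pos0 + lengths[0]]
                break
        verdicts.append(OrthologVerdict(sid, bool(matched), matched))
    return ConservationReport(motif.motif_id, reference_id, start, end, tuple(verdicts))


def star_align(records: list[ProteinRecord], center_id: str) -> MultipleAlignment:
    """Star-progressive multiple alignment with the reference as center.

    Each sequence is aligned pairwise to the center and the pairwise gap
    patterns are merged ("once a gap, always a gap").  Adequate for
    closely related ortholog families; not a general MSA method.
    """
    center = next(r for r in records if r.id == center_id)
    others = [r for r in records if r.id != center_id]
    if not others:
        return MultipleAlignment({center.id: center.sequence})
    pairs = [global_align(center.sequence, o.sequence) for o in others]
    n = len(center.sequence)
    # insertions[k] = gaps needed after center residue k (k=0: before first)
    insertions = [0] * (n + 1)
    per_pair_ins: list[list[int]] = []
    for aln in pairs:
        ins = [0] * (n + 1)
        k = 0
        for ca in aln.gapped_a:
            if ca == GAP:
                ins[k] += 1
            else:
                k += 1
        per_pair_ins.append(ins)
        for i in range(n + 1):
            insertions[i] = max(insertions[i], ins[i])

    def expand_center() -> str:
        out = [GAP * insertions[0]]
        for i, ch in enumerate(center.sequence, start=1):
            out.append(ch + GAP * insertions[i])
        return "".join(out)

    rows = {center.id: expand_center()}
    for other, aln, ins in zip(others, pairs, per_pair_ins):
        chunks: list[str] = []
        current: list[str] = []
        for ca, cb in zip(aln.gapped_a, aln.gapped_b):
            if ca == GAP:
                current.append(cb)
            else:
                chunks.append("".join(current))
                current = [cb]
        chunks.append("".join(current))
        # chunks[0] = other residues before center residue 1 (pure insertion)
        # chunks[i] (i>=1) = other residue aligned to center residue i plus
        # following insertion residues
        aligned = [chunks[0].rjust(insertions[0], GAP)]
        for i in range(1, n + 1):
            block = chunks[i]
            aligned.append(block[0] + block[1:].ljust(insertions[i], GAP))
        rows[other.id] = "".join(aligned)
    return MultipleAlignment(rows)
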