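"""Global alignment, percent identity, column mapping, motif conservation."""

import random

import pytest
from Bio.Align import substitution_matrices

from sydeslim.conservation import (MultipleAlignment, global_align,
                                   map_position, motif_conservation,
                                   percent_identity, read_alignment,
                                   star_align, unmap_column, write_alignment)
from sydeslim.seqio import AMINO_ACIDS, ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def exhaustive_best_score(a, b, gap_open=10.0, gap_extend=0.5):
    """Enumerate every global alignment (move strings) and score it."""
    best = -float("inf")

    def run_cost(length):
        return gap_open + gap_extend * (length - 1)

    def rec(i, j, moves):
        nonlocal best
        if i == len(a) and j == len(b):
            score = 0.0
            k = 0
            while k < len(moves):
                mv = moves[k]
                if mv == "M":
                    score += 0.0
                    k += 1
                else:
                    run = k
                    while run < len(moves) and moves[run] == mv:
                        run += 1
                    score -= run_cost(run - k)
                    k = run
            ia = ib = 0
            for mv in moves:
                if mv == "M":
                    score += BLOSUM62[a[ia], b[ib]]
                    ia += 1
                    ib += 1
                elif mv == "A":
                    ia += 1
                else:
                    ib += 1
            best = max(best, score)
            return
        if i < len(a):
            rec(i + 1, j, moves + "A")
        if j < len(b):
            rec(i, j + 1, moves + "B")
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, moves + "M")

    rec(0, 0, "")
    return best


def test_identical_sequences_align_without_gaps():
    aln = global_align("ACDE", "ACDE")
    assert (aln.gapped_a, aln.gapped_b) == ("ACDE", "ACDE")
    assert percent_identity(aln) == 100.0


def test_single_substitution_column():
    aln = global_align("A", "G")
    assert (aln.gapped_a, aln.gapped_b) == ("A", "G")
    assert percent_identity(aln) == 0.0


def test_alignment_score_equals_exhaustive_enumeration():
    rng = random.Random(17)
    for _ in range(8):
        a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(2, 6)))
        b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(2, 6)))
        aln = global_align(a, b)
        assert aln.score == pytest.approx(exhaustive_best_score(a, b))


def test_gap_removal_recovers_inputs():
    aln = global_align("MKWVTFISLL", "MKWTFISLL")
    assert aln.gapped_a.replace("-", "") == "MKWVTFISLL"
    assert aln.gapped_b.replace("-", "") == "MKWTFISLL"


def test_percent_identity_symmetric():
    rng = random.Random(23)
    for _ in range(5):
        a = "".join(rng.choice(AMINO_ACIDS) for _ in range(30))
        b = "".join(rng.choice(AMINO_ACIDS) for _ in range(25))
        assert percent_identity(global_align(a, b)) == pytest.approx(
            percent_identity(global_align(b, a)), abs=0.2
        )


def test_map_position_ungapped_is_identity():
    msa = MultipleAlignment({"a": "ACDE", "b": "ACDE"})
    for k in range(1, 5):
        assert map_position(msa, "a", k) == k


def test_map_position_with_gaps():
    msa = MultipleAlignment({"a": "-AB", "b": "CAB"})
    assert map_position(msa, "a", 1) == 2
    assert unmap_column(msa, "a", 1) is None
    assert unmap_column(msa, "a", 2) == 1


def test_map_unmap_round_trip_random_gappings():
    rng = random.Random(3)
    for _ in range(20):
        residues = "".join(rng.choice(AMINO_ACIDS) for _ in range(15))
        gapped = "".join(
            ch + ("-" * rng.randint(0, 2)) for ch in residues
        )
        msa = MultipleAlignment({"a": gapped, "pad": "A" * len(gapped)})
        for pos in range(1, 16):
            col = map_position(msa, "a", pos)
            assert unmap_column(msa, "a", col) == pos


def test_map_position_beyond_length_errors():
    msa = MultipleAlignment({"a": "AC--", "b": "ACGG"})
    with pytest.raises(IndexError):
        map_position(msa, "a", 3)


def test_motif_conservation_identical_family(catalog):
    cls = catalog.get_class("doc_pp4")
    seq = "A" * 10 + "FRDP" + "A" * 10
    msa = MultipleAlignment({f"s{i}": seq for i in range(4)})
    rep = motif_conservation(msa, "s0", 11, 14, cls)
    assert rep.conserved_fraction == 1.0
    assert all(v.matched_peptide == "FRDP" for v in rep.verdicts)


def test_motif_conservation_half_destroyed(catalog):
    cls = catalog.get_class("doc_pp4")
    good = "A" * 10 + "FRDP" + "A" * 10
    bad = "A" * 10 + "ARDA" + "A" * 10
    msa = MultipleAlignment({"ref": good, "s1": good, "s2": bad})
    rep = motif_conservation(msa, "ref", 11, 14, cls)
    assert rep.conserved_fraction == 0.5


def test_motif_conservation_nonincreasing_as_slack_shrinks(catalog):
    cls = catalog.get_class("doc_pp4")
    ref = "A" * 10 + "FRDP" + "A" * 10
    shifted = "A" * 13 + "FRDP" + "A" * 7  # motif moved 3 right
    msa = MultipleAlignment({"ref": ref, "s": shifted})
    fractions = [
        motif_conservation(msa, "ref", 11, 14, cls, slack=s).conserved_fraction
        for s in (5, 3, 1, 0)
    ]
    assert fractions == sorted(fractions, reverse=True)
    assert fractions[0] == 1.0 and fractions[-1] == 0.0


def test_alignment_fasta_round_trip(tmp_path):
    msa = MultipleAlignment({"a": "AC-DE", "b": "ACWDE"})
    path = tmp_path / "aln.fasta"
    write_alignment(msa, path)
    assert read_alignment(path).rows == msa.rows


def test_star_align_recovers_simple_indel():
    records = [
        ProteinRecord(id="c", sequence="MKWVTFISLL"),
        ProteinRecord(id="o1", sequence="MKWTFISLL"),   # deletion
        ProteinRecord(id="o2", sequence="MKWVTFISLL"),  # identical
    ]
    msa = star_align(records, "c")
    assert set(msa.rows) == {"c", "o1", "o2"}
    assert msa.rows["c"].replace("-", "") == "MKWVTFISLL"
    assert msa.rows["o1"].replace("-", "") == "MKWTFISLL"
    lengths = {len(v) for v in msa.rows.values()}
    assert len(lengths) == 1
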