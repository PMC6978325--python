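"""Pairwise alignment, back-translation and large-indel masking."""

import functools

import pytest
from hypothesis import given, settings, strategies as st

from Bio.Align import substitution_matrices

from duicompare.codonalign import (
    GAP_CODON,
    align_nucleotides,
    align_proteins,
    back_translate_alignment,
    make_protein_aligner,
    mask_large_indels,
    read_alignment_fasta,
    write_alignment_fasta,
)
from duicompare.model import INVERTEBRATE_MITO, translate_mito

_B62 = substitution_matrices.load("BLOSUM62")


def _brute_force_best(a, b, score, gap_open, gap_extend):
    """Exhaustive optimal global affine-gap alignment score for tiny
    inputs: enumerate all move sequences recursively."""

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):  # state: 0 diagonal, 1 gap-in-b, 2 gap-in-a
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score(a[i], b[j]) + best(i + 1, j + 1, 0))
        if i < len(a):  # a[i] against a gap in b
            cost = gap_extend if state == 1 else gap_open
            options.append(-cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            options.append(-cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


@pytest.mark.parametrize(
    "a,b",
    [("MKV", "MKV"), ("MKVLT", "MKT"), ("WWFA", "AWF"), ("MSPVR", "MR")],
)
def test_protein_alignment_matches_exhaustive_optimum(a, b):
    aligner = make_protein_aligner()
    observed = aligner.score(a, b)
    def s(x, y):
        return _B62[x, y]
    # a length-L gap costs open + (L-1)*extend: first column charges open
    expected = _brute_force_best(a, b, s, 10.0, 0.5)
    assert observed == pytest.approx(expected)
    ra, rb = align_proteins(a, b)
    assert ra.replace("-", "") == a and rb.replace("-", "") == b
    if a == b:
        assert "-" not in ra + rb


@pytest.mark.parametrize("a,b", [("ACGT", "ACGT"), ("ACGT", "AGT"), ("AACCGGTT", "AACGGT")])
def test_nucleotide_alignment_matches_exhaustive_optimum(a, b):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    def s(x, y):
        return 2.0 if x == y else -3.0
    expected = _brute_force_best(a, b, s, 8.0, 2.0)
    assert aligner.score(a, b) == pytest.approx(expected)
    ra, rb = align_nucleotides(a, b)
    assert ra.replace("-", "") == a and rb.replace("-", "") == b


def test_alignment_score_symmetric():
    aligner = make_protein_aligner()
    assert aligner.score("MKVLT", "MKT") == aligner.score("MKT", "MKVLT")


def test_alignment_deterministic():
    assert align_nucleotides("A" * 50, "A" * 49 + "C") == align_nucleotides(
        "A" * 50, "A" * 49 + "C"
    )


_SENSE = sorted(
    c for c, aa in INVERTEBRATE_MITO.codon_to_aa.items() if aa != "*"
)


@settings(derandomize=True, max_examples=30)
@given(
    codons_a=st.lists(st.sampled_from(_SENSE), min_size=3, max_size=40),
    codons_b=st.lists(st.sampled_from(_SENSE), min_size=3, max_size=40),
)
def test_back_translate_round_trip(codons_a, codons_b):
    """back_translate . align_proteins . translate reproduces each input's
    codon sequence once gaps are removed."""
    nt_a, nt_b = "".join(codons_a), "".join(codons_b)
    aa_a, _ = translate_mito(nt_a)
    aa_b, _ = translate_mito(nt_b)
    ra, rb = align_proteins(aa_a, aa_b)
    aln = back_translate_alignment(ra, rb, nt_a, nt_b)
    assert aln.ungapped("a") == nt_a
    assert aln.ungapped("b") == nt_b


def test_back_translate_simple_cases():
    aln = back_translate_alignment("MK", "MK", "ATGAAA", "ATGAAG")
    assert aln.codons_a == ["ATG", "AAA"]
    assert aln.codons_b == ["ATG", "AAG"]
    gapped = back_translate_alignment("M-K", "MLK", "ATGAAA", "ATGTTAAAA")
    assert gapped.codons_a[1] == GAP_CODON


def test_back_translate_rejects_mismatched_nt():
    with pytest.raises(ValueError, match="translation mismatch"):
        back_translate_alignment("MK", "MK", "ATGGGG", "ATGAAA")


def _gappy_alignment(gap_cols, flank=5):
    codons_a = ["ATG"] * flank + [GAP_CODON] * gap_cols + ["TGT"] * flank
    codons_b = ["ATG"] * flank + ["CTT"] * gap_cols + ["TGT"] * flank
    from duicompare.codonalign import CodonAlignment

    return CodonAlignment("toy", "a", "b", codons_a, codons_b)


def test_mask_large_indels_threshold_and_flanks():
    aln = mask_large_indels(_gappy_alignment(40), min_gap_codons=30)
    assert aln.mask[5:45] == ["large_indel"] * 40
    assert aln.mask[:5] == [None] * 5 and aln.mask[45:] == [None] * 5
    untouched = mask_large_indels(_gappy_alignment(1), min_gap_codons=30)
    assert all(m is None for m in untouched.mask)


def test_mask_min_one_masks_every_gap_column():
    aln = mask_large_indels(_gappy_alignment(3), min_gap_codons=1)
    assert [m for m in aln.mask if m == "large_indel"] == ["large_indel"] * 3


def test_masking_idempotent_and_monotone():
    base = _gappy_alignment(35)
    once = mask_large_indels(base, 30)
    twice = mask_large_indels(once, 30)
    assert once.mask == twice.mask
    loose = mask_large_indels(base, 36)
    strict = mask_large_indels(base, 10)
    masked_loose = {i for i, m in enumerate(loose.mask) if m}
    masked_strict = {i for i, m in enumerate(strict.mask) if m}
    assert masked_loose <= masked_strict


def test_alignment_fasta_round_trip(tmp_path):
    aln = mask_large_indels(_gappy_alignment(31), 30)
    path = tmp_path / "aln.fasta"
    write_alignment_fasta(aln, path)
    back = read_alignment_fasta(path)
    assert back.codons_a == aln.codons_a
    assert back.codons_b == aln.codons_b
    assert back.mask == aln.mask
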