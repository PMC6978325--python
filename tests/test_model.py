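"""Core types: genetic code, translation, gene-name canonicalization and
whole-genome validation."""

import pytest
from hypothesis import given, settings, strategies as st

from duicompare.model import (
    GeneFeature,
    INVERTEBRATE_MITO,
    Mitogenome,
    canonical_gene_name,
    linearize_at,
    translate_mito,
    validate_genome,
)


def test_code_matches_independent_table5_for_all_codons():
    """Every codon translates as in an independently maintained table-5
    map (Biopython's CodonTable), including the AGA/AGG=Ser, ATA=Met and
    TGA=Trp reassignments."""
    from Bio.Data import CodonTable

    ref = CodonTable.unambiguous_dna_by_id[5]
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in ref.stop_codons:
                    assert INVERTEBRATE_MITO.codon_to_aa[codon] == "*"
                    assert INVERTEBRATE_MITO.is_stop(codon)
                else:
                    assert (
                        INVERTEBRATE_MITO.codon_to_aa[codon]
                        == ref.forward_table[codon]
                    ), codon
    assert INVERTEBRATE_MITO.codon_to_aa["TGA"] == "W"
    assert not INVERTEBRATE_MITO.is_stop("TGA")


@pytest.mark.parametrize(
    "nt,kwargs,expected",
    [
        ("ATATGATAA", {}, "MW"),            # trailing complete stop dropped
        ("AGAAGG", {}, "SS"),               # AGA/AGG are serine here
        ("ATGAANTAA", {}, "MX"),            # N codon -> X
        ("ATGAAAT", {"incomplete_stop_ok": True}, "MK"),  # T** tail dropped
    ],
)
def test_translate_examples(nt, kwargs, expected):
    protein, internal = translate_mito(nt, **kwargs)
    assert protein == expected
    assert internal == []


def test_translate_flags_internal_stops_without_raising():
    protein, internal = translate_mito("ATGTAAAAATAA")
    assert protein == "M*K"
    assert internal == [1]


def test_translate_rejects_bad_input():
    with pytest.raises(ValueError):
        translate_mito("AT")
    with pytest.raises(ValueError):
        translate_mito("ATGAA")  # partial codon without incomplete_stop_ok
    with pytest.raises(ValueError):
        translate_mito("ATGRAA")  # ambiguity codes other than N


@settings(derandomize=True, max_examples=50)
@given(
    n_codons=st.integers(2, 200),
    stop=st.sampled_from(["TAA", "TAG", "T", "TA", ""]),
    data=st.data(),
)
def test_translate_length_contract(n_codons, stop, data):
    """Protein length equals the codon count after the stated trimming of
    trailing complete stops and polyadenylation tails."""
    sense = [c for c, aa in INVERTEBRATE_MITO.codon_to_aa.items() if aa != "*"]
    codons = data.draw(st.lists(st.sampled_from(sense), min_size=n_codons, max_size=n_codons))
    nt = "".join(codons) + stop
    protein, _ = translate_mito(nt, incomplete_stop_ok=True)
    assert len(protein) == n_codons


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("COIII", ("cox3", None)),
        ("COI", ("cox1", None)),
        ("cox2", ("cox2", None)),
        ("cytb", ("cob", None)),
        ("CYTB", ("cob", None)),
        ("ND4L", ("nad4L", None)),
        ("nad4l", ("nad4L", None)),
        ("NADH2", ("nad2", None)),
        ("ATPase6", ("atp6", None)),
        ("12S", ("rrnS", None)),
        ("16S rRNA", ("rrnL", None)),
        ("trnA_1", ("trnA", "_1")),
        ("tRNA-Leu1", ("trnL1", None)),
        ("trnS2", ("trnS2", None)),
        ("ORF1", ("ORF1", None)),
    ],
)
def test_canonical_gene_name(raw, expected):
    assert canonical_gene_name(raw) == expected


def _toy_genome(features, length=300):
    return Mitogenome("toy", "Toyus toyus", "F", "ACGT" * (length // 4), True, features)


def test_validate_reports_missing_and_duplicated(published_genomes):
    findings = validate_genome(published_genomes["MN528029"])
    assert "trnT missing" in findings
    assert any(f.startswith("trnA duplicated") for f in findings)


def test_validate_clean_simulated_genome(sim_f):
    assert validate_genome(sim_f) == []


def test_validate_reports_nested_pair():
    feats = [
        GeneFeature("rrnL", "rRNA", 0, 200),
        GeneFeature("trnA", "tRNA", 50, 115),
    ]
    findings = validate_genome(_toy_genome(feats))
    assert any("nested feature pair" in f for f in findings)


def test_linearize_preserves_feature_content(sim_f):
    rotated = linearize_at(sim_f, 1234)
    assert rotated.length == sim_f.length
    for orig in sim_f.features:
        moved = rotated.get(orig.name)
        assert moved is not None
        assert rotated.feature_seq(moved) == sim_f.feature_seq(orig)
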