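"""cox2 insertion detection, intact/split architecture and motif anchors."""


from duicompare.codonalign import align_proteins, back_translate_alignment
from duicompare.cox2 import (
    classify_split,
    cox2_report,
    detect_insertions,
    load_reference,
    locate_motifs,
)
from duicompare.divergence import coding_sequence
from duicompare.model import INVERTEBRATE_MITO, GeneFeature, Mitogenome
from duicompare.simulate import SimulationConfig, simulate_pair

# one representative codon per amino acid (table 5)
_CODON_OF = {}
for codon, aa in sorted(INVERTEBRATE_MITO.codon_to_aa.items()):
    if aa != "*" and aa not in _CODON_OF:
        _CODON_OF[aa] = codon


def _reverse_translate(protein):
    return "".join(_CODON_OF[a] for a in protein)


def _cox2_alignment(f, m):
    pf, pm = coding_sequence(f, "cox2"), coding_sequence(m, "cox2")
    aa = align_proteins(pf[1], pm[1])
    return back_translate_alignment(
        aa[0], aa[1], pf[0], pm[0], "cox2", f.identifier, m.identifier
    )


def test_detect_insertions_identical_is_empty(sim_pair):
    f, _, _ = sim_pair
    aln = _cox2_alignment(f, f)
    assert detect_insertions(aln) == []


def test_detect_insertions_recovers_planted_block(sim_pair):
    f, m, truth = sim_pair
    blocks = detect_insertions(_cox2_alignment(f, m))
    assert len(blocks) == 1
    block = blocks[0]
    assert block.m_nt_start == truth.insertion["m_gene_nt_start"]
    assert block.length_nt == truth.insertion["length_nt"]
    assert block.in_frame
    # single clean block: insertion length equals the gene-length difference
    f_len = f.get("cox2").length
    m_len = m.get("cox2").length
    assert block.length_nt == m_len - f_len


def test_detect_insertions_small_planted_block():
    cfg = SimulationConfig(cox2_insertion_codons=100)
    f, m, truth = simulate_pair(cfg, seed=23)
    blocks = detect_insertions(_cox2_alignment(f, m))
    assert len(blocks) == 1
    assert blocks[0].length_codons == 100
    assert blocks[0].m_nt_start == truth.insertion["m_gene_nt_start"]


def test_classify_split_cases():
    intact = "ATG" + "CTT" * 50 + "TAA"
    arch = classify_split(intact)
    assert arch.architecture == "intact" and arch.cox2a is None

    split = "ATG" + "CTT" * 20 + "TAA" + "CTT" * 5 + "ATA" + "CTT" * 20 + "TAG"
    arch = classify_split(split)
    assert arch.architecture == "split"
    assert arch.internal_stop_codon_index == 21
    assert arch.cox2a == (0, 66)
    assert arch.cox2b is not None and split[arch.cox2b[0]:arch.cox2b[0] + 3] == "ATA"


def test_classify_split_ignores_trailing_incomplete_stop():
    gene = "ATG" + "CTT" * 50
    assert classify_split(gene + "TA").architecture == "intact"
    assert classify_split(gene + "TAA").architecture == "intact"


def test_classify_split_without_downstream_start():
    gene = "ATG" + "CTT" * 20 + "TAA" + "CCC" * 30 + "TAG"
    arch = classify_split(gene)
    assert arch.architecture == "split" and arch.cox2b is None


def test_locate_motifs_identity_projection():
    ref = load_reference()
    anchors = locate_motifs(ref[0], ref)
    assert anchors == {name: tuple(iv) for name, iv in ref[1].items()}


def test_locate_motifs_shifts_past_insertion():
    ref_seq, intervals = load_reference()
    query = ref_seq[:120] + "G" * 30 + ref_seq[120:]
    anchors = locate_motifs(query, (ref_seq, intervals))
    assert anchors["heme_patch"] == tuple(intervals["heme_patch"])
    a, b = intervals["cua1"]
    assert anchors["cua1"] == (a + 30, b + 30)


def test_cox2_report_positions_insertion_between_heme_and_cua():
    """An M cox2 built from the reference protein with a large insertion
    between the heme patch and the first Cu_A center is reported as such."""
    ref_seq, intervals = load_reference()
    f_nt = _reverse_translate("M" + ref_seq[1:]) + "TAA"
    ins_protein = "W" * 60
    m_protein = "M" + ref_seq[1:120] + ins_protein + ref_seq[120:]
    m_nt = _reverse_translate(m_protein) + "TAA"
    L = 400
    f_genome = Mitogenome(
        "F1", "t", "F", f_nt + "C" * 20, False,
        [GeneFeature("cox2", "PCG", 0, len(f_nt))],
    )
    m_genome = Mitogenome(
        "M1", "t", "M", m_nt + "C" * 20, False,
        [GeneFeature("cox2", "PCG", 0, len(m_nt))],
    )
    aln = _cox2_alignment(f_genome, m_genome)
    report = cox2_report(f_genome, m_genome, aln)
    assert report.architecture.architecture == "intact"
    assert len(report.insertions) == 1
    assert report.insertion_position == "between_heme_patch_and_cua1"
    assert report.anchors_f["heme_patch"] is not None


def test_cox2_report_on_simulated_pair(sim_pair):
    f, m, truth = sim_pair
    report = cox2_report(f, m, _cox2_alignment(f, m))
    assert report.architecture.architecture == "intact"
    assert len(report.insertions) == 1
    assert report.insertions[0].length_nt == truth.insertion["length_nt"]
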