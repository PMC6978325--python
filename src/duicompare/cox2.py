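"""Characterization of the F-vs-M cox2 gene pair.

Male-transmitted mitogenomes of several DUI bivalves carry a large
in-frame insertion inside cox2.  This module detects such insertions from
the F/M codon alignment, classifies the male gene as intact (one reading
frame end to end) or split into cox2a/cox2b by an internal complete stop,
and positions the insertion relative to the conserved COX2 landmarks
(the two N-terminal transmembrane helices, the heme-patch region and the
Cu_A-binding centers) by projecting motif intervals from a packaged
reference protein onto the query.

The packaged reference (``data/cox2_reference_synthetic.fasta``) is a
constructed stand-in protein whose annotated motif intervals encode the
canonical COX2 domain order; replace it with a real annotated COX2
protein (e.g. a vertebrate one) via ``reference=`` for motif positions
that are meaningful beyond their ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .codonalign import (
    CodonAlignment,
    DEFAULT_MIN_GAP_CODONS,
    GAP_CODON,
    align_proteins,
)
from .model import GeneticCode, INVERTEBRATE_MITO, Mitogenome, translate_mito

__all__ = [
    "InsertionBlock",
    "Cox2Architecture",
    "Cox2Report",
    "detect_insertions",
    "classify_split",
    "locate_motifs",
    "load_reference",
    "cox2_report",
]


@dataclass
class InsertionBlock:
    col_start: int      # codon-column interval in the F/M alignment
    col_end: int
    m_nt_start: int     # nt coordinates within the (stop-trimmed) M gene
    m_nt_end: int
    in_frame: bool

    @property
    def length_nt(self) -> int:
        return self.m_nt_end - self.m_nt_start

    @property
    def length_codons(self) -> int:
        return self.col_end - self.col_start


@dataclass
class Cox2Architecture:
    architecture: str                      # 'intact' | 'split'
    internal_stop_codon_index: int | None  # codon index of the first stop
    cox2a: tuple[int, int] | None          # nt coords within the gene
    cox2b: tuple[int, int] | None          # None when no downstream start found


@dataclass
class Cox2Report:
    architecture: Cox2Architecture
    insertions: list[InsertionBlock]
    anchors_f: dict
    anchors_m: dict
    insertion_position: str | None  # relative to heme_patch / first Cu_A center
    length_uncertain: bool = False


def detect_insertions(
    aln: CodonAlignment, min_block_codons: int = DEFAULT_MIN_GAP_CODONS
) -> list[InsertionBlock]:
    """Maximal runs of >= ``min_block_codons`` F-gap columns, reported as
    insertions in the M gene with nt coordinates in the M coding sequence."""
    blocks = []
    n = len(aln)
    m_codons_before = 0
    i = 0
    while i < n:
        if aln.codons_a[i] == GAP_CODON and aln.codons_b[i] != GAP_CODON:
            j = i
            m_in_block = 0
            while j < n and aln.codons_a[j] == GAP_CODON and aln.codons_b[j] != GAP_CODON:
                m_in_block += 1
                j += 1
            if j - i >= min_block_codons:
                start_nt = 3 * m_codons_before
                end_nt = start_nt + 3 * m_in_block
                blocks.append(
                    InsertionBlock(i, j, start_nt, end_nt, (end_nt - start_nt) % 3 == 0)
                )
            m_codons_before += m_in_block
            i = j
        else:
            if aln.codons_b[i] != GAP_CODON:
                m_codons_before += 1
            i += 1
    return blocks


def classify_split(
    m_cox2: str, code: GeneticCode = INVERTEBRATE_MITO
) -> Cox2Architecture:
    """Intact-vs-split call from the male gene's own reading frame.

    A trailing complete or incomplete stop is trimmed first, so the call
    is invariant to T** annotation.  With an internal complete stop the
    gene splits into cox2a (start through that stop) and cox2b (from the
    next downstream start codon, searched in all three frames).
    """
    nt = m_cox2.upper()
    overhang = len(nt) % 3
    if overhang:
        nt = nt[:-overhang]
    if len(nt) >= 3 and code.is_stop(nt[-3:]):
        nt = nt[:-3]
    _, internal = translate_mito(nt, code)
    if not internal:
        return Cox2Architecture("intact", None, None, None)
    first = internal[0]
    cox2a = (0, 3 * (first + 1))
    search_from = 3 * (first + 1)
    cox2b = None
    for pos in range(search_from, len(m_cox2) - 2):
        codon = m_cox2[pos:pos + 3].upper()
        if code.is_start(codon):
            cox2b = (pos, len(m_cox2))
            break
    return Cox2Architecture("split", first, cox2a, cox2b)


# --- motif anchoring -------------------------------------------------------

def load_reference(fasta=None, motifs=None) -> tuple[str, dict]:
    """Packaged (or user-supplied) reference COX2 protein and its motif
    intervals (0-based half-open residue coordinates)."""
    if fasta is None:
        fasta = resources.files("duicompare.data").joinpath("cox2_reference_synthetic.fasta")
        motifs = resources.files("duicompare.data").joinpath("cox2_reference_synthetic_motifs.json")
    with open(str(fasta)) as fh:
        record = SeqIO.read(fh, "fasta")
    with open(str(motifs)) as fh:
        intervals = {k: tuple(v) for k, v in json.load(fh).items()}
    return str(record.seq), intervals


def locate_motifs(
    protein: str,
    reference: tuple[str, dict] | None = None,
    min_coverage: float = 0.5,
    **align_kwargs,
) -> dict:
    """Project reference motif intervals onto a query COX2 protein.

    The query is globally aligned to the reference protein; each motif
    interval maps to the query residues aligned within it.  Anchors whose
    reference interval is covered by aligned (non-gap) query residues over
    less than ``min_coverage`` are reported as ``None`` (unresolved).
    Returns motif -> (start, end) half-open query-residue intervals.
    """
    ref_seq, intervals = reference or load_reference()
    aln_q, aln_r = align_proteins(protein, ref_seq, **align_kwargs)
    # reference residue index -> query residue index (None at query gaps)
    ref_to_query: list[int | None] = []
    qi = 0
    for cq, cr in zip(aln_q, aln_r):
        if cr != "-":
            ref_to_query.append(qi if cq != "-" else None)
        if cq != "-":
            qi += 1
    anchors = {}
    for name, (a, b) in intervals.items():
        hits = [ref_to_query[i] for i in range(a, min(b, len(ref_to_query)))]
        aligned = [h for h in hits if h is not None]
        if len(aligned) < min_coverage * (b - a):
            anchors[name] = None
        else:
            anchors[name] = (min(aligned), max(aligned) + 1)
    return anchors


def _m_codon_to_column(aln: CodonAlignment) -> list[int]:
    """Column index of each (non-gap) M codon."""
    cols = []
    for i, cb in enumerate(aln.codons_b):
        if cb != GAP_CODON:
            cols.append(i)
    return cols


def cox2_report(
    f: Mitogenome,
    m: Mitogenome,
    aln: CodonAlignment,
    min_block_codons: int = DEFAULT_MIN_GAP_CODONS,
    reference: tuple[str, dict] | None = None,
) -> Cox2Report:
    """Full cox2 characterization from a prepared F/M codon alignment.

    ``aln`` must be the unmasked cox2 codon alignment with row A = F and
    row B = M.  The insertion's position is classified relative to the
    heme-patch and first Cu_A anchors projected onto the M protein.
    """
    insertions = detect_insertions(aln, min_block_codons)
    m_feat = m.get("cox2")
    arch = classify_split(m.feature_seq(m_feat)) if m_feat else Cox2Architecture(
        "intact", None, None, None
    )
    prot_f = translate_mito(aln.ungapped("a"), INVERTEBRATE_MITO)[0] if len(aln) else ""
    prot_m_nt = aln.ungapped("b")
    prot_m = translate_mito(prot_m_nt, INVERTEBRATE_MITO)[0] if prot_m_nt else ""
    anchors_f = locate_motifs(prot_f, reference) if prot_f else {}
    anchors_m = locate_motifs(prot_m.replace("*", "X"), reference) if prot_m else {}

    position = None
    if insertions and anchors_m.get("heme_patch") and anchors_m.get("cua1"):
        cols = _m_codon_to_column(aln)
        heme_end_col = cols[min(anchors_m["heme_patch"][1], len(cols)) - 1]
        cua_start_col = cols[min(anchors_m["cua1"][0], len(cols) - 1)]
        block = max(insertions, key=lambda b: b.length_codons)
        if heme_end_col < block.col_start and block.col_end <= cua_start_col + 1:
            position = "between_heme_patch_and_cua1"
        elif block.col_end <= heme_end_col:
            position = "before_heme_patch"
        else:
            position = "after_cua1"
    uncertain = bool(m_feat is not None and m_feat.incomplete_stop)
    return Cox2Report(arch, insertions, anchors_f, anchors_m, position, uncertain)
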