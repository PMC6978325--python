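"""Protein-guided pairwise codon alignment.

The F-vs-M comparison aligns each gene at the protein level (global,
affine gaps) and threads the nucleotide sequences back through the
protein alignment so every alignment column is one codon.  Columns inside
exceptionally large gap runs — the multi-kilobase male cox2 insertion is
the motivating case — are masked out so divergence statistics only see
the alignable parts of a gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .model import GeneticCode, INVERTEBRATE_MITO, translate_mito

__all__ = [
    "CodonAlignment",
    "align_proteins",
    "align_nucleotides",
    "back_translate_alignment",
    "mask_large_indels",
    "DEFAULT_MIN_GAP_CODONS",
]

GAP_CODON = "---"

#: Gap runs at least this many codons long are treated as structural
#: insertions and masked from every statistic (the published analysis
#: excluded the male-cox2 indel by hand; 30 codons separates that scale
#: from ordinary alignment gaps).
DEFAULT_MIN_GAP_CODONS = 30


@dataclass
class CodonAlignment:
    """Paired codon columns with a per-column exclusion mask.

    ``codons_a``/``codons_b`` hold one codon (or ``---``) per column.  The
    ``mask`` holds ``None`` for usable columns or a reason string
    (``gap`` / ``ambiguity`` / ``large_indel``).  Downstream statistics must
    only consume :meth:`counted_columns`.
    """

    gene: str
    id_a: str
    id_b: str
    codons_a: list[str]
    codons_b: list[str]
    mask: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("column count mismatch")
        if not self.mask:
            self.mask = [None] * len(self.codons_a)
        if len(self.mask) != len(self.codons_a):
            raise ValueError("mask length mismatch")

    def __len__(self) -> int:
        return len(self.codons_a)

    def ungapped(self, which: str = "a") -> str:
        codons = self.codons_a if which == "a" else self.codons_b
        return "".join(c for c in codons if c != GAP_CODON)

    def counted_columns(
        self, code: GeneticCode = INVERTEBRATE_MITO, skip_stops: bool = True
    ) -> list[int]:
        """Indices of columns usable by codon statistics: unmasked, no gap,
        no ambiguity, and (by default) no stop codon in either sequence."""
        out = []
        for i, (ca, cb, m) in enumerate(zip(self.codons_a, self.codons_b, self.mask)):
            if m is not None or ca == GAP_CODON or cb == GAP_CODON:
                continue
            if "N" in ca or "N" in cb:
                continue
            if skip_stops and (code.is_stop(ca) or code.is_stop(cb)):
                continue
            out.append(i)
        return out

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(
            self.gene, self.id_b, self.id_a,
            list(self.codons_b), list(self.codons_a), list(self.mask),
        )


def _first_alignment(aligner: Align.PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]  # canonical first optimum: deterministic
    return str(aln[0]), str(aln[1])


def make_protein_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_proteins(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[str, str]:
    """Global affine-gap alignment of two protein sequences.

    Returns the two gapped strings.  The first optimal alignment reported
    by the dynamic program is taken, which is deterministic for fixed
    inputs and scoring.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    return _first_alignment(make_protein_aligner(matrix, gap_open, gap_extend), a, b)


def align_nucleotides(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 8.0,
    gap_extend: float = 2.0,
) -> tuple[str, str]:
    """Global affine-gap nucleotide alignment (used for the rRNA genes)."""
    if not a or not b:
        raise ValueError("empty nucleotide sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return _first_alignment(aligner, a, b)


def back_translate_alignment(
    aa_a: str,
    aa_b: str,
    nt_a: str,
    nt_b: str,
    gene: str = "",
    id_a: str = "A",
    id_b: str = "B",
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonAlignment:
    """Thread coding nucleotides through a protein alignment, one codon per
    aligned residue (the PAL2NAL construction).

    ``nt_a``/``nt_b`` must be the stop-trimmed coding sequences whose
    translations equal the ungapped ``aa_a``/``aa_b``.
    """
    for label, aa, nt in (("a", aa_a, nt_a), ("b", aa_b, nt_b)):
        plain = aa.replace("-", "")
        if len(nt) != 3 * len(plain):
            raise ValueError(
                f"sequence {label}: {len(nt)} nt cannot encode {len(plain)} residues"
            )
        prot, _ = translate_mito(nt, code) if len(nt) >= 3 else ("", [])
        # translate_mito drops a trailing stop; re-append for comparison
        if len(prot) < len(plain):
            prot = prot + "*" * (len(plain) - len(prot))
        for i, (x, y) in enumerate(zip(plain, prot)):
            if x != y and "X" not in (x, y):
                raise ValueError(
                    f"sequence {label}: translation mismatch at codon {i}: "
                    f"alignment has {x!r}, sequence encodes {y!r}"
                )
    if len(aa_a) != len(aa_b):
        raise ValueError("protein alignment rows differ in length")
    codons_a, codons_b = [], []
    ia = ib = 0
    for ra, rb in zip(aa_a, aa_b):
        if ra == "-":
            codons_a.append(GAP_CODON)
        else:
            codons_a.append(nt_a[3 * ia:3 * ia + 3])
            ia += 1
        if rb == "-":
            codons_b.append(GAP_CODON)
        else:
            codons_b.append(nt_b[3 * ib:3 * ib + 3])
            ib += 1
    return CodonAlignment(gene, id_a, id_b, codons_a, codons_b)


def mask_large_indels(
    aln: CodonAlignment, min_gap_codons: int = DEFAULT_MIN_GAP_CODONS
) -> CodonAlignment:
    """Mask every maximal run of >= ``min_gap_codons`` consecutive gap
    columns with reason ``large_indel``.  Idempotent; smaller thresholds
    mask supersets of larger ones."""
    mask = list(aln.mask)
    n = len(aln)
    i = 0
    while i < n:
        if aln.codons_a[i] == GAP_CODON or aln.codons_b[i] == GAP_CODON:
            j = i
            while j < n and (aln.codons_a[j] == GAP_CODON or aln.codons_b[j] == GAP_CODON):
                j += 1
            if j - i >= min_gap_codons:
                for k in range(i, j):
                    mask[k] = "large_indel"
            i = j
        else:
            i += 1
    return replace(aln, codons_a=list(aln.codons_a), codons_b=list(aln.codons_b), mask=mask)


def write_alignment_fasta(aln: CodonAlignment, path) -> None:
    """Aligned codon rows as a 2-sequence FASTA (masked columns lowercase)."""
    def row(codons):
        return "".join(
            c.lower() if m == "large_indel" else c
            for c, m in zip(codons, aln.mask)
        )
    with open(path, "w") as fh:
        fh.write(f">{aln.id_a} {aln.gene}\n{row(aln.codons_a)}\n")
        fh.write(f">{aln.id_b} {aln.gene}\n{row(aln.codons_b)}\n")


def read_alignment_fasta(path, gene: str = "") -> CodonAlignment:
    """Import an externally produced pairwise codon alignment (FASTA, two
    rows, length a multiple of 3).  Lowercase columns become masked."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 aligned sequences")
    sa, sb = str(records[0].seq), str(records[1].seq)
    if len(sa) != len(sb) or len(sa) % 3:
        raise ValueError(f"{path}: rows must be equal length codon alignments")
    codons_a = [sa[i:i + 3] for i in range(0, len(sa), 3)]
    codons_b = [sb[i:i + 3] for i in range(0, len(sb), 3)]
    mask: list[str | None] = [
        "large_indel" if (ca != ca.upper() or cb != cb.upper()) else None
        for ca, cb in zip(codons_a, codons_b)
    ]
    return CodonAlignment(
        gene or records[0].description.split()[-1],
        records[0].id, records[1].id,
        [c.upper() for c in codons_a], [c.upper() for c in codons_b], mask,
    )
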