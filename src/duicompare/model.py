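"""Core record types and coordinate conventions for annotated mitogenomes.

Coordinates are 0-based half-open internally; every human-readable report
converts to 1-based inclusive.  Genomes are assumed single-coding-strand
(all genes on the heavy strand), the rule in the bivalve mitogenomes this
package compares.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneFeature",
    "Mitogenome",
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "CANONICAL_PCGS",
    "CANONICAL_TRNAS",
    "CANONICAL_RRNAS",
    "canonical_gene_name",
    "translate_mito",
    "validate_genome",
    "linearize_at",
]

#: The 13 OXPHOS protein-coding genes of a canonical metazoan mitogenome.
CANONICAL_PCGS = (
    "cox1", "cox2", "cox3", "nad1", "nad2", "nad3", "nad4", "nad4L",
    "nad5", "nad6", "atp6", "atp8", "cob",
)

#: The 22 canonical tRNA genes (two serine and two leucine isoacceptors).
CANONICAL_TRNAS = tuple(
    "trn" + x
    for x in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)

CANONICAL_RRNAS = ("rrnS", "rrnL")

_CATEGORY_OF = {}
for _g in CANONICAL_PCGS:
    _CATEGORY_OF[_g] = "PCG"
for _g in CANONICAL_TRNAS:
    _CATEGORY_OF[_g] = "tRNA"
for _g in CANONICAL_RRNAS:
    _CATEGORY_OF[_g] = "rRNA"


@dataclass
class GeneFeature:
    """One annotated gene on the coding strand.

    ``start``/``end`` are 0-based half-open.  A feature spanning the
    circular origin carries ``wraps_origin=True`` with ``end`` counted past
    the origin (i.e. ``end`` may exceed the genome length; callers normalise
    through :func:`linearize_at`).  ``incomplete_stop`` marks protein genes
    whose length is not a codon multiple because the stop codon is completed
    post-transcriptionally by polyadenylation (printed as ``T**``).
    """

    name: str
    category: str  # PCG | tRNA | rRNA | other
    start: int
    end: int
    wraps_origin: bool = False
    incomplete_stop: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def base_name(self) -> str:
        """Gene symbol without any duplicate-copy suffix."""
        m = re.match(r"^(.*?)(_\d+)?$", self.name)
        return m.group(1)

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError(f"feature {self.name}: non-positive length")
        if self.category == "PCG" and self.length % 3 != 0 and not self.incomplete_stop:
            raise ValueError(
                f"PCG {self.name}: length {self.length} not a codon multiple "
                "but incomplete_stop is not set"
            )
        expected = _CATEGORY_OF.get(canonical_gene_name(self.base_name)[0])
        if expected is not None and expected != self.category:
            raise ValueError(
                f"feature {self.name}: category {self.category!r}, expected {expected!r}"
            )


@dataclass
class Mitogenome:
    """A circular annotated mitochondrial genome with a sex type (F or M)."""

    identifier: str
    species: str
    sex_type: str  # 'F' | 'M' | 'unknown'
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: GeneFeature) -> str:
        """Nucleotides of a feature, following it across the origin if needed."""
        if feat.end <= self.length:
            return self.sequence[feat.start:feat.end]
        if not (self.circular and feat.wraps_origin):
            raise ValueError(f"feature {feat.name} extends past a linear sequence")
        return self.sequence[feat.start:] + self.sequence[: feat.end - self.length]

    def get(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name or f.base_name == name:
                return f
        return None

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.category == "PCG"]

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def validate(self) -> None:
        if self.length == 0:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        for f in self.features:
            f.validate()
            if not (0 <= f.start < self.length):
                raise ValueError(f"feature {f.name}: start outside genome")
            if f.end > self.length and not (self.circular and f.wraps_origin):
                raise ValueError(f"feature {f.name}: end outside genome")


@dataclass(frozen=True)
class GeneticCode:
    """A nuclear-style codon table restricted to what mitogenome work needs."""

    table_id: int
    codon_to_aa: dict  # 64 sense/stop codons -> 1-letter aa or '*'
    start_codons: frozenset
    stop_codons: frozenset

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper()
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        if "N" in codon:
            return "X"
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise ValueError(f"not a codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return codon.upper() in self.start_codons


def _build_table5() -> dict:
    """NCBI translation table 5 (invertebrate mitochondrial), written out.

    Relative to the standard code: AGA/AGG = Ser, ATA = Met, TGA = Trp;
    only TAA and TAG terminate.
    """
    bases = "TCAG"
    # standard-code amino acids in TCAG nesting order
    standard = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = standard[i]
                i += 1
    table["AGA"] = "S"
    table["AGG"] = "S"
    table["ATA"] = "M"
    table["TGA"] = "W"
    return table


#: Invertebrate mitochondrial code with the start-codon set observed across
#: bivalve mitogenome annotations (ATA/ATG/ATT plus TTG and GTG).
INVERTEBRATE_MITO = GeneticCode(
    table_id=5,
    codon_to_aa=_build_table5(),
    start_codons=frozenset({"ATG", "ATA", "ATT", "TTG", "GTG"}),
    stop_codons=frozenset({"TAA", "TAG"}),
)


# --- gene-name canonicalization -------------------------------------------

_ROMAN = {"i": "1", "ii": "2", "iii": "3", "iv": "4", "v": "5", "vi": "6"}

_SYNONYMS = {
    "cytb": "cob", "cytochromeb": "cob", "cob": "cob",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    "rns": "rrnS", "mtrnr1": "rrnS", "ssurrna": "rrnS", "smallsubunitribosomalrna": "rrnS",
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "rnl": "rrnL", "mtrnr2": "rrnL", "lsurrna": "rrnL", "largesubunitribosomalrna": "rrnL",
    "nad4l": "nad4L", "nd4l": "nad4L",
}

_AA3TO1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def canonical_gene_name(raw: str) -> tuple[str, str | None]:
    """Normalise a raw annotation label to its canonical gene symbol.

    Returns ``(symbol, copy_suffix)`` where the suffix (``"_1"`` etc.)
    distinguishes duplicated gene copies.  Unrecognised labels pass through
    unchanged with no suffix so supernumerary ORFs keep their own names.

    >>> canonical_gene_name("COIII")
    ('cox3', None)
    >>> canonical_gene_name("trnA_1")
    ('trnA', '_1')
    """
    raw = raw.strip()
    suffix = None
    m = re.match(r"^(.*?)(_\d+)$", raw)
    core = raw
    if m:
        core, suffix = m.group(1), m.group(2)
    key = re.sub(r"[\s\-()]", "", core).lower()

    # cox / co with roman or arabic subunit number
    m = re.match(r"^(?:mt)?cox?(i{1,3}|[1-3])$", key)
    if m:
        n = _ROMAN.get(m.group(1), m.group(1))
        return f"cox{n}", suffix
    m = re.match(r"^(?:mt)?n(?:ad|d)h?([1-6])(l)?$", key)
    if m:
        return f"nad{m.group(1)}{'L' if m.group(2) else ''}", suffix
    m = re.match(r"^(?:mt)?atp(?:ase)?([68])$", key)
    if m:
        return f"atp{m.group(1)}", suffix
    if key in _SYNONYMS:
        return _SYNONYMS[key], suffix
    # tRNAs: trnX, trnX(uuc), tRNA-Leu, trnL1/trnL2
    m = re.match(r"^trn([a-z])([12])?$", key)
    if m:
        return f"trn{m.group(1).upper()}{m.group(2) or ''}", suffix
    m = re.match(r"^trna?([a-z]{3})([12])?$", key)
    if m and m.group(1) in _AA3TO1:
        return f"trn{_AA3TO1[m.group(1)]}{m.group(2) or ''}", suffix
    return core, suffix


def category_of(symbol: str) -> str:
    """Feature category implied by a canonical gene symbol."""
    return _CATEGORY_OF.get(symbol, "other")


# --- translation ----------------------------------------------------------

def translate_mito(
    nt: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    incomplete_stop_ok: bool = False,
) -> tuple[str, list[int]]:
    """Translate a coding sequence under the invertebrate mitochondrial code.

    A trailing complete stop codon is dropped.  A trailing 1–2 nt partial
    codon (a polyadenylation-completed stop) is dropped only when
    ``incomplete_stop_ok`` is set.  Codons containing ``N`` translate to
    ``X``.  Internal stop codons do not raise: their codon indices are
    returned so callers can decide (a split gene is a finding, not a crash).

    Returns ``(protein, internal_stop_codon_indices)``.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    if set(nt) - set("ACGTN"):
        raise ValueError("sequence contains symbols outside {A,C,G,T,N}")
    overhang = len(nt) % 3
    if overhang:
        if not incomplete_stop_ok:
            raise ValueError(
                f"length {len(nt)} is not a codon multiple "
                "(pass incomplete_stop_ok=True for T** genes)"
            )
        nt = nt[: len(nt) - overhang]
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    aa = []
    internal_stops = []
    for i, codon in enumerate(codons):
        res = code.translate_codon(codon)
        if res == "*":
            internal_stops.append(i)
        aa.append(res)
    return "".join(aa), internal_stops


# --- whole-genome validation ----------------------------------------------

def validate_genome(genome: Mitogenome) -> list[str]:
    """Report-only audit of a genome against the canonical gene complement.

    Findings cover missing canonical genes, duplicated genes, overlapping
    and nested feature pairs.  An empty list means the annotation looks like
    a textbook 13 PCG + 22 tRNA + 2 rRNA mitogenome.
    """
    findings: list[str] = []
    counts: dict[str, int] = {}
    for f in genome.features:
        counts[f.base_name] = counts.get(f.base_name, 0) + 1
    for gene in CANONICAL_PCGS + CANONICAL_TRNAS + CANONICAL_RRNAS:
        if counts.get(gene, 0) == 0:
            findings.append(f"{gene} missing")
    for gene, n in sorted(counts.items()):
        if n > 1:
            findings.append(f"{gene} duplicated ({n} copies)")
    feats = genome.sorted_features()
    for a, b in zip(feats, feats[1:]):
        if b.start < a.end:
            if b.end <= a.end:
                findings.append(f"nested feature pair: {b.name} inside {a.name}")
            else:
                findings.append(f"overlap: {a.name}/{b.name} ({a.end - b.start} nt)")
    return findings


def linearize_at(genome: Mitogenome, origin: int) -> Mitogenome:
    """Rotate a circular genome so position ``origin`` becomes position 0.

    Features are re-based; a feature that ends up spanning the new origin
    keeps valid half-open coordinates with ``wraps_origin`` set.
    """
    L = genome.length
    origin %= L
    if origin == 0:
        return genome
    if not genome.circular:
        raise ValueError("cannot rotate a linear genome")
    seq = genome.sequence[origin:] + genome.sequence[:origin]
    feats = []
    for f in genome.features:
        start = (f.start - origin) % L
        end = start + f.length
        feats.append(replace(f, start=start, end=end, wraps_origin=end > L))
    feats.sort(key=lambda f: (f.start, f.end))
    return replace(genome, sequence=seq, features=feats)


def linearize_at_gene(genome: Mitogenome, gene: str = "cox1") -> Mitogenome:
    """Rotate so the named gene (default cox1) starts the linear view."""
    f = genome.get(gene)
    if f is None:
        return genome
    return linearize_at(genome, f.start)
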