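"""Screening of unassigned mitogenome regions for supernumerary ORFs.

DUI bivalves carry sex-specific open reading frames (mtORFans) with no
homology to known genes, usually encoding at least one transmembrane
helix.  The screen extracts the unassigned regions between annotated
genes, calls coding-strand ORFs of at least 150 nt in all three frames
under the invertebrate mitochondrial code, and keeps candidates whose
protein has a predicted transmembrane segment.

Transmembrane prediction is a documented Kyte–Doolittle sliding-window
hydropathy scan (window 19, threshold 1.6, minimum merged span 15 aa),
not an HMM: the candidate lists it produces are therefore comparable in
spirit, not residue-for-residue, with HMM-based annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .features import boundary_table
from .model import GeneticCode, INVERTEBRATE_MITO, Mitogenome, translate_mito

log = logging.getLogger(__name__)

__all__ = [
    "IntergenicRegion",
    "OrfCandidate",
    "OrfanConfig",
    "KYTE_DOOLITTLE",
    "unassigned_regions",
    "find_orfs",
    "predict_tmh",
    "screen_orfans",
    "OrfanScreenResult",
]

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass
class IntergenicRegion:
    genome_id: str
    upstream: str
    downstream: str
    start: int  # 0-based, post-linearization; end may exceed genome length
    end: int    # for the wrap region (sequence follows the circle)
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfCandidate:
    region: IntergenicRegion
    start: int        # genome coordinates (may exceed length for wrap regions)
    end: int
    frame: int        # 0/1/2 within the region
    start_codon: str
    nt_length: int    # start through stop codon inclusive
    protein: str      # stop excluded
    tmh_segments: list[tuple[int, int]] = field(default_factory=list)
    passes_filter: bool = False


@dataclass
class OrfanConfig:
    min_region_len: int = 150
    min_orf_len: int = 150           # nt, stop codon included
    tmh_window: int = 19
    tmh_threshold: float = 1.6
    tmh_min_helix: int = 15
    #: (upstream, downstream) region pairs to skip, e.g. the trnF-cox1
    #: spacer that may be a 5' extension of cox1.
    excluded_regions: tuple[tuple[str, str], ...] = ()


def unassigned_regions(genome: Mitogenome, min_len: int = 1) -> list[IntergenicRegion]:
    """Maximal gaps of >= ``min_len`` nt between adjacent annotated
    features, including the wrap gap back to the first feature."""
    table = boundary_table(genome)
    feats = genome.sorted_features()
    ends = {f.name: f.end for f in feats}
    starts = {f.name: f.start for f in feats}
    regions = []
    for i, (up, down, n) in enumerate(table.rows):
        if n < min_len:
            continue
        start = ends[up]
        if i == len(table.rows) - 1:  # wrap pair
            end = starts[down] + genome.length
            seq = genome.sequence[start:] + genome.sequence[:starts[down]]
        else:
            end = starts[down]
            seq = genome.sequence[start:end]
        regions.append(IntergenicRegion(genome.identifier, up, down, start, end, seq))
    return regions


def find_orfs(
    region: IntergenicRegion,
    min_len: int = 150,
    code: GeneticCode = INVERTEBRATE_MITO,
    start_codons: frozenset | None = None,
    stop_codons: frozenset | None = None,
) -> list[OrfCandidate]:
    """Coding-strand ORFs in all three frames of an unassigned region.

    An ORF runs from an allowed start codon to the first in-frame stop,
    both inside the region; nested ORFs sharing a stop are collapsed to
    the longest (earliest start).  ``min_len`` counts start through stop
    codon inclusive.
    """
    starts = start_codons or code.start_codons
    stops = stop_codons or code.stop_codons
    seq = region.sequence.upper()
    out: list[OrfCandidate] = []
    for frame in range(3):
        first_start: int | None = None  # codon-seq offset of earliest start since last stop
        for off in range(frame, len(seq) - 2, 3):
            codon = seq[off:off + 3]
            if codon in stops:
                if first_start is not None:
                    nt_len = off + 3 - first_start
                    if nt_len >= min_len:
                        orf_nt = seq[first_start:off]
                        protein, internal = translate_mito(orf_nt, code)
                        if not internal:
                            out.append(
                                OrfCandidate(
                                    region=region,
                                    start=region.start + first_start,
                                    end=region.start + off + 3,
                                    frame=frame,
                                    start_codon=seq[first_start:first_start + 3],
                                    nt_length=nt_len,
                                    protein=protein,
                                )
                            )
                first_start = None
            elif first_start is None and codon in starts:
                first_start = off
    out.sort(key=lambda o: (o.start, o.end))
    return out


def predict_tmh(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_helix: int = 15,
) -> list[tuple[int, int]]:
    """Candidate transmembrane segments from mean Kyte–Doolittle hydropathy.

    Every length-``window`` stretch whose mean hydropathy exceeds
    ``threshold`` is kept; overlapping windows are merged and merged spans
    shorter than ``min_helix`` residues are discarded.  Returns half-open
    residue intervals.
    """
    protein = protein.upper()
    if len(protein) < window:
        log.info("protein of %d aa shorter than window %d", len(protein), window)
        return []
    scores = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    acc = [0.0]
    for s in scores:
        acc.append(acc[-1] + s)
    spans = []
    for i in range(len(protein) - window + 1):
        if (acc[i + window] - acc[i]) / window > threshold:
            spans.append((i, i + window))
    merged: list[list[int]] = []
    for a, b in spans:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a >= min_helix]


@dataclass
class OrfanScreenResult:
    candidates: list[OrfCandidate]
    skipped_regions: list[IntergenicRegion]
    regions: list[IntergenicRegion]

    def passing(self) -> list[OrfCandidate]:
        return [c for c in self.candidates if c.passes_filter]


def screen_orfans(
    genome: Mitogenome, config: OrfanConfig | None = None
) -> OrfanScreenResult:
    """Compose region extraction, ORF calling and TMH filtering.

    Regions listed in ``config.excluded_regions`` are reported as skipped
    rather than silently dropped; every ORF is returned with its
    ``passes_filter`` flag so callers see the rejected candidates too.
    """
    config = config or OrfanConfig()
    regions = unassigned_regions(genome, min_len=config.min_region_len)
    skipped = [r for r in regions if (r.upstream, r.downstream) in set(config.excluded_regions)]
    skipped_keys = {(r.upstream, r.downstream) for r in skipped}
    candidates: list[OrfCandidate] = []
    for region in regions:
        if (region.upstream, region.downstream) in skipped_keys:
            continue
        for orf in find_orfs(region, min_len=config.min_orf_len):
            orf.tmh_segments = predict_tmh(
                orf.protein, config.tmh_window, config.tmh_threshold, config.tmh_min_helix
            )
            orf.passes_filter = len(orf.tmh_segments) >= 1
            candidates.append(orf)
    return OrfanScreenResult(candidates, skipped, regions)


def write_orfan_report(result: OrfanScreenResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\tframe\tstart_codon\tnt_length\taa_length\t"
                 "tmh_segments\tpasses_filter\n")
        for c in result.candidates:
            segs = ";".join(f"{a + 1}-{b}" for a, b in c.tmh_segments) or "."
            fh.write(
                f"{c.region.upstream}-{c.region.downstream}\t{c.start + 1}\t{c.end}\t"
                f"{c.frame}\t{c.start_codon}\t{c.nt_length}\t{len(c.protein)}\t"
                f"{segs}\t{c.passes_filter}\n"
            )
        for r in result.skipped_regions:
            fh.write(f"# skipped region {r.upstream}-{r.downstream} ({r.length} nt)\n")
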