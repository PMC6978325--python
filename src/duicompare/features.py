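"""Descriptive genome accounting: per-gene tables, boundary/overlap counts,
start/stop codon tallies and F-vs-M size comparison.

These are the bookkeeping views a mitogenome description rests on: each
gene's length and its initiation/termination codons, the number of
nucleotides between every adjacent gene pair (negative when genes overlap,
including the wrap-around pair on the circle), and pooled codon-usage
tallies across a set of genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Mitogenome

__all__ = [
    "GeneRow",
    "BoundaryTable",
    "CodonUsageSummary",
    "gene_table",
    "boundary_table",
    "codon_usage_summary",
    "size_comparison",
    "INCOMPLETE_STOP",
]

#: Display token for a polyadenylation-completed stop codon.
INCOMPLETE_STOP = "T**"


@dataclass(frozen=True)
class GeneRow:
    name: str
    length: int
    start_codon: str | None  # None for RNA genes
    stop_codon: str | None   # INCOMPLETE_STOP for T** genes


@dataclass
class BoundaryTable:
    """Adjacency chain of a linearized genome: one row per neighbouring
    feature pair plus the wrap pair, with the intergenic nucleotide count
    (negative = overlap)."""

    genome_id: str
    genome_length: int
    rows: list[tuple[str, str, int]] = field(default_factory=list)

    def get(self, upstream: str, downstream: str) -> int:
        for u, d, n in self.rows:
            if u == upstream and d == downstream:
                return n
        raise KeyError(f"no boundary {upstream} -> {downstream}")

    def total_intergenic(self) -> int:
        return sum(n for _, _, n in self.rows)


@dataclass
class CodonUsageSummary:
    start_counts: dict[str, int]
    stop_counts: dict[str, int]  # complete stops only
    incomplete_stops: int
    n_pcgs: int

    def __post_init__(self) -> None:
        if sum(self.start_counts.values()) != self.n_pcgs:
            raise ValueError("start-codon counts do not sum to the PCG count")
        if sum(self.stop_counts.values()) + self.incomplete_stops != self.n_pcgs:
            raise ValueError("stop-codon counts do not sum to the PCG count")


def gene_table(genome: Mitogenome) -> list[GeneRow]:
    """Per-gene lengths and, for protein genes, start/stop codons read off
    the sequence.  Order follows the genome's own annotation order."""
    rows = []
    for f in genome.features:
        if f.category == "PCG":
            if f.length < 6:
                raise ValueError(f"{f.name}: PCG of {f.length} nt is shorter than start+stop")
            seq = genome.feature_seq(f)
            start = seq[:3]
            if f.incomplete_stop:
                stop = INCOMPLETE_STOP
            else:
                stop = seq[-3:]
            rows.append(GeneRow(f.name, f.length, start, stop))
        else:
            rows.append(GeneRow(f.name, f.length, None, None))
    return rows


def boundary_table(genome: Mitogenome) -> BoundaryTable:
    """Intergenic nucleotide counts between adjacent features.

    Features are taken in linearized start order; the final row is the wrap
    pair (last feature back around to the first).  Nested features break
    the adjacency-chain model and are rejected.
    """
    feats = genome.sorted_features()
    if len(feats) < 2:
        raise ValueError("need at least two features for a boundary table")
    for a, b in zip(feats, feats[1:]):
        if b.start < a.end and b.end <= a.end:
            raise ValueError(f"nested feature pair: {b.name} inside {a.name}")
    rows = []
    for a, b in zip(feats, feats[1:]):
        rows.append((a.name, b.name, b.start - a.end))
    last, first = feats[-1], feats[0]
    rows.append((last.name, first.name, first.start + genome.length - last.end))
    return BoundaryTable(genome.identifier, genome.length, rows)


def codon_usage_summary(genomes: list[Mitogenome]) -> CodonUsageSummary:
    """Pool start/stop codon tallies over all protein genes of all genomes.

    Incomplete (T**) stops are counted separately, never folded into the
    complete TAA/TAG tallies.
    """
    starts: dict[str, int] = {}
    stops: dict[str, int] = {}
    incomplete = 0
    n = 0
    for g in genomes:
        for row in gene_table(g):
            if row.start_codon is None:
                continue
            n += 1
            starts[row.start_codon] = starts.get(row.start_codon, 0) + 1
            if row.stop_codon == INCOMPLETE_STOP:
                incomplete += 1
            else:
                stops[row.stop_codon] = stops.get(row.stop_codon, 0) + 1
    return CodonUsageSummary(starts, stops, incomplete, n)


def size_comparison(f: Mitogenome, m: Mitogenome) -> tuple[int, int, int]:
    """Genome lengths of an F/M pair and their absolute difference."""
    return f.length, m.length, abs(f.length - m.length)


# --- TSV writers -----------------------------------------------------------

def write_gene_table(rows: list[GeneRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlength_nt\tstart_codon\tstop_codon\n")
        for r in rows:
            fh.write(f"{r.name}\t{r.length}\t{r.start_codon or '.'}\t{r.stop_codon or '.'}\n")


def write_boundary_table(table: BoundaryTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("upstream\tdownstream\tintergenic_nt\n")
        for u, d, n in table.rows:
            fh.write(f"{u}\t{d}\t{n}\n")


def write_codon_usage(summary: CodonUsageSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tcodon\tcount\tof\n")
        for codon, c in sorted(summary.start_counts.items(), key=lambda kv: -kv[1]):
            fh.write(f"start\t{codon}\t{c}\t{summary.n_pcgs}\n")
        for codon, c in sorted(summary.stop_counts.items(), key=lambda kv: -kv[1]):
            fh.write(f"stop\t{codon}\t{c}\t{summary.n_pcgs}\n")
        fh.write(f"stop\t{INCOMPLETE_STOP}\t{summary.incomplete_stops}\t{summary.n_pcgs}\n")
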