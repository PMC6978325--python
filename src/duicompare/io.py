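"""Readers and writers for annotated mitogenomes.

Two formats are supported: GenBank flat files (the deposit format of the
accessions this package was built around) and a FASTA file paired with a
5-column feature table (name, category, start, end, flags) using 1-based
inclusive coordinates, the convention of every human-readable output here.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    GeneFeature,
    Mitogenome,
    canonical_gene_name,
    category_of,
    linearize_at_gene,
)

log = logging.getLogger(__name__)

_AMBIG = re.compile(r"[^ACGTN]")


def _clean_sequence(seq: str, label: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes other than N to N."""
    seq = seq.upper().replace("U", "T")
    n_amb = len(_AMBIG.findall(seq))
    if n_amb:
        log.warning("%s: %d ambiguity symbols mapped to N", label, n_amb)
        seq = _AMBIG.sub("N", seq)
    return seq


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "label", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_genbank(path, linearize: str | None = "cox1") -> Mitogenome:
    """Read one GenBank record into a :class:`Mitogenome`.

    Feature names are canonicalized (COIII -> cox3, 12S -> rrnS, ...) and
    duplicated genes are disambiguated with ``_0``/``_1`` suffixes when the
    annotation itself does not carry them.  By default the circular genome
    is rotated so cox1 opens the linear view; pass ``linearize=None`` to
    keep the deposited rotation.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenBank record: {exc}") from exc
    circular = record.annotations.get("topology", "circular") == "circular"
    seq = _clean_sequence(str(record.seq), record.id)
    L = len(seq)
    if L == 0:
        raise ValueError(f"{path}: record has no sequence")

    feats: list[GeneFeature] = []
    seen_cds_spans: set[tuple[int, int]] = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        raw = _feature_name(feat)
        if raw is None:
            continue
        symbol, suffix = canonical_gene_name(raw)
        cat = category_of(symbol)
        if feat.type == "CDS" and cat == "other":
            cat = "PCG" if symbol.lower().startswith(("nad", "cox", "atp", "cob")) else "other"
        elif feat.type == "tRNA" and cat == "other":
            cat = "tRNA"
        elif feat.type == "rRNA" and cat == "other":
            cat = "rRNA"
        elif feat.type == "gene":
            # gene features duplicate CDS/tRNA/rRNA ones; keep only typed ones
            continue
        loc = feat.location
        wraps = False
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin-spanning join(a..L, 1..b)
            if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == L:
                start = int(parts[1].start)
                end = L + int(parts[0].end)
                wraps = True
            else:
                start, end = int(loc.start), int(loc.end)
        else:
            start, end = int(loc.start), int(loc.end)
        if not (0 <= start < L) or (end > L and not wraps):
            raise ValueError(f"{path}: feature {raw} outside sequence [0,{L})")
        span = (start, end)
        if feat.type == "CDS" and span in seen_cds_spans:
            continue
        if feat.type == "CDS":
            seen_cds_spans.add(span)
        length = end - start
        feats.append(
            GeneFeature(
                name=symbol + (suffix or ""),
                category=cat,
                start=start,
                end=end,
                wraps_origin=wraps,
                incomplete_stop=(cat == "PCG" and length % 3 != 0),
            )
        )
    # disambiguate duplicates lacking suffixes
    by_symbol: dict[str, list[GeneFeature]] = {}
    for f in feats:
        by_symbol.setdefault(f.name, []).append(f)
    for symbol, group in by_symbol.items():
        if len(group) > 1 and "_" not in symbol:
            for i, f in enumerate(group):
                f.name = f"{symbol}_{i}"
    feats.sort(key=lambda f: (f.start, f.end))

    organism = record.annotations.get("organism", record.description or "unknown")
    sex = "unknown"
    desc = (record.description or "").lower()
    if "female" in desc or re.search(r"\bf[- ]?(type|mtdna|mitotype)", desc):
        sex = "F"
    elif "male" in desc or re.search(r"\bm[- ]?(type|mtdna|mitotype)", desc):
        sex = "M"
    genome = Mitogenome(
        identifier=record.id or path.stem,
        species=organism,
        sex_type=sex,
        sequence=seq,
        circular=circular,
        features=feats,
    )
    genome.validate()
    if linearize is not None and genome.circular:
        genome = linearize_at_gene(genome, linearize)
    return genome


def write_genbank(genome: Mitogenome, path) -> None:
    """Write a genome back out as a GenBank flat file (round-trip safe)."""
    seq_record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=re.sub(r"\W", "_", genome.identifier)[:16] or "mitogenome",
        description=f"{genome.species} {genome.sex_type}-type mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
        },
    )
    L = genome.length
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "CDS"}
    for f in genome.features:
        if f.wraps_origin and f.end > L:
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand=1),
                 SimpleLocation(0, f.end - L, strand=1)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand=1)
        quals = {"gene": [f.name]}
        if f.category == "PCG":
            quals["transl_table"] = ["5"]
            if f.incomplete_stop:
                quals["note"] = ["incomplete stop codon (T**) completed by polyadenylation"]
        seq_record.features.append(SeqFeature(loc, type=type_of[f.category], qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write(seq_record, fh, "genbank")


# --- FASTA + feature-table format ------------------------------------------

_TABLE_HEADER = "name\tcategory\tstart\tend\tflags"


def write_fasta_table(genome: Mitogenome, fasta_path, table_path) -> None:
    """Write sequence as FASTA and features as a 5-column TSV.

    Table coordinates are 1-based inclusive; the ``flags`` column is a
    comma-joined subset of {wraps_origin, incomplete_stop} or ``.``.
    """
    header = f"{genome.identifier} {genome.species} sex={genome.sex_type}" + (
        " circular" if genome.circular else " linear"
    )
    with open(fasta_path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")
    with open(table_path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for f in genome.features:
            flags = [n for n in ("wraps_origin", "incomplete_stop") if getattr(f, n)]
            fh.write(
                f"{f.name}\t{f.category}\t{f.start + 1}\t{f.end}\t"
                f"{','.join(flags) or '.'}\n"
            )


def read_fasta_table(fasta_path, table_path) -> Mitogenome:
    """Inverse of :func:`write_fasta_table`."""
    record = SeqIO.read(str(fasta_path), "fasta")
    parts = record.description.split()
    species = "unknown"
    sex = "unknown"
    circular = "circular" in parts
    rest = [p for p in parts[1:] if p not in ("circular", "linear") and not p.startswith("sex=")]
    if rest:
        species = " ".join(rest)
    for p in parts:
        if p.startswith("sex="):
            sex = p.split("=", 1)[1]
    feats = []
    with open(table_path) as fh:
        header = fh.readline().strip()
        if header != _TABLE_HEADER:
            raise ValueError(f"{table_path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ValueError(f"{table_path}:{lineno}: expected 5 columns")
            name, cat, start1, end1, flags = cols
            flagset = set() if flags == "." else set(flags.split(","))
            feats.append(
                GeneFeature(
                    name=name,
                    category=cat,
                    start=int(start1) - 1,
                    end=int(end1),
                    wraps_origin="wraps_origin" in flagset,
                    incomplete_stop="incomplete_stop" in flagset,
                )
            )
    genome = Mitogenome(
        identifier=record.id,
        species=species,
        sex_type=sex,
        sequence=_clean_sequence(str(record.seq), record.id),
        circular=circular,
        features=feats,
    )
    genome.validate()
    return genome


def write_records(genome: Mitogenome, path, format: str = "genbank") -> None:
    """Dispatching writer: ``genbank`` or ``fasta+table``.

    For ``fasta+table`` the path is used as a stem producing ``<stem>.fasta``
    and ``<stem>.tsv``.
    """
    if format == "genbank":
        write_genbank(genome, path)
    elif format == "fasta+table":
        stem = Path(path)
        write_fasta_table(genome, stem.with_suffix(".fasta"), stem.with_suffix(".tsv"))
    else:
        raise ValueError(f"unknown format {format!r}")
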