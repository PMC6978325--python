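"""Synthetic F/M mitogenome pairs with known ground truth.

The generator emulates the structure of a single-coding-strand bivalve
mitogenome (13 protein genes, 22 tRNAs, 2 rRNAs, a large rrnS-trnM
spacer) and derives a male-transmitted counterpart by a seeded
proposal-acceptance codon process: single-nucleotide changes are proposed
with a transition/transversion bias, stop-creating changes are rejected,
nonsynonymous changes are thinned by the acceptance probability omega,
and the process runs until the planted synonymous-divergence budget is
spent.  A large in-frame cox2 insertion, a supernumerary ORF with (or
without) a hydrophobic transmembrane-like stretch, and tRNA
duplication/loss events are planted on top, and every planted quantity is
recorded in a :class:`SimulationTruth` for recovery tests.

Deliberate simplifications, chosen so planted elements are recovered
unambiguously: intergenic spacers use a C/T-only alphabet (no start
codons can arise there) and are copied unchanged into the M genome; the
codon process is a thinned proposal scheme, not a continuous-time codon
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .divergence import ng86_codon_sites
from .model import GeneFeature, INVERTEBRATE_MITO, Mitogenome, category_of

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_f_genome",
    "evolve_m_genome",
    "simulate_pair",
    "DEFAULT_GENE_PLAN",
]

_CODE = INVERTEBRATE_MITO
_SENSE_CODONS = sorted(c for c, aa in _CODE.codon_to_aa.items() if aa != "*")
_STARTS = sorted(_CODE.start_codons)

#: (gene, length) in F-type annotation order, mirroring a real F mitogenome
#: annotation (cob carries an incomplete stop, hence the non-multiple-of-3
#: length).
DEFAULT_GENE_PLAN = (
    ("cox1", 1554), ("nad4", 1323), ("trnH", 65), ("trnS2", 64), ("trnE", 66),
    ("nad3", 348), ("trnI", 68), ("trnK", 64), ("nad4L", 291), ("trnY", 64),
    ("trnT", 63), ("trnL1", 66), ("trnD", 63), ("trnL2", 66), ("nad1", 924),
    ("trnN", 66), ("nad5", 1635), ("trnR", 67), ("cob", 1135), ("cox2", 861),
    ("trnV", 69), ("trnW", 66), ("trnG", 68), ("rrnS", 896), ("trnM", 66),
    ("atp8", 129), ("trnS1", 71), ("nad6", 510), ("rrnL", 1269), ("atp6", 714),
    ("cox3", 882), ("nad2", 996), ("trnP", 66), ("trnQ", 67), ("trnC", 63),
    ("trnA", 65), ("trnF", 63),
)

#: ORF interior building blocks: 4-codon units whose +1/+2 frames contain
#: stop codons, so a planted ORF cannot spawn overlapping-frame ORFs.
_HYDROPHOBIC_BLOCK = "CTAATTATTAAT"   # Leu Ile Ile Asn, mean KD ~ +2.3
_HYDROPHILIC_BLOCK = "ATAAATGATAAT"   # Met Asn Asp Asn, mean KD ~ -2.2


@dataclass(frozen=True)
class OrfanPlant:
    region: tuple[str, str] = ("rrnS", "trnM")
    length_nt: int = 240
    offset: int = 50            # nt into the spacer
    hydrophobic: bool = True    # False plants a TMH-free decoy


@dataclass(frozen=True)
class SimulationConfig:
    gene_plan: tuple = DEFAULT_GENE_PLAN
    incomplete_stop_genes: tuple = ("cob",)
    spacer_range: tuple[int, int] = (0, 80)
    named_spacers: tuple = ((("rrnS", "trnM"), 700),)
    omega: float = 0.1                     # dN/dS acceptance probability
    target_ds: float = 0.5                 # synonymous substitutions per syn site
    kappa: float = 2.0                     # transition/transversion rate ratio
    rna_divergence: float = 0.2            # per-site substitution prob, RNA genes
    cox2_insertion_codons: int = 1606
    cox2_insertion_at_codon: int = 120
    orfan: OrfanPlant | None = OrfanPlant()
    trna_events: tuple = ()                # e.g. (("loss","trnT"), ("dup","trnA"))
    species: str = "Simulicola ficta"

    def omega_for(self, gene: str) -> float:
        return self.omega

    def ds_for(self, gene: str) -> float:
        return self.target_ds


@dataclass
class SimulationTruth:
    per_gene: dict = field(default_factory=dict)  # gene -> realized counts
    insertion: dict | None = None
    orfan: dict | None = None
    trna_events: list = field(default_factory=list)


# --- internal segment representation ---------------------------------------

@dataclass
class _Segment:
    kind: str   # 'gene' | 'spacer'
    name: str
    seq: str
    category: str = ""
    incomplete_stop: bool = False


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    # C/T alphabet: no start codon can occur, keeping unassigned regions inert
    return "".join(rng.choice(["C", "T"], size=length)) if length else ""


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _random_pcg(rng: np.random.Generator, length: int, incomplete: bool) -> str:
    overhang = length % 3
    if incomplete:
        stop = "T" * overhang if overhang else "TAA"
    else:
        if overhang:
            raise ValueError("complete-stop gene length must be a codon multiple")
        stop = str(rng.choice(["TAA", "TAG"]))
    body_codons = (length - 3 - len(stop)) // 3
    if body_codons < 0:
        raise ValueError("gene too short")
    start = str(rng.choice(_STARTS))
    body = "".join(rng.choice(_SENSE_CODONS, size=body_codons))
    return start + body + stop


def _segments_to_genome(
    segments: list[_Segment], identifier: str, species: str, sex: str
) -> Mitogenome:
    seq_parts = []
    feats = []
    pos = 0
    for seg in segments:
        if seg.kind == "gene":
            feats.append(
                GeneFeature(
                    name=seg.name,
                    category=seg.category,
                    start=pos,
                    end=pos + len(seg.seq),
                    incomplete_stop=seg.incomplete_stop,
                )
            )
        seq_parts.append(seg.seq)
        pos += len(seg.seq)
    genome = Mitogenome(identifier, species, sex, "".join(seq_parts), True, feats)
    genome.validate()
    return genome


def _build_segments(config: SimulationConfig, rng: np.random.Generator) -> list[_Segment]:
    named = {pair: ln for pair, ln in config.named_spacers}
    plan = list(config.gene_plan)
    segments: list[_Segment] = []
    for i, (name, length) in enumerate(plan):
        base = name.split("_")[0]
        cat = category_of(base)
        if cat == "PCG":
            incomplete = base in config.incomplete_stop_genes
            seq = _random_pcg(rng, length, incomplete)
        elif cat in ("tRNA", "rRNA"):
            incomplete = False
            seq = _random_rna(rng, length)
        else:
            raise ValueError(f"gene plan entry {name!r} is not a known gene")
        segments.append(_Segment("gene", name, seq, cat, incomplete))
        nxt = plan[(i + 1) % len(plan)][0]
        spacer_len = named.get((name, nxt))
        if spacer_len is None:
            spacer_len = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
        segments.append(_Segment("spacer", f"{name}..{nxt}", _random_spacer(rng, spacer_len)))
    return segments


def simulate_f_genome(
    config: SimulationConfig | None = None, seed: int = 0
) -> Mitogenome:
    """Deterministically generate a female-type genome from a seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    segments = _build_segments(config, rng)
    return _segments_to_genome(segments, f"SIMF{seed:06d}", config.species, "F")


# --- codon-level evolution --------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _propose_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tvs = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
    return tvs[int(rng.integers(0, 2))]


def _inverse_jc(d: float) -> float:
    """Expected proportion of differing sites after JC divergence d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _evolve_cds(
    body: str, omega: float, target_ds: float, kappa: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Evolve the interior codons of a gene (start/stop excluded).

    Returns (evolved body, accepted synonymous, accepted nonsynonymous).
    The synonymous budget is the NG86 synonymous site count times the
    p-proportion implied by the target dS under Jukes-Cantor.
    """
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    s_sites = sum(ng86_codon_sites(c)[0] for c in codons)
    budget = int(round(_inverse_jc(target_ds) * s_sites))
    syn = nonsyn = 0
    attempts = 0
    max_attempts = 1000 * max(budget, 1)
    while syn < budget and attempts < max_attempts:
        attempts += 1
        ci = int(rng.integers(0, len(codons)))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        new = old[:pos] + _propose_base(rng, old[pos], kappa) + old[pos + 1:]
        if _CODE.codon_to_aa[new] == "*":
            continue
        if _CODE.codon_to_aa[new] == _CODE.codon_to_aa[old]:
            codons[ci] = new
            syn += 1
        elif rng.random() < omega:
            codons[ci] = new
            nonsyn += 1
    return "".join(codons), syn, nonsyn


def _evolve_rna(seq: str, p: float, kappa: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        out[i] = _propose_base(rng, out[i], kappa)
    return "".join(out)


def _random_insertion(
    rng: np.random.Generator, n_codons: int, avoid_aa: set[str], depth: int = 2
) -> str:
    """Stop-free random codon run whose edge residues (``depth`` codons at
    each end) avoid the residues flanking the insertion junction, so the
    protein alignment cannot slide the gap block (keeps planted
    coordinates recoverable exactly)."""
    # low-complexity Trp/Cys/Phe interior: compositionally unlike the
    # evolved gene, so no interior stretch aligns spuriously to the F gene
    pool = ["TGG", "TGT", "TGC", "TTT", "TTC"]
    codons = list(rng.choice(pool, size=n_codons))
    for idx in list(range(min(depth, n_codons))) + list(range(max(0, n_codons - depth), n_codons)):
        guard = 0
        while _CODE.codon_to_aa[codons[idx]] in avoid_aa and guard < 200:
            codons[idx] = str(rng.choice(_SENSE_CODONS))
            guard += 1
    return "".join(codons)


def _make_orf(length_nt: int, hydrophobic: bool) -> str:
    block = _HYDROPHOBIC_BLOCK if hydrophobic else _HYDROPHILIC_BLOCK
    interior = length_nt - 6
    if interior < 0 or length_nt % 3:
        raise ValueError("ORF length must be a codon multiple >= 6")
    body = (block * (interior // len(block) + 1))[:interior]
    return "ATG" + body + "TAA"


def evolve_m_genome(
    f: Mitogenome, config: SimulationConfig | None = None, seed: int = 1
) -> tuple[Mitogenome, SimulationTruth]:
    """Derive a male-type genome from an F genome with planted truth.

    Protein genes evolve codon-wise (stop-rejecting, omega-thinned); RNA
    genes evolve under per-site substitution; then the cox2 insertion,
    the supernumerary ORF and any tRNA duplication/loss events are
    planted.  All planted coordinates refer to the returned M genome.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()

    # decompose F into segments (simulated genomes are overlap-free)
    segments: list[_Segment] = []
    feats = f.sorted_features()
    for i, feat in enumerate(feats):
        seq = f.feature_seq(feat)
        segments.append(
            _Segment("gene", feat.name, seq, feat.category, feat.incomplete_stop)
        )
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            spacer = f.sequence[feat.end:nxt.start]
        else:
            spacer = f.sequence[feat.end:] + f.sequence[:feats[0].start]
        segments.append(_Segment("spacer", f"{feat.name}..{nxt.name}", spacer))

    out: list[_Segment] = []
    for seg in segments:
        if seg.kind == "spacer":
            out.append(seg)
            continue
        if seg.category == "PCG":
            start, stop_len = seg.seq[:3], (len(seg.seq) % 3 or 3)
            if seg.incomplete_stop:
                stop = seg.seq[-(len(seg.seq) % 3):] if len(seg.seq) % 3 else seg.seq[-3:]
            else:
                stop = seg.seq[-3:]
            body = seg.seq[3:len(seg.seq) - len(stop)]
            gene = seg.name.split("_")[0]
            evolved, syn, nonsyn = _evolve_cds(
                body, config.omega_for(gene), config.ds_for(gene), config.kappa, rng
            )
            truth.per_gene[seg.name] = {
                "omega": config.omega_for(gene),
                "target_ds": config.ds_for(gene),
                "syn_events": syn,
                "nonsyn_events": nonsyn,
            }
            out.append(replace(seg, seq=start + evolved + stop))
        else:
            out.append(
                replace(seg, seq=_evolve_rna(seg.seq, config.rna_divergence, config.kappa, rng))
            )

    # plant the cox2 in-frame insertion
    if config.cox2_insertion_codons > 0:
        for seg in out:
            if seg.kind == "gene" and seg.name.split("_")[0] == "cox2":
                at = 3 * config.cox2_insertion_at_codon
                if not (3 <= at <= len(seg.seq) - 3):
                    raise ValueError("cox2 insertion point outside the gene body")
                f_feat = f.get("cox2")
                f_seq = f.feature_seq(f_feat) if f_feat else seg.seq
                # pin three codons each side of the junction to the F state
                # so the gap block's optimal placement is the planted one
                pinned = bytearray(seg.seq.encode())
                lo = max(3, at - 9)
                pinned[lo:at] = f_seq[lo:at].encode()
                hi = min(len(seg.seq) - 3, at + 9)
                pinned[at:hi] = f_seq[at:hi].encode()
                seg.seq = pinned.decode()
                avoid = {
                    _CODE.codon_to_aa.get(f_seq[j:j + 3], "X")
                    for j in range(max(0, at - 9), min(len(f_seq) - 2, at + 9), 3)
                }
                ins = _random_insertion(rng, config.cox2_insertion_codons, avoid)
                seg.seq = seg.seq[:at] + ins + seg.seq[at:]
                truth.insertion = {
                    "gene": "cox2",
                    "m_gene_nt_start": at,
                    "length_nt": len(ins),
                    "codons": config.cox2_insertion_codons,
                }
                break

    # plant the supernumerary ORF into its spacer
    if config.orfan is not None:
        up, down = config.orfan.region
        spacer_name = f"{up}..{down}"
        for seg in out:
            if seg.kind == "spacer" and seg.name == spacer_name:
                orf = _make_orf(config.orfan.length_nt, config.orfan.hydrophobic)
                if config.orfan.offset + len(orf) > len(seg.seq):
                    raise ValueError("spacer too short for the planted ORF")
                seg.seq = (
                    seg.seq[:config.orfan.offset]
                    + orf
                    + seg.seq[config.orfan.offset + len(orf):]
                )
                truth.orfan = {
                    "region": (up, down),
                    "spacer_offset": config.orfan.offset,
                    "length_nt": len(orf),
                    "n_tmh": 1 if config.orfan.hydrophobic else 0,
                }
                break
        else:
            raise ValueError(f"no spacer {spacer_name} to plant the ORF into")

    # tRNA duplication / loss events
    for op, gene in config.trna_events:
        if op == "loss":
            idx = next(
                (i for i, s in enumerate(out) if s.kind == "gene" and s.name == gene),
                None,
            )
            if idx is None:
                raise ValueError(f"cannot lose absent gene {gene}")
            out[idx] = _Segment("spacer", f"lost:{gene}", out[idx].seq)
            truth.trna_events.append(("loss", gene))
        elif op == "dup":
            idx = next(
                (i for i, s in enumerate(out) if s.kind == "gene" and s.name == gene),
                None,
            )
            if idx is None:
                raise ValueError(f"cannot duplicate absent gene {gene}")
            orig = out[idx]
            out[idx] = replace(orig, name=f"{gene}_0")
            copy = _Segment("gene", f"{gene}_1", orig.seq, orig.category)
            out.insert(idx + 1, _Segment("spacer", f"{gene}_0..{gene}_1", ""))
            out.insert(idx + 2, copy)
            truth.trna_events.append(("dup", gene))
        else:
            raise ValueError(f"unknown tRNA event {op!r}")

    m = _segments_to_genome(
        out, f.identifier.replace("SIMF", "SIMM"), f.species, "M"
    )
    # resolve planted coordinates in the assembled M genome
    if truth.insertion is not None:
        cox2_feat = m.get("cox2")
        truth.insertion["m_genome_start"] = cox2_feat.start + truth.insertion["m_gene_nt_start"]
        truth.insertion["m_genome_end"] = (
            truth.insertion["m_genome_start"] + truth.insertion["length_nt"]
        )
    if truth.orfan is not None:
        up = truth.orfan["region"][0]
        up_feat = m.get(up)
        start = up_feat.end + truth.orfan["spacer_offset"]
        truth.orfan["m_genome_start"] = start
        truth.orfan["m_genome_end"] = start + truth.orfan["length_nt"]
    return m, truth


def simulate_pair(
    config: SimulationConfig | None = None, seed: int = 0, outdir=None
) -> tuple[Mitogenome, Mitogenome, SimulationTruth]:
    """F genome, evolved M genome and the planted truth; optionally written
    to ``outdir`` as GenBank files plus a TSV truth sidecar."""
    config = config or SimulationConfig()
    f = simulate_f_genome(config, seed)
    m, truth = evolve_m_genome(f, config, seed + 1)
    if outdir is not None:
        from pathlib import Path

        from .io import write_genbank

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genbank(f, outdir / "F.gb")
        write_genbank(m, outdir / "M.gb")
        write_truth(truth, outdir / "truth.tsv")
    return f, m, truth


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        for gene, d in truth.per_gene.items():
            for k, v in d.items():
                fh.write(f"gene.{gene}.{k}\t{v}\n")
        for scope, d in (("insertion", truth.insertion), ("orfan", truth.orfan)):
            if d:
                for k, v in d.items():
                    fh.write(f"{scope}.{k}\t{v}\n")
        for op, gene in truth.trna_events:
            fh.write(f"trna_event\t{op}:{gene}\n")
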