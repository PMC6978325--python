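# Methods

`duicompare` compares the female-transmitted (F) and male-transmitted (M)
mitochondrial genomes that coexist in bivalve species with doubly
uniparental inheritance (DUI). This note documents the models,
conventions and numerical choices behind each stage, what the synthetic
data generator does and does not emulate, and the known limitations.

## Records and coordinates

A `Mitogenome` is a circular, single-coding-strand annotated sequence
with a sex type; features carry 0-based half-open coordinates internally
and every human-readable output (TSVs, reports) converts to 1-based
inclusive. Circular genomes are linearized at the start of cox1 on
ingest; a feature spanning the origin keeps valid half-open coordinates
with a `wraps_origin` flag and round-trips through GenBank `join`
locations. IUPAC ambiguity codes other than N are mapped to N with a
logged warning. Protein genes whose length is not a codon multiple must
carry the incomplete-stop flag (`T**`): such stops are completed by
polyadenylation of the transcript and the trailing 1–2 nt are trimmed
before translation.

Translation uses NCBI table 5 (invertebrate mitochondrial): AGA/AGG are
serine, ATA is methionine, TGA is tryptophan; only TAA/TAG terminate.
The start-codon set used for validation and ORF calling is
{ATG, ATA, ATT, TTG, GTG} — the union observed across bivalve
mitogenome annotations. Internal stop codons in a translation are
returned as positions rather than raised, because a split gene (see
cox2 below) is a finding, not an error.

## Feature accounting

`boundary_table` reports the nucleotides between each pair of adjacent
features in linearized order plus the wrap pair; negative values mean
overlap. Nested features are rejected: the table models a linear
adjacency chain, and the conservation identity

    sum(gene lengths) + sum(boundary counts) = genome length

holds exactly for any non-nested annotation (this identity is exercised
on simulated genomes and on the packaged study annotations).
Codon-usage tallies count incomplete stops separately — they are never
folded into the TAA/TAG counts.

The four deposited study genomes (MN528026/MN528027 for *Scrobicularia
plana* F/M, MN528028/MN528029 for *Limecola balthica* F/M) ship as
packaged TSV annotation summaries (per-gene lengths and start/stop
codons, boundary counts, reported sizes). `published.assemble_genome`
rebuilds coordinate-exact records from them with inert filler sequence,
which supports all feature accounting but carries no divergence signal;
sequence-level statistics on the real genomes require the deposited
records themselves. For *L. balthica* the chained per-gene and boundary
sums close the circle exactly at the reported sizes; for *S. plana* the
published tables are internally inconsistent by 1 bp (F) and 100 bp (M)
and the assembled lengths are reported as computed.

## Codon alignment

Each protein gene pair is aligned at the amino-acid level (global,
affine gaps, BLOSUM62, gap open 10, extend 0.5) and the nucleotide
sequences are threaded back through the protein alignment so every
column is one codon — the standard protein-guided (PAL2NAL-style)
construction. rRNA genes are aligned at the nucleotide level (match 2,
mismatch −3, open 8, extend 2). Alignment is delegated to Biopython's
`PairwiseAligner`; the first optimal alignment of its canonical
traversal is used, which makes results deterministic for fixed inputs
and scoring. Stop codons are removed before alignment.

Maximal runs of at least `min_gap_codons` (default 30) gap columns are
masked with reason `large_indel` and excluded from every downstream
statistic. The default separates multi-kilobase structural insertions —
the male cox2 insertion is the motivating case — from ordinary
alignment gaps; masking is idempotent and monotone in the threshold. An
externally produced codon alignment can be imported from FASTA
(lowercase columns become masked) when exact replication of a published
alignment is wanted.

## Divergence and selection statistics

*p-distance.* Uncorrected proportion of differing sites under pairwise
deletion: a column is compared only when neither row carries a gap or
ambiguity (N at the nucleotide level, X at the amino-acid level).
Site-level p-distances on protein genes are computed over the unmasked
codon columns.

*NG86 counting.* Synonymous/nonsynonymous sites per codon are computed
position by position as the fraction of the (up to 3) non-stop
single-nucleotide neighbours that preserve the amino acid, so every
codon contributes exactly three sites and N + S = 3L holds identically.
Differences between a codon pair are averaged with equal weight over
all minimal mutational pathways; pathways that pass through a stop
codon are dropped and the remainder re-averaged (if every pathway is
blocked the unrestricted average is used, counting stop-visiting steps
as nonsynonymous). Codon columns containing a gap, an N, or a stop in
either sequence are excluded entirely. Note that the textbook bounds
Nd ≤ N and Sd ≤ S hold at gene scale but not pointwise: a single codon
pair can realize one synonymous step while contributing less than one
synonymous site, so only non-negativity is enforced.

*Rate correction.* Ka and Ks apply the one-parameter Jukes–Cantor
transform d = −(3/4)·ln(1 − 4p/3) to pN = Nd/N and pS = Sd/S. At
p ≥ 3/4 the transform is undefined; the rate is reported as NaN with a
saturation flag and the uncorrected proportion remains available.

*Z-test of selection.* Z = (Ka − Ks) / sqrt(Var(Ka) + Var(Ks)). The
default variance is a seeded bootstrap over codon columns (1,000
replicates): per-column site/difference contributions are resampled
with replacement and the replicate rates recomputed, so the bootstrap
costs only column sums. A delta-method analytic variance
(binomial variance of the proportions propagated through the JC
transform) is provided as the alternative. The neutral null (Ka = Ks)
is two-tailed; the purifying (Ka < Ks) and positive (Ka > Ks)
alternatives are one-tailed, and their p-values are complementary.
Identical sequences return the Z = 0 convention. Fewer than 10 usable
codon columns is an error — the normal approximation is not defensible
there, which is also why very short genes (atp8-sized, ~43 codons) give
the test little power.

## ORFan screening

Unassigned regions are the positive boundary-table entries (wrap
included). ORFs are called on the coding strand only — these genomes
encode everything on one strand — in all three frames, from an allowed
start codon to the first in-frame stop, stop included in the minimum
length (default 150 nt); in-frame starts sharing a stop collapse to the
longest ORF. Overlapping ORFs in different frames are all reported.
Candidates are flagged `passes_filter` when the protein carries at
least one transmembrane-like segment.

Transmembrane prediction is a Kyte–Doolittle sliding-window scan:
every 19-residue window with mean hydropathy above 1.6 is kept,
overlapping windows are merged, and merged spans shorter than 15
residues are discarded. This is a transparent stand-in for HMM-based
predictors whose parameters are not reproducible here; it recovers
designed hydrophobic stretches reliably but will not match an HMM
residue-for-residue on borderline real proteins, so candidate *counts*
on real genomes are qualitative. The planted-truth recovery experiments
are the quantitative validation. Regions can be excluded by name (e.g.
a trnF–cox1 spacer that may be a 5' extension of cox1) and are then
reported as skipped rather than silently dropped.

## cox2 characterization

Insertions are maximal runs of at least 30 F-gap codon columns in the
F/M cox2 codon alignment, reported with nt coordinates in the M coding
sequence and an in-frame flag. Architecture is classified from the male
gene's own reading frame after trimming any trailing complete or
incomplete stop: no internal complete stop → `intact`; otherwise
`split` into cox2a (start through the internal stop) and cox2b (from
the next downstream start codon, searched in all three frames because
the sub-gene spacing is not constrained). The split call is invariant
to T** annotation.

Motif anchors (two N-terminal transmembrane helices, the heme-patch
region containing the electron-entry tryptophan, the two Cu_A-binding
centers) are located by aligning the query protein to a packaged
reference COX2 protein and projecting the reference's annotated motif
intervals; an anchor whose interval is covered by aligned query
residues below 50% is reported unresolved. The packaged reference
(`cox2_reference_synthetic.fasta`) is a constructed stand-in encoding
the canonical COX2 domain order, not a real protein — replace it with
an annotated real COX2 (any vertebrate reference works) when absolute
motif positions matter; with the stand-in, motif *ordering* and
insertion position relative to the anchors are the meaningful outputs.

## Synthetic data generator

`simulate_f_genome` emits a circular F genome with the canonical
13 PCG + 22 tRNA + 2 rRNA complement in the F-type gene order of the
study species, per-gene lengths matching a real F annotation, random
sense codons inside protein genes (cob carries an incomplete stop),
random RNA genes, and intergenic spacers drawn uniformly from 0–80 nt
except a named 700-nt rrnS–trnM region (mirroring the large unassigned
region of the real genomes).

`evolve_m_genome` derives the M genome:

* **Protein genes** evolve by proposal–acceptance: a random
  single-nucleotide change is proposed with transition/transversion
  ratio κ (default 2.0), stop-creating changes are rejected, synonymous
  changes are accepted, nonsynonymous changes are accepted with
  probability ω (default 0.1). The process stops when the synonymous
  budget — the NG86 synonymous site count times the proportion implied
  by the target dS (default 0.5) under Jukes–Cantor — is spent. This is
  deliberately not a continuous-time codon model (no GY94 matrix); it
  is simple, seeded and sufficient for recovery testing.
* **RNA genes** receive per-site substitutions at rate 0.2 with the
  same κ bias.
* **Planted elements**: a 1,606-codon stop-free in-frame insertion at
  codon 120 of cox2 (the scale of the real male insertion); a 240-nt
  ORF at offset 50 of the rrnS–trnM spacer whose interior encodes a
  hydrophobic Leu/Ile-rich stretch (or a hydrophilic decoy); optional
  tRNA loss/duplication events (e.g. lose trnT, duplicate trnA,
  mirroring the real male *L. balthica* annotation).

Realized synonymous/nonsynonymous event counts and all planted
coordinates are recorded in a `SimulationTruth`.

Three constructions keep planted truth recoverable exactly rather than
approximately, and are knowingly unrealistic:

* intergenic spacers use a C/T-only alphabet, so no start codon (all
  require A or G) can arise there and the only ORFs in unassigned
  regions are planted ones; spacers are copied unchanged into M;
* planted ORF interiors are built from 4-codon units whose +1/+2
  reading frames contain stops, so a planted ORF cannot spawn
  overlapping-frame candidates above threshold;
* the cox2 insertion pins three codons of F sequence on each side of
  the junction and fills its interior with low-complexity Trp/Cys/Phe
  codons (edge codons resampled away from the junction residues), so
  the optimal protein alignment places the gap block uniquely at the
  planted coordinates instead of sliding or splitting it.

Because proposals carry a κ = 2 transition bias while NG86 weighs all
neighbours equally, the nominal acceptance probability ω and the
realized per-site event-rate ratio differ: NG86 underestimates the
nominal ω by roughly the classical transition-bias factor, while it
recovers the *realized* ratio closely (a κ = 1 control recovers the
nominal ω almost exactly). The recovery experiments therefore report
the estimate against both references.

## Problem sizes and runtime choices

The packaged experiments use sizes chosen to make the statistics stable
while keeping the whole suite quick on one core: rate-recovery and
power experiments run a single ~500-codon gene (the scale of cox1) over
50 seeds with 1,000 bootstrap replicates; planted-element recovery runs
100 full genome pairs; the NG86 oracle comparison enumerates 1,000
random codon pairs. All randomness flows through explicit seeds
(`numpy.random.default_rng`), and identical (config, seed) inputs
reproduce outputs byte for byte.

## Known limitations

* The aligner is a pairwise global DP, not a multiple aligner; exact
  column-level replication of alignments produced by other heuristic
  tools is not guaranteed — gene-level statistics are the replication
  target, and an alignment import hook exists for exact replication.
* NG86 with equal pathway weights ignores transition bias and codon
  frequencies; under strong bias it underestimates dN/dS (see above).
  No likelihood-based codon models are provided.
* The hydropathy TMH predictor is not an HMM; borderline helices
  differ from HMM predictions, so real-genome candidate counts are
  indicative only.
* No multiple-testing correction is applied across genes.
* tRNA/rRNA structure, recombination and masculinization dynamics are
  not modelled by the simulator.
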