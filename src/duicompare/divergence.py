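"""Divergence and selection statistics for F-vs-M gene pairs.

Implements uncorrected p-distances (nucleotide and amino-acid level,
pairwise deletion), Nei–Gojobori (1986) counting of synonymous and
nonsynonymous sites and differences with equal-weight averaging over
minimal mutational pathways, Jukes–Cantor distance correction, and the
codon-based Z-test of selection with bootstrap or analytic (delta-method)
variance.

The NG86 conventions used here:

* per-codon site fractions are computed position-by-position as the
  fraction of the (up to 3) non-stop single-nucleotide neighbours that are
  synonymous, so every codon contributes exactly 3 sites (N + S = 3L);
* differences between a codon pair are averaged with equal weight over
  all minimal mutational pathways, excluding pathways that pass through a
  stop codon (if every pathway is blocked, all are used unweighted).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .codonalign import (
    CodonAlignment,
    DEFAULT_MIN_GAP_CODONS,
    align_nucleotides,
    align_proteins,
    back_translate_alignment,
    mask_large_indels,
)
from .model import (
    CANONICAL_PCGS,
    GeneticCode,
    INVERTEBRATE_MITO,
    Mitogenome,
    translate_mito,
)

__all__ = [
    "NGCounts",
    "DivergenceResult",
    "DivergenceConfig",
    "p_distance",
    "ng86_codon_sites",
    "ng86_pair_differences",
    "ng86_counts",
    "ng86_rates",
    "jukes_cantor",
    "z_test_selection",
    "gene_divergence",
    "divergence_report",
    "coding_sequence",
]

#: Alignments with fewer usable codon columns than this cannot support the
#: normal approximation of the Z-test.
MIN_CODONS_FOR_Z = 10


@dataclass
class NGCounts:
    """Nei–Gojobori site and difference counts over L compared codons."""

    N: float
    S: float
    Nd: float
    Sd: float
    L: int
    stop_columns_skipped: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.N + self.S, 3 * self.L, rel_tol=0, abs_tol=1e-6):
            raise ValueError("site counts violate N + S = 3L")
        # Nd <= N / Sd <= S holds for realistic gene-scale alignments but not
        # pointwise (a single codon pair can realize one synonymous step while
        # carrying under one synonymous site), so only non-negativity is hard.
        if self.Nd < -1e-9 or self.Sd < -1e-9:
            raise ValueError("negative difference counts")


@dataclass
class DivergenceResult:
    gene: str
    p_nt: float | None = None
    p_aa: float | None = None
    sites_nt: int = 0
    sites_aa: int = 0
    pN: float | None = None
    pS: float | None = None
    Ka: float | None = None
    Ks: float | None = None
    ka_saturated: bool = False
    ks_saturated: bool = False
    Z: float | None = None
    p_neutral: float | None = None
    p_purifying: float | None = None
    p_positive: float | None = None
    codons_used: int = 0
    note: str = ""


@dataclass
class DivergenceConfig:
    min_gap_codons: int = DEFAULT_MIN_GAP_CODONS
    variance: str = "bootstrap"       # or "analytic"
    bootstrap_reps: int = 1000
    seed: int = 0
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


# --- p-distance ------------------------------------------------------------

_NT_AMBIG = set("N-")
_AA_AMBIG = set("X-")


def p_distance(
    a: str, b: str, level: str = "nt", deletion: str = "pairwise"
) -> tuple[float, int]:
    """Uncorrected proportion of differing sites between two aligned rows.

    Under pairwise deletion a column is compared only when neither row has
    a gap or ambiguity there (``complete`` deletion is identical for a
    single pair and is accepted as an alias).  Returns ``(p, sites)``.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    ambig = _NT_AMBIG if level == "nt" else _AA_AMBIG
    compared = 0
    diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in ambig or y in ambig:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError("no comparable sites after deletion")
    return diffs / compared, compared


# --- NG86 counting ---------------------------------------------------------

_BASES = "ACGT"


def _neighbours(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1:])
    return out


@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str, table_id: int = 5) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site count of one sense codon.

    Position by position, the fraction of non-stop single-nucleotide
    neighbours coding the same amino acid; each position contributes one
    site so the codon contributes exactly three.
    """
    code = _code_by_id(table_id)
    aa = code.codon_to_aa[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:] for b in _BASES if b != codon[pos]]
        viable = [c for c in alts if code.codon_to_aa[c] != "*"]
        if viable:
            s += sum(1 for c in viable if code.codon_to_aa[c] == aa) / len(viable)
    return s, 3.0 - s


def _code_by_id(table_id: int) -> GeneticCode:
    if table_id != INVERTEBRATE_MITO.table_id:
        raise ValueError(f"unsupported genetic code table {table_id}")
    return INVERTEBRATE_MITO


@lru_cache(maxsize=None)
def ng86_pair_differences(ca: str, cb: str, table_id: int = 5) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weight over all minimal mutational pathways.

    Pathways through a stop codon are dropped and the remainder
    re-averaged; if every pathway is blocked the unrestricted average is
    used so the pair still contributes its full difference count.
    """
    code = _code_by_id(table_id)
    if code.codon_to_aa[ca] == "*" or code.codon_to_aa[cb] == "*":
        raise ValueError("stop codons are excluded from NG86 counting")
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def walk(order):
        sd = nd = 0.0
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if code.codon_to_aa[nxt] == "*":
                return None
            if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all pathways blocked by stops: fall back to the unrestricted average
        def walk_any(order):
            sd = nd = 0.0
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if code.codon_to_aa[nxt] not in ("*", code.codon_to_aa[cur]):
                    nd += 1
                elif code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                    sd += 1
                else:  # through a stop: count as nonsynonymous
                    nd += 1
                cur = nxt
            return sd, nd

        valid = [walk_any(order) for order in itertools.permutations(diff_pos)]
    sd = sum(r[0] for r in valid) / len(valid)
    nd = sum(r[1] for r in valid) / len(valid)
    return sd, nd


def _column_contributions(
    aln: CodonAlignment, code: GeneticCode
) -> tuple[np.ndarray, int]:
    """Per counted column: rows of (S_sites, N_sites, Sd, Nd)."""
    cols = aln.counted_columns(code=code, skip_stops=True)
    all_cols = aln.counted_columns(code=code, skip_stops=False)
    skipped = len(all_cols) - len(cols)
    rows = np.empty((len(cols), 4))
    for r, i in enumerate(cols):
        ca, cb = aln.codons_a[i], aln.codons_b[i]
        sa, na = ng86_codon_sites(ca, code.table_id)
        sb, nb = ng86_codon_sites(cb, code.table_id)
        sd, nd = ng86_pair_differences(ca, cb, code.table_id)
        rows[r] = ((sa + sb) / 2, (na + nb) / 2, sd, nd)
    return rows, skipped


def ng86_counts(
    aln: CodonAlignment, code: GeneticCode = INVERTEBRATE_MITO
) -> NGCounts:
    """Pooled NG86 counts over the usable columns of a codon alignment.

    Columns that are masked, gapped, ambiguous, or contain a stop codon in
    either sequence are excluded (the stop-column tally is reported)."""
    rows, skipped = _column_contributions(aln, code)
    if rows.shape[0] == 0:
        raise ValueError("no usable codon columns")
    s, n, sd, nd = rows.sum(axis=0)
    return NGCounts(N=float(n), S=float(s), Nd=float(nd), Sd=float(sd),
                    L=rows.shape[0], stop_columns_skipped=skipped)


# --- rates and correction --------------------------------------------------

SATURATION_P = 0.75


def jukes_cantor(p: float) -> float:
    """One-parameter multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= SATURATION_P:
        raise ValueError("proportion at or beyond the correction's domain (3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_rates(c: NGCounts) -> dict:
    """Proportions and Jukes–Cantor-corrected rates from NG86 counts.

    Returns ``pN``, ``pS``, ``Ka``, ``Ks`` plus saturation flags; at
    saturation (p >= 3/4) the corrected rate is NaN and the uncorrected
    proportion remains the usable number.
    """
    if c.N <= 0 or c.S <= 0:
        raise ValueError("need positive nonsynonymous and synonymous site counts")
    pN = c.Nd / c.N
    pS = c.Sd / c.S
    out = {"pN": pN, "pS": pS, "ka_saturated": pN >= SATURATION_P,
           "ks_saturated": pS >= SATURATION_P}
    out["Ka"] = float("nan") if out["ka_saturated"] else jukes_cantor(pN)
    out["Ks"] = float("nan") if out["ks_saturated"] else jukes_cantor(pS)
    return out


# --- Z-test of selection ---------------------------------------------------

def _rates_from_sums(sums: np.ndarray) -> tuple[float, float]:
    """(Ka, Ks) from summed (S, N, Sd, Nd); NaN at saturation."""
    s, n, sd, nd = sums
    pn = nd / n if n > 0 else 0.0
    ps = sd / s if s > 0 else 0.0
    ka = float("nan") if pn >= SATURATION_P else -0.75 * math.log1p(-4 * pn / 3)
    ks = float("nan") if ps >= SATURATION_P else -0.75 * math.log1p(-4 * ps / 3)
    return ka, ks


def z_test_selection(
    aln: CodonAlignment,
    alternative: str = "purifying",
    variance: str = "bootstrap",
    n_reps: int = 1000,
    seed: int | None = 0,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> tuple[float, float]:
    """Codon-based Z-test on Ka - Ks.

    ``alternative``: ``neutral`` (two-tailed H0 Ka=Ks), ``purifying``
    (one-tailed, Ka < Ks) or ``positive`` (one-tailed, Ka > Ks).
    ``variance='bootstrap'`` resamples codon columns with replacement
    (``n_reps`` replicates, seeded); ``'analytic'`` uses the delta-method
    binomial variance.  Identical sequences return the Z = 0 convention
    with the corresponding null p-value.
    """
    rows, _ = _column_contributions(aln, code)
    if rows.shape[0] < MIN_CODONS_FOR_Z:
        raise ValueError(
            f"only {rows.shape[0]} usable codon columns; "
            f"need >= {MIN_CODONS_FOR_Z} for the Z-test"
        )
    total = rows.sum(axis=0)
    ka, ks = _rates_from_sums(total)
    if math.isnan(ka) or math.isnan(ks):
        raise ValueError("saturated rates: Z-test undefined beyond the JC domain")

    if variance == "bootstrap":
        rng = np.random.default_rng(seed)
        L = rows.shape[0]
        kas = np.empty(n_reps)
        kss = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.integers(0, L, size=L)
            kar, ksr = _rates_from_sums(rows[idx].sum(axis=0))
            kas[r] = kar
            kss[r] = ksr
        good = ~(np.isnan(kas) | np.isnan(kss))
        if good.sum() < 2:
            raise ValueError("bootstrap replicates all saturated")
        var = float(np.var(kas[good], ddof=1) + np.var(kss[good], ddof=1))
    elif variance == "analytic":
        s, n, sd, nd = total
        pn, ps = nd / n, sd / s
        var_pn = pn * (1 - pn) / n
        var_ps = ps * (1 - ps) / s
        var = var_pn / (1 - 4 * pn / 3) ** 2 + var_ps / (1 - 4 * ps / 3) ** 2
    else:
        raise ValueError(f"unknown variance method {variance!r}")

    if var <= 0:
        z = 0.0
    else:
        z = (ka - ks) / math.sqrt(var)

    if alternative == "neutral":
        p = 2 * (1 - norm.cdf(abs(z)))
    elif alternative == "purifying":
        p = float(norm.cdf(z))
    elif alternative == "positive":
        p = float(1 - norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


# --- per-gene pipeline -----------------------------------------------------

def coding_sequence(genome: Mitogenome, gene: str) -> tuple[str, str] | None:
    """Stop-trimmed CDS and its translation, or None when absent."""
    feat = genome.get(gene)
    if feat is None:
        return None
    nt = genome.feature_seq(feat)
    overhang = len(nt) % 3
    if overhang:
        nt = nt[:-overhang]
    # drop one trailing complete stop codon
    if len(nt) >= 3 and INVERTEBRATE_MITO.is_stop(nt[-3:]):
        nt = nt[:-3]
    if len(nt) < 3:
        return None
    aa, _ = translate_mito(nt, INVERTEBRATE_MITO)
    if len(aa) * 3 < len(nt):  # translate dropped another trailing stop
        aa = aa + "*"
    return nt, aa


_coding_sequence = coding_sequence  # backwards-compatible alias


def gene_divergence(
    f: Mitogenome,
    m: Mitogenome,
    gene: str,
    config: DivergenceConfig | None = None,
) -> DivergenceResult:
    """Full codon pipeline for one protein gene: protein alignment,
    back-translation, large-indel masking, p-distances, NG86 rates and the
    Z-test (neutral two-tailed plus both one-tailed alternatives)."""
    config = config or DivergenceConfig()
    res = DivergenceResult(gene=gene)
    pair_f = _coding_sequence(f, gene)
    pair_m = _coding_sequence(m, gene)
    if pair_f is None or pair_m is None:
        res.note = "gene missing in one genome"
        return res
    nt_f, aa_f = pair_f
    nt_m, aa_m = pair_m
    aln_aa = align_proteins(aa_f, aa_m, config.matrix, config.gap_open, config.gap_extend)
    aln = back_translate_alignment(
        aln_aa[0], aln_aa[1], nt_f, nt_m,
        gene=gene, id_a=f.identifier, id_b=m.identifier,
    )
    aln = mask_large_indels(aln, config.min_gap_codons)

    # site-level p-distance over unmasked codon columns (pairwise deletion)
    row_f = "".join(c for c, msk in zip(aln.codons_a, aln.mask) if msk is None)
    row_m = "".join(c for c, msk in zip(aln.codons_b, aln.mask) if msk is None)
    res.p_nt, res.sites_nt = p_distance(row_f, row_m, level="nt")
    aa_row_f = "".join(x for x, msk in zip(aln_aa[0], _aa_mask(aln)) if msk is None)
    aa_row_m = "".join(x for x, msk in zip(aln_aa[1], _aa_mask(aln)) if msk is None)
    res.p_aa, res.sites_aa = p_distance(
        aa_row_f.replace("*", "X"), aa_row_m.replace("*", "X"), level="aa"
    )

    try:
        counts = ng86_counts(aln)
        rates = ng86_rates(counts)
    except ValueError as exc:
        res.note = str(exc)
        return res
    res.pN, res.pS = rates["pN"], rates["pS"]
    res.Ka, res.Ks = rates["Ka"], rates["Ks"]
    res.ka_saturated = rates["ka_saturated"]
    res.ks_saturated = rates["ks_saturated"]
    res.codons_used = counts.L
    try:
        z, p_neu = z_test_selection(
            aln, "neutral", config.variance, config.bootstrap_reps, config.seed
        )
        res.Z = z
        res.p_neutral = p_neu
        res.p_purifying = float(norm.cdf(z))
        res.p_positive = float(1 - norm.cdf(z))
    except ValueError as exc:
        res.note = str(exc)
    return res


def _aa_mask(aln: CodonAlignment) -> list[str | None]:
    return aln.mask


def divergence_report(
    f: Mitogenome,
    m: Mitogenome,
    config: DivergenceConfig | None = None,
) -> list[DivergenceResult]:
    """Per-gene divergence for the 13 protein genes plus rrnS/rrnL, with a
    trailing averaged row over the protein genes (missing genes excluded).
    """
    config = config or DivergenceConfig()
    results = [gene_divergence(f, m, gene, config) for gene in CANONICAL_PCGS]
    for rrna in ("rrnS", "rrnL"):
        res = DivergenceResult(gene=rrna)
        ff, mf = f.get(rrna), m.get(rrna)
        if ff is None or mf is None:
            res.note = "gene missing in one genome"
        else:
            row_f, row_m = align_nucleotides(f.feature_seq(ff), m.feature_seq(mf))
            res.p_nt, res.sites_nt = p_distance(row_f, row_m, level="nt")
        results.append(res)

    pcg = [r for r in results[:len(CANONICAL_PCGS)] if r.p_nt is not None]
    avg = DivergenceResult(gene="average_pcg")
    if pcg:
        avg.p_nt = sum(r.p_nt for r in pcg) / len(pcg)
        aa = [r for r in pcg if r.p_aa is not None]
        if aa:
            avg.p_aa = sum(r.p_aa for r in aa) / len(aa)
        avg.note = f"mean over {len(pcg)} protein genes"
    results.append(avg)
    return results


def write_divergence_report(results: list[DivergenceResult], path) -> None:
    cols = ("gene", "p_nt", "p_aa", "pN", "pS", "Ka", "Ks", "Z",
            "p_neutral", "p_purifying", "p_positive", "codons_used", "note")
    def fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write("\t".join(fmt(getattr(r, c)) for c in cols) + "\n")
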