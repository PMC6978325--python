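"""p-distances, NG86 counting against a brute-force oracle, rate
correction and the Z-test of selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from Bio.Data import CodonTable

from duicompare.codonalign import CodonAlignment
from duicompare.divergence import (
    DivergenceConfig,
    divergence_report,
    gene_divergence,
    jukes_cantor,
    ng86_counts,
    ng86_pair_differences,
    ng86_rates,
    p_distance,
    z_test_selection,
)
from duicompare.simulate import SimulationConfig, simulate_pair

# --- independent NG86 oracle (built on Biopython's table 5) ---------------

_REF = CodonTable.unambiguous_dna_by_id[5]
_STOPS = set(_REF.stop_codons)
_SENSE = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


def _aa(codon):
    return _REF.forward_table[codon]


def oracle_sites(codon):
    """Per-position fraction of synonymous non-stop neighbours."""
    s = 0.0
    for pos in range(3):
        neigh = [
            codon[:pos] + b + codon[pos + 1:]
            for b in "ACGT" if b != codon[pos]
        ]
        neigh = [c for c in neigh if c not in _STOPS]
        if neigh:
            s += sum(_aa(c) == _aa(codon) for c in neigh) / len(neigh)
    return s, 3.0 - s


def oracle_differences(ca, cb):
    """Equal-weight average over minimal pathways, skipping pathways that
    visit a stop codon (unrestricted average if all are blocked)."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0

    def pathways(restrict):
        results = []
        for order in itertools.permutations(positions):
            cur, sd, nd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in _STOPS:
                    if restrict:
                        ok = False
                        break
                    nd += 1
                elif _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    res = pathways(True) or pathways(False)
    return (
        sum(r[0] for r in res) / len(res),
        sum(r[1] for r in res) / len(res),
    )


def test_ng86_counting_agrees_with_oracle_on_random_pairs():
    """Site and pathway counting match an independent enumeration oracle
    to 1e-9 over 1,000 random sense-codon pairs."""
    rng = np.random.default_rng(2024)
    worst = 0.0
    for _ in range(1000):
        ca, cb = rng.choice(_SENSE, size=2)
        aln = CodonAlignment("g", "a", "b", [str(ca)], [str(cb)])
        c = ng86_counts(aln)
        s_exp = (oracle_sites(str(ca))[0] + oracle_sites(str(cb))[0]) / 2
        sd_exp, nd_exp = oracle_differences(str(ca), str(cb))
        worst = max(
            worst,
            abs(c.S - s_exp),
            abs(c.Sd - sd_exp),
            abs(c.Nd - nd_exp),
        )
    assert worst <= 1e-9


@pytest.mark.parametrize(
    "ca,cb,sd,nd",
    [
        ("TTT", "TTT", 0.0, 0.0),
        ("TTT", "TTC", 1.0, 0.0),   # Phe -> Phe, synonymous
        ("TTT", "TTA", 0.0, 1.0),   # Phe -> Leu
    ],
)
def test_single_step_differences(ca, cb, sd, nd):
    assert ng86_pair_differences(ca, cb) == (sd, nd)


def test_two_step_differences_average_orderings():
    sd, nd = ng86_pair_differences("TTT", "GAT")
    assert sd + nd == pytest.approx(2.0)
    assert (sd, nd) == pytest.approx(oracle_differences("TTT", "GAT"))


@settings(derandomize=True, max_examples=40)
@given(
    codons=st.lists(
        st.tuples(st.sampled_from(_SENSE), st.sampled_from(_SENSE)),
        min_size=1, max_size=60,
    )
)
def test_site_counts_partition_three_per_codon(codons):
    """N + S = 3L for any stop-free codon alignment; difference counts are
    non-negative and bounded by the number of differing positions."""
    aln = CodonAlignment(
        "g", "a", "b", [c[0] for c in codons], [c[1] for c in codons]
    )
    c = ng86_counts(aln)
    assert c.N + c.S == pytest.approx(3 * c.L)
    assert c.Sd >= 0 and c.Nd >= 0
    max_diffs = sum(
        sum(x != y for x, y in zip(ca, cb)) for ca, cb in codons
    )
    assert c.Sd + c.Nd == pytest.approx(max_diffs)


def test_ng86_symmetric_in_sequence_order():
    rng = np.random.default_rng(7)
    codons_a = [str(c) for c in rng.choice(_SENSE, size=50)]
    codons_b = [str(c) for c in rng.choice(_SENSE, size=50)]
    aln = CodonAlignment("g", "a", "b", codons_a, codons_b)
    fwd = ng86_counts(aln)
    rev = ng86_counts(aln.swapped())
    for field in ("N", "S", "Nd", "Sd", "L"):
        assert getattr(fwd, field) == pytest.approx(getattr(rev, field))


# --- p-distance -------------------------------------------------------------

def test_p_distance_examples():
    assert p_distance("AAA", "AAT") == (pytest.approx(1 / 3), 3)
    assert p_distance("A-CG", "ATCG") == (0.0, 3)  # gap column dropped
    with pytest.raises(ValueError):
        p_distance("---", "AAA")


def test_p_distance_monotone_under_added_substitutions():
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list("ACGT"), size=300))
    seq = list(base)
    last = 0.0
    mutated_positions = rng.permutation(300)[:150]
    for i, pos in enumerate(mutated_positions):
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        p, _ = p_distance(base, "".join(seq))
        assert p >= last
        last = p


# --- rates ------------------------------------------------------------------

def test_jukes_cantor_closed_form():
    assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6))
    assert jukes_cantor(0.0) == 0.0
    with pytest.raises(ValueError):
        jukes_cantor(0.8)


def test_rates_saturation_flag():
    from duicompare.divergence import NGCounts

    c = NGCounts(N=200.0, S=100.0, Nd=0.0, Sd=80.0, L=100)
    r = ng86_rates(c)
    assert r["Ka"] == 0.0
    assert r["ks_saturated"] and math.isnan(r["Ks"])


# --- Z-test -----------------------------------------------------------------

def _random_alignment(n, seed, divergence=0.0):
    rng = np.random.default_rng(seed)
    codons_a = [str(c) for c in rng.choice(_SENSE, size=n)]
    codons_b = list(codons_a)
    for i in range(n):
        if rng.random() < divergence:
            codons_b[i] = str(rng.choice(_SENSE))
    return CodonAlignment("g", "a", "b", codons_a, codons_b)


def test_z_test_identical_sequences_convention():
    aln = _random_alignment(100, 1)
    z, p = z_test_selection(aln, "neutral", seed=0)
    assert z == 0.0 and p == 1.0


def test_z_test_requires_enough_codons():
    with pytest.raises(ValueError, match="usable codon columns"):
        z_test_selection(_random_alignment(5, 2), "neutral")


def test_z_test_one_tailed_pvalues_complementary():
    aln = _random_alignment(300, 3, divergence=0.3)
    _, p_pur = z_test_selection(aln, "purifying", seed=1)
    _, p_pos = z_test_selection(aln, "positive", seed=1)
    assert p_pur + p_pos == pytest.approx(1.0)
    assert not (p_pur < 0.5 and p_pos < 0.5)


def test_z_test_analytic_and_bootstrap_agree_in_sign():
    f, m, _ = simulate_pair(SimulationConfig(), seed=21)
    for variance in ("bootstrap", "analytic"):
        res = gene_divergence(
            f, m, "nad5",
            DivergenceConfig(variance=variance, bootstrap_reps=300, seed=4),
        )
        assert res.Z < 0  # purifying regime
        assert res.p_purifying < 0.01


# --- report -----------------------------------------------------------------

def test_divergence_report_structure_and_self_comparison(sim_pair):
    f, m, _ = sim_pair
    self_report = divergence_report(f, f, DivergenceConfig(bootstrap_reps=50, seed=0))
    genes = [r.gene for r in self_report]
    assert genes[-1] == "average_pcg" and "rrnS" in genes and "cox2" in genes
    for r in self_report:
        if r.p_nt is not None:
            assert r.p_nt == 0.0
    pair_report = divergence_report(f, m, DivergenceConfig(bootstrap_reps=50, seed=0))
    avg = pair_report[-1]
    assert 0.0 < avg.p_nt < 0.75
    # rRNA rows carry nucleotide distances only
    rrns = next(r for r in pair_report if r.gene == "rrnS")
    assert rrns.p_nt is not None and rrns.Ka is None


def test_divergence_report_missing_gene_is_na(sim_pair):
    f, m, _ = sim_pair
    from dataclasses import replace

    m_missing = replace(
        m, features=[ft for ft in m.features if ft.base_name != "atp8"]
    )
    report = divergence_report(f, m_missing, DivergenceConfig(bootstrap_reps=50))
    atp8 = next(r for r in report if r.gene == "atp8")
    assert atp8.p_nt is None and "missing" in atp8.note
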