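"""Reusable simulation experiments: parameter recovery, test power, and
planted-element recovery rates.

Each experiment generates its data with the package's own simulator under
seeded conditions and measures the pipeline end to end (alignment included),
so the numbers quantify what the full method recovers, not what isolated
internals produce.
"""

from __future__ import annotations

import statistics


from .codonalign import align_proteins, back_translate_alignment
from .cox2 import detect_insertions
from .divergence import DivergenceConfig, coding_sequence, gene_divergence
from .orfans import screen_orfans
from .simulate import SimulationConfig, evolve_m_genome, simulate_f_genome, simulate_pair

__all__ = [
    "recovery_config",
    "omega_recovery",
    "purifying_power",
    "planted_recovery",
]

#: Single-gene genome for rate experiments: one ~500-codon protein gene
#: (the scale of cox1) plus minimal RNA context.
RECOVERY_GENE_PLAN = (("cox1", 1506), ("trnM", 66), ("rrnS", 300))


def recovery_config(omega: float, target_ds: float) -> SimulationConfig:
    return SimulationConfig(
        gene_plan=RECOVERY_GENE_PLAN,
        incomplete_stop_genes=(),
        named_spacers=(),
        omega=omega,
        target_ds=target_ds,
        cox2_insertion_codons=0,
        orfan=None,
    )


def _estimate_gene(f, m, gene="cox1", seed=0):
    cfg = DivergenceConfig(bootstrap_reps=0, seed=seed, variance="analytic")
    return gene_divergence(f, m, gene, cfg)


def omega_recovery(
    omegas=(0.05, 0.2, 0.5),
    target_ds: float = 0.4,
    n_seeds: int = 50,
    base_seed: int = 0,
) -> dict:
    """Median NG86 Ka/Ks across seeds for each planted omega.

    Returns, per omega: the median estimated ratio, its ratio to the
    nominal acceptance probability, and its ratio to the realized
    event-rate omega recorded in the simulation truth (the two differ
    under transition bias; see the methods note).
    """
    out = {}
    for omega in omegas:
        cfg = recovery_config(omega, target_ds)
        estimates, realized = [], []
        for i in range(n_seeds):
            seed = base_seed + 1000 * i
            f = simulate_f_genome(cfg, seed)
            m, truth = evolve_m_genome(f, cfg, seed + 1)
            res = _estimate_gene(f, m)
            if res.Ka is None or res.Ks in (None, 0):
                continue
            estimates.append(res.Ka / res.Ks)
            t = truth.per_gene["cox1"]
            # realized event-rate ratio on NG86 sites of the F gene
            from .divergence import ng86_codon_sites

            body = coding_sequence(f, "cox1")[0]
            codons = [body[j:j + 3] for j in range(0, len(body), 3)]
            s_sites = sum(ng86_codon_sites(c)[0] for c in codons)
            n_sites = 3 * len(codons) - s_sites
            if t["syn_events"] > 0:
                realized.append(
                    (t["nonsyn_events"] / n_sites) / (t["syn_events"] / s_sites)
                )
        med = statistics.median(estimates)
        out[omega] = {
            "median_kaks": med,
            "vs_nominal": med / omega,
            "vs_realized": med / statistics.median(realized) if realized else float("nan"),
            "n": len(estimates),
        }
    return out


def purifying_power(
    omega: float = 0.1,
    target_ds: float = 0.5,
    n_seeds: int = 50,
    n_boot: int = 1000,
    base_seed: int = 0,
) -> dict:
    """Fraction of simulated 500-codon gene pairs where the one-tailed
    Z-test rejects neutrality in favour of purifying selection at p < 0.01."""
    cfg = recovery_config(omega, target_ds)
    hits = 0
    n = 0
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        f = simulate_f_genome(cfg, seed)
        m, _ = evolve_m_genome(f, cfg, seed + 1)
        res = gene_divergence(
            f, m, "cox1",
            DivergenceConfig(bootstrap_reps=n_boot, seed=seed, variance="bootstrap"),
        )
        if res.p_purifying is None:
            continue
        n += 1
        if res.p_purifying < 0.01:
            hits += 1
    return {"fraction_rejecting": hits / n if n else float("nan"), "n": n}


def planted_recovery(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Coordinate-exact recovery of the planted cox2 insertion and ORFan
    over full simulated genome pairs."""
    insertion_exact = orfan_exact = 0
    length_ok = 0
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        f, m, truth = simulate_pair(SimulationConfig(), seed=seed)
        # ORFan
        scr = screen_orfans(m)
        planted = [
            c for c in scr.candidates
            if c.start == truth.orfan["m_genome_start"]
            and c.end == truth.orfan["m_genome_end"]
            and c.passes_filter
        ]
        if len(planted) == 1 and len(scr.candidates) == 1:
            orfan_exact += 1
        # insertion
        pf, pm = coding_sequence(f, "cox2"), coding_sequence(m, "cox2")
        aa = align_proteins(pf[1], pm[1])
        aln = back_translate_alignment(aa[0], aa[1], pf[0], pm[0], "cox2")
        blocks = detect_insertions(aln)
        if (
            len(blocks) == 1
            and blocks[0].m_nt_start == truth.insertion["m_gene_nt_start"]
            and blocks[0].length_nt == truth.insertion["length_nt"]
        ):
            insertion_exact += 1
        if abs(m.length - f.length - truth.insertion["length_nt"]) <= 200:
            length_ok += 1
    return {
        "insertion_exact_fraction": insertion_exact / n_seeds,
        "orfan_exact_fraction": orfan_exact / n_seeds,
        "n": n_seeds,
    }
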