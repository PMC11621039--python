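"""Independent scalar oracles for the differentiation estimators.

Written straight from the primary formulas in plain Python (no numpy
vectorisation, no shared code with the implementation) so that tests can
compare the library's vectorised estimators against an unrelated derivation.
"""

from __future__ import annotations


def wc84_components(pops: list[tuple[int, float, float]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for one biallelic locus.

    ``pops`` is a list of ``(n_i, p_i, h_i)`` per population: sample size in
    diploids, alt-allele frequency, observed heterozygote fraction.
    Returns (a, b, c): among-population, among-individual-within-population,
    within-individual components.
    """
    r = len(pops)
    ns = [n for n, _, _ in pops]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc84_fst(loci: list[list[tuple[int, float, float]]]) -> float:
    """Ratio-of-sums multi-locus WC84 FST over per-locus population stats."""
    num = den = 0.0
    for pops in loci:
        a, b, c = wc84_components(pops)
        num += a
        den += a + b + c
    return num / den


def nei_chesser_jost_d(loci: list[tuple[tuple[int, float], tuple[int, float]]]) -> float:
    """Pairwise Jost's D from Nei–Chesser bias-corrected HS/HT.

    ``loci`` holds per-locus ``((n1, p1), (n2, p2))``.  HS and HT are
    averaged across loci before combining; D = 2 (HT - HS) / (1 - HS).
    """
    hs_vals, ht_vals = [], []
    for (n1, p1), (n2, p2) in loci:
        n_harm = 2.0 / (1.0 / n1 + 1.0 / n2)
        hs_raw = 1.0 - ((p1 * p1 + (1 - p1) * (1 - p1))
                        + (p2 * p2 + (1 - p2) * (1 - p2))) / 2.0
        pbar = (p1 + p2) / 2.0
        ht_raw = 1.0 - pbar * pbar - (1 - pbar) * (1 - pbar)
        hs_est = hs_raw * 2.0 * n_harm / (2.0 * n_harm - 1.0)
        ht_est = ht_raw + hs_est / (2.0 * n_harm * 2.0)
        hs_vals.append(hs_est)
        ht_vals.append(ht_est)
    hs = sum(hs_vals) / len(hs_vals)
    ht = sum(ht_vals) / len(ht_vals)
    return (ht - hs) / (1.0 - hs) * 2.0


def q0_beta_by_hand(loci: list[tuple[set, set]]) -> float:
    """Order-0 beta diversity from per-locus observed allele sets."""
    betas = []
    for alleles_a, alleles_b in loci:
        if not alleles_a or not alleles_b:
            continue
        gamma = len(alleles_a | alleles_b)
        alpha = (len(alleles_a) + len(alleles_b)) / 2.0
        betas.append(gamma / alpha)
    return sum(betas) / len(betas)
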