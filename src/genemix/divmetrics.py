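"""Pairwise differentiation and diversity metrics.

Implements the estimators used to characterise candidate donor populations:

* Weir & Cockerham (1984) FST from among-population (a), among-individual (b)
  and within-individual (c) variance components, combined across loci as a
  ratio of sums, with a loci-bootstrap significance test;
* pairwise fixed allelic differences and per-population private alleles;
* Jost's D from Nei–Chesser bias-corrected heterozygosities (harmonic-mean
  sample size), HS and HT each averaged across loci before combining;
* order-0 (richness) multiplicative beta diversity, gamma richness over mean
  alpha richness, averaged over loci with data in both populations;
* pooled variant-site observed heterozygosity.

Populations are given as explicit sample-id sequences; resolve names through
a :class:`~genemix.genotype_io.PopulationMap` first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class AlleleFreqTable:
    """Per-population alt-allele frequencies and called-sample counts."""

    freq: pd.DataFrame      # populations x loci, NaN where no data
    n_called: pd.DataFrame  # populations x loci


def _pop_arrays(matrix: GenotypeMatrix, samples: Sequence[str]):
    """(alt freq, n called, observed het fraction) per locus for a subset."""
    dos = matrix.dosages[matrix.sample_indices(samples)]
    called = dos != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=0) / (2.0 * n)
        h = (dos == 1).sum(axis=0) / n
    p[n == 0] = np.nan
    h[n == 0] = np.nan
    return p, n, h


def allele_freq_table(matrix: GenotypeMatrix, popmap: PopulationMap) -> AlleleFreqTable:
    freqs, counts = {}, {}
    for pop in popmap.populations:
        samples = [s for s in popmap.samples_in(pop) if s in matrix.sample_ids]
        p, n, _ = _pop_arrays(matrix, samples)
        freqs[pop], counts[pop] = p, n
    return AlleleFreqTable(
        freq=pd.DataFrame.from_dict(freqs, orient="index", columns=matrix.locus_ids),
        n_called=pd.DataFrame.from_dict(counts, orient="index", columns=matrix.locus_ids),
    )


def observed_het_variant(matrix: GenotypeMatrix, samples: Sequence[str] | None = None) -> float:
    """Pooled variant-site observed heterozygosity of a sample panel.

    Fraction of all non-missing genotype calls (over samples x loci) that are
    heterozygous.  NaN when the panel has no called genotypes.
    """
    dos = matrix.dosages if samples is None else matrix.dosages[matrix.sample_indices(samples)]
    n_called = int((dos != MISSING).sum())
    if n_called == 0:
        return float("nan")
    return float((dos == 1).sum() / n_called)


# ----------------------------------------------------------------------
# Weir & Cockerham (1984) FST
# ----------------------------------------------------------------------

def wc_fst_components(matrix: GenotypeMatrix, popA: Sequence[str],
                      popB: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for two populations.

    Loci without at least one called diploid in each population, or with
    mean sample size <= 1, are NaN in all three components.
    """
    p1, n1, h1 = _pop_arrays(matrix, popA)
    p2, n2, h2 = _pop_arrays(matrix, popB)
    r = 2.0
    n1f, n2f = n1.astype(float), n2.astype(float)
    nbar = (n1f + n2f) / r
    valid = (n1 > 0) & (n2 > 0) & (nbar > 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1f**2 + n2f**2) / (r * nbar)) / (r - 1)
        pbar = (n1f * p1 + n2f * p2) / (r * nbar)
        s2 = (n1f * (p1 - pbar) ** 2 + n2f * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1f * h1 + n2f * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def wc_fst(matrix: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str]) -> float:
    """Multi-locus WC84 FST: sum(a) / sum(a+b+c) over informative loci."""
    a, b, c = wc_fst_components(matrix, popA, popB)
    denom = a + b + c
    use = np.isfinite(denom)
    if not use.any():
        return float("nan")
    num = a[use].sum()
    den = denom[use].sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def fst_bootstrap_p(matrix: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str],
                    n_boot: int = 5000, seed: int | None = None) -> float:
    """One-sided bootstrap p-value for FST > 0.

    Loci are resampled with replacement ``n_boot`` times and the ratio-of-sums
    estimate recomputed; p is the fraction of bootstrap estimates <= 0.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a, bb, c = wc_fst_components(matrix, popA, popB)
    denom = a + bb + c
    keep = np.isfinite(denom)
    a, denom = a[keep], denom[keep]
    if a.size < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    num = a[idx].sum(axis=1)
    den = denom[idx].sum(axis=1)
    theta = np.divide(num, den, out=np.full(n_boot, np.nan), where=den != 0)
    valid = np.isfinite(theta)
    if not valid.any():
        return float("nan")
    return float((theta[valid] <= 0).sum() / valid.sum())


# ----------------------------------------------------------------------
# Allele-sharing metrics
# ----------------------------------------------------------------------

def fixed_differences(matrix: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str],
                      tolerance: float = 0.0) -> int:
    """Count loci where the two populations are fixed for opposite alleles.

    A locus counts when one population's alt frequency is <= ``tolerance``
    and the other's is >= ``1 - tolerance``; loci with no called sample in
    either population are excluded.
    """
    p1, n1, _ = _pop_arrays(matrix, popA)
    p2, n2, _ = _pop_arrays(matrix, popB)
    ok = (n1 > 0) & (n2 > 0)
    lo, hi = tolerance, 1.0 - tolerance
    opposite = ((p1 <= lo) & (p2 >= hi)) | ((p2 <= lo) & (p1 >= hi))
    return int((ok & opposite).sum())


def private_alleles(matrix: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Alleles observed in exactly one population, counted per population."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("private alleles require >= 2 populations")
    ref_present = {}
    alt_present = {}
    for pop in pops:
        samples = [s for s in popmap.samples_in(pop) if s in matrix.sample_ids]
        dos = matrix.dosages[matrix.sample_indices(samples)]
        called = dos != MISSING
        ref_present[pop] = ((dos == 0) | (dos == 1)).any(axis=0) & called.any(axis=0)
        alt_present[pop] = ((dos == 1) | (dos == 2)).any(axis=0)
    counts = {}
    ref_total = np.sum([ref_present[p] for p in pops], axis=0)
    alt_total = np.sum([alt_present[p] for p in pops], axis=0)
    for pop in pops:
        counts[pop] = int((ref_present[pop] & (ref_total == 1)).sum()
                          + (alt_present[pop] & (alt_total == 1)).sum())
    return pd.Series(counts, name="private_alleles")


# ----------------------------------------------------------------------
# Jost's D and q0 beta diversity
# ----------------------------------------------------------------------

def jost_d(matrix: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str]) -> float:
    """Pairwise Jost's D with Nei–Chesser bias-corrected HS and HT.

    Per locus: harmonic-mean sample size n~ of the two populations,
    HS = (2n~/(2n~-1)) * mean expected heterozygosity, HT = pooled expected
    heterozygosity + HS/(4 n~).  HS and HT are each averaged across loci,
    then D = 2 * (HT - HS) / (1 - HS).  Monomorphic pairs give 0.
    """
    p1, n1, _ = _pop_arrays(matrix, popA)
    p2, n2, _ = _pop_arrays(matrix, popB)
    ok = (n1 > 0) & (n2 > 0)
    if not ok.any():
        return float("nan")
    p1, p2 = p1[ok], p2[ok]
    n1f, n2f = n1[ok].astype(float), n2[ok].astype(float)

    nt = 2.0 / (1.0 / n1f + 1.0 / n2f)  # harmonic mean sample size
    hs_raw = 1.0 - 0.5 * (p1**2 + (1 - p1) ** 2 + p2**2 + (1 - p2) ** 2)
    pbar = 0.5 * (p1 + p2)
    ht_raw = 1.0 - pbar**2 - (1 - pbar) ** 2
    hs_est = (2.0 * nt / (2.0 * nt - 1.0)) * hs_raw
    ht_est = ht_raw + hs_est / (4.0 * nt)  # = + HS / (2 n~ r) with r = 2

    hs, ht = float(hs_est.mean()), float(ht_est.mean())
    if hs >= 1.0:
        return float("nan")
    return 2.0 * (ht - hs) / (1.0 - hs)


def q0_beta(matrix: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str]) -> float:
    """Order-0 (richness) beta diversity between two populations.

    Per locus: alpha = mean number of distinct alleles observed per
    population, gamma = distinct alleles in the pooled pair, beta =
    gamma/alpha.  The value is the mean per-locus beta over loci with data in
    both populations; for biallelic loci it lies in [1, 2].
    """
    presence = []
    for pop in (popA, popB):
        dos = matrix.dosages[matrix.sample_indices(pop)]
        ref = ((dos == 0) | (dos == 1)).any(axis=0)
        alt = ((dos == 1) | (dos == 2)).any(axis=0)
        presence.append((ref, alt))
    (r1, a1), (r2, a2) = presence
    ok = (r1 | a1) & (r2 | a2)  # data in both populations
    if not ok.any():
        return float("nan")
    richness1 = r1.astype(int) + a1.astype(int)
    richness2 = r2.astype(int) + a2.astype(int)
    gamma = (r1 | r2).astype(int) + (a1 | a2).astype(int)
    alpha = 0.5 * (richness1 + richness2)
    beta = gamma[ok] / alpha[ok]
    return float(beta.mean())


# ----------------------------------------------------------------------
# Assembly
# ----------------------------------------------------------------------

def metrics_table(matrix: GenotypeMatrix, popmap: PopulationMap, recipient: str,
                  n_boot: int = 0, seed: int | None = None) -> pd.DataFrame:
    """Pairwise metrics of every population against one recipient.

    Columns: fst, fst_p (NaN unless ``n_boot`` > 0), fixed_diffs,
    private_alleles, jost_d, q0_beta, donor_variant_het.  The recipient's own
    row (self pair) holds NaN differentiation values.
    """
    rec = [s for s in popmap.samples_in(recipient) if s in matrix.sample_ids]
    priv = private_alleles(matrix, popmap)
    rows = {}
    for pop in popmap.populations:
        donor = [s for s in popmap.samples_in(pop) if s in matrix.sample_ids]
        if pop == recipient:
            rows[pop] = {
                "fst": np.nan, "fst_p": np.nan, "fixed_diffs": np.nan,
                "jost_d": np.nan, "q0_beta": np.nan,
                "donor_variant_het": observed_het_variant(matrix, donor),
                "private_alleles": int(priv[pop]),
            }
            continue
        rows[pop] = {
            "fst": wc_fst(matrix, rec, donor),
            "fst_p": fst_bootstrap_p(matrix, rec, donor, n_boot=n_boot, seed=seed)
            if n_boot else np.nan,
            "fixed_diffs": fixed_differences(matrix, rec, donor),
            "jost_d": jost_d(matrix, rec, donor),
            "q0_beta": q0_beta(matrix, rec, donor),
            "donor_variant_het": observed_het_variant(matrix, donor),
            "private_alleles": int(priv[pop]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_summary(matrix: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Square population table: FST below the diagonal, fixed allelic
    differences above it, private alleles as a final column."""
    pops = popmap.populations
    out = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=object)
    for i, a in enumerate(pops):
        sa = popmap.samples_in(a)
        for j, b in enumerate(pops):
            if i == j:
                out.loc[a, b] = "-"
            elif i > j:
                out.loc[a, b] = round(wc_fst(matrix, sa, popmap.samples_in(b)), 4)
            else:
                out.loc[a, b] = fixed_differences(matrix, sa, popmap.samples_in(b))
    out["private_alleles"] = private_alleles(matrix, popmap)
    return out
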