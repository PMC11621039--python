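"""Structured synthetic genotype data with a tunable divergence dial.

Populations diverge from a shared ancestral allele frequency under the
Balding–Nichols model: at each locus the ancestral frequency ``p`` is drawn
uniformly from a MAF window, and each population's frequency is Beta
distributed with mean ``p`` and variance ``p(1-p)F``.  ``F`` is that
population's expected differentiation from the ancestor, so a pair of
populations generated at ``F`` has Weir–Cockerham FST near ``F``.  On top of
this, pairs of populations can have fixed allelic differences injected, and a
per-population factor can shrink minor-allele frequencies to emulate a
genetically depauperate (low-heterozygosity) population.

A companion generator produces per-sample site records (DP/AD/QUAL) for the
autosomal-heterozygosity filter, with negative-binomial depths and binomial
allele-depth splits at heterozygous sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap
from .hetfilter import SampleSiteTable


@dataclass
class SynthConfig:
    """Scenario parameters for :func:`generate_structured_populations`.

    populations: list of ``(name, n_samples, F)`` with ``F`` in [0, 1).
    fixed_diff_injections: list of ``(popA, popB, count)`` loci forced to
    opposite fixation between the named pair.
    low_het_scale: optional ``{population: factor}`` multiplying minor-allele
    frequencies (factor < 1 depresses heterozygosity).
    """

    n_loci: int
    populations: list[tuple[str, int, float]]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    fixed_diff_injections: list[tuple[str, str, int]] = field(default_factory=list)
    low_het_scale: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        names = [p[0] for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for name, n, f in self.populations:
            if n < 1:
                raise ValueError(f"population {name}: sample count must be >= 1")
            if not (0.0 <= f < 1.0):
                raise ValueError(f"population {name}: F must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        total = sum(c for _, _, c in self.fixed_diff_injections)
        if total > self.n_loci:
            raise ValueError("injected fixed-difference count exceeds n_loci")
        for a, b, _ in self.fixed_diff_injections:
            if a not in names or b not in names:
                raise ValueError(f"injection names unknown population ({a}, {b})")


@dataclass
class DepthModel:
    """Read-depth / quality model for per-sample site records.

    mean_depth: expected total depth per site; dispersion: negative-binomial
    shape (smaller = more overdispersed); qual_mean/qual_sd: PHRED-like site
    quality, normal truncated at 0.
    """

    mean_depth: float = 30.0
    dispersion: float = 8.0
    qual_mean: float = 60.0
    qual_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0 or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        if self.qual_sd <= 0:
            raise ValueError("qual_sd must be positive")


def generate_structured_populations(config: SynthConfig) -> tuple[GenotypeMatrix, PopulationMap]:
    """Draw a structured multi-population genotype matrix.

    Deterministic for a given config (``config.seed`` drives every draw).
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=L)

    pop_freqs: dict[str, np.ndarray] = {}
    for name, _n, f in config.populations:
        if f > 0:
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            p = rng.beta(a, b)
        else:
            p = p_anc.copy()
        scale = (config.low_het_scale or {}).get(name)
        if scale is not None:
            minor = np.minimum(p, 1.0 - p) * scale
            p = np.where(p <= 0.5, minor, 1.0 - minor)
        pop_freqs[name] = p

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    row_slices: dict[str, slice] = {}
    row = 0
    for name, n, _f in config.populations:
        blocks.append(rng.binomial(2, pop_freqs[name], size=(n, L)).astype(np.int8))
        ids = [f"{name}_{i:03d}" for i in range(n)]
        sample_ids.extend(ids)
        assignments.update({s: name for s in ids})
        row_slices[name] = slice(row, row + n)
        row += n
    dosages = np.vstack(blocks)

    # injected fixed differences draw from a shared pool so pairs are
    # disjoint; each pair is fixed toward the allele popA already favours
    # (so injection barely perturbs popA's heterozygosity) with popB opposite
    pool = rng.permutation(L)
    cursor = 0
    injected: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for a, b, count in config.fixed_diff_injections:
        loci = pool[cursor:cursor + count]
        cursor += count
        fill_a = np.where(pop_freqs[a][loci] <= 0.5, 0, 2).astype(np.int8)
        dosages[row_slices[a], :][:, loci] = fill_a
        dosages[row_slices[b], :][:, loci] = 2 - fill_a
        injected[(a, b)] = (loci, fill_a)

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
        # keep injected loci observable in both involved populations
        for (a, b), (loci, fill_a) in injected.items():
            for name, fill in ((a, fill_a), (b, 2 - fill_a)):
                sl = row_slices[name]
                sub = dosages[sl, :][:, loci]
                dead = (sub == MISSING).all(axis=0)
                if dead.any():
                    dosages[sl.start, loci[dead]] = fill[dead]

    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    labels = [(bases[r], bases[a]) for r, a in zip(ref, alt)]

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_ids=[f"L{i:06d}" for i in range(L)],
        dosages=dosages,
        allele_labels=labels,
    )
    return matrix, PopulationMap(assignments)


def generate_sample_site_records(
    genotypes: np.ndarray,
    model: DepthModel,
    seed: int,
    sample_id: str = "sample",
    site_ids: list[str] | None = None,
) -> SampleSiteTable:
    """Per-site DP/AD/QUAL records for one sample's dosage vector.

    DP is negative-binomial (mean ``model.mean_depth``, shape
    ``model.dispersion``); heterozygous sites split DP binomially 50:50
    between the two alleles, homozygous sites put all depth on the called
    allele; QUAL is normal truncated at zero.  Reproducible by seed.
    """
    genotypes = np.asarray(genotypes)
    rng = np.random.default_rng(seed)
    n = genotypes.size
    r = model.dispersion
    p_nb = r / (r + model.mean_depth)
    dp = rng.negative_binomial(r, p_nb, size=n)
    a, b = (0 - model.qual_mean) / model.qual_sd, np.inf
    qual = stats.truncnorm.rvs(a, b, loc=model.qual_mean, scale=model.qual_sd,
                               size=n, random_state=rng)

    alt_depth = np.zeros(n, dtype=np.int64)
    het = genotypes == 1
    alt_depth[het] = rng.binomial(dp[het], 0.5)
    alt_depth[genotypes == 2] = dp[genotypes == 2]
    ref_depth = dp - alt_depth

    gts = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    records = pd.DataFrame({
        "site_id": site_ids if site_ids is not None else [f"S{i:06d}" for i in range(n)],
        "gt": [gts.get(int(g)) for g in genotypes],  # None where missing
        "alts": [("T",)] * n,
        "dp": dp.astype(float),
        "ad": [(int(rd), int(ad)) for rd, ad in zip(ref_depth, alt_depth)],
        "qual": qual,
    })
    return SampleSiteTable(sample_id=sample_id, records=records)


def founders_with_target_het(n_samples: int, n_loci: int, target_het: float,
                             seed: int = 0) -> GenotypeMatrix:
    """Diploid genotypes whose realised pooled heterozygosity is exact.

    Genotypes start as Hardy–Weinberg draws at the minor-allele frequency q
    solving ``2q(1-q) = target_het``, then a minimal number of calls are
    toggled between heterozygous and homozygous so the realised
    heterozygous-call fraction equals ``round(target * n * L) / (n * L)``.
    Useful for seeding drift runs at a prescribed starting diversity.
    """
    if not (0.0 <= target_het < 0.5):
        raise ValueError("target_het must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    q = (1.0 - np.sqrt(1.0 - 2.0 * target_het)) / 2.0
    dos = rng.binomial(2, q, size=(n_samples, n_loci)).astype(np.int8)
    target_calls = round(target_het * n_samples * n_loci)
    flat = dos.ravel()
    het_idx = np.flatnonzero(flat == 1)
    if het_idx.size > target_calls:
        drop = rng.choice(het_idx, size=het_idx.size - target_calls, replace=False)
        flat[drop] = rng.choice([0, 2], size=drop.size)
    elif het_idx.size < target_calls:
        hom_idx = np.flatnonzero(flat != 1)
        make = rng.choice(hom_idx, size=target_calls - het_idx.size, replace=False)
        flat[make] = 1
    dos = flat.reshape(n_samples, n_loci)

    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n_loci)
    alt = (ref + rng.integers(1, 4, size=n_loci)) % 4
    return GenotypeMatrix(
        sample_ids=[f"G0_{i:03d}" for i in range(n_samples)],
        locus_ids=[f"L{i:06d}" for i in range(n_loci)],
        dosages=dos,
        allele_labels=[(bases[r], bases[a]) for r, a in zip(ref, alt)],
    )


def study_shape_config(seed: int = 0, n_loci: int = 7333,
                       missing_rate: float = 0.08) -> SynthConfig:
    """A 12-population, 137-sample preset emulating the analysis scale.

    One fenced, low-heterozygosity recipient of 21 samples ("REC"), donors of
    4-21 samples at divergence F from 0.03 to 0.45, an extra-depauperate
    4-sample island population, and two highly distinct populations separated
    from the recipient by ~20% of the panel as injected fixed differences —
    the magnitude expected between taxonomically distinct lineages.
    """
    populations = [
        ("REC", 21, 0.05),
        ("NBR", 14, 0.03),
        ("W1", 15, 0.08),
        ("W2", 9, 0.10),
        ("W3", 10, 0.12),
        ("E1", 6, 0.15),
        ("E2", 5, 0.18),
        ("ISL", 4, 0.30),
        ("T1", 9, 0.20),
        ("T2", 4, 0.22),
        ("FAR1", 19, 0.45),
        ("FAR2", 21, 0.45),
    ]
    return SynthConfig(
        n_loci=n_loci,
        populations=populations,
        ancestral_maf_range=(0.05, 0.5),
        missing_rate=missing_rate,
        fixed_diff_injections=[("REC", "FAR1", max(1, round(1500 * n_loci / 7333))),
                               ("REC", "FAR2", max(1, round(1400 * n_loci / 7333)))],
        low_het_scale={"REC": 0.28, "ISL": 0.12},
        seed=seed,
    )
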