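"""Forward-in-time simulated introductions.

A mixing scenario draws founders from a recipient and a donor population
(default 20 + 4), lets the census size grow geometrically (N <- min(round(R*N),
K)) with complete generation replacement until it reaches the ceiling K —
that generation is "generation 0" — and then runs a fixed number of further
non-overlapping panmictic generations at constant size K.  Each offspring is
formed from two distinct, uniformly drawn parents, each transmitting one of
its two alleles per locus independently; mutation and recombination within
markers are taken as negligible, so heterozygosity changes only through
drift and the initial mixing.  Mean variant-site heterozygosity (pooled
heterozygous-call fraction over all panel loci) is recorded at every
generation from 0 to the horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Mixing-scenario parameters (defaults follow the 20:4 introduction)."""

    n_recipient: int = 20
    n_donor: int = 4
    growth_rate: float = 2.0
    ceiling: int = 300
    n_generations: int = 50
    n_replicates: int = 5
    seed: int = 0
    distinct_parents: bool = True

    def __post_init__(self) -> None:
        if self.n_recipient + self.n_donor < 2:
            raise ValueError("need at least 2 founders")
        if self.growth_rate <= 1:
            raise ValueError("growth_rate must be > 1")
        if self.ceiling < self.n_recipient + self.n_donor:
            raise ValueError("ceiling must be >= founder count")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class FounderSet:
    """Founder genotype rows with provenance labels ('recipient'/'donor')."""

    dosages: np.ndarray          # (n_founders, n_loci)
    sample_ids: list[str]
    provenance: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        n = self.dosages.shape[0]
        if len(self.sample_ids) != n or len(self.provenance) != n:
            raise ValueError("founder rows, ids and provenance must align")


@dataclass
class Trajectory:
    """One replicate's heterozygosity series over the stable phase."""

    replicate: int
    scenario: str
    growth_sizes: list[int]      # census sizes from founders to the ceiling
    mean_het: np.ndarray         # generations 0..n_generations


@dataclass
class ReplicateSet:
    scenario: str
    trajectories: list[Trajectory]
    mean: np.ndarray             # cross-replicate mean per generation
    ci_low: np.ndarray           # normal-approximation 95% band
    ci_high: np.ndarray


@dataclass
class MixingSummary:
    scenario: str
    baseline_het: float
    initial_het: float           # generation-0 cross-replicate mean
    max_het: float
    final_het: float
    pct_increase_at_max: float
    pct_change_at_final: float
    pct_decline_from_max: float


def sample_founders(matrix: GenotypeMatrix, popmap: PopulationMap, recipient: str,
                    donor: str, config: SimConfig, rng: np.random.Generator) -> FounderSet:
    """Draw recipient and donor founders uniformly without replacement.

    In the self-donor (no-introduction) scenario the donor rows are drawn
    from the recipient pool; when that pool is smaller than
    ``n_recipient + n_donor`` the donor draw is allowed to overlap the
    resident draw (logged), so the scenario is still runnable.
    """
    rec_pool = [s for s in popmap.samples_in(recipient) if s in matrix.sample_ids]
    don_pool = [s for s in popmap.samples_in(donor) if s in matrix.sample_ids]
    if len(rec_pool) < config.n_recipient:
        raise ValueError(
            f"recipient {recipient!r} has {len(rec_pool)} samples; "
            f"needs {config.n_recipient}")
    if len(don_pool) < config.n_donor:
        raise ValueError(
            f"donor {donor!r} has {len(don_pool)} samples; needs {config.n_donor}")

    residents = list(rng.choice(rec_pool, size=config.n_recipient, replace=False))
    if donor == recipient:
        remaining = [s for s in don_pool if s not in residents]
        if len(remaining) >= config.n_donor:
            donors = list(rng.choice(remaining, size=config.n_donor, replace=False))
        else:
            logger.info("self-donor %s: pool of %d cannot supply %d distinct extras; "
                        "donor draw overlaps residents", donor, len(don_pool),
                        config.n_donor)
            donors = list(rng.choice(don_pool, size=config.n_donor, replace=False))
    else:
        donors = list(rng.choice(don_pool, size=config.n_donor, replace=False))

    ids = residents + donors
    idx = matrix.sample_indices(ids)
    return FounderSet(
        dosages=matrix.dosages[idx].astype(np.int8, copy=True),
        sample_ids=[f"{s}#don" if i >= config.n_recipient else s
                    for i, s in enumerate(ids)],
        provenance=["recipient"] * config.n_recipient + ["donor"] * config.n_donor,
        locus_ids=list(matrix.locus_ids),
    )


def impute_missing(founders: FounderSet, matrix: GenotypeMatrix, popmap: PopulationMap,
                   rng: np.random.Generator) -> FounderSet:
    """Replace missing founder calls by binomial draws from source-population
    allele frequencies.

    Each missing call becomes binomial(2, p) with p the allele frequency
    among the called genotypes of that founder's own source population at
    that locus; loci with no data in the source population fall back to the
    pooled founder frequency, and loci with no data anywhere are dropped
    (logged).
    """
    dos = founders.dosages.copy()
    if not (dos == MISSING).any():
        return founders

    base_ids = [s.split("#")[0] for s in founders.sample_ids]
    pop_of = {s: popmap.assignments[b] for s, b in zip(founders.sample_ids, base_ids)}
    pop_freq: dict[str, np.ndarray] = {}
    for pop in set(pop_of.values()):
        samples = [s for s in popmap.samples_in(pop) if s in matrix.sample_ids]
        sub = matrix.dosages[matrix.sample_indices(samples)]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            pop_freq[pop] = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)

    f_called = dos != MISSING
    f_n = f_called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        pooled = np.where(f_called, dos, 0).sum(axis=0) / (2.0 * f_n)

    for i, sid in enumerate(founders.sample_ids):
        miss = np.flatnonzero(dos[i] == MISSING)
        if miss.size == 0:
            continue
        p = pop_freq[pop_of[sid]][miss]
        fallback = np.isnan(p)
        p[fallback] = pooled[miss][fallback]
        drawable = ~np.isnan(p)
        dos[i, miss[drawable]] = rng.binomial(2, p[drawable]).astype(np.int8)

    dead = np.flatnonzero((dos == MISSING).any(axis=0))
    if dead.size:
        logger.info("impute_missing: dropping %d loci with no data anywhere", dead.size)
        keep = np.setdiff1d(np.arange(dos.shape[1]), dead)
        return FounderSet(
            dosages=dos[:, keep],
            sample_ids=founders.sample_ids,
            provenance=founders.provenance,
            locus_ids=[founders.locus_ids[j] for j in keep],
        )
    return FounderSet(dosages=dos, sample_ids=founders.sample_ids,
                      provenance=founders.provenance, locus_ids=founders.locus_ids)


def next_generation(parents: np.ndarray, n_offspring: int,
                    rng: np.random.Generator, distinct_parents: bool = True) -> np.ndarray:
    """One round of panmictic reproduction with full generation replacement.

    Each offspring draws two parents uniformly (distinct by default; parents
    are reused across offspring) and receives one allele from each parent per
    locus with probability 1/2, independently across loci.
    """
    parents = np.asarray(parents)
    n_par, n_loci = parents.shape
    if n_par < 2:
        raise ValueError("need at least 2 parents")
    p1 = rng.integers(0, n_par, size=n_offspring)
    if distinct_parents:
        shift = rng.integers(1, n_par, size=n_offspring)
        p2 = (p1 + shift) % n_par
    else:
        p2 = rng.integers(0, n_par, size=n_offspring)
    g1 = rng.random((n_offspring, n_loci)) < parents[p1] / 2.0
    g2 = rng.random((n_offspring, n_loci)) < parents[p2] / 2.0
    return (g1.astype(np.int8) + g2.astype(np.int8))


def mean_het(dosages: np.ndarray) -> float:
    """Pooled heterozygous-call fraction over all individuals and loci."""
    return float((dosages == 1).mean())


def run_simulation(founders: FounderSet, config: SimConfig,
                   rng: np.random.Generator, replicate: int = 0,
                   scenario: str = "") -> Trajectory:
    """Growth to the ceiling, then ``n_generations`` stable generations.

    Growth phase: N <- min(round(R*N), K) with full replacement each step;
    the first generation at K is generation 0.  The returned series has
    ``n_generations + 1`` values.
    """
    if (founders.dosages == MISSING).any():
        raise ValueError("founders contain missing genotypes; impute first")
    pop = founders.dosages
    sizes = [pop.shape[0]]
    while sizes[-1] < config.ceiling:
        n_next = min(int(round(config.growth_rate * sizes[-1])), config.ceiling)
        pop = next_generation(pop, n_next, rng, config.distinct_parents)
        sizes.append(n_next)

    series = [mean_het(pop)]  # generation 0 (first generation at the ceiling)
    for _ in range(config.n_generations):
        pop = next_generation(pop, config.ceiling, rng, config.distinct_parents)
        series.append(mean_het(pop))
    return Trajectory(replicate=replicate, scenario=scenario,
                      growth_sizes=sizes, mean_het=np.asarray(series))


def growth_sizes(n_founders: int, growth_rate: float, ceiling: int) -> list[int]:
    """Census-size sequence of the growth phase (founders included)."""
    sizes = [n_founders]
    while sizes[-1] < ceiling:
        sizes.append(min(int(round(growth_rate * sizes[-1])), ceiling))
    return sizes


def run_replicates(matrix: GenotypeMatrix, popmap: PopulationMap, recipient: str,
                   donor: str, config: SimConfig, scenario: str | None = None) -> ReplicateSet:
    """Independent replicate simulations with fresh founder draws.

    Replicate seeds are spawned deterministically from ``config.seed``; the
    95% band is mean +/- 1.96 * sd / sqrt(n_replicates) per generation.
    """
    scenario = scenario or donor
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    trajectories = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        founders = sample_founders(matrix, popmap, recipient, donor, config, rng)
        founders = impute_missing(founders, matrix, popmap, rng)
        trajectories.append(run_simulation(founders, config, rng,
                                           replicate=rep, scenario=scenario))
    het = np.vstack([t.mean_het for t in trajectories])
    mean = het.mean(axis=0)
    sd = het.std(axis=0, ddof=1) if config.n_replicates > 1 else np.zeros_like(mean)
    half = 1.96 * sd / np.sqrt(config.n_replicates)
    return ReplicateSet(scenario=scenario, trajectories=trajectories,
                        mean=mean, ci_low=mean - half, ci_high=mean + half)


def summarize(repset: ReplicateSet, baseline_het: float) -> MixingSummary:
    """Percent heterozygosity changes of a scenario against a baseline.

    ``baseline_het`` is the no-mixing (self-donor) scenario's mean
    generation-0 heterozygosity.  Percentages are undefined (NaN) for a zero
    baseline.
    """
    mean = repset.mean
    max_het = float(mean.max())
    final_het = float(mean[-1])
    if baseline_het > 0:
        inc_max = 100.0 * (max_het - baseline_het) / baseline_het
        chg_fin = 100.0 * (final_het - baseline_het) / baseline_het
    else:
        inc_max = chg_fin = float("nan")
    dec = 100.0 * (max_het - final_het) / max_het if max_het > 0 else float("nan")
    return MixingSummary(
        scenario=repset.scenario,
        baseline_het=baseline_het,
        initial_het=float(mean[0]),
        max_het=max_het,
        final_het=final_het,
        pct_increase_at_max=inc_max,
        pct_change_at_final=chg_fin,
        pct_decline_from_max=dec,
    )
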