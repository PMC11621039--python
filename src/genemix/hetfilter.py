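"""Individualised autosomal-heterozygosity filtering.

One sample at a time, per-site records (genotype, total depth DP, per-allele
depths AD, site quality QUAL) are filtered down to confidently genotyped
sites, polyallelic sites are atomised into biallelic ref-vs-alt records, and
heterozygosity is computed across *all* retained sites — variant and
monomorphic alike.  Because each sample is processed independently, the
estimate does not depend on which other samples were sequenced, making values
comparable across populations with very different sample sizes.

Exclusion predicates are strict inequalities (DP > max, DP < min,
QUAL < threshold, allele depth < minimum), so boundary values pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAR = "*"

#: column layout of ``SampleSiteTable.records``
_COLUMNS = ["site_id", "gt", "alts", "dp", "ad", "qual"]


@dataclass
class SampleSiteTable:
    """One sample's per-site records.

    ``records`` columns: ``site_id`` (str); ``gt`` (allele-index pair tuple,
    or None when missing); ``alts`` (tuple of alt alleles, possibly
    containing the spanning-deletion star); ``dp`` (total depth); ``ad``
    (tuple of per-allele depths, ref first, or None); ``qual`` (float).
    """

    sample_id: str
    records: pd.DataFrame
    filter_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_cols = [c for c in _COLUMNS if c not in self.records.columns]
        if missing_cols:
            raise ValueError(f"site table lacks column(s): {', '.join(missing_cols)}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterConfig:
    """Thresholds defining a confidently genotyped site."""

    max_dp: float = 71
    min_dp: float = 15
    min_qual: float = 25
    min_het_allele_depth: float = 3

    def __post_init__(self) -> None:
        if self.min_dp > self.max_dp:
            raise ValueError("min_dp must be <= max_dp")
        for name in ("max_dp", "min_dp", "min_qual", "min_het_allele_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class HetResult:
    """Autosomal heterozygosity of one sample over its retained sites."""

    sample_id: str
    n_sites_retained: int
    n_het: int
    autosomal_het: float | None  # None when no sites retained (undefined)


def atomize_record(record: pd.Series | dict) -> list[dict]:
    """Split one site record into biallelic ref-vs-alt atoms.

    A site with k alt alleles yields k records.  The genotype at each atom is
    the sample's copy number of that atom's alt allele: 0 copies -> 0/0, one
    copy -> 0/1, two copies -> 1/1.  AD at an atom keeps (ref depth, that
    alt's depth); DP and QUAL are copied unchanged.  Biallelic records come
    back as a single atom identical to the input.
    """
    alts = tuple(record["alts"])
    gt = record["gt"]
    ad = record["ad"]
    atoms = []
    for k, alt in enumerate(alts, start=1):
        atom = {
            "site_id": record["site_id"] if len(alts) == 1 else f"{record['site_id']}:{alt}",
            "alts": (alt,),
            "dp": record["dp"],
            "qual": record["qual"],
        }
        if gt is None:
            atom["gt"] = None
        else:
            copies = sum(1 for a in gt if a == k)
            atom["gt"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[copies]
        if ad is None:
            atom["ad"] = None
        else:
            atom["ad"] = (ad[0], ad[k] if len(ad) > k else 0)
        atoms.append(atom)
    return atoms


def filter_sites(table: SampleSiteTable, config: FilterConfig | None = None) -> SampleSiteTable:
    """Retain confidently genotyped atoms, logging per-step removal counts.

    Steps, in order: drop sites with a star (spanning-deletion) allele; drop
    missing genotypes; drop DP above/below the depth window; drop low QUAL;
    atomise polyallelic sites; drop heterozygous atoms where either allele's
    depth is below the minimum.  Idempotent: filtering a filtered table is a
    no-op.
    """
    config = config or FilterConfig()
    df = table.records
    for col in ("dp", "ad", "qual"):
        if df[col].isna().all() and len(df):
            raise ValueError(f"site table for {table.sample_id} lacks {col.upper()} annotations")

    log: dict[str, int] = {}
    n0 = len(df)
    df = df[~df["alts"].map(lambda a: STAR in a)]
    log["star_allele"] = n0 - len(df)

    n0 = len(df)
    df = df[df["gt"].notna()]
    log["missing_genotype"] = n0 - len(df)

    n0 = len(df)
    df = df[~(df["dp"] > config.max_dp)]
    log["dp_above_max"] = n0 - len(df)

    n0 = len(df)
    df = df[~(df["dp"] < config.min_dp)]
    log["dp_below_min"] = n0 - len(df)

    n0 = len(df)
    df = df[~(df["qual"] < config.min_qual)]
    log["low_qual"] = n0 - len(df)

    n0 = len(df)
    multi = df["alts"].map(len) > 1
    if multi.any():
        atoms = [a for _, rec in df[multi].iterrows() for a in atomize_record(rec)]
        df = pd.concat([df[~multi], pd.DataFrame(atoms, columns=_COLUMNS)],
                       ignore_index=True)
    else:
        df = df.reset_index(drop=True)
    log["atoms_added"] = len(df) - n0

    het = df["gt"].map(lambda g: g is not None and g[0] != g[1])
    low_ad = df["ad"].map(
        lambda ad: ad is None or len(ad) < 2
        or min(ad[0], ad[1]) < config.min_het_allele_depth
    )
    n0 = len(df)
    df = df[~(het & low_ad)]
    log["het_low_allele_depth"] = n0 - len(df)

    return SampleSiteTable(sample_id=table.sample_id,
                           records=df.reset_index(drop=True)[_COLUMNS],
                           filter_log=log)


def autosomal_het(table: SampleSiteTable) -> HetResult:
    """Heterozygous fraction across all retained sites of one sample.

    With zero retained sites the estimate is undefined and reported as None,
    never as 0, so population means are not dragged down by empty samples.
    """
    n = len(table.records)
    n_het = int(table.records["gt"].map(
        lambda g: g is not None and g[0] != g[1]).sum())
    return HetResult(
        sample_id=table.sample_id,
        n_sites_retained=n,
        n_het=n_het,
        autosomal_het=(n_het / n) if n > 0 else None,
    )


def results_frame(results: list[HetResult], popmap=None) -> pd.DataFrame:
    """Tabulate HetResults (sample, n_sites, n_het, het[, population])."""
    df = pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "n_sites": [r.n_sites_retained for r in results],
            "n_het": [r.n_het for r in results],
            "het": [r.autosomal_het for r in results],
        }
    )
    if popmap is not None:
        df["population"] = [popmap.assignments.get(s) for s in df["sample"]]
    return df


def het_site_correlation(results_by_pop: dict[str, list[HetResult]],
                         alpha: float = 0.05) -> pd.DataFrame:
    """QC autocorrelation: retained-site count vs heterozygosity per population.

    Pearson r within each population with >= 3 usable samples (others are
    skipped and listed in ``.attrs['skipped']``).  Significance uses a
    Bonferroni-adjusted threshold ``alpha / n_populations_tested`` stored in
    ``.attrs['threshold']``.  Zero-variance inputs give an undefined (NaN)
    correlation, never a significant one.
    """
    rows = {}
    skipped: list[str] = []
    for pop, results in results_by_pop.items():
        pairs = [(r.n_sites_retained, r.autosomal_het)
                 for r in results if r.autosomal_het is not None]
        if len(pairs) < 3:
            skipped.append(pop)
            continue
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[pop] = (len(pairs), np.nan, np.nan)
            continue
        r, p = stats.pearsonr(x, y)
        rows[pop] = (len(pairs), r, p)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=["n", "r", "p"])
    n_tested = len(df)
    threshold = alpha / n_tested if n_tested else np.nan
    df["significant"] = df["p"] < threshold
    df.attrs["threshold"] = threshold
    df.attrs["skipped"] = skipped
    return df


def table_from_vcf(path, sample: str | None = None) -> SampleSiteTable:
    """Load a single-sample VCF (FORMAT/DP, FORMAT/AD, QUAL) as a site table."""
    from cyvcf2 import VCF

    reader = VCF(str(path))
    samples = list(reader.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError("VCF is multi-sample; pass the sample name explicitly")
        sample = samples[0]
    idx = samples.index(sample)

    recs = []
    for var in reader:
        g = var.genotypes[idx]
        gt = None if (g[0] < 0 or g[1] < 0) else (g[0], g[1])
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        recs.append({
            "site_id": f"{var.CHROM}:{var.POS}",
            "gt": gt,
            "alts": tuple(var.ALT or ()),
            "dp": float(dp.reshape(len(samples), -1)[idx, 0]) if dp is not None else np.nan,
            "ad": tuple(int(x) for x in ad.reshape(len(samples), -1)[idx]) if ad is not None else None,
            "qual": var.QUAL if var.QUAL is not None else np.nan,
        })
    return SampleSiteTable(sample_id=sample, records=pd.DataFrame(recs, columns=_COLUMNS))
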