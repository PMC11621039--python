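"""Genotype data model and I/O for multi-sample VCFs and population maps.

The central container is :class:`GenotypeMatrix`: diploid alt-allele dosages
(samples x loci) with a single missing sentinel.  Multiallelic SNP records are
split into ref-vs-alt biallelic columns on ingestion, so every downstream
module (simulation, differentiation metrics) operates on biallelic loci only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

_BASES = {"A", "C", "G", "T"}


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class PopmapError(ValueError):
    """Raised for malformed population-map files."""


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages for samples x biallelic loci.

    Parameters
    ----------
    sample_ids
        Unique sample names, one per matrix row.
    locus_ids
        Unique locus names, one per column.  Loci created by splitting a
        multiallelic VCF record carry a ``:ALT`` suffix.
    dosages
        ``(n_samples, n_loci)`` integer array with entries in {0, 1, 2} or
        :data:`MISSING`.
    allele_labels
        Per-locus ``(ref, alt)`` nucleotide pair.
    dp, ad_ref, ad_alt
        Optional per-call read-depth annotations (``MISSING`` where absent).
    qual
        Optional per-locus site quality (NaN where absent).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray
    allele_labels: list[tuple[str, str]]
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.locus_ids) != m or len(self.allele_labels) != m:
            raise ValueError("locus_ids/allele_labels length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing sentinel")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            dosages=self.dosages[idx].copy(),
            dp=None if self.dp is None else self.dp[idx].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[idx].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (samples x loci) for inspection/CSV export."""
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.locus_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class PopulationMap:
    """Sample -> population assignment."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise PopmapError("population map is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def missing_from(self, sample_ids: Iterable[str]) -> list[str]:
        """Mapped samples absent from a matrix (flagged, not fatal)."""
        present = set(sample_ids)
        return [s for s in self.assignments if s not in present]


# ----------------------------------------------------------------------
# VCF ingestion
# ----------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.2, GT required) into a :class:`GenotypeMatrix`.

    Multiallelic SNP sites are split into ref-vs-alt biallelic columns whose
    locus ids carry a ``:ALT`` suffix; per-sample dosage at each split column
    is that sample's copy number of the column's alt allele.  Non-SNP records
    (indels, symbolic alleles) are skipped and counted.  Half-missing
    genotypes (``0/.``) are treated as missing; haploid or >2-ploid calls are
    rejected.  FORMAT/DP, FORMAT/AD and QUAL are retained when present.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        reader = VCF(str(path), gts012=False)
    except Exception as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(reader.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has no sample columns")

    locus_ids: list[str] = []
    labels: list[tuple[str, str]] = []
    dosage_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    adr_cols: list[np.ndarray] = []
    ada_cols: list[np.ndarray] = []
    quals: list[float] = []
    any_dp = any_ad = False
    n_skipped = 0

    try:
        for var in reader:
            ref = var.REF
            alts = [a for a in (var.ALT or [])]
            snp_alts = [(k + 1, a) for k, a in enumerate(alts) if a in _BASES]
            if ref not in _BASES or not snp_alts:
                n_skipped += 1
                continue

            gts = var.genotypes  # [a1, a2, phased] per sample
            alleles = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for i, g in enumerate(gts):
                if len(g) == 2:  # haploid call: [allele, phased]
                    raise VcfParseError(
                        f"{path}: haploid genotype for sample {samples[i]} at "
                        f"{var.CHROM}:{var.POS}; only diploid records supported"
                    )
                if len(g) > 3:
                    raise VcfParseError(
                        f"{path}: ploidy {len(g) - 1} at {var.CHROM}:{var.POS}; "
                        "only diploid records supported"
                    )
                alleles[i, 0], alleles[i, 1] = g[0], g[1]
            call_missing = (alleles < 0).any(axis=1)

            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            try:
                ad = var.format("AD")
            except KeyError:
                ad = None
            if dp is not None:
                any_dp = True
            if ad is not None:
                any_ad = True

            base_id = var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
            multi = len(snp_alts) > 1 or len(alts) > 1
            for alt_index, alt in snp_alts:
                dose = (alleles == alt_index).sum(axis=1).astype(np.int8)
                dose[call_missing] = MISSING
                dosage_cols.append(dose)
                locus_ids.append(f"{base_id}:{alt}" if multi else base_id)
                labels.append((ref, alt))
                quals.append(var.QUAL if var.QUAL is not None else np.nan)
                if dp is not None:
                    d = dp.reshape(len(samples), -1)[:, 0].astype(np.int32)
                    dp_cols.append(np.where(d < 0, MISSING, d))
                else:
                    dp_cols.append(np.full(len(samples), MISSING, dtype=np.int32))
                if ad is not None:
                    a = ad.reshape(len(samples), -1)
                    adr = a[:, 0].astype(np.int32)
                    ada = a[:, alt_index].astype(np.int32) if a.shape[1] > alt_index else np.full(len(samples), MISSING, np.int32)
                    adr_cols.append(np.where(adr < 0, MISSING, adr))
                    ada_cols.append(np.where(ada < 0, MISSING, ada))
                else:
                    adr_cols.append(np.full(len(samples), MISSING, dtype=np.int32))
                    ada_cols.append(np.full(len(samples), MISSING, dtype=np.int32))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc

    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP records in %s", n_skipped, path)
    if not dosage_cols:
        raise VcfParseError(f"VCF {path} contains no usable SNP records")

    return GenotypeMatrix(
        sample_ids=samples,
        locus_ids=locus_ids,
        dosages=np.column_stack(dosage_cols),
        allele_labels=labels,
        dp=np.column_stack(dp_cols) if any_dp else None,
        ad_ref=np.column_stack(adr_cols) if any_ad else None,
        ad_alt=np.column_stack(ada_cols) if any_ad else None,
        qual=np.asarray(quals, dtype=float),
    )


_HEADER_TOKENS = {"sample", "sample_id", "id", "individual"}


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a two-column sample<TAB>population map (header optional)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise PopmapError(f"{path}:{lineno}: expected two columns, got {line!r}")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].lower() in _HEADER_TOKENS:
        rows = rows[1:]
    if not rows:
        raise PopmapError(f"population map {path} is empty")
    assignments: dict[str, str] = {}
    for sample, pop in rows:
        if sample in assignments:
            raise PopmapError(f"duplicate sample {sample!r} in {path}")
        assignments[sample] = pop
    return PopulationMap(assignments)


# ----------------------------------------------------------------------
# VCF export
# ----------------------------------------------------------------------

def _chrom_pos(locus_id: str, fallback_pos: int) -> tuple[str, int]:
    parts = locus_id.split(":")
    if len(parts) >= 2 and parts[1].isdigit():
        return parts[0], int(parts[1])
    return "1", fallback_pos


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix as an uncompressed VCF v4.2.

    Each column becomes one biallelic record; the locus id is stored in the
    ID field so that ``read_vcf(write_vcf(m))`` round-trips ids, dosages and
    allele labels exactly.  DP/AD annotations are emitted when present.
    """
    path = Path(path)
    has_dp = matrix.dp is not None
    has_ad = matrix.ad_ref is not None
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["AD"] if has_ad else [])
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

    chroms: dict[str, None] = {}
    records = []
    for j, lid in enumerate(matrix.locus_ids):
        chrom, pos = _chrom_pos(lid, j + 1)
        chroms.setdefault(chrom, None)
        records.append((chrom, pos, lid, j))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genemix\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for chrom, pos, lid, j in records:
            ref, alt = matrix.allele_labels[j]
            qual = "."
            if matrix.qual is not None and np.isfinite(matrix.qual[j]):
                qual = f"{matrix.qual[j]:g}"
            calls = []
            for i in range(matrix.n_samples):
                parts = [gt_strings[int(matrix.dosages[i, j])]]
                if has_dp:
                    d = int(matrix.dp[i, j])
                    parts.append("." if d == MISSING else str(d))
                if has_ad:
                    r_, a_ = int(matrix.ad_ref[i, j]), int(matrix.ad_alt[i, j])
                    parts.append("." if r_ == MISSING else f"{r_},{a_}")
                calls.append(":".join(parts))
            fh.write(f"{chrom}\t{pos}\t{lid}\t{ref}\t{alt}\t{qual}\t.\t.\t"
                     + ":".join(fmt_keys) + "\t" + "\t".join(calls) + "\n")


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
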