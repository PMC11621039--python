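# Methods

## The mixing model

The simulator is a diploid, multi-locus Wright–Fisher model with
non-overlapping generations operating directly on observed genotype rows.
A scenario starts from `n_recipient` + `n_donor` founder individuals drawn
uniformly without replacement from their source populations (defaults
20 + 4 — a 20% addition chosen to limit swamping while avoiding founder
effects).  Census size then grows by `N <- min(round(R*N), K)` per
generation with complete replacement (`R = 2`, `K = 300` by default; from
24 founders the sizes run exactly 24, 48, 96, 192, 300); the first
generation at the ceiling is "generation 0", after which `n_generations`
(default 50) further replacements occur at constant size `K`.

Reproduction: each offspring draws two parents uniformly; every locus
receives one allele from each parent with probability 1/2, independently
across loci (free recombination between markers, none within; no mutation;
no selection; no sexes).  Parents are **distinct by default** — the
"two randomly selected parental genotypes" rule is ambiguous about selfing,
and excluding it avoids importing an unstated selfing assumption; the
`distinct_parents` flag restores textbook Wright–Fisher mating.  The modes
differ only in a constant heterozygote-excess factor (2N/(2N−1), Levene's
correction): in both, heterozygosity between two offspring generations
decays by exactly (1 − 1/2N) per generation, which the drift-law tests
exploit by checking the H(50)/H(10) ratio.

The reported statistic is pooled variant-site observed heterozygosity: the
fraction of all (individual, locus) calls that are heterozygous, over **all
panel loci** including loci monomorphic within the scenario, so
trajectories are comparable across scenarios.  Replicates (default 5)
redraw founders; per-generation 95% bands use the normal approximation
mean ± 1.96·sd/√reps.  Replicate RNGs are spawned from a single seed, so
every run is bit-reproducible.

Missing founder genotypes are imputed before simulation as binomial(2, p)
draws, with p the allele frequency among called genotypes of the founder's
own source population (falling back to the pooled founder frequency, and
dropping — with a logged count — loci with no data anywhere).  The
self-donor scenario is the no-mixing reference; when the recipient pool is
smaller than `n_recipient + n_donor` the donor draw may overlap the
resident draw (logged) so the reference is still runnable from, e.g., a
21-sample pool.

Scenario summaries report percent changes of the cross-replicate mean
trajectory against the self-donor generation-0 mean: increase at the
trajectory maximum, change at the final generation, and decline from
maximum — the last isolates the pure-drift loss, ≈ 1 − (1 − 1/2K)^50 ≈ 8%
at K = 300, independent of the donor.

## Differentiation and diversity metrics

* **Weir–Cockerham F_ST** is computed from the 1984 per-locus variance
  components a (among populations), b (among individuals) and c (within
  individuals), combined across loci as Σa / Σ(a+b+c) (ratio of sums, the
  standard multi-locus convention); per-locus components are exposed for
  inspection.  Loci need ≥ 1 called diploid per population and mean sample
  size > 1.  Significance uses a one-sided loci bootstrap (default 5,000
  resamples): p = fraction of bootstrap estimates ≤ 0, appropriate for
  testing F_ST > 0.
* **Jost's D** per pair uses Nei–Chesser bias-corrected heterozygosities
  with the per-locus harmonic-mean sample size ñ:
  H_S = (2ñ/(2ñ−1)) · mean within-population expected heterozygosity,
  H_T = pooled expected heterozygosity + H_S/(4ñ); H_S and H_T are averaged
  across loci **before** combining into D = 2(H_T − H_S)/(1 − H_S).
  Averaging the per-locus D values instead is a defensible alternative
  convention; the averaged-H form is used here and pinned by oracle tests.
* **q0 beta diversity** (unshared allelic richness): per locus, beta =
  gamma richness of the pooled pair divided by mean per-population
  richness, averaged over loci with data in both populations; range [1, 2]
  for biallelic loci.
* **Fixed allelic differences**: loci with alt frequency ≤ t in one
  population and ≥ 1−t in the other (t = 0 by default).  **Private
  alleles**: ref or alt alleles observed in exactly one population.
* The minimum per-locus calling requirement defaults to a single diploid
  genotype per population; the source analyses do not state one, and the
  threshold is configurable where it matters.

## Individualised autosomal heterozygosity

Per-sample site records (genotype, DP, per-allele AD, QUAL) are filtered
in a fixed order: star (spanning-deletion) alleles, missing genotypes,
DP > 71, DP < 15, QUAL < 25, then atomisation of polyallelic sites, then
removal of heterozygous atoms where either allele's depth is below 3.  All
exclusion predicates are strict inequalities, so boundary values (DP = 15
or 71, QUAL = 25, AD = 3) are retained.  The order matters only for the
per-step removal counts, which the filter logs.

Atomisation maps a k-alt site to k ref-vs-alt atoms; the genotype at each
atom is the sample's copy number of that alt (0 → 0/0, 1 → 0/1, 2 → 1/1)
and AD keeps (ref depth, that alt's depth).  A consequence worth knowing:
atoms derived from alt/alt heterozygotes (e.g. GT 1/2) carry ref depth ≈ 0
and are therefore removed by the heterozygous allele-depth rule.  This is
the faithful composition of the two rules; alternative conventions exist
but would silently change heterozygosity counts.

Heterozygosity is n_het / n_retained over all retained atoms.  A sample
with zero retained sites is reported as undefined, never 0, so population
means are not biased downward.  The QC step computes the within-population
Pearson correlation of retained-site count vs heterozygosity (populations
with < 3 usable samples are skipped) with a Bonferroni-adjusted threshold
alpha / n_populations_tested (0.05/12 ≈ 0.0041 at the study scale); a
sound dataset shows no significant autocorrelation.

Upstream read processing, de-novo assembly and pseudo-reference consensus
construction are out of scope: the filter consumes per-sample site tables,
from a single-sample VCF (FORMAT/DP, FORMAT/AD, QUAL required) or from the
synthetic generator.

## Synthetic data: what it emulates and what it does not

`generate_structured_populations` draws, per locus, an ancestral frequency
p ~ Uniform(MAF window, default 0.05–0.5), then per population a
Balding–Nichols frequency Beta with mean p and variance p(1−p)F; genotypes
are binomial(2, ·).  F is an expected-F_ST dial: the Weir–Cockerham
estimator recovers the generating F of a pair within ±0.05 at 50 samples
and 5,000 loci (a standing parameter-recovery test).  On top of this,
`fixed_diff_injections` forces chosen locus sets to opposite fixation
between named pairs (one called genotype per involved population is kept
observable under missingness, so injections are always recoverable), and
`low_het_scale` multiplies minor-allele frequencies to emulate a
genetically depauperate population.  Missingness is independent per call.

The `study_shape_config` preset mirrors the scale of the motivating
analysis: 12 populations, 137 samples (4–21 each), 7,333 biallelic SNPs,
~8% missingness, one fenced low-heterozygosity recipient of 21 samples
(variant-site Ho ≈ 0.08), an
extra-depauperate 4-sample island population, and two distant populations
separated from the recipient by ~1,500 injected fixed differences (about
20% of the panel, the magnitude expected between taxonomically distinct
lineages — enough that mixing from them roughly doubles the recipient's
heterozygosity).  Injections fix each pair toward the allele the first
population already favours, so forcing fixation barely perturbs an
already-depressed recipient; the recipient's minor-allele scale (0.28)
is set so its panel-wide variant Ho lands near 0.08 after injection.  The
allele-frequency spectrum, linkage, batch effects and the RADseq assay
itself are **not** modelled: passing tests demonstrate correctness of the
estimators and simulator under the generating model, not robustness to
real-data artefacts.

The depth/quality generator draws DP from a negative binomial (mean 30,
shape 8 — about 89% of sites inside the 15–71x window), splits DP
binomially 50:50 across alleles at heterozygous sites (all depth on the
called allele at homozygous sites), and QUAL from a normal (mean 60,
sd 20) truncated at 0.

## Numerical choices and degenerate inputs

* Genotypes are int8 dosages {0,1,2} with −1 as the single missing
  sentinel; half-missing VCF genotypes count as missing; only diploid
  records are accepted.  Multiallelic SNP records are split into biallelic
  columns on ingestion (the simulator and metrics are biallelic); per-alt
  allele-count conservation is property-tested.
* Undefined estimates (no informative loci, all-missing panels, zero
  bootstrap denominators, zero-variance correlations) are NaN/None and
  flagged, never silently 0.
* F_ST may be slightly negative for undifferentiated pairs (unbiasedness
  of WC84), as may Jost's D from bias correction; tests allow |value| <
  0.02 at the null.
* Growth rounding uses round-half-even via `round()`; with R = 2 the sizes
  are exact integers throughout.
* Acceptance-scale runs use 7,000 loci and the default 5 replicates —
  large enough that cross-replicate Monte-Carlo error on the drift decline
  is a few tenths of a percentage point.

## Known limitations

No selection, mutation, linkage, sex structure or overlapping generations
in the simulator; donor scenarios share a single recipient at a time; the
Jost's D and q0-beta multi-locus conventions are documented choices among
several in the literature rather than re-implementations of any specific
package's internals.
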