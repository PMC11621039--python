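# genemix

Simulation and measurement tools for planning **genetic mixing** (genetic
rescue / augmentation) in strongly structured populations: given a
genetically depauperate recipient population and a panel of candidate donor
populations genotyped at thousands of SNPs, which donor gives the largest
and most durable gain in heterozygosity?

The package bundles four pieces that are usually scattered across tools:

1. **A forward-in-time introduction simulator** (`genemix.simintro`).
   Founders are drawn as *n* recipient + *m* donor individuals (default
   20 + 4, a 20% addition).  The census grows by `N <- min(round(R*N), K)`
   with complete generation replacement until it reaches the ceiling *K*
   (that generation is generation 0), then runs 50 non-overlapping
   panmictic generations at constant size.  Each offspring takes one allele
   per locus from each of two distinct, uniformly drawn parents; mutation
   and recombination between markers are neglected, so the mean
   variant-site heterozygosity H_t recorded at each generation changes
   only through mixing and drift.  Under pure drift E[H_t] decays by
   (1 − 1/2K) per generation — about 8% over 50 generations at K = 300.
2. **Differentiation metrics** (`genemix.divmetrics`): Weir–Cockerham
   (1984) F_ST (ratio-of-sums across loci, loci-bootstrap significance),
   pairwise fixed allelic differences, private alleles, Jost's D from
   Nei–Chesser bias-corrected H_S/H_T, and order-0 (richness) beta
   diversity — the candidate predictors of mixing outcomes.
3. **An individualised autosomal-heterozygosity filter**
   (`genemix.hetfilter`): one sample at a time, per-site records are
   filtered to confidently genotyped sites (depth window 15–71x, QUAL ≥ 25,
   per-allele depth ≥ 3 at heterozygous atoms, no stars, no missing
   genotypes; polyallelic sites atomised to biallelic records) and
   heterozygosity is computed over *all* retained sites, variant and
   monomorphic.  Because no cross-sample call-rate filter is involved, the
   estimate is comparable between populations of very different sample
   sizes.
4. **A structured synthetic-data generator** (`genemix.synthetic_data`)
   producing Balding–Nichols multi-population genotype matrices (a
   one-parameter divergence dial F per population, injected fixed
   differences, depressed-heterozygosity presets) and per-sample
   depth/quality site records, so the whole pipeline runs end-to-end with
   no external data.

`genemix.scenario_analysis` ties these together: one mixing scenario per
candidate donor (including the recipient as self-donor — the no-mixing
reference), Pearson correlations of the simulated outcome against each
differentiation/diversity metric, and CSV/figure reports.

## Worked example

```python
import numpy as np
from genemix.synthetic_data import study_shape_config, generate_structured_populations
from genemix.simintro import SimConfig
from genemix.scenario_analysis import run_all_scenarios

matrix, popmap = generate_structured_populations(study_shape_config(seed=0))
results = run_all_scenarios(matrix, popmap, "REC", SimConfig(seed=100))
print(f"baseline {results.baseline_het:.4f}")
print(results.summaries[["final_het", "pct_increase_at_max",
                         "pct_decline_from_max"]]
      .sort_values("pct_increase_at_max", ascending=False).round(3))
```

which prints (12 populations, 7,333 loci, 5 replicates each):

```
baseline 0.0777
      final_het  pct_increase_at_max  pct_decline_from_max
FAR2      0.170              135.994                 7.433
FAR1      0.149              110.104                 8.829
W1        0.137               92.146                 8.144
E1        0.136               90.570                 7.875
...
T2        0.123               72.021                 7.848
ISL       0.120               68.653                 8.198
REC       0.071                0.000                 8.045
```

Reading: the self-donor scenario (`REC`) drifts down ~8% over 50
generations — the pure-drift loss at constant size 300.  Every real donor
raises heterozygosity well above the baseline at its maximum
(`pct_increase_at_max`), after which all scenarios decline by the same
~7–8% drift rate (`pct_decline_from_max`); the two populations carrying
~1,500 fixed allelic differences against the recipient (`FAR1`, `FAR2`)
give by far the largest gains, and even the depauperate 4-sample island
population (`ISL`) provides a substantial, durable increase.  The
numbered scripts under `analysis/` run the same pipeline step by step
(dataset generation, differentiation metrics, autosomal heterozygosity,
mixing scenarios, metric correlations) and write their tables under
`results/`.

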