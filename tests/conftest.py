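import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genemix.genotype_io import MISSING, GenotypeMatrix, PopulationMap

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(dosages, sample_ids=None, locus_ids=None, **kwargs):
    """Build a GenotypeMatrix from a plain nested list of dosages."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        locus_ids=locus_ids or [f"L{j}" for j in range(m)],
        dosages=dosages,
        allele_labels=[("A", "T")] * m,
        **kwargs,
    )


def two_pop_matrix(dosA, dosB):
    """Matrix + popmap for two populations given per-pop dosage lists."""
    dosA, dosB = np.asarray(dosA), np.asarray(dosB)
    dosages = np.vstack([dosA, dosB])
    ids = [f"a{i}" for i in range(len(dosA))] + [f"b{i}" for i in range(len(dosB))]
    matrix = make_matrix(dosages, sample_ids=ids)
    popmap = PopulationMap({**{f"a{i}": "A" for i in range(len(dosA))},
                            **{f"b{i}": "B" for i in range(len(dosB))}})
    return matrix, popmap


@pytest.fixture(scope="session")
def ladder_dataset():
    """Recipient plus donors separated by an increasing number of injected
    fixed differences; shared by mixing-monotonicity and correlation tests."""
    from genemix.synthetic_data import SynthConfig, generate_structured_populations

    scale = {name: 0.18 for name in ("REC", "D0", "D1", "D2", "D3")}
    cfg = SynthConfig(
        n_loci=3000,
        populations=[("REC", 21, 0.05), ("D0", 6, 0.10), ("D1", 6, 0.10),
                     ("D2", 6, 0.10), ("D3", 6, 0.10)],
        ancestral_maf_range=(0.05, 0.5),
        missing_rate=0.02,
        fixed_diff_injections=[("REC", "D1", 150), ("REC", "D2", 400),
                               ("REC", "D3", 800)],
        low_het_scale=scale,
        seed=424242,
    )
    return generate_structured_populations(cfg)
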