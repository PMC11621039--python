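"""Differentiation metrics against independent scalar oracles and brute force."""

import numpy as np
import pytest

from genemix import divmetrics as dm
from genemix.genotype_io import MISSING, PopulationMap
from genemix.synthetic_data import SynthConfig, generate_structured_populations

from .conftest import make_matrix, two_pop_matrix
from .oracles import nei_chesser_jost_d, q0_beta_by_hand, wc84_fst


def pop_stats(dosages):
    """Plain-python (n, p, h) of one population's dosage list at one locus."""
    called = [d for d in dosages if d != MISSING]
    n = len(called)
    p = sum(called) / (2 * n)
    h = sum(1 for d in called if d == 1) / n
    return n, p, h


class TestObservedHet:
    def test_all_homozygous_is_zero(self):
        m = make_matrix([[0, 2], [2, 0]])
        assert dm.observed_het_variant(m) == 0.0

    def test_all_heterozygous_is_one(self):
        m = make_matrix([[1], [1]])
        assert dm.observed_het_variant(m) == 1.0

    def test_matches_hand_tally_with_missing(self):
        rows = [[0, 1, MISSING], [1, 1, 2], [2, MISSING, 0], [1, 0, 0]]
        m = make_matrix(rows)
        flat = [d for row in rows for d in row if d != MISSING]
        expected = sum(1 for d in flat if d == 1) / len(flat)
        assert dm.observed_het_variant(m) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_subset_undefined(self):
        m = make_matrix([[MISSING], [0]])
        assert np.isnan(dm.observed_het_variant(m, ["s0"]))


class TestWcFst:
    @pytest.mark.parametrize("dosA,dosB", [
        # single locus, n=5 each, pA=0.8 / pB=0.2
        ([[2], [2], [2], [1], [1]], [[0], [0], [0], [1], [1]]),
        # unequal sizes, two loci
        ([[2, 1], [1, 0], [2, 2]], [[0, 0], [1, 1], [0, 2], [0, 1], [1, 0]]),
        # with missing calls
        ([[2, MISSING], [1, 1], [2, 0], [1, 2]], [[0, 1], [MISSING, 0], [0, 0]]),
    ])
    def test_matches_independent_oracle(self, dosA, dosB):
        matrix, popmap = two_pop_matrix(dosA, dosB)
        loci = []
        for j in range(matrix.n_loci):
            colA = [row[j] for row in dosA]
            colB = [row[j] for row in dosB]
            loci.append([pop_stats(colA), pop_stats(colB)])
        expected = wc84_fst(loci)
        got = dm.wc_fst(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 400), size=(100, 400))
        matrix, popmap = two_pop_matrix(dos[:50], dos[50:])
        fst = dm.wc_fst(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        assert abs(fst) < 0.02

    def test_opposite_fixation_is_one(self):
        matrix, popmap = two_pop_matrix([[0, 0]] * 4, [[2, 2]] * 4)
        assert dm.wc_fst(matrix, popmap.samples_in("A"),
                         popmap.samples_in("B")) == pytest.approx(1.0)

    def test_symmetry(self):
        matrix, popmap = two_pop_matrix([[2, 1, 0], [1, 0, 1]], [[0, 1, 2], [0, 2, 1]])
        A, B = popmap.samples_in("A"), popmap.samples_in("B")
        assert dm.wc_fst(matrix, A, B) == dm.wc_fst(matrix, B, A)


class TestBootstrap:
    def test_differentiated_pair_significant(self):
        cfg = SynthConfig(n_loci=1000, populations=[("A", 50, 0.2), ("B", 50, 0.2)],
                          seed=9)
        m, pm = generate_structured_populations(cfg)
        p = dm.fst_bootstrap_p(m, pm.samples_in("A"), pm.samples_in("B"),
                               n_boot=1000, seed=1)
        assert p < 0.001

    def test_random_split_not_significant(self):
        rng = np.random.default_rng(17)
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, 300), size=(60, 300))
        matrix, popmap = two_pop_matrix(dos[:30], dos[30:])
        p = dm.fst_bootstrap_p(matrix, popmap.samples_in("A"),
                               popmap.samples_in("B"), n_boot=500, seed=2)
        assert p > 0.05

    def test_zero_bootstraps_rejected(self):
        matrix, popmap = two_pop_matrix([[0, 1]], [[1, 2]])
        with pytest.raises(ValueError):
            dm.fst_bootstrap_p(matrix, popmap.samples_in("A"),
                               popmap.samples_in("B"), n_boot=0)

    def test_deterministic_under_seed(self):
        cfg = SynthConfig(n_loci=200, populations=[("A", 10, 0.05), ("B", 10, 0.05)],
                          seed=3)
        m, pm = generate_structured_populations(cfg)
        args = (m, pm.samples_in("A"), pm.samples_in("B"))
        assert dm.fst_bootstrap_p(*args, n_boot=300, seed=7) == \
            dm.fst_bootstrap_p(*args, n_boot=300, seed=7)


class TestFixedDifferences:
    def test_opposite_fixation_counted(self):
        matrix, popmap = two_pop_matrix([[0], [0]], [[2], [2]])
        assert dm.fixed_differences(matrix, popmap.samples_in("A"),
                                    popmap.samples_in("B")) == 1

    def test_nearly_fixed_not_counted_at_zero_tolerance(self):
        # A at frequency 0.75, B fixed ref
        matrix, popmap = two_pop_matrix([[2], [2], [1], [1]], [[0], [0]])
        assert dm.fixed_differences(matrix, popmap.samples_in("A"),
                                    popmap.samples_in("B")) == 0

    def test_constructed_loci_found_by_scan(self):
        rng = np.random.default_rng(11)
        dos = rng.binomial(2, 0.4, size=(20, 100))
        dos[:10, [5, 40, 77]] = 0
        dos[10:, [5, 40, 77]] = 2
        # remove accidental extra fixations
        matrix, popmap = two_pop_matrix(dos[:10], dos[10:])
        A, B = popmap.samples_in("A"), popmap.samples_in("B")
        count = dm.fixed_differences(matrix, A, B)
        brute = sum(
            1 for j in range(100)
            if len({*dos[:10, j]}) == 1 and len({*dos[10:, j]}) == 1
            and abs(dos[0, j] - dos[10, j]) == 2
        )
        assert count == brute >= 3

    def test_self_comparison_zero(self):
        matrix, popmap = two_pop_matrix([[0, 1], [2, 1]], [[1, 1]])
        A = popmap.samples_in("A")
        assert dm.fixed_differences(matrix, A, A) == 0


class TestPrivateAlleles:
    def test_alt_private_to_one_population(self):
        matrix, popmap = two_pop_matrix([[1], [0]], [[0], [0]])
        counts = dm.private_alleles(matrix, popmap)
        assert counts["A"] == 1 and counts["B"] == 0

    def test_shared_alt_counted_for_neither(self):
        matrix, popmap = two_pop_matrix([[1]], [[1]])
        counts = dm.private_alleles(matrix, popmap)
        assert counts["A"] == 0 and counts["B"] == 0

    def test_multi_population_brute_force(self):
        rng = np.random.default_rng(23)
        pops = {f"P{k}": rng.binomial(2, rng.uniform(0, 0.4, 60), size=(5, 60))
                for k in range(6)}
        ids, rows, assign = [], [], {}
        for pop, dos in pops.items():
            for i in range(dos.shape[0]):
                ids.append(f"{pop}_{i}")
                assign[f"{pop}_{i}"] = pop
                rows.append(dos[i])
        matrix = make_matrix(np.array(rows), sample_ids=ids)
        popmap = PopulationMap(assign)
        counts = dm.private_alleles(matrix, popmap)

        brute = {p: 0 for p in pops}
        for j in range(60):
            for allele in ("ref", "alt"):
                present = [p for p, dos in pops.items()
                           if (allele == "ref" and (dos[:, j] <= 1).any())
                           or (allele == "alt" and (dos[:, j] >= 1).any())]
                if len(present) == 1:
                    brute[present[0]] += 1
        assert dict(counts) == brute


class TestJostD:
    def test_matches_independent_oracle(self):
        dosA = [[2, 1, 0], [1, 0, 1], [2, 1, 0], [1, 2, 0]]
        dosB = [[0, 0, 1], [0, 1, 2], [1, 0, 2]]
        matrix, popmap = two_pop_matrix(dosA, dosB)
        loci = []
        for j in range(3):
            nA, pA, _ = pop_stats([r[j] for r in dosA])
            nB, pB, _ = pop_stats([r[j] for r in dosB])
            loci.append(((nA, pA), (nB, pB)))
        expected = nei_chesser_jost_d(loci)
        got = dm.jost_d(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(29)
        dos = rng.binomial(2, rng.uniform(0.2, 0.5, 500), size=(60, 500))
        matrix, popmap = two_pop_matrix(dos[:30], dos[30:])
        d = dm.jost_d(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        assert abs(d) < 0.02

    def test_opposite_fixation_is_one(self):
        matrix, popmap = two_pop_matrix([[0, 0]] * 5, [[2, 2]] * 5)
        d = dm.jost_d(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_pair_zero(self):
        matrix, popmap = two_pop_matrix([[0, 0]] * 3, [[0, 0]] * 3)
        assert dm.jost_d(matrix, popmap.samples_in("A"),
                         popmap.samples_in("B")) == 0.0


class TestQ0Beta:
    def test_identical_allele_sets_one(self):
        matrix, popmap = two_pop_matrix([[1], [1]], [[1], [1]])
        assert dm.q0_beta(matrix, popmap.samples_in("A"),
                          popmap.samples_in("B")) == 1.0

    def test_opposite_fixation_two(self):
        matrix, popmap = two_pop_matrix([[0]] * 3, [[2]] * 3)
        assert dm.q0_beta(matrix, popmap.samples_in("A"),
                          popmap.samples_in("B")) == 2.0

    def test_mixed_toy_matches_hand_value(self):
        # 2 loci fixed same allele (beta 1), 2 loci oppositely fixed (beta 2)
        dosA = [[0, 0, 0, 0]] * 3
        dosB = [[0, 0, 2, 2]] * 3
        matrix, popmap = two_pop_matrix(dosA, dosB)
        got = dm.q0_beta(matrix, popmap.samples_in("A"), popmap.samples_in("B"))
        expected = q0_beta_by_hand([({"ref"}, {"ref"}), ({"ref"}, {"ref"}),
                                    ({"ref"}, {"alt"}), ({"ref"}, {"alt"})])
        assert got == expected == 1.5

    def test_polymorphic_oracle_agreement(self):
        dosA = [[1, 0, 2], [0, 0, 2], [1, 0, 2]]
        dosB = [[0, 1, 0], [0, 2, 0], [0, 1, 0]]
        matrix, popmap = two_pop_matrix(dosA, dosB)
        sets = []
        for j in range(3):
            sA = {a for d in [r[j] for r in dosA] for a in
                  (("ref",) if d == 0 else ("alt",) if d == 2 else ("ref", "alt"))}
            sB = {a for d in [r[j] for r in dosB] for a in
                  (("ref",) if d == 0 else ("alt",) if d == 2 else ("ref", "alt"))}
            sets.append((sA, sB))
        assert dm.q0_beta(matrix, popmap.samples_in("A"), popmap.samples_in("B")) \
            == pytest.approx(q0_beta_by_hand(sets), abs=1e-12)


class TestSymmetryAndMonotonicity:
    def test_all_pairwise_metrics_symmetric(self):
        rng = np.random.default_rng(31)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 80), size=(20, 80))
        matrix, popmap = two_pop_matrix(dos[:12], dos[12:])
        A, B = popmap.samples_in("A"), popmap.samples_in("B")
        for fn in (dm.wc_fst, dm.jost_d, dm.q0_beta):
            assert fn(matrix, A, B) == fn(matrix, B, A)
        assert dm.fixed_differences(matrix, A, B) == dm.fixed_differences(matrix, B, A)

    def test_adding_opposite_fixed_locus_raises_metrics(self):
        rng = np.random.default_rng(37)
        base = rng.binomial(2, rng.uniform(0.2, 0.5, 50), size=(12, 50))
        extra = np.concatenate([np.zeros((6, 1)), np.full((6, 1), 2)]).astype(int)
        grown = np.hstack([base, extra])
        m1, pm = two_pop_matrix(base[:6], base[6:])
        m2, _ = two_pop_matrix(grown[:6], grown[6:])
        A, B = pm.samples_in("A"), pm.samples_in("B")
        assert dm.fixed_differences(m2, A, B) > dm.fixed_differences(m1, A, B)
        assert dm.jost_d(m2, A, B) > dm.jost_d(m1, A, B)
        assert dm.q0_beta(m2, A, B) > dm.q0_beta(m1, A, B)


class TestMetricsTable:
    def test_table_has_all_donors_and_columns(self):
        cfg = SynthConfig(n_loci=300,
                          populations=[("R", 8, 0.05), ("X", 6, 0.2), ("Y", 5, 0.3)],
                          seed=41)
        m, pm = generate_structured_populations(cfg)
        table = dm.metrics_table(m, pm, "R")
        assert set(table.index) == {"R", "X", "Y"}
        for col in ("fst", "fixed_diffs", "jost_d", "q0_beta",
                    "donor_variant_het", "private_alleles"):
            assert col in table.columns
        assert np.isnan(table.loc["R", "fst"])
        assert table.loc["Y", "fst"] > 0
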