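"""Tests of progeny disentanglement: distances, PCO, clustering,
parentage checks and the selfing test."""

import numpy as np
import pandas as pd
import pytest

from tetramap.disentangle import (
    genetic_distance,
    heterozygosity,
    pco,
    reconstruct_parent,
    reject_parent,
    select_monomorphic_markers,
    selfing_test,
    split_population,
    DistanceMatrix,
)
from tetramap.dosageio import DosageMatrix
from tetramap.pipeline import naive_merge
from tetramap.simcross import (
    SELF,
    CrossDesign,
    MeiosisConfig,
    ObservationConfig,
    observe_dosages,
    simulate_marker_panel,
    simulate_population,
)


def _dm(values, markers=None, samples=None):
    arr = np.asarray(values, dtype=float)
    markers = markers or [f"m{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{i}" for i in range(arr.shape[1])]
    return DosageMatrix(pd.DataFrame(arr, index=markers, columns=samples))


class TestMonomorphicSelection:
    def test_monomorphic_are_nulliplex_or_quadruplex(self):
        dm = _dm(np.zeros((5, 3)))
        parent = pd.Series([0, 1, 2, 3, 4], index=dm.marker_ids)
        assert select_monomorphic_markers(dm, parent) == ["m0", "m4"]

    def test_all_heterozygous_parent_warns_and_returns_empty(self):
        dm = _dm(np.zeros((3, 3)))
        parent = pd.Series([1, 2, 3], index=dm.marker_ids)
        with pytest.warns(UserWarning):
            assert select_monomorphic_markers(dm, parent) == []


class TestGeneticDistance:
    def test_identical_individuals_have_zero_distance(self):
        dm = _dm([[1, 1], [3, 3], [0, 0]])
        d = genetic_distance(dm)
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_are_maximally_distant(self):
        dm = _dm([[0, 4], [4, 0]])
        assert genetic_distance(dm).values[0, 1] == 1.0

    def test_missing_calls_use_shared_markers_only(self):
        dm = _dm([[1, 1], [2, 0], [np.nan, 3]])
        d = genetic_distance(dm)
        # shared markers: |1-1|/4 and |2-0|/4 → mean 0.25
        assert d.values[0, 1] == pytest.approx(0.25)
        assert d.n_markers_used[0, 1] == 2

    def test_triangle_inequality_on_complete_data(self, rng):
        dm = _dm(rng.integers(0, 5, size=(30, 8)))
        d = genetic_distance(dm).values
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPco:
    def test_three_equidistant_points_share_variance_across_two_axes(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pco(DistanceMatrix(["a", "b", "c"], d, np.full((3, 3), 1)), 2)
        assert np.allclose(res.explained_fraction, [0.5, 0.5])

    def test_duplicated_individual_gets_identical_coordinates(self):
        dm = _dm([[0, 0, 4], [1, 1, 0], [4, 4, 2]])
        res = pco(genetic_distance(dm), 2)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_euclidean_distances_are_reproduced_by_coordinates(self, rng):
        x = rng.normal(size=(10, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        res = pco(
            DistanceMatrix([str(i) for i in range(10)], d, np.full((10, 10), 1)),
            10,
        )
        rec = np.sqrt(
            ((res.coordinates[:, None, :] - res.coordinates[None, :, :]) ** 2).sum(-1)
        )
        assert np.allclose(rec, d, atol=1e-8)

    def test_matches_scikit_bio_reference(self, rng):
        skbio = pytest.importorskip("skbio")
        dm = _dm(rng.integers(0, 5, size=(40, 12)))
        dist = genetic_distance(dm)
        mine = pco(dist, 3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.values, ids=dist.ids)
        )
        assert np.allclose(
            mine.explained_fraction,
            ref.proportion_explained.to_numpy()[:3],
            atol=1e-8,
        )
        for k in range(2):
            a = mine.coordinates[:, k]
            b = ref.samples.to_numpy()[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_all_zero_distances_report_zero_explained(self):
        d = np.zeros((4, 4))
        res = pco(DistanceMatrix(list("abcd"), d, np.full((4, 4), 1)), 2)
        assert np.allclose(res.explained_fraction, 0.0)
        assert np.allclose(res.coordinates, 0.0)


class TestSplit:
    def test_two_point_masses_split_exactly(self):
        coords = np.vstack([np.tile([0.0, 0.0], (10, 1)),
                            np.tile([5.0, 0.0], (8, 1))])
        from tetramap.disentangle import PcoResult

        res = PcoResult([f"S{i}" for i in range(18)], coords,
                        np.array([0.9, 0.1]))
        split = split_population(res, seed=0)
        assert split.k == 2
        assert split.silhouette > 0.99
        assert split.assignment.nunique() == 2
        assert split.assignment.iloc[:10].nunique() == 1
        assert split.assignment.iloc[10:].nunique() == 1

    def test_single_cloud_is_not_split(self, rng):
        from tetramap.disentangle import PcoResult

        coords = rng.normal(size=(60, 2))
        res = PcoResult([f"S{i}" for i in range(60)], coords,
                        np.array([0.5, 0.5]))
        split = split_population(res, seed=0)
        assert split.k == 1
        assert split.assignment.nunique() == 1


@pytest.fixture(scope="module")
def outcross_experiment():
    """Admixture-free outcross with mild observation noise, QC-free."""
    mother, father, table = simulate_marker_panel(n_chromosomes=2, seed=5)
    pop = simulate_population(
        CrossDesign(mother, [(father, 100)]), MeiosisConfig(),
        rng=np.random.default_rng(6), markers=table,
    )
    probes = observe_dosages(
        pop.true_dosages(), ObservationConfig(0.0, 0.005, 0.0),
        rng=np.random.default_rng(7),
    )
    merged = naive_merge(probes)
    segregating = table[
        table.apply(
            lambda r: (r.mother_dosage, r.father_dosage)
            in {(1, 0), (0, 1), (1, 1), (2, 0), (0, 2)},
            axis=1,
        )
    ]["marker"].tolist()
    return merged.subset_markers(segregating), mother, father, table


class TestRejectParent:
    def test_true_father_is_not_rejected(self, outcross_experiment):
        dm, mother, father, _ = outcross_experiment
        rejected, fraction, _ = reject_parent(
            dm, mother.dosage_vector(), father.dosage_vector()
        )
        assert not rejected
        assert fraction < 0.01

    def test_unrelated_candidate_is_rejected(self, outcross_experiment):
        dm, mother, father, _ = outcross_experiment
        rng = np.random.default_rng(8)
        fd = father.dosage_vector()
        wrong = pd.Series(rng.permutation(fd.to_numpy()), index=fd.index)
        rejected, fraction, _ = reject_parent(dm, mother.dosage_vector(), wrong)
        assert rejected and fraction > 0.05

    def test_mother_explains_her_own_selfed_progeny(self):
        mother, _, table = simulate_marker_panel(n_chromosomes=1, seed=9)
        pop = simulate_population(
            CrossDesign(mother, [(SELF, 100)]), MeiosisConfig(),
            rng=np.random.default_rng(10), markers=table,
        )
        dm = DosageMatrix(pop.true_dosages())
        md = mother.dosage_vector()
        rejected, fraction, _ = reject_parent(dm, md, md)
        assert not rejected


class TestReconstructParent:
    def test_one_to_one_counts_give_nulliplex_father(self):
        dm = _dm([[0] * 50 + [1] * 50])
        md = pd.Series([1], index=dm.marker_ids)
        rec = reconstruct_parent(dm, md)
        assert rec.loc["m0", "father_dosage"] == 0

    def test_one_four_one_counts_give_duplex_father(self):
        dm = _dm([[0] * 17 + [1] * 66 + [2] * 17])
        md = pd.Series([0], index=dm.marker_ids)
        rec = reconstruct_parent(dm, md)
        assert rec.loc["m0", "father_dosage"] == 2

    def test_matches_brute_force_likelihood_table(self, rng):
        """For a tetraplex mother every father is class-compatible; the ML
        answer must match an exhaustive log-likelihood table."""
        from tetramap.segqc import expected_offspring_distribution

        counts = np.zeros(5)
        counts[2:] = rng.integers(5, 40, size=3)
        calls = np.repeat(np.arange(5), counts.astype(int)).astype(float)
        dm = _dm([calls])
        md = pd.Series([4], index=dm.marker_ids)
        rec = reconstruct_parent(dm, md)
        ll = []
        for df_ in range(5):
            p = expected_offspring_distribution(4, df_)
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(counts > 0, counts * np.log(p), 0.0).sum()
            ll.append(v)
        assert rec.loc["m0", "father_dosage"] == int(np.argmax(ll))

    def test_all_missing_marker_is_undetermined(self):
        dm = _dm([[np.nan, np.nan, np.nan]])
        md = pd.Series([1], index=dm.marker_ids)
        rec = reconstruct_parent(dm, md)
        assert rec.loc["m0", "status"] == "undetermined"

    def test_recovers_simulated_father_dosages(self, outcross_experiment):
        dm, mother, father, table = outcross_experiment
        rec = reconstruct_parent(dm, mother.dosage_vector())
        truth = father.dosage_vector().loc[rec.index]
        ok = (rec["father_dosage"] == truth).mean()
        assert ok > 0.9


class TestSelfing:
    def test_selfed_population_is_detected(self):
        mother, father, table = simulate_marker_panel(n_chromosomes=2, seed=12)
        pop = simulate_population(
            CrossDesign(mother, [(SELF, 120)]), MeiosisConfig(),
            rng=np.random.default_rng(13), markers=table,
        )
        dm = DosageMatrix(pop.true_dosages())
        # reference list: the markers that are S×N (mother side) in an
        # outcross — here directly the (1, 0) truth classes
        ref = table[(table.mother_dosage == 1) & (table.father_dosage == 0)][
            "marker"
        ].tolist()
        ev = selfing_test(dm, mother.dosage_vector(), ref, seed=1)
        assert ev.sxn_to_sxs_consistency > 0.95
        assert ev.verdict == "selfing-consistent"
        assert ev.offspring_mean_heterozygosity < ev.parent_heterozygosity

    def test_outcross_population_is_not_selfing(self, outcross_experiment):
        dm, mother, father, table = outcross_experiment
        ref = table[(table.mother_dosage == 1) & (table.father_dosage == 0)][
            "marker"
        ].tolist()
        ev = selfing_test(dm, mother.dosage_vector(), ref, seed=2)
        assert ev.sxn_to_sxs_consistency < 0.95
        assert ev.verdict == "not-selfing"

    def test_simplex_everywhere_parent_gives_three_quarter_heterozygosity(self):
        """Selfing a fully simplex parent: offspring heterozygosity tends
        to 3/4 while the parent's is 1."""
        from tetramap.simcross import Chromosome, ParentalHaplotypes

        alleles = np.zeros((4, 40), dtype=np.int8)
        alleles[0, :] = 1
        names = [f"K{i:03d}_1" for i in range(40)]
        mother = ParentalHaplotypes(
            "M", [Chromosome("c1", np.linspace(0, 100, 40), alleles, names)]
        )
        pop = simulate_population(
            CrossDesign(mother, [(SELF, 400)]), MeiosisConfig(),
            rng=np.random.default_rng(14),
        )
        dm = DosageMatrix(pop.true_dosages())
        md = mother.dosage_vector()
        ev = selfing_test(dm, md, None, seed=3)
        assert ev.parent_heterozygosity == 1.0
        assert abs(ev.offspring_mean_heterozygosity - 0.75) < 0.02

    def test_heterozygosity_helper(self):
        assert heterozygosity([0, 4, np.nan]) == 0.0
        assert heterozygosity([1, 2, 3, 0]) == 0.75
        assert np.isnan(heterozygosity([np.nan]))
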