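"""Tests of the Kosambi function, linkage grouping, homolog separation,
ordering/WLS fitting and map summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetramap.mapbuild import (
    GeneticMap,
    connect_homologs,
    contig_id,
    group_markers,
    inverse_kosambi,
    kosambi,
    order_and_fit,
    phase_components,
    split_homologs,
    summarize_maps,
    write_map_tsv,
    write_mapchart,
)


class TestKosambi:
    def test_reference_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(1 / 3) == pytest.approx(40.236, abs=0.001)
        assert kosambi(0.25) == pytest.approx(25 * np.log(3), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)
        with pytest.raises(ValueError):
            inverse_kosambi(-1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.499, allow_nan=False))
    def test_roundtrip_and_monotonicity(self, r):
        d = kosambi(r)
        assert abs(inverse_kosambi(d) - r) < 1e-10
        if r < 0.49:
            assert kosambi(r + 0.009) > d


def _pairs(rows):
    return pd.DataFrame(
        rows, columns=["marker1", "marker2", "r_hat", "lod", "mirrored"]
    )


class TestGrouping:
    def test_threshold_above_max_lod_gives_singletons(self):
        pairs = _pairs([("a", "b", 0.1, 3.0, False)])
        groups, singles = group_markers(pairs, lod_threshold=4.0)
        assert not groups and set(singles) == {"a", "b"}

    def test_components_partition_markers_independent_of_order(self):
        rows = [
            ("a", "b", 0.1, 10.0, False),
            ("b", "c", 0.1, 8.0, False),
            ("x", "y", 0.1, 9.0, False),
        ]
        g1, s1 = group_markers(_pairs(rows))
        g2, s2 = group_markers(_pairs(rows[::-1]))
        assert [g.markers for g in g1] == [g.markers for g in g2]
        all_markers = {m for g in g1 for m in g.markers} | set(s1)
        assert all_markers == {"a", "b", "c", "x", "y"}
        assert sum(len(g.markers) for g in g1) + len(s1) == 5

    def test_spurious_single_edge_merges_components(self):
        """One chance LOD-4.1 edge joins two coupling clusters into a
        single component — documented; downstream separation rescues it."""
        rows = [
            ("a1", "a2", 0.05, 20.0, False), ("a2", "a3", 0.05, 20.0, False),
            ("b1", "b2", 0.05, 20.0, False), ("b2", "b3", 0.05, 20.0, False),
            ("a3", "b1", 0.45, 4.1, False),
        ]
        groups, _ = group_markers(_pairs(rows))
        assert len(groups) == 1 and len(groups[0].markers) == 6

    def test_phase_components_split_on_mirrored_edges(self):
        """Repulsion (mirrored-orientation) linkage does not join homologs."""
        rows = [
            ("a1", "a2", 0.05, 20.0, False), ("a2", "a3", 0.05, 20.0, False),
            ("b1", "b2", 0.05, 20.0, False), ("b2", "b3", 0.05, 20.0, False),
            ("a1", "b1", 0.02, 12.0, True), ("a3", "b3", 0.02, 11.0, True),
        ]
        comps = phase_components(
            ["a1", "a2", "a3", "b1", "b2", "b3"], _pairs(rows)
        )
        assert sorted(map(tuple, comps)) == [
            ("a1", "a2", "a3"), ("b1", "b2", "b3")
        ]

    def test_phase_components_prune_spurious_bridges(self):
        """A lone coupling edge between two well-populated sides is
        treated as spurious linkage and removed."""
        rows = (
            [(f"a{i}", f"a{j}", 0.05, 20.0, False)
             for i in range(4) for j in range(i + 1, 4)]
            + [(f"b{i}", f"b{j}", 0.05, 20.0, False)
               for i in range(4) for j in range(i + 1, 4)]
            + [("a3", "b0", 0.3, 5.0, False)]
        )
        markers = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        comps = phase_components(markers, _pairs(rows))
        assert len(comps) == 2


class TestHomologSeparation:
    def test_split_at_large_gaps(self):
        gmap = GeneticMap(
            "g", list("abcde"), np.array([0.0, 2.0, 5.0, 46.0, 48.0])
        )
        frags = split_homologs(gmap, gap_threshold_cm=35.0)
        assert frags == [["a", "b", "c"], ["d", "e"]]

    def test_no_gap_single_fragment(self):
        gmap = GeneticMap("g", list("abc"), np.array([0.0, 10.0, 20.0]))
        assert split_homologs(gmap) == [["a", "b", "c"]]

    def test_contig_rule_connects_homolog_groups(self):
        groups = [["K001_123", "K002_1"], ["K001_857", "K003_1"], ["K009_1"]]
        clusters, flags = connect_homologs(groups, None, use_contigs=True)
        assert [0, 1] in clusters and [2] in clusters
        assert not any(flags)
        assert contig_id("K001_123") == "K001"

    def test_bridge_marker_connects_groups(self):
        groups = [["a1", "a2"], ["b1", "b2"]]
        bridges = pd.DataFrame(
            {
                "marker1": ["bridge", "bridge"],
                "marker2": ["a1", "b1"],
                "r_hat": [0.05, 0.08],
                "lod": [9.0, 7.0],
                "mother_overlap": [1, 1],
                "mirrored": [False, False],
            }
        )
        clusters, flags = connect_homologs(groups, bridges, use_contigs=False)
        assert clusters == [[0, 1]]

    def test_no_bridges_leaves_groups_unchanged(self):
        groups = [["a1", "a2"], ["b1", "b2"]]
        clusters, _ = connect_homologs(groups, None, use_contigs=False)
        assert sorted(clusters) == [[0], [1]]

    def test_more_than_four_homologs_is_flagged(self):
        groups = [[f"K001_{i}"] for i in range(5)]
        clusters, flags = connect_homologs(groups, None, use_contigs=True)
        assert clusters == [[0, 1, 2, 3, 4]] and flags == [True]


def _equal_lod_pairs(rows):
    return pd.DataFrame(
        rows, columns=["marker1", "marker2", "r_hat", "lod", "mirrored"]
    )


class TestOrderAndFit:
    def test_three_marker_wls_matches_closed_form(self):
        """WLS over all three pairs with equal weights; the oracle solves
        the 2×2 normal equations for the adjacent increments."""
        d12 = kosambi(0.10)
        d23 = kosambi(0.10)
        d13 = kosambi(0.18)
        # oracle: minimise (a-d12)² + (b-d23)² + (a+b-d13)²
        A = np.array([[2.0, 1.0], [1.0, 2.0]])
        b = np.array([d12 + d13, d23 + d13])
        a_inc, b_inc = np.linalg.solve(A, b)
        pairs = _equal_lod_pairs(
            [("m1", "m2", 0.10, 10.0, False), ("m2", "m3", 0.10, 10.0, False),
             ("m1", "m3", 0.18, 10.0, False)]
        )
        gmap = order_and_fit(["m1", "m2", "m3"], pairs)
        assert gmap.markers == ["m1", "m2", "m3"] or gmap.markers == ["m3", "m2", "m1"]
        assert gmap.positions[1] == pytest.approx(a_inc, abs=1e-6)
        assert gmap.positions[2] == pytest.approx(a_inc + b_inc, abs=1e-6)

    def test_two_marker_map_length_is_kosambi_distance(self):
        pairs = _equal_lod_pairs([("m1", "m2", 0.2, 10.0, False)])
        gmap = order_and_fit(["m1", "m2"], pairs)
        assert gmap.length_cm == pytest.approx(kosambi(0.2), abs=1e-6)

    def test_disconnected_group_raises_naming_components(self):
        pairs = _equal_lod_pairs(
            [("m1", "m2", 0.1, 10.0, False), ("m3", "m4", 0.1, 10.0, False)]
        )
        with pytest.raises(ValueError, match="disconnected"):
            order_and_fit(["m1", "m2", "m3", "m4"], pairs)

    def test_order_recovery_is_reversal_invariant(self):
        """Simulated chain of 12 markers: fitted order matches the truth up
        to reversal, independently of marker input order."""
        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 80, 12))
        rows = []
        names = [f"m{i:02d}" for i in range(12)]
        for i in range(12):
            for j in range(i + 1, 12):
                r = inverse_kosambi(abs(pos[j] - pos[i]))
                r_obs = float(np.clip(r + rng.normal(0, 0.01), 0, 0.49))
                rows.append((names[i], names[j], r_obs, 10.0, False))
        pairs = _equal_lod_pairs(rows)
        g1 = order_and_fit(list(names), pairs)
        g2 = order_and_fit(list(reversed(names)), pairs)
        from scipy.stats import spearmanr

        rho1 = abs(spearmanr(
            [names.index(m) for m in g1.markers], range(12)
        ).statistic)
        rho2 = abs(spearmanr(
            [names.index(m) for m in g2.markers], range(12)
        ).statistic)
        assert rho1 > 0.99 and rho2 > 0.99


class TestSummary:
    def test_single_map_statistics(self):
        g = GeneticMap("g1", list("abc"), np.array([0.0, 1.0, 3.0]))
        s = summarize_maps([g])
        assert s.total_length_cm == 3.0
        assert s.mean_interval_cm == pytest.approx(1.5)
        assert s.max_interval_cm == 2.0

    def test_totals_sum_over_groups(self):
        g1 = GeneticMap("g1", list("ab"), np.array([0.0, 10.0]))
        g2 = GeneticMap("g2", list("cd"), np.array([0.0, 20.0]))
        s = summarize_maps([g1, g2])
        assert s.total_length_cm == 30.0
        assert s.total_markers == 4
        assert s.max_interval_cm >= s.mean_interval_cm

    def test_writers_roundtrip_format(self, tmp_path):
        g = GeneticMap("g1", ["K001_1", "K001_2"], np.array([0.0, 5.0]))
        write_map_tsv([g], tmp_path / "map.tsv")
        df = pd.read_csv(tmp_path / "map.tsv", sep="\t")
        assert list(df["marker"]) == ["K001_1", "K001_2"]
        write_mapchart([g], tmp_path / "chart.txt")
        text = (tmp_path / "chart.txt").read_text()
        assert text.startswith("group g1\n")
        assert "K001_2 5.000" in text


@pytest.fixture(scope="module")
def recovered():
    from tetramap.pipeline import PipelineConfig, build_parent_maps
    from tetramap.segqc import QcThresholds, filter_markers
    from tetramap.simcross import (
        CrossDesign,
        MeiosisConfig,
        ObservationConfig,
        observe_dosages,
        simulate_marker_panel,
        simulate_population,
    )

    mother, father, table = simulate_marker_panel(
        n_chromosomes=7,
        class_counts={(1, 0): 100},  # 25 per homolog on average
        seed=17,
    )
    pop = simulate_population(
        CrossDesign(mother, [(father, 200)]), MeiosisConfig(),
        rng=np.random.default_rng(18), markers=table,
    )
    probes = observe_dosages(
        pop.true_dosages(), ObservationConfig(0, 0, 0),
        rng=np.random.default_rng(19),
    )
    retained, report = filter_markers(
        probes, mother.dosage_vector(), father.dosage_vector(),
        QcThresholds(),
    )
    cfg = PipelineConfig()
    res = build_parent_maps(retained, report, "mother", cfg, "clean")
    return res, table


class TestCleanDataRecovery:
    """Map recovery on clean simulated data: 7 chromosomes, 25 S×N markers
    per homolog, n = 200 offspring, LOD > 4."""

    def test_homolog_membership_at_least_95_percent(self, recovered):
        res, table = recovered
        truth = table.set_index("marker")
        n_ok = n_tot = 0
        for g in res["maps"]:
            sub = truth.loc[g.markers]
            lab = sub["chrom"] + ":" + sub["mother_homologs"]
            maj = lab.mode().iloc[0]
            n_ok += int((lab == maj).sum())
            n_tot += len(sub)
        assert n_tot > 500
        assert n_ok / n_tot >= 0.95

    def test_per_homolog_order_correlation_at_least_095(self, recovered):
        from scipy.stats import spearmanr

        res, table = recovered
        truth = table.set_index("marker")
        for g in res["maps"]:
            if g.n_markers < 6:
                continue
            sub = truth.loc[g.markers]
            rho = abs(spearmanr(g.positions, sub["pos_cM"]).statistic)
            assert rho >= 0.95, f"{g.name}: rho={rho:.3f}"

    def test_total_length_within_20_percent_of_truth(self, recovered):
        res, table = recovered
        truth = table.set_index("marker")
        tot_fit = tot_true = 0.0
        for g in res["maps"]:
            sub = truth.loc[g.markers]
            tot_fit += g.length_cm
            tot_true += float(sub["pos_cM"].max() - sub["pos_cM"].min())
        assert abs(tot_fit / tot_true - 1.0) <= 0.20
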