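import itertools
import math

import networkx as nx
import numpy as np
import pytest

from allopath.allostery import (
    MIMatrix,
    Pathway,
    TorsionSeries,
    allosteric_paths,
    build_graph,
    cluster_pipelines,
    extract_torsions,
    hub_scores,
    mi_bias_bound,
    residue_mi_matrix,
    torsion_mi,
)
from allopath.errors import InputError, SelectionError
from allopath.structure_io import Trajectory
from allopath.synthetic import (
    TorsionSystemSpec,
    ca_chain_structure,
    generate_torsion_system,
)

from conftest import build_backbone, make_model, place_atom, static_trajectory


# -- torsion extraction ------------------------------------------------------


class TestExtractTorsions:
    def test_ideal_helix_phi_psi(self):
        n = 8
        model = build_backbone([None] + [-57.0] * (n - 1), [-47.0] * n)
        traj = static_trajectory(model, 3)
        series, skipped = extract_torsions(traj)
        by = {(t.residue, t.name): t for t in series}
        for i in range(2, n):  # interior residues
            np.testing.assert_allclose(by[(("A", i, ""), "phi")].values, -57.0, atol=1e-6)
        for i in range(1, n):
            np.testing.assert_allclose(by[(("A", i, ""), "psi")].values, -47.0, atol=1e-6)

    def test_glycine_emits_no_chi(self):
        model = build_backbone([None, -60.0, -60.0], [-45.0] * 3, resname="GLY")
        series, _ = extract_torsions(static_trajectory(model, 2))
        assert not any(t.name.startswith("chi") for t in series)

    def test_planted_chi1_schedule_recovered(self):
        # ASP side chain: chi1 = N-CA-CB-CG, placed frame by frame via NeRF
        schedule = np.array([-60.0, 180.0, 60.0, -175.0, -60.0])
        base = [
            ("N", "N", "A", 1, "ASP", "", (0.0, 0.0, 0.0)),
            ("CA", "C", "A", 1, "ASP", "", (1.458, 0.0, 0.0)),
            ("C", "C", "A", 1, "ASP", "", (2.0, 1.4, 0.0)),
            ("CB", "C", "A", 1, "ASP", "", tuple(place_atom((2.0, 1.4, 0.0), (0, 0, 0), (1.458, 0, 0), 1.53, 110.5, -120.0))),
        ]
        model = make_model(base + [("CG", "C", "A", 1, "ASP", "", (0, 0, 0))])
        coords = np.repeat(model.coords[None], len(schedule), axis=0)
        n_pos, ca_pos, cb_pos = model.coords[0], model.coords[1], model.coords[3]
        for f, chi in enumerate(schedule):
            coords[f, 4] = place_atom(n_pos, ca_pos, cb_pos, 1.52, 113.0, chi)
        traj = Trajectory(model=model, coords=coords)
        series, skipped = extract_torsions(traj)
        chi1 = [t for t in series if t.name == "chi1"]
        assert len(chi1) == 1
        from allopath.geometry import wrap_angle

        np.testing.assert_allclose(chi1[0].values, wrap_angle(schedule), atol=1e-6)
        # chi2 skipped (no OD1 present), logged not raised
        assert any("chi2" in s for s in skipped)

    def test_missing_backbone_atom_skips_torsion(self, two_residue_model):
        # the GLY/ALA two-residue model lacks residue 0's preceding C, so
        # residue 1 has no phi; psi of residue 1 exists
        series, _ = extract_torsions(static_trajectory(two_residue_model, 2))
        names = {(t.residue[1], t.name) for t in series}
        assert (1, "phi") not in names
        assert (1, "psi") in names


# -- mutual information ------------------------------------------------------


def mi_oracle_from_counts(counts: np.ndarray) -> float:
    """Independent plug-in evaluation from a joint count table."""
    n = counts.sum()
    mi = 0.0
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c > 0:
                mi += (c / n) * math.log((c * n) / (rows[i] * cols[j]))
    return mi


def _series_from_counts(counts, centers_x, centers_y):
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [centers_x[i]] * int(counts[i, j])
            ys += [centers_y[j]] * int(counts[i, j])
    return np.asarray(xs, float), np.asarray(ys, float)


class TestTorsionMI:
    def test_hand_evaluated_two_by_two_table(self):
        counts = np.array([[40, 10], [10, 40]])
        x, y = _series_from_counts(counts, [-60.0, 180.0 - 1e-9], [-60.0, 180.0 - 1e-9])
        got = torsion_mi(x, y, bins=24)
        # direct hand evaluation: 0.8 ln 1.6 + 0.2 ln 0.4 = 0.192745...
        hand = 0.8 * math.log(1.6) + 0.2 * math.log(0.4)
        assert got == pytest.approx(hand, abs=1e-12)
        assert got == pytest.approx(0.1927448, abs=1e-6)

    def test_matches_oracle_on_random_tables(self, rng):
        edges = np.linspace(-180, 180, 25)
        centers = (edges[:-1] + edges[1:]) / 2
        for _ in range(100):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 30, size=(k, k))
            counts[0, 0] += 1  # nonempty
            bx = rng.choice(24, size=k, replace=False)
            by = rng.choice(24, size=k, replace=False)
            x, y = _series_from_counts(counts, centers[bx], centers[by])
            assert torsion_mi(x, y, bins=24) == pytest.approx(
                mi_oracle_from_counts(counts), abs=1e-12
            )

    def test_perfect_coswitching_is_ln2(self, rng):
        n = 10_000
        state = rng.integers(2, size=n)
        x = np.where(state == 0, -60.0, 160.0) + rng.normal(scale=2.0, size=n)
        y = np.where(state == 0, 55.0, -170.0) + rng.normal(scale=2.0, size=n)
        from allopath.geometry import wrap_angle

        mi = torsion_mi(wrap_angle(x), wrap_angle(y), bins=24)
        assert mi == pytest.approx(math.log(2), abs=2e-3)

    def test_independent_below_bias_bound(self, rng):
        n = 10_000
        bound = mi_bias_bound(24, n)
        below = 0
        trials = 50
        for _ in range(trials):
            x = np.degrees(rng.vonmises(np.radians(-60.0), 50.0, size=n))
            y = np.degrees(rng.vonmises(np.radians(180.0), 50.0, size=n)) % 360 - 180
            if torsion_mi(np.clip(x, -180, 179.9), np.clip(y, -180, 179.9), bins=24) < bound:
                below += 1
        assert below >= int(0.95 * trials)

    def test_symmetry(self, rng):
        x = np.degrees(rng.vonmises(0.0, 5.0, size=500))
        y = np.degrees(rng.vonmises(1.0, 5.0, size=500))
        from allopath.geometry import wrap_angle

        x, y = wrap_angle(x), wrap_angle(y)
        assert torsion_mi(x, y) == pytest.approx(torsion_mi(y, x), abs=1e-12)

    def test_shuffle_destroys_dependence(self, rng):
        spec = TorsionSystemSpec(n_residues=2, n_frames=5000, relay=(0, 1), coupling=1.0, seed=3)
        series, _ = generate_torsion_system(spec)
        x, y = series[0].values, series[1].values
        assert torsion_mi(x, y) > 0.5
        y_shuffled = y.copy()
        rng.shuffle(y_shuffled)
        assert torsion_mi(x, y_shuffled) < mi_bias_bound(24, 5000)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            torsion_mi(np.zeros(100), np.zeros(99))

    def test_too_short(self):
        with pytest.raises(InputError):
            torsion_mi(np.zeros(10), np.zeros(10), bins=24)


class TestResidueMIMatrix:
    def _mk(self, key, name, values):
        return TorsionSeries(residue=key, name=name, values=values)

    def test_max_aggregation_picks_planted_channel(self, rng):
        n = 3000
        state = rng.integers(2, size=n)
        planted_a = np.where(state == 0, -60.0, 160.0) + rng.normal(scale=2, size=n)
        planted_b = np.where(state == 0, 50.0, -170.0) + rng.normal(scale=2, size=n)
        from allopath.geometry import wrap_angle

        torsions = [
            self._mk(("A", 1, ""), "chi1", wrap_angle(planted_a)),
            self._mk(("A", 1, ""), "phi", wrap_angle(rng.uniform(-180, 179, n))),
            self._mk(("A", 10, ""), "chi1", wrap_angle(planted_b)),
            self._mk(("A", 10, ""), "psi", wrap_angle(rng.uniform(-180, 179, n))),
        ]
        mat = residue_mi_matrix(torsions, aggregation="max")
        direct = torsion_mi(wrap_angle(planted_a), wrap_angle(planted_b))
        assert mat.values[0, 1] == pytest.approx(direct, abs=1e-12)
        assert mat.provenance[(0, 1)] == ("chi1", "chi1")

    def test_all_independent_below_bound(self, rng):
        n = 4000
        torsions = [
            self._mk(("A", i * 5 + 1, ""), "chi1",
                     np.degrees(rng.vonmises(0.0, 3.0, size=n)) % 360 - 180)
            for i in range(4)
        ]
        mat = residue_mi_matrix(torsions)
        iu = np.triu_indices(4, 1)
        assert np.all(mat.values[iu] < mi_bias_bound(24, n) * 3)

    def test_matches_bruteforce_double_loop(self, rng):
        from allopath.geometry import wrap_angle

        n = 600
        keys = [("A", i + 1, "") for i in range(5)]
        torsions = []
        for i, k in enumerate(keys):
            for name in ("phi", "chi1")[: 1 + i % 2]:
                torsions.append(
                    self._mk(k, name, wrap_angle(rng.uniform(-180, 180, n)))
                )
        for agg in ("max", "sum"):
            mat = residue_mi_matrix(torsions, aggregation=agg, min_sequence_separation=3)
            by_res = {}
            for t in torsions:
                by_res.setdefault(t.residue, []).append(t)
            for i, j in itertools.combinations(range(5), 2):
                vals = [
                    torsion_mi(a.values, b.values)
                    for a in by_res[keys[i]]
                    for b in by_res[keys[j]]
                ]
                expected = max(vals) if agg == "max" else sum(vals)
                assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_sequence_separation_flags_eligibility(self, rng):
        from allopath.geometry import wrap_angle

        n = 200
        torsions = [
            self._mk(("A", i + 1, ""), "chi1", wrap_angle(rng.uniform(-180, 180, n)))
            for i in range(5)
        ]
        mat = residue_mi_matrix(torsions, min_sequence_separation=3)
        assert not mat.eligible[0, 1]  # adjacent
        assert not mat.eligible[0, 2]
        assert mat.eligible[0, 3]
        assert mat.values[0, 1] >= 0  # still reported

    def test_symmetric_and_diagonal_excluded(self, rng):
        from allopath.geometry import wrap_angle

        torsions = [
            self._mk(("A", i + 1, ""), "chi1", wrap_angle(np.asarray(rng.uniform(-180, 180, 100))))
            for i in range(3)
        ]
        mat = residue_mi_matrix(torsions)
        np.testing.assert_array_equal(mat.values, mat.values.T)
        with pytest.raises(InputError):
            mat.pair(1, 1)


# -- graph construction ------------------------------------------------------


def _matrix_from_values(values, eligible=None):
    r = len(values)
    keys = [("A", i + 1, "") for i in range(r)]
    vals = np.asarray(values, dtype=float)
    elig = np.ones((r, r), dtype=bool) if eligible is None else eligible
    np.fill_diagonal(elig, False)
    return MIMatrix(
        residues=keys, values=vals, eligible=elig, provenance={},
        bins=24, aggregation="max",
    )


class TestBuildGraph:
    def test_decile_of_ten_pairs(self):
        # 5 residues -> 10 pairs with MI 1..10: top 10% keeps only the max
        vals = np.zeros((5, 5))
        mi_iter = iter(range(1, 11))
        for i in range(5):
            for j in range(i + 1, 5):
                vals[i, j] = vals[j, i] = next(mi_iter)
        g = build_graph(_matrix_from_values(vals), top_fraction=0.10)
        assert g.graph.number_of_edges() == 1
        (u, v, data), = g.graph.edges(data=True)
        assert data["mi"] == 10.0
        assert data["weight"] == 0.0

    def test_all_equal_ties_all_retained(self):
        vals = np.full((4, 4), 2.5)
        np.fill_diagonal(vals, 0)
        g = build_graph(_matrix_from_values(vals), top_fraction=0.10)
        assert g.graph.number_of_edges() == 6  # every pair ties at threshold

    def test_sort_and_slice_oracle_with_ties(self, rng):
        r = 21  # 210 pairs
        vals = np.zeros((r, r))
        raw = rng.choice(np.arange(1, 50), size=210).astype(float)  # forces ties
        iu = np.triu_indices(r, 1)
        vals[iu] = raw
        vals = vals + vals.T
        g = build_graph(_matrix_from_values(vals), top_fraction=0.10)
        k = math.ceil(0.10 * 210)
        threshold = np.sort(raw)[::-1][k - 1]
        expected = int(np.sum(raw >= threshold))
        assert g.graph.number_of_edges() == expected
        assert g.threshold == threshold

    def test_weights_nonnegative_and_normalized(self, rng):
        vals = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        vals[iu] = rng.uniform(0.1, 1.0, size=len(iu[0]))
        vals = vals + vals.T
        g = build_graph(_matrix_from_values(vals), top_fraction=0.5)
        for _, _, data in g.graph.edges(data=True):
            assert data["weight"] >= 0
            assert data["weight"] == pytest.approx(-math.log(data["mi"] / g.mi_max))

    def test_all_zero_rejected(self):
        vals = np.zeros((4, 4))
        with pytest.raises(InputError):
            build_graph(_matrix_from_values(vals))

    def test_ineligible_pairs_excluded(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 5.0
        vals[0, 3] = vals[3, 0] = 1.0
        elig = np.ones((4, 4), dtype=bool)
        elig[0, 1] = elig[1, 0] = False
        g = build_graph(_matrix_from_values(vals, elig), top_fraction=1.0)
        assert not g.graph.has_edge(("A", 1, ""), ("A", 2, ""))
        assert g.graph.has_edge(("A", 1, ""), ("A", 4, ""))


# -- pathways ----------------------------------------------------------------


def _line_structure(n, spacing=12.0):
    return make_model(
        [
            ("CA", "C", "A", i + 1, "ALA", "", (i * spacing, (i % 2) * 0.5, 0.0))
            for i in range(n)
        ]
    )


def _graph_of(edges, nodes):
    from allopath.allostery import AllostericGraph

    g = nx.Graph()
    g.add_nodes_from(nodes)
    mi_max = max(mi for _, _, mi in edges)
    for u, v, mi in edges:
        g.add_edge(u, v, mi=mi, weight=-math.log(mi / mi_max))
    return AllostericGraph(graph=g, mi_max=mi_max, threshold=0.0, top_fraction=1.0)


class TestAllostericPaths:
    def test_direct_edge_pathway(self):
        structure = _line_structure(2)
        keys = structure.residue_keys
        ag = _graph_of([(keys[0], keys[1], 1.0)], keys)
        paths, unreachable = allosteric_paths(ag, [keys[0]], structure)
        assert len(paths) == 1
        assert paths[0].residues == [keys[0], keys[1]]
        assert paths[0].total_weight == 0.0
        assert unreachable == 0

    def test_below_separation_skipped(self):
        structure = _line_structure(2, spacing=8.0)
        keys = structure.residue_keys
        ag = _graph_of([(keys[0], keys[1], 1.0)], keys)
        paths, _ = allosteric_paths(ag, [keys[0]], structure, min_separation=10.0)
        assert paths == []

    def test_unreachable_counted(self):
        structure = _line_structure(3)
        keys = structure.residue_keys
        ag = _graph_of([(keys[0], keys[1], 1.0)], keys)  # key 2 isolated
        paths, unreachable = allosteric_paths(ag, [keys[0]], structure)
        assert len(paths) == 1
        assert unreachable == 1

    def test_empty_sources_rejected(self):
        structure = _line_structure(2)
        ag = _graph_of([(structure.residue_keys[0], structure.residue_keys[1], 1.0)],
                       structure.residue_keys)
        with pytest.raises(InputError):
            allosteric_paths(ag, [], structure)

    def test_source_not_in_graph(self):
        structure = _line_structure(3)
        keys = structure.residue_keys
        ag = _graph_of([(keys[0], keys[1], 1.0)], keys[:2])
        with pytest.raises(SelectionError):
            allosteric_paths(ag, [keys[2]], structure)

    @pytest.mark.parametrize("seed", range(10))
    def test_optimal_vs_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 9)
        structure = _line_structure(int(n))
        keys = structure.residue_keys
        edges = []
        for i, j in itertools.combinations(range(int(n)), 2):
            if rng.random() < 0.5:
                edges.append((keys[i], keys[j], float(rng.uniform(0.05, 1.0))))
        if not edges:
            return
        ag = _graph_of(edges, keys)
        for source in keys:
            paths, _ = allosteric_paths(ag, [source], structure)
            for p in paths:
                best = min(
                    sum(
                        ag.graph[a][b]["weight"]
                        for a, b in zip(path, path[1:])
                    )
                    for path in nx.all_simple_paths(ag.graph, p.source, p.sink)
                )
                assert p.total_weight == pytest.approx(best, abs=1e-9)

    def test_deterministic_across_runs(self, rng):
        structure = _line_structure(8)
        keys = structure.residue_keys
        edges = [
            (keys[i], keys[j], float(rng.uniform(0.1, 1.0)))
            for i, j in itertools.combinations(range(8), 2)
            if rng.random() < 0.6
        ]
        ag = _graph_of(edges, keys)
        p1, _ = allosteric_paths(ag, [keys[0]], structure)
        p2, _ = allosteric_paths(ag, [keys[0]], structure)
        assert [p.residues for p in p1] == [p.residues for p in p2]


# -- pipelines ---------------------------------------------------------------


def single_linkage_oracle(dmat, cutoff):
    """Union-find transitive closure at the cutoff."""
    n = len(dmat)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted([sorted(g) for g in groups.values()])


def _path(keys, mi=1.0):
    return Pathway(
        residues=list(keys), total_weight=0.0, total_mi=mi,
        source=keys[0], sink=keys[-1], ca_separation=99.0,
    )


class TestClusterPipelines:
    def test_identical_pathways_one_pipeline(self):
        structure = _line_structure(4)
        keys = structure.residue_keys
        paths = [_path(keys[:3]), _path(keys[:3])]
        clusters = cluster_pipelines(paths, structure)
        assert len(clusters) == 1
        assert clusters[0].population == 2

    def test_distant_pathways_split(self):
        structure = _line_structure(10, spacing=12.0)
        keys = structure.residue_keys
        clusters = cluster_pipelines([_path(keys[0:2]), _path(keys[8:10])], structure)
        assert len(clusters) == 2
        assert all(c.population == 1 for c in clusters)

    def test_matches_single_linkage_oracle(self, rng):
        from allopath.allostery import _path_distance

        structure = ca_chain_structure(40)
        keys = structure.residue_keys
        paths = []
        for _ in range(12):
            start = int(rng.integers(0, 30))
            length = int(rng.integers(2, 6))
            paths.append(_path(keys[start : start + length], mi=float(rng.uniform(0.5, 2))))
        ca = [
            np.stack([structure.coords[structure.ca_index(k)] for k in p.residues])
            for p in paths
        ]
        dmat = np.zeros((12, 12))
        for i in range(12):
            for j in range(i + 1, 12):
                dmat[i, j] = dmat[j, i] = _path_distance(ca[i], ca[j])
        expected = single_linkage_oracle(dmat, 7.0)
        clusters = cluster_pipelines(paths, structure, proximity=7.0)
        got = sorted(sorted(c.members) for c in clusters)
        assert got == expected

    def test_ranking_population_then_mi(self):
        structure = _line_structure(20, spacing=12.0)
        keys = structure.residue_keys
        paths = [
            _path(keys[0:2], mi=1.0), _path(keys[0:2], mi=1.0),  # population 2
            _path(keys[10:12], mi=5.0),  # population 1, high MI
            _path(keys[18:20], mi=0.1),  # population 1, low MI
        ]
        clusters = cluster_pipelines(paths, structure)
        assert clusters[0].population == 2
        assert clusters[1].total_mi > clusters[2].total_mi

    def test_partition_property(self, rng):
        structure = ca_chain_structure(30)
        keys = structure.residue_keys
        paths = [
            _path(keys[int(rng.integers(0, 25)) :][: int(rng.integers(2, 5))])
            for _ in range(8)
        ]
        clusters = cluster_pipelines(paths, structure)
        members = sorted(m for c in clusters for m in c.members)
        assert members == list(range(8))
        for c in clusters:
            assert c.representative in c.members

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            cluster_pipelines([], _line_structure(2))


class TestHubScores:
    def test_empty_pathways(self):
        assert hub_scores([]).total() == 0

    def test_shared_residue_counted_per_pathway(self):
        structure = _line_structure(5)
        keys = structure.residue_keys
        paths = [
            _path([keys[0], keys[2], keys[4]]),
            _path([keys[1], keys[2]]),
            _path([keys[2], keys[3]]),
        ]
        hubs = hub_scores(paths)
        assert hubs.score(keys[2]) == 3

    def test_conservation_and_tally(self, rng):
        structure = ca_chain_structure(30)
        keys = structure.residue_keys
        paths = []
        for _ in range(20):
            start = int(rng.integers(0, 25))
            paths.append(_path(keys[start : start + int(rng.integers(2, 6))]))
        hubs = hub_scores(paths)
        assert hubs.total() == sum(len(p) for p in paths)
        tally = {}
        for p in paths:
            for k in p.residues:
                tally[k] = tally.get(k, 0) + 1
        for k, v in tally.items():
            assert hubs.score(k) == v


class TestCouplingMonotonicity:
    def test_relay_mi_nondecreasing_in_coupling(self):
        previous = -1.0
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = TorsionSystemSpec(
                n_residues=4, n_frames=4000, relay=(0, 3), coupling=c, seed=9
            )
            series, truth = generate_torsion_system(spec)
            by = {t.residue: t for t in series}
            a, b = truth.relay_chain
            mi = torsion_mi(by[a].values, by[b].values)
            assert mi >= previous - 1e-3
            previous = mi
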