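"""Contact-network construction, spectral partition and participation."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aromaflex.contact_network import (
    ContactNetwork,
    DisconnectedNetworkError,
    boundary_report,
    build_network,
    degrees,
    delta_participation,
    hierarchical_partition,
    laplacian,
    pairwise_distances,
    participation,
    spectral_bipartition,
)
from aromaflex.structure_io import CalphaStructure, Residue


def structure_from_coords(coords) -> CalphaStructure:
    return CalphaStructure(
        residues=[
            Residue("A", i + 1, "", "ALA", tuple(map(float, c)))
            for i, c in enumerate(coords)
        ]
    )


def net_from_adjacency(adj) -> ContactNetwork:
    adj = np.asarray(adj)
    return ContactNetwork(
        adjacency=adj, node_ids=[("A", i, "") for i in range(len(adj))]
    )


def path_graph(n):
    a = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return net_from_adjacency(a)


def clique_pair(n1, n2):
    """Two cliques joined by a single bridge edge (node 0 of each)."""
    n = n1 + n2
    a = np.zeros((n, n), dtype=int)
    a[:n1, :n1] = 1
    a[n1:, n1:] = 1
    np.fill_diagonal(a, 0)
    a[0, n1] = a[n1, 0] = 1
    return net_from_adjacency(a)


def cut_size(adj, labels):
    labels = np.asarray(labels)
    return int(adj[np.ix_(labels == 0, labels == 1)].sum())


def min_cut_exhaustive(adj):
    """Minimum cut over all nontrivial bipartitions (brute force, n <= 12)."""
    n = len(adj)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        labels = [(mask >> i) & 1 for i in range(n)]
        best = min(best, cut_size(adj, labels))
    return best


# ---------------------------------------------------------------- distances


def test_pairwise_distance_pythagoras_and_symmetry():
    s = structure_from_coords([(0, 0, 0), (3, 4, 0)])
    d = pairwise_distances(s)
    assert d[0, 1] == pytest.approx(5.0)
    assert d[0, 0] == 0.0
    np.testing.assert_array_equal(d, d.T)


def test_pairwise_distances_match_double_loop_oracle(rng):
    coords = rng.uniform(0, 30, (10, 3))
    s = structure_from_coords(coords)
    d = pairwise_distances(s)
    for i in range(10):
        for j in range(10):
            expect = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            assert abs(d[i, j] - expect) < 1e-12


# ------------------------------------------------------------------ network


@pytest.mark.parametrize(
    "distance,edge",
    [(3.8, False), (5.0, True), (8.0, False), (4.0, False), (7.999, True)],
)
def test_contact_window_is_strict(distance, edge):
    s = structure_from_coords([(0, 0, 0), (distance, 0, 0)])
    net = build_network(s)
    assert bool(net.adjacency[0, 1]) is edge


def test_degrees_triangle_edgeless_and_oracle(rng):
    tri = net_from_adjacency(1 - np.eye(3, dtype=int))
    np.testing.assert_array_equal(degrees(tri), [2, 2, 2])
    none = net_from_adjacency(np.zeros((4, 4), dtype=int))
    np.testing.assert_array_equal(degrees(none), [0, 0, 0, 0])
    a = rng.integers(0, 2, (12, 12))
    a = np.triu(a, 1)
    a = a + a.T
    net = net_from_adjacency(a)
    k = degrees(net)
    np.testing.assert_array_equal(k, [sum(a[i]) for i in range(12)])
    assert k.sum() == 2 * net.n_edges


def test_laplacian_triangle_and_row_sums():
    tri = net_from_adjacency(1 - np.eye(3, dtype=int))
    lap = laplacian(tri)
    np.testing.assert_array_equal(lap, [[2, -1, -1], [-1, 2, -1], [-1, -1, 2]])
    np.testing.assert_allclose(lap @ np.ones(3), 0.0, atol=1e-12)


def test_path_laplacian_eigenvalues_closed_form():
    lap = laplacian(path_graph(4))
    vals = np.linalg.eigvalsh(lap)
    expect = sorted(2 - 2 * np.cos(np.pi * k / 4) for k in range(4))
    np.testing.assert_allclose(vals, expect, atol=1e-10)
    # 2 - sqrt(2), 2, 2 + sqrt(2) alongside 0
    np.testing.assert_allclose(
        vals, [0, 2 - np.sqrt(2), 2, 2 + np.sqrt(2)], atol=1e-10
    )


def test_zero_eigenvalue_count_equals_component_count(rng):
    a = np.zeros((9, 9), dtype=int)
    for block in (slice(0, 3), slice(3, 6), slice(6, 9)):
        a[block, block] = 1
    np.fill_diagonal(a, 0)
    vals = np.linalg.eigvalsh(laplacian(net_from_adjacency(a)))
    assert np.sum(np.abs(vals) < 1e-8) == 3


# ---------------------------------------------------------------- partition


def test_bipartition_recovers_clique_pair_minimum_cut():
    net = clique_pair(4, 4)
    part = spectral_bipartition(net)
    assert cut_size(net.adjacency, part.labels) == min_cut_exhaustive(net.adjacency) == 1
    # clusters are exactly the cliques
    assert len(set(part.labels[:4])) == 1
    assert len(set(part.labels[4:])) == 1
    assert part.labels[0] != part.labels[4]


def test_path_of_four_splits_in_half():
    part = spectral_bipartition(path_graph(4))
    assert part.labels.tolist() == [0, 0, 1, 1]
    # analytic Fiedler pattern + + - -
    assert np.all(part.fiedler_values[:2] > 0)
    assert np.all(part.fiedler_values[2:] < 0)


def test_complete_graph_degeneracy_warning():
    k5 = net_from_adjacency(1 - np.eye(5, dtype=int))
    part = spectral_bipartition(k5)
    assert any("degenerate" in w for w in part.warnings)


def test_disconnected_raises_and_largest_component_option():
    a = np.zeros((7, 7), dtype=int)
    a[:4, :4] = 1
    a[4:, 4:] = 1
    np.fill_diagonal(a, 0)
    net = net_from_adjacency(a)
    with pytest.raises(DisconnectedNetworkError, match="largest"):
        spectral_bipartition(net)
    part = spectral_bipartition(net, on_disconnected="largest")
    assert sorted(part.excluded) == [4, 5, 6]
    assert np.all(part.labels[4:] == -1)


def test_hierarchical_depth1_equals_bipartition():
    net = clique_pair(4, 4)
    p1 = spectral_bipartition(net)
    ph = hierarchical_partition(net, depth=1)
    np.testing.assert_array_equal(p1.labels, ph.labels)


def test_hierarchical_depth2_recovers_four_cliques_in_a_chain():
    n = 16
    a = np.zeros((n, n), dtype=int)
    for c in range(4):
        sl = slice(4 * c, 4 * c + 4)
        a[sl, sl] = 1
    np.fill_diagonal(a, 0)
    for c in range(3):  # single edge between consecutive cliques
        i, j = 4 * c + 3, 4 * (c + 1)
        a[i, j] = a[j, i] = 1
    net = net_from_adjacency(a)
    part = hierarchical_partition(net, depth=2)
    groups = [set(part.labels[4 * c : 4 * c + 4].tolist()) for c in range(4)]
    assert all(len(g) == 1 for g in groups)
    assert len(set.union(*groups)) == 4
    # each split attains the brute-force minimum cut at its level
    assert cut_size(a, (part.labels >= 2).astype(int)) == min_cut_exhaustive(a)


def test_small_cluster_not_split_further():
    net = clique_pair(3, 2)  # the 2-clique cannot be split again
    part = hierarchical_partition(net, depth=2)
    assert any("not split" in w for w in part.warnings)


# ------------------------------------------------------------ participation


def test_participation_formula_and_bounds():
    # star-ish node: k=3, two neighbours in own cluster
    a = np.zeros((4, 4), dtype=int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    net = net_from_adjacency(a)
    from aromaflex.contact_network import Partition

    labels = np.array([0, 0, 0, 1])
    part = Partition(labels=labels, depth=1, fiedler_values=np.zeros(4))
    prof = participation(net, part)
    assert prof.p[0] == pytest.approx(1 - (2 / 3) ** 2)  # 5/9
    # all neighbours in own cluster -> 0; all in other -> 1
    assert prof.p[1] == pytest.approx(0.0)
    assert prof.p[3] == pytest.approx(1.0)


def test_isolated_node_undefined_and_excluded_from_mean():
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = a[1, 0] = 1
    net = net_from_adjacency(a)
    from aromaflex.contact_network import Partition

    part = Partition(labels=np.array([0, 1, 0]), depth=1, fiedler_values=np.zeros(3))
    prof = participation(net, part)
    assert np.isnan(prof.p[2])
    assert prof.mean_p == pytest.approx(1.0)  # the two linked nodes cross


def test_component_isolating_partition_gives_zero_p():
    a = np.zeros((6, 6), dtype=int)
    a[:3, :3] = 1
    a[3:, 3:] = 1
    np.fill_diagonal(a, 0)
    net = net_from_adjacency(a)
    from aromaflex.contact_network import Partition

    part = Partition(
        labels=np.array([0, 0, 0, 1, 1, 1]), depth=1, fiedler_values=np.zeros(6)
    )
    prof = participation(net, part)
    np.testing.assert_allclose(prof.p, 0.0)
    assert prof.mean_p == 0.0


@given(st.integers(0, 2**32 - 1))
def test_participation_invariant_under_label_swap(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, (8, 8))
    a = np.triu(a, 1)
    a = a + a.T
    net = net_from_adjacency(a)
    from aromaflex.contact_network import Partition

    labels = rng.integers(0, 2, 8)
    p1 = participation(net, Partition(labels, 1, np.zeros(8)))
    p2 = participation(net, Partition(1 - labels, 1, np.zeros(8)))
    np.testing.assert_array_equal(np.nan_to_num(p1.p, nan=-1), np.nan_to_num(p2.p, nan=-1))


# ------------------------------------------------------------------- deltas


def test_delta_zero_for_identical_structures(rng):
    coords = rng.uniform(0, 25, (20, 3))
    s = structure_from_coords(coords)
    net = build_network(s)
    part = spectral_bipartition(net, on_disconnected="largest")
    prof = participation(net, part)
    delta = delta_participation(prof, prof)
    d = delta.table["delta"].to_numpy()
    # isolated residues have undefined P (NaN) in both forms; all others 0
    np.testing.assert_allclose(d[~np.isnan(d)], 0.0, atol=1e-15)
    np.testing.assert_array_equal(np.isnan(d), np.isnan(prof.p))
    assert not delta.unmatched_apo and not delta.unmatched_holo


def test_delta_localized_to_rewired_contacts():
    """Rewiring one edge changes delta only for its endpoints (brute force)."""
    net_a = clique_pair(4, 4)
    adj_b = net_a.adjacency.copy()
    adj_b[1, 5] = adj_b[5, 1] = 1  # extra cross-cluster contact
    net_b = ContactNetwork(adjacency=adj_b, node_ids=net_a.node_ids)
    from aromaflex.contact_network import Partition

    labels = np.array([0] * 4 + [1] * 4)
    part = Partition(labels, 1, np.zeros(8))
    prof_a = participation(net_a, part)
    prof_b = participation(net_b, part)
    delta = delta_participation(prof_a, prof_b)
    changed = set(delta.table.loc[delta.table["delta"] != 0, "resnum"])
    assert changed == {1, 5}  # exactly the rewired endpoints
    # direct formula at an endpoint: k goes 3 -> 4, k_same stays 3
    assert prof_b.p[1] == pytest.approx(1 - (3 / 4) ** 2)


def test_delta_requires_shared_residues(rng):
    coords = rng.uniform(0, 20, (12, 3))
    s1 = structure_from_coords(coords)
    s2 = CalphaStructure(
        residues=[
            Residue("B", i + 100, "", "ALA", r.coord) for i, r in enumerate(s1.residues)
        ]
    )
    net1, net2 = build_network(s1), build_network(s2)
    part1 = spectral_bipartition(net1, on_disconnected="largest")
    prof1 = participation(net1, part1)
    prof2 = participation(net2, spectral_bipartition(net2, on_disconnected="largest"))
    with pytest.raises(ValueError, match="common"):
        delta_participation(prof1, prof2)


def test_label_alignment_survives_global_swap():
    """ΔP reporting must not depend on the arbitrary Fiedler sign."""
    net = clique_pair(5, 5)
    from aromaflex.contact_network import Partition

    labels = np.array([0] * 5 + [1] * 5)
    prof = participation(net, Partition(labels, 1, np.zeros(10)))
    prof_swapped = participation(net, Partition(1 - labels, 1, np.zeros(10)))
    delta = delta_participation(prof, prof_swapped)
    assert delta.label_alignment == {0: 1, 1: 0}
    aligned = delta.table["cluster_holo_aligned"].to_numpy()
    np.testing.assert_array_equal(aligned, labels)


# ----------------------------------------------------------------- boundary


def test_boundary_report_ranks_bridge_endpoints_first():
    net = clique_pair(4, 4)
    part = spectral_bipartition(net)
    prof = participation(net, part)
    report = boundary_report(net, prof, top_fraction=0.25)
    assert set(report.loc[report["top"], "node"]) == {0, 4}


def test_boundary_report_stable_under_ties():
    tri = net_from_adjacency(1 - np.eye(4, dtype=int))
    from aromaflex.contact_network import Partition

    prof = participation(tri, Partition(np.zeros(4, dtype=int), 1, np.zeros(4)))
    report = boundary_report(tri, prof)
    assert report["node"].tolist() == [0, 1, 2, 3]
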