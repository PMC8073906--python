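"""Protein contact networks: construction, spectral partition, participation.

A protein contact network (PCN) places one node per residue (its Cα) and an
unweighted edge between residues whose Cα–Cα distance lies strictly inside a
window, by default 4 Å < d < 8 Å. The lower cutoff removes covalent
backbone neighbours (consecutive Cα sit at ≈ 3.8 Å), so edges represent
significant noncovalent contacts only; the boundaries themselves are
non-edges.

The network is split into modules by spectral clustering on the graph
Laplacian L = D − A: the sign pattern of the Fiedler eigenvector (the
eigenvector of the second-smallest eigenvalue) yields a two-way partition,
applied recursively for 2^depth clusters. How much a residue talks across
the module border is measured by the participation coefficient

    P_i = 1 − (k_si / k_i)²

where k_i is the degree of node i and k_si its degree restricted to its own
cluster. P_i = 0 for a node whose contacts all stay inside its module and
P_i = 1 for one whose contacts all cross; high-P residues sit at the
cluster frontier. Comparing per-residue P between two conformations of the
same sequence (ΔP = P_holo − P_apo) localises where ligand binding rewires
the contact topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_io import CalphaStructure

__all__ = [
    "ContactNetwork",
    "Partition",
    "ParticipationProfile",
    "DeltaProfile",
    "DisconnectedNetworkError",
    "pairwise_distances",
    "build_network",
    "degrees",
    "laplacian",
    "spectral_bipartition",
    "hierarchical_partition",
    "participation",
    "delta_participation",
    "boundary_report",
    "analyze_structure",
]

# eigenvalues closer than this are treated as a degenerate block
DEGENERACY_TOL = 1e-8


class DisconnectedNetworkError(ValueError):
    """The Fiedler vector is undefined on a disconnected graph."""


@dataclass
class ContactNetwork:
    adjacency: np.ndarray  # (n, n) symmetric binary, zero diagonal
    node_ids: list[tuple]
    d_min: float = 4.0
    d_max: float = 8.0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    def subnetwork(self, idx: np.ndarray) -> "ContactNetwork":
        idx = np.asarray(idx)
        return ContactNetwork(
            adjacency=self.adjacency[np.ix_(idx, idx)],
            node_ids=[self.node_ids[i] for i in idx],
            d_min=self.d_min,
            d_max=self.d_max,
        )


@dataclass
class Partition:
    """Cluster labels from (recursive) spectral bipartition.

    ``labels`` are in {0 … 2^depth − 1}; nodes excluded from the analysed
    component (disconnected graphs handled with ``on_disconnected='largest'``)
    carry the label −1 and are listed in ``excluded``. ``fiedler_values``
    holds each node's component of the first-split Fiedler vector (NaN for
    excluded nodes).
    """

    labels: np.ndarray
    depth: int
    fiedler_values: np.ndarray
    warnings: list[str] = field(default_factory=list)
    excluded: list[int] = field(default_factory=list)


@dataclass
class ParticipationProfile:
    p: np.ndarray          # NaN where undefined (k = 0)
    k: np.ndarray
    k_same: np.ndarray
    labels: np.ndarray
    mean_p: float
    node_ids: list[tuple] | None = None

    @property
    def defined(self) -> np.ndarray:
        return self.k > 0


@dataclass
class DeltaProfile:
    table: pd.DataFrame                 # residue id, p_apo, p_holo, delta
    unmatched_apo: list[tuple]
    unmatched_holo: list[tuple]
    label_alignment: dict[int, int]     # holo label -> apo label


def pairwise_distances(s: CalphaStructure) -> np.ndarray:
    """Symmetric Euclidean Cα–Cα distance matrix in Å."""
    if len(s) < 2:
        raise ValueError("need at least 2 residues")
    return squareform(pdist(s.coords))


def build_network(
    s: CalphaStructure, d_min: float = 4.0, d_max: float = 8.0
) -> ContactNetwork:
    """Binary contact network with edges where d_min < d < d_max (strict)."""
    if not d_min < d_max:
        raise ValueError("require d_min < d_max")
    d = pairwise_distances(s)
    a = ((d > d_min) & (d < d_max)).astype(np.int8)
    np.fill_diagonal(a, 0)
    return ContactNetwork(adjacency=a, node_ids=s.node_ids, d_min=d_min, d_max=d_max)


def degrees(net: ContactNetwork) -> np.ndarray:
    """Node degrees k_i = Σ_j A_ij."""
    return net.adjacency.sum(axis=1).astype(int)


def laplacian(net: ContactNetwork) -> np.ndarray:
    """Graph Laplacian L = D − A."""
    a = net.adjacency.astype(float)
    return np.diag(a.sum(axis=1)) - a


def _components(adj: np.ndarray) -> tuple[int, np.ndarray]:
    return connected_components(csr_matrix(adj), directed=False)


def _bipartition_connected(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Fiedler-sign split of a connected graph.

    Returns (labels in {0,1}, fiedler vector, warnings). The eigenvector
    sign is fixed so the first node is non-negative; exact zeros join the
    non-negative cluster.
    """
    lap = np.diag(adj.sum(axis=1).astype(float)) - adj.astype(float)
    vals, vecs = eigh(lap)
    warnings: list[str] = []
    if len(vals) > 2 and (vals[2] - vals[1]) < DEGENERACY_TOL:
        warnings.append(
            f"degenerate second eigenvalue (gap {vals[2] - vals[1]:.2e}); "
            "partition uses the first eigenvector of the degenerate block"
        )
    fiedler = vecs[:, 1]
    if fiedler[0] < 0:
        fiedler = -fiedler
    labels = np.where(fiedler >= 0, 0, 1)
    return labels, fiedler, warnings


def spectral_bipartition(
    net: ContactNetwork, on_disconnected: str = "error"
) -> Partition:
    """Two-way split of the network along the Fiedler eigenvector.

    Parameters
    ----------
    on_disconnected:
        ``"error"`` (default) raises :class:`DisconnectedNetworkError`;
        ``"largest"`` partitions the largest connected component and labels
        the remaining nodes −1, listing them in ``Partition.excluded``.
    """
    n = net.n_nodes
    n_comp, comp = _components(net.adjacency)
    labels = np.full(n, -1, dtype=int)
    fiedler_full = np.full(n, np.nan)
    excluded: list[int] = []
    warnings: list[str] = []
    if n_comp > 1:
        if on_disconnected == "error":
            raise DisconnectedNetworkError(
                f"network has {n_comp} connected components; the Fiedler vector "
                "is undefined — rerun with on_disconnected='largest' to "
                "partition the largest component"
            )
        if on_disconnected != "largest":
            raise ValueError("on_disconnected must be 'error' or 'largest'")
        sizes = np.bincount(comp)
        keep = int(np.argmax(sizes))
        idx = np.flatnonzero(comp == keep)
        excluded = np.flatnonzero(comp != keep).tolist()
        warnings.append(
            f"{len(excluded)} node(s) outside the largest component excluded"
        )
    else:
        idx = np.arange(n)
    sub = net.adjacency[np.ix_(idx, idx)]
    lab, fied, w = _bipartition_connected(sub)
    warnings.extend(w)
    labels[idx] = lab
    fiedler_full[idx] = fied
    return Partition(
        labels=labels,
        depth=1,
        fiedler_values=fiedler_full,
        warnings=warnings,
        excluded=excluded,
    )


def hierarchical_partition(
    net: ContactNetwork, depth: int, on_disconnected: str = "error"
) -> Partition:
    """Recursive binary spectral partition into at most 2^depth clusters.

    Each level re-runs the Fiedler split on the subgraph induced by every
    current cluster. Sub-clusters smaller than 3 nodes are not split
    further (warning recorded); a disconnected sub-cluster is split into
    its largest component versus the rest, which is the zero-cost cut.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    part = spectral_bipartition(net, on_disconnected=on_disconnected)
    labels = part.labels.copy()
    warnings = list(part.warnings)
    for _level in range(1, depth):
        new_labels = labels.copy()
        for lab in sorted(set(labels[labels >= 0])):
            idx = np.flatnonzero(labels == lab)
            if len(idx) < 3:
                warnings.append(
                    f"cluster {lab} has {len(idx)} node(s); not split further"
                )
                new_labels[idx] = labels[idx] * 2
                continue
            sub = net.adjacency[np.ix_(idx, idx)]
            n_comp, comp = _components(sub)
            if n_comp > 1:
                sizes = np.bincount(comp)
                child = (comp != np.argmax(sizes)).astype(int)
                warnings.append(
                    f"cluster {lab} disconnected; split along components"
                )
            else:
                child, _, w = _bipartition_connected(sub)
                warnings.extend(w)
            new_labels[idx] = labels[idx] * 2 + child
        labels = new_labels
    return Partition(
        labels=labels,
        depth=depth,
        fiedler_values=part.fiedler_values,
        warnings=warnings,
        excluded=part.excluded,
    )


def participation(net: ContactNetwork, part: Partition) -> ParticipationProfile:
    """Per-node participation coefficients P_i = 1 − (k_si/k_i)².

    Isolated nodes (k = 0) have undefined P (NaN) and are excluded from
    ``mean_p``, which is the plain arithmetic mean over the remaining nodes.
    """
    if len(part.labels) != net.n_nodes:
        raise ValueError("partition does not cover the network")
    a = net.adjacency
    k = a.sum(axis=1).astype(float)
    same = (part.labels[:, None] == part.labels[None, :]).astype(float)
    k_same = (a * same).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - (k_same / k) ** 2
    p[k == 0] = np.nan
    mean_p = float(np.nanmean(p)) if np.any(k > 0) else float("nan")
    return ParticipationProfile(
        p=p,
        k=k.astype(int),
        k_same=k_same.astype(int),
        labels=part.labels.copy(),
        mean_p=mean_p,
        node_ids=list(net.node_ids),
    )


def _align_labels(
    apo: ParticipationProfile,
    holo: ParticipationProfile,
    pairs: list[tuple[int, int]],
) -> dict[int, int]:
    """Map holo cluster labels onto apo labels by maximal residue overlap.

    The Fiedler sign (hence the 0/1 labelling) is arbitrary per structure;
    a Hungarian assignment on the label-overlap table makes cluster-aware
    comparisons independent of it.
    """
    apo_labs = sorted(set(apo.labels.tolist()))
    holo_labs = sorted(set(holo.labels.tolist()))
    overlap = np.zeros((len(holo_labs), len(apo_labs)))
    for ia, ih in pairs:
        la = apo_labs.index(apo.labels[ia])
        lh = holo_labs.index(holo.labels[ih])
        overlap[lh, la] += 1
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {holo_labs[r]: apo_labs[c] for r, c in zip(rows, cols)}
    for lh in holo_labs:  # holo labels with no counterpart keep their own id
        mapping.setdefault(lh, lh)
    return mapping


def delta_participation(
    apo: ParticipationProfile, holo: ParticipationProfile
) -> DeltaProfile:
    """Per-residue ΔP = P_holo − P_apo for two conformations of one sequence.

    Residues are matched by (chain, residue number, insertion code); both
    profiles must carry ``node_ids``. Unmatched residues are reported, never
    silently dropped.
    """
    if apo.node_ids is None or holo.node_ids is None:
        raise ValueError("both profiles need node_ids for residue matching")
    apo_index = {rid: i for i, rid in enumerate(apo.node_ids)}
    holo_index = {rid: i for i, rid in enumerate(holo.node_ids)}
    shared = [rid for rid in apo.node_ids if rid in holo_index]
    if not shared:
        raise ValueError("no residues in common between the two structures")
    pairs = [(apo_index[rid], holo_index[rid]) for rid in shared]
    mapping = _align_labels(apo, holo, pairs)
    rows = []
    for rid, (ia, ih) in zip(shared, pairs):
        rows.append(
            {
                "chain": rid[0],
                "resnum": rid[1],
                "icode": rid[2],
                "p_apo": apo.p[ia],
                "p_holo": holo.p[ih],
                "delta": holo.p[ih] - apo.p[ia],
                "cluster_apo": int(apo.labels[ia]),
                "cluster_holo_aligned": int(mapping[holo.labels[ih]]),
            }
        )
    table = pd.DataFrame(rows)
    return DeltaProfile(
        table=table,
        unmatched_apo=[rid for rid in apo.node_ids if rid not in holo_index],
        unmatched_holo=[rid for rid in holo.node_ids if rid not in apo_index],
        label_alignment=mapping,
    )


def boundary_report(
    net: ContactNetwork,
    prof: ParticipationProfile,
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Residues ranked by descending P; the top fraction is flagged.

    The sort is stable, so ties keep file order. High-P residues are the
    ones lying at the cluster border.
    """
    df = pd.DataFrame(
        {
            "node": range(net.n_nodes),
            "id": [str(i) for i in net.node_ids],
            "cluster": prof.labels,
            "k": prof.k,
            "k_same": prof.k_same,
            "p": prof.p,
        }
    )
    df = df.sort_values("p", ascending=False, kind="stable", na_position="last")
    df = df.reset_index(drop=True)
    n_top = int(np.ceil(top_fraction * net.n_nodes))
    df["top"] = df.index < n_top
    return df


@dataclass
class NetworkAnalysis:
    network: ContactNetwork
    partition: Partition
    profile: ParticipationProfile

    @property
    def mean_p(self) -> float:
        return self.profile.mean_p


def analyze_structure(
    s: CalphaStructure,
    d_min: float = 4.0,
    d_max: float = 8.0,
    depth: int = 1,
    on_disconnected: str = "largest",
) -> NetworkAnalysis:
    """Build network, partition it, compute participation — the whole chain."""
    net = build_network(s, d_min=d_min, d_max=d_max)
    part = hierarchical_partition(net, depth=depth, on_disconnected=on_disconnected)
    prof = participation(net, part)
    return NetworkAnalysis(network=net, partition=part, profile=prof)
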