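"""Correlation-weighted dynamical network analysis.

Nodes are protein residues (anchored at C-alpha) and two nodes per
nucleotide: a base node anchored at N1 (pyrimidines) or N9 (purines) owning
the base-ring atoms, and a sugar-phosphate node anchored at P owning the
sugar and phosphate atoms.  Two nodes are connected by an edge when any
heavy-atom pair between the components they represent lies within the
distance cutoff (4.5 A default) in at least the occupancy fraction of frames
(75% default), excluding neighbouring nodes (same residue, adjacent residues
in a chain).  Edges are weighted by the node-node cross-correlation:
w_ij = -log |C_ij| (strong correlation = short network distance; |C| floored
at 1e-6), with the linear alternative 1 - |C| available.

All-pairs shortest paths use Floyd-Warshall; the characteristic path length
(CPL) is the mean shortest-path distance over connected unordered pairs.
Communities come from divisive Girvan-Newman edge-betweenness removal with
the partition chosen at maximum modularity; delta-CPL scans measure the CPL
change when a node's edges (or the node itself) are deleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .constants import (
    AA_ONE_LETTER,
    AMINO_ACIDS_3,
    BASE_ATOM_NAMES,
    NUCLEOTIDES,
    PURINES,
    SUGAR_PHOSPHATE_ATOM_NAMES,
)
from .essential_dynamics import CorrelationMatrix, dccm
from .trajio import AtomSelection, Structure, Trajectory

logger = logging.getLogger("stardynet")

__all__ = [
    "NetworkNode",
    "DynamicalNetwork",
    "CommunityPartition",
    "CplReport",
    "define_nodes",
    "node_correlation",
    "build_network",
    "shortest_paths",
    "characteristic_path_length",
    "communities",
    "delta_cpl_scan",
]


@dataclass
class NetworkNode:
    label: str
    kind: str            # "residue" | "base" | "sugar_phosphate"
    anchor_id: int       # atom id of CA / N1 / N9 / P
    atom_ids: np.ndarray  # heavy atoms of the represented component
    chain: str
    resseq: int


@dataclass
class DynamicalNetwork:
    """Occupancy-filtered, correlation-weighted graph over network nodes."""

    nodes: list
    graph: nx.Graph
    occupancy_cutoff: float
    distance_cutoff: float

    @property
    def labels(self) -> list:
        return [n.label for n in self.nodes]


def define_nodes(topology: Structure) -> list:
    """Network nodes of a topology: one per amino-acid residue, two per
    nucleotide.  Raises if a residue lacks its anchor atom."""
    residues: dict[tuple, dict] = {}
    order: list[tuple] = []
    for i in range(topology.n_atoms):
        key = (str(topology.chain_ids[i]), int(topology.residue_seqs[i]))
        if key not in residues:
            residues[key] = {"resname": str(topology.residue_names[i]),
                             "atoms": []}
            order.append(key)
        residues[key]["atoms"].append(i)
    nodes: list[NetworkNode] = []
    for key in order:
        chain, resseq = key
        info = residues[key]
        resname = info["resname"]
        names = {str(topology.atom_names[i]): i for i in info["atoms"]}
        heavy = np.array(
            [i for i in info["atoms"]
             if str(topology.elements[i]).upper() != "H"], dtype=int,
        )
        if resname in AMINO_ACIDS_3:
            if "CA" not in names:
                raise ValueError(
                    f"residue {resname}{resseq} (chain {chain}) has no CA "
                    f"anchor atom"
                )
            label = f"{AA_ONE_LETTER.get(resname, resname)}{resseq}"
            nodes.append(NetworkNode(label, "residue", names["CA"], heavy,
                                     chain, resseq))
        elif resname in NUCLEOTIDES:
            base_anchor = "N9" if resname in PURINES else "N1"
            if base_anchor not in names:
                raise ValueError(
                    f"nucleotide {resname}{resseq} (chain {chain}) has no "
                    f"{base_anchor} anchor atom"
                )
            if "P" not in names:
                raise ValueError(
                    f"nucleotide {resname}{resseq} (chain {chain}) has no P "
                    f"anchor atom"
                )
            base_ids = np.array(
                [i for i in heavy
                 if str(topology.atom_names[i]) in BASE_ATOM_NAMES],
                dtype=int,
            )
            sugar_ids = np.array(
                [i for i in heavy
                 if str(topology.atom_names[i]) in SUGAR_PHOSPHATE_ATOM_NAMES],
                dtype=int,
            )
            nodes.append(NetworkNode(f"{resname}{resseq}:base", "base",
                                     names[base_anchor], base_ids, chain,
                                     resseq))
            nodes.append(NetworkNode(f"{resname}{resseq}:sugar",
                                     "sugar_phosphate", names["P"], sugar_ids,
                                     chain, resseq))
        else:
            logger.warning("residue %s%s not protein or nucleic; skipped",
                           resname, resseq)
    return nodes


def _neighbor_exclusion(a: NetworkNode, b: NetworkNode) -> bool:
    """Neighbouring nodes carry no edge: same residue (base-sugar of one
    nucleotide) or adjacent residues of the same chain."""
    return a.chain == b.chain and abs(a.resseq - b.resseq) <= 1


def node_correlation(
    traj: Trajectory, nodes: list, fit: bool = True
) -> CorrelationMatrix:
    """DCCM over the node anchor atoms (C-alpha, N1/N9, P), labeled by node."""
    anchors = np.array([n.anchor_id for n in nodes])
    sel = AtomSelection(expression="<node anchors>", resolved_ids=anchors)
    order = np.argsort(anchors)
    inverse = np.argsort(order)
    c = dccm(traj, sel, fit=fit)
    m = c.matrix[np.ix_(inverse, inverse)]
    return CorrelationMatrix(labels=[n.label for n in nodes], matrix=m)


def build_network(
    traj: Trajectory,
    topology: Structure | None = None,
    occupancy_cutoff: float = 0.75,
    distance_cutoff: float = 4.5,
    correlation: CorrelationMatrix | None = None,
    weight_scheme: str = "neglog",
    nodes: list | None = None,
) -> DynamicalNetwork:
    """Build the occupancy-filtered, correlation-weighted dynamical network.

    A node pair is in contact in a frame when any heavy-atom pair between
    their components is within ``distance_cutoff``; an edge is kept when the
    contact occupancy is >= ``occupancy_cutoff``.  ``correlation`` defaults
    to the anchor-atom DCCM of the trajectory; its labels must align with the
    node list.  ``weight_scheme`` is "neglog" (-log |C|) or "linear"
    (1 - |C|).
    """
    topology = topology if topology is not None else traj.topology
    nodes = nodes if nodes is not None else define_nodes(topology)
    if correlation is None:
        correlation = node_correlation(traj, nodes)
    if correlation.matrix.shape[0] != len(nodes):
        raise ValueError(
            f"correlation matrix size {correlation.matrix.shape[0]} does not "
            f"match {len(nodes)} network nodes"
        )
    n = len(nodes)
    occ = np.zeros((n, n))
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if not _neighbor_exclusion(nodes[i], nodes[j])
        and len(nodes[i].atom_ids) and len(nodes[j].atom_ids)
    ]
    for i, j in candidates:
        a = traj.frames[:, nodes[i].atom_ids]  # (F, na, 3)
        b = traj.frames[:, nodes[j].atom_ids]  # (F, nb, 3)
        d2 = ((a[:, :, None, :] - b[:, None, :, :]) ** 2).sum(axis=-1)
        dmin2 = d2.reshape(traj.n_frames, -1).min(axis=1)
        occ[i, j] = float((dmin2 <= distance_cutoff**2).mean())
    g = nx.Graph()
    for k, node in enumerate(nodes):
        g.add_node(node.label, kind=node.kind, index=k)
    for i, j in candidates:
        if occ[i, j] >= occupancy_cutoff:
            c = correlation.matrix[i, j]
            g.add_edge(
                nodes[i].label,
                nodes[j].label,
                occupancy=float(occ[i, j]),
                correlation=float(c),
                weight=edge_weight(c, weight_scheme),
            )
    return DynamicalNetwork(nodes=nodes, graph=g,
                            occupancy_cutoff=occupancy_cutoff,
                            distance_cutoff=distance_cutoff)


def write_graphml(net, path) -> None:
    """Export the network (occupancy/correlation/weight edge attributes) as
    GraphML for external graph tools."""
    nx.write_graphml(_as_graph(net), path)


def edge_weight(correlation: float, scheme: str = "neglog") -> float:
    """Map a cross-correlation to a non-negative network distance."""
    c = max(abs(float(correlation)), 1e-6)
    if scheme == "neglog":
        return float(-np.log(c))
    if scheme == "linear":
        return float(1.0 - c)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, DynamicalNetwork) else net


@dataclass
class ShortestPaths:
    labels: list
    distances: np.ndarray  # (n, n), inf for unreachable
    cpl: float
    n_unreachable_pairs: int


def shortest_paths(net) -> ShortestPaths:
    """All-pairs shortest-path distances (Floyd-Warshall) and the CPL.

    CPL is the mean over all unordered connected node pairs; unreachable
    pairs are excluded from the mean and counted.
    """
    g = _as_graph(net)
    labels = sorted(g.nodes)
    w = nx.to_numpy_array(g, nodelist=labels, weight="weight",
                          nonedge=np.inf)
    np.fill_diagonal(w, 0.0)
    if np.any(w[np.isfinite(w)] < 0):
        raise ValueError("edge weights must be >= 0")
    d = floyd_warshall(w, directed=False)
    iu, ju = np.triu_indices(len(labels), k=1)
    finite = np.isfinite(d[iu, ju])
    cpl = float(d[iu, ju][finite].mean()) if finite.any() else np.nan
    return ShortestPaths(
        labels=labels,
        distances=d,
        cpl=cpl,
        n_unreachable_pairs=int((~finite).sum()),
    )


def characteristic_path_length(net) -> float:
    return shortest_paths(net).cpl


@dataclass
class CommunityPartition:
    assignment: dict          # label -> community id (dense from 0)
    n_communities: int
    modularity: float
    removal_sequence: list = field(default_factory=list)


def _partition_ids(g: nx.Graph) -> dict:
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    return {node: k for k, comp in enumerate(comps) for node in sorted(comp)}


def communities(net) -> CommunityPartition:
    """Girvan-Newman community detection on the weighted network.

    Edges of maximum weighted betweenness (shortest paths on the distance
    weights) are removed iteratively until none remain; ties break on the
    lexicographically smallest edge label for determinism.  The reported
    partition is the connected-component split of maximum modularity
    (evaluated unweighted on the original edge set) over the whole removal
    sequence.
    """
    g0 = _as_graph(net)
    if g0.number_of_edges() == 0:
        raise ValueError("community detection needs at least one edge")
    work = g0.copy()
    best = None
    removal = []
    while True:
        part = _partition_ids(work)
        groups = [
            {n for n, k in part.items() if k == kk}
            for kk in range(max(part.values()) + 1)
        ]
        q = nx.community.modularity(g0, groups, weight=None)
        if best is None or q > best[0] + 1e-12:
            best = (q, part)
        if work.number_of_edges() == 0:
            break
        bet = nx.edge_betweenness_centrality(work, weight="weight",
                                             normalized=False)
        max_b = max(bet.values())
        candidates_ = sorted(
            tuple(sorted(e, key=str)) for e, b in bet.items()
            if b >= max_b - 1e-12
        )
        edge = candidates_[0]
        work.remove_edge(*edge)
        removal.append(edge)
    q, part = best
    return CommunityPartition(
        assignment=part,
        n_communities=max(part.values()) + 1,
        modularity=float(q),
        removal_sequence=removal,
    )


@dataclass
class CplReport:
    baseline_cpl: float
    labels: list
    delta_cpl: np.ndarray        # per node
    n_disconnected: np.ndarray   # pairs connected at baseline, lost on removal
    mode: str


def delta_cpl_scan(net, mode: str = "edge_removal") -> CplReport:
    """Per-node CPL perturbation scan.

    ``edge_removal`` deletes every edge incident to the node (the node stays,
    isolated); ``node_removal`` deletes the node itself.  delta-CPL is
    CPL(perturbed) - CPL(baseline) computed over the node pairs connected in
    both graphs (the baseline mean is re-evaluated on those same pairs), and
    the count of pairs disconnected by the perturbation is reported per node.
    """
    if mode not in ("edge_removal", "node_removal"):
        raise ValueError(f"unknown scan mode {mode!r}")
    g0 = _as_graph(net)
    base = shortest_paths(g0)
    labels = base.labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    d0 = base.distances
    deltas = np.zeros(n)
    lost = np.zeros(n, dtype=int)
    for lab in labels:
        v = index[lab]
        g = g0.copy()
        if mode == "edge_removal":
            g.remove_edges_from(list(g.edges(lab)))
            keep_labels = labels
        else:
            g.remove_node(lab)
            keep_labels = [x for x in labels if x != lab]
        w = nx.to_numpy_array(g, nodelist=keep_labels, weight="weight",
                              nonedge=np.inf)
        np.fill_diagonal(w, 0.0)
        d1_sub = floyd_warshall(w, directed=False)
        d1 = np.full((n, n), np.inf)
        keep_idx = np.array([index[x] for x in keep_labels])
        d1[np.ix_(keep_idx, keep_idx)] = d1_sub
        pair_mask = np.ones(len(iu), dtype=bool)
        if mode == "edge_removal":
            pair_mask &= (iu != v) & (ju != v)
        both = pair_mask & np.isfinite(d0[iu, ju]) & np.isfinite(d1[iu, ju])
        lost[v] = int(
            (pair_mask & np.isfinite(d0[iu, ju]) & ~np.isfinite(d1[iu, ju]))
            .sum()
        )
        if both.any():
            deltas[v] = float(d1[iu, ju][both].mean()
                              - d0[iu, ju][both].mean())
        else:
            deltas[v] = 0.0
    return CplReport(
        baseline_cpl=base.cpl,
        labels=labels,
        delta_cpl=deltas,
        n_disconnected=lost,
        mode=mode,
    )
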