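"""Allosteric communication analysis from torsion-angle ensembles.

The chain of results: per-residue torsion time series -> pairwise mutual
information (MI, nats) between residue torsion distributions -> undirected
graph over the top fraction of MI pairs with edge weight ``-ln(MI/MI_max)``
-> minimum-weight (i.e. maximum MI-product) pathways between spatially
separated residue pairs via Dijkstra -> structural clustering of pathways
into pipelines -> per-residue hub scores (number of pathways through each
residue, endpoints included).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InputError, SelectionError
from .geometry import dihedral_series
from .structure_io import ResidueKey, StructureModel, Trajectory

# -- torsion atom definitions ------------------------------------------------

# chi_k: four heavy atoms per standard residue type, outward from the backbone
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

TORSION_NAMES = ("phi", "psi", "chi1", "chi2", "chi3", "chi4")


@dataclass
class TorsionSeries:
    """Circular angle time series of one named torsion of one residue."""

    residue: ResidueKey
    name: str  # phi | psi | chi1..chi4
    values: np.ndarray  # degrees in [-180, 180)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -180.0) or np.any(self.values >= 180.0):
            raise InputError("torsion values must be wrapped to [-180, 180)")


def extract_torsions(traj: Trajectory) -> tuple[list[TorsionSeries], list[str]]:
    """phi, psi and chi1-chi4 series for every residue where defined.

    Torsions whose atoms are missing (chain breaks, nonstandard residues,
    Gly/Ala chi) are skipped and reported in the returned log, never
    NaN-filled.
    """
    model = traj.model
    keys = model.residue_keys
    series: list[TorsionSeries] = []
    skipped: list[str] = []

    def atom(key: ResidueKey, name: str) -> int | None:
        return model.find_atom(key, name)

    for pos, key in enumerate(keys):
        resname = model.residue_name(key)
        prev_key = keys[pos - 1] if pos > 0 and keys[pos - 1][0] == key[0] else None
        next_key = (
            keys[pos + 1] if pos + 1 < len(keys) and keys[pos + 1][0] == key[0] else None
        )
        quads: list[tuple[str, list[int | None]]] = []
        if prev_key is not None:
            quads.append(
                ("phi", [atom(prev_key, "C"), atom(key, "N"), atom(key, "CA"), atom(key, "C")])
            )
        if next_key is not None:
            quads.append(
                ("psi", [atom(key, "N"), atom(key, "CA"), atom(key, "C"), atom(next_key, "N")])
            )
        for k, quad in enumerate(CHI_ATOMS.get(resname, [])):
            quads.append((f"chi{k + 1}", [atom(key, nm) for nm in quad]))
        for name, idx in quads:
            if any(i is None for i in idx):
                skipped.append(f"{key} {resname} {name}: missing atoms")
                continue
            series.append(
                TorsionSeries(residue=key, name=name, values=dihedral_series(traj, idx))
            )
    return series, skipped


# -- mutual information ------------------------------------------------------


def torsion_mi(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = 24,
    miller_madow: bool = False,
) -> float:
    """Plug-in mutual information (nats) between two circular angle series.

    The joint distribution is estimated on a fixed ``bins x bins`` grid over
    ``[-180, 180)``; zero-count cells contribute nothing.  The optional
    Miller-Madow correction subtracts the first-order plug-in bias.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("torsion series must be equal-length 1-D arrays")
    n = len(x)
    if n < bins:
        raise InputError(f"series length {n} shorter than bin count {bins}")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])))
    if miller_madow:
        kx = int(np.count_nonzero(px))
        ky = int(np.count_nonzero(py))
        kxy = int(np.count_nonzero(pxy))
        mi -= (kxy - kx - ky + 1) / (2.0 * n)
    return max(mi, 0.0)


def mi_bias_bound(bins: int, n: int) -> float:
    """First-order plug-in MI bias for independent series: (B-1)^2 / (2N)."""
    return (bins - 1) ** 2 / (2.0 * n)


@dataclass
class MIMatrix:
    """Symmetric residue-pair MI (nats) with estimator provenance."""

    residues: list[ResidueKey]
    values: np.ndarray  # (R, R), diagonal set to 0 and excluded from use
    eligible: np.ndarray  # (R, R) bool: pair may become a graph edge
    provenance: dict[tuple[int, int], tuple[str, str]]
    bins: int
    aggregation: str
    miller_madow: bool = False

    def pair(self, i: int, j: int) -> float:
        if i == j:
            raise InputError("MI(i, i) is undefined")
        return float(self.values[i, j])


def residue_mi_matrix(
    torsions: list[TorsionSeries],
    aggregation: str = "max",
    min_sequence_separation: int = 3,
    bins: int = 24,
    miller_madow: bool = False,
) -> MIMatrix:
    """Aggregate torsion-pair MI into a residue-pair matrix.

    ``aggregation`` is ``max`` (strongest torsion channel, default) or
    ``sum``.  Pairs on the same chain closer than
    ``min_sequence_separation`` in residue order are computed but flagged
    ineligible for graph construction (adjacent residues share backbone
    atoms, which inflates MI trivially).
    """
    if aggregation not in ("max", "sum"):
        raise InputError(f"unknown aggregation {aggregation!r}")
    by_res: dict[ResidueKey, list[TorsionSeries]] = {}
    for ts in torsions:
        by_res.setdefault(ts.residue, []).append(ts)
    residues = list(by_res)
    r = len(residues)
    if r < 2:
        raise InputError("MI matrix needs >= 2 residues with torsions")
    # residue order within its chain, for the sequence-separation rule
    chain_pos: dict[ResidueKey, int] = {}
    counter: dict[str, int] = {}
    for key in residues:
        counter[key[0]] = counter.get(key[0], 0) + 1
        chain_pos[key] = counter[key[0]]
    values = np.zeros((r, r))
    eligible = np.ones((r, r), dtype=bool)
    np.fill_diagonal(eligible, False)
    provenance: dict[tuple[int, int], tuple[str, str]] = {}
    for i in range(r):
        for j in range(i + 1, r):
            best = 0.0
            best_pair = ("", "")
            total = 0.0
            for ti in by_res[residues[i]]:
                for tj in by_res[residues[j]]:
                    mi = torsion_mi(
                        ti.values, tj.values, bins=bins, miller_madow=miller_madow
                    )
                    total += mi
                    if mi > best:
                        best = mi
                        best_pair = (ti.name, tj.name)
            val = best if aggregation == "max" else total
            values[i, j] = values[j, i] = val
            provenance[(i, j)] = best_pair
            same_chain = residues[i][0] == residues[j][0]
            if same_chain and abs(chain_pos[residues[i]] - chain_pos[residues[j]]) < min_sequence_separation:
                eligible[i, j] = eligible[j, i] = False
    return MIMatrix(
        residues=residues,
        values=values,
        eligible=eligible,
        provenance=provenance,
        bins=bins,
        aggregation=aggregation,
        miller_madow=miller_madow,
    )


# -- graph and pathways ------------------------------------------------------


@dataclass
class AllostericGraph:
    graph: nx.Graph  # nodes: ResidueKey; edges carry "mi" and "weight"
    mi_max: float
    threshold: float
    top_fraction: float


def build_graph(mi: MIMatrix, top_fraction: float = 0.10) -> AllostericGraph:
    """Edges = eligible residue pairs whose MI falls in the top fraction.

    The threshold is the ``ceil(fraction * n_eligible)``-th largest eligible
    MI; ties at the threshold are always included.  Edge weight is
    ``-ln(MI / MI_max) >= 0`` so that minimum-weight paths maximize the
    product of normalized MI along the path.
    """
    if not 0 < top_fraction <= 1:
        raise InputError("top fraction must be in (0, 1]")
    iu = np.triu_indices(len(mi.residues), k=1)
    elig = mi.eligible[iu]
    vals = mi.values[iu][elig]
    if len(vals) == 0 or np.max(vals) <= 0:
        raise InputError("no eligible residue pair with MI > 0; graph is empty")
    k = math.ceil(top_fraction * len(vals))
    threshold = float(np.sort(vals)[::-1][k - 1])
    mi_max = float(np.max(vals))
    g = nx.Graph()
    g.add_nodes_from(mi.residues)
    rows, cols = iu
    for i, j, ok in zip(rows, cols, mi.eligible[iu]):
        v = mi.values[i, j]
        if ok and v >= threshold and v > 0:
            g.add_edge(
                mi.residues[i],
                mi.residues[j],
                mi=float(v),
                weight=float(-np.log(v / mi_max)),
            )
    return AllostericGraph(
        graph=g, mi_max=mi_max, threshold=threshold, top_fraction=top_fraction
    )


@dataclass
class Pathway:
    residues: list[ResidueKey]  # ordered source -> sink
    total_weight: float
    total_mi: float  # sum of edge MI along the path
    source: ResidueKey
    sink: ResidueKey
    ca_separation: float  # source-sink C-alpha distance on the reference

    def __len__(self) -> int:
        return len(self.residues)


def _dijkstra(g: nx.Graph, source: ResidueKey):
    """Single-source Dijkstra with deterministic lexicographic tie-breaking
    (neighbors visited in sorted order; only strict improvements relax)."""
    dist: dict[ResidueKey, float] = {source: 0.0}
    prev: dict[ResidueKey, ResidueKey] = {}
    heap: list[tuple[float, ResidueKey]] = [(0.0, source)]
    done: set[ResidueKey] = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in sorted(g.neighbors(u)):
            nd = d + g[u][v]["weight"]
            if nd < dist.get(v, np.inf) - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, prev


def allosteric_paths(
    agraph: AllostericGraph,
    sources: list[ResidueKey],
    structure: StructureModel,
    sinks: list[ResidueKey] | None = None,
    min_separation: float = 10.0,
) -> tuple[list[Pathway], int]:
    """Maximum-MI pathways from each source to every admissible sink.

    A (source, sink) pair is admissible when its C-alpha separation on the
    reference structure exceeds ``min_separation`` (default 10 A) and the
    sink is reachable in the graph.  Returns the pathways plus the count of
    admissible-but-unreachable pairs.
    """
    g = agraph.graph
    if not sources:
        raise InputError("empty source set")
    bad = [s for s in sources if s not in g]
    if bad:
        raise SelectionError(f"source residues not in graph: {bad[:5]}")
    sink_set = sorted(g.nodes) if sinks is None else sorted(sinks)
    source_set = set(sources)
    ca = {k: structure.coords[structure.ca_index(k)] for k in set(sink_set) | source_set}
    paths: list[Pathway] = []
    unreachable = 0
    seen_pairs: set[frozenset] = set()
    for source in sorted(sources):
        dist, prev = _dijkstra(g, source)
        for sink in sink_set:
            if sink == source:
                continue
            pair = frozenset((source, sink))
            if pair in seen_pairs:
                continue
            sep = float(np.linalg.norm(ca[source] - ca[sink]))
            if sep <= min_separation:
                continue
            seen_pairs.add(pair)
            if sink not in dist:
                unreachable += 1
                continue
            chain = [sink]
            while chain[-1] != source:
                chain.append(prev[chain[-1]])
            chain.reverse()
            total_mi = sum(g[a][b]["mi"] for a, b in zip(chain, chain[1:]))
            paths.append(
                Pathway(
                    residues=chain,
                    total_weight=float(dist[sink]),
                    total_mi=float(total_mi),
                    source=source,
                    sink=sink,
                    ca_separation=sep,
                )
            )
    return paths, unreachable


# -- pipelines and hub scores ------------------------------------------------


@dataclass
class PipelineCluster:
    members: list[int]  # indices into the pathway list
    population: int
    representative: int  # member pathway index
    rank: int
    total_mi: float


def _path_distance(ca_a: np.ndarray, ca_b: np.ndarray) -> float:
    """Symmetrized mean nearest-residue C-alpha distance between two paths."""
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def cluster_pipelines(
    paths: list[Pathway],
    structure: StructureModel,
    proximity: float = 7.0,
) -> list[PipelineCluster]:
    """Single-linkage clustering of pathways by structural proximity.

    Two pathways join the same pipeline when their symmetrized mean
    nearest-residue C-alpha distance is at or below ``proximity`` (single
    linkage: connectivity is transitive).  Pipelines are ranked by
    population, ties by summed pathway MI.
    """
    if not paths:
        raise InputError("cannot cluster an empty pathway set")
    n = len(paths)
    ca = [
        np.stack([structure.coords[structure.ca_index(k)] for k in p.residues])
        for p in paths
    ]
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _path_distance(ca[i], ca[j])
    linked = nx.Graph()
    linked.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if dmat[i, j] <= proximity:
                linked.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(linked)]
    clusters: list[PipelineCluster] = []
    for members in comps:
        if len(members) == 1:
            rep = members[0]
        else:
            sub = dmat[np.ix_(members, members)]
            mean_d = sub.sum(axis=1) / (len(members) - 1)
            rep = members[int(np.argmin(mean_d))]  # argmin: lowest index on ties
        clusters.append(
            PipelineCluster(
                members=members,
                population=len(members),
                representative=rep,
                rank=-1,
                total_mi=float(sum(paths[m].total_mi for m in members)),
            )
        )
    clusters.sort(key=lambda c: (-c.population, -c.total_mi, c.members[0]))
    for rank, c in enumerate(clusters):
        c.rank = rank
    return clusters


@dataclass
class HubScoreTable:
    scores: dict[ResidueKey, int] = field(default_factory=dict)

    def score(self, key: ResidueKey) -> int:
        return self.scores.get(key, 0)

    def total(self) -> int:
        return sum(self.scores.values())


def hub_scores(paths: list[Pathway]) -> HubScoreTable:
    """Number of pathways containing each residue (endpoints included)."""
    scores: dict[ResidueKey, int] = {}
    for p in paths:
        for key in p.residues:
            scores[key] = scores.get(key, 0) + 1
    return HubScoreTable(scores=scores)
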