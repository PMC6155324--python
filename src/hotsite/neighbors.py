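"""Residue neighborhood graphs.

Two adjacency relations over one structure: *euclidean* (minimum
heavy-atom distance below a cutoff, default 5 A) and *voronoi* (a pair
of residues contributes atoms to at least one common Delaunay
tetrahedron of the all-heavy-atom tessellation).  Both graphs are
symmetric and irreflexive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .structure import Structure

__all__ = [
    "NeighborGraph",
    "euclidean_neighbors",
    "voronoi_neighbors",
    "voronoi_contacts",
    "write_edge_list",
    "DEFAULT_EUCLIDEAN_CUTOFF",
    "DEFAULT_VORONOI_MAX_EDGE",
]

DEFAULT_EUCLIDEAN_CUTOFF = 5.0
DEFAULT_VORONOI_MAX_EDGE = 8.0

Rid = tuple[str, int, str]


@dataclass
class NeighborGraph:
    kind: str  # "euclidean" | "voronoi"
    edges: set[frozenset] = field(default_factory=set)
    nodes: list[Rid] = field(default_factory=list)

    def add_edge(self, a: Rid, b: Rid) -> None:
        if a == b:
            raise ValueError("neighbor graphs are irreflexive")
        self.edges.add(frozenset((a, b)))

    def neighbors(self, rid: Rid) -> list[Rid]:
        out = []
        for e in self.edges:
            if rid in e:
                (other,) = e - {rid}
                out.append(other)
        return sorted(out)

    def degree(self, rid: Rid) -> int:
        return sum(1 for e in self.edges if rid in e)

    def are_neighbors(self, a: Rid, b: Rid) -> bool:
        return frozenset((a, b)) in self.edges


def _heavy_atom_index(structure: Structure):
    coords, owner = [], []
    for idx, res in enumerate(structure.residues):
        for a in res.heavy_atoms:
            coords.append(a.coord)
            owner.append(idx)
    return np.asarray(coords, dtype=float), np.asarray(owner)


def euclidean_neighbors(structure: Structure,
                        cutoff: float = DEFAULT_EUCLIDEAN_CUTOFF,
                        ) -> NeighborGraph:
    """Residues adjacent iff their minimum heavy-atom distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    graph = NeighborGraph(kind="euclidean",
                          nodes=[r.rid for r in structure.residues])
    coords, owner = _heavy_atom_index(structure)
    if coords.size == 0:
        return graph
    tree = cKDTree(coords)
    rids = [r.rid for r in structure.residues]
    for i, j in tree.query_pairs(cutoff):
        if owner[i] != owner[j]:
            graph.add_edge(rids[owner[i]], rids[owner[j]])
    return graph


def _jitter(coords: np.ndarray, seed: int, scale: float = 1e-6) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, scale, size=coords.shape)


def voronoi_neighbors(structure: Structure,
                      max_edge: float | None = DEFAULT_VORONOI_MAX_EDGE,
                      jitter: bool = True,
                      jitter_seed: int = 0,
                      ) -> NeighborGraph:
    """Delaunay tessellation of all heavy atoms; residues adjacent iff
    some tetrahedron contains an atom of each.

    ``max_edge`` drops adjacencies whose minimum heavy-atom distance
    exceeds it, suppressing long convex-hull artifacts (set ``None`` to
    keep all).  Degenerate (cospherical/coplanar) inputs are retried
    once with a deterministic 1e-6 A jitter when ``jitter`` is on,
    otherwise they raise.
    """
    graph = NeighborGraph(kind="voronoi",
                          nodes=[r.rid for r in structure.residues])
    coords, owner = _heavy_atom_index(structure)
    if len(coords) < 4:
        raise ValueError("need >= 4 heavy atoms for a Delaunay tessellation")
    degenerate_msg = ("degenerate (coplanar/cospherical) coordinates; "
                      "jitter the fixture coordinates before tessellating")
    try:
        tess = Delaunay(coords)
    except QhullError as exc:
        if not jitter:
            raise ValueError(degenerate_msg) from exc
        try:
            tess = Delaunay(_jitter(coords, jitter_seed))
        except QhullError as exc2:
            raise ValueError(degenerate_msg) from exc2
    rids = [r.rid for r in structure.residues]
    pairs: set[tuple[int, int]] = set()
    for simplex in tess.simplices:
        owners = sorted(set(int(owner[v]) for v in simplex))
        for a, b in combinations(owners, 2):
            pairs.add((a, b))
    if max_edge is not None:
        min_dist = _min_residue_distances(structure, pairs)
    for a, b in pairs:
        if max_edge is not None and min_dist[(a, b)] > max_edge:
            continue
        graph.add_edge(rids[a], rids[b])
    return graph


def _min_residue_distances(structure: Structure,
                           pairs: set[tuple[int, int]]) -> dict:
    cache = {}
    res = structure.residues
    coords = [r.heavy_coords() for r in res]
    for a, b in pairs:
        d = np.sqrt(((coords[a][:, None, :] - coords[b][None, :, :]) ** 2
                     ).sum(-1)).min()
        cache[(a, b)] = float(d)
    return cache


def voronoi_contacts(structure: Structure, graph: NeighborGraph,
                     ) -> dict[Rid, tuple[float, float]]:
    """Per residue: (same-side, cross-side) Voronoi neighbor counts."""
    if structure.partition is None:
        raise ValueError("structure needs a partition")
    side = {r.rid: structure.side_of(r) for r in structure.residues}
    out: dict[Rid, tuple[float, float]] = {}
    for r in structure.residues:
        same = cross = 0
        for nb in graph.neighbors(r.rid):
            if side[nb] == side[r.rid]:
                same += 1
            else:
                cross += 1
        out[r.rid] = (float(same), float(cross))
    return out


def write_edge_list(graph: NeighborGraph, path) -> None:
    """Text export: one ``chain:resnum:icode  chain:resnum:icode  kind`` line per edge."""
    def fmt(rid: Rid) -> str:
        return f"{rid[0]}:{rid[1]}:{rid[2].strip() or '-'}"

    lines = sorted(tuple(sorted(map(fmt, e))) for e in graph.edges)
    with open(path, "w") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{b}\t{graph.kind}\n")
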