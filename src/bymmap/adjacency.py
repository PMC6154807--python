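"""Areal adjacency graphs for the spatial prior.

The intrinsic autoregression penalizes squared differences across edges of a
symmetric neighbor graph.  Neighbors are derived either from polygon
contiguity (queen rule: boundaries sharing at least one point) or from a
plain-text adjacency list.  Vertices are aligned to the lexicographic area
order used throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape
from shapely.strtree import STRtree

from .areal_data import ValidationError

logger = logging.getLogger(__name__)

QUEEN_SNAP_TOL = 1e-9  # coordinate-unit tolerance when testing shared boundary points


@dataclass
class AdjacencyGraph:
    """Symmetric, loop-free neighbor structure over ``n`` areas.

    ``edges`` is the canonical representation: unordered pairs (i, j) with
    i < j, indices into ``area_ids``.  Neighbor lists, degrees and connected
    components are derived on construction.
    """

    area_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    neighbors: tuple[tuple[int, ...], ...] = field(init=False, repr=False)
    degrees: np.ndarray = field(init=False, repr=False)
    component_labels: np.ndarray = field(init=False, repr=False)
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.area_ids = tuple(str(a) for a in self.area_ids)
        n = len(self.area_ids)
        seen = set()
        canon = []
        for i, j in self.edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValidationError(f"self-loop on area {self.area_ids[i]!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"edge ({i},{j}) references unknown vertex")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValidationError(f"duplicate edge ({i},{j})")
            seen.add((i, j))
            canon.append((i, j))
        self.edges = tuple(sorted(canon))
        nbr: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.edges:
            nbr[i].append(j)
            nbr[j].append(i)
        self.neighbors = tuple(tuple(sorted(v)) for v in nbr)
        self.degrees = np.array([len(v) for v in self.neighbors], dtype=int)
        labels, c = _components_from_edges(n, self.edges)
        self.component_labels = labels
        self.n_components = c

    @property
    def n(self) -> int:
        return len(self.area_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two index arrays (empty-safe)."""
        if not self.edges:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        e = np.asarray(self.edges, dtype=int)
        return e[:, 0], e[:, 1]

    def to_sparse(self) -> sp.csr_matrix:
        """Binary adjacency matrix W in CSR form."""
        ei, ej = self.edge_arrays()
        data = np.ones(2 * len(ei))
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in self.edges:
                fh.write(f"{self.area_ids[i]}\t{self.area_ids[j]}\n")

    def write_adjacency_list(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, a in enumerate(self.area_ids):
                ids = ",".join(self.area_ids[j] for j in self.neighbors[i])
                fh.write(f"{a}: {ids}\n")


def _components_from_edges(
    n: int, edges: Sequence[tuple[int, int]]
) -> tuple[np.ndarray, int]:
    if n == 0:
        return np.empty(0, dtype=int), 0
    if edges:
        e = np.asarray(edges, dtype=int)
        W = sp.coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
        )
    else:
        W = sp.coo_matrix((n, n))
    c, labels = connected_components(W, directed=False)
    return labels.astype(int), int(c)


def components(graph: AdjacencyGraph) -> tuple[np.ndarray, int]:
    """Connected-component labels and count; isolated areas are singletons."""
    return _components_from_edges(graph.n, graph.edges)


def _load_geojson(source: str | Path | Mapping) -> Mapping:
    if isinstance(source, Mapping):
        return source
    with open(source, "r", encoding="utf-8") as fh:
        return json.load(fh)


def graph_from_polygons(
    source: str | Path | Mapping,
    area_ids: Sequence[str] | None = None,
    id_property: str = "area_id",
    tol: float = QUEEN_SNAP_TOL,
) -> AdjacencyGraph:
    """Queen-contiguity graph from a GeoJSON FeatureCollection.

    Two areas are neighbors iff their boundaries share at least one point
    (distance <= *tol* in coordinate units).  Features are keyed by the
    *id_property* property.  If *area_ids* is given, every listed area must
    have a geometry.  The result is invariant to feature order: vertices are
    the sorted area ids.
    """
    gj = _load_geojson(source)
    feats = gj.get("features")
    if feats is None:
        raise ValidationError("polygon source is not a GeoJSON FeatureCollection")
    geoms: dict[str, object] = {}
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise ValidationError(f"feature {k} lacks the {id_property!r} property")
        aid = str(props[id_property])
        if aid in geoms:
            raise ValidationError(f"duplicate geometry for area {aid!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValidationError(f"invalid geometry for area {aid!r}")
        geoms[aid] = geom
    if area_ids is not None:
        missing = sorted(set(map(str, area_ids)) - set(geoms))
        if missing:
            raise ValidationError(f"areas with no geometry: {missing}")
        ids = tuple(sorted(map(str, area_ids)))
    else:
        ids = tuple(sorted(geoms))
    glist = [geoms[a] for a in ids]
    tree = STRtree(glist)
    edges = set()
    for i, g in enumerate(glist):
        for j in tree.query(g, predicate="dwithin", distance=max(tol, 0.0)):
            j = int(j)
            if j > i:
                edges.add((i, j))
    return AdjacencyGraph(ids, tuple(sorted(edges)))


def graph_from_list(
    path: str | Path, area_ids: Sequence[str]
) -> AdjacencyGraph:
    """Adjacency graph from a text file of lines ``area_id: id1,id2,...``.

    Declarations are symmetrized (the union of both directions); each
    asymmetric declaration that had to be repaired is logged as a warning.
    Unknown ids raise with the offending line number.  Areas with an empty
    neighbor list (or no line at all) become islands.
    """
    ids = tuple(sorted(map(str, area_ids)))
    index = {a: i for i, a in enumerate(ids)}
    declared: set[tuple[int, int]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValidationError(
                    f"line {lineno}: expected 'area_id: id1,id2,...', got {line!r}"
                )
            left, right = line.split(":", 1)
            src = left.strip()
            if src not in index:
                raise ValidationError(f"line {lineno}: unknown area id {src!r}")
            for tok in right.split(","):
                tok = tok.strip()
                if not tok:
                    continue
                if tok not in index:
                    raise ValidationError(f"line {lineno}: unknown area id {tok!r}")
                if tok == src:
                    raise ValidationError(f"line {lineno}: self-neighbor {src!r}")
                declared.add((index[src], index[tok]))
    edges = set()
    for i, j in declared:
        if (j, i) not in declared:
            logger.warning(
                "adjacency list declares %s -> %s but not the reverse; "
                "edge symmetrized", ids[i], ids[j],
            )
        edges.add((min(i, j), max(i, j)))
    return AdjacencyGraph(ids, tuple(sorted(edges)))
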