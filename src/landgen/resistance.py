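"""Circuit-theoretic distances on resistance rasters.

A resistance raster becomes an undirected conductance graph (4- or
8-neighbor; edge conductance is the reciprocal of the mean of the two cell
resistances, diagonal edges additionally divided by sqrt(2) for the longer
step).  Commute distance between nodes i, j is

    C(i, j) = vol(G) * R_eff(i, j)

with vol(G) the sum of weighted node degrees and R_eff the two-point
effective resistance — the expected round-trip steps of the weighted random
walk.  Current maps solve the Kirchhoff system for unit source/sink pairs
and accumulate per-cell current magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .pairwise import PairwiseMatrix
from .raster import RasterSurface


@dataclass
class ConductanceGraph:
    """Sparse weighted graph over the non-missing cells of a raster."""

    weights: sp.csr_matrix          # symmetric conductances, zero diagonal
    node_cells: np.ndarray          # (n_nodes, 2) row/col of each node
    cell_index: np.ndarray          # raster-shaped map cell -> node id (-1 missing)
    raster: RasterSurface

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    @property
    def volume(self) -> float:
        return float(self.degrees.sum())

    def laplacian(self) -> sp.csr_matrix:
        return sp.diags(self.degrees) - self.weights

    def snap_nodes(self, xy: np.ndarray) -> np.ndarray:
        """Node ids nearest to projected coordinates (ties: lower row/col)."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        nodes = np.empty(len(xy), dtype=int)
        for k, (x, y) in enumerate(xy):
            r, c = self.raster.snap(x, y)
            nodes[k] = self.cell_index[r, c]
        return nodes


def build_graph(raster: RasterSurface, connectivity: int = 8) -> ConductanceGraph:
    """Conductance graph from a resistance raster.

    Edge conductance = 1 / mean(R_i, R_j); diagonal edges divided by
    sqrt(2).  Missing cells are excluded.  Resistances must be >= some
    positive floor (cost surfaces start at 1).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    r = raster.values
    valid = ~np.isnan(r)
    if valid.sum() < 2:
        raise ValueError("need at least 2 non-missing cells")
    if np.nanmin(r) <= 0:
        raise ValueError("resistances must be positive")
    nr, nc = r.shape
    cell_index = np.full((nr, nc), -1, dtype=int)
    cell_index[valid] = np.arange(valid.sum())
    node_cells = np.argwhere(valid)

    rows, cols, vals = [], [], []
    # each undirected edge added once (down/right/diagonal shifts), mirrored below
    for dr, dc in [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 8 else []):
        a_sl = (slice(max(0, -dr), nr - max(0, dr)), slice(max(0, -dc), nc - max(0, dc)))
        b_sl = (slice(max(0, dr), nr - max(0, -dr)), slice(max(0, dc), nc - max(0, -dc)))
        a_idx = cell_index[a_sl].ravel()
        b_idx = cell_index[b_sl].ravel()
        ra = r[a_sl].ravel()
        rb = r[b_sl].ravel()
        ok = (a_idx >= 0) & (b_idx >= 0)
        cond = 1.0 / (0.5 * (ra[ok] + rb[ok]))
        if dr and dc:
            cond = cond / np.sqrt(2.0)
        rows.append(a_idx[ok])
        cols.append(b_idx[ok])
        vals.append(cond)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    if len(vals) == 0:
        raise ValueError("graph has no edges")
    n = int(valid.sum())
    w = sp.coo_matrix((np.concatenate([vals, vals]),
                       (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                      shape=(n, n)).tocsr()
    return ConductanceGraph(w, node_cells, cell_index, raster)


def _require_connected(graph: ConductanceGraph, nodes: np.ndarray) -> None:
    ncomp, labels = connected_components(graph.weights, directed=False)
    if ncomp > 1 and len(set(labels[nodes])) > 1:
        comps = {int(l): [int(v) for v in nodes[labels[nodes] == l]]
                 for l in set(labels[nodes])}
        raise ValueError(f"query nodes span disconnected components: {comps}")


def effective_resistance(graph: ConductanceGraph, nodes: np.ndarray) -> np.ndarray:
    """Pairwise two-point effective resistances among ``nodes``.

    Grounds one query node and solves the reduced (SPD) Laplacian system for
    the remaining query nodes with a single sparse LU factorization; agrees
    with the dense pseudoinverse formula L+_ii + L+_jj − 2 L+_ij.
    """
    nodes = np.asarray(nodes, dtype=int)
    _require_connected(graph, nodes)
    m = len(nodes)
    ground = int(nodes[0])
    L = graph.laplacian().tocsc()
    keep = np.ones(graph.n_nodes, dtype=bool)
    keep[ground] = False
    Lred = L[keep][:, keep].tocsc()
    pos = np.cumsum(keep) - 1  # original node -> reduced index
    lu = splu(Lred)
    sols = {}
    for nd in nodes[1:]:
        e = np.zeros(Lred.shape[0])
        e[pos[nd]] = 1.0
        sols[int(nd)] = lu.solve(e)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = int(nodes[i]), int(nodes[j])
            if a == ground:
                reff = sols[b][pos[b]]
            elif b == ground:
                reff = sols[a][pos[a]]
            else:
                reff = sols[a][pos[a]] + sols[b][pos[b]] - 2.0 * sols[a][pos[b]]
            out[i, j] = out[j, i] = reff
    return out


def commute_distance(graph: ConductanceGraph, xy: np.ndarray,
                     ids: list[str] | None = None) -> PairwiseMatrix:
    """Commute distances among sampling locations (snapped to cells)."""
    nodes = graph.snap_nodes(xy)
    reff = effective_resistance(graph, nodes)
    vals = graph.volume * reff
    if ids is None:
        ids = [f"loc{k}" for k in range(len(nodes))]
    np.fill_diagonal(vals, np.nan)
    return PairwiseMatrix(list(ids), vals, "commute")


def commute_distance_nodes(graph: ConductanceGraph, nodes: np.ndarray) -> np.ndarray:
    """Commute-distance matrix among explicit node ids (zero diagonal)."""
    return graph.volume * effective_resistance(graph, np.asarray(nodes))


def current_map(graph: ConductanceGraph, pairs: list[tuple[int, int]]) -> RasterSurface:
    """Cumulative current raster for unit source/sink node pairs.

    For each pair, inject 1 A at the source and extract at the sink, solve
    the Laplacian system, and accumulate per-cell current magnitude (half
    the summed absolute edge currents at interior cells; the injected 1 A
    at terminals).
    """
    if not pairs:
        raise ValueError("no pairs given")
    L = graph.laplacian().tocsc()
    W = graph.weights.tocoo()
    total = np.zeros(graph.n_nodes)
    for s, t in pairs:
        s, t = int(s), int(t)
        if s == t:
            raise ValueError("source and sink coincide")
        _require_connected(graph, np.array([s, t]))
        keep = np.ones(graph.n_nodes, dtype=bool)
        keep[t] = False
        pos = np.cumsum(keep) - 1
        rhs = np.zeros(graph.n_nodes - 1)
        rhs[pos[s]] = 1.0
        v = np.zeros(graph.n_nodes)
        v[keep] = splu(L[keep][:, keep].tocsc()).solve(rhs)
        edge_cur = W.data * (v[W.row] - v[W.col])  # each edge twice, +/-
        node_abs = np.bincount(W.row, weights=np.abs(edge_cur),
                               minlength=graph.n_nodes) / 2.0
        node_abs[[s, t]] = 1.0
        total += node_abs
    vals = np.full(graph.raster.shape, np.nan)
    vals[tuple(graph.node_cells.T)] = total
    return graph.raster.copy(values=vals, tag="current")


def random_walk_commute(graph: ConductanceGraph, a: int, b: int,
                        n_walks: int, rng: np.random.Generator) -> float:
    """Monte-Carlo mean round-trip steps a -> b -> a of the weighted walk.

    Simulation oracle for :func:`commute_distance`; only sensible on small
    graphs.
    """
    W = graph.weights.tocsr()
    deg = graph.degrees
    idx = W.indices
    ptr = W.indptr
    dat = W.data
    steps_total = 0
    for _ in range(n_walks):
        cur, target, legs = a, b, 0
        steps = 0
        while legs < 2:
            lo, hi = ptr[cur], ptr[cur + 1]
            p = dat[lo:hi] / deg[cur]
            cur = int(idx[lo + rng.choice(hi - lo, p=p)])
            steps += 1
            if cur == target:
                legs += 1
                target = a if target == b else b
        steps_total += steps
    return steps_total / n_walks
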