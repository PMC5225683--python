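"""Seeded random-walker segmentation as a combinatorial Dirichlet problem.

Each pixel is a graph node; 4- or 8-neighbour edges carry weights

    w_ij = exp(-beta * (g_i - g_j)^2)                    (intensity term)
    w_s  = exp(-((x_i-x_j)^2 + (y_i-y_j)^2) / lambda_s)  (spatial term)
    W_ij = w_ij * w_s + omega     (or w_ij + omega without the spatial term)

on intensities g normalised to [0, 1].  Larger beta makes intensity steps
harder for a walker to cross, so labels follow strong edges; beta = 0
reduces to uniform weights and labels are decided by seed geometry alone.
The additive floor omega keeps every edge crossable (regularisation).

For each label L, the probability that a walker started at pixel i first
reaches an L-seed is the harmonic function with boundary values 1 on
L-seeds and 0 on other seeds.  Splitting the combinatorial Laplacian
(degrees d_v on the diagonal, -W_ij off it) over seeded (v_m) and unseeded
(v_u) nodes,

    L = [ L_M  B ; B^T  L_U ],

the unseeded probabilities solve the sparse SPD system
``L_U x_U = -B^T m`` with m the one-hot seed indicator for L.  Only L-1
systems are solved; probabilities sum to 1 at every node, so the last
label is the complement.  Pixels take the argmax label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, spilu, splu, LinearOperator


class MissingSeedsError(ValueError):
    """No seeded pixels were supplied."""


@dataclass
class RandomWalkerParams:
    """Tunable parameters of the walker's edge-weighting function.

    beta : intensity contrast scaling (>= 0), on [0, 1] intensities.
    omega : additive regularisation floor added to every edge weight.
    lambda_s : spatial scale of the locality term (> 0 when used).
    connectivity : 4 or 8 neighbours per interior pixel.
    use_spatial : multiply the spatial similarity term into the weight.
    """

    beta: float = 90.0
    omega: float = 1e-6
    lambda_s: float = 2.0
    connectivity: int = 8
    use_spatial: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.use_spatial and self.lambda_s <= 0:
            raise ValueError("lambda_s must be > 0 when use_spatial is set")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def edge_weight(
    g_i: float, g_j: float, p_i: tuple[float, float], p_j: tuple[float, float], params: RandomWalkerParams
) -> float:
    """Weight of the edge between two pixels (scalar convenience form)."""
    w = np.exp(-params.beta * (float(g_i) - float(g_j)) ** 2)
    if params.use_spatial:
        d2 = (p_i[0] - p_j[0]) ** 2 + (p_i[1] - p_j[1]) ** 2
        w = w * np.exp(-d2 / params.lambda_s)
    return float(w + params.omega)


@dataclass
class WeightedPixelGraph:
    """Undirected weighted pixel graph with its seeded/unseeded partition."""

    shape: tuple[int, int]
    edges: np.ndarray  # (n_edges, 2) node-index pairs, i < j
    weights: np.ndarray  # (n_edges,) positive symmetric weights
    seed_labels: np.ndarray  # flat per-node label, 0 = unseeded
    labels: tuple[int, ...] = field(default=())  # label ids with >= 1 seed

    @property
    def n_nodes(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def seeded(self) -> np.ndarray:
        return np.flatnonzero(self.seed_labels)

    @property
    def unseeded(self) -> np.ndarray:
        return np.flatnonzero(self.seed_labels == 0)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        np.add.at(d, self.edges[:, 0], self.weights)
        np.add.at(d, self.edges[:, 1], self.weights)
        return d

    def adjacency(self) -> sp.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.weights
        return sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()

    def laplacian(self) -> sp.csr_matrix:
        adj = self.adjacency()
        return (sp.diags(self.degrees()) - adj).tocsr()

    def incidence(self) -> sp.csr_matrix:
        """Edge-node incidence matrix A (arbitrary orientation i -> j)."""
        n_e = len(self.weights)
        rows = np.repeat(np.arange(n_e), 2)
        cols = self.edges.ravel()
        vals = np.tile([1.0, -1.0], n_e)
        return sp.coo_matrix((vals, (rows, cols)), shape=(n_e, self.n_nodes)).tocsr()


def _grid_edges(shape: tuple[int, int], connectivity: int) -> np.ndarray:
    """Node-index pairs of the 4- or 8-connected pixel lattice."""
    rows, cols = shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    pairs = [
        np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1),  # horizontal
        np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1),  # vertical
    ]
    if connectivity == 8:
        pairs.append(np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1))
        pairs.append(np.stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()], axis=1))
    return np.concatenate(pairs)


def build_graph(image: np.ndarray, seed_map: np.ndarray, params: RandomWalkerParams) -> WeightedPixelGraph:
    """Build the weighted pixel graph for an image with seed labels.

    ``image`` holds intensities in [0, 1]; ``seed_map`` is an integer array
    of the same shape (0 = unseeded).  Labels with no seeds are ignored.
    """
    image = np.asarray(image, dtype=np.float64)
    seed_map = np.asarray(seed_map)
    if image.shape != seed_map.shape:
        raise ValueError("image and seed map shapes differ")
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    label_ids = tuple(int(l) for l in np.unique(seed_map) if l != 0)
    if not label_ids:
        raise MissingSeedsError("seed map contains no seeded pixels")

    edges = _grid_edges(image.shape, params.connectivity)
    flat = image.ravel()
    diff = flat[edges[:, 0]] - flat[edges[:, 1]]
    w = np.exp(-params.beta * diff**2)
    if params.use_spatial:
        rr = edges // image.shape[1]
        cc = edges % image.shape[1]
        d2 = (rr[:, 0] - rr[:, 1]) ** 2 + (cc[:, 0] - cc[:, 1]) ** 2
        w = w * np.exp(-d2.astype(np.float64) / params.lambda_s)
    w = w + params.omega
    return WeightedPixelGraph(
        shape=image.shape,
        edges=edges,
        weights=w,
        seed_labels=seed_map.ravel().astype(np.int64),
        labels=label_ids,
    )


@dataclass
class LabelProbabilities:
    """Per-node, per-label probabilities; rows sum to 1, seeds one-hot."""

    shape: tuple[int, int]
    labels: tuple[int, ...]
    probs: np.ndarray  # (n_labels, n_nodes)

    def as_images(self) -> dict[int, np.ndarray]:
        return {lab: self.probs[k].reshape(self.shape) for k, lab in enumerate(self.labels)}


# direct factorization up to this many unseeded unknowns, CG beyond
_DIRECT_SOLVE_LIMIT = 1_000_000
_CG_TOL = 1e-8


class SolverFailure(RuntimeError):
    """The sparse Dirichlet solve did not reach the residual contract."""


def _solve_spd(L_u: sp.csr_matrix, rhs: np.ndarray) -> np.ndarray:
    """Solve L_u X = rhs for possibly several right-hand sides."""
    rhs = np.atleast_2d(rhs.T).T  # (n, k)
    n = L_u.shape[0]
    if n <= _DIRECT_SOLVE_LIMIT:
        lu = splu(L_u.tocsc())
        x = np.column_stack([lu.solve(rhs[:, k]) for k in range(rhs.shape[1])])
    else:
        try:
            ilu = spilu(L_u.tocsc(), drop_tol=1e-5, fill_factor=10)
            M = LinearOperator(L_u.shape, ilu.solve)
        except RuntimeError:
            M = None
        cols = []
        for k in range(rhs.shape[1]):
            xk, info = cg(L_u, rhs[:, k], rtol=_CG_TOL, maxiter=2000, M=M)
            if info != 0:
                raise SolverFailure(f"conjugate gradient did not converge (info={info})")
            cols.append(xk)
        x = np.column_stack(cols)
    # residual contract: ||L_U x - b|| / ||b|| <= 1e-6 per system
    for k in range(rhs.shape[1]):
        bnorm = np.linalg.norm(rhs[:, k])
        if bnorm > 0:
            res = np.linalg.norm(L_u @ x[:, k] - rhs[:, k]) / bnorm
            if res > 1e-6:
                raise SolverFailure(f"residual {res:.2e} exceeds contract")
    return x


def solve_probabilities(graph: WeightedPixelGraph) -> LabelProbabilities:
    """Solve the Dirichlet problem for all labels on the graph.

    Solves one sparse SPD system per label except the last, which is
    obtained as the complement (probabilities at a node sum to 1).
    Connected components containing no seed get uniform probabilities.
    """
    labels = graph.labels
    if not labels:
        raise MissingSeedsError("graph has no seeded labels")
    n = graph.n_nodes
    n_lab = len(labels)
    probs = np.zeros((n_lab, n))

    seeded = graph.seeded
    unseeded = graph.unseeded
    seed_lab = graph.seed_labels

    # one-hot probabilities on the seeds
    for k, lab in enumerate(labels):
        probs[k, seeded[seed_lab[seeded] == lab]] = 1.0
    if unseeded.size == 0:
        return LabelProbabilities(graph.shape, labels, probs)

    adj = graph.adjacency()
    n_comp, comp = connected_components(adj, directed=False)
    seeded_comps = np.unique(comp[seeded])
    orphan = ~np.isin(comp, seeded_comps)
    if orphan.any():
        probs[:, orphan] = 1.0 / n_lab

    solvable = unseeded[~orphan[unseeded]]
    if solvable.size:
        lap = graph.laplacian()
        L_u = lap[solvable][:, solvable].tocsr()
        B_T = lap[solvable][:, seeded].tocsr()  # coupling block B^T
        # right-hand sides for the first n_lab - 1 labels
        if n_lab == 1:
            probs[0, solvable] = 1.0
        else:
            m = np.zeros((seeded.size, n_lab - 1))
            for k, lab in enumerate(labels[:-1]):
                m[:, k] = (seed_lab[seeded] == lab).astype(np.float64)
            x = _solve_spd(L_u, -(B_T @ m))
            for k in range(n_lab - 1):
                probs[k, solvable] = x[:, k]
            probs[n_lab - 1, solvable] = 1.0 - x.sum(axis=1)
    np.clip(probs, 0.0, 1.0, out=probs)
    # renormalise away clip/solver round-off
    probs /= probs.sum(axis=0, keepdims=True)
    return LabelProbabilities(graph.shape, labels, probs)


def assign_labels(probabilities: LabelProbabilities, seed_map: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel argmax label; ties break to the lowest label id.

    Seeded pixels keep their seed label when ``seed_map`` is given.
    """
    order = np.argsort(probabilities.labels)  # ascending ids
    p_sorted = probabilities.probs[order]
    winner = np.argmax(p_sorted, axis=0)  # first (lowest id) wins ties
    lab_arr = np.asarray(probabilities.labels)[order]
    out = lab_arr[winner].reshape(probabilities.shape)
    if seed_map is not None:
        seed_map = np.asarray(seed_map)
        out = np.where(seed_map != 0, seed_map, out)
    return out


def segment_slice(
    image: np.ndarray, seed_map: np.ndarray, params: RandomWalkerParams
) -> tuple[np.ndarray, LabelProbabilities]:
    """Convenience: graph -> probabilities -> label image for one slice."""
    graph = build_graph(image, seed_map, params)
    probs = solve_probabilities(graph)
    return assign_labels(probs, seed_map), probs
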