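"""Spatial and temporal neighbourhood structures and intrinsic CAR densities.

The spatial prior on area effects and the first-order random-walk (RW1)
prior on temporal effects are both intrinsic conditional autoregressive
(ICAR) Gaussian Markov random fields: each node is conditionally normal
around the mean of its graph neighbours.  The spatial graph W links areas
that share a border; the temporal graph Q is the path graph on ordered
time points (RW1).  The joint ICAR kernel is rank deficient (flat along
the constant direction of every connected component), so densities here
are improper and models identify the level through sum-to-zero centring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class AdjacencyStructure:
    """Undirected, binary neighbourhood graph.

    Attributes
    ----------
    n : int
        Number of nodes (areas or time points).
    edges : ndarray of shape (m, 2)
        Unique undirected edges as sorted index pairs.
    neighbor_counts : ndarray of shape (n,)
        Number of neighbours N_i of each node.
    component_labels : ndarray of shape (n,)
        Connected-component id per node; isolated nodes ("islands") form
        singleton components and contribute nothing to ICAR kernels.
    """

    n: int
    edges: np.ndarray
    neighbor_counts: np.ndarray
    component_labels: np.ndarray

    # cached derived quantities, not part of identity
    _coloring: tuple = field(default=None, compare=False, repr=False)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n else 0

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR precision kernel)."""
        lap = np.zeros((self.n, self.n))
        for i, j in self.edges:
            lap[i, j] -= 1.0
            lap[j, i] -= 1.0
        lap[np.diag_indices(self.n)] = self.neighbor_counts
        return lap

    def coloring(self) -> list[np.ndarray]:
        """Partition nodes into independent sets (greedy graph colouring).

        Nodes in one colour class share no edge, so single-site Metropolis
        proposals within a class can be accepted simultaneously.
        """
        if self._coloring is not None:
            return [np.asarray(c) for c in self._coloring]
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        colors = nx.greedy_color(g, strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        classes = [np.array(sorted(v for v, c in colors.items() if c == ci),
                            dtype=np.int64) for ci in range(k)]
        object.__setattr__(self, "_coloring", tuple(tuple(c) for c in classes))
        return classes

    def neighbor_matrix(self):
        """Sparse CSR adjacency matrix W (binary, symmetric)."""
        from scipy import sparse

        m = self.n_edges
        if m == 0:
            return sparse.csr_matrix((self.n, self.n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * m)
        return sparse.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(self.n, self.n)
        )


def build_adjacency(n: int, edges) -> AdjacencyStructure:
    """Build a symmetric neighbourhood structure from an edge list.

    Duplicate and reversed pairs collapse to a single undirected edge.
    Self-loops and out-of-range indices are rejected.
    """
    if n < 1:
        raise ValueError("need at least one node")
    seen = set()
    for pair in edges:
        i, j = int(pair[0]), int(pair[1])
        if i == j:
            raise ValueError(f"self-loop at node {i} is not allowed")
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i},{j}) out of range for n={n}")
        seen.add((min(i, j), max(i, j)))
    edge_arr = (np.array(sorted(seen), dtype=np.int64)
                if seen else np.empty((0, 2), dtype=np.int64))
    counts = np.zeros(n, dtype=np.int64)
    for i, j in edge_arr:
        counts[i] += 1
        counts[j] += 1

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edge_arr))
    labels = np.empty(n, dtype=np.int64)
    for cid, comp in enumerate(nx.connected_components(g)):
        labels[list(comp)] = cid
    return AdjacencyStructure(n=n, edges=edge_arr, neighbor_counts=counts,
                              component_labels=labels)


def temporal_path_adjacency(T: int) -> AdjacencyStructure:
    """Path graph on T ordered time points: q_ht = 1 iff |h - t| = 1.

    This is the RW1 prior's neighbourhood structure.
    """
    if T < 2:
        raise ValueError("a temporal structure needs T >= 2")
    edges = [(t, t + 1) for t in range(T - 1)]
    return build_adjacency(T, edges)


def lattice_adjacency(rows: int, cols: int) -> AdjacencyStructure:
    """Rook-neighbourhood rectangular grid (test-scale stand-in geography)."""
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs at least two cells")
    edges = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            if c + 1 < cols:
                edges.append((k, k + 1))
            if r + 1 < rows:
                edges.append((k, k + cols))
    return build_adjacency(rows * cols, edges)


def icar_quadform(x, A: AdjacencyStructure) -> float:
    """Pairwise-difference ICAR kernel: sum over edges of (x_i - x_j)^2.

    Equals x' (D - W) x; zero iff x is constant within every component.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != A.n:
        raise ValueError(f"vector length {x.shape[-1]} != n={A.n}")
    if A.n_edges == 0:
        return 0.0 if x.ndim == 1 else np.zeros(x.shape[:-1])
    d = x[..., A.edges[:, 0]] - x[..., A.edges[:, 1]]
    q = np.sum(d * d, axis=-1)
    return float(q) if x.ndim == 1 else q


def icar_logpdf(x, A: AdjacencyStructure, sigma2: float) -> float:
    """Improper joint ICAR log density (up to an additive constant).

    -quadform/(2 sigma2) - ((n - c)/2) log sigma2, with c the number of
    connected components; the rank-deficient normaliser keeps the variance
    hyperparameter identifiable while parameter-free constants are dropped.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    nc = A.n - A.n_components
    return -icar_quadform(x, A) / (2.0 * sigma2) - 0.5 * nc * np.log(sigma2)


def sum_to_zero(x, A: AdjacencyStructure) -> np.ndarray:
    """Centre x to mean zero within each connected component."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != A.n:
        raise ValueError(f"vector length {x.shape[0]} != n={A.n}")
    out = x.copy()
    for cid in range(A.n_components):
        mask = A.component_labels == cid
        out[mask] -= out[mask].mean()
    return out


def read_gal(path) -> AdjacencyStructure:
    """Read a GAL-style neighbour list.

    Format: first non-comment line gives the node count; then for each
    node a line ``id  n_neighbors`` followed by a line of neighbour ids.
    Both 0-based and 1-based id conventions are accepted; 1-based files
    (ids covering 1..n with no 0) are converted on read.
    """
    with open(path) as fh:
        tokens_lines = [ln.split() for ln in fh
                        if ln.strip() and not ln.startswith(("!", "#", "%"))]
    header = tokens_lines[0]
    # GAL headers are sometimes "0 n shp id"; take the count field
    n = int(header[1]) if len(header) > 1 and header[0] == "0" else int(header[0])
    flat = [tok for ln in tokens_lines[1:] for tok in ln]
    pos = 0
    raw: dict[int, list[int]] = {}
    while pos < len(flat):
        node = int(flat[pos])
        deg = int(flat[pos + 1])
        nbrs = [int(t) for t in flat[pos + 2: pos + 2 + deg]]
        raw[node] = nbrs
        pos += 2 + deg
    ids = set(raw) | {j for v in raw.values() for j in v}
    one_based = (0 not in ids) and (max(ids, default=0) == n) and (min(ids, default=1) >= 1)
    off = 1 if one_based else 0
    edges = [(i - off, j - off) for i, nbrs in raw.items() for j in nbrs]
    return build_adjacency(n, edges)
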