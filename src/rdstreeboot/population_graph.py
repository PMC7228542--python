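"""Hidden population graphs for respondent-driven sampling.

The population is an undirected simple graph G on N vertices; each vertex
carries a binary trait x(i) in {0, 1} and, optionally, a block label.  The
RDS recruitment process is a random walk on G: from vertex i the next
recruit is uniform over i's neighbours, so the transition matrix has entry
P(i, j) = 1/deg(i) on edges.  At stationarity vertices are sampled with
probability proportional to degree, pi_i = deg(i) / sum_j deg(j).

A stochastic-block-model (SBM) generator with 2K equal blocks provides the
test populations.  With within-block edge probability p and between-block
probability r, the walk's trait process satisfies a central limit theorem
when the mixing parameter p~ = p / {p + r(K-1)} lies strictly inside
(1/(2K), 1/(2K) + 1/(2*sqrt(2))); `below_threshold` evaluates that
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PopulationGraph",
    "TransitionKernel",
    "SbmParams",
    "make_sbm",
    "symmetric_block_traits",
    "transition_kernel",
    "stationary_distribution",
    "tilde_p",
    "below_threshold",
]


class GraphError(ValueError):
    """Raised for structurally invalid population graphs."""


@dataclass(frozen=True)
class PopulationGraph:
    """An undirected simple graph with per-vertex binary traits.

    Parameters
    ----------
    num_vertices
        Number of vertices N; vertices are labelled 0..N-1.
    edges
        Unordered vertex pairs.  Self-loops and duplicate pairs are
        rejected: a self-referral is not an RDS referral.
    trait
        Per-vertex indicator in {0, 1} (e.g. HIV status).
    block_label
        Optional per-vertex block membership (SBM populations).
    """

    num_vertices: int
    edges: frozenset[frozenset[int]]
    trait: np.ndarray
    block_label: Optional[np.ndarray] = None
    _nx: nx.Graph = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.num_vertices <= 0:
            raise GraphError("graph must have at least one vertex")
        trait = np.asarray(self.trait, dtype=np.int64)
        if trait.shape != (self.num_vertices,):
            raise GraphError(
                f"trait vector has shape {trait.shape}, expected ({self.num_vertices},)"
            )
        if not np.isin(trait, (0, 1)).all():
            raise GraphError("traits must be 0 or 1")
        g = nx.Graph()
        g.add_nodes_from(range(self.num_vertices))
        for pair in self.edges:
            uv = tuple(sorted(pair))
            if len(uv) != 2:
                raise GraphError(f"self-loop at vertex {uv[0]} is not allowed")
            u, v = uv
            if not (0 <= u < self.num_vertices and 0 <= v < self.num_vertices):
                raise GraphError(f"edge ({u}, {v}) references a vertex outside 0..{self.num_vertices - 1}")
            g.add_edge(u, v)
        object.__setattr__(self, "trait", trait)
        object.__setattr__(self, "_nx", g)
        object.__setattr__(self, "_cache", {})
        if self.block_label is not None:
            bl = np.asarray(self.block_label, dtype=np.int64)
            if bl.shape != (self.num_vertices,):
                raise GraphError("block_label length must equal num_vertices")
            object.__setattr__(self, "block_label", bl)

    @classmethod
    def from_edges(
        cls,
        num_vertices: int,
        edges: Iterable[tuple[int, int]],
        trait: Sequence[int],
        block_label: Optional[Sequence[int]] = None,
    ) -> "PopulationGraph":
        pairs = set()
        for u, v in edges:
            if u == v:
                raise GraphError(f"self-loop at vertex {u} is not allowed")
            pairs.add(frozenset((int(u), int(v))))
        return cls(
            num_vertices=int(num_vertices),
            edges=frozenset(pairs),
            trait=np.asarray(trait),
            block_label=None if block_label is None else np.asarray(block_label),
        )

    @property
    def degrees(self) -> np.ndarray:
        """deg_G(i) for every vertex, as an integer array."""
        cache = self._cache
        if "degrees" not in cache:
            cache["degrees"] = np.array(
                [self._nx.degree(i) for i in range(self.num_vertices)], dtype=np.int64
            )
        return cache["degrees"]

    def neighbors(self, vertex: int) -> list[int]:
        return sorted(self._nx.neighbors(vertex))

    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened sorted adjacency lists with per-vertex offsets."""
        cache = self._cache
        if "csr" not in cache:
            neigh = [self.neighbors(v) for v in range(self.num_vertices)]
            offsets = np.zeros(self.num_vertices + 1, dtype=np.int64)
            offsets[1:] = np.cumsum([len(a) for a in neigh])
            flat = (
                np.concatenate([np.asarray(a, dtype=np.int64) for a in neigh])
                if offsets[-1]
                else np.arange(0)
            )
            cache["csr"] = (flat, offsets)
        return cache["csr"]

    def is_connected(self) -> bool:
        cache = self._cache
        if "connected" not in cache:
            cache["connected"] = self.num_vertices == 1 or nx.is_connected(self._nx)
        return cache["connected"]

    def require_connected(self) -> None:
        if not self.is_connected():
            raise GraphError(
                "population graph is disconnected; the random-walk model "
                "requires a connected graph"
            )

    @property
    def total_degree(self) -> int:
        """sum_j deg_G(j) = 2 |E|; the IPW normalising constant."""
        return 2 * self._nx.number_of_edges()

    @property
    def mu0(self) -> float:
        """True population mean mu_0 = (1/N) sum_i x(i)."""
        return float(self.trait.mean())

    @property
    def mu(self) -> float:
        """Walk-stationary trait mean mu = sum_i x(i) pi_i."""
        return float(self.trait @ stationary_distribution(self, check_connected=False))


@dataclass(frozen=True)
class TransitionKernel:
    """Random-walk transition matrix P(i, j) = 1/deg(i) on edges, else 0."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise GraphError("transition kernel must be a square matrix")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class SbmParams:
    """Stochastic block model with 2K equal blocks of ``block_size`` vertices.

    ``p_within`` is the edge probability inside a block, ``r_between``
    between distinct blocks.
    """

    half_blocks: int
    block_size: int
    p_within: float
    r_between: float

    def __post_init__(self) -> None:
        if self.half_blocks < 1:
            raise GraphError("half_blocks (K) must be a positive integer")
        if self.block_size < 1:
            raise GraphError("block_size must be a positive integer")
        for name, val in (("p_within", self.p_within), ("r_between", self.r_between)):
            if not 0.0 <= val <= 1.0:
                raise GraphError(f"{name}={val} is not a probability")

    @property
    def num_blocks(self) -> int:
        return 2 * self.half_blocks

    @property
    def num_vertices(self) -> int:
        return self.num_blocks * self.block_size


def symmetric_block_traits(params: SbmParams) -> Callable[[int], int]:
    """Default trait rule: the first K of the 2K blocks carry trait 1.

    Gives a population mean of exactly 1/2 with the trait aligned to block
    membership, the symmetric outcome regime of the SBM limit theorem.
    """

    def rule(block: int) -> int:
        return 1 if block < params.half_blocks else 0

    return rule


def make_sbm(
    params: SbmParams,
    trait_rule: Optional[Callable[[int], int]] = None,
    rng_seed: int = 0,
    trait_vector: Optional[Sequence[int]] = None,
    require_connected: bool = False,
    max_retries: int = 100,
) -> PopulationGraph:
    """Draw one SBM population graph.

    Each within-block vertex pair is an edge independently with probability
    ``p_within``; each between-block pair with probability ``r_between``.
    The trait of a vertex is ``trait_rule(block)`` (default: first half of
    the blocks trait 1), unless an explicit per-vertex ``trait_vector``
    overrides it.

    With ``require_connected=True`` the draw is repeated with fresh
    sub-seeds until connected (at most ``max_retries`` times); otherwise a
    disconnected draw is returned as-is and rejected later by walk-time
    checks.
    """
    if trait_rule is None and trait_vector is None:
        trait_rule = symmetric_block_traits(params)
    n = params.num_vertices
    blocks = np.repeat(np.arange(params.num_blocks), params.block_size)
    if trait_vector is not None:
        trait = np.asarray(trait_vector, dtype=np.int64)
        if trait.shape != (n,):
            raise GraphError(f"trait_vector must have length {n}")
    else:
        trait = np.array([trait_rule(b) for b in blocks], dtype=np.int64)

    root = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        rng = np.random.default_rng(root.integers(2**31))
        iu, ju = np.triu_indices(n, k=1)
        same_block = blocks[iu] == blocks[ju]
        prob = np.where(same_block, params.p_within, params.r_between)
        keep = rng.random(prob.shape) < prob
        edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
        graph = PopulationGraph.from_edges(n, edges, trait, block_label=blocks)
        if not require_connected or graph.is_connected():
            return graph
    raise GraphError(
        f"no connected SBM draw in {max_retries} attempts; "
        "increase edge probabilities or max_retries"
    )


def transition_kernel(graph: PopulationGraph) -> TransitionKernel:
    """Build P with P(i, j) = 1/deg(i) if {i, j} is an edge, else 0."""
    deg = graph.degrees
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise GraphError(f"vertex {int(isolated[0])} is isolated (degree 0)")
    n = graph.num_vertices
    p = np.zeros((n, n))
    for pair in graph.edges:
        u, v = tuple(pair)
        p[u, v] = 1.0 / deg[u]
        p[v, u] = 1.0 / deg[v]
    return TransitionKernel(matrix=p)


def stationary_distribution(graph: PopulationGraph, check_connected: bool = True) -> np.ndarray:
    """pi_i = deg(i) / sum_j deg(j), the degree-proportional sampling law."""
    if check_connected:
        graph.require_connected()
    deg = graph.degrees.astype(float)
    total = deg.sum()
    if total == 0:
        raise GraphError("graph has no edges; stationary distribution undefined")
    return deg / total


def tilde_p(params: SbmParams) -> float:
    """Mixing parameter p~ = p / {p + r(K-1)} of the 2K-block SBM."""
    denom = params.p_within + params.r_between * (params.half_blocks - 1)
    if denom <= 0:
        raise GraphError("p + r(K-1) must be positive to define p~")
    return params.p_within / denom


def below_threshold(params: SbmParams) -> bool:
    """Whether the SBM walk sits strictly below the critical threshold.

    The trait process of the walk obeys a central limit theorem when
    1/(2K) < p~ < 1/(2K) + 1/(2*sqrt(2)); both inequalities are strict, and
    the boundary counts as not below threshold.
    """
    k = params.half_blocks
    pt = tilde_p(params)
    lo = 1.0 / (2 * k)
    hi = lo + 1.0 / (2 * np.sqrt(2.0))
    return bool(lo < pt < hi)
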