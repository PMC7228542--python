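"""Simulation of the respondent-driven sampling process as a tree-indexed walk.

The observed RDS sample is a recruitment forest: k seed-rooted complete
m-ary trees of height h, so each tree has l = (m^{h+1} - 1)/(m - 1) nodes
and the sample size is n = k*l.  Node identities evolve as a Markov walk on
the population graph indexed by the tree: each seed's population member is
drawn from the stationary (degree-proportional) distribution, and each
recruit is drawn uniformly among its recruiter's neighbours, independently
per coupon slot and with replacement — the same contact can be recruited
several times.

Nodes are laid out deterministically: tree j occupies the id range
[j*l, (j+1)*l), breadth-first within the tree, so the children of any
internal node are computable from its id.  The bootstrap module exploits
this layout for vectorised resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .population_graph import GraphError, PopulationGraph, stationary_distribution

__all__ = [
    "ForestDesign",
    "RecruitmentForest",
    "ForestError",
    "tree_size",
    "simulate_forest",
    "forest_waves",
]


class ForestError(ValueError):
    """Raised for malformed recruitment forests or designs."""


@dataclass(frozen=True)
class ForestDesign:
    """Shape of a complete m-ary recruitment forest.

    ``num_seeds`` (k) trees, branching factor ``branching`` (m, the number
    of coupons each participant hands out), ``height`` (h) waves of
    recruitment below the seeds.
    """

    num_seeds: int
    branching: int
    height: int

    def __post_init__(self) -> None:
        if self.num_seeds < 1:
            raise ForestError("num_seeds (k) must be >= 1")
        if self.branching < 1:
            raise ForestError("branching (m) must be >= 1")
        if self.height < 0:
            raise ForestError("height (h) must be >= 0")

    @property
    def nodes_per_tree(self) -> int:
        return tree_size(self)

    @property
    def num_nodes(self) -> int:
        """Total sample size n = k * l."""
        return self.num_seeds * self.nodes_per_tree

    def wave_start(self, wave: int) -> int:
        """Within-tree offset of the first node of the given wave."""
        m = self.branching
        if m == 1:
            return wave
        return (m**wave - 1) // (m - 1)

    def wave_width(self, wave: int) -> int:
        return self.branching**wave


def tree_size(design: ForestDesign) -> int:
    """Nodes per tree, l = (m^{h+1} - 1)/(m - 1); l = h + 1 when m = 1."""
    m, h = design.branching, design.height
    if m == 1:
        return h + 1
    return (m ** (h + 1) - 1) // (m - 1)


@dataclass(frozen=True)
class RecruitmentForest:
    """An observed RDS sample: a complete m-ary forest of trait/degree records.

    Arrays are indexed by node id in the deterministic breadth-first
    layout.  ``member`` may be None when the forest was read from a file
    that did not record population identities; traits and degrees are
    always present, as in real RDS data.
    """

    design: ForestDesign
    trait: np.ndarray
    degree: np.ndarray
    member: Optional[np.ndarray] = None
    tree_id: np.ndarray = field(init=False, repr=False)
    wave: np.ndarray = field(init=False, repr=False)
    parent: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.design.num_nodes
        trait = np.asarray(self.trait, dtype=np.int64)
        degree = np.asarray(self.degree, dtype=np.int64)
        if trait.shape != (n,):
            raise ForestError(f"trait array has length {trait.shape}, expected {n}")
        if degree.shape != (n,):
            raise ForestError(f"degree array has length {degree.shape}, expected {n}")
        if not np.isin(trait, (0, 1)).all():
            raise ForestError("node traits must be 0 or 1")
        if (degree <= 0).any():
            bad = int(np.flatnonzero(degree <= 0)[0])
            raise ForestError(f"node {bad} has non-positive degree {int(degree[bad])}")
        object.__setattr__(self, "trait", trait)
        object.__setattr__(self, "degree", degree)
        if self.member is not None:
            member = np.asarray(self.member, dtype=np.int64)
            if member.shape != (n,):
                raise ForestError("member array length must equal n")
            object.__setattr__(self, "member", member)
        tree_id, wave, parent = _layout_arrays(self.design)
        object.__setattr__(self, "tree_id", tree_id)
        object.__setattr__(self, "wave", wave)
        object.__setattr__(self, "parent", parent)

    @property
    def num_nodes(self) -> int:
        return self.design.num_nodes

    def roots(self) -> np.ndarray:
        l = self.design.nodes_per_tree
        return np.arange(self.design.num_seeds) * l

    def children(self, node: int) -> np.ndarray:
        """Ids of the m children of an internal node (empty for leaves)."""
        d = self.design
        l = d.nodes_per_tree
        tree, pos = divmod(int(node), l)
        w = int(self.wave[node])
        if w >= d.height:
            return np.arange(0)
        rank = pos - d.wave_start(w)
        first = tree * l + d.wave_start(w + 1) + rank * d.branching
        return np.arange(first, first + d.branching)

    def validate_against_graph(self, graph: PopulationGraph) -> None:
        """Check member/trait/degree coherence and that recruitments follow edges."""
        if self.member is None:
            raise ForestError("forest carries no member ids to validate")
        deg = graph.degrees
        if not np.array_equal(self.trait, graph.trait[self.member]):
            raise ForestError("node traits do not match the graph's traits")
        if not np.array_equal(self.degree, deg[self.member]):
            raise ForestError("node degrees do not match the graph's degrees")
        for s in range(self.num_nodes):
            p = int(self.parent[s])
            if p < 0:
                continue
            u, v = int(self.member[p]), int(self.member[s])
            if v not in graph._nx[u]:
                raise ForestError(
                    f"node {s}: recruitment {u} -> {v} is not an edge of the graph"
                )


def _layout_arrays(design: ForestDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """tree_id, wave and parent arrays for the breadth-first layout."""
    l = design.nodes_per_tree
    k, m, h = design.num_seeds, design.branching, design.height
    wave_one = np.concatenate([np.full(design.wave_width(w), w) for w in range(h + 1)])
    parent_one = np.full(l, -1, dtype=np.int64)
    for w in range(1, h + 1):
        start, prev = design.wave_start(w), design.wave_start(w - 1)
        width = design.wave_width(w)
        parent_one[start : start + width] = prev + np.arange(width) // m
    tree_id = np.repeat(np.arange(k), l)
    wave = np.tile(wave_one, k)
    parent = np.concatenate([np.where(parent_one >= 0, parent_one + j * l, -1) for j in range(k)])
    return tree_id, wave, parent


def simulate_forest(
    graph: PopulationGraph,
    design: ForestDesign,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    seed_members: Optional[Sequence[int]] = None,
) -> RecruitmentForest:
    """Draw one recruitment forest from the tree-indexed walk on ``graph``.

    The k seed members are i.i.d. from the stationary distribution (or the
    caller-specified ``seed_members``, a convenience-seed mode for realism
    studies); every recruit is uniform over its recruiter's neighbours,
    independently per coupon slot, with replacement.
    """
    graph.require_connected()
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    pi = stationary_distribution(graph, check_connected=False)
    flat, offsets = graph.neighbor_csr()
    deg = offsets[1:] - offsets[:-1]

    k, m, h = design.num_seeds, design.branching, design.height
    l = design.nodes_per_tree
    member_waves = []
    if seed_members is not None:
        roots = np.asarray(seed_members, dtype=np.int64)
        if roots.shape != (k,):
            raise ForestError(f"seed_members must have length k={k}")
    else:
        roots = rng.choice(graph.num_vertices, size=k, p=pi)
    member_waves.append(roots)
    current = roots
    for _ in range(h):
        parents = np.repeat(current, m)
        picks = rng.integers(0, deg[parents])
        current = flat[offsets[parents] + picks]
        member_waves.append(current)

    # interleave waves back into the per-tree breadth-first layout
    member = np.empty(k * l, dtype=np.int64)
    for w, vals in enumerate(member_waves):
        width = design.wave_width(w)
        start = design.wave_start(w)
        block = vals.reshape(k, width)
        for j in range(k):
            member[j * l + start : j * l + start + width] = block[j]

    all_deg = graph.degrees
    return RecruitmentForest(
        design=design,
        trait=graph.trait[member],
        degree=all_deg[member],
        member=member,
    )


def forest_waves(forest: RecruitmentForest, wave: int) -> np.ndarray:
    """Node ids at the given recruitment depth (wave 0 = the k seeds)."""
    if not 0 <= wave <= forest.design.height:
        raise ForestError(
            f"wave {wave} out of range 0..{forest.design.height}"
        )
    return np.flatnonzero(forest.wave == wave)
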