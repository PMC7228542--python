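"""The tree bootstrap for respondent-driven samples.

One replicate is drawn by resampling the k seeds uniformly with
replacement, then recursively resampling each selected node's m recruits
uniformly with replacement, down to the leaves.  Because every tree is a
complete m-ary tree, a replicate always has exactly the shape of the
original forest — the number of sampled vertices never changes between
bootstrap samples.

Besides Monte Carlo replicate generation this module enumerates the exact
bootstrap distribution on small forests.  Counting order-distinguished
resampled trees, each seed tree admits a = f(h) of them, with f(0) = 1 and
f(d) = (m * f(d-1))^m, for a total of K = a*k across seeds.  Conditional on
the sample, the bootstrap mean is the average of k i.i.d. draws, each
uniform over the K (seed, resampled-tree) pairs:

    P(U = sum of traits over a resampled tree / l) = 1/K,

so the exact law of the bootstrap mean is the k-fold convolution of that
single-draw law.  Its mean is exactly the sample mean of the original
forest (the bootstrap mean is unbiased for X_bar), a property the test
suite checks by full enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import ipw_estimate, sample_mean, vh_estimate
from .rds_simulator import ForestDesign, ForestError, RecruitmentForest

__all__ = [
    "BootstrapForest",
    "ExactBootstrapDistribution",
    "BootstrapSummary",
    "tree_resample",
    "resample_origin_ids",
    "bootstrap_replicates",
    "exact_distribution",
    "per_tree_count",
    "bootstrap_variance",
    "bootstrap_ci",
]

ENUMERATION_GUARD = 10**7

_ALIASES = {
    "mean": "sample_mean",
    "sample_mean": "sample_mean",
    "ipw": "ipw",
    "vh": "volz_heckathorn",
    "volz_heckathorn": "volz_heckathorn",
}


def canonical_estimator(name: str) -> str:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown estimator {name!r}; expected one of {sorted(set(_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class BootstrapForest:
    """One tree-bootstrap replicate; ``origin`` maps nodes to source nodes."""

    forest: RecruitmentForest
    origin: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=np.int64)
        if origin.shape != (self.forest.num_nodes,):
            raise ForestError("origin array length must equal the forest size")
        object.__setattr__(self, "origin", origin)


@dataclass(frozen=True)
class ExactBootstrapDistribution:
    """Full enumeration of the bootstrap-mean law on a small forest."""

    per_seed_supports: list[np.ndarray]
    per_tree_count: int
    total_count: int
    support: np.ndarray
    probability: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.support @ self.probability)

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(((self.support - mu) ** 2) @ self.probability)


@dataclass(frozen=True)
class BootstrapSummary:
    """Replicate values and derived uncertainty summaries."""

    replicate_values: np.ndarray
    estimator_name: str
    point_estimate: float
    variance: Optional[float] = None
    interval: Optional[tuple[float, float]] = None
    method: Optional[str] = None

    @property
    def num_replicates(self) -> int:
        return len(self.replicate_values)


def per_tree_count(design: ForestDesign) -> int:
    """a = f(h): order-distinguished resampled trees per seed tree."""
    a = 1
    for _ in range(design.height):
        a = (design.branching * a) ** design.branching
    return a


def resample_origin_ids(
    forest: RecruitmentForest, num_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised resampling engine: (B, n) matrix of source node ids.

    Row b lists, in breadth-first wave order, the original node each node of
    replicate b maps to.  Column order within a row is irrelevant for the
    sum-based estimators this backs.
    """
    d = forest.design
    k, m, l = d.num_seeds, d.branching, d.nodes_per_tree
    B = num_replicates
    root_slots = rng.integers(0, k, size=(B, k))
    cur = root_slots * l  # origin ids of the replicate roots
    blocks = [cur]
    for w in range(d.height):
        ws, ws1 = d.wave_start(w), d.wave_start(w + 1)
        tree, pos = np.divmod(cur, l)
        base = tree * l + ws1 + (pos - ws) * m
        slot = rng.integers(0, m, size=(B, cur.shape[1] * m))
        cur = np.repeat(base, m, axis=1) + slot
        blocks.append(cur)
    return np.concatenate(blocks, axis=1)


def tree_resample(
    forest: RecruitmentForest,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BootstrapForest:
    """Draw a single tree-bootstrap replicate with explicit origin links."""
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    d = forest.design
    wave_blocks = []
    row = resample_origin_ids(forest, 1, rng)[0]
    # re-interleave the wave-ordered row into the per-tree layout
    offset = 0
    for w in range(d.height + 1):
        width = d.wave_width(w)
        wave_blocks.append(row[offset : offset + d.num_seeds * width].reshape(d.num_seeds, width))
        offset += d.num_seeds * width
    l = d.nodes_per_tree
    origin = np.empty(forest.num_nodes, dtype=np.int64)
    for w, block in enumerate(wave_blocks):
        start = d.wave_start(w)
        for j in range(d.num_seeds):
            origin[j * l + start : j * l + start + block.shape[1]] = block[j]
    rep = RecruitmentForest(
        design=d,
        trait=forest.trait[origin],
        degree=forest.degree[origin],
        member=None if forest.member is None else forest.member[origin],
    )
    return BootstrapForest(forest=rep, origin=origin)


def _replicate_estimates(
    forest: RecruitmentForest,
    estimator: str,
    ids: np.ndarray,
    total_degree: Optional[float],
    population_size: Optional[int],
) -> np.ndarray:
    trait = forest.trait.astype(float)
    deg = forest.degree.astype(float)
    if estimator == "sample_mean":
        return trait[ids].mean(axis=1)
    if estimator == "ipw":
        if total_degree is None or population_size is None:
            raise ValueError("ipw bootstrap requires total_degree and population_size")
        w = trait / deg
        return total_degree / population_size * w[ids].mean(axis=1)
    if estimator == "volz_heckathorn":
        num = (trait / deg)[ids].sum(axis=1)
        den = (1.0 / deg)[ids].sum(axis=1)
        return num / den
    raise ValueError(f"unknown estimator {estimator!r}")


def _point_estimate(
    forest: RecruitmentForest,
    estimator: str,
    total_degree: Optional[float],
    population_size: Optional[int],
) -> float:
    if estimator == "sample_mean":
        return sample_mean(forest).value
    if estimator == "ipw":
        return ipw_estimate(forest, total_degree, population_size).value
    return vh_estimate(forest).value


def bootstrap_replicates(
    forest: RecruitmentForest,
    estimator: str = "sample_mean",
    num_replicates: int = 2000,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    total_degree: Optional[float] = None,
    population_size: Optional[int] = None,
    chunk_size: int = 1 << 22,
) -> BootstrapSummary:
    """Generate B tree-bootstrap replicates of an estimator.

    The estimator is recomputed in full on each replicate's (trait, degree)
    records; no re-weighting shortcut is taken.  Replicates are generated in
    memory-bounded chunks from a single seeded stream: a given seed and
    chunk size reproduce bit-identical values (both have fixed defaults).
    """
    if num_replicates < 1:
        raise ValueError("need at least one replicate")
    estimator = canonical_estimator(estimator)
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    n = forest.num_nodes
    per_chunk = max(1, chunk_size // max(n, 1))
    out = np.empty(num_replicates)
    done = 0
    while done < num_replicates:
        b = min(per_chunk, num_replicates - done)
        ids = resample_origin_ids(forest, b, rng)
        out[done : done + b] = _replicate_estimates(
            forest, estimator, ids, total_degree, population_size
        )
        done += b
    return BootstrapSummary(
        replicate_values=out,
        estimator_name=estimator,
        point_estimate=_point_estimate(forest, estimator, total_degree, population_size),
    )


def _enumerate_subtree_sums(
    forest: RecruitmentForest, values: np.ndarray, node: int
) -> list[float]:
    """Sums over all order-distinguished resampled subtrees rooted at ``node``."""
    children = forest.children(node)
    if children.size == 0:
        return [values[node]]
    # each of the m coupon slots independently picks a child, then one of
    # that child's resampled subtrees
    slot_options: list[float] = []
    for c in children:
        slot_options.extend(_enumerate_subtree_sums(forest, values, int(c)))
    base = values[node]
    m = forest.design.branching
    return [base + sum(combo) for combo in itertools.product(slot_options, repeat=m)]


def exact_distribution(
    forest: RecruitmentForest,
    estimator: str = "sample_mean",
    total_degree: Optional[float] = None,
    population_size: Optional[int] = None,
    values: Optional[Sequence[float]] = None,
) -> ExactBootstrapDistribution:
    """Enumerate the exact bootstrap law of the mean-type estimator.

    Supported estimators are the sample mean and, by relabelling each node's
    trait to total_degree * X_s / (N * deg_s), the IPW estimator.  The
    Volz-Heckathorn ratio is not a per-node relabelling and has no exact
    enumeration here.  Enumeration is refused above ``ENUMERATION_GUARD``
    total resampled trees; use Monte Carlo replicates instead.
    """
    estimator = canonical_estimator(estimator)
    if values is not None:
        vals = np.asarray(values, dtype=float)
        if vals.shape != (forest.num_nodes,):
            raise ValueError("values must have one entry per forest node")
    elif estimator == "sample_mean":
        vals = forest.trait.astype(float)
    elif estimator == "ipw":
        if total_degree is None or population_size is None:
            raise ValueError("ipw enumeration requires total_degree and population_size")
        vals = total_degree * forest.trait / (population_size * forest.degree.astype(float))
    else:
        raise ValueError(
            "exact enumeration supports sample_mean and ipw (value-relabelled) only"
        )

    d = forest.design
    a = per_tree_count(d)
    total = a * d.num_seeds
    if total > ENUMERATION_GUARD:
        raise ValueError(
            f"{total} resampled trees exceed the enumeration guard "
            f"({ENUMERATION_GUARD}); use bootstrap_replicates (Monte Carlo)"
        )

    per_seed = []
    for root in forest.roots():
        sums = np.asarray(_enumerate_subtree_sums(forest, vals, int(root)))
        assert len(sums) == a
        per_seed.append(sums)

    # single-draw law: uniform over the K = a*k (seed, resampled tree) pairs
    draw_sums = np.concatenate(per_seed)
    sup, inv = np.unique(np.round(draw_sums, 12), return_inverse=True)
    probs = np.bincount(inv).astype(float) / total

    # bootstrap-mean law: k-fold convolution of the single-draw sum law
    conv_sup, conv_p = sup, probs
    for _ in range(d.num_seeds - 1):
        grid = conv_sup[:, None] + sup[None, :]
        pgrid = conv_p[:, None] * probs[None, :]
        conv_sup, inv = np.unique(np.round(grid.ravel(), 12), return_inverse=True)
        conv_p = np.zeros_like(conv_sup)
        np.add.at(conv_p, inv, pgrid.ravel())

    return ExactBootstrapDistribution(
        per_seed_supports=per_seed,
        per_tree_count=a,
        total_count=total,
        support=conv_sup / forest.num_nodes,
        probability=conv_p,
    )


def bootstrap_variance(summary: BootstrapSummary) -> float:
    """sigma^2_{B,n}: population-style (1/B) variance of the replicates.

    The 1/B normalisation matches the exact-enumeration limit without a
    finite-B correction.
    """
    if summary.num_replicates < 2:
        raise ValueError("variance requires at least two replicates")
    return float(np.var(summary.replicate_values))


def bootstrap_ci(
    summary: BootstrapSummary, level: float = 0.95, method: str = "percentile"
) -> BootstrapSummary:
    """Attach a confidence interval to a replicate summary.

    ``percentile``: empirical (alpha/2, 1-alpha/2) quantiles of the
    replicates with linear interpolation.  ``normal``: point estimate
    +/- z_{1-alpha/2} * sqrt(bootstrap variance).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    alpha = 1.0 - level
    var = bootstrap_variance(summary)
    if method == "percentile":
        lo, hi = np.quantile(
            summary.replicate_values, [alpha / 2, 1 - alpha / 2], method="linear"
        )
    elif method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        lo, hi = summary.point_estimate - half, summary.point_estimate + half
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return replace(summary, variance=var, interval=(float(lo), float(hi)), method=method)
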