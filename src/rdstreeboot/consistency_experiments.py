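"""Empirical consistency study for the tree bootstrap.

The bootstrap is consistent when, conditional on the sample, the law of
sqrt(n) * (X_bar* - X_bar) approaches the sampling law of
sqrt(n) * (X_bar - mu) in the Kolmogorov (sup-CDF) metric as the design
grows with l = o(sqrt(n)) and l -> infinity, below the SBM critical
threshold.  "Almost sure" convergence is not testable; the empirical
surrogate exercised here is a fixed-seed multi-stage trend: across a
schedule of growing designs the median Kolmogorov distance (over repeated
samples) shrinks, the spread of the scaled bootstrap variance n * sigma^2
tightens around the sampling variance rho^2, and bootstrap confidence
interval coverage approaches its nominal level.

The default schedule grows k = l^2 (so l/sqrt(n) = l^{-1/2} -> 0), one
admissible choice among many; both l and k increase along it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .population_graph import (
    PopulationGraph,
    SbmParams,
    below_threshold,
    make_sbm,
    stationary_distribution,
)
from .rds_simulator import ForestDesign, simulate_forest, tree_size
from .tree_bootstrap import (
    bootstrap_ci,
    bootstrap_replicates,
    bootstrap_variance,
    canonical_estimator,
)
from .estimators import ipw_estimate, sample_mean, vh_estimate

__all__ = [
    "GrowthSchedule",
    "StageRecord",
    "ExperimentResult",
    "ExperimentConfig",
    "kolmogorov_distance",
    "make_schedule",
    "sampling_distribution",
    "run_consistency_experiment",
]

logger = logging.getLogger("rdstreeboot")


def kolmogorov_distance(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Sup-distance between the empirical CDFs of two samples.

    Both EDFs are right-continuous; the supremum of |F_a - F_b| is attained
    at a jump point, so it suffices to scan the pooled sample values.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(fa - fb).max())


@dataclass(frozen=True)
class GrowthSchedule:
    """A sequence of forest designs with l increasing and l/sqrt(n) decreasing."""

    branching: int
    stages: tuple[tuple[int, int], ...]  # (height h_t, seeds k_t)
    rule: str = "custom"

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a growth schedule needs at least two stages")
        ls, ratios = [], []
        for h, k in self.stages:
            d = ForestDesign(num_seeds=k, branching=self.branching, height=h)
            ls.append(d.nodes_per_tree)
            ratios.append(d.nodes_per_tree / np.sqrt(d.num_nodes))
        if not all(x < y for x, y in zip(ls, ls[1:])):
            raise ValueError("tree size l must increase strictly along the schedule")
        if not all(x > y for x, y in zip(ratios, ratios[1:])):
            raise ValueError(
                "l/sqrt(n) must decrease strictly along the schedule "
                "(the growing-design condition l = o(sqrt(n)))"
            )

    def designs(self) -> list[ForestDesign]:
        return [
            ForestDesign(num_seeds=k, branching=self.branching, height=h)
            for h, k in self.stages
        ]


def make_schedule(
    branching: int,
    num_stages: int,
    rule: str = "k_eq_l_squared",
    custom_stages: Optional[Sequence[tuple[int, int]]] = None,
) -> GrowthSchedule:
    """Build a growth schedule.

    The default ``k_eq_l_squared`` rule sets h_t = t and k_t = l_t^2 for
    t = 1..num_stages, which makes l/sqrt(n) = 1/sqrt(l) strictly
    decreasing.
    """
    if rule == "k_eq_l_squared":
        stages = []
        for t in range(1, num_stages + 1):
            l = tree_size(ForestDesign(1, branching, t))
            stages.append((t, l * l))
        return GrowthSchedule(branching=branching, stages=tuple(stages), rule=rule)
    if rule == "custom":
        if custom_stages is None:
            raise ValueError("custom rule requires custom_stages")
        return GrowthSchedule(branching=branching, stages=tuple(custom_stages), rule=rule)
    raise ValueError(f"unknown schedule rule {rule!r}")


def _target_mean(graph: PopulationGraph, estimator: str) -> float:
    """mu for the sample mean; mu_0 for the degree-weighted estimators."""
    if estimator == "sample_mean":
        return graph.mu
    return graph.mu0


def _estimate(graph: PopulationGraph, forest, estimator: str) -> float:
    if estimator == "sample_mean":
        return sample_mean(forest).value
    if estimator == "ipw":
        return ipw_estimate(forest, graph.total_degree, graph.num_vertices).value
    return vh_estimate(forest).value


def sampling_distribution(
    graph: PopulationGraph,
    design: ForestDesign,
    estimator: str = "sample_mean",
    reps: int = 2000,
    rng_seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Monte Carlo draw of the centred, sqrt(n)-scaled sampling law.

    Returns ``reps`` independent values of sqrt(n) * (estimate - target),
    the law that a consistent bootstrap must reproduce.
    """
    if reps < 2:
        raise ValueError("need at least two replications")
    estimator = canonical_estimator(estimator)
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    target = _target_mean(graph, estimator)
    root_n = np.sqrt(design.num_nodes)
    vals = np.empty(reps)
    for i in range(reps):
        forest = simulate_forest(graph, design, rng=rng)
        vals[i] = root_n * (_estimate(graph, forest, estimator) - target)
    return vals


@dataclass(frozen=True)
class StageRecord:
    stage: int
    n: int
    k: int
    h: int
    l: int
    ks_median: float
    coverage: float
    scaled_var_median: float
    scaled_var_iqr: float
    rho2_hat: float


@dataclass(frozen=True)
class ExperimentResult:
    stages: tuple[StageRecord, ...]
    below_threshold: bool
    warning: Optional[str] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "n": s.n,
                    "k": s.k,
                    "h": s.h,
                    "l": s.l,
                    "ks_median": s.ks_median,
                    "coverage": s.coverage,
                    "scaled_var_median": s.scaled_var_median,
                    "rho2_hat": s.rho2_hat,
                }
                for s in self.stages
            ]
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one consistency study."""

    sbm: SbmParams = field(
        default_factory=lambda: SbmParams(
            half_blocks=2, block_size=50, p_within=0.3, r_between=0.2
        )
    )
    schedule: Optional[GrowthSchedule] = None
    estimator: str = "sample_mean"
    num_samples: int = 200  # R: sampled forests per stage
    sampling_reps: int = 2000  # Monte Carlo size of the reference sampling law
    num_boot: int = 2000  # B: bootstrap replicates per sampled forest
    level: float = 0.95
    ci_method: str = "percentile"
    rng_seed: int = 0
    graph_seed: Optional[int] = None  # overrides the seed derived from rng_seed
    require_connected: bool = True
    trait_rule: Optional[Callable[[int], int]] = None  # block -> {0,1}; default symmetric

    def resolved_schedule(self) -> GrowthSchedule:
        return self.schedule if self.schedule is not None else make_schedule(2, 2)


def run_consistency_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the multi-stage bootstrap-consistency study.

    Per stage: draw the reference sampling law by Monte Carlo; then for each
    of R fresh samples run the bootstrap, record the Kolmogorov distance of
    the centred bootstrap law to the reference, whether the CI covers the
    target, and the scaled bootstrap variance n * sigma^2.  Medians and the
    coverage fraction are aggregated per stage.
    """
    estimator = canonical_estimator(config.estimator)
    schedule = config.resolved_schedule()
    ss = np.random.SeedSequence(config.rng_seed)
    graph_seed, *stage_seeds = ss.spawn(1 + len(schedule.stages))
    if config.graph_seed is not None:
        sbm_seed = config.graph_seed
    else:
        sbm_seed = int(graph_seed.generate_state(1)[0] % 2**31)
    graph = make_sbm(
        config.sbm,
        trait_rule=config.trait_rule,
        rng_seed=sbm_seed,
        require_connected=config.require_connected,
    )
    graph.require_connected()
    below = below_threshold(config.sbm)
    warning = None
    if not below:
        warning = (
            "SBM parameters are not below the critical threshold; the "
            "consistency guarantee does not apply to this configuration"
        )
        logger.warning(warning)
    target = _target_mean(graph, estimator)

    records = []
    for t, (design, stage_ss) in enumerate(zip(schedule.designs(), stage_seeds), start=1):
        t0 = time.monotonic()
        rng = np.random.default_rng(stage_ss)
        n = design.num_nodes
        root_n = np.sqrt(n)
        reference = sampling_distribution(
            graph, design, estimator, reps=config.sampling_reps, rng=rng
        )
        rho2_hat = float(np.var(reference))

        distances = np.empty(config.num_samples)
        scaled_vars = np.empty(config.num_samples)
        covered = np.zeros(config.num_samples, dtype=bool)
        for i in range(config.num_samples):
            forest = simulate_forest(graph, design, rng=rng)
            summ = bootstrap_replicates(
                forest,
                estimator,
                num_replicates=config.num_boot,
                rng=rng,
                total_degree=graph.total_degree,
                population_size=graph.num_vertices,
            )
            centred = root_n * (summ.replicate_values - summ.point_estimate)
            distances[i] = kolmogorov_distance(centred, reference)
            scaled_vars[i] = n * bootstrap_variance(summ)
            ci = bootstrap_ci(summ, level=config.level, method=config.ci_method)
            covered[i] = ci.interval[0] <= target <= ci.interval[1]

        q25, q75 = np.quantile(scaled_vars, [0.25, 0.75])
        rec = StageRecord(
            stage=t,
            n=n,
            k=design.num_seeds,
            h=design.height,
            l=design.nodes_per_tree,
            ks_median=float(np.median(distances)),
            coverage=float(covered.mean()),
            scaled_var_median=float(np.median(scaled_vars)),
            scaled_var_iqr=float(q75 - q25),
            rho2_hat=rho2_hat,
        )
        records.append(rec)
        logger.info(
            "stage %d: n=%d k=%d h=%d | ks_median=%.4f coverage=%.3f "
            "scaled_var_median=%.4f rho2_hat=%.4f (%.1fs)",
            t, n, design.num_seeds, design.height,
            rec.ks_median, rec.coverage, rec.scaled_var_median, rho2_hat,
            time.monotonic() - t0,
        )

    return ExperimentResult(stages=tuple(records), below_threshold=below, warning=warning)
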