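"""Point estimators for respondent-driven samples.

Three estimators of a binary-trait prevalence are covered, all computed
from the (trait, degree) records of the recruitment forest alone:

* the sample mean X_bar = (1/n) sum_s X_s, unbiased for the walk-stationary
  mean mu = sum_i x(i) pi_i;
* the inverse-probability-weighted (Horvitz-Thompson) estimator
  mu_IPW = (sum_j deg(j) / (n N)) * sum_s X_s / deg(W_s), unbiased for the
  population mean mu_0 but requiring the total-degree normalising constant;
* the Volz-Heckathorn (Hajek) estimator, the self-normalising ratio
  (sum_s X_s/deg_s) / (sum_s 1/deg_s), which needs no normalising constant.

The pi-transform x^pi(i) = x(i) / (pi_i N) links the first two: the sample
mean of the transformed values is exactly the IPW estimator, which is how
sample-mean asymptotics transfer to IPW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rds_simulator import RecruitmentForest

__all__ = [
    "EstimateResult",
    "sample_mean",
    "ipw_estimate",
    "vh_estimate",
    "pi_transform",
    "ESTIMATOR_NAMES",
]

ESTIMATOR_NAMES = ("sample_mean", "ipw", "volz_heckathorn")


@dataclass(frozen=True)
class EstimateResult:
    estimator_name: str
    value: float
    normalizer: Optional[float] = None

    def __post_init__(self) -> None:
        if self.estimator_name not in ESTIMATOR_NAMES:
            raise ValueError(f"unknown estimator {self.estimator_name!r}")
        if self.normalizer is not None and self.normalizer <= 0:
            raise ValueError("normalizer must be positive when present")


def sample_mean(forest: RecruitmentForest) -> EstimateResult:
    """X_bar = (1/n) sum over all forest nodes of the binary trait."""
    if forest.num_nodes == 0:
        raise ValueError("empty forest")
    return EstimateResult("sample_mean", float(forest.trait.mean()))


def ipw_estimate(
    forest: RecruitmentForest, total_degree: float, population_size: int
) -> EstimateResult:
    """Horvitz-Thompson estimate of mu_0 with known total degree.

    value = (total_degree / (n N)) * sum_s X_s / deg(W_s).  The caller
    supplies total_degree = sum_j deg_G(j); no estimation of it is
    attempted (known-normaliser regime).
    """
    if total_degree <= 0:
        raise ValueError("total_degree must be positive")
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    n = forest.num_nodes
    weighted = float((forest.trait / forest.degree).sum())
    value = total_degree / (n * population_size) * weighted
    return EstimateResult("ipw", value, normalizer=float(total_degree))


def vh_estimate(forest: RecruitmentForest) -> EstimateResult:
    """Volz-Heckathorn (Hajek) estimate: inverse-degree-weighted trait ratio.

    value = sum_s X_s/deg_s / sum_s 1/deg_s = (1/(nH)) sum_s X_s/deg_s with
    H = (1/n) sum_s 1/deg_s reported as the normaliser.  Degrees are those
    of the sampled members (their reported network sizes).
    """
    n = forest.num_nodes
    inv = 1.0 / forest.degree
    h = float(inv.mean())
    value = float((forest.trait * inv).sum()) / (n * h)
    return EstimateResult("volz_heckathorn", value, normalizer=h)


def pi_transform(trait: float, sampling_prob: float, population_size: int) -> float:
    """x^pi = x / (pi N): reweights a trait so its sample mean is the IPW value."""
    if sampling_prob <= 0:
        raise ValueError("sampling_prob must be positive")
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    return trait / (sampling_prob * population_size)
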