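"""Mating-system model comparison and effective-population-size arithmetic.

This module consumes maximum log-likelihoods of competing mating-system
models (monogamy, polygyny-or-polyandry, polygamy) — e.g. from a sibship
reconstruction program — and computes Bayes factors and posterior
probabilities under equal priors.  It also converts the mutation-scaled
coalescent parameter theta into effective population size via
theta = 4*Ne*mu, and Ne into a census size via an Ne:N ratio.

The Bayes factor convention is BF_m = 2*(logL_m - max logL), with natural
logs, so the best model has BF 0 and models with BF below -2 are
considered significantly worse fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BF_SIGNIFICANCE = -2.0


@dataclass(frozen=True)
class ModelLikelihood:
    model: str
    log_likelihood: float  # natural log

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_likelihood):
            raise ValueError(f"{self.model}: log-likelihood must be finite")


def bayes_factors(models: list[ModelLikelihood]) -> pd.DataFrame:
    """Per-model log Bayes factor vs the best model, BF = 2*delta logL.

    Returns a table with columns model, log_likelihood, bayes_factor and
    significantly_worse (BF < -2)."""
    if len(models) < 2:
        raise ValueError("need >=2 models")
    best = max(m.log_likelihood for m in models)
    rows = [
        {
            "model": m.model,
            "log_likelihood": m.log_likelihood,
            "bayes_factor": 2.0 * (m.log_likelihood - best),
        }
        for m in models
    ]
    table = pd.DataFrame(rows)
    table["significantly_worse"] = table["bayes_factor"] < BF_SIGNIFICANCE
    return table


def model_posteriors(
    models: list[ModelLikelihood], bf_precision: int | None = None
) -> pd.DataFrame:
    """Posterior model probabilities under equal priors:
    exp(BF_m) / sum exp(BF_m').

    ``bf_precision`` rounds the Bayes factors to that many decimals before
    exponentiating — the convention of published model-comparison tables
    whose posterior column is derived from the printed (rounded) BF column
    rather than the unrounded log-likelihoods.
    """
    table = bayes_factors(models)
    bf = table["bayes_factor"].to_numpy()
    if bf_precision is not None:
        bf = np.round(bf, bf_precision)
    weights = np.exp(bf)
    table["posterior"] = weights / weights.sum()
    return table


def theta_to_ne(theta: float, mu: float) -> float:
    """Ne = theta / (4*mu); mu is the per-locus per-generation mutation
    rate."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (4.0 * mu)


def ne_to_theta(ne: float, mu: float) -> float:
    """Inverse of :func:`theta_to_ne`."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return 4.0 * ne * mu


def ne_to_census(ne: float, ratio: float = 10.0) -> float:
    """Census size from effective size (default Ne:N ratio 1:10)."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ne < 0:
        raise ValueError("ne must be non-negative")
    return ratio * ne
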