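"""One-way deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full model at the low and high bound of each declared
parameter range (all else held at base) and records the incremental net
monetary benefit of a comparison strategy versus a reference — the tornado
diagram's bars.  Derived parameters (weight complements, composed upfront
costs, schedules filled from scalars) are re-derived after each assignment so
a varied fraction never breaks the sum-to-one invariant.

The PSA draws each parameter from its declared distribution: beta for
quantities on [0, 1] and gamma for costs, both moment-matched so the base
value is the mean and the declared bounds span a 95% range
(sd = (high - low) / (2 * 1.96)); uniform on its support; "fixed" passes the
base through.  When the implied sd is infeasible for the family the draw
falls back to uniform on the bounds with a logged warning.  Draws are
consumed in the order distributions are declared, so a run is reproducible
given (spec, n, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from adtcea.cea_stats import nmb
from adtcea.markov_engine import evaluate_strategy
from adtcea.model_spec import (
    ModelSpec,
    ParamDistribution,
    SpecValidationError,
    apply_derived_params,
    set_path,
    validate_spec,
)

__all__ = ["TornadoEntry", "PSAResult", "one_way_dsa", "sample_psa_spec", "run_psa", "ceac"]

logger = logging.getLogger(__name__)


@dataclass
class TornadoEntry:
    """One bar of the tornado: incremental NMB at each bound of one range."""

    param_path: str
    low_value: float
    high_value: float
    inmb_at_low: float
    inmb_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.inmb_at_high - self.inmb_at_low)


@dataclass
class PSAResult:
    """Monte-Carlo sample set: per-draw cost and QALYs for every strategy.

    ``costs`` and ``qalys`` have shape (n, n_strategies), columns ordered as
    ``strategy_names``.
    """

    strategy_names: list[str]
    costs: np.ndarray
    qalys: np.ndarray
    seed: int
    n: int

    def column(self, strategy_name: str) -> int:
        return self.strategy_names.index(strategy_name)


def _evaluate_inmb(spec: ModelSpec, comparison: tuple[str, str], wtp: float | None) -> float:
    strat = evaluate_strategy(spec.strategy(comparison[0]), spec)
    ref = evaluate_strategy(spec.strategy(comparison[1]), spec)
    w = spec.econ.wtp if wtp is None else wtp
    return nmb(strat, w) - nmb(ref, w)


def one_way_dsa(
    spec: ModelSpec,
    comparison: tuple[str, str],
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """Tornado entries for every declared DSA range, sorted by spread.

    For each range the model is re-evaluated with that one parameter at its
    low and then high bound; the entry records the incremental NMB of
    ``comparison[0]`` versus ``comparison[1]`` at each bound.  ``wtp=None``
    uses the (possibly varied) spec's own threshold, so a WTP range in the
    DSA behaves as expected.
    """
    if not spec.dsa_ranges:
        raise ValueError("spec declares no DSA ranges")
    spec.strategy(comparison[0])
    spec.strategy(comparison[1])
    entries = []
    for rng in spec.dsa_ranges:
        inmbs = []
        for bound in (rng.low, rng.high):
            varied = spec.copy()
            set_path(varied, rng.param_path, bound)
            apply_derived_params(varied)
            violations = validate_spec(varied)
            if violations:
                raise SpecValidationError(violations)
            inmbs.append(_evaluate_inmb(varied, comparison, wtp))
        entries.append(
            TornadoEntry(
                param_path=rng.param_path,
                low_value=rng.low,
                high_value=rng.high,
                inmb_at_low=inmbs[0],
                inmb_at_high=inmbs[1],
            )
        )
    entries.sort(key=lambda e: -e.spread)
    return entries


def _draw(dist: ParamDistribution, rng: np.random.Generator) -> float:
    lo, hi = dist.bound_low, dist.bound_high
    m = dist.base
    if dist.family == "fixed" or hi == lo:
        return m
    if dist.family == "uniform":
        return float(rng.uniform(lo, hi))
    sd = (hi - lo) / (2.0 * 1.96)
    if dist.family == "beta":
        var = sd * sd
        if 0.0 < m < 1.0 and var < m * (1.0 - m):
            nu = m * (1.0 - m) / var - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        logger.warning(
            "beta moment match infeasible for %s (mean %g, sd %g); "
            "falling back to uniform on bounds",
            dist.param_path, m, sd,
        )
        return float(rng.uniform(lo, hi))
    if dist.family == "gamma":
        if m > 0.0:
            shape = (m / sd) ** 2
            scale = sd * sd / m
            return float(rng.gamma(shape, scale))
        logger.warning(
            "gamma moment match infeasible for %s (mean %g); "
            "falling back to uniform on bounds",
            dist.param_path, m,
        )
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown distribution family {dist.family!r}")


def sample_psa_spec(spec: ModelSpec, rng_seed: int | np.random.Generator) -> ModelSpec:
    """One PSA draw: a sampled copy of the spec with derived params re-applied."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sampled = spec.copy()
    for dist in spec.psa_distributions:
        set_path(sampled, dist.param_path, _draw(dist, rng))
    apply_derived_params(sampled)
    return sampled


def run_psa(spec: ModelSpec, n: int, seed: int) -> PSAResult:
    """Evaluate every strategy on ``n`` independent sampled specs.

    Reproducible given (spec, n, seed): a single seeded generator drives all
    draws, consumed in declaration order within each draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = [s.name for s in spec.strategies]
    costs = np.empty((n, len(names)))
    qalys = np.empty((n, len(names)))
    for d in range(n):
        try:
            sampled = sample_psa_spec(spec, rng)
            for j, strat in enumerate(sampled.strategies):
                res = evaluate_strategy(strat, sampled)
                costs[d, j] = res.cost
                qalys[d, j] = res.qaly
        except Exception as exc:
            raise RuntimeError(f"PSA draw {d} failed: {exc}") from exc
    return PSAResult(strategy_names=names, costs=costs, qalys=qalys, seed=seed, n=n)


def ceac(
    psa: PSAResult,
    comparison: tuple[str, str],
    wtp_grid: list[float],
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve for a pairwise comparison.

    For each WTP, the fraction of draws in which the incremental NMB of
    ``comparison[0]`` versus ``comparison[1]`` is strictly positive (ties
    count as not cost-effective).
    """
    if psa.n < 1:
        raise ValueError("empty PSA result")
    a = psa.column(comparison[0])
    b = psa.column(comparison[1])
    d_cost = psa.costs[:, a] - psa.costs[:, b]
    d_qaly = psa.qalys[:, a] - psa.qalys[:, b]
    return [
        (float(w), float(np.mean(w * d_qaly - d_cost > 0.0))) for w in wtp_grid
    ]
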