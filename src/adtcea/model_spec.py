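"""Model specification: the typed parameterization every other module consumes.

A :class:`ModelSpec` fully describes one cost-effectiveness analysis: the
treatment strategies (each a mixture of homogeneous sub-cohort *arms*), the
economic inputs (costs, utilities, discount rate, willingness-to-pay), the
shared mortality process, run settings (horizon, cycle length, half-cycle
correction), and the parameter ranges/distributions used by the sensitivity
analyses.

Specs serialize to a documented YAML/JSON schema (see ``adtcea/data/
model_spec.schema.json`` and docs/methods.md).  Sensitivity analyses address
individual parameters through dotted paths such as ``econ.utility_on_adt`` or
``strategies[2].components[0].weight``; quantities that must co-vary (mixture
weights and their complements, upfront costs assembled from shared drug/test
prices, schedules filled from a scalar per-cycle probability) are re-derived
after every assignment via :class:`DerivedParam` rules, so one-way and
probabilistic analyses can never break the sum-to-one or cost-composition
invariants.
"""

from __future__ import annotations

import copy
import functools
import json
import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "Arm",
    "StrategyComponent",
    "Strategy",
    "EconomicInputs",
    "MortalityInputs",
    "ParamDistribution",
    "DSARange",
    "DerivedParam",
    "ModelSpec",
    "Violation",
    "SpecValidationError",
    "get_path",
    "set_path",
    "apply_derived_params",
    "validate_spec",
    "load_model_spec",
    "write_model_spec",
    "schema_path",
]

WEIGHT_TOL = 1e-9


class HealthState(IntEnum):
    """The four Markov health states.

    ``STABLE_ON_ADT`` is enterable only at model start and is occupied for at
    most one cycle (the ADT utility decrement lasts one year); the transition
    engine moves its survivors to ``STABLE_OFF_ADT``.  ``DEAD`` is absorbing.
    """

    STABLE_ON_ADT = 0
    STABLE_OFF_ADT = 1
    METASTATIC = 2
    DEAD = 3


N_STATES = len(HealthState)


@dataclass
class Arm:
    """One homogeneous sub-cohort, e.g. "biomarker-positive, receives ADT".

    Parameters
    ----------
    id
        Text label, unique within a strategy.
    receives_adt
        Whether this sub-cohort starts on ADT (enters in ``STABLE_ON_ADT``
        and carries the on-ADT utility for its first cycle).
    p_metastasis
        Per-cycle probability of developing metastatic disease, length equal
        to the model horizon.
    upfront_cost
        One-time cycle-0 cost in USD: biomarker test price (if tested) plus
        the ADT course drug/administration cost (if treated).  Applied
        undiscounted.
    """

    id: str
    receives_adt: bool
    p_metastasis: list[float]
    upfront_cost: float = 0.0


@dataclass
class StrategyComponent:
    weight: float
    arm: Arm


@dataclass
class Strategy:
    """A treatment policy: a probability mixture over arms (weights sum to 1)."""

    name: str
    components: list[StrategyComponent]


@dataclass
class EconomicInputs:
    """Costs (USD), utility weights, discount rate and WTP threshold.

    Utilities are QALY weights in [0, 1]; being on ADT cannot improve
    quality of life, so ``utility_on_adt <= utility_off_adt``.
    """

    cost_metastatic: float
    cost_eol_cancer: float
    cost_eol_noncancer: float
    utility_on_adt: float
    utility_off_adt: float
    utility_metastatic: float
    discount_rate: float = 0.03
    wtp: float = 100_000.0


@dataclass
class MortalityInputs:
    """The death process shared by all strategies (equal overall survival).

    ``p_death_other`` is the per-cycle other-cause death probability (from a
    life table starting at the cohort entry age); ``p_death_metastatic_excess``
    is the additional per-cycle cancer death probability applied in the
    metastatic state.
    """

    p_death_other: list[float]
    p_death_metastatic_excess: list[float]


@dataclass
class ParamDistribution:
    """PSA sampling rule for one parameter.

    family "beta" (quantities in [0, 1]) and "gamma" (non-negative costs) are
    moment-matched: mean = ``base``, sd = (bound_high - bound_low) / (2 * 1.96),
    i.e. the bounds are read as a 95% range.  "uniform" samples the support
    directly; "fixed" passes ``base`` through.
    """

    param_path: str
    family: str
    base: float
    bound_low: float
    bound_high: float


@dataclass
class DSARange:
    """One-way sensitivity range: the parameter is set to ``low`` then ``high``."""

    param_path: str
    low: float
    high: float


@dataclass
class DerivedParam:
    """A parameter whose value is recomputed from others after any assignment.

    kind "complement": ``target`` must be a component weight; it is set to one
    minus the sum of its sibling component weights.  kind "sum": ``target`` is
    set to the sum of the values at ``sources``.  kind "difference":
    ``target`` is set to ``sources[0] - sources[1]``.  kind "fill":
    ``target`` must be a per-cycle schedule; every entry is set to the scalar
    at ``sources[0]``.
    """

    target: str
    kind: str
    sources: list[str] = field(default_factory=list)


@dataclass
class ModelSpec:
    """Complete parameterization of one analysis run."""

    strategies: list[Strategy]
    econ: EconomicInputs
    mortality: MortalityInputs
    horizon: int = 15
    cycle_length: float = 1.0
    half_cycle_correction: bool = True
    params: dict[str, float] = field(default_factory=dict)
    derived_params: list[DerivedParam] = field(default_factory=list)
    dsa_ranges: list[DSARange] = field(default_factory=list)
    psa_distributions: list[ParamDistribution] = field(default_factory=list)

    def copy(self) -> "ModelSpec":
        """Copy deep enough for sensitivity analyses to mutate safely.

        Arms, economics, mortality schedules and the params mapping are
        copied; the DSA/PSA/derived declarations (never mutated by the
        analyses) are shared.
        """
        return ModelSpec(
            strategies=[
                Strategy(
                    s.name,
                    [
                        StrategyComponent(
                            c.weight,
                            Arm(
                                c.arm.id,
                                c.arm.receives_adt,
                                list(c.arm.p_metastasis),
                                c.arm.upfront_cost,
                            ),
                        )
                        for c in s.components
                    ],
                )
                for s in self.strategies
            ],
            econ=copy.copy(self.econ),
            mortality=MortalityInputs(
                list(self.mortality.p_death_other),
                list(self.mortality.p_death_metastatic_excess),
            ),
            horizon=self.horizon,
            cycle_length=self.cycle_length,
            half_cycle_correction=self.half_cycle_correction,
            params=dict(self.params),
            derived_params=list(self.derived_params),
            dsa_ranges=list(self.dsa_ranges),
            psa_distributions=list(self.psa_distributions),
        )

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def to_dict(self) -> dict:
        return _to_dict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return _spec_from_dict(data)


# ---------------------------------------------------------------------------
# Dotted-path addressing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)|\[(\d+)\]|\.")


@functools.lru_cache(maxsize=4096)
def _tokenize(path: str) -> tuple[str | int, ...]:
    tokens: list[str | int] = []
    pos = 0
    while pos < len(path):
        m = _TOKEN_RE.match(path, pos)
        if m is None:
            raise ValueError(f"malformed parameter path {path!r} at position {pos}")
        if m.group(1) is not None:
            tokens.append(m.group(1))
        elif m.group(2) is not None:
            tokens.append(int(m.group(2)))
        pos = m.end()
    if not tokens:
        raise ValueError(f"empty parameter path {path!r}")
    return tuple(tokens)


def _step(obj: Any, token: str | int, path: str) -> Any:
    try:
        if isinstance(token, int):
            return obj[token]
        if isinstance(obj, dict):
            return obj[token]
        return getattr(obj, token)
    except (AttributeError, KeyError, IndexError, TypeError) as exc:
        raise KeyError(f"parameter path {path!r} does not resolve: {exc}") from None


def get_path(spec: Any, path: str) -> Any:
    """Resolve a dotted parameter path (e.g. ``"econ.wtp"``) on a spec."""
    obj = spec
    for token in _tokenize(path):
        obj = _step(obj, token, path)
    return obj


def set_path(spec: Any, path: str, value: Any) -> None:
    """Assign ``value`` at a dotted parameter path on a spec, in place."""
    tokens = _tokenize(path)
    obj = spec
    for token in tokens[:-1]:
        obj = _step(obj, token, path)
    last = tokens[-1]
    _step(obj, last, path)  # existence check; raises KeyError if absent
    if isinstance(last, int) or isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


def apply_derived_params(spec: ModelSpec) -> None:
    """Recompute every derived parameter, in declaration order, in place."""
    for rule in spec.derived_params:
        if rule.kind == "complement":
            tokens = _tokenize(rule.target)
            if len(tokens) < 3 or tokens[-1] != "weight" or tokens[-3] != "components":
                raise ValueError(
                    f"complement target {rule.target!r} must address a component weight"
                )
            strategy_path_tokens = tokens[:-3]
            strat = spec
            for t in strategy_path_tokens:
                strat = _step(strat, t, rule.target)
            j = tokens[-2]
            others = sum(c.weight for k, c in enumerate(strat.components) if k != j)
            strat.components[j].weight = 1.0 - others
        elif rule.kind == "sum":
            set_path(spec, rule.target, float(sum(get_path(spec, s) for s in rule.sources)))
        elif rule.kind == "difference":
            set_path(
                spec,
                rule.target,
                float(get_path(spec, rule.sources[0]) - get_path(spec, rule.sources[1])),
            )
        elif rule.kind == "fill":
            value = float(get_path(spec, rule.sources[0]))
            set_path(spec, rule.target, [value] * spec.horizon)
        else:
            raise ValueError(f"unknown derived-parameter kind {rule.kind!r}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    """One invariant violation, addressed by parameter path."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class SpecValidationError(ValueError):
    """Raised when a spec fails validation; carries the violation list."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid model spec:\n" + "\n".join(f"  - {v}" for v in violations)
        )


def _check_prob(value: float, path: str, out: list[Violation], name: str = "probability") -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(path, f"{name} {value!r} outside [0, 1]"))


def validate_spec(spec: ModelSpec) -> list[Violation]:
    """Check every structural invariant; return violations (empty iff valid).

    Violations are returned, never raised, so callers can report all problems
    at once.  :func:`load_model_spec` raises :class:`SpecValidationError` when
    this list is non-empty.
    """
    v: list[Violation] = []

    if spec.horizon < 1:
        v.append(Violation("horizon", f"horizon must be >= 1, got {spec.horizon}"))
    if spec.cycle_length <= 0:
        v.append(Violation("cycle_length", "cycle length must be positive"))

    if not spec.strategies:
        v.append(Violation("strategies", "at least one strategy is required"))
    for i, strat in enumerate(spec.strategies):
        spath = f"strategies[{i}]"
        if not strat.components:
            v.append(Violation(f"{spath}.components", "strategy has no components"))
            continue
        total = sum(c.weight for c in strat.components)
        if abs(total - 1.0) > WEIGHT_TOL:
            v.append(
                Violation(
                    f"{spath}.components",
                    f"component weights sum to {total!r}, expected 1 within {WEIGHT_TOL}",
                )
            )
        for j, comp in enumerate(strat.components):
            cpath = f"{spath}.components[{j}]"
            _check_prob(comp.weight, f"{cpath}.weight", v, "weight")
            arm = comp.arm
            if arm.upfront_cost < 0:
                v.append(Violation(f"{cpath}.arm.upfront_cost", "upfront cost must be >= 0"))
            if len(arm.p_metastasis) != spec.horizon:
                v.append(
                    Violation(
                        f"{cpath}.arm.p_metastasis",
                        f"schedule length {len(arm.p_metastasis)} != horizon {spec.horizon}",
                    )
                )
            for t, p in enumerate(arm.p_metastasis):
                _check_prob(p, f"{cpath}.arm.p_metastasis[{t}]", v)

    econ = spec.econ
    for name in ("utility_on_adt", "utility_off_adt", "utility_metastatic"):
        _check_prob(getattr(econ, name), f"econ.{name}", v, "utility")
    utilities_in_range = all(
        0.0 <= getattr(econ, n) <= 1.0
        for n in ("utility_on_adt", "utility_off_adt")
    )
    if utilities_in_range and econ.utility_on_adt > econ.utility_off_adt:
        v.append(
            Violation(
                "econ.utility_on_adt",
                "utility on ADT must not exceed utility off ADT",
            )
        )
    for name in ("cost_metastatic", "cost_eol_cancer", "cost_eol_noncancer"):
        if getattr(econ, name) < 0:
            v.append(Violation(f"econ.{name}", "cost must be >= 0"))
    if econ.discount_rate < 0:
        v.append(Violation("econ.discount_rate", "discount rate must be >= 0"))
    if econ.wtp < 0:
        v.append(Violation("econ.wtp", "willingness-to-pay must be >= 0"))

    for name in ("p_death_other", "p_death_metastatic_excess"):
        sched = getattr(spec.mortality, name)
        if len(sched) < spec.horizon:
            v.append(
                Violation(
                    f"mortality.{name}",
                    f"schedule length {len(sched)} shorter than horizon {spec.horizon}",
                )
            )
        for t, p in enumerate(sched):
            _check_prob(p, f"mortality.{name}[{t}]", v)

    def _resolvable(path: str, where: str) -> None:
        try:
            get_path(spec, path)
        except (KeyError, ValueError) as exc:
            v.append(Violation(where, str(exc)))

    for i, rng in enumerate(spec.dsa_ranges):
        _resolvable(rng.param_path, f"dsa_ranges[{i}].param_path")
        if rng.low > rng.high:
            v.append(Violation(f"dsa_ranges[{i}]", "low bound exceeds high bound"))
    for i, dist in enumerate(spec.psa_distributions):
        dpath = f"psa_distributions[{i}]"
        _resolvable(dist.param_path, f"{dpath}.param_path")
        if dist.family not in ("beta", "gamma", "uniform", "fixed"):
            v.append(Violation(f"{dpath}.family", f"unknown family {dist.family!r}"))
        if dist.bound_low > dist.bound_high:
            v.append(Violation(dpath, "bound_low exceeds bound_high"))
        if not (dist.bound_low <= dist.base <= dist.bound_high):
            v.append(Violation(f"{dpath}.base", "base must lie within [bound_low, bound_high]"))
        if dist.family == "beta" and not (0.0 <= dist.bound_low and dist.bound_high <= 1.0):
            v.append(Violation(dpath, "beta bounds must lie in [0, 1]"))
        if dist.family == "gamma" and dist.bound_low < 0:
            v.append(Violation(dpath, "gamma bounds must be non-negative"))
    for i, rule in enumerate(spec.derived_params):
        rpath = f"derived_params[{i}]"
        if rule.kind not in ("complement", "sum", "difference", "fill"):
            v.append(Violation(f"{rpath}.kind", f"unknown kind {rule.kind!r}"))
            continue
        _resolvable(rule.target, f"{rpath}.target")
        for s in rule.sources:
            _resolvable(s, f"{rpath}.sources")

    return v


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _to_dict(obj: Any) -> Any:
    if isinstance(obj, ModelSpec):
        return {
            "horizon": obj.horizon,
            "cycle_length": obj.cycle_length,
            "half_cycle_correction": obj.half_cycle_correction,
            "econ": _to_dict(obj.econ),
            "mortality": _to_dict(obj.mortality),
            "params": dict(obj.params),
            "strategies": [_to_dict(s) for s in obj.strategies],
            "derived_params": [
                {"target": r.target, "kind": r.kind, "sources": list(r.sources)}
                for r in obj.derived_params
            ],
            "dsa_ranges": [
                {"param_path": r.param_path, "low": r.low, "high": r.high}
                for r in obj.dsa_ranges
            ],
            "psa_distributions": [
                {
                    "param_path": d.param_path,
                    "family": d.family,
                    "base": d.base,
                    "bound_low": d.bound_low,
                    "bound_high": d.bound_high,
                }
                for d in obj.psa_distributions
            ],
        }
    if isinstance(obj, Strategy):
        return {"name": obj.name, "components": [_to_dict(c) for c in obj.components]}
    if isinstance(obj, StrategyComponent):
        return {"weight": obj.weight, "arm": _to_dict(obj.arm)}
    if isinstance(obj, Arm):
        return {
            "id": obj.id,
            "receives_adt": obj.receives_adt,
            "p_metastasis": [float(p) for p in obj.p_metastasis],
            "upfront_cost": obj.upfront_cost,
        }
    if isinstance(obj, EconomicInputs):
        return {
            "cost_metastatic": obj.cost_metastatic,
            "cost_eol_cancer": obj.cost_eol_cancer,
            "cost_eol_noncancer": obj.cost_eol_noncancer,
            "utility_on_adt": obj.utility_on_adt,
            "utility_off_adt": obj.utility_off_adt,
            "utility_metastatic": obj.utility_metastatic,
            "discount_rate": obj.discount_rate,
            "wtp": obj.wtp,
        }
    if isinstance(obj, MortalityInputs):
        return {
            "p_death_other": [float(p) for p in obj.p_death_other],
            "p_death_metastatic_excess": [float(p) for p in obj.p_death_metastatic_excess],
        }
    raise TypeError(f"cannot serialize {type(obj)!r}")


def _require(data: dict, key: str, where: str) -> Any:
    if key not in data:
        raise SpecValidationError([Violation(f"{where}.{key}" if where else key, "missing required key")])
    return data[key]


def _float_list(values: Iterable[Any]) -> list[float]:
    return [float(x) for x in values]


def _arm_from_dict(data: dict, where: str) -> Arm:
    return Arm(
        id=str(_require(data, "id", where)),
        receives_adt=bool(_require(data, "receives_adt", where)),
        p_metastasis=_float_list(_require(data, "p_metastasis", where)),
        upfront_cost=float(data.get("upfront_cost", 0.0)),
    )


def _spec_from_dict(data: dict) -> ModelSpec:
    if not isinstance(data, dict):
        raise SpecValidationError([Violation("", "top level must be a mapping")])
    econ_d = _require(data, "econ", "")
    econ = EconomicInputs(
        cost_metastatic=float(_require(econ_d, "cost_metastatic", "econ")),
        cost_eol_cancer=float(_require(econ_d, "cost_eol_cancer", "econ")),
        cost_eol_noncancer=float(_require(econ_d, "cost_eol_noncancer", "econ")),
        utility_on_adt=float(_require(econ_d, "utility_on_adt", "econ")),
        utility_off_adt=float(_require(econ_d, "utility_off_adt", "econ")),
        utility_metastatic=float(_require(econ_d, "utility_metastatic", "econ")),
        discount_rate=float(econ_d.get("discount_rate", 0.03)),
        wtp=float(econ_d.get("wtp", 100_000.0)),
    )
    mort_d = _require(data, "mortality", "")
    mortality = MortalityInputs(
        p_death_other=_float_list(_require(mort_d, "p_death_other", "mortality")),
        p_death_metastatic_excess=_float_list(
            _require(mort_d, "p_death_metastatic_excess", "mortality")
        ),
    )
    strategies = []
    for i, sd in enumerate(_require(data, "strategies", "")):
        where = f"strategies[{i}]"
        comps = []
        for j, cd in enumerate(_require(sd, "components", where)):
            cwhere = f"{where}.components[{j}]"
            comps.append(
                StrategyComponent(
                    weight=float(_require(cd, "weight", cwhere)),
                    arm=_arm_from_dict(_require(cd, "arm", cwhere), f"{cwhere}.arm"),
                )
            )
        strategies.append(Strategy(name=str(_require(sd, "name", where)), components=comps))
    spec = ModelSpec(
        strategies=strategies,
        econ=econ,
        mortality=mortality,
        horizon=int(data.get("horizon", 15)),
        cycle_length=float(data.get("cycle_length", 1.0)),
        half_cycle_correction=bool(data.get("half_cycle_correction", True)),
        params={str(k): float(x) for k, x in data.get("params", {}).items()},
        derived_params=[
            DerivedParam(
                target=str(_require(rd, "target", f"derived_params[{i}]")),
                kind=str(_require(rd, "kind", f"derived_params[{i}]")),
                sources=[str(s) for s in rd.get("sources", [])],
            )
            for i, rd in enumerate(data.get("derived_params", []))
        ],
        dsa_ranges=[
            DSARange(
                param_path=str(_require(rd, "param_path", f"dsa_ranges[{i}]")),
                low=float(_require(rd, "low", f"dsa_ranges[{i}]")),
                high=float(_require(rd, "high", f"dsa_ranges[{i}]")),
            )
            for i, rd in enumerate(data.get("dsa_ranges", []))
        ],
        psa_distributions=[
            ParamDistribution(
                param_path=str(_require(dd, "param_path", f"psa_distributions[{i}]")),
                family=str(_require(dd, "family", f"psa_distributions[{i}]")),
                base=float(_require(dd, "base", f"psa_distributions[{i}]")),
                bound_low=float(_require(dd, "bound_low", f"psa_distributions[{i}]")),
                bound_high=float(_require(dd, "bound_high", f"psa_distributions[{i}]")),
            )
            for i, dd in enumerate(data.get("psa_distributions", []))
        ],
    )
    return spec


def load_model_spec(path: str | Path) -> ModelSpec:
    """Read and validate a model spec from a YAML or JSON file.

    Defaults (discount rate 0.03, WTP 100 000, horizon 15 cycles, half-cycle
    correction on) are applied for absent keys.  Raises
    :class:`SpecValidationError` naming the offending parameter path when a
    required key is missing or any invariant fails.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    spec = _spec_from_dict(data)
    violations = validate_spec(spec)
    if violations:
        raise SpecValidationError(violations)
    return spec


def write_model_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec to YAML (default) or JSON, re-loadable by load_model_spec."""
    path = Path(path)
    data = spec.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def schema_path() -> Path:
    """Path to the bundled JSON-Schema document for the spec file format."""
    return Path(__file__).parent / "data" / "model_spec.schema.json"
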