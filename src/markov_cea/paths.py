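"""Dotted parameter paths into a :class:`DecisionModel`.

Sensitivity and probabilistic analyses address individual numeric inputs
by path:

* ``settings.<field>`` -- a model-settings field, e.g.
  ``settings.discount_rate_annual``;
* ``<strategy>/<field>`` -- a strategy field, e.g. ``prp/utility_improved``;
* ``<strategy>/cost_schedule.<field>`` -- a cost component, e.g.
  ``prp/cost_schedule.injection_unit_cost``;
* ``*/<field>`` -- a shared parameter: every strategy whose current value
  for the field is non-zero carries it, and setting writes the same value
  to all carriers (zero-valued arms, e.g. a drug cost an arm never incurs,
  are left untouched).  Reading a shared path requires the carriers to
  agree.

Models are immutable; ``set_param`` returns a new model.
"""

from __future__ import annotations

from dataclasses import replace

from .model import DecisionModel, StrategyDefinition

__all__ = ["get_param", "set_param", "resolve_carriers"]


def _split(path: str) -> tuple[str, str]:
    if path.startswith("settings."):
        return "settings", path[len("settings.") :]
    if "/" not in path:
        raise KeyError(
            f"cannot resolve parameter path {path!r}: expected 'settings.<field>' or "
            f"'<strategy>/<field>'"
        )
    strategy, field_path = path.split("/", 1)
    return strategy, field_path


def _get_strategy_field(s: StrategyDefinition, field_path: str) -> float:
    if field_path.startswith("cost_schedule."):
        return float(getattr(s.cost_schedule, field_path[len("cost_schedule.") :]))
    return float(getattr(s, field_path))


def _set_strategy_field(s: StrategyDefinition, field_path: str, value: float) -> StrategyDefinition:
    if field_path.startswith("cost_schedule."):
        sub = field_path[len("cost_schedule.") :]
        if not hasattr(s.cost_schedule, sub):
            raise KeyError(f"strategy {s.name!r} cost schedule has no field {sub!r}")
        return replace(s, cost_schedule=replace(s.cost_schedule, **{sub: value}))
    if not hasattr(s, field_path):
        raise KeyError(f"strategy {s.name!r} has no field {field_path!r}")
    return replace(s, **{field_path: value})


def resolve_carriers(model: DecisionModel, path: str) -> list[str]:
    """Names of the strategies a path addresses (empty for settings paths)."""
    head, field_path = _split(path)
    if head == "settings":
        if not hasattr(model.settings, field_path):
            raise KeyError(f"settings has no field {field_path!r}")
        return []
    if head == "*":
        carriers = [
            s.name for s in model.strategies if _get_strategy_field(s, field_path) != 0.0
        ]
        if not carriers:
            raise KeyError(f"no strategy carries shared parameter {path!r} (all zero)")
        return carriers
    model.strategy(head)  # raises KeyError for unknown names
    return [head]


def get_param(model: DecisionModel, path: str) -> float:
    head, field_path = _split(path)
    if head == "settings":
        return float(getattr(model.settings, field_path))
    carriers = resolve_carriers(model, path)
    values = {_get_strategy_field(model.strategy(n), field_path) for n in carriers}
    if len(values) > 1:
        raise ValueError(f"shared parameter {path!r} has diverging values {sorted(values)}")
    return values.pop()


def set_param(model: DecisionModel, path: str, value: float) -> DecisionModel:
    """Return a copy of the model with the addressed parameter set to
    ``value`` (validators run on the rebuilt objects)."""
    head, field_path = _split(path)
    if head == "settings":
        if not hasattr(model.settings, field_path):
            raise KeyError(f"settings has no field {field_path!r}")
        return replace(model, settings=replace(model.settings, **{field_path: value}))
    carriers = set(resolve_carriers(model, path))
    new_strategies = tuple(
        _set_strategy_field(s, field_path, value) if s.name in carriers else s
        for s in model.strategies
    )
    return replace(model, strategies=new_strategies)
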