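"""Configuration I/O: YAML/JSON (de)serialization of decision models and
the bundled androgenetic-alopecia reference configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from importlib import resources
from pathlib import Path

import yaml

from .model import (
    CostSchedule,
    DecisionModel,
    LifeTable,
    ModelSettings,
    StrategyDefinition,
)
from .synthetic import LifeTableModel, make_life_table

__all__ = [
    "model_from_dict",
    "model_to_dict",
    "load_model",
    "save_model",
    "load_aga_reference",
    "MINOXIDIL",
    "MINOXIDIL_PRP",
    "PRP",
]

#: Canonical strategy names in the bundled reference configuration.
MINOXIDIL = "minoxidil"
MINOXIDIL_PRP = "minoxidil_prp"
PRP = "prp"


def _life_table_from_spec(spec, base_dir: Path | None) -> LifeTable:
    if spec in (None, "synthetic-default"):
        return make_life_table(LifeTableModel())
    if not isinstance(spec, dict):
        raise ValueError(f"unrecognised life_table spec: {spec!r}")
    kind = spec.get("type", "inline")
    if kind == "gompertz_makeham":
        params = {k: v for k, v in spec.items() if k != "type"}
        return make_life_table(LifeTableModel(**params))
    if kind == "csv":
        path = Path(spec["path"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return LifeTable.from_csv(path)
    if kind == "inline":
        return LifeTable(tuple(spec["ages"]), tuple(spec["q_annual"]))
    raise ValueError(f"unrecognised life_table type: {kind!r}")


def model_from_dict(data: dict, base_dir: Path | None = None) -> DecisionModel:
    """Build a :class:`DecisionModel` from a plain configuration mapping.

    ``base_dir`` anchors relative life-table CSV paths (the directory of
    the configuration file, when loaded from disk).
    """
    try:
        settings = ModelSettings(**data.get("settings", {}))
        strategies = tuple(
            StrategyDefinition(
                **{**sd, "cost_schedule": CostSchedule(**sd.get("cost_schedule", {}))}
            )
            for sd in data["strategies"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid model configuration: {exc}") from exc
    life_table = _life_table_from_spec(data.get("life_table"), base_dir)
    return DecisionModel(strategies, settings, life_table)


def model_to_dict(model: DecisionModel, name: str | None = None) -> dict:
    """Serialize a model to plain types; the life table is inlined so the
    round-trip is exact."""
    settings = asdict(model.settings)
    settings["perspective"] = model.settings.perspective.value
    settings["nochange_first_cycle_mode"] = model.settings.nochange_first_cycle_mode.value
    out = {
        "settings": settings,
        "life_table": {
            "type": "inline",
            "ages": list(model.life_table.ages),
            "q_annual": list(model.life_table.q_annual),
        },
        "strategies": [asdict(s) for s in model.strategies],
    }
    if name is not None:
        out = {"name": name, **out}
    return out


def load_model(path) -> DecisionModel:
    """Load a model configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return model_from_dict(data, base_dir=path.parent)


def save_model(model: DecisionModel, path, name: str | None = None) -> None:
    path = Path(path)
    data = model_to_dict(model, name=name)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_aga_reference(**settings_overrides) -> DecisionModel:
    """The bundled androgenetic-alopecia model (three strategies, published
    base-case inputs, default synthetic life table).

    Keyword arguments override individual :class:`ModelSettings` fields,
    e.g. ``load_aga_reference(perspective="societal")``.
    """
    with resources.files("markov_cea.data").joinpath("aga_minoxidil_prp.yaml").open() as fh:
        data = yaml.safe_load(fh)
    model = model_from_dict(data)
    if settings_overrides:
        model = replace(model, settings=replace(model.settings, **settings_overrides))
    return model
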