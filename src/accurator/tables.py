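"""Config-driven batch evaluation of screening/intervention scenario sets.

A *scenario set* is an ordered list of labelled columns, each pairing a
:class:`~accurator.core_metrics.CohortScenario` with an
:class:`~accurator.intervention.EffectivenessModel`. Evaluating a set yields
the standard stack of rows — prevalence, relative risk, target fraction,
PPV, NPV, accuracy, sensitivity, specificity, effectiveness, percent of
preventable events captured, percent of all events prevented, NNT All,
NNT Targeted — as raw fractions and, separately, in the integer-percent
rendering conventional for published screening tables.

Two presets ship with the package: ``rare_vs_common`` scans modeled
prevalence/relative-risk/effectiveness combinations for a rare (2%) and a
common (20%) condition, and ``observed_conditions`` covers opioid use
disorder, coronary events under intensive blood-pressure therapy, and
osteoporotic bone fracture at literature-reported prevalences and projected
score strengths. They are also importable under the aliases ``table1`` and
``table2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .core_metrics import (
    CohortScenario,
    confusion_from_scenario,
    round_half_away,
    round_percent,
    summarize,
)
from .errors import AccuratorError, DomainError, InfeasibleScenarioError
from .intervention import EffectivenessModel, intervention_outcomes

__all__ = [
    "ScenarioColumn",
    "ScenarioSet",
    "ROW_ORDER",
    "evaluate_set",
    "render_table",
    "load_scenarios",
    "load_preset",
    "PRESET_NAMES",
]

ROW_ORDER = [
    "Prevalence",
    "Relative Risk",
    "Target",
    "PPV/Precision",
    "NPV",
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Effectiveness",
    "Percent of Preventable",
    "Percent of All Prevented",
    "NNT All",
    "NNT Targeted",
]

#: rows holding fractions that render as integer percents
_PERCENT_ROWS = [
    "PPV/Precision",
    "NPV",
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Percent of Preventable",
    "Percent of All Prevented",
]

_DISCRIMINATION_KEYS = {"relative_risk": "relative_risk", "sensitivity": "sensitivity", "ppv": "ppv"}
_COLUMN_KEYS = (
    {"label", "prevalence", "target", "effectiveness", "effect_target", "effect_remainder"}
    | set(_DISCRIMINATION_KEYS)
)

PRESET_NAMES = ("rare_vs_common", "observed_conditions")
_PRESET_ALIASES = {"table1": "rare_vs_common", "table2": "observed_conditions"}


@dataclass(frozen=True)
class ScenarioColumn:
    label: str
    scenario: CohortScenario
    effectiveness: EffectivenessModel


@dataclass(frozen=True)
class ScenarioSet:
    name: str
    columns: tuple[ScenarioColumn, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.columns]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise DomainError(f"duplicate column labels: {dupes}")
        if not self.columns:
            raise DomainError("a scenario set needs at least one column")


def _evaluate_column(col: ScenarioColumn) -> dict[str, float]:
    try:
        summary = summarize(confusion_from_scenario(col.scenario))
        outcome = intervention_outcomes(col.scenario, col.effectiveness)
    except AccuratorError as exc:
        raise InfeasibleScenarioError(f"column {col.label!r}: {exc}") from exc
    eff = col.effectiveness
    return {
        "Prevalence": col.scenario.prevalence,
        "Relative Risk": summary.relative_risk,
        "Target": col.scenario.target_fraction,
        "PPV/Precision": summary.ppv,
        "NPV": summary.npv,
        "Accuracy": summary.accuracy,
        "Sensitivity": summary.sensitivity,
        "Specificity": summary.specificity,
        "Effectiveness": eff.effect_target if eff.is_uniform else (eff.effect_target, eff.effect_remainder),
        "Percent of Preventable": outcome.percent_preventable,
        "Percent of All Prevented": outcome.percent_all_prevented,
        "NNT All": outcome.nnt_all,
        "NNT Targeted": outcome.nnt_targeted,
    }


def evaluate_set(scenario_set: ScenarioSet) -> pd.DataFrame:
    """Evaluate every column; raw values (fractions, ratios, raw NNTs).

    Returns a DataFrame with metric rows in :data:`ROW_ORDER` and one column
    per scenario, in input order. Pure function of its input. An infeasible
    column raises :class:`InfeasibleScenarioError` naming the column.
    """
    data = {col.label: _evaluate_column(col) for col in scenario_set.columns}
    return pd.DataFrame(data, index=ROW_ORDER, columns=[c.label for c in scenario_set.columns])


def _fmt_number(x: float) -> str:
    return f"{x:g}"


def render_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Published-table-style string rendering of :func:`evaluate_set` output.

    Percent rows become nearest-integer percents (half away from zero);
    prevalence and target are shown in percent units; NNTs round to the
    nearest integer; differential effectiveness renders as ``"75/25%"``.
    """
    out = {}
    for label in raw.columns:
        col = raw[label]
        eff = col["Effectiveness"]
        eff_str = (
            f"{_fmt_number(100 * eff[0])}/{_fmt_number(100 * eff[1])}%"
            if isinstance(eff, tuple)
            else f"{_fmt_number(100 * eff)}%"
        )
        rendered = {
            "Prevalence": _fmt_number(100 * col["Prevalence"]),
            "Relative Risk": f"{col['Relative Risk']:.3g}",
            "Target": f"{round_percent(col['Target'])}%",
            "Effectiveness": eff_str,
            "NNT All": str(round_half_away(col["NNT All"])),
            "NNT Targeted": str(round_half_away(col["NNT Targeted"])),
        }
        for row in _PERCENT_ROWS:
            rendered[row] = str(round_percent(col[row]))
        out[label] = rendered
    return pd.DataFrame(out, index=ROW_ORDER, columns=list(raw.columns))


def _parse_effectiveness(label: str, spec: dict) -> EffectivenessModel:
    has_uniform = "effectiveness" in spec
    has_split = "effect_target" in spec or "effect_remainder" in spec
    if has_uniform and has_split:
        raise DomainError(
            f"column {label!r}: give either 'effectiveness' or the "
            f"'effect_target'/'effect_remainder' pair, not both"
        )
    if has_uniform:
        return EffectivenessModel.uniform(float(spec["effectiveness"]))
    if "effect_target" in spec and "effect_remainder" in spec:
        return EffectivenessModel(float(spec["effect_target"]), float(spec["effect_remainder"]))
    raise DomainError(
        f"column {label!r}: missing effectiveness ('effectiveness' or both "
        f"'effect_target' and 'effect_remainder')"
    )


def _parse_column(i: int, spec) -> ScenarioColumn:
    if not isinstance(spec, dict):
        raise DomainError(f"column #{i + 1}: expected a mapping, got {type(spec).__name__}")
    label = str(spec.get("label", f"column_{i + 1}"))
    unknown = set(spec) - _COLUMN_KEYS
    if unknown:
        raise DomainError(f"column {label!r}: unknown keys {sorted(unknown)}")
    for req in ("prevalence", "target"):
        if req not in spec:
            raise DomainError(f"column {label!r}: missing required key '{req}'")
    disc = [k for k in _DISCRIMINATION_KEYS if k in spec]
    if len(disc) != 1:
        raise DomainError(
            f"column {label!r}: exactly one of {sorted(_DISCRIMINATION_KEYS)} required, "
            f"got {disc or 'none'}"
        )
    try:
        scenario = CohortScenario(
            prevalence=float(spec["prevalence"]),
            target_fraction=float(spec["target"]),
            discrimination=float(spec[disc[0]]),
            kind=disc[0],
        )
    except InfeasibleScenarioError as exc:
        raise InfeasibleScenarioError(f"column {label!r}: {exc}") from exc
    return ScenarioColumn(
        label=label, scenario=scenario, effectiveness=_parse_effectiveness(label, spec)
    )


def load_scenarios(config_text: str) -> ScenarioSet:
    """Parse a YAML scenario-set document.

    Schema: a mapping with a ``name`` and a ``columns`` list; each column is
    a flat mapping with ``label``, ``prevalence``, ``target``, exactly one of
    ``relative_risk`` / ``sensitivity`` / ``ppv``, and either ``effectiveness``
    or both ``effect_target`` and ``effect_remainder``. All values are plain
    decimal fractions (``target: 0.05`` targets the top 5%). Unknown keys are
    rejected.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise DomainError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise DomainError("config must be a mapping with 'name' and 'columns'")
    unknown = set(doc) - {"name", "columns"}
    if unknown:
        raise DomainError(f"unknown top-level keys {sorted(unknown)}")
    columns = doc.get("columns")
    if not isinstance(columns, list) or not columns:
        raise DomainError("'columns' must be a non-empty list")
    parsed = tuple(_parse_column(i, spec) for i, spec in enumerate(columns))
    scenario_set = ScenarioSet(name=str(doc.get("name", "unnamed")), columns=parsed)
    evaluate_set(scenario_set)  # every column independently feasible
    return scenario_set


def load_preset(name: str) -> ScenarioSet:
    """Load a shipped preset by name (or alias ``table1`` / ``table2``)."""
    canonical = _PRESET_ALIASES.get(name, name)
    if canonical not in PRESET_NAMES:
        raise DomainError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES + tuple(_PRESET_ALIASES))}"
        )
    text = resources.files("accurator").joinpath(f"presets/{canonical}.yaml").read_text()
    return load_scenarios(text)


def table_to_tsv(rendered: pd.DataFrame) -> str:
    """Rendered table as TSV with an ``Attribute`` header column."""
    return rendered.rename_axis("Attribute").reset_index().to_csv(sep="\t", index=False)


def table_to_json(raw: pd.DataFrame) -> str:
    """Raw table as JSON: column label -> {row -> raw value}."""
    payload = {}
    for label in raw.columns:
        col = {}
        for row in raw.index:
            v = raw.at[row, label]
            col[row] = list(v) if isinstance(v, tuple) else float(v)
        payload[label] = col
    return json.dumps(payload, indent=2)
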