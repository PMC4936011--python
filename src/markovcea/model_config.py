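"""Declarative model specification for Markov cohort cost-effectiveness models.

A model is a set of mutually exclusive health states, one or more treatment
strategies, per-strategy annual transition probabilities, per-state annual
costs and utilities, discounting settings and a closed cohort.  The types
here are deliberately permissive about *semantic* invariants (exit-row sums,
single death state, utility ranges): those are checked by
:func:`validate_model_spec`, which reports findings as data so that invalid
specifications can be inspected rather than merely rejected.  Shape errors
(wrong types, missing fields) are caught at parse time by pydantic.

The bundled benign prostatic hyperplasia (BPH) parameterization — dutasteride
monotherapy (DM) versus fixed-dose dutasteride–tamsulosin (FDCT) — is exposed
by :func:`bph_reference_model` and shipped as a YAML data file.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "HealthStateDef",
    "TransitionEntry",
    "DiscountSettings",
    "CohortSettings",
    "ModelSpec",
    "Finding",
    "ValidationReport",
    "ConfigError",
    "SchemaError",
    "InvalidSpecError",
    "load_model_spec",
    "save_model_spec",
    "validate_model_spec",
    "bph_reference_model",
    "reference_reported_results",
    "DEFAULT_WTP",
]

#: Default willingness-to-pay threshold, US$ per QALY (twice the 2012 Nigerian
#: gross national income per capita).
DEFAULT_WTP = 2450.0


class ConfigError(ValueError):
    """A model document failed to parse as YAML/JSON."""


class SchemaError(ValueError):
    """A parsed document violates the model schema; names the offending field."""


class InvalidSpecError(ValueError):
    """An operation was handed a spec with outstanding validation findings."""


class HealthStateDef(BaseModel):
    """One mutually exclusive health state.

    ``utility`` is the QALY weight accrued per person-year of occupancy
    (1 = full health, 0 = death, negative = worse than death).
    ``annual_state_cost_by_strategy`` maps strategy name to US$ per
    person-year of occupancy.  ``event_cost`` is a US$ amount charged once
    per entry into the state (and once per explicit self-loop "repeat"
    flow), used for episode costs such as acute urinary retention (AUR)
    and transurethral resection of the prostate (TURP).
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    utility: float = 0.0
    annual_state_cost_by_strategy: dict[str, float] = Field(default_factory=dict)
    is_death: bool = False
    event_cost: float = 0.0


class TransitionEntry(BaseModel):
    """Annual probability of moving ``from_state`` → ``to_state`` under ``strategy``.

    A self-referential entry (``from_state == to_state``) does not alter the
    transition matrix — staying probabilities are always ``1 − Σ exits`` — but
    is counted as a repeat-event flow (e.g. repeat TURP) and re-incurs the
    state's ``event_cost``.
    """

    model_config = ConfigDict(extra="forbid")

    strategy: str
    from_state: str
    to_state: str
    annual_probability: float


class DiscountSettings(BaseModel):
    """Annual discounting of costs and effects.

    ``convention`` picks the exponent applied to cycle ``t`` (1-based):
    ``first-cycle-undiscounted`` weights cycle 1 rewards by 1 (exponent
    ``t − 1``); ``first-cycle-discounted`` weights them by ``1/(1+rate)``
    (exponent ``t``).
    """

    model_config = ConfigDict(extra="forbid")

    annual_rate: float = 0.06
    convention: str = "first-cycle-undiscounted"


class CohortSettings(BaseModel):
    """Closed-cohort settings: size, entry distribution and horizon.

    ``incidence_scaling`` is an optional multiplier (e.g. an annual disease
    incidence proportion) applied to ``cohort_size`` before the model is run;
    disabled (``None``) by default.
    """

    model_config = ConfigDict(extra="forbid")

    cohort_size: float
    initial_distribution: dict[str, float]
    horizon_cycles: int
    cycle_length_years: float = 1.0
    incidence_scaling: Optional[float] = None

    def effective_cohort_size(self) -> float:
        if self.incidence_scaling is None:
            return float(self.cohort_size)
        return float(self.cohort_size) * float(self.incidence_scaling)


class ModelSpec(BaseModel):
    """The whole declarative model.

    ``states`` is ordered; the order defines transition-matrix row/column
    indices.  Exactly one state must be flagged ``is_death`` for the spec to
    validate.
    """

    model_config = ConfigDict(extra="forbid")

    states: list[HealthStateDef]
    strategies: list[str]
    transitions: list[TransitionEntry]
    discount: DiscountSettings = Field(default_factory=DiscountSettings)
    cohort: CohortSettings
    wtp_threshold: float = DEFAULT_WTP

    # -- convenience accessors -------------------------------------------------

    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state(self, name: str) -> HealthStateDef:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def death_state(self) -> HealthStateDef:
        deaths = [s for s in self.states if s.is_death]
        if len(deaths) != 1:
            raise InvalidSpecError(
                f"exactly one death state required, found {len(deaths)}"
            )
        return deaths[0]

    def transition(self, strategy: str, from_state: str, to_state: str) -> float:
        """Declared annual probability for a (strategy, from, to) triple, 0 if absent."""
        for t in self.transitions:
            if (
                t.strategy == strategy
                and t.from_state == from_state
                and t.to_state == to_state
            ):
                return t.annual_probability
        return 0.0

    def exit_sum(self, strategy: str, from_state: str) -> float:
        """Sum of declared exit probabilities (self-loops excluded)."""
        return sum(
            t.annual_probability
            for t in self.transitions
            if t.strategy == strategy
            and t.from_state == from_state
            and t.to_state != from_state
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


class Finding(BaseModel):
    """One validation finding: where and what."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class ValidationReport(BaseModel):
    findings: list[Finding] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, path: str, message: str) -> None:
        self.findings.append(Finding(path=path, message=message))


_EXIT_SUM_TOL = 1e-9


def validate_model_spec(spec: ModelSpec) -> ValidationReport:
    """Check every semantic invariant of a model specification.

    Returns a report whose ``findings`` list is empty iff the spec is valid:
    utilities in [−1, 1], costs ≥ 0, probabilities in [0, 1], exactly one
    death state (utility 0, costs 0, no declared exits), all transition
    references resolvable, (strategy, from, to) triples unique, initial
    distribution a probability vector over declared states, and, for every
    (strategy, from_state), declared exit probabilities summing to ≤ 1.
    """
    report = ValidationReport()
    names = spec.state_names()
    name_set = set(names)

    if len(name_set) != len(names):
        report.add("states", "state names must be unique")
    if len(spec.strategies) != len(set(spec.strategies)):
        report.add("strategies", "strategy names must be unique")
    if not spec.strategies:
        report.add("strategies", "at least one strategy required")

    deaths = [s for s in spec.states if s.is_death]
    if len(deaths) != 1:
        report.add("states", f"exactly one death state required, found {len(deaths)}")

    for s in spec.states:
        base = f"states[{s.name}]"
        if not -1.0 <= s.utility <= 1.0:
            report.add(f"{base}.utility", f"utility {s.utility} outside [-1, 1]")
        if s.event_cost < 0:
            report.add(f"{base}.event_cost", f"cost {s.event_cost} negative")
        for strat, c in s.annual_state_cost_by_strategy.items():
            if strat not in spec.strategies:
                report.add(
                    f"{base}.annual_state_cost_by_strategy",
                    f"unknown strategy {strat!r}",
                )
            if c < 0:
                report.add(
                    f"{base}.annual_state_cost_by_strategy[{strat}]",
                    f"cost {c} negative",
                )
        if s.is_death:
            if s.utility != 0.0:
                report.add(f"{base}.utility", "death state must have utility 0")
            if s.event_cost != 0.0 or any(
                c != 0.0 for c in s.annual_state_cost_by_strategy.values()
            ):
                report.add(base, "death state must carry zero costs")

    seen: set[tuple[str, str, str]] = set()
    for i, t in enumerate(spec.transitions):
        base = f"transitions[{i}]"
        key = (t.strategy, t.from_state, t.to_state)
        if key in seen:
            report.add(base, f"duplicate transition {key}")
        seen.add(key)
        if t.strategy not in spec.strategies:
            report.add(f"{base}.strategy", f"unknown strategy {t.strategy!r}")
        for field_name, state in (("from_state", t.from_state), ("to_state", t.to_state)):
            if state not in name_set:
                report.add(f"{base}.{field_name}", f"unknown state {state!r}")
        if not 0.0 <= t.annual_probability <= 1.0:
            report.add(
                f"{base}.annual_probability",
                f"annual_probability {t.annual_probability} outside [0, 1]",
            )
        if t.from_state in name_set and spec.state(t.from_state).is_death:
            report.add(base, "death state must not have outgoing transitions")

    for strat in spec.strategies:
        for s in spec.states:
            if s.is_death:
                continue
            total = spec.exit_sum(strat, s.name)
            if total > 1.0 + _EXIT_SUM_TOL:
                report.add(
                    f"transitions[{strat}:{s.name}]",
                    f"exit probabilities exceed 1 (sum {total:.6g})",
                )

    cohort = spec.cohort
    if cohort.cohort_size <= 0:
        report.add("cohort.cohort_size", f"cohort_size {cohort.cohort_size} must be > 0")
    if cohort.horizon_cycles < 1:
        report.add("cohort.horizon_cycles", "horizon_cycles must be >= 1")
    if cohort.cycle_length_years <= 0:
        report.add("cohort.cycle_length_years", "cycle_length_years must be > 0")
    if cohort.incidence_scaling is not None and not 0 < cohort.incidence_scaling <= 1:
        report.add("cohort.incidence_scaling", "incidence_scaling must be in (0, 1]")
    dist_total = 0.0
    for name, p in cohort.initial_distribution.items():
        if name not in name_set:
            report.add("cohort.initial_distribution", f"unknown state {name!r}")
        if p < 0:
            report.add(
                f"cohort.initial_distribution[{name}]", f"proportion {p} negative"
            )
        dist_total += p
    if not math.isclose(dist_total, 1.0, rel_tol=0, abs_tol=1e-9):
        report.add(
            "cohort.initial_distribution",
            f"proportions must sum to 1 (sum {dist_total:.6g})",
        )

    if not 0.0 <= spec.discount.annual_rate < 1.0:
        report.add(
            "discount.annual_rate",
            f"annual_rate {spec.discount.annual_rate} outside [0, 1)",
        )
    if spec.discount.convention not in (
        "first-cycle-undiscounted",
        "first-cycle-discounted",
    ):
        report.add("discount.convention", f"unknown convention {spec.discount.convention!r}")
    if spec.wtp_threshold < 0:
        report.add("wtp_threshold", f"wtp_threshold {spec.wtp_threshold} negative")

    return report


def require_valid(spec: ModelSpec) -> None:
    """Raise :class:`InvalidSpecError` listing findings if the spec is invalid."""
    report = validate_model_spec(spec)
    if not report.ok:
        msgs = "; ".join(str(f) for f in report.findings)
        raise InvalidSpecError(f"invalid model spec: {msgs}")


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------


def _parse_document(document: str | Path) -> dict:
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).suffix
        in {".yaml", ".yml", ".json"}
    ):
        path = Path(document)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read model document {path}: {exc}") from exc
    else:
        text = str(document)
    try:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"model document does not parse{loc}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("model document must be a mapping at the top level")
    return data


def load_model_spec(document: str | Path) -> ModelSpec:
    """Read a model spec from a YAML/JSON document (text or file path).

    Raises :class:`ConfigError` on parse failure (naming the line when
    available), and :class:`SchemaError` naming the offending field when the
    document is well-formed but violates the schema or a semantic invariant.
    """
    data = _parse_document(document)
    try:
        spec = ModelSpec.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise SchemaError(f"{field}: {first['msg']}") from exc
    report = validate_model_spec(spec)
    if not report.ok:
        f = report.findings[0]
        raise SchemaError(f"{f.path}: {f.message}")
    return spec


def save_model_spec(spec: ModelSpec, path: str | Path, fmt: str | None = None) -> None:
    """Write a spec to ``path`` as YAML (default) or JSON, round-trip stable.

    Refuses to persist an invalid spec (raises :class:`InvalidSpecError`
    listing the findings).  ``load_model_spec(path)`` reproduces the spec
    field-for-field.
    """
    require_valid(spec)
    p = Path(path)
    if not str(p):
        raise OSError("empty path")
    data = spec.model_dump(exclude_none=True)
    if fmt is None:
        fmt = "json" if p.suffix == ".json" else "yaml"
    try:
        if fmt == "json":
            p.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")
        else:
            p.write_text(yaml.safe_dump(data, sort_keys=False))
    except OSError as exc:
        raise OSError(f"cannot write model document {p}: {exc}") from exc


# ---------------------------------------------------------------------------
# Bundled BPH parameterization
# ---------------------------------------------------------------------------

DM = "DM"
FDCT = "FDCT"

# (from_state, to_state, p_DM, p_FDCT); the combined moderate/severe rows for
# AUR and TURP apply identically from both states, the single death rate from
# every alive state, and AUR is a one-cycle event state whose survivors return
# to severe the next cycle.
_BPH_TRANSITIONS: list[tuple[str, str, float, float]] = [
    ("healthy", "mild", 0.29, 0.29),
    ("mild", "moderate", 0.29, 0.29),
    ("moderate", "severe", 0.16, 0.058),
    ("moderate", "aur", 0.13, 0.04),
    ("severe", "aur", 0.13, 0.04),
    ("moderate", "turp", 0.16, 0.056),
    ("severe", "turp", 0.16, 0.056),
    ("turp", "turp", 0.48, 0.48),  # repeat-procedure self-loop
    ("severe", "moderate", 0.46, 0.49),
    ("moderate", "mild", 0.46, 0.49),
    ("aur", "severe", 1.0 - 0.013, 1.0 - 0.013),
    ("healthy", "death", 0.013, 0.013),
    ("mild", "death", 0.013, 0.013),
    ("moderate", "death", 0.013, 0.013),
    ("severe", "death", 0.013, 0.013),
    ("aur", "death", 0.013, 0.013),
    ("turp", "death", 0.013, 0.013),
]

_SEVERE_UTILITY = 0.382
_AUR_DISUTILITY = -0.145


def bph_reference_model(start_state: str = "mild") -> ModelSpec:
    """The bundled BPH model: DM versus FDCT over a Nigerian cohort.

    Seven states (healthy, mild, moderate, severe, AUR, TURP, death) banded
    by IPSS symptom score; annual cycles; a closed cohort of 2,862,363 men
    aged 50 entering in the mild state; 10-year horizon; 6 %/yr discounting;
    WTP threshold US$2450/QALY.  Annual drug/consultation cost accrues in the
    moderate and severe states (US$223.53 under DM, US$338.82 under FDCT);
    TURP and AUR carry per-episode costs of US$484.97 and US$29.41.  The AUR
    state utility is the severe-state utility plus the AUR disutility
    (0.382 − 0.145 = 0.237).

    ``start_state`` selects the entry state ("mild" default; "healthy" is the
    incidence-driven alternative with healthy→mild 0.29).
    """
    annual = {DM: 223.53, FDCT: 338.82}
    states = [
        HealthStateDef(name="healthy", utility=1.0),
        HealthStateDef(name="mild", utility=0.883),
        HealthStateDef(name="moderate", utility=0.787, annual_state_cost_by_strategy=dict(annual)),
        HealthStateDef(name="severe", utility=_SEVERE_UTILITY, annual_state_cost_by_strategy=dict(annual)),
        HealthStateDef(name="aur", utility=_SEVERE_UTILITY + _AUR_DISUTILITY, event_cost=29.41),
        HealthStateDef(name="turp", utility=0.833, event_cost=484.97),
        HealthStateDef(name="death", is_death=True),
    ]
    transitions = [
        TransitionEntry(
            strategy=strategy, from_state=frm, to_state=to, annual_probability=p
        )
        for frm, to, p_dm, p_fdct in _BPH_TRANSITIONS
        for strategy, p in ((DM, p_dm), (FDCT, p_fdct))
    ]
    if start_state not in {s.name for s in states}:
        raise KeyError(start_state)
    return ModelSpec(
        states=states,
        strategies=[DM, FDCT],
        transitions=transitions,
        discount=DiscountSettings(annual_rate=0.06),
        cohort=CohortSettings(
            cohort_size=2_862_363,
            initial_distribution={start_state: 1.0},
            horizon_cycles=10,
        ),
        wtp_threshold=DEFAULT_WTP,
    )


def bundled_model_path() -> Path:
    """Filesystem path of the shipped BPH model YAML."""
    return Path(str(resources.files("markovcea").joinpath("data/bph_model.yaml")))


def reference_reported_results() -> dict:
    """Published summary results of the original BPH cost-effectiveness study.

    Used as *inputs* for arithmetic cross-checks (incremental differences and
    ICER ratios over the published strategy totals), never as model output.
    Keys: per-horizon strategy totals and the published increments/ICER.
    Note the published 15-year increments are not the difference of the
    published 15-year totals; both readings are preserved as printed.
    """
    return {
        "10yr": {
            "FDCT": {"total_cost": 1_450_279_504.76, "total_qalys": 18_836_849.43},
            "DM": {"total_cost": 855_743_567.15, "total_qalys": 18_435_657.43},
            "incremental_cost": 594_535_937.61,
            "incremental_qalys": 401_192.00,
            "icer": 1481.92,
        },
        "15yr": {
            "FDCT": {"total_cost": 2_194_123_563.22, "total_qalys": 23_890_352.46},
            "DM": {"total_cost": 1_578_867_548.20, "total_qalys": 20_879_011.27},
            "incremental_cost": 852_086_147.24,
            "incremental_qalys": 938_291.33,
            "icer": 908.13,
        },
    }
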