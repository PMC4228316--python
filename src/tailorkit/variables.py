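"""Three-tier variable algebra for computer-tailored interventions.

A tailoring catalog declares *raw* variables (direct survey responses),
*intermediate* variables (values derived from raw responses, e.g. whether a
participant meets the aerobic activity guideline) and *feedback* variables
(first-match rule chains that select the message each participant receives).
Rule chains are ordered if/else-if/else cascades: the first clause whose
conjunction of atomic comparisons holds wins, and a default code covers
non-response, so every participant always maps to exactly one message.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import CatalogError, RuleTypeError

logger = logging.getLogger(__name__)

#: A bound value: numeric response, category code, or free text.  ``None``
#: (or an absent key) marks a missing response ("empty = not entered").
Value = Union[int, float, str]

WAVES = ("baseline", "update1", "update2")

#: Reserved assignment code for an intermediate variable whose inputs were
#: missing and which declares no default (e.g. the guideline classifier on an
#: incomplete activity profile).  Downstream chains treat it as missing.
UNRESOLVED = 0


# ---------------------------------------------------------------------------
# Domains and variable definitions
# ---------------------------------------------------------------------------

class ValueDomain(BaseModel):
    """Admissible values for one variable.

    ``numeric`` domains may carry finite bounds; ``coded-category`` domains
    enumerate integer level codes with labels (1-based, as printed on the
    survey); ``free-text`` domains hold short strings.  The empty cell is the
    missing sentinel in every kind.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["numeric", "coded-category", "free-text"]
    lower: Optional[float] = None
    upper: Optional[float] = None
    levels: Optional[dict[int, str]] = None
    max_length: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "ValueDomain":
        if self.kind == "coded-category":
            if not self.levels:
                raise ValueError("coded-category domain requires level codes")
        elif self.levels is not None:
            raise ValueError(f"{self.kind} domain cannot declare level codes")
        for bound in (self.lower, self.upper):
            if bound is not None and not math.isfinite(bound):
                raise ValueError("numeric bounds must be finite")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        return self

    def contains(self, value: Value) -> bool:
        if self.kind == "free-text":
            return isinstance(value, str)
        if isinstance(value, str):
            return False
        if self.kind == "coded-category":
            return int(value) == value and int(value) in self.levels
        if self.lower is not None and value < self.lower:
            return False
        if self.upper is not None and value > self.upper:
            return False
        return True

    def coerce(self, cell: str) -> Optional[Value]:
        """Parse one CSV cell; empty or whitespace-only means missing."""
        text = cell.strip() if isinstance(cell, str) else cell
        if text is None or text == "" or (isinstance(text, float) and math.isnan(text)):
            return None
        if self.kind == "free-text":
            return str(text)
        number = float(text)
        if self.kind == "coded-category":
            code = int(number)
            if code != number or code not in self.levels:
                raise ValueError(f"code {text!r} not a declared level")
            return code
        return int(number) if number == int(number) else number


class RawVariableDef(BaseModel):
    """A directly assessed survey item."""

    model_config = ConfigDict(frozen=True)

    name: str
    description: str = ""
    domain: ValueDomain


# ---------------------------------------------------------------------------
# Rule chains
# ---------------------------------------------------------------------------

Operator = Literal["<", "<=", "==", ">=", ">", "in"]


class Comparison(BaseModel):
    """One atomic comparison ``variable <op> constant``."""

    model_config = ConfigDict(frozen=True)

    variable: str
    op: Operator
    value: Union[float, int, tuple[int, ...]]

    @model_validator(mode="after")
    def _check(self) -> "Comparison":
        if self.op == "in":
            if not isinstance(self.value, tuple):
                raise ValueError("'in' comparisons need a tuple of codes")
        elif isinstance(self.value, tuple):
            raise ValueError(f"operator {self.op!r} takes a scalar constant")
        return self

    def holds(self, bound: Optional[Value]) -> bool:
        """Evaluate against a binding; a missing binding never matches."""
        if bound is None:
            return False
        if isinstance(bound, str):
            raise RuleTypeError(
                f"variable {self.variable!r}: free-text value compared "
                f"against numeric constant {self.value!r}"
            )
        if self.op == "in":
            return bound in self.value
        if self.op == "<":
            return bound < self.value
        if self.op == "<=":
            return bound <= self.value
        if self.op == "==":
            return bound == self.value
        if self.op == ">=":
            return bound >= self.value
        return bound > self.value


class LogicClause(BaseModel):
    """A conjunction of comparisons mapping to a result code."""

    model_config = ConfigDict(frozen=True)

    when: tuple[Comparison, ...]
    result: int

    @field_validator("when")
    @classmethod
    def _nonempty(cls, v: tuple[Comparison, ...]) -> tuple[Comparison, ...]:
        if not v:
            raise ValueError("clause needs at least one comparison")
        return v


class RuleChain(BaseModel):
    """Ordered first-match cascade with a mandatory default code."""

    model_config = ConfigDict(frozen=True)

    clauses: tuple[LogicClause, ...]
    default: int

    @property
    def referenced_variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for clause in self.clauses:
            for cmp_ in clause.when:
                seen.setdefault(cmp_.variable)
        return tuple(seen)

    @property
    def codes(self) -> tuple[int, ...]:
        """All codes the chain can syntactically emit (default last)."""
        out: dict[int, None] = {}
        for clause in self.clauses:
            out.setdefault(clause.result)
        out.setdefault(self.default)
        return tuple(out)


def evaluate_rule_chain(chain: RuleChain, bindings: Mapping[str, Optional[Value]]) -> int:
    """Return the result code of the first clause whose conjunction holds.

    Missing bindings make every clause touching them false, so a fully
    unanswered assessment falls through to the chain's default code — the
    default-message rule for non-response.  Pure: ``bindings`` is not
    modified and evaluation order is the declared clause order.
    """
    for clause in chain.clauses:
        if all(c.holds(bindings.get(c.variable)) for c in clause.when):
            return clause.result
    return chain.default


# ---------------------------------------------------------------------------
# Guideline classification
# ---------------------------------------------------------------------------

class ActivityProfile(BaseModel):
    """One participant's self-reported weekly aerobic activity.

    Sessions are counts per week; minutes are the average duration of one
    session.  The disability rating (1 "not at all limited" … 5 "completely
    limited") and the post-diagnosis change code (1 same / 2 more / 3 less)
    feed the feedback chain downstream of the guideline classifier.
    """

    model_config = ConfigDict(frozen=True)

    strenuous_sessions: Optional[float] = None
    strenuous_minutes: Optional[float] = None
    moderate_sessions: Optional[float] = None
    moderate_minutes: Optional[float] = None
    disability_rating: Optional[int] = Field(default=None, ge=1, le=5)
    post_diagnosis_change: Optional[int] = Field(default=None, ge=1, le=3)

    @model_validator(mode="after")
    def _nonnegative(self) -> "ActivityProfile":
        for name in ("strenuous_sessions", "strenuous_minutes",
                     "moderate_sessions", "moderate_minutes"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        return self


GUIDELINE_NOT_MEETING = 1
GUIDELINE_MEETING = 2

#: Weekly weighted-minute threshold of the aerobic guideline.
GUIDELINE_MINUTES = 150.0
#: Weekly session threshold of the aerobic guideline.
GUIDELINE_SESSIONS = 5.0


def _sessions_and_weighted(profile: ActivityProfile) -> Optional[tuple[float, float]]:
    """Total weekly sessions and vigorous-weighted weekly minutes.

    Vigorous minutes count double.  Missing minutes are tolerated only when
    the matching session count is zero (no sessions, no duration to report);
    otherwise the profile is unresolved.
    """
    total_sessions = 0.0
    weighted = 0.0
    for sessions, minutes, weight in (
        (profile.strenuous_sessions, profile.strenuous_minutes, 2.0),
        (profile.moderate_sessions, profile.moderate_minutes, 1.0),
    ):
        if sessions is None:
            return None
        total_sessions += sessions
        if sessions > 0:
            if minutes is None:
                return None
            weighted += weight * sessions * minutes
    return total_sessions, weighted


def classify_aerobic_guideline(
    profile: ActivityProfile,
    mode: Literal["weekly-total", "literal"] = "weekly-total",
) -> Optional[int]:
    """Classify a profile against the aerobic guideline (>=150 weighted
    min/wk across >=5 sessions, vigorous minutes doubled).

    ``weekly-total`` (default) multiplies per-session minutes by session
    counts before comparing to the weekly thresholds.  ``literal`` applies
    the published two-branch decision table directly to per-session minutes
    (2*strenuous + moderate); profiles covered by neither branch are
    conservatively classified as not meeting, with a logged warning.

    Returns ``GUIDELINE_MEETING`` (2), ``GUIDELINE_NOT_MEETING`` (1), or
    ``None`` when a required item is missing.
    """
    if mode == "weekly-total":
        parts = _sessions_and_weighted(profile)
        if parts is None:
            return None
        sessions, weighted = parts
        meeting = sessions >= GUIDELINE_SESSIONS and weighted >= GUIDELINE_MINUTES
        return GUIDELINE_MEETING if meeting else GUIDELINE_NOT_MEETING

    if mode != "literal":
        raise ValueError(f"unknown mode {mode!r}")
    fields = (profile.strenuous_sessions, profile.strenuous_minutes,
              profile.moderate_sessions, profile.moderate_minutes)
    if any(f is None for f in fields):
        return None
    st_sess, st_min, mo_sess, mo_min = fields
    sessions = st_sess + mo_sess
    per_session_weighted = 2.0 * st_min + mo_min
    if sessions < GUIDELINE_SESSIONS and per_session_weighted <= GUIDELINE_MINUTES:
        return GUIDELINE_NOT_MEETING
    if sessions >= GUIDELINE_SESSIONS and per_session_weighted >= GUIDELINE_MINUTES:
        return GUIDELINE_MEETING
    logger.warning(
        "literal-mode guideline branches cover neither (sessions=%s, "
        "weighted per-session minutes=%s); classifying as not meeting",
        sessions, per_session_weighted,
    )
    return GUIDELINE_NOT_MEETING


#: Built-in intermediate formulas that cannot be expressed as comparison
#: chains (they involve arithmetic over several raw items).
BUILTIN_FORMULAS = ("aerobic_guideline",)

#: Raw-item roles a builtin formula consumes, in catalog ``inputs`` order.
AEROBIC_INPUT_ROLES = ("strenuous_sessions", "strenuous_minutes",
                       "moderate_sessions", "moderate_minutes")


# ---------------------------------------------------------------------------
# Variable definitions above the raw tier
# ---------------------------------------------------------------------------

class IntermediateVariableDef(BaseModel):
    """A value derived from raw responses.

    Either a first-match ``chain`` over raw variables or a named ``builtin``
    formula (currently only the aerobic guideline classifier, whose raw
    inputs are bound through ``inputs``: role -> raw variable name).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    description: str = ""
    chain: Optional[RuleChain] = None
    builtin: Optional[Literal["aerobic_guideline"]] = None
    inputs: dict[str, str] = Field(default_factory=dict)
    codes: dict[int, str] = Field(default_factory=dict)
    default: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "IntermediateVariableDef":
        if (self.chain is None) == (self.builtin is None):
            raise ValueError(f"{self.name}: declare exactly one of chain or builtin")
        if self.builtin == "aerobic_guideline":
            missing = set(AEROBIC_INPUT_ROLES) - set(self.inputs)
            if missing:
                raise ValueError(f"{self.name}: builtin inputs missing roles {sorted(missing)}")
        return self

    @property
    def output_codes(self) -> tuple[int, ...]:
        if self.chain is not None:
            return self.chain.codes
        codes = tuple(self.codes) or (GUIDELINE_NOT_MEETING, GUIDELINE_MEETING)
        if self.default is not None and self.default not in codes:
            codes = codes + (self.default,)
        return codes

    @property
    def referenced_variables(self) -> tuple[str, ...]:
        if self.chain is not None:
            return self.chain.referenced_variables
        return tuple(self.inputs.values())


class FeedbackVariableDef(BaseModel):
    """The message selector: a chain over raw + intermediate variables whose
    output codes are message identifiers in the bound library slot."""

    model_config = ConfigDict(frozen=True)

    name: str
    description: str = ""
    chain: RuleChain

    @property
    def output_codes(self) -> tuple[int, ...]:
        return self.chain.codes


class VariableCatalog(BaseModel):
    """A validated catalog of raw, intermediate and feedback variables.

    ``aliases`` maps alternative spellings (as they appear in rule text or
    input files) onto declared names; lookups are alias-transparent.
    """

    model_config = ConfigDict(frozen=True)

    raw: tuple[RawVariableDef, ...] = ()
    intermediate: tuple[IntermediateVariableDef, ...] = ()
    feedback: tuple[FeedbackVariableDef, ...] = ()
    aliases: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _validate(self) -> "VariableCatalog":
        if not (self.raw or self.intermediate or self.feedback):
            raise ValueError("no variables declared")
        names: set[str] = set()
        for defn in (*self.raw, *self.intermediate, *self.feedback):
            if defn.name in names:
                raise ValueError(f"duplicate variable name {defn.name!r}")
            names.add(defn.name)
        for alias, target in self.aliases.items():
            if alias in names:
                raise ValueError(f"alias {alias!r} shadows a declared variable")
            if target not in names:
                raise ValueError(f"alias {alias!r} points at undeclared {target!r}")
        raw_names = {d.name for d in self.raw}
        inter_names = {d.name for d in self.intermediate}

        def canon(name: str) -> str:
            return self.aliases.get(name, name)

        for defn in self.intermediate:
            for ref in defn.referenced_variables:
                if canon(ref) not in raw_names:
                    raise ValueError(
                        f"intermediate {defn.name!r} references {ref!r}, "
                        "which is not a declared raw variable"
                    )
        for defn in self.feedback:
            for ref in defn.chain.referenced_variables:
                if canon(ref) not in raw_names | inter_names:
                    raise ValueError(
                        f"feedback {defn.name!r} references undeclared variable {ref!r}"
                    )
        return self

    # -- lookups ----------------------------------------------------------

    def canonical(self, name: str) -> str:
        return self.aliases.get(name, name)

    @property
    def raw_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.raw)

    @property
    def topological_order(self) -> tuple[str, ...]:
        """Evaluation order: raw, then intermediate, then feedback.  The
        tiered reference rules make this a valid topological order of the
        dependency DAG by construction."""
        return tuple(d.name for d in (*self.raw, *self.intermediate, *self.feedback))

    def raw_def(self, name: str) -> RawVariableDef:
        name = self.canonical(name)
        for d in self.raw:
            if d.name == name:
                return d
        raise KeyError(name)

    def feedback_def(self, name: str) -> FeedbackVariableDef:
        for d in self.feedback:
            if d.name == name:
                return d
        raise KeyError(name)


def load_catalog(doc: Mapping) -> VariableCatalog:
    """Validate a catalog document (parsed JSON/YAML) into a catalog.

    Raises :class:`CatalogError` with the offending variable named on any
    schema violation.
    """
    try:
        return VariableCatalog.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise CatalogError(str(exc)) from exc


def read_catalog(path: Union[str, Path]) -> VariableCatalog:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return load_catalog(doc)


# ---------------------------------------------------------------------------
# Participant records and resolution
# ---------------------------------------------------------------------------

class ParticipantRecord(BaseModel):
    """One participant's variable bindings per assessment wave."""

    participant_id: str
    bindings: dict[str, dict[str, Optional[Value]]]

    @model_validator(mode="after")
    def _check(self) -> "ParticipantRecord":
        unknown = set(self.bindings) - set(WAVES)
        if unknown:
            raise ValueError(f"unknown waves {sorted(unknown)}")
        if "baseline" not in self.bindings:
            raise ValueError("baseline bindings are required")
        return self

    def merged_bindings(self, wave: str, aliases: Mapping[str, str] = ()) -> dict[str, Optional[Value]]:
        """Baseline bindings overlaid with the given wave's updates, keys
        canonicalised through ``aliases``."""
        merged: dict[str, Optional[Value]] = {}
        layers = [self.bindings["baseline"]]
        if wave != "baseline":
            layers.append(self.bindings.get(wave, {}))
        alias_map = dict(aliases) if aliases else {}
        for layer in layers:
            for key, value in layer.items():
                merged[alias_map.get(key, key)] = value
        return merged


class _AliasView(Mapping):
    """Read-only binding view that resolves alias spellings on lookup, so
    rule text may reference either spelling of an aliased variable."""

    def __init__(self, data: Mapping[str, Optional[Value]], aliases: Mapping[str, str]):
        self._data = data
        self._aliases = aliases

    def get(self, key: str, default: Optional[Value] = None) -> Optional[Value]:
        return self._data.get(self._aliases.get(key, key), default)

    def __getitem__(self, key: str) -> Optional[Value]:
        return self._data[self._aliases.get(key, key)]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)


def _profile_from_bindings(
    defn: IntermediateVariableDef, bindings: Mapping[str, Optional[Value]]
) -> ActivityProfile:
    kwargs = {role: bindings.get(raw_name) for role, raw_name in defn.inputs.items()
              if role in ActivityProfile.model_fields}
    return ActivityProfile(**kwargs)


def resolve_record(
    catalog: VariableCatalog,
    record: ParticipantRecord,
    wave: str = "baseline",
    mode: Literal["weekly-total", "literal"] = "weekly-total",
) -> dict[str, int]:
    """Resolve every intermediate and feedback variable for one wave.

    Variables are evaluated in topological order: builtins and intermediate
    chains first, their results added to the binding environment, then the
    feedback chains.  The returned map is total — missing inputs land on
    defaults (or the reserved :data:`UNRESOLVED` code for a defaultless
    builtin) — and deterministic in the record content, not in binding
    insertion order.
    """
    if wave not in WAVES:
        raise ValueError(f"unknown wave {wave!r}")
    env = record.merged_bindings(wave, catalog.aliases)
    view = _AliasView(env, catalog.aliases)
    assignments: dict[str, int] = {}
    for defn in catalog.intermediate:
        if defn.builtin == "aerobic_guideline":
            result = classify_aerobic_guideline(_profile_from_bindings(defn, view), mode)
            if result is None:
                result = defn.default
        else:
            try:
                result = evaluate_rule_chain(defn.chain, view)
            except RuleTypeError as exc:
                raise RuleTypeError(f"{defn.name}: {exc}") from exc
        if result is None:
            assignments[defn.name] = UNRESOLVED
            env[defn.name] = None
        else:
            assignments[defn.name] = result
            env[defn.name] = result
    for defn in catalog.feedback:
        try:
            assignments[defn.name] = evaluate_rule_chain(defn.chain, view)
        except RuleTypeError as exc:
            raise RuleTypeError(f"{defn.name}: {exc}") from exc
    logger.debug("resolved %s/%s: %s", record.participant_id, wave, assignments)
    return assignments


# ---------------------------------------------------------------------------
# Cohort CSV I/O (one row per participant per wave, empty cell = missing)
# ---------------------------------------------------------------------------

def load_cohort_csv(path: Union[str, Path], catalog: VariableCatalog) -> list[ParticipantRecord]:
    """Read participant data laid out as one row per participant per wave,
    with columns ``participant_id``, ``wave`` and the raw variable names."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_records(frame, catalog)


def frame_to_records(frame: pd.DataFrame, catalog: VariableCatalog) -> list[ParticipantRecord]:
    required = {"participant_id", "wave"}
    if not required <= set(frame.columns):
        raise CatalogError(f"cohort table needs columns {sorted(required)}")
    known = set(catalog.raw_names) | set(catalog.aliases)
    var_cols = [c for c in frame.columns if c not in required]
    unknown = [c for c in var_cols if c not in known]
    if unknown:
        raise CatalogError(f"cohort table has undeclared variable columns {unknown}")
    by_pid: dict[str, dict[str, dict[str, Optional[Value]]]] = {}
    for _, row in frame.iterrows():
        wave = row["wave"]
        if wave not in WAVES:
            raise CatalogError(f"unknown wave {wave!r} in cohort table")
        binding: dict[str, Optional[Value]] = {}
        for col in var_cols:
            name = catalog.canonical(col)
            value = catalog.raw_def(name).domain.coerce(row[col])
            if value is not None:
                binding[name] = value
        by_pid.setdefault(str(row["participant_id"]), {})[wave] = binding
    return [
        ParticipantRecord(participant_id=pid, bindings=waves)
        for pid, waves in by_pid.items()
    ]


def records_to_frame(records: Sequence[ParticipantRecord], catalog: VariableCatalog) -> pd.DataFrame:
    """Flatten records back to the one-row-per-wave CSV contract."""
    rows = []
    for record in records:
        for wave in WAVES:
            if wave not in record.bindings:
                continue
            row: dict[str, object] = {"participant_id": record.participant_id, "wave": wave}
            for name in catalog.raw_names:
                value = record.bindings[wave].get(name)
                row[name] = "" if value is None else value
            rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "wave", *catalog.raw_names])


def assignments_to_json(
    assignments: Mapping[str, Mapping[str, Mapping[str, int]]]
) -> str:
    """Serialise assignment maps keyed by participant id and wave."""
    return json.dumps(assignments, indent=2, sort_keys=True)
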