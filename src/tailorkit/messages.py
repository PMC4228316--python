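"""Message library, merge-field rendering and newsletter assembly.

Each newsletter follows a fixed five-slot layout: a welcome message, targeted
expert advice (non-tailored), feedback on activity behaviour, a persuasive
message content-matched on Social Cognitive Theory constructs, and an action
planning task.  Tailored slots are bound to a feedback variable; the variable
engine's assignment map selects which message block fills the slot.  Assembly
is a pure function of its inputs, so identical inputs give byte-identical
documents.
"""

from __future__ import annotations

import itertools
import json
import re
from typing import Literal, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import AssemblyError, LibraryError, MergeFieldError
from .variables import (
    ActivityProfile,
    ParticipantRecord,
    RuleChain,
    Value,
    VariableCatalog,
    WAVES,
    _sessions_and_weighted,
    evaluate_rule_chain,
)

#: The five newsletter slots, in printed order.
SLOTS = ("welcome", "expert_advice", "behaviour_feedback", "persuasive_sct", "action_plan")

#: Social Cognitive Theory construct taxonomy used to index message content.
SCT_CONSTRUCTS = frozenset({
    "self-efficacy",
    "environment",
    "behavioural capability",
    "expectations",
    "self-control",
    "observational learning",
})

#: Guideline reference level shown on every feedback chart (weighted min/wk).
CHART_REFERENCE = 150.0

_FIELD_RE = re.compile(r"\{\{\s*([A-Za-z_][A-Za-z0-9_.]*)\s*\}\}")

DEFAULT_FALLBACKS: dict[str, str] = {"first_name": "participant"}


class MessageBlockDef(BaseModel):
    """One message variant: body text with merge fields, indexed by slot and
    (for tailored slots) by the feedback code that selects it."""

    model_config = ConfigDict(frozen=True)

    slot: str
    code: Optional[int] = None
    objective: str = ""
    constructs: tuple[str, ...] = ()
    body: str
    tailored: bool = False

    @model_validator(mode="after")
    def _check(self) -> "MessageBlockDef":
        if self.slot not in SLOTS:
            raise ValueError(f"unknown slot {self.slot!r}")
        bad = set(self.constructs) - SCT_CONSTRUCTS
        if bad:
            raise ValueError(f"unknown SCT construct(s) {sorted(bad)}")
        if self.tailored and self.code is None:
            raise ValueError(f"tailored block in slot {self.slot!r} needs a code")
        if not self.tailored and self.code is not None:
            raise ValueError(f"non-tailored block in slot {self.slot!r} must not set a code")
        return self

    @property
    def merge_fields(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(_FIELD_RE.findall(self.body)))


class NewsletterTemplate(BaseModel):
    """Per-wave layout: which feedback variable (if any) drives each slot."""

    model_config = ConfigDict(frozen=True)

    wave: int = Field(ge=1, le=3)
    bindings: dict[str, Optional[str]]

    @field_validator("bindings")
    @classmethod
    def _exact_slots(cls, v: dict[str, Optional[str]]) -> dict[str, Optional[str]]:
        if tuple(v) != SLOTS:
            raise ValueError(f"template must list exactly the slots {SLOTS} in order")
        return v


class MessageLibrary(BaseModel):
    """Validated message content plus the per-wave templates.

    ``declared_fields`` is the closed set of merge fields bodies may use;
    ``fallbacks`` supplies default text when a binding is missing (e.g. the
    salutation for a participant who left the name field empty).
    """

    model_config = ConfigDict(frozen=True)

    blocks: tuple[MessageBlockDef, ...]
    templates: tuple[NewsletterTemplate, ...]
    declared_fields: tuple[str, ...] = ()
    fallbacks: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_FALLBACKS))

    @model_validator(mode="after")
    def _check(self) -> "MessageLibrary":
        seen: set[tuple[str, Optional[int]]] = set()
        declared = set(self.declared_fields)
        for block in self.blocks:
            key = (block.slot, block.code)
            if key in seen:
                raise ValueError(f"duplicate message for slot/code {key}")
            seen.add(key)
            undeclared = set(block.merge_fields) - declared
            if undeclared:
                raise ValueError(
                    f"block {key} uses undeclared merge field(s) {sorted(undeclared)}"
                )
        waves = [t.wave for t in self.templates]
        if len(set(waves)) != len(waves):
            raise ValueError("duplicate template wave numbers")
        for template in self.templates:
            bound = template.bindings["persuasive_sct"]
            if bound is not None:
                persuasive = [b for b in self.blocks if b.slot == "persuasive_sct"]
                if persuasive and not any(b.constructs for b in persuasive):
                    raise ValueError("persuasive_sct blocks must declare >=1 SCT construct")
        return self

    def block_for(self, slot: str, code: Optional[int]) -> Optional[MessageBlockDef]:
        for block in self.blocks:
            if block.slot == slot and block.code == code:
                return block
        return None

    def codes_for(self, slot: str) -> tuple[int, ...]:
        return tuple(b.code for b in self.blocks if b.slot == slot and b.code is not None)

    def template_for(self, wave: int) -> NewsletterTemplate:
        for template in self.templates:
            if template.wave == wave:
                return template
        raise LibraryError(f"no template for wave {wave}")


def load_library(doc: Mapping) -> MessageLibrary:
    """Validate a library document (parsed JSON/YAML)."""
    try:
        return MessageLibrary.model_validate(doc)
    except Exception as exc:
        raise LibraryError(str(exc)) from exc


def read_library(path) -> MessageLibrary:
    from pathlib import Path

    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return load_library(doc)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_block(
    block: MessageBlockDef,
    bindings: Mapping[str, Optional[Value]],
    fallbacks: Optional[Mapping[str, str]] = None,
    declared_fields: Optional[Sequence[str]] = None,
) -> str:
    """Substitute every merge field in the block body.

    Missing bindings fall back to the configured default text (the
    default-message principle extended to merge fields); a field with
    neither binding nor fallback, or one outside ``declared_fields``, raises
    :class:`MergeFieldError`.  The output never contains the ``{{``
    delimiter.
    """
    fallbacks = dict(DEFAULT_FALLBACKS if fallbacks is None else fallbacks)

    def substitute(match: re.Match) -> str:
        field = match.group(1)
        if declared_fields is not None and field not in declared_fields:
            raise MergeFieldError(f"undeclared merge field {field!r}")
        value = bindings.get(field)
        if value is None or value == "":
            if field in fallbacks:
                return fallbacks[field]
            raise MergeFieldError(f"no binding or fallback for merge field {field!r}")
        return str(value)

    return _FIELD_RE.sub(substitute, block.body)


# ---------------------------------------------------------------------------
# Feedback chart
# ---------------------------------------------------------------------------

class FeedbackChart(BaseModel):
    """Weekly weighted aerobic minutes per wave, against the guideline
    reference line — the past-behaviour graph printed in each newsletter."""

    model_config = ConfigDict(frozen=True)

    series: tuple[float, ...]
    labels: tuple[str, ...]
    reference: float = CHART_REFERENCE
    available: bool = True

    @model_validator(mode="after")
    def _check(self) -> "FeedbackChart":
        if len(self.series) != len(self.labels):
            raise ValueError("series and labels must align")
        return self


def _weighted_minutes(
    bindings: Mapping[str, Optional[Value]], inputs: Mapping[str, str]
) -> Optional[float]:
    kwargs = {role: bindings.get(name) for role, name in inputs.items()
              if role in ActivityProfile.model_fields}
    parts = _sessions_and_weighted(ActivityProfile(**kwargs))
    return None if parts is None else parts[1]


def activity_inputs(catalog: VariableCatalog) -> Mapping[str, str]:
    """Role -> raw-variable mapping of the catalog's guideline classifier."""
    for defn in catalog.intermediate:
        if defn.builtin == "aerobic_guideline":
            return defn.inputs
    raise LibraryError("catalog declares no aerobic_guideline intermediate")


def build_feedback_chart(
    record: ParticipantRecord,
    wave: int,
    catalog: VariableCatalog,
) -> FeedbackChart:
    """Chart the weighted weekly minutes of every wave with data up to and
    including ``wave``.  Waves with unresolved activity are skipped; a chart
    with no points is flagged unavailable."""
    inputs = activity_inputs(catalog)
    series: list[float] = []
    labels: list[str] = []
    for wave_name in WAVES[:wave]:
        bindings = record.bindings.get(wave_name)
        if not bindings:
            continue
        minutes = _weighted_minutes(bindings, inputs)
        if minutes is not None:
            series.append(float(minutes))
            labels.append(wave_name)
    return FeedbackChart(
        series=tuple(series), labels=tuple(labels), available=bool(series)
    )


def plot_feedback_chart(chart: FeedbackChart, path) -> None:
    """Optional raster rendering of a chart (the canonical payload is the
    data itself)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(chart.series)), chart.series, tick_label=list(chart.labels))
    ax.axhline(chart.reference, color="red", linestyle="--", label="guideline")
    ax.set_ylabel("weighted aerobic minutes per week")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Coverage validation
# ---------------------------------------------------------------------------

class SlotCoverage(BaseModel):
    wave: int
    slot: str
    feedback_variable: str
    needed_codes: tuple[int, ...]
    unmapped_codes: tuple[int, ...]
    orphan_codes: tuple[int, ...]
    default_code: int
    default_present: bool


class CoverageReport(BaseModel):
    entries: tuple[SlotCoverage, ...]

    @property
    def passed(self) -> bool:
        return all(not e.unmapped_codes and e.default_present for e in self.entries)

    @property
    def warnings(self) -> tuple[str, ...]:
        return tuple(
            f"wave {e.wave} slot {e.slot}: message(s) {list(e.orphan_codes)} "
            "are never produced by the bound chain"
            for e in self.entries
            if e.orphan_codes
        )


_ENUMERATION_LIMIT = 20_000


def _value_space(catalog: VariableCatalog, name: str) -> Optional[list[Optional[Value]]]:
    """Finite value space (including missing) of a chain input, or None when
    the variable is numeric/free-text and cannot be enumerated."""
    name = catalog.canonical(name)
    for defn in catalog.intermediate:
        if defn.name == name:
            return [None, *defn.output_codes]
    try:
        domain = catalog.raw_def(name).domain
    except KeyError:
        return None
    if domain.kind == "coded-category":
        return [None, *domain.levels]
    return None


def reachable_codes(catalog: VariableCatalog, chain: RuleChain) -> tuple[int, ...]:
    """Codes a chain can actually emit, by brute-force enumeration over the
    (finite) domains of its referenced variables.  Falls back to the
    syntactic code set when a referenced domain is not enumerable or the
    product space is too large."""
    spaces = []
    for ref in chain.referenced_variables:
        space = _value_space(catalog, ref)
        if space is None:
            return chain.codes
        spaces.append(space)
    total = 1
    for space in spaces:
        total *= len(space)
        if total > _ENUMERATION_LIMIT:
            return chain.codes
    names = chain.referenced_variables
    reached: set[int] = set()
    for combo in itertools.product(*spaces):
        reached.add(evaluate_rule_chain(chain, dict(zip(names, combo))))
    return tuple(sorted(reached))


def validate_coverage(library: MessageLibrary, catalog: VariableCatalog) -> CoverageReport:
    """Check that every code a tailored slot's chain can produce has a
    message, that the default message exists, and flag orphan messages."""
    entries = []
    for template in library.templates:
        for slot, feedback_name in template.bindings.items():
            if feedback_name is None:
                continue
            chain = catalog.feedback_def(feedback_name).chain
            needed = reachable_codes(catalog, chain)
            have = set(library.codes_for(slot))
            unmapped = tuple(c for c in needed if c not in have)
            orphans = tuple(sorted(have - set(needed)))
            entries.append(SlotCoverage(
                wave=template.wave,
                slot=slot,
                feedback_variable=feedback_name,
                needed_codes=needed,
                unmapped_codes=unmapped,
                orphan_codes=orphans,
                default_code=chain.default,
                default_present=chain.default in have,
            ))
    return CoverageReport(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class RenderedBlock(BaseModel):
    model_config = ConfigDict(frozen=True)

    slot: str
    code: Optional[int]
    constructs: tuple[str, ...]
    text: str


class NewsletterDocument(BaseModel):
    """One assembled newsletter: five rendered blocks plus the chart payload.

    ``iterative`` records whether update-card data informed the content;
    it is always False for the first wave.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    wave: int
    blocks: tuple[RenderedBlock, ...]
    chart: FeedbackChart
    iterative: bool = False

    @model_validator(mode="after")
    def _check(self) -> "NewsletterDocument":
        if tuple(b.slot for b in self.blocks) != SLOTS:
            raise ValueError("document must hold one block per slot, in order")
        if self.wave == 1 and self.iterative:
            raise ValueError("wave-1 documents cannot be iterative")
        return self


def assemble_newsletter(
    template: NewsletterTemplate,
    library: MessageLibrary,
    assignments: Mapping[str, int],
    record: ParticipantRecord,
    chart: FeedbackChart,
    iterative: bool = False,
    wave_key: str = "baseline",
) -> NewsletterDocument:
    """Fill the five slots deterministically from the assignment map.

    A tailored slot whose feedback code has no message raises
    :class:`AssemblyError`; this cannot happen for inputs that passed
    :func:`validate_coverage`.
    """
    bindings = record.merged_bindings(wave_key)
    rendered: list[RenderedBlock] = []
    for slot, feedback_name in template.bindings.items():
        if feedback_name is None:
            block = library.block_for(slot, None)
            if block is None:
                raise AssemblyError(f"library has no non-tailored block for slot {slot!r}")
        else:
            if feedback_name not in assignments:
                raise AssemblyError(
                    f"assignment map lacks a code for feedback variable {feedback_name!r}"
                )
            code = assignments[feedback_name]
            block = library.block_for(slot, code)
            if block is None:
                raise AssemblyError(
                    f"no message for slot {slot!r} code {code} "
                    f"(feedback variable {feedback_name!r})"
                )
        text = render_block(block, bindings, library.fallbacks,
                            library.declared_fields or None)
        rendered.append(RenderedBlock(
            slot=slot, code=block.code, constructs=block.constructs, text=text,
        ))
    return NewsletterDocument(
        participant_id=record.participant_id,
        wave=template.wave,
        blocks=tuple(rendered),
        chart=chart,
        iterative=iterative,
    )


def document_to_json(document: NewsletterDocument) -> str:
    """Canonical serialisation: sorted keys, fixed separators, so identical
    inputs give byte-identical output."""
    return json.dumps(document.model_dump(mode="json"), sort_keys=True,
                      separators=(",", ":"))


def document_to_html(document: NewsletterDocument) -> str:
    """Minimal human-readable rendering of an assembled newsletter."""
    parts = [
        "<html><body>",
        f"<h1>Newsletter {document.wave} — participant "
        f"{document.participant_id}</h1>",
    ]
    for block in document.blocks:
        parts.append(f"<h2>{block.slot}</h2>")
        parts.append(f"<p>{block.text}</p>")
    if document.chart.available:
        points = ", ".join(
            f"{label}: {minutes:g} min"
            for label, minutes in zip(document.chart.labels, document.chart.series)
        )
        parts.append(
            f"<p>Weekly weighted aerobic minutes ({points}; "
            f"guideline {document.chart.reference:g} min/wk)</p>"
        )
    parts.append("</body></html>")
    return "\n".join(parts)
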