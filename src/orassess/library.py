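"""The scenario library: manifest, placeholder bindings, and rendering.

The needs-assessment document is assembled from a fixed library of 45
hypothetical OR-management scenarios organized into 19 chapters (from
definitions of OR efficiency through releasing allocated time, moving
cases, and sequencing urgent cases).  Each scenario body may contain
placeholders ``[S1]``..``[S9]`` that are bound to facility-specific
values (service names, OR names, clock times, counts) derived from the
facility's case log, so the cues managers read match their daily reality.

Two scenario bodies in the library are full published worked examples —
the release-of-allocated-time scenario and the day-of-surgery
prioritization scenario; the remaining bodies are stand-ins authored to
their chapter topics and flagged ``stand_in`` in the manifest.  Two
scenarios are not adaptable from case-log data at all (they would need
per-case anesthesia-provider type and procedure vocabularies) and always
render with their library text.

Placeholder binding follows one of two schemes:

* ``release`` — S1 = ORs allocated to named services on the chosen
  weekday, S2–S4 = three alphabetical single-OR services, S5 = that
  weekday (plural), S6 = the median number of first-case starts;
* ``priority`` — S1/S2 = the two busiest ORs, S3 = modal workday start,
  S4 = the late-running end (workday end + 2 h), S5 = workday end.

Clock times render with a non-breaking space before AM/PM so a line wrap
can never split them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .errors import BindingError, ManifestError, RenderError
from .parameters import FacilityProfile
from .times import WEEKDAY_NAMES, format_clock

PLACEHOLDER_RE = re.compile(r"\[S(\d)\]")

N_CHAPTERS = 19
N_SCENARIOS = 45
N_ADAPTABLE = 43

PREDICATES = (
    "ALWAYS",
    "NEEDS_3_SINGLE_OR_SERVICES",
    "NEEDS_OTHER_EXACTLY_1_OR",
    "NEEDS_PARTIAL_WEEK_SERVICE",
    "NEEDS_MULTI_OR_SERVICE",
)


@dataclass(frozen=True)
class Chapter:
    index: int
    title: str
    n_scenarios: int
    explanation: str


@dataclass(frozen=True)
class ScenarioTemplate:
    chapter_index: int
    ordinal: int
    body: str
    adaptable: bool
    applicability_rule: str
    scheme: str  # "release", "priority", or "none"
    stand_in: bool

    @property
    def placeholders(self) -> list[str]:
        """Distinct placeholder keys present in the body, e.g. ["S1", "S2"]."""
        seen: list[str] = []
        for m in PLACEHOLDER_RE.finditer(self.body):
            key = f"S{m.group(1)}"
            if key not in seen:
                seen.append(key)
        return seen

    @property
    def n_params(self) -> int:
        return len(self.placeholders)


def _read_data_text(name: str) -> str:
    return (resources.files("orassess") / "data" / name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def _load_raw():
    return yaml.safe_load(_read_data_text("manifest.yaml"))


def load_manifest() -> tuple[list[Chapter], list[ScenarioTemplate]]:
    """Load and integrity-check the packaged chapter/scenario manifest.

    Guarantees: 19 chapters with contiguous indices, per-chapter scenario
    counts matching the shipped templates and summing to 45, exactly 2
    non-adaptable templates, and 0–9 distinct placeholders per body.
    """
    raw = _load_raw()
    chapters = [
        Chapter(
            index=int(c["index"]),
            title=str(c["title"]),
            n_scenarios=int(c["scenarios"]),
            explanation=str(c["explanation"]).strip(),
        )
        for c in raw["chapters"]
    ]
    if [c.index for c in chapters] != list(range(1, N_CHAPTERS + 1)):
        raise ManifestError("chapter indices must be contiguous 1..19")
    if sum(c.n_scenarios for c in chapters) != N_SCENARIOS:
        raise ManifestError("chapter scenario counts must sum to 45")

    templates: list[ScenarioTemplate] = []
    for t in raw["templates"]:
        body = _read_data_text(f"templates/{t['file']}")
        tpl = ScenarioTemplate(
            chapter_index=int(t["chapter"]),
            ordinal=int(t["ordinal"]),
            body=body.strip("\n"),
            adaptable=bool(t["adaptable"]),
            applicability_rule=str(t["predicate"]),
            scheme=str(t.get("scheme", "none")),
            stand_in=bool(t.get("stand_in", True)),
        )
        if tpl.applicability_rule not in PREDICATES:
            raise ManifestError(f"unknown predicate {tpl.applicability_rule!r} in {t['file']}")
        if tpl.n_params > 9:
            raise ManifestError(f"template {t['file']} has {tpl.n_params} placeholders (max 9)")
        if not tpl.adaptable and tpl.n_params > 0:
            raise ManifestError(f"non-adaptable template {t['file']} contains placeholders")
        templates.append(tpl)
    templates.sort(key=lambda t: (t.chapter_index, t.ordinal))

    per_chapter: dict[int, int] = {}
    for tpl in templates:
        per_chapter[tpl.chapter_index] = per_chapter.get(tpl.chapter_index, 0) + 1
    for c in chapters:
        if per_chapter.get(c.index, 0) != c.n_scenarios:
            raise ManifestError(
                f"chapter {c.index} lists {c.n_scenarios} scenarios but "
                f"{per_chapter.get(c.index, 0)} templates are packaged"
            )
    if sum(1 for t in templates if not t.adaptable) != N_SCENARIOS - N_ADAPTABLE:
        raise ManifestError("exactly 2 templates must be non-adaptable")
    return chapters, templates


def default_bindings(scheme: str) -> dict[str, str]:
    """Library-default placeholder values used for non-adapted rendering."""
    raw = _load_raw()
    return {k: str(v) for k, v in raw["default_bindings"].get(scheme, {}).items()}


def bindings_from_profile(
    profile: FacilityProfile, template: ScenarioTemplate
) -> dict[str, str]:
    """Bind every placeholder in the template from the facility profile.

    Numbers render as plain integers, clock times as ``h:MM AM/PM`` with
    a non-breaking space, weekdays in plural ("Thursdays").  A placeholder
    whose source parameter is absent from the profile raises
    :class:`~orassess.errors.BindingError` naming the placeholder.
    """
    values: dict[str, str | None] = {}
    if template.scheme == "release":
        values["S1"] = (
            None if profile.n_allocated_ors is None else str(profile.n_allocated_ors)
        )
        svcs = profile.single_or_services or [None, None, None]
        values["S2"], values["S3"], values["S4"] = svcs[0], svcs[1], svcs[2]
        values["S5"] = (
            None
            if profile.single_or_day is None
            else WEEKDAY_NAMES[profile.single_or_day] + "s"
        )
        n_starts = (
            profile.median_first_starts.get(profile.single_or_day)
            if profile.single_or_day is not None
            else None
        )
        values["S6"] = None if n_starts is None else str(n_starts)
    elif template.scheme == "priority":
        ors = profile.busiest_ors
        values["S1"] = ors[0] if len(ors) > 0 else None
        values["S2"] = ors[1] if len(ors) > 1 else None
        values["S3"] = None if profile.workday_start is None else format_clock(profile.workday_start)
        values["S4"] = (
            None if profile.scenario_end_late is None else format_clock(profile.scenario_end_late)
        )
        values["S5"] = None if profile.workday_end is None else format_clock(profile.workday_end)
    elif template.scheme != "none":
        raise BindingError(f"unknown binding scheme {template.scheme!r}")

    out: dict[str, str] = {}
    for key in template.placeholders:
        if values.get(key) is None:
            raise BindingError(
                f"placeholder [{key}] of chapter {template.chapter_index} scenario "
                f"{template.ordinal} cannot be bound: source parameter absent from profile"
            )
        out[key] = values[key]
    return out


def render(template: ScenarioTemplate | str, binding: dict[str, str]) -> str:
    """Substitute every placeholder occurrence; the result contains no "[S".

    An unbound placeholder in the body raises
    :class:`~orassess.errors.RenderError`; a binding key absent from the
    body only warns.
    """
    body = template.body if isinstance(template, ScenarioTemplate) else template
    present = {f"S{m.group(1)}" for m in PLACEHOLDER_RE.finditer(body)}
    unbound = present - set(binding)
    if unbound:
        raise RenderError(f"unbound placeholder(s): {sorted(unbound)}")
    unused = set(binding) - present
    if unused:
        warnings.warn(f"binding keys not present in body: {sorted(unused)}", stacklevel=2)
    return PLACEHOLDER_RE.sub(lambda m: binding[f"S{m.group(1)}"], body)


def applicable(template: ScenarioTemplate, profile: FacilityProfile) -> bool:
    """Decide whether a scenario applies to the facility.

    Scenarios whose premise cannot occur at the facility (e.g. one built
    around a service holding several ORs when no named service is
    allocated more than one) are excluded from its collection.
    """
    rule = template.applicability_rule
    named = [a for a in profile.allocations if a.service != "OTHER" and not a.pooled_to_other]
    if rule == "ALWAYS":
        return True
    if rule == "NEEDS_3_SINGLE_OR_SERVICES":
        return profile.single_or_day is not None
    if rule == "NEEDS_OTHER_EXACTLY_1_OR":
        return any(
            a.service == "OTHER" and a.n_ors == 1 for a in profile.allocations
        )
    if rule == "NEEDS_PARTIAL_WEEK_SERVICE":
        # some named service allocated OR time on some but not all of Mon-Fri
        by_service: dict[str, set[int]] = {}
        for a in named:
            if a.n_ors > 0 and a.weekday < 5:
                by_service.setdefault(a.service, set()).add(a.weekday)
        return any(0 < len(days) < 5 for days in by_service.values())
    if rule == "NEEDS_MULTI_OR_SERVICE":
        return any(a.n_ors >= 2 for a in named)
    raise ManifestError(f"unknown predicate {rule!r}")
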