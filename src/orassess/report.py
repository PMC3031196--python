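"""Assembly of the needs-assessment document.

The document presented to a facility's OR managers contains an
automatically generated table of contents, one explanation per retained
chapter, one page per retained scenario (header = chapter title plus the
scenario's within-chapter number in parentheses), and a bibliography.
Scenarios whose applicability predicate fails for the facility are
excluded, and the remaining scenarios are renumbered within each chapter
— which is exactly why the table of contents must be generated rather
than fixed.

When the facility failed the workload-stationarity check (or for the two
scenarios that cannot be adapted from case-log data), scenario bodies
render with the library's default parameter values instead of
facility-derived ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError
from .library import (
    Chapter,
    ScenarioTemplate,
    applicable,
    bindings_from_profile,
    default_bindings,
    load_manifest,
    render,
)
from .parameters import FacilityProfile


@dataclass(frozen=True)
class ScenarioPage:
    chapter_index: int
    chapter_title: str
    number_in_chapter: int
    header: str
    body: str
    adapted: bool


@dataclass
class NeedsAssessmentReport:
    facility_id: str
    chapters: list[Chapter] = field(default_factory=list)  # retained, in order
    pages: list[ScenarioPage] = field(default_factory=list)
    explanations: dict[int, str] = field(default_factory=dict)
    bibliography: str = ""

    @property
    def toc(self) -> list[tuple[int, str, int]]:
        """(chapter index, title, retained scenario count), in chapter order."""
        counts: dict[int, int] = {}
        for p in self.pages:
            counts[p.chapter_index] = counts.get(p.chapter_index, 0) + 1
        return [(c.index, c.title, counts[c.index]) for c in self.chapters]


def build_report(
    profile: FacilityProfile,
    library: tuple[list[Chapter], list[ScenarioTemplate]] | None = None,
) -> NeedsAssessmentReport:
    """Select, adapt, and order the scenarios for one facility.

    Applies each template's applicability predicate, renders retained
    templates with profile-derived bindings (library defaults when the
    template is non-adaptable or facility adaptation is disabled), and
    numbers the retained scenarios 1..k within each chapter.
    """
    chapters, templates = library if library is not None else load_manifest()
    by_index = {c.index: c for c in chapters}
    pages: list[ScenarioPage] = []
    counters: dict[int, int] = {}
    for tpl in templates:  # already sorted by (chapter, ordinal)
        if not applicable(tpl, profile):
            continue
        adapt = tpl.adaptable and profile.adaptation_enabled and tpl.scheme != "none"
        if adapt:
            binding = bindings_from_profile(profile, tpl)
        else:
            binding = {
                k: v
                for k, v in default_bindings(tpl.scheme).items()
                if k in tpl.placeholders
            }
        body = render(tpl, binding)
        counters[tpl.chapter_index] = counters.get(tpl.chapter_index, 0) + 1
        title = by_index[tpl.chapter_index].title
        k = counters[tpl.chapter_index]
        pages.append(
            ScenarioPage(
                chapter_index=tpl.chapter_index,
                chapter_title=title,
                number_in_chapter=k,
                header=f"{title} - Scenario ({k})",
                body=body,
                adapted=adapt,
            )
        )
    if not pages:
        raise ValidationError("no scenario applies to this facility; nothing to report")
    retained = [by_index[i] for i in sorted(counters)]
    bibliography = (resources.files("orassess") / "data" / "bibliography.md").read_text(
        encoding="utf-8"
    )
    return NeedsAssessmentReport(
        facility_id=profile.facility_id,
        chapters=retained,
        pages=pages,
        explanations={c.index: c.explanation for c in retained},
        bibliography=bibliography,
    )


def write_markdown(report: NeedsAssessmentReport, path: str | Path) -> None:
    """Write the report as deterministic Markdown (byte-identical per input).

    Layout: title, table of contents, then per chapter its explanation
    followed by one page-delimited section per scenario, then the
    bibliography.
    """
    lines: list[str] = []
    lines.append(f"# Needs Assessment — {report.facility_id}")
    lines.append("")
    lines.append("## Table of Contents")
    lines.append("")
    for index, title, count in report.toc:
        noun = "scenario" if count == 1 else "scenarios"
        lines.append(f"{index}. {title} ({count} {noun})")
    lines.append("")
    for chapter in report.chapters:
        lines.append(f"## {chapter.index}. {chapter.title}")
        lines.append("")
        lines.append("### Explanation")
        lines.append("")
        lines.append(report.explanations[chapter.index])
        lines.append("")
        for page in report.pages:
            if page.chapter_index != chapter.index:
                continue
            lines.append("---")
            lines.append("")
            lines.append(f"### {page.header}")
            lines.append("")
            lines.append(page.body)
            lines.append("")
    lines.append("## Bibliography")
    lines.append("")
    lines.append(report.bibliography.strip())
    lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
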