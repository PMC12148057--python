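"""Per-task prompt templates and augmented-prompt rendering.

Templates are plain-text package resources (one file per task) with
single-brace named placeholders and a brace-doubling escape, so users can
edit them or point ``template_dir`` at overrides.  Substituted values are
inserted literally — a value containing ``{name}`` is never re-expanded.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ._errors import TemplateError

TASK_IDS = (
    "analyze_quality",
    "recommend_normalization",
    "analyze_variable_features",
    "recommend_pcs",
    "analyze_pcs",
    "recommend_k",
    "recommend_res",
    "analyze_and_annotate",
    "analyze_enrichment",
    "summary_network",
)

EXPERIMENT_PLACEHOLDER = "experiment_description"
NO_DESCRIPTION_SENTENCE = "No experiment description was provided."


@dataclass
class PromptTemplate:
    task_id: str
    text: str
    required_placeholders: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        found = placeholders_in(self.text)
        if not self.required_placeholders:
            self.required_placeholders = tuple(sorted(found))
        else:
            missing = set(self.required_placeholders) - found
            if missing:
                raise TemplateError(
                    f"template {self.task_id}: required placeholders not in "
                    f"text: {sorted(missing)}"
                )


@dataclass
class AugmentedPrompt:
    task_id: str
    text: str
    substitutions: dict[str, str] = field(default_factory=dict)


def placeholders_in(text: str) -> set[str]:
    names = set()
    for _, name, _, _ in string.Formatter().parse(text):
        if name:
            names.add(name)
    return names


def get_template(task_id: str, template_dir: str | Path | None = None) -> PromptTemplate:
    """Return the packaged template for a task, or the user override when a
    ``template_dir`` contains ``<task_id>.txt``."""
    if task_id not in TASK_IDS:
        raise TemplateError(
            f"unknown task {task_id!r}; valid tasks: {', '.join(TASK_IDS)}"
        )
    if template_dir is not None:
        override = Path(template_dir) / f"{task_id}.txt"
        if override.exists():
            return PromptTemplate(task_id, override.read_text(encoding="utf-8"))
    ref = resources.files("scadvisor").joinpath("templates", f"{task_id}.txt")
    return PromptTemplate(task_id, ref.read_text(encoding="utf-8"))


class _LiteralFormatter(string.Formatter):
    """str.format semantics, but raises a named error on missing keys and
    never applies conversions/format specs to untrusted values."""

    def get_value(self, key, args, kwargs):
        try:
            return kwargs[key]
        except KeyError:
            raise TemplateError(f"unfilled: {key}") from None

    def format_field(self, value, format_spec):
        return str(value)


def render_prompt(
    template: PromptTemplate,
    values: dict[str, str],
    experiment_description: str | None = None,
) -> AugmentedPrompt:
    """Substitute every placeholder; deterministic and non-recursive.

    ``experiment_description`` fills its dedicated placeholder; when absent
    it resolves to a fixed "not provided" sentence rather than empty text.
    """
    subs = {k: str(v) for k, v in values.items()}
    if EXPERIMENT_PLACEHOLDER in placeholders_in(template.text):
        subs.setdefault(
            EXPERIMENT_PLACEHOLDER,
            experiment_description or NO_DESCRIPTION_SENTENCE,
        )
    elif experiment_description:
        subs.setdefault(EXPERIMENT_PLACEHOLDER, experiment_description)
    rendered = _LiteralFormatter().vformat(template.text, (), subs)
    applied = {k: subs[k] for k in placeholders_in(template.text) if k in subs}
    return AugmentedPrompt(
        task_id=template.task_id, text=rendered, substitutions=applied
    )


def format_number(x) -> str:
    """Full-precision rendering so the LLM sees exactly what was computed."""
    if isinstance(x, float):
        return repr(x)
    return str(x)
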