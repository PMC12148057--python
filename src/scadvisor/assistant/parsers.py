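"""Structured parsing of LLM response text into task payloads.

Parsers are intentionally forgiving about surrounding prose but strict
about the core structure: when the structure is absent they raise
:class:`ParseError` and the caller preserves the raw text.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .._errors import ParseError

_NUMBER = r"[-+]?\d{1,3}(?:,\d{3})+(?:\.\d+)?|[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"


def _to_float(token: str) -> float:
    return float(token.replace(",", ""))


# ---------------------------------------------------------------------------
# resolution ranges
# ---------------------------------------------------------------------------

@dataclass
class ResolutionRange:
    start: float
    stop: float
    step: float
    reasoning: str = ""

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ParseError(f"step must be positive, got {self.step}")
        if self.start > self.stop:
            raise ParseError(
                f"range start {self.start} exceeds stop {self.stop}"
            )
        if (
            self.start != self.stop
            and self.step > (self.stop - self.start) + 1e-9
        ):
            raise ParseError(
                f"step {self.step} exceeds span {self.stop - self.start}"
            )


_SEQ_RE = re.compile(
    rf"seq\(\s*({_NUMBER})\s*,\s*({_NUMBER})\s*,\s*({_NUMBER})\s*\)"
)
_TO_RE = re.compile(
    rf"({_NUMBER})\s+to\s+({_NUMBER})\s+(?:\w+\s+){{0,3}}?"
    rf"(?:steps?|increments?)\s+of\s+({_NUMBER})",
    re.IGNORECASE,
)


def parse_seq_range(text: str) -> ResolutionRange:
    """Parse ``seq(a, b, s)`` or ``a to b ... (steps|increments) of s``.

    The first recognizable match wins; free prose with no range raises.
    """
    if not text:
        raise ParseError("empty text")
    matches = []
    for regex in (_SEQ_RE, _TO_RE):
        m = regex.search(text)
        if m:
            matches.append(m)
    if not matches:
        raise ParseError("no recognizable range (seq(a,b,s) or 'a to b ... of s')")
    m = min(matches, key=lambda m: m.start())
    rng = ResolutionRange(
        start=_to_float(m.group(1)),
        stop=_to_float(m.group(2)),
        step=_to_float(m.group(3)),
    )
    rng.reasoning = _reasoning_after(text, m.end())
    return rng


def format_seq_range(rng: ResolutionRange, dialect: str = "seq") -> str:
    if dialect == "seq":
        return f"seq({rng.start}, {rng.stop}, {rng.step})"
    if dialect == "prose":
        return f"{rng.start} to {rng.stop} in increments of {rng.step}"
    raise ValueError(f"unknown dialect {dialect!r}")


def _reasoning_after(text: str, pos: int) -> str:
    tail = text[pos:].strip()
    m = re.search(r"reasoning\W*", tail, re.IGNORECASE)
    if m:
        tail = tail[m.end():].strip()
    return tail


# ---------------------------------------------------------------------------
# filtering cutoffs
# ---------------------------------------------------------------------------

#: common host-workflow aliases for the canonical metric names
METRIC_ALIASES = {
    "nCount_RNA": "total_counts",
    "nFeature_RNA": "n_genes_detected",
    "percent.mt": "percent_mito",
    "percent.mito": "percent_mito",
}

_LOWER_CUES = ("min", "minimum", "above", "at least", "greater", "over", ">")
_UPPER_CUES = ("max", "maximum", "below", "at most", "less", "fewer", "under", "<")


@dataclass
class FilterCutoffs:
    bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    reasoning: str = ""

    def __post_init__(self) -> None:
        for metric, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and lo >= hi:
                raise ParseError(
                    f"{metric}: lower bound {lo} must be < upper bound {hi}"
                )


def parse_cutoffs(text: str, metric_names: list[str]) -> FilterCutoffs:
    """Bind numbers in the text to metrics and bound directions.

    Each number is attached to the nearest preceding metric mention; the
    nearest preceding direction cue ("min"/"above"/">" vs "max"/"below"/"<")
    decides lower vs upper bound.
    """
    if not text:
        raise ParseError("empty text")
    known = {m.lower(): m for m in metric_names}
    for alias, canonical in METRIC_ALIASES.items():
        if canonical in metric_names:
            known[alias.lower()] = canonical

    mention_positions: list[tuple[int, str]] = []
    for token, canonical in known.items():
        for m in re.finditer(re.escape(token), text, re.IGNORECASE):
            mention_positions.append((m.start(), canonical))
    mention_positions.sort()
    if not mention_positions:
        raise ParseError(
            f"no metric mention found; expected one of {sorted(set(known.values()))}"
        )

    cue_positions: list[tuple[int, str]] = []
    for cue, kind in [(c, "lower") for c in _LOWER_CUES] + [
        (c, "upper") for c in _UPPER_CUES
    ]:
        pattern = re.escape(cue) if not cue.isalpha() else rf"\b{re.escape(cue)}\b"
        for m in re.finditer(pattern, text, re.IGNORECASE):
            cue_positions.append((m.start(), kind))
    cue_positions.sort()

    raw: dict[str, dict[str, float]] = {}
    found_any = False
    for m in re.finditer(_NUMBER, text):
        pos = m.start()
        metric = _last_before(mention_positions, pos)
        if metric is None:
            continue
        kind = _last_before(cue_positions, pos)
        if kind is None:
            continue
        found_any = True
        slot = raw.setdefault(metric, {})
        slot.setdefault(kind, _to_float(m.group(0)))
    if not found_any:
        raise ParseError("no metric mention with an associated number and bound")
    bounds = {
        metric: (slot.get("lower"), slot.get("upper"))
        for metric, slot in raw.items()
    }
    return FilterCutoffs(bounds=bounds, reasoning=_reasoning_tail(text))


def _last_before(positions: list[tuple[int, str]], pos: int):
    best = None
    for p, value in positions:
        if p >= pos:
            break
        best = value
    return best


def _reasoning_tail(text: str) -> str:
    m = re.search(r"reasoning\W*", text, re.IGNORECASE)
    return text[m.end():].strip() if m else ""


# ---------------------------------------------------------------------------
# cluster annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    labels: dict[str, str]
    reasoning: dict[str, str] = field(default_factory=dict)


_CLUSTER_LINE = re.compile(
    r"cluster\s*[#]?\s*(\w+)\s*[:\-–]\s*(.+)", re.IGNORECASE
)


def parse_annotations(text: str, clusters: list[str]) -> AnnotationTable:
    """Map ``Cluster <id>: <label> - <reasoning>`` lines onto the clusters.

    Every passed cluster must appear; extra clusters in the text are
    ignored with a warning.
    """
    if not clusters:
        raise ParseError("no clusters supplied")
    wanted = [str(c) for c in clusters]
    labels: dict[str, str] = {}
    reasoning: dict[str, str] = {}
    for line in text.splitlines():
        m = _CLUSTER_LINE.search(line.strip().lstrip("*-# "))
        if not m:
            continue
        cid, rest = m.group(1), m.group(2).strip()
        label, _, why = _split_label(rest)
        if cid not in wanted:
            warnings.warn(f"ignoring annotation for unknown cluster {cid}",
                          stacklevel=2)
            continue
        labels[cid] = label
        if why:
            reasoning[cid] = why
    missing = [c for c in wanted if c not in labels]
    if missing:
        raise ParseError(f"annotations missing: {', '.join(missing)}")
    return AnnotationTable(labels=labels, reasoning=reasoning)


def _split_label(rest: str) -> tuple[str, str, str]:
    for sep in (" — ", " – ", " - ", "—", "–"):
        if sep in rest:
            label, why = rest.split(sep, 1)
            return label.strip().strip("*").strip(), sep, why.strip()
    return rest.strip().strip("*").strip(), "", ""


# ---------------------------------------------------------------------------
# scalar / range recommendations
# ---------------------------------------------------------------------------

_INT_RANGE_RE = re.compile(
    r"(\d+)\s*(?:to|-|–|and)\s*(\d+)", re.IGNORECASE
)


def parse_int_range(text: str) -> tuple[int, int]:
    """Parse an integer range like ``10 to 30`` / ``between 10 and 30``."""
    if not text:
        raise ParseError("empty text")
    m = _INT_RANGE_RE.search(text)
    if not m:
        single = re.search(r"\b(\d+)\b", text)
        if single:
            v = int(single.group(1))
            return v, v
        raise ParseError("no integer range found")
    lo, hi = int(m.group(1)), int(m.group(2))
    if lo > hi:
        raise ParseError(f"range lower bound {lo} exceeds upper bound {hi}")
    return lo, hi


def parse_n_pcs(text: str) -> int:
    """Extract a recommended PC count from the response text."""
    m = re.search(
        r"(?:number\s+of\s+PCs|PCs)\s*[:\-]?\s*(\d+)", text, re.IGNORECASE
    )
    if m is None:
        m = re.search(r"(\d+)\s*(?:PCs|principal components)", text, re.IGNORECASE)
    if m is None:
        raise ParseError("no PC count found")
    n = int(m.group(1))
    if n < 1:
        raise ParseError(f"PC count must be >= 1, got {n}")
    return n


def parse_method_choice(text: str, menu: list[str]) -> str:
    """Pick the recommended method name out of the response, preferring an
    explicit 'Recommended normalization: X' statement."""
    explicit = re.search(
        r"recommended\s+normalization\s*(?:method)?\s*[:\-]?\s*([A-Za-z0-9_]+)",
        text,
        re.IGNORECASE,
    )
    lowered = {m.lower(): m for m in menu}
    if explicit and explicit.group(1).lower() in lowered:
        return lowered[explicit.group(1).lower()]
    hits = [
        (m.start(), lowered[m.group(0).lower()])
        for m in re.finditer(
            "|".join(re.escape(x) for x in menu), text, re.IGNORECASE
        )
    ]
    if not hits:
        raise ParseError(f"no method from menu {menu} mentioned")
    return min(hits)[1]


# ---------------------------------------------------------------------------
# metric echoes (audit which computed metrics the response cited)
# ---------------------------------------------------------------------------

#: phrases the tasks inject whose cited values are worth auditing
METRIC_PHRASES = {
    "mean_expression_variability": r"mean\s+expression\s+variability",
    "median_neighbor_distance": r"median\s+neighbor\s+distance",
    "n_cells": r"(?:number|total\s+number)\s+of\s+cells",
    "n_hvg": r"(?:number\s+of\s+)?highly\s+variable\s+genes",
}


def extract_metric_echoes(
    text: str, phrases: dict[str, str] | None = None
) -> dict[str, float]:
    """Extract the numeric metric values a response claims to have used.

    Recognizes ``<phrase> of <number>``, ``<phrase> is/was/= <number>`` and
    ``<phrase>: <number>`` forms; first occurrence per metric wins.
    """
    phrases = phrases or METRIC_PHRASES
    echoes: dict[str, float] = {}
    for name, phrase in phrases.items():
        m = re.search(
            rf"{phrase}\s*(?:of|is|was|=|:)\s*({_NUMBER})", text, re.IGNORECASE
        )
        if m:
            echoes[name] = _to_float(m.group(1))
    return echoes


# ---------------------------------------------------------------------------
# network edges
# ---------------------------------------------------------------------------

def parse_edge_lines(text: str) -> list[tuple[str, str, str]]:
    """Parse ``source|relation|target`` lines; malformed lines are skipped
    with a warning, duplicates and self-loops dropped."""
    edges: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for line in text.splitlines():
        line = line.strip().strip("`")
        if not line:
            continue
        parts = [p.strip() for p in line.split("|")]
        if len(parts) != 3 or not all(parts):
            if "|" in line or re.match(r"^\w", line):
                warnings.warn(f"skipping malformed edge line: {line!r}",
                              stacklevel=2)
            continue
        src, rel, dst = parts
        if src == dst:
            warnings.warn(f"skipping self-loop: {line!r}", stacklevel=2)
            continue
        edge = (src, rel, dst)
        if edge in seen:
            continue
        seen.add(edge)
        edges.append(edge)
    if not edges:
        raise ParseError("zero parsable network edges")
    return edges
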