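"""Prompt rendering, backend dispatch and structured-output parsing.

The extraction stage turns one article plus its GEM context (genes, species,
GE tools) into a canonical :class:`ExtractionRecord` with six list-valued
fields: targeted genes, differentially expressed genes, species, GE tools,
GE events and phenotypes (the first-round template trades phenotypes for
three free-text summary fields). The language model is abstracted behind a
minimal backend contract — any callable mapping prompt text to raw output
text — so deterministic mock and replay backends can stand in for a hosted
model during testing and offline runs.

Raw model output is rarely clean JSON: it may be wrapped in prose or code
fences and may use the ``'Not mentioned'`` sentinel the prompts request for
absent information. Parsing therefore extracts the longest brace-delimited
span that parses as an object and maps sentinel values (``Not mentioned``,
``None``, empty strings; case-insensitive) to empty lists.
"""

from __future__ import annotations

import ast
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

from .corpus_io import ArticleContext, ArticleText

logger = logging.getLogger(__name__)

SLOT_PATTERN = re.compile(r"\{\{([A-Z_]+)\}\}")

#: List-valued output fields shared by both templates, in schema order.
LIST_FIELDS = [
    "targeted_genes",
    "differentially_expressed_genes",
    "species",
    "genome_editing_tools",
    "genome_editing_event",
    "phenotypes",
]
TEXT_FIELDS = ["study_context", "key_findings", "implications"]

ROUND1_OUTPUT_FIELDS = LIST_FIELDS[:5] + TEXT_FIELDS
ROUND2_OUTPUT_FIELDS = list(LIST_FIELDS)

_SENTINELS = {"not mentioned", "none", "n/a", ""}


class TemplateError(ValueError):
    """Fatal prompt-template problem (unknown or missing slot)."""


@dataclass
class PromptTemplate:
    """A named prompt body with double-brace slots and an output schema."""

    name: str
    body: str
    required_slots: list[str]
    output_fields: list[str]

    def __post_init__(self) -> None:
        found = SLOT_PATTERN.findall(self.body)
        for slot in self.required_slots:
            if found.count(slot) != 1:
                raise TemplateError(
                    f"template {self.name!r}: slot {slot!r} must appear exactly once"
                )

    @property
    def list_fields(self) -> list[str]:
        return [f for f in self.output_fields if f in LIST_FIELDS]

    @property
    def text_fields(self) -> list[str]:
        return [f for f in self.output_fields if f in TEXT_FIELDS]


def get_template(name: str) -> PromptTemplate:
    """Load one of the built-in templates (``round1`` or ``round2``)."""
    specs = {
        "round1": (["GENES", "SPECIES", "ABSTRACT", "TITLE"], ROUND1_OUTPUT_FIELDS),
        "round2": (
            ["GENES", "SPECIES", "TOOLS", "TITLE", "ABSTRACT", "METHODS", "RESULTS"],
            ROUND2_OUTPUT_FIELDS,
        ),
    }
    if name not in specs:
        raise TemplateError(f"unknown template {name!r}")
    body = (resources.files("geinfo") / "templates" / f"{name}.txt").read_text()
    slots, fields_ = specs[name]
    return PromptTemplate(name=name, body=body, required_slots=slots, output_fields=fields_)


def load_template(path: str | Path, name: str, output_fields: Sequence[str]) -> PromptTemplate:
    """Load a user-supplied template file with the given output schema."""
    body = Path(path).read_text()
    slots = sorted(set(SLOT_PATTERN.findall(body)))
    return PromptTemplate(
        name=name, body=body, required_slots=slots, output_fields=list(output_fields)
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class ExtractionRecord:
    """The structured per-article extraction result.

    When ``status == "ok"`` every list field is present (possibly empty) and
    the ``Not mentioned`` sentinel never appears inside a stored list; a
    record with ``status == "parse_failed"`` has all lists empty.
    """

    pmid: str = ""
    targeted_genes: list[str] = field(default_factory=list)
    differentially_expressed_genes: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    genome_editing_tools: list[str] = field(default_factory=list)
    genome_editing_event: list[str] = field(default_factory=list)
    phenotypes: list[str] = field(default_factory=list)
    study_context: str | None = None
    key_findings: str | None = None
    implications: str | None = None
    status: str = "ok"
    backend: str = ""

    def to_json(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "ExtractionRecord":
        return cls(**json.loads(line))


def write_records(records: Sequence[ExtractionRecord], path: str | Path) -> None:
    """Persist records as line-delimited JSON, one object per article."""
    with Path(path).open("w") as handle:
        for record in records:
            handle.write(record.to_json() + "\n")


def load_records(path: str | Path) -> list[ExtractionRecord]:
    return [
        ExtractionRecord.from_json(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_prompt(
    template: PromptTemplate,
    genes: Sequence[str],
    species: Sequence[str],
    tools: Sequence[str],
    article: ArticleText,
) -> str:
    """Fill every slot of ``template``; absent sections become empty strings.

    Rendering is pure string substitution, so identical inputs give
    byte-identical prompts. A slot in the body with no known value is a
    fatal template error.
    """
    values = {
        "GENES": ", ".join(genes),
        "SPECIES": ", ".join(species),
        "TOOLS": ", ".join(tools),
        "TITLE": article.title or "",
        "ABSTRACT": article.abstract or "",
        "METHODS": article.methods or "",
        "RESULTS": article.results or "",
    }

    def replace(match: re.Match) -> str:
        slot = match.group(1)
        if slot not in values:
            raise TemplateError(f"template {template.name!r}: unknown slot {slot!r}")
        return values[slot]

    return SLOT_PATTERN.sub(replace, template.body)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _is_sentinel(value: str) -> bool:
    return value.strip().strip(".").casefold() in _SENTINELS


def _clean_list(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [] if _is_sentinel(value) else [value.strip()]
    if isinstance(value, (list, tuple)):
        return [str(v).strip() for v in value if isinstance(v, (str, int)) and not _is_sentinel(str(v))]
    return []


def _brace_spans(raw: str) -> list[str]:
    """All balanced top-level ``{...}`` spans in ``raw``, longest first."""
    spans: list[str] = []
    depth = 0
    start = -1
    for i, char in enumerate(raw):
        if char == "{":
            if depth == 0:
                start = i
            depth += 1
        elif char == "}" and depth > 0:
            depth -= 1
            if depth == 0:
                spans.append(raw[start : i + 1])
    spans.sort(key=len, reverse=True)
    return spans


def _try_parse_object(span: str) -> dict | None:
    for loader in (json.loads, ast.literal_eval):
        try:
            obj = loader(span)
        except (ValueError, SyntaxError):
            continue
        if isinstance(obj, dict):
            return obj
    # last resort: strip //-style trailing comments and retry as JSON
    stripped = re.sub(r"//[^\n\"]*$", "", span, flags=re.MULTILINE)
    try:
        obj = json.loads(stripped)
    except ValueError:
        return None
    return obj if isinstance(obj, dict) else None


def parse_output(raw: str, template: PromptTemplate) -> ExtractionRecord:
    """Parse raw backend output into an :class:`ExtractionRecord`.

    Strips code fences and surrounding prose by taking the longest balanced
    brace-delimited span that parses as an object (JSON first, then a
    Python-literal fallback for single-quoted output). Sentinel values and
    lists containing only sentinels become empty lists; fields missing from
    the object become empty lists with a logged warning. If nothing parses,
    a ``parse_failed`` record with all lists empty is returned.
    """
    cleaned = re.sub(r"```[a-zA-Z0-9]*", "", raw)
    obj = None
    for span in _brace_spans(cleaned):
        obj = _try_parse_object(span)
        if obj is not None:
            break
    if obj is None:
        logger.warning("no parseable object in backend output (%d chars)", len(raw))
        return ExtractionRecord(status="parse_failed")

    record = ExtractionRecord(status="ok")
    for name in template.list_fields:
        if name not in obj:
            logger.warning("field %r missing from backend output", name)
        setattr(record, name, _clean_list(obj.get(name)))
    for name in template.text_fields:
        value = obj.get(name)
        if isinstance(value, str) and not _is_sentinel(value):
            setattr(record, name, value.strip())
        else:
            setattr(record, name, "")
    # serialized records carry their identity along; adopt it when present
    if isinstance(obj.get("pmid"), str):
        record.pmid = obj["pmid"]
    if isinstance(obj.get("backend"), str):
        record.backend = obj["backend"]
    return record


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class BackendProtocol(Protocol):
    name: str
    deterministic: bool

    def __call__(self, prompt: str) -> str: ...


@dataclass
class Backend:
    """Minimal backend contract: a named callable prompt -> raw text."""

    name: str
    fn: Callable[[str], str]
    deterministic: bool = True

    def __call__(self, prompt: str) -> str:
        return self.fn(prompt)


def prompt_digest(prompt: str) -> str:
    return hashlib.sha256(prompt.encode()).hexdigest()


class ReplayBackend:
    """Deterministic backend replaying recorded raw outputs.

    Outputs are keyed by the SHA-256 of the exact prompt, so a replay run
    reproduces a recorded run byte for byte or fails loudly.
    """

    def __init__(self, outputs: Mapping[str, str], name: str = "replay") -> None:
        self.name = name
        self.deterministic = True
        self._outputs = dict(outputs)

    @classmethod
    def from_jsonl(cls, path: str | Path, name: str = "replay") -> "ReplayBackend":
        outputs = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                row = json.loads(line)
                outputs[row["prompt_sha256"]] = row["raw"]
        return cls(outputs, name=name)

    def __call__(self, prompt: str) -> str:
        key = prompt_digest(prompt)
        if key not in self._outputs:
            raise KeyError(f"no recorded output for prompt {key[:12]}…")
        return self._outputs[key]


# ---------------------------------------------------------------------------
# Batch extraction
# ---------------------------------------------------------------------------


def extract_article(
    article: ArticleText,
    context: ArticleContext,
    template: PromptTemplate,
    backend: BackendProtocol,
) -> ExtractionRecord:
    """Render, call the backend (one retry on failure) and parse.

    A backend exception yields a ``parse_failed`` record and a logged error;
    it never aborts a batch.
    """
    prompt = render_prompt(
        template, context.genes, context.species, context.tools, article
    )
    raw = None
    for attempt in (1, 2):
        try:
            raw = backend(prompt)
            break
        except Exception as exc:  # noqa: BLE001 - backend faults must not kill batches
            logger.error(
                "backend %s failed for pmid %s (attempt %d): %s",
                backend.name,
                article.pmid,
                attempt,
                exc,
            )
    if raw is None:
        record = ExtractionRecord(status="parse_failed")
    else:
        record = parse_output(raw, template)
    record.pmid = article.pmid
    record.backend = backend.name
    return record


def run_extraction(
    articles: Sequence[ArticleText],
    contexts: Mapping[str, ArticleContext],
    template: PromptTemplate,
    backend: BackendProtocol,
    out_path: str | Path | None = None,
) -> list[ExtractionRecord]:
    """Extract every article in order; exactly one record per article.

    ``contexts`` maps pmid to the article's GEM context (an article with no
    context gets an empty one). Summary ok/parse_failed counts are logged
    and records are optionally persisted as line-delimited JSON.
    """
    records = []
    for article in articles:
        context = contexts.get(article.pmid, ArticleContext(pmid=article.pmid))
        records.append(extract_article(article, context, template, backend))
    n_ok = sum(r.status == "ok" for r in records)
    logger.info(
        "extraction finished: %d ok, %d parse_failed of %d articles",
        n_ok,
        len(records) - n_ok,
        len(records),
    )
    if out_path is not None:
        write_records(records, out_path)
    return records
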