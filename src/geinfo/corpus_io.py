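"""Tabular and text I/O for GEM-style genome-editing metadata.

The Genome Editing Meta-database (GEM) links genome-editing (GE) articles to
genes, species and GE tools, with one entry per (article, gene) association.
This module reads and writes the pipeline's flat-file inputs — GEM entry
tables (CSV or line-delimited JSON), article text records (line-delimited
JSON) and gene query lists (one identifier per line) — and implements the
first pipeline stage: selecting the GE-related entries for a gene query and
grouping them per article, so that each article carries the union of its
GEM gene/species/tool context into prompt construction.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Default separator for list-valued cells in CSV exports.
LIST_DELIMITER = "|"

GEM_COLUMNS = ["pmid", "pmcid", "gene_id", "gene_symbol", "species", "ge_tools", "year"]
ARTICLE_FIELDS = ["pmcid", "pmid", "title", "abstract", "methods", "results"]


class CorpusError(ValueError):
    """Fatal problem with a corpus file or query."""


def normalize_token(value: str) -> str:
    """Canonical form used for gene and species comparisons: trim + casefold."""
    return value.strip().casefold()


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass
class GemEntry:
    """One (article, gene) metadata row as stored in GEM.

    ``pmid`` must be non-empty and at least one of ``gene_id`` /
    ``gene_symbol`` must be set; ``species`` and ``ge_tools`` are always
    lists, possibly empty.
    """

    pmid: str
    pmcid: str = ""
    gene_id: str = ""
    gene_symbol: str = ""
    species: list[str] = field(default_factory=list)
    ge_tools: list[str] = field(default_factory=list)
    year: int | None = None

    def __post_init__(self) -> None:
        if not str(self.pmid).strip():
            raise CorpusError("GemEntry requires a non-empty pmid")
        if not (str(self.gene_id).strip() or str(self.gene_symbol).strip()):
            raise CorpusError(
                f"GemEntry for pmid {self.pmid} needs gene_id or gene_symbol"
            )
        self.pmid = str(self.pmid).strip()
        self.gene_id = str(self.gene_id).strip()
        self.gene_symbol = str(self.gene_symbol).strip()


@dataclass
class ArticleText:
    """Sectioned article text (title/abstract/methods/results).

    Any section may be empty but all are present; ``pmcid`` is required
    because full text is fetched from PubMed Central.
    """

    pmcid: str
    pmid: str = ""
    title: str = ""
    abstract: str = ""
    methods: str = ""
    results: str = ""

    def __post_init__(self) -> None:
        if not str(self.pmcid).strip():
            raise CorpusError("ArticleText requires a non-empty pmcid")


@dataclass
class GeneQuery:
    """A gene query: NCBI Gene IDs (``by_id``) or symbols (``by_symbol``)."""

    mode: str
    values: list[str]

    def __post_init__(self) -> None:
        if self.mode not in {"by_id", "by_symbol"}:
            raise CorpusError(f"unknown query mode {self.mode!r}")
        cleaned: list[str] = []
        seen: set[str] = set()
        for raw in self.values:
            value = str(raw).strip()
            if not value:
                continue
            key = normalize_token(value)
            if key in seen:
                continue
            seen.add(key)
            cleaned.append(value)
        if not cleaned:
            raise CorpusError("gene query is empty")
        self.values = cleaned

    @classmethod
    def from_file(cls, path: str | Path, mode: str) -> "GeneQuery":
        """Load a query from a plain-text file, one identifier per line."""
        lines = Path(path).read_text().splitlines()
        return cls(mode=mode, values=lines)


@dataclass
class ArticleContext:
    """Per-article GEM context: deduplicated genes, species and tool unions."""

    pmid: str
    genes: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    tools: list[str] = field(default_factory=list)


@dataclass
class SelectionResult:
    """Output of :func:`select_entries`: unique (gene, pmid) pairs plus the
    GemEntry rows they came from and the distinct article count."""

    pairs: list[tuple[str, str]]
    entries: list[GemEntry]
    n_articles: int


# ---------------------------------------------------------------------------
# Loading / writing
# ---------------------------------------------------------------------------


def _split_list(cell: str, delimiter: str) -> list[str]:
    return [part.strip() for part in str(cell).split(delimiter) if part.strip()]


def _entry_from_mapping(row: dict, delimiter: str) -> GemEntry:
    species = row.get("species", []) or []
    tools = row.get("ge_tools", []) or []
    if isinstance(species, str):
        species = _split_list(species, delimiter)
    if isinstance(tools, str):
        tools = _split_list(tools, delimiter)
    year_raw = row.get("year")
    year = int(year_raw) if year_raw not in (None, "") else None
    return GemEntry(
        pmid=row.get("pmid", "") or "",
        pmcid=str(row.get("pmcid", "") or ""),
        gene_id=str(row.get("gene_id", "") or ""),
        gene_symbol=str(row.get("gene_symbol", "") or ""),
        species=list(species),
        ge_tools=list(tools),
        year=year,
    )


def load_gem_entries(
    path: str | Path,
    format: str | None = None,
    delimiter: str = LIST_DELIMITER,
    strict: bool = False,
) -> list[GemEntry]:
    """Load GEM entries from CSV or line-delimited JSON, preserving row order.

    Rows violating the entry invariants (missing pmid, no gene identifier)
    are rejected with a logged error naming the 1-based row index; with
    ``strict=True`` the first bad row raises instead. An unreadable file is
    always fatal.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".json"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise CorpusError(f"unknown GEM table format {format!r}")
    try:
        text = path.read_text()
    except OSError as exc:  # unreadable file is fatal
        raise CorpusError(f"cannot read GEM table {path}: {exc}") from exc

    if format == "csv":
        raw_rows: Iterable[dict] = csv.DictReader(text.splitlines())
    else:
        raw_rows = (json.loads(line) for line in text.splitlines() if line.strip())

    entries: list[GemEntry] = []
    for index, row in enumerate(raw_rows, start=1):
        try:
            entries.append(_entry_from_mapping(row, delimiter))
        except (CorpusError, TypeError, ValueError) as exc:
            if strict:
                raise CorpusError(f"row {index}: {exc}") from exc
            logger.error("rejected GEM row %d: %s", index, exc)
    return entries


def write_gem_entries(
    entries: Sequence[GemEntry],
    path: str | Path,
    format: str | None = None,
    delimiter: str = LIST_DELIMITER,
) -> None:
    """Write GEM entries back out (inverse of :func:`load_gem_entries`)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".json"} else "csv"
    if format == "csv":
        with path.open("w", newline="") as handle:
            writer = csv.DictWriter(handle, fieldnames=GEM_COLUMNS)
            writer.writeheader()
            for entry in entries:
                writer.writerow(
                    {
                        "pmid": entry.pmid,
                        "pmcid": entry.pmcid,
                        "gene_id": entry.gene_id,
                        "gene_symbol": entry.gene_symbol,
                        "species": delimiter.join(entry.species),
                        "ge_tools": delimiter.join(entry.ge_tools),
                        "year": "" if entry.year is None else entry.year,
                    }
                )
    else:
        with path.open("w") as handle:
            for entry in entries:
                handle.write(
                    json.dumps(
                        {
                            "pmid": entry.pmid,
                            "pmcid": entry.pmcid,
                            "gene_id": entry.gene_id,
                            "gene_symbol": entry.gene_symbol,
                            "species": entry.species,
                            "ge_tools": entry.ge_tools,
                            "year": entry.year,
                        }
                    )
                    + "\n"
                )


def load_articles(path: str | Path) -> list[ArticleText]:
    """Load article text records from line-delimited JSON."""
    articles = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        data = json.loads(line)
        articles.append(ArticleText(**{k: data.get(k, "") for k in ARTICLE_FIELDS}))
    return articles


def write_articles(articles: Sequence[ArticleText], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for article in articles:
            handle.write(
                json.dumps({k: getattr(article, k) for k in ARTICLE_FIELDS}) + "\n"
            )


# ---------------------------------------------------------------------------
# Step 1: select entries for a gene query and group them per article
# ---------------------------------------------------------------------------


def select_entries(entries: Sequence[GemEntry], query: GeneQuery) -> SelectionResult:
    """Select the GEM entries matching a gene query.

    Matching is exact on ``gene_id`` (mode ``by_id``) or case-insensitive
    after trimming on ``gene_symbol`` (mode ``by_symbol``); no alias
    expansion is attempted. Duplicate (gene, pmid) pairs collapse to one.
    The returned pair set is independent of input order (first-seen order
    is kept for reproducible output).
    """
    canonical = {normalize_token(v): v for v in query.values}
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    matched: list[GemEntry] = []
    for entry in entries:
        key = entry.gene_id if query.mode == "by_id" else normalize_token(entry.gene_symbol)
        if query.mode == "by_id":
            gene = canonical.get(normalize_token(key)) if key else None
        else:
            gene = canonical.get(key) if key else None
        if gene is None:
            continue
        matched.append(entry)
        pair = (gene, entry.pmid)
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    n_articles = len({pmid for _, pmid in pairs})
    logger.info(
        "selected %d (gene, pmid) pairs over %d articles", len(pairs), n_articles
    )
    return SelectionResult(pairs=pairs, entries=matched, n_articles=n_articles)


def group_by_article(selection: SelectionResult) -> dict[str, ArticleContext]:
    """Group selected pairs per article, merging GEM species/tool context.

    One group per distinct pmid; the gene list is deduplicated and species
    and tools are unions over the article's matched entries.
    """
    groups: dict[str, ArticleContext] = {}
    for gene, pmid in selection.pairs:
        context = groups.setdefault(pmid, ArticleContext(pmid=pmid))
        if gene not in context.genes:
            context.genes.append(gene)
    for entry in selection.entries:
        context = groups.get(entry.pmid)
        if context is None:
            continue
        for name in entry.species:
            if name not in context.species:
                context.species.append(name)
        for tool in entry.ge_tools:
            if tool not in context.tools:
                context.tools.append(tool)
    return groups
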