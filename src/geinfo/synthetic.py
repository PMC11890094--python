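"""Self-consistent synthetic corpora with ground truth and error injection.

Live runs of the pipeline depend on a hosted literature database and a
hosted language model, neither of which is reproducible offline. This
module generates everything the downstream stages consume — sectioned
article texts with embedded gene-role sentences, the matching GEM-style
entry table, ground-truth extraction records, and a curation table using
the 0/1/2 label scheme — all mutually consistent by construction, plus a
rule-based mock extraction backend with injectable false-positive /
false-negative rates whose injection log serves as an exact oracle for the
evaluation stage.

Sentence templates are deliberately simple and unambiguous (one fact per
sentence) so the mock extractor recovers the truth exactly; linguistic
realism is not a goal. Each (gene, article) pair is assigned one role:

* ``target`` — the gene is edited; curated 1 (or 2 with a species memo when
  the article studies a non-default species) and deg label 2 (excluded from
  GE_deg scoring);
* ``deg`` — differentially expressed after editing; curated 0/1;
* ``unrelated`` — studied in the article without a GE role; curated 0/0;
* ``error`` — a collection artifact: the gene appears in the entry table
  but nowhere in the article text; curated 0/0.

Default role probabilities mirror the curated category proportions
observed in manually reviewed GEM annotation pairs (~39% targets, ~24%
differentially expressed, ~8% collection errors), and the default error
profile reproduces the per-pair FP/FN rates implied by the best published
extraction run's confusion matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field, model_validator

from .corpus_io import (
    ArticleContext,
    ArticleText,
    GemEntry,
    normalize_token,
    write_articles,
    write_gem_entries,
)
from .evaluation import AnnotationPair, write_curation
from .extraction import ExtractionRecord, write_records

logger = logging.getLogger(__name__)

DEFAULT_GENE_POOL = [
    "PKD1", "FOS", "SLC7A5", "TXNIP", "STAT6", "SPP1", "SLC3A2", "TUBB3",
    "SLC26A4", "CARD11", "MEGF10", "HSPA6", "CNBD1", "GPR37L1", "PILRA",
    "BTLA", "TMPRSS4", "ADAMTS2", "MPO", "CDKN1C", "CRYAB", "CD74", "CPT1A",
    "HMOX1", "NQO1", "GCLC", "SOD2", "CAT", "GPX1", "NFE2L2", "KEAP1",
    "PARK7", "PINK1", "PRKN", "SNCA", "LRRK2", "GBA1", "VPS35", "ATP13A2",
    "FBXO7",
]
DEFAULT_SPECIES_POOL = [
    "Homo sapiens", "Mus musculus", "Danio rerio", "Rattus norvegicus",
]
DEFAULT_TOOL_POOL = ["CRISPR-Cas9", "TALEN", "ZFN", "base editor", "prime editor"]
PHENOTYPE_POOL = [
    "reduced proliferation", "increased apoptosis", "impaired migration",
    "elevated oxidative stress", "no overt phenotype",
]

# sentence templates shared by the generator and the mock extractor
_EVENT_PHRASES = {"knockout": "knocked out", "knockin": "knocked in", "knockdown": "knocked down"}
_PHRASE_EVENTS = {v: k for k, v in _EVENT_PHRASES.items()}
_TARGET_RE = re.compile(r"(\S+) was (knocked out|knocked in|knocked down) using ([^.]+?) in ([^.]+?)\.")
_DEG_RE = re.compile(r"Expression of (\S+) was significantly altered")
_SPECIES_RE = re.compile(r"All experiments were conducted in ([^.]+?)\.")
_TOOLS_RE = re.compile(r"Genome editing was performed with ([^.]+?)\.")
_PHENO_RE = re.compile(r"The edited cells exhibited ([^.]+?)\.")


class CorpusSpec(BaseModel):
    """Parameters of a synthetic corpus; identical seed gives an identical
    corpus, byte for byte."""

    n_articles: int = 260
    gene_pool: list[str] = Field(default_factory=lambda: list(DEFAULT_GENE_POOL))
    species_pool: list[str] = Field(default_factory=lambda: list(DEFAULT_SPECIES_POOL))
    tool_pool: list[str] = Field(default_factory=lambda: list(DEFAULT_TOOL_POOL))
    p_target: float = 0.39
    p_deg: float = 0.24
    p_error: float = 0.08
    nondefault_species_rate: float = 0.15
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CorpusSpec":
        if self.n_articles < 0:
            raise ValueError("n_articles must be non-negative")
        if not (self.gene_pool and self.species_pool and self.tool_pool):
            raise ValueError("gene, species and tool pools must be non-empty")
        for name in ("p_target", "p_deg", "p_error", "nondefault_species_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_target + self.p_deg + self.p_error > 1.0 + 1e-12:
            raise ValueError("p_target + p_deg + p_error must not exceed 1")
        return self


class ErrorProfile(BaseModel):
    """Per-pair error-injection rates for the mock extractor.

    Defaults reproduce the per-pair FP/FN rates implied by the confusion
    matrices of the best-performing published extraction run (9 FP over 163
    target-negative and 4 FN over 103 target-positive pairs; 18 FP over 98
    and 6 FN over 65 for differential expression).
    """

    fp_rate_target: float = 9 / 163
    fn_rate_target: float = 4 / 103
    fp_rate_deg: float = 18 / 98
    fn_rate_deg: float = 6 / 65
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ErrorProfile":
        for name in ("fp_rate_target", "fn_rate_target", "fp_rate_deg", "fn_rate_deg"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        return self

    @classmethod
    def zero(cls, seed: int = 0) -> "ErrorProfile":
        return cls(fp_rate_target=0, fn_rate_target=0, fp_rate_deg=0, fn_rate_deg=0, seed=seed)


@dataclass
class InjectionEvent:
    """One deliberately flipped extraction outcome."""

    kind: str  # fp_target | fn_target | fp_deg | fn_deg
    pmid: str
    gene: str


@dataclass
class SyntheticCorpus:
    """A generated corpus bundle: articles, GEM entries, ground truth and
    curation, plus per-article gene context."""

    spec: CorpusSpec
    articles: list[ArticleText] = field(default_factory=list)
    entries: list[GemEntry] = field(default_factory=list)
    truth: list[ExtractionRecord] = field(default_factory=list)
    curation: list[AnnotationPair] = field(default_factory=list)
    article_genes: dict[str, list[str]] = field(default_factory=dict)

    def contexts(self) -> dict[str, ArticleContext]:
        """GEM context per article, equivalent to select+group on the entries."""
        contexts: dict[str, ArticleContext] = {}
        for entry in self.entries:
            context = contexts.setdefault(entry.pmid, ArticleContext(pmid=entry.pmid))
            if entry.gene_symbol not in context.genes:
                context.genes.append(entry.gene_symbol)
            for name in entry.species:
                if name not in context.species:
                    context.species.append(name)
            for tool in entry.ge_tools:
                if tool not in context.tools:
                    context.tools.append(tool)
        return contexts

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the bundle in the exact formats the pipeline consumes."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "gem_entries": directory / "gem_entries.csv",
            "articles": directory / "articles.jsonl",
            "truth_records": directory / "truth_records.jsonl",
            "curation": directory / "curation.csv",
            "gene_query": directory / "gene_query.txt",
        }
        write_gem_entries(self.entries, paths["gem_entries"])
        write_articles(self.articles, paths["articles"])
        write_records(self.truth, paths["truth_records"])
        write_curation(self.curation, paths["curation"])
        paths["gene_query"].write_text("\n".join(self.spec.gene_pool) + "\n")
        return paths


def _gene_ids(pool: Sequence[str]) -> dict[str, str]:
    return {symbol: str(100001 + i) for i, symbol in enumerate(pool)}


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a corpus realizing ``spec``; all outputs are mutually
    consistent and the generation is deterministic in ``spec.seed``."""
    rng = random.Random(spec.seed)
    ids = _gene_ids(spec.gene_pool)
    corpus = SyntheticCorpus(spec=spec)
    default_species = spec.species_pool[0]

    for i in range(spec.n_articles):
        pmid = str(80000001 + i)
        pmcid = f"PMC{7000001 + i}"
        if len(spec.species_pool) > 1 and rng.random() < spec.nondefault_species_rate:
            species = rng.choice(spec.species_pool[1:])
        else:
            species = default_species

        k = rng.choices([1, 2, 3], weights=[0.75, 0.20, 0.05])[0]
        genes = rng.sample(spec.gene_pool, min(k, len(spec.gene_pool)))
        roles: dict[str, str] = {}
        for gene in genes:
            u = rng.random()
            if u < spec.p_target:
                roles[gene] = "target"
            elif u < spec.p_target + spec.p_deg:
                roles[gene] = "deg"
            elif u < spec.p_target + spec.p_deg + spec.p_error:
                roles[gene] = "error"
            else:
                roles[gene] = "unrelated"

        targets = [g for g in genes if roles[g] == "target"]
        degs = [g for g in genes if roles[g] == "deg"]
        unrelated = [g for g in genes if roles[g] == "unrelated"]

        tools: list[str] = []
        events: list[str] = []
        target_sentences = []
        for gene in targets:
            tool = rng.choice(spec.tool_pool)
            event = rng.choice(list(_EVENT_PHRASES))
            if tool not in tools:
                tools.append(tool)
            if event not in events:
                events.append(event)
            target_sentences.append(
                f"{gene} was {_EVENT_PHRASES[event]} using {tool} in {species}."
            )
        if degs and not tools:
            # editing of an off-panel locus drives the expression changes
            tools.append(rng.choice(spec.tool_pool))
        deg_sentences = [
            f"Expression of {gene} was significantly altered following genome editing."
            for gene in degs
        ]
        unrelated_sentences = [
            f"{gene} levels were recorded for reference purposes without genome editing."
            for gene in unrelated
        ]
        phenotypes = [rng.choice(PHENOTYPE_POOL)] if targets else []

        title = f"Genome editing study {i + 1:05d} in {species}"
        abstract = " ".join(
            ["We investigated gene function using genome editing."]
            + target_sentences
            + deg_sentences
        )
        methods_parts = [f"All experiments were conducted in {species}."]
        if tools:
            methods_parts.append(f"Genome editing was performed with {', '.join(tools)}.")
        methods = " ".join(methods_parts)
        results = " ".join(
            target_sentences
            + deg_sentences
            + unrelated_sentences
            + [f"The edited cells exhibited {p}." for p in phenotypes]
        )

        corpus.articles.append(
            ArticleText(
                pmcid=pmcid, pmid=pmid, title=title,
                abstract=abstract, methods=methods, results=results,
            )
        )
        corpus.truth.append(
            ExtractionRecord(
                pmid=pmid,
                targeted_genes=list(targets),
                differentially_expressed_genes=list(degs),
                species=[species],
                genome_editing_tools=list(tools),
                genome_editing_event=list(events),
                phenotypes=list(phenotypes),
                status="ok",
                backend="truth",
            )
        )
        corpus.article_genes[pmid] = list(genes)
        year = 2015 + (i % 10)
        for gene in genes:
            corpus.entries.append(
                GemEntry(
                    pmid=pmid, pmcid=pmcid, gene_id=ids[gene], gene_symbol=gene,
                    species=[species], ge_tools=list(tools), year=year,
                )
            )
            role = roles[gene]
            if role == "target":
                label = 1 if species == default_species else 2
                memo = species if label == 2 else ""
                pair = AnnotationPair(ids[gene], gene, pmid, label, 2, memo, "target")
            elif role == "deg":
                pair = AnnotationPair(ids[gene], gene, pmid, 0, 1, "", "deg")
            elif role == "unrelated":
                pair = AnnotationPair(ids[gene], gene, pmid, 0, 0, "", "unrelated")
            else:
                pair = AnnotationPair(ids[gene], gene, pmid, 0, 0, "", "error")
            corpus.curation.append(pair)

    _validate_corpus(corpus)
    return corpus


def _validate_corpus(corpus: SyntheticCorpus) -> None:
    """Cross-validate curation against ground truth on every generation."""
    truth_by_pmid = {r.pmid: r for r in corpus.truth}
    for pair in corpus.curation:
        record = truth_by_pmid[pair.pmid]
        is_target = pair.gene_symbol in record.targeted_genes
        is_deg = pair.gene_symbol in record.differentially_expressed_genes
        if (pair.curation_gene in (1, 2)) != is_target:
            raise AssertionError(
                f"curation/truth target disagreement for ({pair.gene_symbol}, {pair.pmid})"
            )
        if (pair.deg == 1) != is_deg:
            raise AssertionError(
                f"curation/truth deg disagreement for ({pair.gene_symbol}, {pair.pmid})"
            )
        if pair.category == "error":
            article = next(a for a in corpus.articles if a.pmid == pair.pmid)
            text = " ".join([article.title, article.abstract, article.methods, article.results])
            if pair.gene_symbol in text:
                raise AssertionError(
                    f"collection-error gene {pair.gene_symbol} appears in article {pair.pmid}"
                )


# ---------------------------------------------------------------------------
# Mock extraction
# ---------------------------------------------------------------------------


def recover_truth(article: ArticleText) -> dict[str, list[str]]:
    """Recover the embedded facts of a templated article by pattern matching."""
    text = "\n".join([article.title, article.abstract, article.methods, article.results])

    def uniq(items: Sequence[str]) -> list[str]:
        out: list[str] = []
        for item in items:
            if item not in out:
                out.append(item)
        return out

    targets, events, tools, species = [], [], [], []
    for match in _TARGET_RE.finditer(text):
        targets.append(match.group(1))
        events.append(_PHRASE_EVENTS[match.group(2)])
        tools.append(match.group(3))
        species.append(match.group(4))
    degs = [m.group(1) for m in _DEG_RE.finditer(text)]
    species += [m.group(1) for m in _SPECIES_RE.finditer(text)]
    for m in _TOOLS_RE.finditer(text):
        tools += [part.strip() for part in m.group(1).split(", ")]
    phenotypes = [m.group(1) for m in _PHENO_RE.finditer(text)]
    return {
        "targeted_genes": uniq(targets),
        "differentially_expressed_genes": uniq(degs),
        "species": uniq(species),
        "genome_editing_tools": uniq(tools),
        "genome_editing_event": uniq(events),
        "phenotypes": uniq(phenotypes),
    }


def _article_rng(profile: ErrorProfile, pmid: str) -> random.Random:
    digest = hashlib.sha256(f"{profile.seed}:{pmid}".encode()).digest()
    return random.Random(int.from_bytes(digest[:8], "big"))


def mock_extract(
    article: ArticleText,
    context_genes: Sequence[str],
    profile: ErrorProfile,
) -> tuple[str, list[InjectionEvent]]:
    """Emit raw extraction output for one article with injected errors.

    The truth is recovered by sentence-pattern matching, then per-pair
    errors are injected: every true gene is dropped with the corresponding
    FN rate, and every decoy candidate (a context gene that is not a true
    positive for the role, restricted to genes actually entering that
    role's evaluation) is added with the FP rate. Every flip is returned in
    the injection log. The draw sequence is seeded from (profile seed,
    pmid), so outputs are deterministic and order-independent across the
    batch.
    """
    truth = recover_truth(article)
    rng = _article_rng(profile, article.pmid)
    log: list[InjectionEvent] = []

    targets = list(truth["targeted_genes"])
    degs = list(truth["differentially_expressed_genes"])
    target_keys = {normalize_token(g) for g in targets}
    deg_keys = {normalize_token(g) for g in degs}

    kept_targets = []
    for gene in targets:
        if rng.random() < profile.fn_rate_target:
            log.append(InjectionEvent("fn_target", article.pmid, gene))
        else:
            kept_targets.append(gene)
    for gene in context_genes:
        if normalize_token(gene) in target_keys:
            continue
        if rng.random() < profile.fp_rate_target:
            log.append(InjectionEvent("fp_target", article.pmid, gene))
            kept_targets.append(gene)

    kept_degs = []
    for gene in degs:
        if rng.random() < profile.fn_rate_deg:
            log.append(InjectionEvent("fn_deg", article.pmid, gene))
        else:
            kept_degs.append(gene)
    for gene in context_genes:
        key = normalize_token(gene)
        if key in deg_keys or key in target_keys:
            # true targets are excluded from GE_deg evaluation
            continue
        if rng.random() < profile.fp_rate_deg:
            log.append(InjectionEvent("fp_deg", article.pmid, gene))
            kept_degs.append(gene)

    payload = dict(truth)
    payload["targeted_genes"] = kept_targets
    payload["differentially_expressed_genes"] = kept_degs
    for name, value in payload.items():
        if not value:
            payload[name] = ["Not mentioned"]
    return json.dumps(payload), log


class MockBackend:
    """Deterministic rule-based backend over a synthetic corpus.

    Resolves the article from the prompt's TITLE section, recovers the
    embedded truth and applies the error profile. Keeps an
    ``injection_log`` of every flipped outcome for oracle-style checks.
    """

    def __init__(self, corpus: SyntheticCorpus, profile: ErrorProfile | None = None) -> None:
        self.name = "mock"
        self.deterministic = True
        self.profile = profile or ErrorProfile()
        self._by_title = {
            article.title: (article, corpus.article_genes.get(article.pmid, []))
            for article in corpus.articles
        }
        self.injection_log: list[InjectionEvent] = []

    def reset_log(self) -> None:
        self.injection_log = []

    def __call__(self, prompt: str) -> str:
        match = re.search(r"^TITLE:(.*)$", prompt, re.MULTILINE) or re.search(
            r"^Title:(.*)$", prompt, re.MULTILINE
        )
        if match is None:
            raise KeyError("prompt has no TITLE section")
        title = match.group(1).strip()
        if title not in self._by_title:
            raise KeyError(f"unknown article title {title!r}")
        article, context_genes = self._by_title[title]
        raw, events = mock_extract(article, context_genes, self.profile)
        self.injection_log.extend(events)
        return raw
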