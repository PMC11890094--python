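"""Gold-standard curation schema and extraction-performance evaluation.

Each curated unit is an *annotation pair*: one (gene, article) combination.
Two roles are scored independently against the extraction records:

* **GE_target** — the gene was the direct target of genome editing.
  ``curation_gene`` label 1 marks a confirmed target, 0 a non-target, and 2
  a target edited in a non-default species, with the correct species noted
  in the memo column.
* **GE_deg** — the gene was reported as differentially expressed because
  *other* genes were edited. ``deg`` label 2 excludes the pair from GE_deg
  scoring (it is already a target, and a model may plausibly infer
  expression changes in an edited gene without textual support).

Counting rules: a label-1 pair is a true positive when the extracted list
contains the gene, otherwise a false negative; a label-0 pair is a true
negative when absent, a false positive when present. A label-2 target pair
is a true positive only when the gene is present *and* the extracted
species matches the memo species; otherwise it counts as a false negative
(the gene-in-context was not correctly recovered — these cases are logged
distinctly so they can be re-scored as false positives if preferred).

Metrics use the standard confusion-matrix formulas
(accuracy=(TP+TN)/total, precision=TP/(TP+FP), recall=TP/(TP+FN), F1 the
harmonic mean of precision and recall) and are reported rounded to four
decimal places, half up.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import normalize_token
from .extraction import ExtractionRecord

logger = logging.getLogger(__name__)

CURATION_COLUMNS = ["gene_id", "gene_symbol", "pmid", "curation_gene", "deg", "memo", "category"]

#: Common-name to binomial mapping used by the species matcher.
COMMON_SPECIES_NAMES = {
    "human": "homo sapiens",
    "mouse": "mus musculus",
    "mice": "mus musculus",
    "rat": "rattus norvegicus",
    "zebrafish": "danio rerio",
    "fruit fly": "drosophila melanogaster",
    "yeast": "saccharomyces cerevisiae",
    "nematode": "caenorhabditis elegans",
    "chicken": "gallus gallus",
    "pig": "sus scrofa",
}


class EvaluationError(ValueError):
    """Fatal evaluation-input problem (bad labels, records missing)."""


@dataclass
class AnnotationPair:
    """One curated (gene, article) pair with target/deg labels."""

    gene_id: str
    gene_symbol: str
    pmid: str
    curation_gene: int
    deg: int
    memo_species: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        self.curation_gene = int(self.curation_gene)
        self.deg = int(self.deg)
        if self.curation_gene not in {0, 1, 2} or self.deg not in {0, 1, 2}:
            raise EvaluationError(
                f"pair ({self.gene_symbol or self.gene_id}, {self.pmid}): "
                "labels must be 0, 1 or 2"
            )
        if self.curation_gene == 2 and not self.memo_species.strip():
            raise EvaluationError(
                f"pair ({self.gene_symbol or self.gene_id}, {self.pmid}): "
                "curation_gene=2 requires the species memo"
            )


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass
class EvalMetrics:
    """Accuracy/precision/recall/F1, rounded to 4 decimals (half up)."""

    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class CurationSummary:
    """Category counts and percentages over a curation table."""

    total: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    deg_evaluated: int = 0


# ---------------------------------------------------------------------------
# Curation I/O
# ---------------------------------------------------------------------------


def load_curation(path: str | Path) -> list[AnnotationPair]:
    """Load the curation CSV (columns: gene_id, gene_symbol, pmid,
    curation_gene, deg, memo, category)."""
    pairs = []
    with Path(path).open() as handle:
        for index, row in enumerate(csv.DictReader(handle), start=1):
            try:
                pairs.append(
                    AnnotationPair(
                        gene_id=row.get("gene_id", "").strip(),
                        gene_symbol=row.get("gene_symbol", "").strip(),
                        pmid=row.get("pmid", "").strip(),
                        curation_gene=int(row["curation_gene"]),
                        deg=int(row["deg"]),
                        memo_species=row.get("memo", "").strip(),
                        category=row.get("category", "").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise EvaluationError(f"curation row {index}: {exc}") from exc
    return pairs


def write_curation(pairs: Sequence[AnnotationPair], path: str | Path) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=CURATION_COLUMNS)
        writer.writeheader()
        for pair in pairs:
            writer.writerow(
                {
                    "gene_id": pair.gene_id,
                    "gene_symbol": pair.gene_symbol,
                    "pmid": pair.pmid,
                    "curation_gene": pair.curation_gene,
                    "deg": pair.deg,
                    "memo": pair.memo_species,
                    "category": pair.category,
                }
            )


# ---------------------------------------------------------------------------
# Matching helpers
# ---------------------------------------------------------------------------


def gene_in_list(pair: AnnotationPair, names: Iterable[str]) -> bool:
    """Case-insensitive membership of the pair's symbol or ID in a list."""
    normalized = {normalize_token(n) for n in names}
    candidates = {normalize_token(v) for v in (pair.gene_symbol, pair.gene_id) if v}
    return bool(candidates & normalized)


def species_match(memo: str, extracted: Iterable[str]) -> bool:
    """True when any extracted species name matches the curated memo.

    Comparison is case-insensitive after trimming, accepting either name as
    a substring of the other; a small common-name table maps e.g. "mouse"
    to "Mus musculus" before comparison.
    """
    a = normalize_token(memo)
    a = COMMON_SPECIES_NAMES.get(a, a)
    if not a:
        return False
    for name in extracted:
        b = normalize_token(name)
        b = COMMON_SPECIES_NAMES.get(b, b)
        if b and (a in b or b in a):
            return True
    return False


def _records_by_pmid(
    pairs: Sequence[AnnotationPair], records: Sequence[ExtractionRecord]
) -> Mapping[str, ExtractionRecord]:
    index = {record.pmid: record for record in records}
    missing = sorted({pair.pmid for pair in pairs if pair.pmid not in index})
    if missing:
        raise EvaluationError(
            f"no extraction record for {len(missing)} pmid(s): {', '.join(missing[:10])}"
        )
    return index


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------


def evaluate_target(
    pairs: Sequence[AnnotationPair], records: Sequence[ExtractionRecord]
) -> ConfusionMatrix:
    """Score GE_target extraction over all annotation pairs."""
    index = _records_by_pmid(pairs, records)
    matrix = ConfusionMatrix()
    for pair in pairs:
        record = index[pair.pmid]
        present = gene_in_list(pair, record.targeted_genes)
        if pair.curation_gene == 1:
            if present:
                matrix.tp += 1
            else:
                matrix.fn += 1
        elif pair.curation_gene == 0:
            if present:
                matrix.fp += 1
            else:
                matrix.tn += 1
        else:  # label 2: non-default species target
            if present and species_match(pair.memo_species, record.species):
                matrix.tp += 1
            else:
                matrix.fn += 1
                if present:
                    logger.info(
                        "label-2 species mismatch scored as FN: (%s, %s) memo=%r got %r",
                        pair.gene_symbol or pair.gene_id,
                        pair.pmid,
                        pair.memo_species,
                        record.species,
                    )
    return matrix


def evaluate_deg(
    pairs: Sequence[AnnotationPair], records: Sequence[ExtractionRecord]
) -> ConfusionMatrix:
    """Score GE_deg extraction; pairs with deg label 2 are excluded."""
    evaluated = [pair for pair in pairs if pair.deg != 2]
    index = _records_by_pmid(evaluated, records)
    matrix = ConfusionMatrix()
    for pair in evaluated:
        record = index[pair.pmid]
        present = gene_in_list(pair, record.differentially_expressed_genes)
        if pair.deg == 1:
            if present:
                matrix.tp += 1
            else:
                matrix.fn += 1
        else:
            if present:
                matrix.fp += 1
            else:
                matrix.tn += 1
    return matrix


# ---------------------------------------------------------------------------
# Metrics and summaries
# ---------------------------------------------------------------------------


def round_half_up(value: float, digits: int) -> float:
    if math.isnan(value):
        return value
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_metrics(matrix: ConfusionMatrix) -> EvalMetrics:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    An undefined ratio (no predicted positives for precision, no condition
    positives for recall) is reported as NaN with a warning; F1 is NaN if
    either component is.
    """
    if matrix.total == 0:
        raise EvaluationError("cannot compute metrics over zero evaluated pairs")
    accuracy = (matrix.tp + matrix.tn) / matrix.total
    if matrix.tp + matrix.fp == 0:
        logger.warning("precision undefined (tp+fp=0); reporting NaN")
        precision = math.nan
    else:
        precision = matrix.tp / (matrix.tp + matrix.fp)
    if matrix.tp + matrix.fn == 0:
        logger.warning("recall undefined (tp+fn=0); reporting NaN")
        recall = math.nan
    else:
        recall = matrix.tp / (matrix.tp + matrix.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalMetrics(
        accuracy=round_half_up(accuracy, 4),
        precision=round_half_up(precision, 4),
        recall=round_half_up(recall, 4),
        f1=round_half_up(f1, 4),
    )


def summarize_curation(pairs: Sequence[AnnotationPair]) -> CurationSummary:
    """Counts and percentages of the four curated gene categories.

    ``ge_target`` counts pairs with curation_gene 1 or 2; ``ge_deg`` counts
    deg label 1; ``unrelated`` (studied but not GE-related) and
    ``extraction_error`` come from the auxiliary category column.
    Percentages are over all pairs, rounded to 2 decimals. ``deg_evaluated``
    is the number of pairs entering GE_deg scoring (deg label != 2).
    """
    total = len(pairs)
    counts = {
        "ge_target": sum(p.curation_gene in (1, 2) for p in pairs),
        "ge_deg": sum(p.deg == 1 for p in pairs),
        "unrelated": sum(p.category == "unrelated" for p in pairs),
        "extraction_error": sum(p.category == "error" for p in pairs),
    }
    percentages = {
        name: round_half_up(100.0 * count / total, 2) if total else 0.0
        for name, count in counts.items()
    }
    return CurationSummary(
        total=total,
        counts=counts,
        percentages=percentages,
        deg_evaluated=sum(p.deg != 2 for p in pairs),
    )


def write_evaluation_report(
    matrices: Mapping[str, ConfusionMatrix],
    metrics: Mapping[str, EvalMetrics],
    csv_path: str | Path,
    text_path: str | Path | None = None,
) -> None:
    """Write confusion-matrix cells plus metrics as CSV and readable text."""
    with Path(csv_path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["task", "tp", "fp", "fn", "tn", "evaluated", "accuracy", "precision", "recall", "f1"]
        )
        for task, matrix in matrices.items():
            m = metrics[task]
            writer.writerow(
                [task, matrix.tp, matrix.fp, matrix.fn, matrix.tn, matrix.total,
                 m.accuracy, m.precision, m.recall, m.f1]
            )
    if text_path is not None:
        lines = []
        for task, matrix in matrices.items():
            m = metrics[task]
            lines.append(f"{task}: TP={matrix.tp} FP={matrix.fp} FN={matrix.fn} TN={matrix.tn}")
            lines.append(
                f"  accuracy={m.accuracy} precision={m.precision} "
                f"recall={m.recall} f1={m.f1} (n={matrix.total})"
            )
        Path(text_path).write_text("\n".join(lines) + "\n")
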