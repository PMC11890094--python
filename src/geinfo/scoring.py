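"""Per-gene genome-editing metrics and weighted min–max gene ranking.

From the extraction records two literature-derived metrics are counted per
queried gene: ``ge_target_count`` (distinct articles in which the gene was
itself the editing target) and ``ge_deg_count`` (distinct articles reporting
the gene as differentially expressed after editing of other genes). Any
number of externally supplied custom metrics — e.g. a transcriptomics
meta-analysis score, or the count of disease-association articles — can be
merged alongside.

Each metric column is min–max normalized to [0, 1],

    x' = (x - min) / (max - min),

and metrics flagged *lower-is-better* (understudied genes should rank
higher) are complemented, x' = 1 - (x - min)/(max - min). A constant column
carries no information and normalizes to all zeros. The cumulative score is
the weighted sum of normalized values; genes are ranked in descending score
order with ties broken alphabetically for deterministic output. The default
weights are ge_target_count 0.35, ge_deg_count 0.15, meta_analysis_score
0.45 and pd_score 0.05, with ge_target_count and pd_score lower-is-better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .corpus_io import normalize_token
from .extraction import ExtractionRecord

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {
    "ge_target_count": 0.35,
    "ge_deg_count": 0.15,
    "meta_analysis_score": 0.45,
    "pd_score": 0.05,
}
DEFAULT_LOWER_IS_BETTER = {"ge_target_count", "pd_score"}


class ScoringError(ValueError):
    """Fatal scoring-configuration problem."""


@dataclass
class GeneMetricsRow:
    """Raw per-gene metric values: the two GE counts plus custom metrics."""

    gene_symbol: str
    ge_target_count: int = 0
    ge_deg_count: int = 0
    custom: dict[str, float] = field(default_factory=dict)

    def value(self, metric: str) -> float:
        if metric == "ge_target_count":
            return float(self.ge_target_count)
        if metric == "ge_deg_count":
            return float(self.ge_deg_count)
        if metric in self.custom:
            return float(self.custom[metric])
        raise KeyError(metric)


class WeightConfig(BaseModel):
    """Metric weights and lower-is-better orientation flags."""

    weights: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    lower_is_better: set[str] = Field(
        default_factory=lambda: set(DEFAULT_LOWER_IS_BETTER)
    )

    @field_validator("weights")
    @classmethod
    def _check_weights(cls, weights: dict[str, float]) -> dict[str, float]:
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in weights.values()):
            raise ValueError("at least one weight must be positive")
        return weights


@dataclass
class ScoredGene:
    """One ranked gene: raw and normalized metric values, score, 1-based rank."""

    gene_symbol: str
    raw: dict[str, float]
    normalized: dict[str, float]
    score: float
    rank: int = 0


# ---------------------------------------------------------------------------
# Metric counting
# ---------------------------------------------------------------------------


def count_ge_metrics(
    records: Sequence[ExtractionRecord], genes: Sequence[str]
) -> list[GeneMetricsRow]:
    """Count per-gene GE_target and GE_deg articles from extraction records.

    Both counts are distinct-article counts (a gene listed twice in one
    article counts once). Genes never mentioned get zeros; matching uses the
    same case-insensitive normalization as gene selection.
    """
    target_articles: dict[str, set[str]] = {normalize_token(g): set() for g in genes}
    deg_articles: dict[str, set[str]] = {normalize_token(g): set() for g in genes}
    for record in records:
        for name in record.targeted_genes:
            key = normalize_token(name)
            if key in target_articles:
                target_articles[key].add(record.pmid)
        for name in record.differentially_expressed_genes:
            key = normalize_token(name)
            if key in deg_articles:
                deg_articles[key].add(record.pmid)
    return [
        GeneMetricsRow(
            gene_symbol=gene,
            ge_target_count=len(target_articles[normalize_token(gene)]),
            ge_deg_count=len(deg_articles[normalize_token(gene)]),
        )
        for gene in genes
    ]


def merge_custom_metrics(
    rows: Sequence[GeneMetricsRow], metrics: Mapping[str, Mapping[str, float]]
) -> list[GeneMetricsRow]:
    """Attach custom metric columns (metric name -> gene -> value) to rows.

    Genes without a value for a metric get 0.0 so every row has a value for
    every configured metric.
    """
    merged = []
    for row in rows:
        custom = dict(row.custom)
        for metric, per_gene in metrics.items():
            lookup = {normalize_token(g): v for g, v in per_gene.items()}
            custom[metric] = float(lookup.get(normalize_token(row.gene_symbol), 0.0))
        merged.append(
            GeneMetricsRow(row.gene_symbol, row.ge_target_count, row.ge_deg_count, custom)
        )
    return merged


def load_custom_metrics(path) -> dict[str, dict[str, float]]:
    """Read a custom-metrics CSV (gene_symbol plus one column per metric)."""
    frame = pd.read_csv(path)
    if "gene_symbol" not in frame.columns:
        raise ScoringError("custom metrics CSV needs a gene_symbol column")
    out: dict[str, dict[str, float]] = {}
    for column in frame.columns:
        if column == "gene_symbol":
            continue
        out[column] = dict(zip(frame["gene_symbol"].astype(str), frame[column].astype(float)))
    return out


# ---------------------------------------------------------------------------
# Normalization and ranking
# ---------------------------------------------------------------------------


def minmax_normalize(
    values: Sequence[float], orientation: str = "higher_better"
) -> list[float]:
    """Min–max normalize a metric column to [0, 1].

    ``lower_better`` complements the result (1 - x'). A constant column maps
    to all zeros: with no spread the metric cannot separate genes, so it
    contributes nothing rather than dividing by zero.
    """
    if len(values) == 0:
        raise ScoringError("cannot normalize an empty column")
    if orientation not in {"higher_better", "lower_better"}:
        raise ScoringError(f"unknown orientation {orientation!r}")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    scaled = [(v - lo) / (hi - lo) for v in values]
    if orientation == "lower_better":
        scaled = [1.0 - s for s in scaled]
    return scaled


def weighted_rank(
    rows: Sequence[GeneMetricsRow], config: WeightConfig | None = None
) -> list[ScoredGene]:
    """Normalize every weighted metric column and rank genes by weighted sum.

    Rows are sorted by descending cumulative score, ties broken by ascending
    gene symbol; ranks are 1-based. A weighted metric absent from the rows is
    a fatal configuration error naming the metric.
    """
    if config is None:
        config = WeightConfig()
    rows = list(rows)
    if not rows:
        return []
    columns: dict[str, list[float]] = {}
    for metric in config.weights:
        try:
            columns[metric] = [row.value(metric) for row in rows]
        except KeyError as exc:
            raise ScoringError(
                f"weighted metric {metric!r} missing from the metric rows"
            ) from exc
    normalized_columns = {
        metric: minmax_normalize(
            column,
            "lower_better" if metric in config.lower_is_better else "higher_better",
        )
        for metric, column in columns.items()
    }
    scored = []
    for i, row in enumerate(rows):
        normalized = {metric: normalized_columns[metric][i] for metric in config.weights}
        score = sum(config.weights[m] * normalized[m] for m in config.weights)
        scored.append(
            ScoredGene(
                gene_symbol=row.gene_symbol,
                raw={m: columns[m][i] for m in config.weights},
                normalized=normalized,
                score=score,
            )
        )
    scored.sort(key=lambda g: (-g.score, g.gene_symbol))
    for rank, gene in enumerate(scored, start=1):
        gene.rank = rank
    return scored


def top_n(scored: Sequence[ScoredGene], n: int = 40) -> list[ScoredGene]:
    """First ``n`` ranked genes (default 40, the reporting slice)."""
    if n > len(scored):
        logger.warning("requested top %d but only %d genes are ranked", n, len(scored))
    return list(scored[: max(n, 0)])


def scores_to_frame(scored: Sequence[ScoredGene]) -> pd.DataFrame:
    """Score table: raw metrics, normalized metrics, cumulative score, rank."""
    rows = []
    for gene in scored:
        row: dict[str, object] = {"gene_symbol": gene.gene_symbol}
        row.update(gene.raw)
        row.update({f"norm_{m}": v for m, v in gene.normalized.items()})
        row["score"] = gene.score
        row["rank"] = gene.rank
        rows.append(row)
    return pd.DataFrame(rows)
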