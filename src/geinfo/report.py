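"""Reporting surfaces: searchable tables and the top-N ranking bar plot.

Two tabular views are produced: a per-article extraction table joining each
record with its GEM metadata (``table_vis1``), and the per-gene score table
with raw metrics, normalized metrics, cumulative score and rank
(``table_vis2``). Both are written as CSV and as static HTML with a
client-side search box (no server component). The ranking is additionally
visualized as a bar plot of the top-N genes by cumulative score.
"""

from __future__ import annotations

import html
import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .corpus_io import GemEntry  # noqa: E402
from .extraction import ExtractionRecord  # noqa: E402
from .scoring import ScoredGene, scores_to_frame  # noqa: E402

logger = logging.getLogger(__name__)

_HTML_PAGE = """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
th, td {{ border: 1px solid #999; padding: 4px 8px; text-align: left; }}
th {{ background: #eee; }}
input {{ margin-bottom: 1em; padding: 4px; width: 24em; }}
</style>
</head>
<body>
<h1>{title}</h1>
<input id="q" type="text" placeholder="Search rows..." onkeyup="filterRows()">
{table}
<script>
function filterRows() {{
  var q = document.getElementById('q').value.toLowerCase();
  var rows = document.querySelectorAll('tbody tr');
  rows.forEach(function(row) {{
    row.style.display = row.textContent.toLowerCase().includes(q) ? '' : 'none';
  }});
}}
</script>
</body>
</html>
"""


def extraction_table(
    records: Sequence[ExtractionRecord], entries: Sequence[GemEntry] = ()
) -> pd.DataFrame:
    """Per-article table joining extraction results with GEM metadata."""
    gem_genes: dict[str, list[str]] = {}
    for entry in entries:
        gem_genes.setdefault(entry.pmid, [])
        if entry.gene_symbol and entry.gene_symbol not in gem_genes[entry.pmid]:
            gem_genes[entry.pmid].append(entry.gene_symbol)
    rows = []
    for record in records:
        rows.append(
            {
                "pmid": record.pmid,
                "gem_genes": "|".join(gem_genes.get(record.pmid, [])),
                "targeted_genes": "|".join(record.targeted_genes),
                "differentially_expressed_genes": "|".join(
                    record.differentially_expressed_genes
                ),
                "species": "|".join(record.species),
                "genome_editing_tools": "|".join(record.genome_editing_tools),
                "genome_editing_event": "|".join(record.genome_editing_event),
                "phenotypes": "|".join(record.phenotypes),
                "status": record.status,
                "backend": record.backend,
            }
        )
    return pd.DataFrame(rows)


def write_html_table(frame: pd.DataFrame, path: str | Path, title: str) -> None:
    """Write a static searchable HTML view of a table."""
    table_html = frame.to_html(index=False, border=0)
    Path(path).write_text(_HTML_PAGE.format(title=html.escape(title), table=table_html))


def plot_top_genes(
    scored: Sequence[ScoredGene],
    n: int = 40,
    path: str | Path | None = None,
):
    """Bar plot of the top-``n`` genes by cumulative score.

    Returns the matplotlib figure; one bar per plotted gene, highest score
    first.
    """
    from .scoring import top_n as take_top

    top = take_top(list(scored), n)
    fig, ax = plt.subplots(figsize=(10, max(3, 0.25 * len(top) + 1)))
    symbols = [g.gene_symbol for g in top]
    values = [g.score for g in top]
    ax.barh(range(len(top)), values, color="#4878a8")
    ax.set_yticks(range(len(top)))
    ax.set_yticklabels(symbols)
    ax.invert_yaxis()  # rank 1 at the top
    ax.set_xlabel("cumulative score")
    ax.set_title(f"Top {len(top)} genes by weighted score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        logger.info("wrote ranking plot with %d bars to %s", len(top), path)
    return fig


def write_report(
    records: Sequence[ExtractionRecord],
    entries: Sequence[GemEntry],
    scored: Sequence[ScoredGene],
    out_dir: str | Path,
    top: int = 40,
) -> dict[str, Path]:
    """Write table_vis1/table_vis2 as CSV + HTML and the top-N bar plot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vis1 = extraction_table(records, entries)
    vis2 = scores_to_frame(scored)
    paths = {
        "table_vis1_csv": out_dir / "table_vis1.csv",
        "table_vis1_html": out_dir / "table_vis1.html",
        "table_vis2_csv": out_dir / "table_vis2.csv",
        "table_vis2_html": out_dir / "table_vis2.html",
        "plot": out_dir / "top_genes.png",
    }
    vis1.to_csv(paths["table_vis1_csv"], index=False)
    write_html_table(vis1, paths["table_vis1_html"], "Extraction results")
    vis2.to_csv(paths["table_vis2_csv"], index=False)
    write_html_table(vis2, paths["table_vis2_html"], "Gene scores")
    fig = plot_top_genes(scored, n=top, path=paths["plot"])
    plt.close(fig)
    return paths
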