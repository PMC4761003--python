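"""Result bundles: summary CSV, one static HTML page per query, zip archive.

The bundle mirrors the local-PC workflow the pipeline supports: a CSV table
of per-siRNA profiles (sequence, GC content, mismatch level, target count
and the HTML file name) next to self-contained HTML result pages, all zipped
for download.  HTML page names follow the anti-collision rule of 20 random
alphanumeric characters (62-symbol alphabet) plus a YYYYMMDDhhmmss
timestamp, so repeated runs never overwrite each other; under a seeded
random source and a frozen clock the whole bundle is byte-reproducible.
"""

from __future__ import annotations

import csv
import html
import io
import random
import string
import zipfile
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Callable

from .align import edit_string
from .annotation import AnnotationTable, DEFAULT_LINK_TEMPLATES
from .expression import ExpressionDataSet, significant_profiles
from .search import QueryResult

__all__ = [
    "NAME_ALPHABET",
    "ReportRow",
    "BundlePaths",
    "make_result_name",
    "render_query_html",
    "write_bundle",
    "rows_from_results",
]

NAME_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits  # 62

CSV_COLUMNS = [
    "query_name",
    "passenger",
    "guide",
    "gc_percent",
    "k_used",
    "n_target_genes",
    "html_file_name",
]


@dataclass(frozen=True)
class ReportRow:
    query_name: str
    passenger: str
    guide: str
    gc_percent: str
    k_used: str
    n_target_genes: int
    html_file_name: str

    def as_list(self) -> list:
        return [
            self.query_name,
            self.passenger,
            self.guide,
            self.gc_percent,
            self.k_used,
            self.n_target_genes,
            self.html_file_name,
        ]


@dataclass(frozen=True)
class BundlePaths:
    csv: Path
    html: dict[str, Path]
    zip: Path


def make_result_name(
    random_source: random.Random, clock: Callable[[], datetime]
) -> str:
    """``<20 chars from [A-Za-z0-9]>_<YYYYMMDDhhmmss>.html``; deterministic
    under a fixed seed and a frozen clock."""
    token = "".join(random_source.choice(NAME_ALPHABET) for _ in range(20))
    return f"{token}_{clock().strftime('%Y%m%d%H%M%S')}.html"


# --------------------------------------------------------------------------
# HTML rendering (stdlib string assembly; pages are static and self-contained)

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
pre {{ background: #f4f4f4; padding: 0.5em; overflow-x: auto; }}
.passenger {{ background: #ffe08a; font-weight: bold; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; }}
.error {{ color: #a00; }}
</style>
</head>
<body>
{body}
</body>
</html>
"""


def _highlight_read(result: QueryResult) -> str:
    seq = result.read_sequence
    d = result.duplex
    if not seq:
        return f"<pre>{html.escape(d.passenger)}</pre>"
    s, e = d.source_start, d.source_end
    return (
        "<pre>"
        + html.escape(seq[:s])
        + f'<span class="passenger">{html.escape(seq[s:e])}</span>'
        + html.escape(seq[e:])
        + "</pre>"
    )


def render_query_html(
    result: QueryResult,
    annotation: AnnotationTable | None = None,
    datasets: list[ExpressionDataSet] | None = None,
    alpha: float = 0.01,
    link_templates: dict[str, str] | None = None,
) -> str:
    """One self-contained result page: highlighted input, alignment blocks,
    annotation links and significant expression profiles."""
    esc = html.escape
    parts: list[str] = [f"<h1>Query {esc(result.query_name)}</h1>"]
    if result.error:
        parts.append(f'<p class="error">Error: {esc(result.error)}</p>')
        return _PAGE.format(title=esc(result.query_name), body="\n".join(parts))

    d = result.duplex
    parts.append("<h2>Input sequence</h2>")
    parts.append(_highlight_read(result))
    parts.append("<h2>siRNA duplex</h2>")
    parts.append("<table>")
    parts.append(f"<tr><th>passenger (5'→3')</th><td><code>{esc(d.passenger)}</code></td></tr>")
    parts.append(f"<tr><th>guide (5'→3')</th><td><code>{esc(d.guide)}</code></td></tr>")
    parts.append(f"<tr><th>GC content</th><td>{d.gc_percent:.2f}%</td></tr>")
    parts.append(
        f"<tr><th>capture</th><td>{d.source_start + 1}–{d.source_end} "
        f"({esc(d.source_orientation)})</td></tr>"
    )
    parts.append("</table>")

    parts.append("<h2>Predicted targets</h2>")
    if result.k_used is None:
        parts.append("<p>No alignment found within the allowed mismatches (no target).</p>")
    else:
        parts.append(
            f"<p>{result.n_target_genes} target gene(s) at {result.k_used} mismatch(es). "
            "Alignment scoring: match +2, mismatch −1, gap −2 (package default).</p>"
        )
        for hit in result.hits:
            parts.append(
                f"<h3>{esc(hit.gene_symbol)} ({esc(hit.accession)}) "
                f"position {hit.position + 1}, {hit.mismatches} mismatch(es), plus strand</h3>"
            )
            if hit.alignment is not None:
                parts.append(f"<pre>{esc(hit.alignment.as_text())}</pre>")
            if annotation is not None:
                links = annotation.lookup(hit.gene_symbol).links(link_templates)
                if links:
                    items = "".join(
                        f'<li><a href="{esc(url)}">{esc(db)}</a></li>' for db, url in links
                    )
                    parts.append(f"<ul>{items}</ul>")
        if datasets:
            parts.append("<h2>Significant expression profiles (Welch's t, P &lt; %s)</h2>" % alpha)
            any_profile = False
            for gene in result.target_genes:
                for prof in significant_profiles(gene, datasets, alpha):
                    any_profile = True
                    link = (
                        f' — <a href="{esc(prof.source_url)}">source</a>'
                        if prof.source_url
                        else ""
                    )
                    parts.append(
                        f"<p>{esc(gene)} in {esc(prof.dataset_id)}: "
                        f"t={prof.t_statistic:.3f}, df={prof.degrees_of_freedom:.2f}, "
                        f"P={prof.p_value:.3g}{link}</p>"
                    )
            if not any_profile:
                parts.append("<p>No dataset shows a significant difference for these targets.</p>")
    return _PAGE.format(title=esc(result.query_name), body="\n".join(parts))


# --------------------------------------------------------------------------
# bundle assembly


def rows_from_results(results: list[QueryResult], names: list[str]) -> list[ReportRow]:
    rows = []
    for result, name in zip(results, names):
        if result.error:
            rows.append(
                ReportRow(result.query_name, "", "", "", "error", 0, name)
            )
            continue
        d = result.duplex
        rows.append(
            ReportRow(
                query_name=result.query_name,
                passenger=d.passenger,
                guide=d.guide,
                gc_percent=f"{d.gc_percent:.2f}",
                k_used="none" if result.k_used is None else str(result.k_used),
                n_target_genes=result.n_target_genes,
                html_file_name=name,
            )
        )
    return rows


def _csv_bytes(rows: list[ReportRow], delimiter: str = ",") -> bytes:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    writer.writerow(CSV_COLUMNS)
    for row in rows:
        writer.writerow(row.as_list())
    return buf.getvalue().encode("utf-8")


def write_bundle(
    results: list[QueryResult],
    out_dir,
    annotation: AnnotationTable | None = None,
    datasets: list[ExpressionDataSet] | None = None,
    alpha: float = 0.01,
    link_templates: dict[str, str] | None = None,
    random_source: random.Random | None = None,
    clock: Callable[[], datetime] | None = None,
    tsv: bool = False,
    run_name: str = "shrnascan_run",
    max_name_retries: int = 100,
) -> BundlePaths:
    """Write the summary table, per-query HTML pages and the zip archive.

    Name collisions are resolved by regenerating (bounded retries).  The zip
    entries' timestamps come from ``clock``, so a frozen clock plus a seeded
    ``random_source`` make the archive byte-identical across reruns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random_source or random.Random()
    clk = clock or datetime.now

    names: list[str] = []
    used: set[str] = set()
    for _ in results:
        name = make_result_name(rng, clk)
        retries = 0
        while name in used:
            retries += 1
            if retries > max_name_retries:
                raise RuntimeError("could not generate a unique result name")
            name = make_result_name(rng, clk)
        used.add(name)
        names.append(name)

    pages = {
        name: render_query_html(result, annotation, datasets, alpha, link_templates)
        for result, name in zip(results, names)
    }
    rows = rows_from_results(results, names)
    table_name = f"{run_name}.{'tsv' if tsv else 'csv'}"
    table_bytes = _csv_bytes(rows, "\t" if tsv else ",")

    csv_path = out / table_name
    csv_path.write_bytes(table_bytes)
    html_paths: dict[str, Path] = {}
    for name, page in pages.items():
        p = out / name
        p.write_text(page, encoding="utf-8")
        html_paths[name] = p

    zip_path = out / f"{run_name}.zip"
    stamp = clk().timetuple()[:6]
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo(table_name, date_time=stamp)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, table_bytes)
        for name, page in pages.items():
            info = zipfile.ZipInfo(name, date_time=stamp)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, page.encode("utf-8"))
    return BundlePaths(csv=csv_path, html=html_paths, zip=zip_path)
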