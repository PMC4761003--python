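"""Local gene annotation tables and outbound database links.

Live nomenclature/ontology/literature lookups are replaced by a local TSV
(symbol, synonyms and per-database id lists) plus URL templates, so reports
can link out to HGNC, GO, OMIM, PubMed, miRTarBase, REACTOME and HPRD without
any network access at analysis time.  Lookup is case-insensitive and
synonym-aware: querying a legacy alias (e.g. HTATIP) resolves to the current
symbol (KAT5) when the table lists it as a synonym.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .expression import ExpressionDataSet, significant_profiles

__all__ = [
    "GeneAnnotation",
    "AnnotationTable",
    "load_annotation",
    "load_link_templates",
    "profile_counts",
    "DEFAULT_LINK_TEMPLATES",
    "ANNOTATION_COLUMNS",
]

ANNOTATION_COLUMNS = [
    "symbol",
    "synonyms",
    "go_terms",
    "omim_ids",
    "pubmed_ids",
    "mirtarbase_ids",
    "reactome_ids",
    "hprd_ids",
]

# {id} is interpolated per stored identifier; HGNC links by the symbol itself.
DEFAULT_LINK_TEMPLATES = {
    "HGNC": "https://www.genenames.org/data/gene-symbol-report/#!/symbol/{id}",
    "GO": "https://amigo.geneontology.org/amigo/term/{id}",
    "OMIM": "https://omim.org/entry/{id}",
    "PubMed": "https://pubmed.ncbi.nlm.nih.gov/{id}/",
    "miRTarBase": "https://mirtarbase.cuhk.edu.cn/php/detail.php?mirtid={id}",
    "REACTOME": "https://reactome.org/content/detail/{id}",
    "HPRD": "http://www.hprd.org/protein/{id}",
}

_ID_FIELDS = [
    ("go_terms", "GO"),
    ("omim_ids", "OMIM"),
    ("pubmed_ids", "PubMed"),
    ("mirtarbase_ids", "miRTarBase"),
    ("reactome_ids", "REACTOME"),
    ("hprd_ids", "HPRD"),
]


@dataclass(frozen=True)
class GeneAnnotation:
    symbol: str
    synonyms: tuple[str, ...] = ()
    go_terms: tuple[str, ...] = ()
    omim_ids: tuple[str, ...] = ()
    pubmed_ids: tuple[str, ...] = ()
    mirtarbase_ids: tuple[str, ...] = ()
    reactome_ids: tuple[str, ...] = ()
    hprd_ids: tuple[str, ...] = ()
    known: bool = False  # present in the loaded table

    def links(self, templates: dict[str, str] | None = None) -> list[tuple[str, str]]:
        """(database, url) pairs; generated only for non-empty id lists."""
        tpl = templates or DEFAULT_LINK_TEMPLATES
        out: list[tuple[str, str]] = []
        if self.known and "HGNC" in tpl:
            out.append(("HGNC", tpl["HGNC"].format(id=self.symbol)))
        for fld, db in _ID_FIELDS:
            if db not in tpl:
                continue
            for ident in getattr(self, fld):
                out.append((db, tpl[db].format(id=ident)))
        return out


class AnnotationTable:
    """Symbol-keyed annotation with a case-insensitive synonym index.

    Lookup is total: unknown names return an empty annotation (with the
    queried name as symbol and no links) rather than raising.
    """

    def __init__(self, annotations: list[GeneAnnotation]):
        self._by_name: dict[str, GeneAnnotation] = {}
        self.annotations = annotations
        for ann in annotations:
            self._by_name[ann.symbol.lower()] = ann
            for syn in ann.synonyms:
                # primary symbols win over another gene's synonym
                self._by_name.setdefault(syn.lower(), ann)

    def lookup(self, name: str) -> GeneAnnotation:
        found = self._by_name.get(name.lower())
        if found is not None:
            return found
        return GeneAnnotation(symbol=name)

    def __len__(self) -> int:
        return len(self.annotations)


def _split(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    return tuple(tok for tok in str(cell).split("|") if tok)


def load_annotation(tsv_path) -> AnnotationTable:
    """Read the annotation TSV (header per ``ANNOTATION_COLUMNS``; multi-valued
    cells pipe-separated; missing cells allowed)."""
    df = pd.read_csv(Path(tsv_path), sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"annotation table {tsv_path} is missing columns: {missing}", missing=missing
        )
    anns = [
        GeneAnnotation(
            symbol=row["symbol"],
            synonyms=_split(row["synonyms"]),
            go_terms=_split(row["go_terms"]),
            omim_ids=_split(row["omim_ids"]),
            pubmed_ids=_split(row["pubmed_ids"]),
            mirtarbase_ids=_split(row["mirtarbase_ids"]),
            reactome_ids=_split(row["reactome_ids"]),
            hprd_ids=_split(row["hprd_ids"]),
            known=True,
        )
        for _, row in df.iterrows()
    ]
    return AnnotationTable(anns)


def load_link_templates(path) -> dict[str, str]:
    """Flat ``name=template`` file; templates carry one ``{id}`` slot."""
    templates = dict(DEFAULT_LINK_TEMPLATES)
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, tpl = line.partition("=")
        templates[name.strip()] = tpl.strip()
    return templates


def profile_counts(
    genes: list[str],
    table: AnnotationTable,
    datasets: list[ExpressionDataSet],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene GO-term and significant-GEO-profile counts plus a summary.

    Returns a DataFrame indexed by gene with columns ``n_go_terms`` and
    ``n_significant_geo_profiles``, and a summary dict of median and
    quartiles per column — the shape used to compare the annotation
    profiles of two target-gene sets.
    """
    rows = []
    for gene in genes:
        ann = table.lookup(gene)
        n_sig = len(significant_profiles(ann.symbol, datasets, alpha))
        rows.append((gene, len(ann.go_terms), n_sig))
    df = pd.DataFrame(
        rows, columns=["gene", "n_go_terms", "n_significant_geo_profiles"]
    ).set_index("gene")
    summary: dict[str, dict[str, float]] = {}
    for col in df.columns:
        if len(df):
            q1, med, q3 = np.percentile(df[col].to_numpy(float), [25, 50, 75])
            summary[col] = {"q1": float(q1), "median": float(med), "q3": float(q3)}
        else:
            summary[col] = {}
    return df, summary
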