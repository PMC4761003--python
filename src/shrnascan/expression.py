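"""Two-condition expression DataSets and Welch's t-test flagging.

Mirrors the curated-expression step of the pipeline: from a collection of
microarray-style DataSets (each a gene × sample value matrix whose samples
are grouped into subsets by one experimental variable), keep only datasets
that compare exactly two conditions with enough replicates, then flag a gene
as differentially expressed in a dataset when the unequal-variance (Welch)
two-sample t-test gives a two-sided P below alpha (default 0.01).

No multiple-testing correction is applied: the flag is a raw per-dataset
P < alpha, by design.  Values are tested as stored; whether they are on a
log scale is the caller's responsibility (``already_log`` is carried as
metadata only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientReplicatesError, SchemaError

__all__ = [
    "ExpressionDataSet",
    "WelchResult",
    "DifferentialResult",
    "welch_t",
    "filter_datasets",
    "significant_profiles",
    "load_dataset",
    "load_dataset_collection",
    "write_dataset",
]


@dataclass
class ExpressionDataSet:
    """A GEO-DataSet-like bundle: value matrix plus subset metadata."""

    dataset_id: str
    organism: str
    subset_type: str
    subsets: list[tuple[str, list[str]]]  # (label, sample ids), order preserved
    values: pd.DataFrame  # gene rows × sample columns
    source_url: str = ""
    already_log: bool = False

    def __post_init__(self):
        cols = set(self.values.columns)
        seen: set[str] = set()
        for label, samples in self.subsets:
            missing = [s for s in samples if s not in cols]
            if missing:
                raise SchemaError(
                    f"dataset {self.dataset_id}: subset {label!r} references "
                    f"samples missing from the matrix: {missing}"
                )
            dup = seen.intersection(samples)
            if dup:
                raise SchemaError(
                    f"dataset {self.dataset_id}: samples {sorted(dup)} appear in more than one subset"
                )
            seen.update(samples)
        if self.values.shape[0] < 1:
            raise SchemaError(f"dataset {self.dataset_id}: matrix has no gene rows")

    def group_values(self, gene: str) -> list[np.ndarray]:
        row = self.values.loc[gene]
        return [row[samples].to_numpy(dtype=float) for _, samples in self.subsets]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False  # both groups had zero variance


@dataclass(frozen=True)
class DifferentialResult:
    dataset_id: str
    gene: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    source_url: str = ""


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance t with Welch–Satterthwaite df and two-sided p.

    Conventions for degenerate inputs: both groups constant with equal means
    gives (t=0, p=1); both constant with unequal means gives (t=±inf, p=0),
    flagged ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            f"Welch's t needs >=2 values per group, got {a.size} and {b.size}"
        )
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            return WelchResult(0.0, float(na + nb - 2), 1.0, degenerate=True)
        return WelchResult(math.copysign(math.inf, ma - mb), float(na + nb - 2), 0.0, degenerate=True)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), degenerate=False)


def filter_datasets(
    datasets: list[ExpressionDataSet],
    organism: str,
    min_samples_per_subset: int = 3,
) -> list[ExpressionDataSet]:
    """Keep datasets comparing exactly two conditions of one variable in the
    right organism, with at least ``min_samples_per_subset`` samples each.

    The replicate floor defaults to 3 (a strict reading of "more than two
    samples in each condition"); pass 2 for the permissive reading.  Order is
    preserved and the operation is idempotent.
    """
    out = []
    for ds in datasets:
        if ds.organism != organism:
            continue
        if len(ds.subsets) != 2:
            continue
        if any(len(samples) < min_samples_per_subset for _, samples in ds.subsets):
            continue
        out.append(ds)
    return out


def differential_expression(
    gene: str, dataset: ExpressionDataSet, alpha: float = 0.01
) -> DifferentialResult:
    """Welch-test one gene in one two-subset dataset."""
    (la, sa), (lb, sb) = dataset.subsets
    va, vb = dataset.group_values(gene)
    res = welch_t(va, vb)
    return DifferentialResult(
        dataset_id=dataset.dataset_id,
        gene=gene,
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        n_a=len(va),
        n_b=len(vb),
        t_statistic=res.t,
        degrees_of_freedom=res.df,
        p_value=res.p,
        significant=res.p < alpha,
        source_url=dataset.source_url,
    )


def significant_profiles(
    gene: str, datasets: list[ExpressionDataSet], alpha: float = 0.01
) -> list[DifferentialResult]:
    """Datasets in which ``gene`` is differentially expressed at P < alpha.

    Datasets not containing the gene are skipped silently; each result
    carries the dataset's source URL for report links.
    """
    out = []
    for ds in datasets:
        if gene not in ds.values.index:
            continue
        res = differential_expression(gene, ds, alpha)
        if res.significant:
            out.append(res)
    return out


# --------------------------------------------------------------------------
# on-disk bundle format: <dir>/matrix.tsv + <dir>/meta.tsv

_META_KEYS = {"dataset_id", "organism", "subset_type"}


def load_dataset(directory) -> ExpressionDataSet:
    """Read one DataSet bundle directory (matrix.tsv + meta.tsv) and validate it."""
    directory = Path(directory)
    matrix_path, meta_path = directory / "matrix.tsv", directory / "meta.tsv"
    for p in (matrix_path, meta_path):
        if not p.exists():
            raise SchemaError(f"dataset bundle {directory} is missing {p.name}")
    meta: dict[str, str] = {}
    subsets: list[tuple[str, list[str]]] = []
    for line in meta_path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        if key.startswith("subset:"):
            subsets.append((key[len("subset:") :], [s for s in value.split(",") if s]))
        else:
            meta[key] = value
    missing = sorted(_META_KEYS - meta.keys())
    if missing:
        raise SchemaError(f"{meta_path} is missing keys: {missing}", missing=missing)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return ExpressionDataSet(
        dataset_id=meta["dataset_id"],
        organism=meta["organism"],
        subset_type=meta["subset_type"],
        subsets=subsets,
        values=values,
        source_url=meta.get("source_url", ""),
        already_log=meta.get("already_log", "false").lower() == "true",
    )


def load_dataset_collection(parent_dir) -> list[ExpressionDataSet]:
    """All bundle subdirectories of ``parent_dir``, sorted by name."""
    parent = Path(parent_dir)
    return [
        load_dataset(d)
        for d in sorted(parent.iterdir())
        if d.is_dir() and (d / "meta.tsv").exists()
    ]


def write_dataset(ds: ExpressionDataSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        f"dataset_id\t{ds.dataset_id}",
        f"organism\t{ds.organism}",
        f"subset_type\t{ds.subset_type}",
    ]
    for label, samples in ds.subsets:
        lines.append(f"subset:{label}\t{','.join(samples)}")
    if ds.source_url:
        lines.append(f"source_url\t{ds.source_url}")
    if ds.already_log:
        lines.append("already_log\ttrue")
    (directory / "meta.tsv").write_text("\n".join(lines) + "\n")
    ds.values.to_csv(directory / "matrix.tsv", sep="\t", index_label="gene")
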