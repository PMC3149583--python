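"""Reading expression tables, class labels and pair lists; writing results.

All text formats are tab-delimited UTF-8 with a header row. On input the
tokens "" / "NA" / "NaN" / "null" (case-insensitive) denote a missing
expression value; on output "NA" is the sole missing token. Output rows are
deterministically sorted so repeated runs are diffable.
"""

from __future__ import annotations

import html as _html
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dapnet")

MISSING_TOKENS = {"", "na", "nan", "null"}

#: fixed column order of the comprehensive result table
RESULT_COLUMNS = [
    "gene1_id", "gene1_annotation", "gene2_id", "gene2_annotation",
    "assoc_class1", "stat_class1", "p_class1",
    "assoc_class2", "stat_class2", "p_class2",
    "delta", "z_diff", "p_diff", "p_diff_adj", "p_perm", "p_perm_adj",
]

#: DapRecord fields that may serve as Cytoscape edge weights
NUMERIC_RECORD_FIELDS = [
    "assoc_class1", "stat_class1", "p_class1",
    "assoc_class2", "stat_class2", "p_class2",
    "delta", "z_diff", "p_diff", "p_diff_adj", "p_perm", "p_perm_adj",
]


@dataclass
class ExpressionDataset:
    """Two-phenotype expression matrix: genes in rows, samples in columns.

    Values are log-scale expression (unitless). ``missing_mask`` is True
    wherever a value is absent or non-finite; the constructor enforces this.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    class_labels: np.ndarray  # (n_samples,) labels, exactly 2 distinct values
    values: np.ndarray        # (n_genes, n_samples) float
    missing_mask: np.ndarray | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = np.asarray(self.class_labels)
        if not self.gene_ids:
            raise ValueError("dataset has no genes")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene IDs: {sorted(dupes)}")
        if _duplicates(self.sample_ids):
            raise ValueError(f"duplicate sample IDs: {sorted(_duplicates(self.sample_ids))}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.class_labels.shape != (len(self.sample_ids),):
            raise ValueError("class_labels length does not match sample_ids")
        nonfinite = ~np.isfinite(self.values)
        if self.missing_mask is None:
            self.missing_mask = nonfinite
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool) | nonfinite
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> tuple:
        """The two phenotype labels, sorted for a stable class-1/class-2 order."""
        return tuple(sorted(set(self.class_labels.tolist()), key=str))

    def require_two_classes(self) -> None:
        cls = set(self.class_labels.tolist())
        if len(cls) != 2:
            raise ValueError(
                f"DAP testing requires exactly 2 classes, got {len(cls)}: {sorted(map(str, cls))}"
            )

    def class_sample_indices(self, label) -> np.ndarray:
        return np.flatnonzero(self.class_labels == label)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene ID: {gene_id!r}") from None

    def annotation(self, gene_id: str) -> str:
        return self.annotations.get(gene_id, "")


@dataclass
class GenePairList:
    """Ordered list of canonical (lexicographically sorted) gene-ID pairs."""

    pairs: list[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class DapRecord:
    """One row of the comprehensive output: everything tested for one pair."""

    gene1_id: str
    gene2_id: str
    gene1_annotation: str = ""
    gene2_annotation: str = ""
    metric: str = "pearson"
    assoc_class1: float | None = None
    assoc_class2: float | None = None
    n_eff_class1: int = 0
    n_eff_class2: int = 0
    stat_class1: float | None = None
    p_class1: float | None = None
    stat_class2: float | None = None
    p_class2: float | None = None
    delta: float | None = None
    z_diff: float | None = None
    p_diff: float | None = None
    p_perm: float | None = None
    p_diff_adj: float | None = None
    p_perm_adj: float | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)


@dataclass
class RunReport:
    """Settings echo + diagnostics for the HTML run report."""

    settings: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    top_z: list[DapRecord] = field(default_factory=list)
    top_perm: list[DapRecord] = field(default_factory=list)
    include_top10: bool = True


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        (dup if it in seen else seen).add(it)
    return dup


def _is_missing_token(tok: str) -> bool:
    return tok.strip().lower() in MISSING_TOKENS


def canonical_pair(g1: str, g2: str) -> tuple[str, str]:
    """Pair identity independent of input order: lexicographically smaller first."""
    return (g1, g2) if g1 <= g2 else (g2, g1)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression_table(
    path,
    label_path,
    annotation_columns: Iterable[str] = (),
    require_two_classes: bool = True,
) -> ExpressionDataset:
    """Read a genes×samples TSV plus a two-column sample→class label TSV.

    The first column of the expression table is the unique gene ID; any
    columns named in ``annotation_columns`` are per-gene annotation; every
    remaining column is a sample. Samples present in the matrix but absent
    from the label file are dropped with a logged warning.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if table.shape[1] < 2:
        raise ValueError(f"expression table {path} has fewer than 2 columns")
    gene_col = table.columns[0]
    gene_ids = table[gene_col].astype(str).tolist()
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"duplicate gene IDs in {path}: {sorted(dupes)}")

    ann_cols = [c for c in annotation_columns if c in table.columns]
    missing_ann = set(annotation_columns) - set(ann_cols)
    if missing_ann:
        raise ValueError(f"annotation columns not found: {sorted(missing_ann)}")
    annotations = {}
    if ann_cols:
        for gid, row in zip(gene_ids, table[ann_cols].itertuples(index=False)):
            annotations[gid] = "; ".join(str(v) for v in row if str(v).strip())

    sample_cols = [c for c in table.columns[1:] if c not in ann_cols]
    labels_df = pd.read_csv(label_path, sep="\t", dtype=str, keep_default_na=False)
    if labels_df.shape[1] < 2:
        raise ValueError(f"label file {label_path} needs 2 columns (sample_id, class)")
    label_map = dict(zip(labels_df.iloc[:, 0].astype(str), labels_df.iloc[:, 1].astype(str)))

    kept = [c for c in sample_cols if c in label_map]
    dropped = [c for c in sample_cols if c not in label_map]
    if dropped:
        logger.warning("dropping %d unlabeled sample(s): %s", len(dropped), dropped)
    if not kept:
        raise ValueError("no samples in the expression table are present in the label file")

    raw = table[kept].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for idx, tok in np.ndenumerate(raw):
        s = str(tok)
        if _is_missing_token(s):
            values[idx] = np.nan
        else:
            try:
                values[idx] = float(s)
            except ValueError:
                values[idx] = np.nan

    ds = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=kept,
        class_labels=np.array([label_map[c] for c in kept]),
        values=values,
        annotations=annotations,
    )
    if require_two_classes:
        ds.require_two_classes()
    return ds


def read_pair_list(path, dataset: ExpressionDataset) -> GenePairList:
    """Read a two-column TSV of gene-ID pairs, canonicalize and deduplicate.

    Self-pairs and pairs naming a gene absent from ``dataset`` are excluded
    with a logged warning; an empty result is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"pair list {path} needs 2 tab-delimited columns")
    known = set(dataset.gene_ids)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for g1, g2 in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        if g1 == g2:
            logger.warning("excluding self-pair (%s, %s)", g1, g2)
            continue
        unknown = [g for g in (g1, g2) if g not in known]
        if unknown:
            logger.warning("excluding pair (%s, %s): unknown gene ID(s) %s", g1, g2, unknown)
            continue
        pair = canonical_pair(g1, g2)
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    if not pairs:
        raise ValueError(f"pair list {path} contains no resolvable pairs")
    return GenePairList(pairs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float) and not math.isfinite(value):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def sort_records(records: Sequence[DapRecord]) -> list[DapRecord]:
    """Deterministic output order: ascending p_diff (NA last), then pair IDs."""
    def key(r: DapRecord):
        p = r.p_diff
        missing = p is None or not math.isfinite(p)
        return (missing, p if not missing else 0.0, r.gene1_id, r.gene2_id)
    return sorted(records, key=key)


def write_result_table(records: Sequence[DapRecord], path) -> None:
    """Write the comprehensive per-pair result table (TSV, fixed column order)."""
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for rec in sort_records(records):
            fh.write("\t".join(_fmt(getattr(rec, col)) for col in RESULT_COLUMNS) + "\n")


def read_result_table(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_result_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_cytoscape_edges(records: Sequence[DapRecord], path, weight_field: str = "delta") -> None:
    """Write a Cytoscape-importable edge list: source, target, interaction, weight."""
    if weight_field not in NUMERIC_RECORD_FIELDS:
        raise ValueError(
            f"weight_field {weight_field!r} is not numeric; valid fields: {NUMERIC_RECORD_FIELDS}"
        )
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinteraction\tweight\n")
        for rec in sort_records(records):
            fh.write(f"{rec.gene1_id}\t{rec.gene2_id}\tcoexpr\t{_fmt(getattr(rec, weight_field))}\n")


_REPORT_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>DAP analysis report</title>
<style>body{{font-family:sans-serif;margin:2em}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 8px}}</style></head>
<body>
<h1>Differentially associated pair analysis</h1>
<h2>Settings</h2>
<table>{settings_rows}</table>
<h2>Diagnostics</h2>
<table>{diag_rows}</table>
{top_sections}
</body></html>
"""


def _kv_rows(d: dict) -> str:
    return "".join(
        f"<tr><th>{_html.escape(str(k))}</th><td>{_html.escape(_fmt(v))}</td></tr>"
        for k, v in d.items()
    )


def _record_table(records: Sequence[DapRecord]) -> str:
    head = "".join(f"<th>{c}</th>" for c in RESULT_COLUMNS)
    rows = "".join(
        "<tr>" + "".join(f"<td>{_html.escape(_fmt(getattr(r, c)))}</td>" for c in RESULT_COLUMNS) + "</tr>"
        for r in records
    )
    return f"<table><tr>{head}</tr>{rows}</table>"


def write_html_report(report: RunReport, path) -> None:
    """Write a self-contained HTML report with settings echo and diagnostics."""
    sections = ""
    if report.include_top10:
        if report.top_z:
            sections += "<h2>Top 10 Fisher Z-test results</h2>" + _record_table(report.top_z)
        if report.top_perm:
            sections += "<h2>Top 10 permutation test results</h2>" + _record_table(report.top_perm)
    content = _REPORT_TEMPLATE.format(
        settings_rows=_kv_rows(report.settings),
        diag_rows=_kv_rows(report.diagnostics),
        top_sections=sections,
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(content)
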