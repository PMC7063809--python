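"""Expression, annotation and trait-table ingestion.

Reads expression matrices from plain TSV or GEO Series Matrix files,
transcript-to-gene annotation maps (2-column TSV or GEO ``.annot``-style
tables), and clinical trait tables (CSV plus a small YAML schema sidecar).
Transcript-level matrices are collapsed to gene level by keeping, for each
gene, the transcript with the highest mean expression.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "AnnotationMap",
    "TraitMeta",
    "TraitTable",
    "FormatError",
    "SchemaError",
    "read_expression_table",
    "read_annotation",
    "collapse_to_genes",
    "read_trait_table",
    "default_trait_schema",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class SchemaError(ValueError):
    """Raised when a trait schema entry is invalid."""


class ExpressionMatrix:
    """Feature x sample matrix of (log-scale) expression intensities.

    Rows are features (transcripts or genes), columns are samples.  Feature
    and sample identifiers must be unique and all values finite.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature identifiers: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at feature {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_features} features x {self.n_samples} samples)"

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")


@dataclasses.dataclass
class AnnotationMap:
    """Many-to-one transcript -> gene-symbol mapping.

    Transcripts without a usable symbol are kept in ``unmapped`` so that
    dropped features are auditable.
    """

    mapping: dict[str, str]
    unmapped: list[str] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mapping)

    def genes(self) -> set[str]:
        return set(self.mapping.values())


@dataclasses.dataclass
class TraitMeta:
    """Per-trait metadata: measurement kind, timepoint, adjustment covariates."""

    kind: str  # "quantitative" | "categorical"
    timepoint: str = "static"  # BL | 3M | 6M | 12M | static
    adjustment_covariates: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "categorical"):
            raise SchemaError(f"unknown trait kind {self.kind!r}")
        if self.timepoint not in ("BL", "3M", "6M", "12M", "static"):
            raise SchemaError(f"unknown timepoint {self.timepoint!r}")


class TraitTable:
    """Sample x trait clinical table with per-trait metadata.

    ``data`` is indexed by sample id; missing values stay missing (NaN).
    Categorical traits must show at least two levels among observed values.
    ``zero_variance`` lists quantitative traits that are constant — they load
    fine but are flagged so downstream correlation steps can skip them.
    """

    def __init__(self, data: pd.DataFrame, meta: Mapping[str, TraitMeta]):
        if data.index.has_duplicates:
            raise FormatError("duplicate sample identifiers in trait table")
        missing = [t for t in meta if t not in data.columns]
        if missing:
            raise SchemaError(f"schema names traits absent from table: {missing}")
        self.data = data
        self.meta = dict(meta)
        self.zero_variance: list[str] = []
        for name, m in self.meta.items():
            col = data[name].dropna()
            if m.kind == "categorical":
                if col.nunique() < 2:
                    raise FormatError(
                        f"categorical trait {name!r} has fewer than 2 observed levels"
                    )
            else:
                vals = pd.to_numeric(col, errors="coerce")
                if len(vals) and float(np.nanstd(vals.to_numpy(dtype=float))) == 0.0:
                    self.zero_variance.append(name)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def trait_names(self) -> list[str]:
        return list(self.meta)

    def quantitative(self) -> list[str]:
        return [t for t, m in self.meta.items() if m.kind == "quantitative"]

    def categorical(self) -> list[str]:
        return [t for t, m in self.meta.items() if m.kind == "categorical"]

    def aligned_to(self, samples: Sequence[str]) -> "TraitTable":
        """Restrict and order rows to the given sample ids."""
        keep = [s for s in samples if s in self.data.index]
        return TraitTable(self.data.loc[keep], self.meta)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="sample_id")

    def schema_dict(self) -> dict:
        return {
            t: {
                "kind": m.kind,
                "timepoint": m.timepoint,
                "adjust": list(m.adjustment_covariates),
            }
            for t, m in self.meta.items()
        }


# ---------------------------------------------------------------------------
# readers


def _parse_numeric_block(rows: list[list[str]], path: str) -> pd.DataFrame:
    header, *body = rows
    sample_ids = [h.strip().strip('"') for h in header[1:]]
    index, records = [], []
    for i, row in enumerate(body):
        index.append(row[0].strip().strip('"'))
        rec = []
        for j, cell in enumerate(row[1:]):
            try:
                rec.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at data row {i + 1}, "
                    f"column {sample_ids[j] if j < len(sample_ids) else j + 1}: {cell!r}"
                ) from None
        records.append(rec)
    return pd.DataFrame(records, index=index, columns=sample_ids)


def read_expression_table(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO Series Matrix file.

    ``tsv``: first row is the sample-id header, first column feature ids.
    ``geo_series_matrix``: only rows fenced between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` are
    parsed; all metadata lines are skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if format == "tsv":
        rows = [ln.split("\t") for ln in lines if ln.strip()]
    elif format == "geo_series_matrix":
        rows, inside = [], False
        for ln in lines:
            tag = ln.strip().lower()
            if tag == "!series_matrix_table_begin":
                inside = True
                continue
            if tag == "!series_matrix_table_end":
                inside = False
                continue
            if inside and ln.strip():
                rows.append(ln.split("\t"))
        if not rows:
            raise FormatError(f"{path}: no series_matrix_table fence found")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if len(rows) < 2:
        raise FormatError(f"{path}: no data rows")
    return ExpressionMatrix(_parse_numeric_block(rows, str(path)))


def read_annotation(path: str | Path, format: str = "tsv") -> AnnotationMap:
    """Read a transcript -> gene-symbol map.

    ``tsv``: two columns (transcript id, gene symbol), optional header.
    ``geo_annot``: GEO ``.annot``-style tab table; metadata lines starting
    with ``!``, ``#`` or ``^`` are skipped and the columns named ``ID`` and
    ``Gene symbol`` are used.  Empty or ambiguous (``A///B``) symbols are
    recorded as unmapped.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if format == "geo_annot":
        lines = [ln for ln in lines if not ln.startswith(("!", "#", "^"))]
        if not lines:
            raise FormatError(f"{path}: no annotation rows")
        header = [h.strip() for h in lines[0].split("\t")]
        try:
            id_col = header.index("ID")
            sym_col = header.index("Gene symbol")
        except ValueError:
            raise FormatError(
                f"{path}: .annot header must contain 'ID' and 'Gene symbol'"
            ) from None
        body = lines[1:]
    elif format == "tsv":
        id_col, sym_col = 0, 1
        body = lines
        first = body[0].split("\t")
        if len(first) >= 2 and first[1].lower() in ("gene", "symbol", "gene_symbol"):
            body = body[1:]
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    for ln in body:
        cells = ln.split("\t")
        tid = cells[id_col].strip()
        sym = cells[sym_col].strip() if len(cells) > sym_col else ""
        if tid in mapping or tid in unmapped:
            raise FormatError(f"{path}: duplicate transcript id {tid!r}")
        if not sym or "///" in sym:
            unmapped.append(tid)
        else:
            mapping[tid] = sym
    return AnnotationMap(mapping=mapping, unmapped=unmapped)


def collapse_to_genes(expr: ExpressionMatrix, annot: AnnotationMap) -> ExpressionMatrix:
    """Collapse transcripts to genes.

    For each gene symbol, the transcript with the highest arithmetic mean
    across samples (on the stored log scale) is retained; ties are broken by
    the lexicographically smallest transcript id.  Unmapped transcripts are
    dropped.
    """
    present = [t for t in expr.feature_ids if t in annot.mapping]
    if not present:
        raise FormatError("no transcript in the matrix appears in the annotation")
    means = expr.data.loc[present].mean(axis=1)
    by_gene: dict[str, str] = {}
    for tid in sorted(present):
        gene = annot.mapping[tid]
        best = by_gene.get(gene)
        if best is None or means[tid] > means[best]:
            by_gene[gene] = tid
    genes = sorted(by_gene)
    out = expr.data.loc[[by_gene[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(out)


# Paper-style variable naming: height/weight/BMI/fat traits are adjusted for
# sex and race at baseline and for sex alone at later timepoints.
_BODY_PREFIXES = ("WT", "BMI", "HEIGHT", "SUBTOT", "WB_TOT", "WB_")
_TIMEPOINTS = {"BL": "BL", "3M": "3M", "6M": "6M", "12M": "12M"}


def default_trait_schema(
    columns: Sequence[str],
    sex_col: str = "sex",
    race_col: str = "race",
    categorical: Sequence[str] = (),
) -> dict[str, TraitMeta]:
    """Build trait metadata from conventionally suffixed column names.

    Columns ending in ``_BL``/``_3M``/``_6M``/``_12M`` get that timepoint.
    Body-size traits (weight, height, BMI, fat fractions) are adjusted for
    sex and race at baseline and for sex at the later timepoints.
    """
    cats = set(categorical) | {sex_col, race_col}
    meta: dict[str, TraitMeta] = {}
    for col in columns:
        if col in cats:
            meta[col] = TraitMeta(kind="categorical")
            continue
        upper = col.upper()
        timepoint = "static"
        for suffix, tp in _TIMEPOINTS.items():
            if upper.endswith("_" + suffix):
                timepoint = tp
                break
        adjust: list[str] = []
        if upper.startswith(_BODY_PREFIXES) or upper == "HEIGHT":
            # body-size traits: sex + race at baseline (incl. once-measured
            # traits like height), sex alone at follow-up timepoints
            if timepoint in ("BL", "static"):
                adjust = [sex_col, race_col]
            else:
                adjust = [sex_col]
        meta[col] = TraitMeta(
            kind="quantitative", timepoint=timepoint, adjustment_covariates=adjust
        )
    return meta


def read_trait_table(
    path: str | Path, schema_path: str | Path | None = None
) -> TraitTable:
    """Read a trait CSV (must contain ``sample_id``) plus optional YAML schema.

    The schema maps trait name -> {kind, timepoint, adjust}.  Traits absent
    from the schema fall back to :func:`default_trait_schema` inference.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: trait table must contain a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    inferred = default_trait_schema(df.columns)
    if schema_path is not None:
        raw = yaml.safe_load(Path(schema_path).read_text()) or {}
        for name, entry in raw.items():
            if name not in df.columns:
                raise SchemaError(f"schema trait {name!r} not in table")
            inferred[name] = TraitMeta(
                kind=entry.get("kind", "quantitative"),
                timepoint=entry.get("timepoint", "static"),
                adjustment_covariates=list(entry.get("adjust", [])),
            )
    return TraitTable(df, inferred)
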