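"""Readers and writers for the tabular formats the pipeline touches.

Everything is plain text: tab-separated expression matrices (genes in rows
by default), tab-separated phenotype tables, GMT gene-set collections, and
tab-separated results tables.  Expression values are expected on the log2
scale and must be complete — a missing or non-numeric cell is an error,
never silently imputed, because the harmonized input data this pipeline is
designed for has no missing entries.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITION_CASE = "PE"
CONDITION_CONTROL = "non-PE"
CONDITIONS = (CONDITION_CONTROL, CONDITION_CASE)

_CONDITION_ALIASES = {
    "pe": CONDITION_CASE,
    "non-pe": CONDITION_CONTROL,
    "nonpe": CONDITION_CONTROL,
    "non_pe": CONDITION_CONTROL,
    "non pe": CONDITION_CONTROL,
}

_TRUTHY = {"true", "t", "yes", "y", "1", "1.0"}
_FALSY = {"false", "f", "no", "n", "0", "0.0", ""}


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


def normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values for one cohort.

    ``values`` is a dense :class:`pandas.DataFrame` indexed by uppercase
    gene symbols with sample identifiers as columns.  All entries must be
    finite.
    """

    values: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.index = [normalize_gene(g) for g in df.index]
        df.index.name = "gene"
        df.columns = [str(c) for c in df.columns]
        arr = df.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )
        dup_g = df.index[df.index.duplicated()].unique()
        if len(dup_g):
            raise ValidationError(f"duplicate gene ids after uppercasing: {list(dup_g)}")
        dup_s = df.columns[df.columns.duplicated()].unique()
        if len(dup_s):
            raise ValidationError(f"duplicate sample ids: {list(dup_s)}")
        self.values = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values[ids], cohort_label=self.cohort_label)

    def require_genes(self, genes: Iterable[str]) -> None:
        missing = [g for g in map(normalize_gene, genes) if g not in self.values.index]
        if missing:
            raise ValidationError(
                f"genes missing from cohort {self.cohort_label or '<unnamed>'}: {missing}"
            )


@dataclass
class PhenotypeTable:
    """Per-sample phenotype: condition (PE / non-PE) and a preterm flag."""

    table: pd.DataFrame  # index sample_id; columns condition, preterm, dataset_id

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.index = [str(i) for i in df.index]
        df.index.name = "sample_id"
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dups)}")
        if "condition" not in df.columns:
            raise ValidationError("phenotype table lacks a 'condition' column")
        df["condition"] = [_normalize_condition(c) for c in df["condition"]]
        if "preterm" not in df.columns:
            df["preterm"] = False
        df["preterm"] = [_normalize_bool(v) for v in df["preterm"]]
        if "dataset_id" not in df.columns:
            df["dataset_id"] = ""
        self.table = df[["condition", "preterm", "dataset_id"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def condition_mask(self, condition: str) -> pd.Series:
        if condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        return self.table["condition"] == condition

    def samples_with(self, condition: str) -> list[str]:
        return list(self.table.index[self.condition_mask(condition)])

    def term_subset(self) -> "PhenotypeTable":
        """Drop every preterm sample (birth before 37 weeks)."""
        keep = self.table[~self.table["preterm"]]
        if keep.empty:
            raise ValidationError("no term (non-preterm) samples remain")
        return PhenotypeTable(keep.copy())

    def check_matches(self, expr: ExpressionMatrix) -> None:
        expr_ids = set(expr.sample_ids)
        pheno_ids = set(self.sample_ids)
        if expr_ids - pheno_ids:
            raise ValidationError(
                f"samples in expression but not phenotype: {sorted(expr_ids - pheno_ids)}"
            )


def _normalize_condition(value: object) -> str:
    key = str(value).strip().lower()
    if key in _CONDITION_ALIASES:
        return _CONDITION_ALIASES[key]
    raise ValidationError(
        f"unknown condition {value!r}; allowed values (case-insensitive): {CONDITIONS}"
    )


def _normalize_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in _TRUTHY:
        return True
    if key in _FALSY:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean preterm flag")


@dataclass
class GeneSetCollection:
    """Ordered mapping set name -> (description, gene symbols).

    Gene lists are de-duplicated and uppercase-normalized on construction;
    insertion order of the sets is preserved.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, genes) in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(normalize_gene(g), None)
            if not seen:
                raise ValidationError(f"gene set {name!r} is empty after de-duplication")
            cleaned[str(name)] = (str(desc), tuple(seen))
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def items(self):
        return self.sets.items()

    def restricted_to(
        self,
        universe: Iterable[str],
        min_size: int = 1,
        max_size: int | None = None,
    ) -> "GeneSetCollection":
        """Intersect every set with ``universe`` and apply size bounds."""
        uni = {normalize_gene(g) for g in universe}
        kept: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, genes) in self.sets.items():
            inter = tuple(g for g in genes if g in uni)
            if len(inter) < max(1, min_size):
                continue
            if max_size is not None and len(inter) > max_size:
                continue
            kept[name] = (desc, inter)
        return GeneSetCollection(kept)


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path,
    orientation: str = "genes_in_rows",
    cohort_label: str | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ids, first row header)."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if orientation == "samples_in_rows":
        raw = raw.T
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: missing or non-numeric value at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    label = cohort_label if cohort_label is not None else str(path)
    return ExpressionMatrix(numeric, cohort_label=label)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes), found {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, tuple(g for g in genes if g.strip()))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, (desc, genes) in collection.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Phenotypes and results


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: phenotype table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", lineterminator="\n")


_PVALUE_COLS = {"p", "q", "fdr", "p_value", "adj_p", "p_adj", "pvalue"}


def write_results(
    df: pd.DataFrame,
    path,
    float_formats: Mapping[str, str] | None = None,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a results table with deterministic column order and formatting.

    p/q-like columns get 4 decimals, other floats 2 decimals, unless
    overridden through ``float_formats`` (column name -> printf format).
    """
    out = df.copy()
    formats = dict(float_formats or {})
    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        fmt = formats.get(col)
        if fmt is None:
            fmt = "%.4f" if col.lower() in _PVALUE_COLS else "%.2f"
        out[col] = [("" if _isnan(v) else fmt % v) for v in out[col]]
    with open(path, "w", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _isnan(v: float) -> bool:
    try:
        return math.isnan(v)
    except TypeError:
        return False
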