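"""Labelled tabular datasets as fundamental sets of associations.

An associative-memory classifier learns from a *fundamental set*: a finite
collection of associations ``{(x^mu, y^mu) | mu = 1..p}`` pairing an input
pattern ``x^mu`` (an n-vector of attribute values) with its class label
``y^mu``.  This module holds that data model plus readers and writers for
the two tabular formats common in the clinical-benchmark setting, CSV and
ARFF (the attribute-relation file format used by data-mining workbenches).

Attribute values are stored numerically.  Nominal ARFF attributes whose
declared values are not numbers are encoded by their declaration-order
index; the schema records the allowed codes.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

KINDS = ("numeric", "categorical-ordinal", "binary")


@dataclass(frozen=True)
class AttributeSchema:
    """Description of one input attribute.

    Parameters
    ----------
    name:
        Column label, unique within a dataset.
    kind:
        ``"numeric"``, ``"categorical-ordinal"`` or ``"binary"``.
    allowed_values:
        Enumerated admissible codes; required (non-empty) for the two
        discrete kinds, e.g. ``(0, 1, 2)`` for a resting-ECG category.
    units:
        Optional free-text units (e.g. ``"mmHg"``).
    """

    name: str
    kind: str = "numeric"
    allowed_values: tuple[float, ...] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind != "numeric" and not self.allowed_values:
            raise SchemaError(
                f"attribute {self.name!r} of kind {self.kind!r} needs allowed_values"
            )

    def admits(self, value: float) -> bool:
        if self.allowed_values is None:
            return bool(np.isfinite(value))
        return any(value == v for v in self.allowed_values)


@dataclass(frozen=True)
class ClassLabel:
    """A class as (index, name); indices are positions in ``class_names``."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if self.index < 0:
            raise SchemaError("class index must be non-negative")


@dataclass
class FundamentalSet:
    """The learned-from set of p associations plus its attribute schema.

    ``X`` is the (p, n) matrix of patterns (row mu is x^mu), ``y`` the
    length-p vector of class indices.  ``class_names`` fixes the
    index -> name mapping; a one-hot view of the labels is derived, not
    stored.
    """

    X: np.ndarray
    y: np.ndarray
    schema: list[AttributeSchema]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise SchemaError("X must be a 2-D (p, n) array")
        if self.y.shape != (self.X.shape[0],):
            raise SchemaError("y must have one label per pattern")

    # -- derived quantities -------------------------------------------------

    @property
    def p(self) -> int:
        """Cardinality of the fundamental set."""
        return self.X.shape[0]

    @property
    def n(self) -> int:
        """Pattern dimensionality (number of input attributes)."""
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label(self, mu: int) -> ClassLabel:
        idx = int(self.y[mu])
        return ClassLabel(idx, self.class_names[idx])

    def one_hot(self) -> np.ndarray:
        """Derived (p, m) one-hot view of the output vectors y^mu."""
        out = np.zeros((self.p, self.n_classes), dtype=int)
        out[np.arange(self.p), self.y] = 1
        return out

    def fingerprint(self) -> tuple[int, int, str]:
        """(p, n, checksum) identity used to tie transforms/memories to data."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(np.ascontiguousarray(self.y).tobytes())
        h.update("|".join(self.class_names).encode())
        return (self.p, self.n, h.hexdigest()[:16])

    def with_values(self, X: np.ndarray) -> "FundamentalSet":
        """Same labels/schema with replaced pattern values (used by transforms)."""
        return FundamentalSet(X, self.y.copy(), list(self.schema), list(self.class_names))

    def subset(self, rows: Sequence[int]) -> "FundamentalSet":
        rows = np.asarray(rows, dtype=int)
        return FundamentalSet(
            self.X[rows], self.y[rows], list(self.schema), list(self.class_names)
        )


def validate_schema(
    fs: FundamentalSet, for_learning: bool = False, check_values: bool = True
) -> list[str]:
    """Check every FundamentalSet invariant; return violation descriptions.

    Violations are returned, never raised: each names the offending row
    and/or attribute and the rule broken.  ``for_learning`` additionally
    requires at least one association per declared class.  ``check_values``
    enforces the per-attribute allowed sets; it is switched off for sets
    that have been translated, where only structure can be checked.
    """
    violations: list[str] = []
    if fs.p < 1:
        violations.append("fundamental set is empty (p must be >= 1)")
    if len(fs.schema) != fs.n:
        violations.append(
            f"schema lists {len(fs.schema)} attributes but patterns have n={fs.n}"
        )
    names = [a.name for a in fs.schema]
    if len(set(names)) != len(names):
        dupes = sorted({nm for nm in names if names.count(nm) > 1})
        violations.append(f"duplicate attribute names: {dupes}")
    if fs.n_classes < 1:
        violations.append("no classes declared")
    for mu in range(fs.p):
        if not (0 <= fs.y[mu] < fs.n_classes):
            violations.append(f"row {mu}: class index {fs.y[mu]} out of range")
    if check_values:
        for j, attr in enumerate(fs.schema[: fs.n]):
            col = fs.X[:, j]
            bad = [mu for mu in range(fs.p) if not attr.admits(col[mu])]
            for mu in bad:
                violations.append(
                    f"row {mu}, attribute {attr.name!r}: value {col[mu]} outside allowed set"
                )
    if for_learning:
        counts = np.bincount(fs.y, minlength=fs.n_classes) if fs.p else np.zeros(fs.n_classes)
        for c, cnt in enumerate(counts):
            if cnt == 0:
                violations.append(
                    f"class {fs.class_names[c]!r} has zero associations (learning needs >= 1)"
                )
    return violations


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _classes_from_column(
    raw: Iterable, class_order: Sequence[str] | None
) -> tuple[list[str], np.ndarray]:
    """Map raw class values to indices in first-appearance order (or a given order)."""
    values = [str(v) for v in raw]
    if class_order is not None:
        names = list(class_order)
        unknown = sorted(set(values) - set(names))
        if unknown:
            raise SchemaError(f"class values {unknown} not in class_order {names}")
    else:
        names = list(dict.fromkeys(values))
    index = {nm: i for i, nm in enumerate(names)}
    return names, np.array([index[v] for v in values], dtype=int)


def _frame_to_fundamental_set(
    df: pd.DataFrame,
    class_column: str,
    schema: Sequence[AttributeSchema] | None,
    class_order: Sequence[str] | None,
    drop_missing: bool,
) -> FundamentalSet:
    if class_column not in df.columns:
        raise SchemaError(
            f"class column {class_column!r} not found; columns are {list(df.columns)}"
        )
    if df[class_column].isna().any():
        raise ValidationError("missing values in the class column")
    n_before = len(df)
    if df.drop(columns=[class_column]).isna().any().any():
        if not drop_missing:
            bad = df.index[df.drop(columns=[class_column]).isna().any(axis=1)].tolist()
            raise ValidationError(
                f"missing attribute values in rows {bad[:10]} (drop_missing=False)"
            )
        df = df.dropna()
        logger.info("dropped %d incomplete rows", n_before - len(df))
    if len(df) == 0:
        raise SchemaError("no data rows after reading")

    attr_cols = [c for c in df.columns if c != class_column]
    X = np.empty((len(df), len(attr_cols)), dtype=float)
    for j, col in enumerate(attr_cols):
        try:
            X[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"attribute {col!r} is not numerically encoded: {exc}"
            ) from exc

    class_names, y = _classes_from_column(df[class_column], class_order)
    if schema is None:
        schema_list = [AttributeSchema(name=c) for c in attr_cols]
    else:
        schema_list = list(schema)
        got = [a.name for a in schema_list]
        if got != attr_cols:
            raise SchemaError(f"schema attributes {got} do not match columns {attr_cols}")
    fs = FundamentalSet(X, y, schema_list, class_names)
    problems = validate_schema(fs)
    if problems:
        raise ValidationError("; ".join(problems))
    return fs


def read_csv(
    path: str | Path,
    class_column: str,
    schema: Sequence[AttributeSchema] | None = None,
    class_order: Sequence[str] | None = None,
    drop_missing: bool = False,
) -> FundamentalSet:
    """Read a header-required, comma-separated, '.'-decimal CSV file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=",", header=0, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except FileNotFoundError:
        raise
    return _frame_to_fundamental_set(df, class_column, schema, class_order, drop_missing)


_ARFF_ATTR = re.compile(r"@attribute\s+('([^']*)'|\"([^\"]*)\"|(\S+))\s+(.+)", re.IGNORECASE)


def _parse_arff(path: Path) -> tuple[list[tuple[str, list[str] | None]], list[list[str]]]:
    """Parse @relation/@attribute/@data sections.

    Returns (attributes, rows) where each attribute is (name, nominal_values)
    with nominal_values None for numeric attributes.  Strings/dates rejected.
    """
    attributes: list[tuple[str, list[str] | None]] = []
    rows: list[list[str]] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            if in_data:
                cells = [c.strip().strip("'\"") for c in line.split(",")]
                rows.append(cells)
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if low.startswith("@attribute"):
                m = _ARFF_ATTR.match(line)
                if not m:
                    raise ParseError(f"{path}:{lineno}: malformed @attribute line")
                name = m.group(2) or m.group(3) or m.group(4)
                spec = m.group(5).strip()
                if spec.startswith("{"):
                    if not spec.endswith("}"):
                        raise ParseError(f"{path}:{lineno}: unterminated nominal set")
                    vals = [v.strip().strip("'\"") for v in spec[1:-1].split(",")]
                    attributes.append((name, vals))
                elif spec.lower() in ("numeric", "real", "integer"):
                    attributes.append((name, None))
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unsupported attribute type {spec!r} "
                        "(only numeric and nominal are supported)"
                    )
                continue
            raise ParseError(f"{path}:{lineno}: unexpected line outside @data: {line!r}")
    if not attributes:
        raise ParseError(f"{path}: no @attribute declarations found")
    if not in_data:
        raise ParseError(f"{path}: missing @data section")
    for i, r in enumerate(rows):
        if len(r) != len(attributes):
            raise ParseError(
                f"{path}: data row {i + 1} has {len(r)} fields, expected {len(attributes)}"
            )
    return attributes, rows


def read_arff(
    path: str | Path,
    class_column: str,
    schema: Sequence[AttributeSchema] | None = None,
    class_order: Sequence[str] | None = None,
    drop_missing: bool = False,
) -> FundamentalSet:
    """Read an ARFF file (numeric and nominal attributes only).

    Nominal attribute values that are not themselves numbers are encoded by
    their declaration-order index; the nominal set of the class attribute
    fixes the class order unless ``class_order`` overrides it.
    """
    path = Path(path)
    attributes, rows = _parse_arff(path)
    names = [a for a, _ in attributes]
    if class_column not in names:
        raise SchemaError(f"class column {class_column!r} not among ARFF attributes {names}")

    columns: dict[str, list] = {nm: [] for nm in names}
    inferred: list[AttributeSchema] = []
    for (name, nominal) in attributes:
        if name == class_column:
            continue
        if nominal is None:
            inferred.append(AttributeSchema(name=name))
        else:
            try:
                codes = tuple(float(v) for v in nominal)
            except ValueError:
                codes = tuple(float(i) for i in range(len(nominal)))
            kind = "binary" if len(codes) == 2 and set(codes) == {0.0, 1.0} else "categorical-ordinal"
            inferred.append(AttributeSchema(name=name, kind=kind, allowed_values=codes))

    nominal_maps = {
        name: {v: i for i, v in enumerate(nom)}
        for name, nom in attributes
        if nom is not None and name != class_column
    }
    for r in rows:
        for (name, nominal), cell in zip(attributes, r):
            if name == class_column:
                columns[name].append(cell)
            elif cell == "?":
                columns[name].append(np.nan)
            elif nominal is not None and name in nominal_maps:
                try:
                    columns[name].append(float(cell))
                except ValueError:
                    if cell not in nominal_maps[name]:
                        raise ValidationError(
                            f"attribute {name!r}: value {cell!r} not in nominal set"
                        )
                    columns[name].append(float(nominal_maps[name][cell]))
            else:
                try:
                    columns[name].append(float(cell))
                except ValueError as exc:
                    raise ValidationError(f"attribute {name!r}: non-numeric value {cell!r}") from exc

    df = pd.DataFrame(columns)[names]
    class_nominal = dict(attributes).get(class_column)
    if class_order is None and class_nominal is not None:
        class_order = class_nominal
    return _frame_to_fundamental_set(
        df, class_column, schema if schema is not None else inferred, class_order, drop_missing
    )


def read_table(
    path: str | Path,
    format: str,
    class_column: str,
    schema: Sequence[AttributeSchema] | None = None,
    class_order: Sequence[str] | None = None,
    drop_missing: bool = False,
) -> FundamentalSet:
    """Read a labelled table into a FundamentalSet.

    ``format`` is ``"csv"`` or ``"arff"``; class labels are mapped to indices
    in first-appearance order unless ``class_order`` (or the ARFF class
    nominal set) dictates otherwise.  p equals the number of data rows and
    attribute order is preserved.
    """
    if format == "csv":
        return read_csv(path, class_column, schema, class_order, drop_missing)
    if format == "arff":
        return read_arff(path, class_column, schema, class_order, drop_missing)
    raise SchemaError(f"unknown format {format!r}; expected 'csv' or 'arff'")


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_csv(fs: FundamentalSet, path: str | Path, class_column: str = "class") -> None:
    df = pd.DataFrame(fs.X, columns=[a.name for a in fs.schema])
    for j, a in enumerate(fs.schema):
        if np.all(fs.X[:, j] == np.round(fs.X[:, j])):
            df[a.name] = df[a.name].astype(int)
    df[class_column] = [fs.class_names[i] for i in fs.y]
    df.to_csv(path, index=False)


def write_arff(
    fs: FundamentalSet,
    path: str | Path,
    class_column: str = "class",
    relation: str = "deltamem",
) -> None:
    lines = [f"@relation {relation}", ""]
    for a in fs.schema:
        if a.allowed_values is not None:
            vals = ",".join(_fmt_value(v) for v in a.allowed_values)
            lines.append(f"@attribute {a.name} {{{vals}}}")
        else:
            lines.append(f"@attribute {a.name} numeric")
    lines.append(f"@attribute {class_column} {{{','.join(fs.class_names)}}}")
    lines.append("")
    lines.append("@data")
    for mu in range(fs.p):
        cells = [_fmt_value(v) for v in fs.X[mu]] + [fs.class_names[fs.y[mu]]]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_table(
    fs: FundamentalSet, path: str | Path, format: str, class_column: str = "class"
) -> None:
    """Write a FundamentalSet to CSV or ARFF (round-trips with read_table)."""
    if format == "csv":
        write_csv(fs, path, class_column)
    elif format == "arff":
        write_arff(fs, path, class_column)
    else:
        raise SchemaError(f"unknown format {format!r}; expected 'csv' or 'arff'")
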