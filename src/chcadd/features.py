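"""Feature engineering for the deleteriousness classifier.

Raw per-variant annotation tables become the design matrix through four
steps: imputation of missing numerics, one-hot expansion of categoricals,
availability indicators for conditionally defined scores (e.g. amino-acid
substitution scores that exist only for missense consequences), and
categorical-by-numeric interaction columns.  Each column is finally scaled
by its sample standard deviation (no centering; the intercept absorbs
offsets), and the scale factors are stored so new variants are scored on
the training scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"
CONDITIONAL_NUMERIC = "conditional-numeric"


@dataclass(frozen=True)
class AnnotationSpec:
    """One raw annotation column and how to encode it.

    kind:
      - numeric: passed through; missing values imputed with ``impute_value``
      - categorical: one-hot expanded over ``categories``; a missing value
        becomes an all-zero block
      - conditional-numeric: numeric defined only under some condition
        (operationally: wherever it is non-missing); gains a companion
        ``<name>_available`` indicator and is imputed where unavailable
    """

    name: str
    kind: str
    impute_value: float = 0.0
    categories: tuple[str, ...] = ()
    allow_other: bool = False  # unseen category -> "other" column vs error

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, CATEGORICAL, CONDITIONAL_NUMERIC):
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.kind == CATEGORICAL and not self.categories:
            raise ValueError(f"categorical annotation {self.name!r} needs categories")


@dataclass
class AnnotationSchema:
    """Ordered collection of annotation specs; every matrix column traces to
    exactly one spec or one declared interaction."""

    specs: list[AnnotationSpec]

    def __iter__(self):
        return iter(self.specs)

    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> AnnotationSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def onehot_columns(self, name: str) -> list[str]:
        s = self.spec(name)
        if s.kind != CATEGORICAL:
            raise ValueError(f"{name!r} is not categorical")
        cols = [f"{name}={c}" for c in s.categories]
        if s.allow_other:
            cols.append(f"{name}=other")
        return cols


@dataclass
class FeatureMatrix:
    """Encoded design matrix with variant identities and 0/1 class labels
    (0 = derived/proxy-benign, 1 = simulated/proxy-deleterious)."""

    X: pd.DataFrame
    y: np.ndarray | None = None
    schema: AnnotationSchema | None = None
    scale_factors: pd.Series | None = None  # set after scale()
    constant_columns: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, rows) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X.iloc[rows].reset_index(drop=True),
            y=None if self.y is None else self.y[rows],
            schema=self.schema,
            scale_factors=self.scale_factors,
            constant_columns=list(self.constant_columns),
        )


def encode(raw_table: pd.DataFrame, schema: AnnotationSchema,
           labels: Sequence[int] | None = None) -> FeatureMatrix:
    """Impute, one-hot encode and add availability indicators.

    Raw table columns must be a subset of the schema; schema annotations
    absent from the table are treated as entirely missing.
    """
    unknown = set(raw_table.columns) - set(schema.names()) - {
        "chrom", "pos", "ref", "alt", "label"}
    if unknown:
        raise ValueError(f"columns not in schema: {sorted(unknown)}")
    out: dict[str, np.ndarray] = {}
    n = len(raw_table)
    for spec in schema:
        col = raw_table[spec.name] if spec.name in raw_table else \
            pd.Series([np.nan] * n)
        if spec.kind == NUMERIC:
            out[spec.name] = pd.to_numeric(col).fillna(spec.impute_value).to_numpy(float)
        elif spec.kind == CONDITIONAL_NUMERIC:
            vals = pd.to_numeric(col)
            out[f"{spec.name}_available"] = (~vals.isna()).to_numpy(float)
            out[spec.name] = vals.fillna(spec.impute_value).to_numpy(float)
        else:  # categorical
            known = set(spec.categories)
            observed = col.notna()
            bad = sorted(set(col[observed].astype(str)) - known)
            if bad and not spec.allow_other:
                raise ValueError(
                    f"categories {bad} of {spec.name!r} absent from schema")
            for cat in spec.categories:
                out[f"{spec.name}={cat}"] = (
                    (col.astype("object") == cat) & observed).to_numpy(float)
            if spec.allow_other:
                is_other = observed & ~col.astype(str).isin(spec.categories)
                out[f"{spec.name}=other"] = is_other.to_numpy(float)
    X = pd.DataFrame(out)
    y = None if labels is None else np.asarray(labels, dtype=int)
    if y is not None and len(y) != n:
        raise ValueError("label length mismatch")
    return FeatureMatrix(X=X, y=y, schema=schema)


def combine(matrix: FeatureMatrix,
            pairs: Iterable[tuple[str, str]]) -> FeatureMatrix:
    """Append categorical-by-numeric interaction columns.

    Each pair names a categorical annotation (its whole one-hot block) and a
    numeric column; for a p-level block, p product columns named
    ``"<block>=<level> x <numeric>"`` are appended.
    """
    if matrix.schema is None:
        raise ValueError("combine requires a schema-bearing matrix")
    X = matrix.X.copy()
    for block_name, numeric_name in pairs:
        block_spec = matrix.schema.spec(block_name)
        if block_spec.kind != CATEGORICAL:
            raise ValueError(
                f"left member of a pair must be categorical, got {block_name!r}")
        num_spec = matrix.schema.spec(numeric_name)
        if num_spec.kind == CATEGORICAL:
            raise ValueError("pairing two categorical blocks is unsupported")
        if numeric_name not in X:
            raise KeyError(numeric_name)
        for col in matrix.schema.onehot_columns(block_name):
            X[f"{col} x {numeric_name}"] = X[col] * X[numeric_name]
    return FeatureMatrix(X=X, y=matrix.y, schema=matrix.schema,
                         constant_columns=list(matrix.constant_columns))


def scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each column by its sample (n-1) standard deviation.

    Constant columns are left unscaled and flagged; factors are recorded for
    reuse at scoring time.
    """
    if matrix.X.empty:
        raise ValueError("empty matrix")
    sds = matrix.X.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    factors = sds.copy()
    factors[constant] = 1.0
    return FeatureMatrix(
        X=matrix.X / factors,
        y=matrix.y, schema=matrix.schema,
        scale_factors=factors, constant_columns=constant,
    )


def apply_scale(matrix: FeatureMatrix, factors: pd.Series) -> FeatureMatrix:
    """Apply stored training-time scale factors to a new matrix."""
    missing = set(matrix.X.columns) - set(factors.index)
    if missing:
        raise ValueError(f"no stored scale factor for columns {sorted(missing)}")
    return FeatureMatrix(
        X=matrix.X / factors[matrix.X.columns],
        y=matrix.y, schema=matrix.schema, scale_factors=factors,
        constant_columns=list(matrix.constant_columns),
    )


def demo_schema() -> AnnotationSchema:
    """Small demonstration schema: a conservation-like score, a consequence
    category, distance to the transcription start site, GC content, and an
    availability-gated substitution score."""
    return AnnotationSchema([
        AnnotationSpec("conservation", NUMERIC, impute_value=0.0),
        AnnotationSpec("consequence", CATEGORICAL,
                       categories=("intergenic", "intronic", "missense",
                                   "synonymous")),
        AnnotationSpec("tss_distance", NUMERIC, impute_value=1e6),
        AnnotationSpec("gc_content", NUMERIC, impute_value=0.5),
        AnnotationSpec("substitution_score", CONDITIONAL_NUMERIC,
                       impute_value=0.0),
    ])
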