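"""Feature schema for treatment-plan parameter tables and mixed-type encoding.

A plan is described by a flat record of raw feature slots (one column per
field-specific parameter).  Continuous features occupy one encoded column
each; categorical features expand to one-hot blocks.  The encoded design
matrix carries a per-column mask so downstream losses can split binary from
continuous dimensions.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaMismatchError",
    "ValidationError",
    "FeatureSpec",
    "FeatureSchema",
    "PlanRecord",
    "PlanTable",
    "DimMask",
    "EncodedMatrix",
    "default_schema",
    "load_plan_table",
    "one_hot_encode",
    "encode_table",
    "decode_matrix",
]

FIELD_GROUPS = ("IMRT", "tangent", "both")
VALUE_KINDS = ("continuous", "categorical")
SCALE_KINDS = ("none", "minmax", "zscore")

#: canonical field order for 4-field plans: two IMRT fields then two tangents
FIELD_ORDER = ("IMRT1", "IMRT2", "tangent1", "tangent2")

NORMAL_LABEL = "normal"
ABNORMAL_LABEL = "abnormal"


class SchemaMismatchError(ValueError):
    """A table's columns do not match the schema."""


class ValidationError(ValueError):
    """Cell values violate the schema's typing or categorical domains."""


@dataclass(frozen=True)
class FeatureSpec:
    """One raw feature, possibly replicated across several fields."""

    name: str
    field_group: str
    per_field_count: int
    value_kind: str
    unit: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.field_group not in FIELD_GROUPS:
            raise ValueError(f"unknown field_group {self.field_group!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.per_field_count < 1:
            raise ValueError("per_field_count must be >= 1")
        if self.value_kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical feature {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels in {self.name!r}")
        elif self.levels:
            raise ValueError(f"continuous feature {self.name!r} must not declare levels")

    @property
    def is_categorical(self) -> bool:
        return self.value_kind == "categorical"

    def column_names(self) -> list[str]:
        return [f"{self.name}_f{k + 1}" for k in range(self.per_field_count)]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature specs describing one plan record."""

    specs: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique within a schema")

    @property
    def raw_feature_count(self) -> int:
        return sum(s.per_field_count for s in self.specs)

    def column_names(self) -> list[str]:
        cols: list[str] = []
        for spec in self.specs:
            cols.extend(spec.column_names())
        return cols

    def spec_for_column(self, column: str) -> FeatureSpec:
        for spec in self.specs:
            if column in spec.column_names():
                return spec
        raise KeyError(column)

    @property
    def encoded_dim(self) -> int:
        return sum(
            s.per_field_count * (len(s.levels) if s.is_categorical else 1)
            for s in self.specs
        )

    def to_yaml(self) -> str:
        doc = [
            {
                "name": s.name,
                "field_group": s.field_group,
                "per_field_count": s.per_field_count,
                "value_kind": s.value_kind,
                "unit": s.unit,
                "levels": list(s.levels),
            }
            for s in self.specs
        ]
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FeatureSchema":
        doc = yaml.safe_load(text)
        specs = tuple(
            FeatureSpec(
                name=d["name"],
                field_group=d["field_group"],
                per_field_count=int(d["per_field_count"]),
                value_kind=d["value_kind"],
                unit=d.get("unit", ""),
                levels=tuple(str(x) for x in d.get("levels", ())),
            )
            for d in doc
        )
        return cls(specs)


# Default protocol-derived level sets.  Normal plans use four beams at
# right-angle spacing drawn from {0, 90, 180, 270}; the off-pattern angles
# 45/315 exist in the domain so spacing violations remain schema-valid.
GANTRY_LEVELS = ("0", "45", "90", "180", "270", "315")
#: segment counts; the protocol allows 5-7, levels 8/9 are violations
SEGMENT_LEVELS = ("5", "6", "7", "8", "9")


def default_schema() -> FeatureSchema:
    """The 8-spec, 30-raw-feature schema of a 4-field breast plan.

    Two IMRT fields contribute segment counts; SSD, the four collimator
    jaws, gantry angle and monitor units are recorded for all four fields.
    Gantry angle and segment count are categorical (integer protocol
    levels); everything else is continuous.
    """
    return FeatureSchema(
        (
            FeatureSpec("segment", "IMRT", 2, "categorical", "count", SEGMENT_LEVELS),
            FeatureSpec("ssd", "both", 4, "continuous", "cm"),
            FeatureSpec("collx1", "both", 4, "continuous", "cm"),
            FeatureSpec("collx2", "both", 4, "continuous", "cm"),
            FeatureSpec("colly1", "both", 4, "continuous", "cm"),
            FeatureSpec("colly2", "both", 4, "continuous", "cm"),
            FeatureSpec("gantry", "both", 4, "categorical", "degree", GANTRY_LEVELS),
            FeatureSpec("meterset", "both", 4, "continuous", "MU"),
        )
    )


@dataclass(frozen=True)
class PlanRecord:
    """One plan: values aligned with ``schema.column_names()``.

    Continuous slots hold floats, categorical slots hold level labels.
    """

    values: tuple

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PlanTable:
    """Raw plan records plus optional ground-truth labels and identifiers."""

    schema: FeatureSchema
    records: list[PlanRecord]
    labels: list[str] | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValidationError("labels length must match records length")
        if self.ids is not None and len(self.ids) != len(self.records):
            raise ValidationError("ids length must match records length")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def label_array(self) -> np.ndarray | None:
        if self.labels is None:
            return None
        return np.array([1 if l == ABNORMAL_LABEL else 0 for l in self.labels])

    def to_dataframe(self, include_meta: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            [rec.values for rec in self.records], columns=self.schema.column_names()
        )
        if include_meta and self.ids is not None:
            df.insert(0, "plan_id", self.ids)
        if include_meta and self.labels is not None:
            df["is_abnormal"] = [1 if l == ABNORMAL_LABEL else 0 for l in self.labels]
        return df

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = self.to_dataframe()
        if isinstance(path, (str, Path)):
            df.to_csv(path, index=False, lineterminator="\n")
        else:
            df.to_csv(path, index=False, lineterminator="\n")


def validate_record(schema: FeatureSchema, values: Sequence) -> PlanRecord:
    """Type-check one row of raw values against the schema."""
    cols = schema.column_names()
    if len(values) != len(cols):
        raise ValidationError(
            f"record has {len(values)} values, schema expects {len(cols)}"
        )
    out = []
    for col, value in zip(cols, values):
        spec = schema.spec_for_column(col)
        if spec.is_categorical:
            label = str(value)
            if label not in spec.levels:
                raise ValidationError(
                    f"value {label!r} for {col!r} not in levels {list(spec.levels)}"
                )
            out.append(label)
        else:
            try:
                out.append(float(value))
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"non-numeric value {value!r} in {col!r}") from exc
    return PlanRecord(tuple(out))


def load_plan_table(
    source, format: str = "csv", schema: FeatureSchema | None = None
) -> PlanTable:
    """Read a plan table from CSV or JSON and validate it against the schema.

    An optional ``plan_id`` column provides identifiers and an optional
    ``is_abnormal`` column (0/1) provides ground-truth labels.
    """
    if schema is None:
        schema = default_schema()
    if format == "csv":
        df = pd.read_csv(source, dtype=object)
    elif format == "json":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                rows = json.load(fh)
        else:
            rows = json.load(source)
        df = pd.DataFrame(rows, dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    cols = schema.column_names()
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaMismatchError(f"missing required columns: {missing}")

    errors: list[str] = []
    records: list[PlanRecord] = []
    for i, row in enumerate(df[cols].itertuples(index=False)):
        try:
            records.append(validate_record(schema, row))
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("invalid cells:\n" + "\n".join(errors))

    labels = None
    if "is_abnormal" in df.columns:
        raw = df["is_abnormal"].astype(int).tolist()
        bad = sorted(set(raw) - {0, 1})
        if bad:
            raise ValidationError(f"is_abnormal must be 0/1, got {bad}")
        labels = [ABNORMAL_LABEL if v else NORMAL_LABEL for v in raw]
    ids = df["plan_id"].astype(str).tolist() if "plan_id" in df.columns else None
    return PlanTable(schema=schema, records=records, labels=labels, ids=ids)


def one_hot_encode(value: str, levels: Sequence[str]) -> np.ndarray:
    """One-hot vector over ``levels`` with a single 1 at the value's index."""
    value = str(value)
    if value not in levels:
        raise ValidationError(f"value {value!r} not in levels {list(levels)}")
    vec = np.zeros(len(levels))
    vec[list(levels).index(value)] = 1.0
    return vec


@dataclass(frozen=True)
class DimColumn:
    """Provenance of a single encoded column."""

    name: str
    source: str  # raw column name, e.g. "gantry_f2"
    feature: str  # feature spec name
    kind: str  # "binary" | "continuous"
    level: str | None = None


@dataclass(frozen=True)
class DimMask:
    """Per-encoded-column flags splitting binary from continuous dimensions."""

    columns: tuple[DimColumn, ...]

    @property
    def n_dims(self) -> int:
        return len(self.columns)

    @property
    def is_binary(self) -> np.ndarray:
        return np.array([c.kind == "binary" for c in self.columns])

    @property
    def binary_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_binary)

    @property
    def continuous_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_binary)

    def block_slices(self) -> dict[str, slice]:
        """Contiguous encoded-column slice for every raw source column."""
        out: dict[str, slice] = {}
        start = 0
        current = None
        for i, col in enumerate(self.columns):
            if col.source != current:
                if current is not None:
                    out[current] = slice(start, i)
                current, start = col.source, i
        if current is not None:
            out[current] = slice(start, len(self.columns))
        return out

    def fingerprint(self) -> str:
        payload = json.dumps(
            [[c.name, c.source, c.kind, c.level] for c in self.columns]
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class EncodedMatrix:
    """Numeric design matrix with its mask and scaling state."""

    values: np.ndarray
    mask: DimMask
    scale: str = "none"
    scaler_state: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_plans(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def fingerprint(self) -> str:
        return f"{self.mask.fingerprint()}:{self.scale}"


def _build_mask(schema: FeatureSchema) -> DimMask:
    cols: list[DimColumn] = []
    for spec in schema.specs:
        for raw in spec.column_names():
            if spec.is_categorical:
                for level in spec.levels:
                    cols.append(
                        DimColumn(f"{raw}={level}", raw, spec.name, "binary", level)
                    )
            else:
                cols.append(DimColumn(raw, raw, spec.name, "continuous"))
    return DimMask(tuple(cols))


def encode_table(
    table: PlanTable, schema: FeatureSchema | None = None, scale: str = "minmax"
) -> EncodedMatrix:
    """Encode raw records into the mixed binary/continuous design matrix.

    Categorical features expand to one-hot blocks; continuous features are
    scaled per ``scale`` with the scaler state retained for inverse
    transforms.  Constant continuous columns pass through unscaled with a
    warning.
    """
    if schema is None:
        schema = table.schema
    if scale not in SCALE_KINDS:
        raise ValueError(f"unknown scale {scale!r}")
    if len(table) == 0:
        raise ValidationError("cannot encode an empty table")

    mask = _build_mask(schema)
    raw_cols = schema.column_names()
    n = len(table)
    X = np.zeros((n, mask.n_dims))
    blocks = mask.block_slices()

    for j, raw in enumerate(raw_cols):
        spec = schema.spec_for_column(raw)
        sl = blocks[raw]
        if spec.is_categorical:
            for i, rec in enumerate(table.records):
                X[i, sl] = one_hot_encode(rec.values[j], spec.levels)
        else:
            X[:, sl.start] = [float(rec.values[j]) for rec in table.records]

    scaler_state: dict[str, tuple[float, float]] = {}
    if scale != "none":
        for idx in mask.continuous_idx:
            name = mask.columns[idx].name
            col = X[:, idx]
            if scale == "minmax":
                lo, rng = float(col.min()), float(col.max() - col.min())
                if rng == 0.0:
                    warnings.warn(
                        f"constant column {name!r} passed through unscaled", UserWarning
                    )
                    continue
                X[:, idx] = (col - lo) / rng
                scaler_state[name] = (lo, rng)
            else:  # zscore
                mu, sd = float(col.mean()), float(col.std())
                if sd == 0.0:
                    warnings.warn(
                        f"constant column {name!r} passed through unscaled", UserWarning
                    )
                    continue
                X[:, idx] = (col - mu) / sd
                scaler_state[name] = (mu, sd)

    return EncodedMatrix(values=X, mask=mask, scale=scale, scaler_state=scaler_state)


def decode_matrix(encoded: EncodedMatrix, schema: FeatureSchema) -> pd.DataFrame:
    """Invert the encoding: arg-max one-hot blocks, un-scale continuous columns."""
    blocks = encoded.mask.block_slices()
    out: dict[str, list] = {}
    for raw in schema.column_names():
        spec = schema.spec_for_column(raw)
        sl = blocks[raw]
        block = encoded.values[:, sl]
        if spec.is_categorical:
            out[raw] = [spec.levels[k] for k in block.argmax(axis=1)]
        else:
            col = block[:, 0].copy()
            name = encoded.mask.columns[sl.start].name
            if name in encoded.scaler_state:
                a, b = encoded.scaler_state[name]  # (min, range) or (mean, sd)
                col = col * b + a
            out[raw] = col.tolist()
    return pd.DataFrame(out)
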