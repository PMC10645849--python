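"""Tabular cohort schema, I/O and summaries.

A cohort is a table of patient records: a unique patient identifier, a set
of mostly binary risk factors (demographics, pregnancy conditions, medical
history, fetal characteristics), a parity stratum (parous / nulliparous),
and one binary label column per adverse outcome (low birth weight, preterm
birth, very preterm birth). Every downstream stage — knowledge-graph
construction, embedding, autoencoder scoring — consumes the
:class:`CohortTable` defined here.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Adverse-outcome label columns a cohort may carry.
OUTCOMES = ("LBW", "PTB", "vPTB")

#: Allowed parity strata. Analyses are always stratified; strata are never pooled.
PARITY_LEVELS = ("parous", "nulliparous")

FEATURE_KINDS = ("binary", "categorical", "continuous")


class CohortError(ValueError):
    """Raised when a cohort file or table violates the schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """One risk factor: its name, kind, and (for categoricals) allowed levels."""

    name: str
    kind: str = "binary"
    levels: tuple = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise CohortError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise CohortError(f"categorical feature {self.name!r} needs levels")


@dataclass
class RiskFactorSchema:
    """The risk-factor set of a cohort.

    Binary features admit exactly the levels {0, 1}; categorical features
    carry an explicit level list; continuous features are discretized by
    quartile bins when they enter the knowledge graph. ``missing_code`` is
    the sentinel written in CSV cells for missing values; internally missing
    values are NaN.
    """

    features: list[FeatureSpec]
    missing_code: str = "NA"

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CohortError(f"duplicate feature names: {dupes}")
        for f in self.features:
            if f.kind == "categorical" and self.missing_code in {str(l) for l in f.levels}:
                raise CohortError(
                    f"missing code {self.missing_code!r} collides with a level of {f.name!r}"
                )

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        doc = {
            "missing_code": self.missing_code,
            "features": [
                {"name": f.name, "kind": f.kind, **({"levels": list(f.levels)} if f.levels else {})}
                for f in self.features
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RiskFactorSchema":
        doc = yaml.safe_load(Path(path).read_text())
        feats = [
            FeatureSpec(d["name"], d.get("kind", "binary"), tuple(d.get("levels", ())))
            for d in doc["features"]
        ]
        return cls(feats, missing_code=doc.get("missing_code", "NA"))


@dataclass
class CohortTable:
    """Validated patient records.

    ``features`` is an n x f float frame (NaN = missing) whose columns follow
    the schema order; ``labels`` holds one {0,1} column per outcome present.
    Row order is meaningful: embedding blocks and outlier scores align to it.
    """

    patient_id: pd.Index
    features: pd.DataFrame
    parity: pd.Series
    labels: pd.DataFrame
    schema: RiskFactorSchema

    def __post_init__(self):
        if self.patient_id.has_duplicates:
            dupes = sorted(self.patient_id[self.patient_id.duplicated()].unique())
            raise CohortError(f"duplicate patient_id: {dupes}")
        bad_parity = set(self.parity.unique()) - set(PARITY_LEVELS)
        if bad_parity:
            raise CohortError(f"invalid parity values: {sorted(bad_parity)}")
        for col in self.labels.columns:
            vals = set(self.labels[col].unique())
            if not vals <= {0, 1}:
                raise CohortError(f"label {col!r} has non-binary values {sorted(vals - {0, 1})}")

    @property
    def n(self) -> int:
        return len(self.patient_id)

    @property
    def f(self) -> int:
        return self.features.shape[1]

    @property
    def outcome_names(self) -> list[str]:
        return list(self.labels.columns)

    def to_frame(self) -> pd.DataFrame:
        """Flat frame in the on-disk column layout (missing as sentinel)."""
        out = pd.DataFrame({"patient_id": self.patient_id})
        out["parity"] = self.parity.to_numpy()
        for name in self.features.columns:
            col = self.features[name]
            spec = self.schema[name]
            mc = self.schema.missing_code
            if spec.kind == "continuous":
                cells = col.map(lambda v: mc if pd.isna(v) else repr(float(v)))
            elif spec.kind == "binary":
                cells = col.map(lambda v: mc if pd.isna(v) else str(int(v)))
            else:  # categorical: stored as level index, written as the level itself
                cells = col.map(lambda v: mc if pd.isna(v) else str(spec.levels[int(v)]))
            out[name] = cells.to_numpy()
        for name in self.labels.columns:
            out[name] = self.labels[name].to_numpy()
        return out

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-outcome class balance of one cohort stratum."""

    total: int
    normal: int
    abnormal: int
    abnormality_pct: float

    def __post_init__(self):
        assert self.normal + self.abnormal == self.total


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention behind printed percentages)."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _parse_feature_column(raw: pd.Series, spec: FeatureSpec, missing_code: str):
    """Parse one raw string column; returns (float series, list of row errors)."""
    errors = []
    vals = np.full(len(raw), np.nan)
    for i, cell in enumerate(raw.astype(str).str.strip()):
        if cell == missing_code or cell == "" or cell.lower() == "nan":
            continue
        if spec.kind == "binary":
            if cell not in ("0", "1"):
                errors.append((i, f"non-binary value {cell!r} in binary column {spec.name!r}"))
                continue
            vals[i] = float(cell)
        elif spec.kind == "categorical":
            levels = [str(l) for l in spec.levels]
            if cell not in levels:
                errors.append((i, f"value {cell!r} not a level of categorical {spec.name!r}"))
                continue
            vals[i] = float(levels.index(cell))
        else:
            try:
                vals[i] = float(cell)
            except ValueError:
                errors.append((i, f"non-numeric value {cell!r} in continuous column {spec.name!r}"))
    return pd.Series(vals, name=spec.name), errors


def read_cohort_table(path, schema: RiskFactorSchema) -> CohortTable:
    """Read and validate a cohort CSV against ``schema``.

    The file must have a header row with ``patient_id``, ``parity``, one
    column per schema feature, and at least one outcome label column. Rows
    violating the schema are reported with row numbers (1-based, excluding
    the header) and column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    required = {"patient_id", "parity", *schema.names}
    missing = required - set(raw.columns)
    if missing:
        raise CohortError(f"missing columns: {sorted(missing)}")
    label_cols = [c for c in OUTCOMES if c in raw.columns]
    unknown = set(raw.columns) - required - set(OUTCOMES)
    if unknown:
        raise CohortError(f"unknown columns: {sorted(unknown)}")

    errors: list[str] = []
    ids = pd.Index(raw["patient_id"].str.strip(), name="patient_id")
    if ids.has_duplicates:
        dupes = sorted(ids[ids.duplicated()].unique())
        raise CohortError(f"duplicate patient_id: {dupes}")

    feat_cols = {}
    for spec in schema.features:
        col, errs = _parse_feature_column(raw[spec.name], spec, schema.missing_code)
        feat_cols[spec.name] = col
        errors.extend(f"row {i + 1}: {msg}" for i, msg in errs)

    parity = raw["parity"].str.strip()
    for i, v in enumerate(parity):
        if v not in PARITY_LEVELS:
            errors.append(f"row {i + 1}: invalid parity {v!r}")

    labels = {}
    for c in label_cols:
        lab = np.zeros(len(raw), dtype=int)
        for i, cell in enumerate(raw[c].astype(str).str.strip()):
            if cell not in ("0", "1"):
                errors.append(f"row {i + 1}: label {c!r} must be 0/1, got {cell!r}")
            else:
                lab[i] = int(cell)
        labels[c] = lab

    if errors:
        raise CohortError("cohort file rejected:\n" + "\n".join(errors))
    return CohortTable(
        patient_id=ids,
        features=pd.DataFrame(feat_cols, columns=schema.names),
        parity=pd.Series(parity.to_numpy(), name="parity"),
        labels=pd.DataFrame(labels, dtype=int),
        schema=schema,
    )


def summarize_cohort(table: CohortTable, outcome: str) -> DatasetSummary:
    """Class balance of ``table`` for one outcome.

    ``abnormality_pct`` is 100 * abnormal / total rounded half-away-from-zero
    to one decimal — the convention of printed cohort tables.
    """
    if outcome not in table.labels.columns:
        raise CohortError(
            f"unknown outcome {outcome!r}; available: {list(table.labels.columns)}"
        )
    lab = table.labels[outcome].to_numpy()
    abnormal = int(lab.sum())
    total = int(len(lab))
    pct = _round_half_away(100.0 * abnormal / total) if total else 0.0
    return DatasetSummary(total=total, normal=total - abnormal, abnormal=abnormal,
                          abnormality_pct=pct)
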