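"""Design-matrix assembly: normalization, one-hot encoding, merging.

Continuous clinical variables and radiomics features are min-max scaled
to [0, 1]; categorical clinical variables are one-hot encoded against a
fixed schema (category lists are part of the schema, never inferred from
the data, so encodings are identical across folds).  Normalization
statistics are fitted on training rows only and applied with clipping to
test rows, to keep test information out of the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalSchema",
    "DEFAULT_SCHEMA",
    "FEATURE_SETS",
    "DesignMatrix",
    "MinMaxNormalizer",
    "SchemaError",
    "AssemblyError",
    "minmax_normalize",
    "one_hot",
    "assemble",
]

FEATURE_SETS = ("damico", "tnm", "clinical", "clinical_radiomics")


class SchemaError(ValueError):
    """A value falls outside the declared schema."""


class AssemblyError(ValueError):
    """Sources cannot be merged into a design matrix."""


@dataclass(frozen=True)
class ClinicalSchema:
    """Which clinical columns are continuous, categorical or binary."""

    continuous: tuple = ("age", "initial_psa", "gleason_primary", "gleason_secondary")
    categorical: dict = field(
        default_factory=lambda: {
            "grade_group": ("I", "II", "III", "IV", "V"),
            "t_stage": ("T1", "T2", "T3", "T4"),
            "n_stage": ("N0", "N1"),
            "risk_class": ("low", "intermediate", "high"),
        }
    )
    binary: tuple = (
        "rp",
        "rt",
        "adt",
        "hifu",
        "cryotherapy",
        "active_surveillance",
        "diabetes",
        "chronic_pulmonary_disease",
        "cerebrovascular_disease",
        "peptic_ulcer_disease",
    )
    version: str = "1.0"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClinicalSchema":
        raw = json.loads(Path(path).read_text())
        raw["continuous"] = tuple(raw["continuous"])
        raw["binary"] = tuple(raw["binary"])
        raw["categorical"] = {k: tuple(v) for k, v in raw["categorical"].items()}
        return cls(**raw)


DEFAULT_SCHEMA = ClinicalSchema()


def minmax_normalize(
    column: np.ndarray, fit_on: np.ndarray | None = None
) -> np.ndarray:
    """Scale values to [0, 1] by the min/max of ``fit_on`` (default: itself).

    A constant fitting range maps everything to 0; values outside the
    fitted range (test rows beyond the training extremes) are clipped.
    """
    column = np.asarray(column, dtype=np.float64)
    if column.size == 0:
        raise ValueError("empty column")
    ref = column if fit_on is None else np.asarray(fit_on, dtype=np.float64)
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        return np.zeros_like(column)
    return np.clip((column - lo) / (hi - lo), 0.0, 1.0)


def one_hot(
    column: pd.Series | np.ndarray, categories: tuple, name: str | None = None
) -> pd.DataFrame:
    """One binary column per schema category (full encoding, none dropped)."""
    s = pd.Series(column) if not isinstance(column, pd.Series) else column
    name = name or s.name or "cat"
    bad = s[~s.isin(categories)]
    if len(bad):
        row = bad.index[0]
        raise SchemaError(
            f"column {name!r}: value {bad.iloc[0]!r} at row {row!r} is not in "
            f"schema categories {tuple(categories)}"
        )
    out = pd.DataFrame(
        {f"{name}={c}": (s == c).astype(np.float64) for c in categories},
        index=s.index,
    )
    return out


@dataclass
class DesignMatrix:
    """Model-ready feature table with labels.

    ``normalize_columns`` names the columns whose min-max transform must
    be refit on training rows within each CV fold (continuous clinical
    plus all radiomics columns); one-hot and binary columns pass through.
    """

    X: pd.DataFrame
    y: np.ndarray
    normalize_columns: tuple
    feature_set: str

    @property
    def patient_ids(self):
        return self.X.index

    def __post_init__(self):
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise AssemblyError(f"missing values in columns {bad}")


class MinMaxNormalizer:
    """Train-only min-max transform over a fixed set of columns."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        self.bounds_: dict[str, tuple[float, float]] | None = None

    def fit(self, X: pd.DataFrame) -> "MinMaxNormalizer":
        self.bounds_ = {
            c: (float(X[c].min()), float(X[c].max())) for c in self.columns
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.bounds_ is None:
            raise RuntimeError("normalizer not fitted")
        out = X.copy()
        for c in self.columns:
            lo, hi = self.bounds_[c]
            if hi == lo:
                out[c] = 0.0
            else:
                out[c] = np.clip((out[c] - lo) / (hi - lo), 0.0, 1.0)
        return out

    def to_dict(self) -> dict:
        return {"columns": list(self.columns), "bounds": self.bounds_}


def _validate_clinical(clinical: pd.DataFrame, schema: ClinicalSchema) -> None:
    needed = (
        set(schema.continuous) | set(schema.categorical) | set(schema.binary) | {"label"}
    )
    missing = needed - set(clinical.columns)
    if missing:
        raise AssemblyError(f"clinical table lacks columns {sorted(missing)}")
    if clinical[sorted(needed)].isna().any().any():
        bad = clinical.index[clinical[sorted(needed)].isna().any(axis=1)].tolist()
        raise AssemblyError(f"records with missing values rejected: {bad}")


def assemble(
    clinical: pd.DataFrame,
    radiomics: pd.DataFrame | None,
    schema: ClinicalSchema = DEFAULT_SCHEMA,
    feature_set: str = "clinical_radiomics",
) -> DesignMatrix:
    """Merge clinical and radiomics sources into one design matrix.

    ``feature_set`` selects the variant: ``"damico"`` (risk class only),
    ``"tnm"`` (T and N stage only), ``"clinical"`` (all schema columns) or
    ``"clinical_radiomics"`` (clinical plus the radiomics table).  Rows
    are canonically sorted by patient id; continuous columns are returned
    raw, with their names listed in ``normalize_columns`` for per-fold
    scaling.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    _validate_clinical(clinical, schema)
    clinical = clinical.sort_index()
    y = clinical["label"].to_numpy(dtype=int)

    blocks: list[pd.DataFrame] = []
    norm_cols: list[str] = []

    if feature_set == "damico":
        cat_cols = {"risk_class": schema.categorical["risk_class"]}
        cont_cols: tuple = ()
        bin_cols: tuple = ()
    elif feature_set == "tnm":
        cat_cols = {
            "t_stage": schema.categorical["t_stage"],
            "n_stage": schema.categorical["n_stage"],
        }
        cont_cols = ()
        bin_cols = ()
    else:
        cat_cols = schema.categorical
        cont_cols = schema.continuous
        bin_cols = schema.binary

    if cont_cols:
        cont = clinical[list(cont_cols)].astype(np.float64)
        blocks.append(cont)
        norm_cols.extend(cont_cols)
    for name, cats in cat_cols.items():
        blocks.append(one_hot(clinical[name], cats, name))
    if bin_cols:
        blocks.append(clinical[list(bin_cols)].astype(np.float64))

    if feature_set == "clinical_radiomics":
        if radiomics is None or radiomics.empty:
            raise AssemblyError("feature_set 'clinical_radiomics' needs radiomics data")
        radiomics = radiomics.sort_index()
        missing = clinical.index.difference(radiomics.index).tolist()
        if missing:
            raise AssemblyError(f"patients missing radiomics features: {missing}")
        rad = radiomics.loc[clinical.index].astype(np.float64)
        blocks.append(rad)
        norm_cols.extend(rad.columns)

    X = pd.concat(blocks, axis=1)
    if X.columns.duplicated().any():
        raise AssemblyError("duplicate column names after assembly")
    return DesignMatrix(
        X=X, y=y, normalize_columns=tuple(norm_cols), feature_set=feature_set
    )
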