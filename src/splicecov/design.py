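"""Encoding of sample metadata (condition + covariates) into design matrices.

Numerical covariates are centered and scaled (z-scored with the population
standard deviation, divisor N); categorical covariates are integer-coded
0..K-1 in sorted level order. The condition variable is expanded into K-1
indicator columns against the first (sorted) level as reference, so each
non-reference condition carries its own coefficient in the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITION = "condition"


@dataclass
class SampleSheet:
    """Per-sample metadata: unique ids, a condition label, covariate values."""

    table: pd.DataFrame  # columns: sample_id, condition, covariates...

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def conditions(self) -> pd.Series:
        return self.table[CONDITION]

    @property
    def condition_levels(self) -> list:
        return sorted(self.table[CONDITION].unique())


def read_sample_sheet(path: str) -> SampleSheet:
    """TSV with header: sample_id, condition, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


@dataclass
class DesignMatrix:
    """Encoded N x P design with provenance for exact re-encoding.

    ``condition_cols`` indexes the condition indicator columns; the null
    design (no condition effect) is obtained by dropping them.
    """

    matrix: np.ndarray
    column_names: list
    condition_cols: list
    sample_ids: list
    condition_labels: list  # raw per-sample condition label
    condition_levels: list  # sorted unique levels; levels[0] is the reference
    scaling_info: dict = field(default_factory=dict)  # numeric col -> (mean, sd)
    encoding_info: dict = field(default_factory=dict)  # categorical col -> {level: code}

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_conditions(self) -> int:
        return len(self.condition_levels)

    def condition_index(self) -> np.ndarray:
        """Per-sample integer condition code in sorted level order."""
        lut = {lv: k for k, lv in enumerate(self.condition_levels)}
        return np.array([lut[c] for c in self.condition_labels], dtype=np.int64)

    def samples_in(self, level) -> np.ndarray:
        return np.array([c == level for c in self.condition_labels], dtype=bool)


def _is_numeric(values: pd.Series) -> bool:
    if pd.api.types.is_numeric_dtype(values):
        return True
    try:
        pd.to_numeric(values)
        return True
    except (ValueError, TypeError):
        return False


def encode(
    sheet: SampleSheet,
    covariate_names: list | None = None,
    categorical: tuple = (),
) -> DesignMatrix:
    """Build the design matrix from a sample sheet.

    Parameters
    ----------
    covariate_names : covariate columns to include (default: all columns
        other than sample_id and condition).
    categorical : names forced to categorical coding even if all-numeric.
    """
    df = sheet.table
    if covariate_names is None:
        covariate_names = [c for c in df.columns if c not in ("sample_id", CONDITION)]
    for name in covariate_names:
        if name not in df.columns:
            raise ValueError(f"covariate {name!r} not in sample sheet")
        nulls = df[name].isna()
        if nulls.any():
            sid = df.loc[nulls, "sample_id"].iloc[0]
            raise ValueError(f"missing value for covariate {name!r} in sample {sid!r}")
    levels = sorted(df[CONDITION].unique())
    if len(levels) < 2:
        raise ValueError("condition must have at least 2 levels")

    cols, names = [], []
    condition_cols = []
    # condition: K-1 indicators vs the first sorted level
    for lv in levels[1:]:
        condition_cols.append(len(cols))
        names.append(f"{CONDITION}[{lv}]")
        cols.append((df[CONDITION] == lv).to_numpy(dtype=float))

    scaling_info: dict = {}
    encoding_info: dict = {}
    for name in covariate_names:
        vals = df[name]
        if _is_numeric(vals) and name not in categorical:
            x = pd.to_numeric(vals).to_numpy(dtype=float)
            mean = float(x.mean())
            sd = float(x.std(ddof=0))  # population sd
            if sd == 0.0:
                warnings.warn(f"covariate {name!r} is constant; encoded as zeros")
                col = np.zeros_like(x)
                scaling_info[name] = (mean, 0.0)
            else:
                col = (x - mean) / sd
                scaling_info[name] = (mean, sd)
            cols.append(col)
            names.append(name)
        else:
            cov_levels = sorted(map(str, vals.unique()))
            lut = {lv: float(k) for k, lv in enumerate(cov_levels)}
            encoding_info[name] = {lv: int(code) for lv, code in lut.items()}
            cols.append(np.array([lut[str(v)] for v in vals], dtype=float))
            names.append(name)

    matrix = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return DesignMatrix(
        matrix=matrix,
        column_names=names,
        condition_cols=condition_cols,
        sample_ids=list(df["sample_id"]),
        condition_labels=list(df[CONDITION]),
        condition_levels=levels,
        scaling_info=scaling_info,
        encoding_info=encoding_info,
    )


def null_design(design: DesignMatrix) -> DesignMatrix:
    """Drop the condition column(s); covariate columns are untouched."""
    keep = [j for j in range(design.n_cols) if j not in set(design.condition_cols)]
    return replace(
        design,
        matrix=design.matrix[:, keep],
        column_names=[design.column_names[j] for j in keep],
        condition_cols=[],
    )


def drop_covariates(design: DesignMatrix) -> DesignMatrix:
    """Keep only the condition column(s) (a covariate-blind design)."""
    keep = list(design.condition_cols)
    return replace(
        design,
        matrix=design.matrix[:, keep],
        column_names=[design.column_names[j] for j in keep],
        condition_cols=list(range(len(keep))),
        scaling_info={},
        encoding_info={},
    )
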