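"""CSV/TSV readers and writers for the pipeline's tables.

Dialect is chosen by file extension (``.tsv`` -> tab, otherwise comma).
Numeric values round-trip at full double precision (pandas writes
shortest-round-trip representations); missing entries are empty fields.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .screening import FeatureMatrix
from .subtyping import RiskModel, SingleCellMatrix

__all__ = [
    "read_single_cell_matrix",
    "write_single_cell_matrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_patient_table",
    "write_patient_table",
    "read_risk_model",
    "write_risk_model",
]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() == ".tsv" else ","


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicated {what} {dup!r}")


def write_single_cell_matrix(
    matrix: SingleCellMatrix, values_path, annotations_path
) -> None:
    matrix.concentrations.to_csv(values_path, sep=_sep(values_path))
    matrix.cells.to_csv(annotations_path, sep=_sep(annotations_path))


def read_single_cell_matrix(values_path, annotations_path) -> SingleCellMatrix:
    conc = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    _check_unique(conc.index, "cell_id")
    non_numeric = conc.columns[
        ~conc.dtypes.map(lambda d: pd.api.types.is_numeric_dtype(d))
    ]
    if len(non_numeric):
        raise ValueError(f"non-numeric concentration columns: {list(non_numeric)}")
    cells = pd.read_csv(annotations_path, sep=_sep(annotations_path), index_col=0)
    _check_unique(cells.index, "cell_id")
    return SingleCellMatrix(concentrations=conc, cells=cells)


def write_feature_matrix(matrix: FeatureMatrix, values_path, samples_path) -> None:
    matrix.intensities.to_csv(values_path, sep=_sep(values_path))
    samples = matrix.samples.copy()
    samples.insert(0, "is_feature_id", matrix.is_feature_id or "")
    samples.to_csv(samples_path, sep=_sep(samples_path))


def read_feature_matrix(values_path, samples_path) -> FeatureMatrix:
    intens = pd.read_csv(values_path, sep=_sep(values_path), index_col=0)
    _check_unique(intens.index, "feature_id")
    samples = pd.read_csv(samples_path, sep=_sep(samples_path), index_col=0)
    _check_unique(samples.index, "sample_id")
    is_id = None
    if "is_feature_id" in samples.columns:
        ids = samples.pop("is_feature_id").dropna().unique()
        ids = [i for i in ids if i != ""]
        if len(ids) > 1:
            raise ValueError(f"conflicting internal-standard ids: {ids}")
        is_id = ids[0] if ids else None
    return FeatureMatrix(intensities=intens, samples=samples, is_feature_id=is_id)


def write_patient_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep(path))


def read_patient_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=_sep(path), index_col=0)
    _check_unique(table.index, "patient_id")
    return table


def write_risk_model(model: RiskModel, path) -> None:
    Path(path).write_text(model.to_json() + "\n")


def read_risk_model(path) -> RiskModel:
    return RiskModel.from_json(Path(path).read_text())
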