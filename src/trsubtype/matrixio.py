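"""Expression-matrix and sample-design I/O.

The whole pipeline works on log2-scale expression values held in an
:class:`ExpressionMatrix` (probes x samples) together with a list of
:class:`SampleDesign` records describing each sample's experimental factors
(cell line, receptor, ligand, dose, time, cycloheximide flag, replicate).
Matrices and designs are exchanged as plain tab-delimited text.

Fold changes only ever materialise as ``2 ** (log2 difference)`` at reporting
boundaries; everything upstream stays on the log2 scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

RECEPTORS = ("parental", "TRA", "TRB")
LIGANDS = ("vehicle", "T3")


class FormatError(ValueError):
    """A file or in-memory table violates the expected schema."""


@dataclass(frozen=True)
class SampleDesign:
    """Factor levels of one experimental sample.

    Parameters
    ----------
    sample_id : unique sample identifier (matrix column name).
    cell_line : e.g. ``"HepG2"`` or ``"HeLa"``.
    receptor : ``"parental"`` (no exogenous receptor), ``"TRA"`` or ``"TRB"``.
    ligand : ``"vehicle"`` or ``"T3"``.
    dose_nM : T3 concentration; 0 for vehicle.
    time_hr : hours of treatment.
    chx : True if the sample was pretreated with cycloheximide.
    replicate : 1-based replicate index within its condition.
    """

    sample_id: str
    cell_line: str
    receptor: str
    ligand: str
    dose_nM: float
    time_hr: float
    chx: bool
    replicate: int

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise FormatError(f"unknown receptor {self.receptor!r} for sample {self.sample_id!r}")
        if self.ligand not in LIGANDS:
            raise FormatError(f"unknown ligand {self.ligand!r} for sample {self.sample_id!r}")
        if self.dose_nM < 0:
            raise FormatError(f"negative dose for sample {self.sample_id!r}")
        if self.ligand == "vehicle" and self.dose_nM != 0:
            raise FormatError(f"vehicle sample {self.sample_id!r} has nonzero dose")
        if self.time_hr < 0:
            raise FormatError(f"negative time for sample {self.sample_id!r}")
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1 for sample {self.sample_id!r}")


_DESIGN_COLUMNS = [f.name for f in dataclasses.fields(SampleDesign)]


def designs_to_frame(designs: list[SampleDesign]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(d) for d in designs], columns=_DESIGN_COLUMNS)


def frame_to_designs(frame: pd.DataFrame) -> list[SampleDesign]:
    designs = []
    for _, row in frame.iterrows():
        designs.append(
            SampleDesign(
                sample_id=str(row["sample_id"]),
                cell_line=str(row["cell_line"]),
                receptor=str(row["receptor"]),
                ligand=str(row["ligand"]),
                dose_nM=float(row["dose_nM"]),
                time_hr=float(row["time_hr"]),
                chx=_as_bool(row["chx"]),
                replicate=int(row["replicate"]),
            )
        )
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise FormatError(f"duplicate sample_id {dup!r} in design sheet")
    return designs


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean CHX flag")


class ExpressionMatrix:
    """Probes x samples matrix of finite log2 intensities.

    Wraps a pandas DataFrame whose index holds unique probe identifiers and
    whose columns hold unique sample identifiers. Construction validates the
    container so downstream stages never see NaN/inf or duplicated ids.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        try:
            values = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression value: {exc}") from exc
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value at probe {values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self._data = values
        self._data.index = self._data.index.astype(str)
        self._data.columns = self._data.columns.astype(str)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._data.columns]
        if missing:
            raise FormatError(f"sample id(s) not in matrix: {missing}")
        return ExpressionMatrix(self._data[sample_ids])

    def check_design(self, designs: list[SampleDesign]) -> None:
        """Require the matrix columns to match the design sheet exactly."""
        design_ids = {d.sample_id for d in designs}
        if len(design_ids) != len(designs):
            raise FormatError("duplicate sample ids in design set")
        matrix_ids = set(self.sample_ids)
        if design_ids != matrix_ids:
            only_m = sorted(matrix_ids - design_ids)
            only_d = sorted(design_ids - matrix_ids)
            raise FormatError(
                f"matrix/design mismatch: matrix-only={only_m[:5]}, design-only={only_d[:5]}"
            )


def read_matrix(path) -> ExpressionMatrix:
    """Load a tab-delimited matrix (first column probe id, header sample ids)."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate probe id {dup!r} in {path}")
    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() | raw[col].isna()
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise FormatError(
                f"non-numeric or missing value at probe {probe!r}, sample {col!r} in {path}"
            )
        numeric[col] = converted
    return ExpressionMatrix(numeric)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="probe_id", lineterminator="\n")


def read_design(path) -> list[SampleDesign]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _DESIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"design sheet {path} missing column(s) {missing}")
    return frame_to_designs(frame)


def write_design(designs: list[SampleDesign], path) -> None:
    designs_to_frame(designs).to_csv(path, sep="\t", index=False, lineterminator="\n")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the same value distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    each column's values are replaced by the reference values at their ranks.
    Ties within a column receive the mean of the reference values spanned by
    the tied rank range, so the map is well defined and idempotent.
    """
    X = matrix.values
    n, m = X.shape
    if m < 2:
        raise FormatError("quantile normalization requires at least 2 samples")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.take_along_axis(X, order, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(m):
        o = order[:, j]
        sorted_col = X[o, j]
        # group tied runs; each run gets the mean reference over its span
        starts = np.r_[0, np.nonzero(np.diff(sorted_col))[0] + 1]
        counts = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(ref, starts) / counts
        out[o, j] = np.repeat(group_means, counts)
    return ExpressionMatrix(pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids))


def validate_files(matrix_path, design_path) -> list[str]:
    """Schema check used by the CLI ``validate`` subcommand.

    Returns a list of human-readable problems (empty if everything is fine).
    """
    problems: list[str] = []
    matrix = designs = None
    try:
        matrix = read_matrix(matrix_path)
    except FormatError as exc:
        problems.append(f"matrix: {exc}")
    try:
        designs = read_design(design_path)
    except FormatError as exc:
        problems.append(f"design: {exc}")
    if matrix is not None and designs is not None:
        try:
            matrix.check_design(designs)
        except FormatError as exc:
            problems.append(str(exc))
    return problems
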