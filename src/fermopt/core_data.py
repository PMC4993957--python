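"""Domain types, min-max scaling, CSV I/O and packaged reference datasets.

The optimization problem has nine decision variables, the concentrations of
the medium components used in submerged fermentation of *Phellinus
igniarius*, and one response, the total-flavonoid concentration of the broth
(TF, in μg/mL).  Everything downstream — the neural-network surrogate and
the genetic algorithm — indexes components by the canonical order defined in
:data:`COMPONENTS`.

Concentration columns are treated as unitless "values as printed": the
reference tables, the search-box bounds and the summary averages that
accompany them are not mutually consistent in unit labels, and min-max
scaling makes the surrogate invariant to any single column's unit anyway.
The known inconsistencies are recorded in each fixture's provenance text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPONENTS",
    "TARGET",
    "SHORT_NAMES",
    "SchemaError",
    "ParseError",
    "DegenerateColumnError",
    "FermentationRecord",
    "Dataset",
    "ScalingParams",
    "load_dataset",
    "table1_fixture",
    "table2_fixture",
    "TABLE2_REPORTED_MEANS",
    "fit_scaler",
    "scale",
    "inverse_scale",
    "column_means",
]

#: Canonical component order.  Every matrix of conditions in this package has
#: its columns in this order.
COMPONENTS: tuple[str, ...] = (
    "glucose",
    "maltose",
    "mannitol",
    "corn_powder",
    "yeast",
    "cupric_sulfate",
    "sodium_chloride",
    "ferrous_sulfate",
    "vitamin_b1",
)

#: Name of the response column (total flavonoids, μg/mL).
TARGET = "total_flavonoids"

#: Short column headers used in CSV files, in canonical order.
SHORT_NAMES: dict[str, str] = {
    "Glu": "glucose",
    "Mal": "maltose",
    "Mann": "mannitol",
    "CP": "corn_powder",
    "Yeast": "yeast",
    "CS": "cupric_sulfate",
    "SC": "sodium_chloride",
    "FS": "ferrous_sulfate",
    "VB1": "vitamin_b1",
    "TF": TARGET,
}
LONG_TO_SHORT = {v: k for k, v in SHORT_NAMES.items()}


class SchemaError(ValueError):
    """A CSV header does not match the expected component columns."""


class ParseError(ValueError):
    """A CSV cell could not be parsed as a number."""


class DegenerateColumnError(ValueError):
    """A constant column cannot be min-max scaled; drop or impute it."""


class FermentationRecord(NamedTuple):
    """One fermentation experiment: nine concentrations plus measured yield.

    ``total_flavonoids`` is ``None`` for unlabeled conditions (e.g. candidate
    media that have not been run in the lab).
    """

    glucose: float
    maltose: float
    mannitol: float
    corn_powder: float
    yeast: float
    cupric_sulfate: float
    sodium_chloride: float
    ferrous_sulfate: float
    vitamin_b1: float
    total_flavonoids: float | None = None


def _format_cell(value: float) -> str:
    # shortest exact decimal for the values we handle (12 significant digits)
    return format(float(value), ".12g")


@dataclass
class Dataset:
    """An ordered collection of fermentation records.

    Thin wrapper around a :class:`pandas.DataFrame` whose columns are the
    nine canonical components, optionally followed by the target column.
    """

    frame: pd.DataFrame
    provenance: str = ""
    column_order: tuple[str, ...] = COMPONENTS

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        expected = list(self.column_order)
        if cols not in (expected, expected + [TARGET]):
            raise SchemaError(
                f"dataset columns {cols} do not match canonical order "
                f"{expected} (+ optional {TARGET!r})"
            )
        if len(self.frame) < 1:
            raise ValueError("dataset must contain at least one record")
        values = self.frame[list(self.column_order)].to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("all concentrations must be finite and >= 0")
        if self.has_target:
            y = self.frame[TARGET].to_numpy(dtype=float)
            if not np.isfinite(y).all() or (y <= 0).any():
                raise ValueError("total_flavonoids must be finite and > 0")

    @property
    def has_target(self) -> bool:
        return TARGET in self.frame.columns

    @property
    def X(self) -> np.ndarray:
        """(n, 9) matrix of component concentrations in canonical order."""
        return self.frame[list(self.column_order)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray | None:
        """Yield vector (μg/mL), or ``None`` for unlabeled datasets."""
        if not self.has_target:
            return None
        return self.frame[TARGET].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, i: int) -> FermentationRecord:
        row = self.frame.iloc[i]
        tf = float(row[TARGET]) if self.has_target else None
        return FermentationRecord(
            *(float(row[c]) for c in self.column_order), total_flavonoids=tf
        )

    def __iter__(self) -> Iterator[FermentationRecord]:
        return (self[i] for i in range(len(self)))

    @property
    def records(self) -> list[FermentationRecord]:
        return list(self)

    def to_csv(self, path: str | Path | None = None) -> str | None:
        """Serialize with short headers and shortest-exact decimal cells.

        Returns the CSV text when ``path`` is ``None``.
        """
        cols = list(self.frame.columns)
        buf = io.StringIO()
        buf.write(",".join(LONG_TO_SHORT[c] for c in cols) + "\n")
        for _, row in self.frame.iterrows():
            buf.write(",".join(_format_cell(row[c]) for c in cols) + "\n")
        text = buf.getvalue()
        if path is None:
            return text
        Path(path).write_text(text, encoding="utf-8")
        return None

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray | None = None,
        provenance: str = "",
    ) -> "Dataset":
        X = np.asarray(X, dtype=float)
        frame = pd.DataFrame(X, columns=list(COMPONENTS))
        if y is not None:
            frame[TARGET] = np.asarray(y, dtype=float)
        return cls(frame, provenance=provenance)


def _normalize_header(columns: Sequence[str]) -> list[str]:
    """Map CSV headers (short or long form) onto canonical names."""
    aliases = {**SHORT_NAMES, **{c: c for c in COMPONENTS}, TARGET: TARGET}
    out = []
    for col in columns:
        key = col.strip()
        if key not in aliases:
            raise SchemaError(f"unrecognized column {col!r}")
        out.append(aliases[key])
    return out


def load_dataset(
    path: str | Path, has_target: bool | None = None, provenance: str = ""
) -> Dataset:
    """Read a conditions CSV (header row, '.' decimal separator).

    Parameters
    ----------
    path
        CSV file with the nine component columns (short ``Glu``..``VB1`` or
        long canonical headers) and an optional ``TF`` target column.
    has_target
        If given, assert the presence/absence of the target column.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = _normalize_header(raw.columns)
    missing = [c for c in COMPONENTS if c not in cols]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(cols) != len(set(cols)):
        raise SchemaError(f"duplicate column(s) in header: {list(raw.columns)}")
    raw.columns = cols

    target_present = TARGET in cols
    if has_target is True and not target_present:
        raise SchemaError(f"expected a {TARGET!r} (TF) column")
    if has_target is False and target_present:
        raise SchemaError(f"unexpected {TARGET!r} (TF) column")

    parsed = {}
    for col in cols:
        vals = []
        for i, cell in enumerate(raw[col]):
            try:
                vals.append(float(cell))
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i + 1}, column {col!r}"
                ) from None
        parsed[col] = vals
    order = list(COMPONENTS) + ([TARGET] if target_present else [])
    frame = pd.DataFrame(parsed)[order]
    return Dataset(frame, provenance=provenance or str(path))


def _load_packaged(name: str, provenance: str) -> Dataset:
    ref = resources.files("fermopt.data").joinpath(name)
    with resources.as_file(ref) as p:
        return load_dataset(p, has_target=True, provenance=provenance)


def table1_fixture() -> Dataset:
    """The 25 training conditions with their measured flavone yields.

    These are the published fermentation runs (selected from a much larger
    screening campaign) used to train the surrogate.  Yields printed in
    scientific notation are stored as plain μg/mL numbers.  Note that the
    cupric-sulfate, ferrous-sulfate and vitamin-B1 values lie far outside
    the search-box bounds used by the optimizer (see :mod:`fermopt.ga_opt`);
    the column/unit mapping is preserved exactly as printed.
    """
    return _load_packaged(
        "table1.csv",
        provenance=(
            "published training set: 25 fermentation conditions with "
            "measured total flavonoids (μg/mL); values as printed"
        ),
    )


def table2_fixture() -> Dataset:
    """The 10 published optimized conditions with surrogate-predicted yields.

    Headers are preserved exactly as printed.  Caveat for interpretation:
    the printed 'SC' column (range 0.22–0.55) and 'FS' column (9.74–9.99)
    appear swapped relative to the stated bounds (NaCl 0–10, FeSO4 0–0.5)
    and to the published summary averages (NaCl 9.89, FeSO4 0.3); the
    'VB1' values (~1.0–1.11) exceed the stated 0–0.1 bound.
    """
    return _load_packaged(
        "table2.csv",
        provenance=(
            "published optimized conditions: 10 rows, surrogate-predicted "
            "total flavonoids (μg/mL); SC/FS headers appear swapped vs the "
            "stated bounds and summary averages; VB1 exceeds its stated "
            "bound; values as printed"
        ),
    )


#: Summary averages published alongside the optimized-conditions table.
#: Four of them (corn_powder, yeast, cupric_sulfate, vitamin_b1, and the
#: 2200 yield figure) are not the arithmetic means of the printed cells
#: under any rounding; :func:`fermopt.pipeline.summarize_results` reports
#: the discrepancies.
TABLE2_REPORTED_MEANS: dict[str, float] = {
    "glucose": 15.1,
    "maltose": 15.264,
    "mannitol": 29.83,
    "corn_powder": 5.23,
    "yeast": 5.14,
    "cupric_sulfate": 0.18,
    "sodium_chloride": 9.89,
    "ferrous_sulfate": 0.3,
    "vitamin_b1": 1.03,
    TARGET: 2200.0,
}


@dataclass(frozen=True)
class ScalingParams:
    """Per-column min/max for the affine scaling y = (x - min)/(max - min).

    Fitted on a training set; covers the nine components and the target.
    ``feature_range`` selects the image of the training envelope: ``(0, 1)``
    applies the formula literally, ``(-1, 1)`` composes it with 2y - 1.
    Values outside the training envelope map outside the range (no
    clamping): extrapolation is deliberate and visible.
    """

    columns: tuple[str, ...]
    x_min: np.ndarray
    x_max: np.ndarray
    feature_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.x_min) or len(self.columns) != len(
            self.x_max
        ):
            raise ValueError("columns/x_min/x_max length mismatch")
        if (self.x_max < self.x_min).any():
            raise ValueError("x_max must be >= x_min per column")
        lo, hi = self.feature_range
        if not hi > lo:
            raise ValueError("feature_range must be increasing")

    def _index(self, column: str) -> int:
        try:
            return self.columns.index(column)
        except ValueError:
            raise KeyError(f"unknown column {column!r}") from None

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (unscalable) columns."""
        return self.x_max == self.x_min

    def is_degenerate(self, column: str) -> bool:
        return bool(self.degenerate[self._index(column)])

    def _check(self, column: str) -> int:
        i = self._index(column)
        if self.degenerate[i]:
            raise DegenerateColumnError(
                f"column {column!r} is constant in the training set "
                "(min == max); drop it or impute variation before scaling"
            )
        return i

    def scale(self, x, column: str):
        i = self._check(column)
        lo, hi = self.feature_range
        unit = (np.asarray(x, dtype=float) - self.x_min[i]) / (
            self.x_max[i] - self.x_min[i]
        )
        out = lo + (hi - lo) * unit
        return float(out) if np.isscalar(x) else out

    def inverse_scale(self, y, column: str):
        i = self._check(column)
        lo, hi = self.feature_range
        unit = (np.asarray(y, dtype=float) - lo) / (hi - lo)
        out = self.x_min[i] + unit * (self.x_max[i] - self.x_min[i])
        return float(out) if np.isscalar(y) else out

    # -- matrix helpers (canonical component order) --------------------

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        """Scale an (n, 9) raw matrix column-by-column."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = [self.scale(X[:, j], c) for j, c in enumerate(COMPONENTS)]
        return np.column_stack(cols)

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        return self.scale(np.asarray(y, dtype=float), TARGET)

    def inverse_transform_target(self, y: np.ndarray):
        return self.inverse_scale(y, TARGET)

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "x_min": [float(v) for v in self.x_min],
            "x_max": [float(v) for v in self.x_max],
            "feature_range": list(self.feature_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            columns=tuple(d["columns"]),
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            feature_range=tuple(d["feature_range"]),
        )


def fit_scaler(
    data: Dataset, feature_range: tuple[float, float] = (0.0, 1.0)
) -> ScalingParams:
    """Observed per-column min/max over the training set, target included."""
    if len(data) == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    cols = list(data.frame.columns)
    values = data.frame.to_numpy(dtype=float)
    return ScalingParams(
        columns=tuple(cols),
        x_min=values.min(axis=0),
        x_max=values.max(axis=0),
        feature_range=feature_range,
    )


def scale(x, column: str, params: ScalingParams):
    """Affine map of ``x`` onto the scaler's feature range for ``column``."""
    return params.scale(x, column)


def inverse_scale(y, column: str, params: ScalingParams):
    """Exact inverse of :func:`scale` for ``column``."""
    return params.inverse_scale(y, column)


def column_means(data: Dataset) -> pd.Series:
    """Exact arithmetic mean of every column; rounding is the caller's job."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    return data.frame.mean(axis=0)
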