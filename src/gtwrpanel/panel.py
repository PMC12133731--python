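"""Long-format city-year panel container shared by every stage of the analysis.

A panel holds one record per (city, year): planar coordinates, the birth rate
response in per-mille (births per 1,000 population per year), and a fixed,
ordered set of socioeconomic covariates. Model fitting requires projected
planar coordinates so that Euclidean distance is metric; longitude/latitude
input can be converted with :func:`project_lonlat`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "PanelError",
    "IngestionError",
    "TransformError",
    "DegenerateInputError",
    "REQUIRED_COLUMNS",
    "project_lonlat",
]

#: Columns every panel table must provide, in canonical order.
REQUIRED_COLUMNS = ("city_id", "u", "v", "year", "birth_rate")

EARTH_RADIUS_KM = 6371.0088


class PanelError(ValueError):
    """Base class for panel-related errors."""


class IngestionError(PanelError):
    """Raised when an input table violates the panel contract."""


class TransformError(PanelError):
    """Raised when a variable transform cannot be applied to a record."""


class DegenerateInputError(PanelError):
    """Raised when an input is structurally valid but statistically degenerate
    (e.g. a constant field handed to an autocorrelation statistic)."""


def project_lonlat(lon: np.ndarray, lat: np.ndarray, lon0: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project longitude/latitude (degrees) to planar km with the sinusoidal
    equal-area projection, u = R·(λ−λ0)·cos(φ), v = R·φ.

    The sinusoidal projection is equal-area and, near the central meridian
    ``lon0`` (default: the data mean), approximately equidistant — adequate for
    the kernel-distance computations here, which only need a metric planar
    frame, not cartographic fidelity.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    lam = np.radians(lon - lon0)
    phi = np.radians(lat)
    return EARTH_RADIUS_KM * lam * np.cos(phi), EARTH_RADIUS_KM * phi


@dataclasses.dataclass
class PanelDataset:
    """City-year records with coordinates, response and covariates.

    Parameters
    ----------
    data:
        Long-format frame with the :data:`REQUIRED_COLUMNS` plus one column
        per covariate. ``(city_id, year)`` must be unique and no required
        value may be missing.
    variable_names:
        Ordered covariate column names; this order is the coefficient order
        of every downstream fit.
    transform_log:
        Record of variable transforms already applied (see pipeline module).
    truth:
        Optional per-record true coefficient table (synthetic panels only),
        aligned row-for-row with ``data``; columns ``beta_intercept`` and
        ``beta_<variable>``.
    dropped_count:
        Number of incomplete records removed at ingestion.
    """

    data: pd.DataFrame
    variable_names: list[str]
    transform_log: list[str] = dataclasses.field(default_factory=list)
    truth: pd.DataFrame | None = None
    dropped_count: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise IngestionError(f"panel table is missing required columns: {missing}")
        absent = [c for c in self.variable_names if c not in self.data.columns]
        if absent:
            raise IngestionError(f"declared covariates absent from table: {absent}")
        dup = self.data.duplicated(subset=["city_id", "year"])
        if dup.any():
            offenders = self.data.loc[dup, ["city_id", "year"]].to_records(index=False).tolist()
            raise IngestionError(f"duplicate (city_id, year) keys: {offenders[:10]}")
        used = list(REQUIRED_COLUMNS) + list(self.variable_names)
        if self.data[used].isna().any().any():
            bad = self.data[used].isna().any()
            raise IngestionError(
                f"missing values in columns {list(bad.index[bad])}; filter rows before constructing a panel"
            )
        if (self.data["birth_rate"] < 0).any():
            raise IngestionError("birth_rate must be non-negative (per-mille scale)")
        self.data = self.data.reset_index(drop=True)
        if self.truth is not None:
            self.truth = self.truth.reset_index(drop=True)
            if len(self.truth) != len(self.data):
                raise IngestionError("truth table must align row-for-row with the panel data")

    # -- basic views ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.data["year"].unique())

    def city_table(self) -> pd.DataFrame:
        """One row per city: ``city_id, u, v`` (first occurrence wins)."""
        return (
            self.data[["city_id", "u", "v"]]
            .drop_duplicates(subset="city_id")
            .reset_index(drop=True)
        )

    def cross_section(self, year: int) -> pd.DataFrame:
        return self.data[self.data["year"] == year].reset_index(drop=True)

    def design_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(X, y, coords, t)`` with X carrying a leading intercept
        column and covariates in declared order."""
        k = len(self.variable_names)
        X = np.empty((self.n, k + 1), dtype=float)
        X[:, 0] = 1.0
        if k:
            X[:, 1:] = self.data[self.variable_names].to_numpy(dtype=float)
        y = self.data["birth_rate"].to_numpy(dtype=float)
        coords = self.data[["u", "v"]].to_numpy(dtype=float)
        t = self.data["year"].to_numpy(dtype=float)
        return X, y, coords, t

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        cols = list(REQUIRED_COLUMNS) + list(self.variable_names)
        self.data[cols].to_csv(path, index=False)
        if truth_path is not None:
            if self.truth is None:
                raise PanelError("panel carries no truth table to write")
            out = pd.concat(
                [self.data[["city_id", "year"]], self.truth], axis=1
            )
            out.to_csv(truth_path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        variable_names: Sequence[str] | None = None,
    ) -> "PanelDataset":
        df = pd.read_csv(path)
        if variable_names is None:
            variable_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
        return cls(data=df, variable_names=list(variable_names))


def filter_complete(df: pd.DataFrame, required: Iterable[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows with a missing value in any required column.

    Returns the filtered frame and the number of rows dropped (the exclusion
    count logged at ingestion).
    """
    required = list(required)
    keep = ~df[required].isna().any(axis=1)
    return df[keep].reset_index(drop=True), int((~keep).sum())
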