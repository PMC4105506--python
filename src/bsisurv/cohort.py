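"""Patient-level cohort container and delimited-text I/O.

One row per patient: identifier, age (years), twelve regional BSI values
(percent of skeletal mass), total BSI, observed follow-up time (years),
event indicator (1 = death, 0 = censored) and an optional lesion count.
The on-disk format is comma-separated UTF-8 with a required header in the
canonical column order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bsi import REGIONS

#: Canonical file column order; ``lesions`` is optional on read.
COHORT_COLUMNS: tuple[str, ...] = ("id", "age", *REGIONS, "total_bsi", "time_years", "event", "lesions")

_TOTAL_TOL = 1e-6


class CohortSchemaError(ValueError):
    """A cohort table violates the schema (missing column, bad value)."""


@dataclass
class Cohort:
    """In-memory cohort: parallel arrays over patients.

    ``total_bsi`` is derived (sum of the regional columns), never stored
    independently, so it cannot drift out of sync.
    """

    ids: np.ndarray
    age: np.ndarray
    regional: np.ndarray  # (n, 12) in REGIONS order
    time: np.ndarray
    event: np.ndarray
    lesions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.age = np.asarray(self.age, dtype=float)
        self.regional = np.asarray(self.regional, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.lesions is not None:
            self.lesions = np.asarray(self.lesions, dtype=int)
        n = self.ids.shape[0]
        if self.regional.shape != (n, len(REGIONS)):
            raise CohortSchemaError(
                f"regional matrix must be ({n}, {len(REGIONS)}), got {self.regional.shape}"
            )
        for name, arr in (("age", self.age), ("time", self.time), ("event", self.event)):
            if arr.shape[0] != n:
                raise CohortSchemaError(f"column {name} has length {arr.shape[0]}, expected {n}")
        if np.any(self.regional < 0):
            rows = np.unique(np.nonzero(self.regional < 0)[0])
            raise CohortSchemaError(f"negative regional BSI in rows {rows.tolist()}")
        if np.any(self.time <= 0):
            rows = np.nonzero(self.time <= 0)[0]
            raise CohortSchemaError(f"non-positive follow-up time in rows {rows.tolist()}")
        if not np.isin(self.event, (0, 1)).all():
            rows = np.nonzero(~np.isin(self.event, (0, 1)))[0]
            raise CohortSchemaError(f"event indicator not in {{0,1}} in rows {rows.tolist()}")
        if self.lesions is not None and np.any(self.lesions < 0):
            raise CohortSchemaError("lesion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.ids.shape[0])

    @property
    def total_bsi(self) -> np.ndarray:
        return self.regional.sum(axis=1)

    def region_column(self, region: str) -> np.ndarray:
        return self.regional[:, REGIONS.index(region)]

    def covariate_matrix(self, names: list[str] | tuple[str, ...]) -> np.ndarray:
        """Assemble an (n, len(names)) matrix from named covariates.

        Valid names: ``"age"``, ``"total_bsi"``, and the twelve region
        labels.
        """
        cols = []
        for name in names:
            if name == "age":
                cols.append(self.age)
            elif name == "total_bsi":
                cols.append(self.total_bsi)
            elif name in REGIONS:
                cols.append(self.region_column(name))
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return np.column_stack(cols)

    def subset(self, rows: np.ndarray) -> "Cohort":
        return Cohort(
            ids=self.ids[rows],
            age=self.age[rows],
            regional=self.regional[rows],
            time=self.time[rows],
            event=self.event[rows],
            lesions=None if self.lesions is None else self.lesions[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "age": self.age}
        for i, r in enumerate(REGIONS):
            data[r] = self.regional[:, i]
        data["total_bsi"] = self.total_bsi
        data["time_years"] = self.time
        data["event"] = self.event
        if self.lesions is not None:
            data["lesions"] = self.lesions
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        required = [c for c in COHORT_COLUMNS if c != "lesions"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"missing column(s): {', '.join(missing)}")
        regional = df[list(REGIONS)].to_numpy(dtype=float)
        total = df["total_bsi"].to_numpy(dtype=float)
        mismatch = np.abs(regional.sum(axis=1) - total) > _TOTAL_TOL * np.maximum(1.0, total)
        if mismatch.any():
            rows = np.nonzero(mismatch)[0]
            raise CohortSchemaError(
                f"total_bsi differs from the regional sum in rows {rows.tolist()}"
            )
        return cls(
            ids=df["id"].to_numpy(),
            age=df["age"].to_numpy(dtype=float),
            regional=regional,
            time=df["time_years"].to_numpy(dtype=float),
            event=df["event"].to_numpy(),
            lesions=df["lesions"].to_numpy() if "lesions" in df.columns else None,
        )


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from a comma-separated file (header required)."""
    df = pd.read_csv(path)
    return Cohort.from_frame(df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as comma-separated text, lossless to float precision."""
    cohort.to_frame().to_csv(path, index=False, float_format="%.10g")
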