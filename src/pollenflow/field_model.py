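"""Field-experiment data model and the cross-pollination (CP) rate statistic.

A field experiment consists of a donor plot (coloured-grain pollen source)
and a recipient plot separated by an optional unplanted *field border* (FB).
The recipient plot is planted in rows 0.75 m apart with plants 0.25 m apart
within a row, and is divided into sampling grids; each sampled cob carries a
count of cross-pollinated (CP) grains, identified by grain colour.

Distances are stored *raw* — as planted, FB included — and every
model-specific subtraction (FB width, row spacing) happens in
:func:`effective_distance`, so a single dataset serves all model variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROW_SPACING",
    "PLANT_SPACING",
    "GeometryError",
    "ExperimentLayout",
    "SampleRecord",
    "Dataset",
    "effective_distance",
    "cp_rate",
    "grid_summary",
]

#: Spacing between recipient rows, metres.
ROW_SPACING = 0.75
#: Spacing between plants within a row, metres.
PLANT_SPACING = 0.25

#: Default average grain number per cob (K); configurable on every Dataset.
DEFAULT_K_GRAINS = 400.0


class GeometryError(ValueError):
    """Raised when a distance/variant combination yields a negative d*."""


@dataclass(frozen=True)
class ExperimentLayout:
    """Geometry of one field experiment.

    Parameters
    ----------
    experiment_id
        Label, e.g. ``"2009-2B"``.
    fb_width
        Width of the unplanted field border between donor and recipient
        plots, metres (0 when the plots are adjacent).
    n_recipient_rows
        Number of recipient rows.
    recipient_row_distances
        Distance of each recipient row from the donor plot edge, FB
        included, strictly increasing. With an FB the first row sits at the
        far edge of the border (distance == fb_width); without one it sits
        one row spacing from the donor edge.
    grid_map
        Optional mapping ``grid_id -> (distance, n_cobs)`` describing the
        sampling design; by default one grid per recipient row.
    """

    experiment_id: str
    fb_width: float
    n_recipient_rows: int
    recipient_row_distances: tuple[float, ...]
    row_spacing: float = ROW_SPACING
    plant_spacing: float = PLANT_SPACING
    grid_map: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fb_width < 0:
            raise ValueError(f"fb_width must be >= 0, got {self.fb_width}")
        d = np.asarray(self.recipient_row_distances, dtype=float)
        if len(d) != self.n_recipient_rows:
            raise ValueError(
                f"{self.n_recipient_rows} rows declared but "
                f"{len(d)} row distances given"
            )
        if len(d) and np.any(np.diff(d) <= 0):
            raise ValueError("recipient_row_distances must be strictly increasing")
        if len(d) and d[0] <= 0:
            raise ValueError("recipient row distances must be positive")
        if len(d) and d[0] < self.fb_width - 1e-9:
            raise ValueError(
                f"first recipient row of {self.experiment_id} is at {d[0]} m, "
                f"inside the {self.fb_width} m field border"
            )

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "fb_width": self.fb_width,
            "row_spacing": self.row_spacing,
            "plant_spacing": self.plant_spacing,
            "n_recipient_rows": self.n_recipient_rows,
            "recipient_row_distances": list(self.recipient_row_distances),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentLayout":
        d = dict(d)
        d["recipient_row_distances"] = tuple(d["recipient_row_distances"])
        return cls(**d)


@dataclass(frozen=True)
class SampleRecord:
    """One sampled cob: CP grain count plus location metadata."""

    experiment_id: str
    grid_id: str
    distance: float  # raw shortest distance to the nearest donor, FB included
    fb_width: float
    cp_grains: int
    total_grains: int | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError(f"distance must be > 0, got {self.distance}")
        if self.fb_width < 0:
            raise ValueError(f"fb_width must be >= 0, got {self.fb_width}")
        if self.cp_grains < 0 or int(self.cp_grains) != self.cp_grains:
            raise ValueError(f"cp_grains must be a nonnegative integer, got {self.cp_grains}")
        if self.total_grains is not None and self.total_grains <= 0:
            raise ValueError("total_grains must be positive when given")


#: Canonical dataframe columns, in order.
DATASET_COLUMNS = ["experiment_id", "grid_id", "distance_m", "fb_width_m", "cp_grains"]


@dataclass
class Dataset:
    """A collection of sampled cobs plus the dataset-level grain count K.

    The canonical container is a pandas DataFrame with columns
    ``experiment_id, grid_id, distance_m, fb_width_m, cp_grains`` and an
    optional ``total_grains``.  ``k_grains`` is the average grain number per
    cob (K), used to map kernel output to expected CP counts and counts back
    to CP rates.
    """

    df: pd.DataFrame
    k_grains: float = DEFAULT_K_GRAINS
    layouts: dict[str, ExperimentLayout] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if self.k_grains <= 0:
            raise ValueError(f"k_grains must be > 0, got {self.k_grains}")
        df = self.df.reset_index(drop=True)
        bad = df.index[df["cp_grains"] < 0]
        if len(bad):
            raise ValueError(f"negative cp_grains at rows {list(bad[:5])}")
        bad = df.index[df["distance_m"] <= 0]
        if len(bad):
            raise ValueError(f"nonpositive distance_m at rows {list(bad[:5])}")
        bad = df.index[df["fb_width_m"] < 0]
        if len(bad):
            raise ValueError(f"negative fb_width_m at rows {list(bad[:5])}")
        if self.layouts:
            unknown = set(df["experiment_id"]) - set(self.layouts)
            if unknown:
                raise ValueError(f"records reference unknown experiments: {sorted(unknown)}")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls,
        records: list[SampleRecord],
        k_grains: float = DEFAULT_K_GRAINS,
        layouts: dict[str, ExperimentLayout] | None = None,
    ) -> "Dataset":
        df = pd.DataFrame(
            {
                "experiment_id": [r.experiment_id for r in records],
                "grid_id": [r.grid_id for r in records],
                "distance_m": [r.distance for r in records],
                "fb_width_m": [r.fb_width for r in records],
                "cp_grains": [r.cp_grains for r in records],
            }
        )
        return cls(df=df, k_grains=k_grains, layouts=layouts or {})

    @property
    def records(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                experiment_id=row.experiment_id,
                grid_id=row.grid_id,
                distance=row.distance_m,
                fb_width=row.fb_width_m,
                cp_grains=int(row.cp_grains),
            )
            for row in self.df.itertuples(index=False)
        ]

    def subset(self, index) -> "Dataset":
        """Row-subset (by positional index) keeping K and layouts."""
        return Dataset(
            df=self.df.iloc[np.asarray(index)].reset_index(drop=True),
            k_grains=self.k_grains,
            layouts=self.layouts,
        )

    def concat(self, other: "Dataset") -> "Dataset":
        if other.k_grains != self.k_grains:
            raise ValueError("cannot concatenate datasets with different k_grains")
        return Dataset(
            df=pd.concat([self.df, other.df], ignore_index=True),
            k_grains=self.k_grains,
            layouts={**self.layouts, **other.layouts},
        )


def effective_distance(
    distance,
    fb_width,
    *,
    fb_effect: bool,
    kernel: str,
    row_spacing: float = ROW_SPACING,
):
    """Model-variant effective distance d*.

    With the FB effect the border width is subtracted from the raw
    distance.  Without it, the compound-exponential variant uses the raw
    distance unchanged while the modified-Cauchy variant subtracts one row
    spacing (0.75 m).  Works on scalars or arrays.

    Raises
    ------
    GeometryError
        If the result would be negative (the location lies inside the
        subtracted zone for the chosen variant).  d* = 0 is valid: with an
        FB the first recipient row sits exactly at the border's far edge.
    """
    d = np.asarray(distance, dtype=float)
    fb = np.asarray(fb_width, dtype=float)
    if fb_effect:
        out = d - fb
    elif kernel == "cauchy":
        out = d - row_spacing
    elif kernel == "expo":
        out = d + 0.0
    else:
        raise ValueError(f"unknown kernel family {kernel!r}")
    if np.any(out < -1e-9):
        raise GeometryError(
            "effective distance is negative: raw distance smaller than the "
            f"subtracted width for variant (fb_effect={fb_effect}, kernel={kernel})"
        )
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(distance) else out


def cp_rate(cp_grain_counts, k_grains: float) -> float:
    """Average cross-pollination rate of a set of cobs, in percent.

    CP(%) = 100 * sum_i Cob_i / (n * K), where Cob_i is the CP grain count
    on cob i, n the number of cobs and K the average grain number per cob.
    """
    counts = np.asarray(cp_grain_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cp_rate needs at least one cob")
    if k_grains <= 0:
        raise ValueError(f"k_grains must be > 0, got {k_grains}")
    if np.any(counts < 0):
        raise ValueError("cp grain counts must be nonnegative")
    return float(100.0 * counts.sum() / (counts.size * k_grains))


def grid_summary(dataset: Dataset) -> pd.DataFrame:
    """Per-grid summary: experiment, grid, distance, n cobs, CP rate (%).

    One row per (experiment, grid); grids at the same distance are *not*
    pooled — the grid is the summarisation unit of the sampling design.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rows = []
    for (exp, grid), g in dataset.df.groupby(["experiment_id", "grid_id"], sort=True):
        if len(g) == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"grid {exp}/{grid} has no cobs; excluded")
            continue
        dists = g["distance_m"].unique()
        if len(dists) > 1:
            warnings.warn(f"grid {exp}/{grid} spans several distances; using the minimum")
        rows.append(
            {
                "experiment_id": exp,
                "grid_id": grid,
                "distance_m": float(dists.min()),
                "fb_width_m": float(g["fb_width_m"].iloc[0]),
                "n_cobs": int(len(g)),
                "cp_rate_percent": cp_rate(g["cp_grains"].to_numpy(), dataset.k_grains),
            }
        )
    return pd.DataFrame(rows)
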