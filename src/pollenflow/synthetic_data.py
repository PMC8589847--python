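"""Synthetic field-experiment generator.

Emulates the three maize cross-pollination experiments the modelling
framework was designed around, so the full pipeline (fitting, validation,
diagnostics, posterior prediction) is exercisable without any field data:

* ``2009-1``  — no field border (FB); 82 recipient rows starting 0.75 m
  from the donor edge.
* ``2009-2A`` — no FB; 82 rows, first row at 0.75 m.
* ``2009-2B`` — 6.75 m FB; 82 rows, first row at the border's far edge
  (6.75 m).
* ``2010-1``  — 7.5 m FB; 91 rows, first row at 7.5 m (second at 8.25 m).

Row spacing is 0.75 m throughout.  Sampling is grid-based with one grid
per recipient row by default and a configurable number of cobs per grid
(default 5); the average grain number per cob K defaults to 400.  Counts
are drawn from the generative chain of the dispersal models: effective
distance → kernel γ → λ = K·γ → (ZIP) logistic q_s → per-cob count.

The default truth for the bundled suite is the ZExpoB model at its
reference posterior-mean parameters (see ``SUITE_TRUTH_PARAMS``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field_model import ROW_SPACING, Dataset, ExperimentLayout
from .models import DispersalModelSpec
from .observation_models import mixing_weight, poisson_weight

__all__ = [
    "PRESET_NAMES",
    "SUITE_TRUTH_PARAMS",
    "SimulationConfig",
    "make_layout_preset",
    "simulate_experiment",
    "paper_scale_suite",
]

PRESET_NAMES = ("2009-1", "2009-2A", "2009-2B", "2010-1")

_PRESET_GEOMETRY = {
    # name: (fb_width, n_rows)
    "2009-1": (0.0, 82),
    "2009-2A": (0.0, 82),
    "2009-2B": (6.75, 82),
    "2010-1": (7.5, 91),
}

#: Reference truth for the bundled suite: ZExpoB posterior means.
SUITE_TRUTH_PARAMS = {
    "K_e": 0.6760,
    "a1": 0.6073,
    "a2": 0.0506,
    "D": 2.8480,
    "k": 0.3552,
    "b1": 2.7621,
    "b2": 0.0275,
}

DEFAULT_COBS_PER_GRID = 5
DEFAULT_K_GRAINS = 400.0


def make_layout_preset(name: str, row_stride: int = 1) -> ExperimentLayout:
    """Layout of one of the emulated experiments.

    With an FB the first recipient row sits at the far edge of the border
    (distance == FB width); without one, at a single row spacing from the
    donor edge.  Subsequent rows step by 0.75 m.

    ``row_stride`` keeps every ``row_stride``-th row (1 = all rows), for
    scaled-down simulation studies; the first row is always kept.
    """
    if name not in _PRESET_GEOMETRY:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    if row_stride < 1:
        raise ValueError("row_stride must be >= 1")
    fb, n_rows = _PRESET_GEOMETRY[name]
    start = fb if fb > 0 else ROW_SPACING
    distances = tuple(
        round(start + i * ROW_SPACING, 6) for i in range(0, n_rows, row_stride)
    )
    return ExperimentLayout(
        experiment_id=name,
        fb_width=fb,
        n_recipient_rows=len(distances),
        recipient_row_distances=distances,
    )


@dataclass
class SimulationConfig:
    """Everything needed to simulate one experiment."""

    layout: ExperimentLayout
    truth_spec: DispersalModelSpec
    truth_params: dict
    k_grains: float = DEFAULT_K_GRAINS
    cobs_per_grid: int = DEFAULT_COBS_PER_GRID
    seed: int = 0
    zip_weight: str = "one_minus_q"

    def __post_init__(self) -> None:
        if self.cobs_per_grid < 1:
            raise ValueError("cobs_per_grid must be >= 1")
        if self.k_grains <= 0:
            raise ValueError("k_grains must be > 0")
        # fail fast on incomplete truth
        self.truth_spec.pack(self.truth_params)


def simulate_experiment(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Dataset:
    """Draw one synthetic dataset for a single experiment layout.

    One sampling grid per recipient row; per cob the count is drawn from
    the truth model's observation distribution at that row's distance.
    Records carry raw distances (FB included), so any of the eight model
    variants can be fitted to the result.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.truth_spec
    layout = config.layout
    n_grids = len(layout.recipient_row_distances)
    distances = np.repeat(
        np.asarray(layout.recipient_row_distances, dtype=float), config.cobs_per_grid
    )
    fb = np.full_like(distances, layout.fb_width)
    grid_ids = np.repeat(
        [f"r{i + 1:03d}" for i in range(n_grids)], config.cobs_per_grid
    )

    # generative chain: d* -> gamma -> lambda (-> q_s -> w) -> count
    from .field_model import effective_distance

    d_star = effective_distance(
        distances, fb, fb_effect=spec.fb_effect, kernel=spec.kernel
    )
    lam = config.k_grains * spec.gamma(d_star, fb, config.truth_params)
    if not np.all(np.isfinite(lam)):
        bad = int(np.flatnonzero(~np.isfinite(lam))[0])
        raise FloatingPointError(
            f"non-finite expected count at grid {grid_ids[bad]} "
            f"(distance {distances[bad]} m)"
        )
    counts = rng.poisson(lam)
    if spec.observation == "zip":
        q = mixing_weight(d_star, config.truth_params["b1"], config.truth_params["b2"])
        w = poisson_weight(q, config.zip_weight)
        counts = np.where(rng.random(len(counts)) < w, counts, 0)

    df = pd.DataFrame(
        {
            "experiment_id": layout.experiment_id,
            "grid_id": grid_ids,
            "distance_m": distances,
            "fb_width_m": fb,
            "cp_grains": counts.astype(np.int64),
        }
    )
    return Dataset(
        df=df, k_grains=config.k_grains, layouts={layout.experiment_id: layout}
    )


def paper_scale_suite(
    seed: int = 0,
    truth_spec: DispersalModelSpec | None = None,
    truth_params: dict | None = None,
    cobs_per_grid: int = DEFAULT_COBS_PER_GRID,
    k_grains: float = DEFAULT_K_GRAINS,
    row_stride: int = 1,
    zip_weight: str = "one_minus_q",
) -> list[Dataset]:
    """The three-experiment suite: 2009-1, 2009-2A+2009-2B, 2010-1.

    Returns three datasets (the 2009-2 pair is combined into one, as it
    was one split experiment); concatenate them for cross-validation runs.
    Default truth is ZExpoB at ``SUITE_TRUTH_PARAMS``.
    """
    if truth_spec is None:
        truth_spec = DispersalModelSpec.from_code("ZExpoB")
    if truth_params is None:
        truth_params = dict(SUITE_TRUTH_PARAMS)
    rng = np.random.default_rng(seed)

    def sim(name: str) -> Dataset:
        cfg = SimulationConfig(
            layout=make_layout_preset(name, row_stride=row_stride),
            truth_spec=truth_spec,
            truth_params=truth_params,
            k_grains=k_grains,
            cobs_per_grid=cobs_per_grid,
            zip_weight=zip_weight,
        )
        return simulate_experiment(cfg, rng=rng)

    return [
        sim("2009-1"),
        sim("2009-2A").concat(sim("2009-2B")),
        sim("2010-1"),
    ]
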