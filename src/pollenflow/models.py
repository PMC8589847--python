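"""Dispersal model specifications (the eight model codes).

A dispersal model is an observation model (Poisson or zero-inflated
Poisson) composed with a dispersal kernel (compound exponential or modified
Cauchy), with or without the field-border (FB) effect:

====== =========== ========== =========
code   observation kernel     FB effect
====== =========== ========== =========
PExpoN Poisson     exponential    no
PExpoB Poisson     exponential    yes
PCauchyN Poisson   Cauchy         no
PCauchyB Poisson   Cauchy         yes
ZExpoN ZIP         exponential    no
ZExpoB ZIP         exponential    yes
ZCauchyN ZIP       Cauchy         no
ZCauchyB ZIP       Cauchy         yes
====== =========== ========== =========

This module also owns the flat parameter-vector representation shared by
the MLE and MCMC routes: positivity-constrained kernel parameters are
optimised/sampled on the log scale, the logistic mixing parameters b1, b2
on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_model import Dataset, effective_distance
from .kernels import CauchyKernelParams, ExpoKernelParams, kernel_cauchy, kernel_expo

__all__ = ["MODEL_CODES", "DispersalModelSpec"]

MODEL_CODES = (
    "PExpoN",
    "PExpoB",
    "PCauchyN",
    "PCauchyB",
    "ZExpoN",
    "ZExpoB",
    "ZCauchyN",
    "ZCauchyB",
)

_EXPO_NAMES = ("K_e", "a1", "a2", "D")
_CAUCHY_NAMES = ("beta", "c1", "D")
_ZIP_NAMES = ("b1", "b2")


@dataclass(frozen=True)
class DispersalModelSpec:
    """One of the eight dispersal-model variants."""

    observation: str  # "poisson" | "zip"
    kernel: str  # "expo" | "cauchy"
    fb_effect: bool

    @classmethod
    def from_code(cls, code: str) -> "DispersalModelSpec":
        if code not in MODEL_CODES:
            raise ValueError(
                f"unknown model code {code!r}; valid codes: {', '.join(MODEL_CODES)}"
            )
        observation = "poisson" if code[0] == "P" else "zip"
        kernel = "expo" if "Expo" in code else "cauchy"
        return cls(observation=observation, kernel=kernel, fb_effect=code.endswith("B"))

    @property
    def code(self) -> str:
        return (
            ("P" if self.observation == "poisson" else "Z")
            + ("Expo" if self.kernel == "expo" else "Cauchy")
            + ("B" if self.fb_effect else "N")
        )

    # ------------------------------------------------------------------
    # parameter-vector plumbing
    # ------------------------------------------------------------------
    @property
    def param_names(self) -> tuple[str, ...]:
        names = list(_EXPO_NAMES if self.kernel == "expo" else _CAUCHY_NAMES)
        if self.fb_effect:
            names.append("k")
        if self.observation == "zip":
            names.extend(_ZIP_NAMES)
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def log_scale(self) -> np.ndarray:
        """Boolean mask: which entries of the parameter vector live on the
        log scale (all positivity-constrained kernel parameters)."""
        return np.array([n not in _ZIP_NAMES for n in self.param_names])

    def pack(self, params: dict) -> np.ndarray:
        missing = [n for n in self.param_names if n not in params]
        if missing:
            raise ValueError(f"missing parameters for {self.code}: {missing}")
        return np.array([float(params[n]) for n in self.param_names])

    def unpack(self, vector) -> dict:
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_params,):
            raise ValueError(
                f"{self.code} expects {self.n_params} parameters, got {vector.shape}"
            )
        return dict(zip(self.param_names, vector.tolist()))

    def to_unconstrained(self, vector) -> np.ndarray:
        v = np.asarray(vector, dtype=float).copy()
        mask = self.log_scale
        v[mask] = np.log(v[mask])
        return v

    def from_unconstrained(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float).copy()
        mask = self.log_scale
        z[mask] = np.exp(z[mask])
        return z

    def kernel_params(self, params: dict):
        """Build the typed kernel-parameter object from a parameter dict."""
        k = float(params.get("k", 0.0))
        if self.kernel == "expo":
            return ExpoKernelParams(
                K_e=params["K_e"], a1=params["a1"], a2=params["a2"], D=params["D"], k=k
            )
        return CauchyKernelParams(
            beta=params["beta"], c1=params["c1"], D=params["D"], k=k
        )

    # ------------------------------------------------------------------
    # model evaluation on a dataset
    # ------------------------------------------------------------------
    def effective_distances(self, dataset: Dataset) -> np.ndarray:
        """d* for every record under this variant's distance convention."""
        return effective_distance(
            dataset.df["distance_m"].to_numpy(dtype=float),
            dataset.df["fb_width_m"].to_numpy(dtype=float),
            fb_effect=self.fb_effect,
            kernel=self.kernel,
        )

    def gamma(self, d_star, fb_width, params: dict):
        kp = self.kernel_params(params)
        if self.kernel == "expo":
            return kernel_expo(d_star, fb_width, kp, fb_effect=self.fb_effect)
        return kernel_cauchy(d_star, fb_width, kp, fb_effect=self.fb_effect)

    def mean_counts(
        self, dataset: Dataset, params: dict, zip_weight: str = "one_minus_q"
    ) -> np.ndarray:
        """Model-mean CP grain count E[Y_s] per record.

        Poisson: λ_s = K·γ.  ZIP: w_s·λ_s with w_s the Poisson-component
        weight (see :mod:`pollenflow.observation_models` for the
        ``zip_weight`` convention).
        """
        from .observation_models import mixing_weight, poisson_weight

        d_star = self.effective_distances(dataset)
        fb = dataset.df["fb_width_m"].to_numpy(dtype=float)
        lam = dataset.k_grains * self.gamma(d_star, fb, params)
        if self.observation == "poisson":
            return lam
        q = mixing_weight(d_star, params["b1"], params["b2"])
        return poisson_weight(q, zip_weight) * lam

    def predicted_grid_cp(
        self, dataset: Dataset, params: dict, zip_weight: str = "one_minus_q"
    ):
        """Predicted CP rate (%) per grid: 100·mean(E[Y])/K over the grid's
        cobs.  Returns a DataFrame aligned with
        :func:`pollenflow.field_model.grid_summary`."""
        df = dataset.df.copy()
        df["_mean"] = self.mean_counts(dataset, params, zip_weight=zip_weight)
        out = (
            df.groupby(["experiment_id", "grid_id"], sort=True)["_mean"]
            .mean()
            .reset_index()
        )
        out["predicted_cp_percent"] = 100.0 * out["_mean"] / dataset.k_grains
        return out.drop(columns="_mean")
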