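"""Dispersal kernels: compound exponential and modified Cauchy.

Both kernels map the effective distance d* between a recipient location s
and its nearest donor source s' to the relative donor pollen density
γ(s, s') at s.  Each is a two-branch curve with a changepoint D: a steep
near-source decline and a slower far-field decline, continuous at d* = D.
The *field-border* (FB) effect multiplies either kernel by exp(-k·√FB),
modelling the empirical exponential drop of first-row pollen density with
border width.

The expected CP grain count at s is λ_s = K·γ(s, s') with K the average
grain number per cob.

γ is not normalised and is not constrained to be ≤ 1 by the functional
form; a γ > 1 during fitting triggers a warning, never an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpoKernelParams",
    "CauchyKernelParams",
    "kernel_expo",
    "kernel_cauchy",
    "expected_cp_grains",
]


@dataclass(frozen=True)
class ExpoKernelParams:
    """Compound-exponential kernel parameters.

    K_e    amplitude at d* = 0 (dimensionless, > 0)
    a1     near-source decline rate, per metre (> 0)
    a2     far-field decline rate, per metre (> 0)
    D      changepoint distance, metres (> 0)
    k      FB decline rate, per √metre (>= 0; irrelevant without FB effect)
    """

    K_e: float
    a1: float
    a2: float
    D: float
    k: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K_e", "a1", "a2", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class CauchyKernelParams:
    """Modified-Cauchy kernel parameters.

    beta   scale of the Cauchy core, metres (> 0); controls the decline rate
    c1     far-field flattening factor (dimensionless, > 0): the quadratic
           growth of the denominator beyond D is damped by c1 < 1
    D      changepoint distance, metres (> 0)
    k      FB decline rate, per √metre (>= 0)
    """

    beta: float
    c1: float
    D: float
    k: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta", "c1", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


def _fb_factor(fb_width, k: float, fb_effect: bool):
    if not fb_effect:
        return 1.0
    return np.exp(-k * np.sqrt(np.asarray(fb_width, dtype=float)))


def kernel_expo(d_star, fb_width, params: ExpoKernelParams, fb_effect: bool = True):
    """Compound-exponential pollen density γ at effective distance d*.

    γ = K_e·exp(-a1·d*)·F            for d* <= D
    γ = K_e·exp(-a1·D - a2·(d*-D))·F for d* >  D

    with F = exp(-k·√FB) when ``fb_effect`` is on, else 1.  Continuous at
    d* = D by construction.  Accepts scalars or arrays; negative d* is an
    error.
    """
    d = np.asarray(d_star, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_star must be >= 0")
    # the far-branch exponent is positive (and may overflow) where d < D,
    # but np.where never selects those lanes
    with np.errstate(over="ignore"):
        near = np.exp(-params.a1 * d)
        far = np.exp(-params.a1 * params.D - params.a2 * (d - params.D))
    gamma = params.K_e * np.where(d <= params.D, near, far) * _fb_factor(
        fb_width, params.k, fb_effect
    )
    return float(gamma) if np.ndim(gamma) == 0 else gamma


def kernel_cauchy(d_star, fb_width, params: CauchyKernelParams, fb_effect: bool = True):
    """Modified-Cauchy pollen density γ at effective distance d*.

    γ = 2β / (π·[β² + d*²])·F                    for d* <= D
    γ = 2β / (π·[β² + D² + c1·(d*-D)²])·F        for d* >  D

    with F = exp(-k·√FB) when ``fb_effect`` is on, else 1.  The far branch
    replaces d*² by D² + c1·(d*-D)², flattening the tail for c1 < 1;
    continuous at d* = D.
    """
    d = np.asarray(d_star, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_star must be >= 0")
    b2 = params.beta**2
    denom_near = b2 + d**2
    denom_far = b2 + params.D**2 + params.c1 * (d - params.D) ** 2
    gamma = (
        2.0
        * params.beta
        / (np.pi * np.where(d <= params.D, denom_near, denom_far))
        * _fb_factor(fb_width, params.k, fb_effect)
    )
    return float(gamma) if np.ndim(gamma) == 0 else gamma


def expected_cp_grains(gamma, k_grains: float, warn_gamma: bool = False):
    """Expected CP grain count λ_s = K·γ(s, s').

    ``warn_gamma`` emits a warning when γ > 1 (possible during fitting; the
    kernel is not normalised, so this is legal but worth flagging).
    """
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("gamma must be >= 0")
    if k_grains <= 0:
        raise ValueError(f"k_grains must be > 0, got {k_grains}")
    if warn_gamma and np.any(g > 1):
        warnings.warn("kernel output gamma > 1: expected CP grains exceed K")
    lam = k_grains * g
    return float(lam) if np.isscalar(gamma) else lam
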