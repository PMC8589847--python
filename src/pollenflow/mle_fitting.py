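"""Maximum-likelihood fitting, fit metrics, and grouped cross-validation.

All eight dispersal-model variants are fitted by direct maximisation of
the observation-model log-likelihood.  Positivity-constrained kernel
parameters are optimised on the log scale; the logistic mixing parameters
b1, b2 on the natural scale.  The optimiser is a multi-start Nelder-Mead
(>= 5 jittered starts by default) followed by a quasi-Newton polish, with
the best likelihood kept.

Fit quality is summarised by AIC = -2ℓ + 2p, deviance = -2ℓ, and an R²
between observed and model-predicted grid-level CP rates; predictive
ability on held-out data by the Pearson correlation r between actual and
predicted grid CP rates.

Validation follows a grouped threefold protocol: observations sharing a
field design and distance form a group, each group is split into three
parts, and each fold validates on one part of every group — so every fold
spans the full distance range of every experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .field_model import Dataset, grid_summary
from .models import DispersalModelSpec
from .observation_models import log_likelihood

__all__ = [
    "FitResult",
    "CrossValReport",
    "fit_mle",
    "fit_metrics",
    "predictive_r",
    "crossval_threefold",
    "auto_init",
]

_UNCONSTRAINED_BOUND = 20.0  # |transformed parameter| guard


@dataclass
class FitResult:
    """MLE point estimates with fit metrics."""

    spec: DispersalModelSpec
    estimates: dict
    log_likelihood: float
    aic: float
    deviance: float
    r_squared: float | None
    converged: bool
    n_obs: int
    n_starts_used: int = 0
    zip_weight: str = "one_minus_q"

    @property
    def n_params(self) -> int:
        return self.spec.n_params


def auto_init(dataset: Dataset, spec: DispersalModelSpec) -> dict:
    """Data-driven starting values.

    Near/far decline rates come from a log-linear regression of nonzero
    grid CP rates on distance; the kernel amplitude from the first-row CP
    rate; the FB rate k from the ratio of first-row CP between FB and
    no-FB experiments when both are present.  Logistic parameters start at
    b1 = 2, b2 = 0.03 (their typical magnitudes for per-mille-scale
    mixing).
    """
    gs = grid_summary(dataset)
    nonzero = gs[gs["cp_rate_percent"] > 0]
    slope = -0.3
    if len(nonzero) >= 3 and nonzero["distance_m"].nunique() >= 2:
        slope, _ = np.polyfit(
            nonzero["distance_m"], np.log(nonzero["cp_rate_percent"] / 100.0), 1
        )
    a1 = float(np.clip(-slope, 0.05, 3.0))
    first = gs.loc[gs["distance_m"].idxmin()]
    amp = float(np.clip(first["cp_rate_percent"] / 100.0, 1e-3, 5.0))

    k0 = 0.3
    if spec.fb_effect:
        by_fb = gs.groupby(gs["fb_width_m"] > 0)
        if True in by_fb.groups and False in by_fb.groups:
            fb_rows = gs[gs["fb_width_m"] > 0]
            nofb_rows = gs[gs["fb_width_m"] == 0]
            cp_fb = fb_rows.loc[fb_rows["distance_m"].idxmin(), "cp_rate_percent"]
            cp_no = nofb_rows.loc[nofb_rows["distance_m"].idxmin(), "cp_rate_percent"]
            fbw = fb_rows["fb_width_m"].min()
            if cp_fb > 0 and cp_no > 0 and fbw > 0:
                k0 = float(np.clip(np.log(cp_no / cp_fb) / np.sqrt(fbw), 0.01, 3.0))

    init = {"D": 3.0}
    if spec.kernel == "expo":
        init.update({"K_e": amp, "a1": a1, "a2": max(a1 / 5.0, 0.01)})
    else:
        init.update({"beta": max(2.0 / (np.pi * amp), 0.2), "c1": 0.3})
    if spec.fb_effect:
        init["k"] = k0
    if spec.observation == "zip":
        init.update({"b1": 2.0, "b2": 0.03})
    return init


# finite penalty (not inf) keeps Nelder-Mead's simplex arithmetic clean
_PENALTY = 1e12


def _objective(spec: DispersalModelSpec, dataset: Dataset, zip_weight: str):
    def negloglik(z: np.ndarray) -> float:
        excess = np.abs(z) - _UNCONSTRAINED_BOUND
        if np.any(excess > 0):
            return _PENALTY + float(np.sum(excess[excess > 0]))
        params = spec.unpack(spec.from_unconstrained(z))
        try:
            ll = log_likelihood(dataset, spec, params, zip_weight=zip_weight)
        except FloatingPointError:
            return _PENALTY
        return _PENALTY if not np.isfinite(ll) else -ll

    return negloglik


def fit_mle(
    dataset: Dataset,
    spec: DispersalModelSpec | str,
    init: dict | str = "auto",
    n_starts: int = 5,
    max_iter: int = 20000,
    tol: float = 1e-8,
    seed: int = 0,
    jitter_sd: float = 0.3,
    zip_weight: str = "one_minus_q",
) -> FitResult:
    """Fit one dispersal-model variant by maximum likelihood.

    Runs ``n_starts`` optimisations from jittered starting points (the
    first start is unjittered), keeps the best likelihood, and polishes it
    with BFGS.  Ties are broken by the smaller parameter-vector norm.
    """
    if isinstance(spec, str):
        spec = DispersalModelSpec.from_code(spec)
    if len(dataset) == 0:
        raise ValueError("cannot fit an empty dataset")
    init_params = auto_init(dataset, spec) if init == "auto" else dict(init)
    z0 = spec.to_unconstrained(spec.pack(init_params))
    rng = np.random.default_rng(seed)
    negloglik = _objective(spec, dataset, zip_weight)

    best = None
    failures = []
    for start in range(max(1, n_starts)):
        z_start = z0 if start == 0 else z0 + rng.normal(0.0, jitter_sd, size=z0.shape)
        res = optimize.minimize(
            negloglik,
            z_start,
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "maxfev": max_iter,
                "fatol": tol,
                "xatol": 1e-6,
                "adaptive": True,
            },
        )
        if not np.isfinite(res.fun) or res.fun >= _PENALTY:
            failures.append(str(res.message))
            continue
        key = (res.fun, float(np.linalg.norm(res.x)))
        if best is None or key < (best.fun, float(np.linalg.norm(best.x))):
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_starts} optimisation starts failed for {spec.code}: {failures}"
        )
    converged = bool(best.success)
    polish = optimize.minimize(negloglik, best.x, method="BFGS", options={"maxiter": 500})
    if np.isfinite(polish.fun) and polish.fun <= best.fun:
        best = polish
        converged = converged or bool(polish.success)

    estimates = spec.unpack(spec.from_unconstrained(best.x))
    ll = -float(best.fun)
    result = FitResult(
        spec=spec,
        estimates=estimates,
        log_likelihood=ll,
        aic=-2.0 * ll + 2.0 * spec.n_params,
        deviance=-2.0 * ll,
        r_squared=None,
        converged=converged,
        n_obs=len(dataset),
        n_starts_used=max(1, n_starts),
        zip_weight=zip_weight,
    )
    result.r_squared = _grid_r_squared(result, dataset)
    return result


def _grid_table(fit: FitResult, dataset: Dataset) -> pd.DataFrame:
    obs = grid_summary(dataset)
    pred = fit.spec.predicted_grid_cp(dataset, fit.estimates, zip_weight=fit.zip_weight)
    return obs.merge(pred, on=["experiment_id", "grid_id"], validate="one_to_one")


def _grid_r_squared(fit: FitResult, dataset: Dataset) -> float | None:
    tab = _grid_table(fit, dataset)
    obs = tab["cp_rate_percent"].to_numpy()
    pred = tab["predicted_cp_percent"].to_numpy()
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        return None
    return float(1.0 - np.sum((obs - pred) ** 2) / sst)


def fit_metrics(fit: FitResult, dataset: Dataset) -> tuple[float, float, float | None]:
    """(AIC, deviance, R²) of a fit evaluated on ``dataset``.

    AIC and deviance come from the fit's log-likelihood; R² compares
    observed and predicted grid-level CP rates as 1 - SSE/SST and is None
    when the observed rates have zero variance.
    """
    return fit.aic, fit.deviance, _grid_r_squared(fit, dataset)


def predictive_r(fit: FitResult, validation: Dataset) -> float:
    """Pearson correlation between actual and predicted grid CP rates."""
    tab = _grid_table(fit, validation)
    if len(tab) < 3:
        raise ValueError(
            f"need at least 3 validation grids to compute r, got {len(tab)}"
        )
    r, _ = stats.pearsonr(tab["cp_rate_percent"], tab["predicted_cp_percent"])
    return float(r)


@dataclass
class CrossValReport:
    """Per-fold fits and fold-averaged metrics of a threefold run."""

    spec: DispersalModelSpec
    per_fold: list[dict] = field(default_factory=list)

    def _values(self, key: str) -> np.ndarray:
        return np.array([f[key] for f in self.per_fold], dtype=float)

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for key in ("aic", "deviance", "r_squared", "r_validation"):
            v = self._values(key)
            rows.append(
                {"metric": key, "mean": float(np.nanmean(v)), "sd": float(np.nanstd(v, ddof=1))}
            )
        return pd.DataFrame(rows)

    def mean(self, key: str) -> float:
        return float(np.nanmean(self._values(key)))


def threefold_partition(dataset: Dataset, seed: int) -> list[np.ndarray]:
    """Grouped threefold partition of record indices.

    Observations with the same (experiment, distance) form a group; each
    group is shuffled and dealt into three parts, so every fold contains a
    share of every group.  Raises if any group has fewer than 3 records.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[], [], []]
    groups = dataset.df.groupby(["experiment_id", "distance_m"], sort=True).indices
    small = [g for g, idx in groups.items() if len(idx) < 3]
    if small:
        raise ValueError(
            f"groups with fewer than 3 observations cannot be split threefold: {small[:5]}"
        )
    for _, idx in sorted(groups.items()):
        perm = rng.permutation(np.asarray(idx))
        offset = rng.integers(3)  # rotate which fold gets the remainder
        for j, record in enumerate(perm):
            folds[(j + offset) % 3].append(int(record))
    return [np.array(sorted(f), dtype=int) for f in folds]


def crossval_threefold(
    dataset: Dataset,
    spec: DispersalModelSpec | str,
    seed: int = 0,
    **fit_kwargs,
) -> CrossValReport:
    """Threefold grouped cross-validation of one model variant.

    Per fold: fit on two parts, validate on the third; reports training
    AIC/deviance/R² (training folds only) and validation r, averaged as
    mean ± SD over the three folds.
    """
    if isinstance(spec, str):
        spec = DispersalModelSpec.from_code(spec)
    folds = threefold_partition(dataset, seed)
    all_idx = np.arange(len(dataset))
    report = CrossValReport(spec=spec)
    for v in range(3):
        train_idx = np.setdiff1d(all_idx, folds[v])
        train = dataset.subset(train_idx)
        valid = dataset.subset(folds[v])
        fit = fit_mle(train, spec, seed=seed + v, **fit_kwargs)
        report.per_fold.append(
            {
                "fold": v,
                "fit": fit,
                "aic": fit.aic,
                "deviance": fit.deviance,
                "r_squared": np.nan if fit.r_squared is None else fit.r_squared,
                "r_validation": predictive_r(fit, valid),
                "n_train": len(train),
                "n_valid": len(valid),
            }
        )
    return report
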