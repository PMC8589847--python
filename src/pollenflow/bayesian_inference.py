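"""Bayesian estimation of the ZIP dispersal models.

Sampler: adaptive random-walk Metropolis on the unconstrained parameter
scale (log for positivity-constrained kernel parameters, natural for the
logistic b1, b2).  During burn-in the joint Gaussian proposal adapts both
its global scale (targeting ~30% acceptance) and its covariance (scaled
empirical chain covariance); adaptation is frozen when burn-in ends, so
the retained chain is a valid Metropolis sample.

Priors default to "noninformative": flat on the unconstrained scale within
a wide guard box (|transformed value| <= 20), which keeps the posterior
proper in practice.  Pass ``log_prior`` to override.

Model comparison uses the deviance information criterion in the
Spiegelhalter form, DIC = D̄ + pD with pD = D̄ - D(θ̄) and θ̄ the posterior
mean on the sampling scale.

Posterior-predictive 95% credible bands for the CP rate versus distance
are built by resampling parameter draws, simulating per-cob counts from
the observation model, converting to CP% as 100·y/K, and taking empirical
2.5/97.5 percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field_model import Dataset, effective_distance
from .models import DispersalModelSpec
from .observation_models import log_likelihood, mixing_weight, poisson_weight

__all__ = [
    "McmcSettings",
    "PosteriorResult",
    "PredictiveBand",
    "sample_posterior",
    "run_mcmc",
    "dic",
    "posterior_predictive_band",
    "effective_sample_size",
    "plot_band",
]

_UNCONSTRAINED_BOUND = 20.0


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length and proposal settings.

    Defaults are the short *test profile* (20,000 iterations, 10,000
    burn-in, thin 5 → 2,000 retained draws).  :meth:`paper_profile`
    returns the full-length configuration (500,000 iterations, 450,000
    burn-in, thin 25 → 2,000 retained draws).
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    proposal_scale: tuple[float, ...] | None = None
    adapt: bool = True
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "McmcSettings":
        return cls(n_iter=500_000, burn_in=450_000, thin=25, seed=seed)


@dataclass
class PosteriorResult:
    """Thinned posterior draws plus summaries."""

    spec: DispersalModelSpec
    draws: pd.DataFrame  # one column per parameter, sampling scale
    acceptance_rate: float
    settings: McmcSettings
    k_grains: float
    zip_weight: str = "one_minus_q"
    log_post: np.ndarray | None = None

    @property
    def posterior_mean(self) -> pd.Series:
        return self.draws.mean()

    @property
    def posterior_sd(self) -> pd.Series:
        return self.draws.std(ddof=1)


def _default_log_prior(z: np.ndarray) -> float:
    return 0.0 if np.all(np.abs(z) <= _UNCONSTRAINED_BOUND) else -np.inf


def sample_posterior(
    log_post,
    x0: np.ndarray,
    settings: McmcSettings,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Adaptive random-walk Metropolis.

    ``log_post`` maps an unconstrained parameter vector to an unnormalised
    log posterior density.  Returns (thinned draws on the unconstrained
    scale, their log-posterior values, post-burn-in acceptance rate).
    Fully deterministic given ``settings.seed``.
    """
    rng = np.random.default_rng(settings.seed)
    x = np.asarray(x0, dtype=float).copy()
    d = len(x)
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError(
            "log posterior is not finite at the initial point; "
            "initialise from an MLE fit or supply explicit starting values"
        )

    base_scale = (
        np.asarray(settings.proposal_scale, dtype=float)
        if settings.proposal_scale is not None
        else np.full(d, 0.1)
    )
    chol = np.diag(base_scale)
    log_s = 0.0  # global log scale factor
    # running moments for covariance adaptation
    mean = x.copy()
    m2 = np.zeros((d, d))
    n_seen = 1

    n_keep = settings.n_retained
    draws = np.empty((n_keep, d))
    lps = np.empty(n_keep)
    kept = 0
    accepted_post = 0
    n_post = 0
    window_acc = 0
    window_n = 0

    for it in range(settings.n_iter):
        prop = x + np.exp(log_s) * (chol @ rng.standard_normal(d))
        lp_prop = float(log_post(prop))
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        if it >= settings.burn_in:
            n_post += 1
            accepted_post += int(accept)
            if (it - settings.burn_in) % settings.thin == 0 and kept < n_keep:
                draws[kept] = x
                lps[kept] = lp
                kept += 1
        # --- adaptation, burn-in only ---
        if settings.adapt and it < settings.burn_in:
            delta = x - mean
            mean += delta / (n_seen + 1)
            m2 += np.outer(delta, x - mean)
            n_seen += 1
            window_acc += int(accept)
            window_n += 1
            if window_n == 50:
                rate = window_acc / window_n
                log_s += 0.5 * (rate - settings.target_accept)
                window_acc = window_n = 0
            if n_seen in (1000, 2000, 5000) or (n_seen % 10_000 == 0 and n_seen > 0):
                cov = m2 / max(n_seen - 1, 1)
                cov = (2.38**2 / d) * cov + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                    log_s = 0.0
                except np.linalg.LinAlgError:
                    pass

    acc_rate = accepted_post / max(n_post, 1)
    return draws[:kept], lps[:kept], acc_rate


def run_mcmc(
    dataset: Dataset,
    spec: DispersalModelSpec | str,
    settings: McmcSettings | None = None,
    init: dict | str = "mle",
    log_prior=None,
    zip_weight: str = "one_minus_q",
) -> PosteriorResult:
    """Sample the posterior of one ZIP dispersal model.

    ``init="mle"`` starts the chain at the maximum-likelihood estimate
    (recommended; with 10% of the iterations spent in the short-profile
    burn-in, a remote start can leave the chain unconverged).
    """
    if isinstance(spec, str):
        spec = DispersalModelSpec.from_code(spec)
    if spec.observation != "zip":
        raise ValueError(
            f"Bayesian route is defined for the ZIP models, got {spec.code}"
        )
    if settings is None:
        settings = McmcSettings()
    if log_prior is None:
        log_prior = _default_log_prior

    if init == "mle":
        from .mle_fitting import fit_mle

        init_params = fit_mle(
            dataset, spec, seed=settings.seed, n_starts=3, zip_weight=zip_weight
        ).estimates
    else:
        init_params = dict(init)
    z0 = spec.to_unconstrained(spec.pack(init_params))

    def log_post(z: np.ndarray) -> float:
        lp = log_prior(z)
        if not np.isfinite(lp):
            return -np.inf
        params = spec.unpack(spec.from_unconstrained(z))
        try:
            ll = log_likelihood(dataset, spec, params, zip_weight=zip_weight)
        except FloatingPointError:
            return -np.inf
        return lp + ll

    z_draws, lps, acc = sample_posterior(log_post, z0, settings)
    natural = np.vstack([spec.from_unconstrained(z) for z in z_draws])
    return PosteriorResult(
        spec=spec,
        draws=pd.DataFrame(natural, columns=list(spec.param_names)),
        acceptance_rate=acc,
        settings=settings,
        k_grains=dataset.k_grains,
        zip_weight=zip_weight,
        log_post=lps,
    )


def dic(result: PosteriorResult, dataset: Dataset) -> tuple[float, float]:
    """Deviance information criterion.

    Returns ``(DIC, pD)`` with DIC = D̄ + pD, pD = D̄ - D(θ̄), D = -2ℓ, and
    θ̄ the posterior mean on the sampling scale.  A negative pD (poorly
    identified posterior) triggers a warning but is still returned.
    """
    spec = result.spec
    devs = np.array(
        [
            -2.0
            * log_likelihood(
                dataset, spec, spec.unpack(row), zip_weight=result.zip_weight
            )
            for row in result.draws.to_numpy()
        ]
    )
    d_bar = float(devs.mean())
    d_at_mean = -2.0 * log_likelihood(
        dataset,
        spec,
        spec.unpack(result.posterior_mean.to_numpy()),
        zip_weight=result.zip_weight,
    )
    p_d = d_bar - d_at_mean
    if p_d < 0:
        warnings.warn(f"pD = {p_d:.3g} < 0: poorly identified posterior")
    return d_bar + p_d, p_d


def posterior_predictive_band(
    result: PosteriorResult,
    distance_grid,
    fb_width: float,
    k_grains: float | None = None,
    n_draws: int = 20_000,
    seed: int = 0,
    aggregate: int = 1,
) -> "PredictiveBand":
    """95% posterior-predictive credible band for the CP rate vs distance.

    Per grid distance: resample parameter draws with replacement, simulate
    a per-cob count from the ZIP observation model, convert to CP% as
    100·y/K; the band is the empirical 2.5/97.5 percentile envelope and
    ``mean_cp`` the average simulated CP%.  ``aggregate > 1`` predicts the
    mean CP of that many cobs per grid instead of a single cob.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for stable percentiles")
    if aggregate < 1:
        raise ValueError("aggregate must be >= 1")
    k_grains = result.k_grains if k_grains is None else k_grains
    spec = result.spec
    distance_grid = np.asarray(distance_grid, dtype=float)
    rng = np.random.default_rng(seed)
    draws = result.draws.to_numpy()
    names = list(result.draws.columns)
    i_b1, i_b2 = names.index("b1"), names.index("b2")

    lower = np.empty(len(distance_grid))
    upper = np.empty(len(distance_grid))
    mean_cp = np.empty(len(distance_grid))
    for j, dist in enumerate(distance_grid):
        d_star = effective_distance(
            dist, fb_width, fb_effect=spec.fb_effect, kernel=spec.kernel
        )
        idx = rng.integers(len(draws), size=n_draws)
        sub = draws[idx]
        # evaluate the kernel once per unique draw, then scatter back
        uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
        gam = np.array([spec.gamma(d_star, fb_width, spec.unpack(row)) for row in uniq])
        gam_draws = gam[inverse]
        lam = k_grains * gam_draws
        q = mixing_weight(d_star, sub[:, i_b1], sub[:, i_b2])
        w = poisson_weight(q, result.zip_weight)
        if aggregate == 1:
            y = rng.poisson(lam)
            y = np.where(rng.random(n_draws) < w, y, 0)
        else:
            y = np.where(
                rng.random((n_draws, aggregate)) < w[:, None],
                rng.poisson(np.broadcast_to(lam[:, None], (n_draws, aggregate))),
                0,
            ).mean(axis=1)
        cp = 100.0 * y / k_grains
        lower[j] = np.percentile(cp, 2.5)
        upper[j] = np.percentile(cp, 97.5)
        mean_cp[j] = cp.mean()
    return PredictiveBand(
        distance_grid=distance_grid,
        fb_width=fb_width,
        mean_cp=mean_cp,
        lower_2_5=lower,
        upper_97_5=upper,
        n_draws=n_draws,
    )


@dataclass
class PredictiveBand:
    """Pointwise 95% posterior-predictive envelope of the CP rate."""

    distance_grid: np.ndarray
    fb_width: float
    mean_cp: np.ndarray
    lower_2_5: np.ndarray
    upper_97_5: np.ndarray
    n_draws: int

    def __post_init__(self) -> None:
        if np.any(self.lower_2_5 > self.upper_97_5 + 1e-12):
            raise ValueError("band lower bound exceeds upper bound")

    @property
    def width(self) -> np.ndarray:
        return self.upper_97_5 - self.lower_2_5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_m": self.distance_grid,
                "fb_width_m": self.fb_width,
                "mean_cp_percent": self.mean_cp,
                "lower_2_5_percent": self.lower_2_5,
                "upper_97_5_percent": self.upper_97_5,
            }
        )


def effective_sample_size(result: PosteriorResult) -> pd.Series:
    """Per-parameter effective sample size of the retained chain (arviz)."""
    import arviz as az

    data = az.convert_to_dataset(
        {c: result.draws[c].to_numpy()[None, :] for c in result.draws.columns}
    )
    ess = az.ess(data)
    return pd.Series({c: float(ess[c].values) for c in result.draws.columns})


def plot_band(band: PredictiveBand, ax=None, observed: pd.DataFrame | None = None):
    """Plot a predictive band (and optional observed grid CP rates)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(
        band.distance_grid,
        band.lower_2_5,
        band.upper_97_5,
        alpha=0.3,
        label="95% credible band",
    )
    ax.plot(band.distance_grid, band.mean_cp, label="predicted mean CP")
    if observed is not None:
        ax.scatter(
            observed["distance_m"], observed["cp_rate_percent"], s=12, c="k",
            label="observed grid CP",
        )
    ax.set_xlabel("distance (m)")
    ax.set_ylabel("CP rate (%)")
    ax.legend()
    return ax
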