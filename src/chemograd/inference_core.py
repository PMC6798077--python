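"""Bayesian machinery for one observation time.

The unknowns are the effective diffusivity ``D`` (mm^2/s), the advection
velocity ``u`` (mm/s) and the noise standard deviation ``sigma``
(normalized fluorescence units).  Measured profiles are modelled as the
forward solution plus additive i.i.d. Gaussian noise,
``Cbar(x_i, t) = C(x_i, t) + eps_i`` with ``eps_i ~ N(0, sigma^2)``, giving
the Gaussian log-likelihood used throughout.  Posteriors
``pi(theta | data) \\propto pi(data | theta) pi(theta)`` are sampled with a
random-walk Metropolis-Hastings chain whose proposal scales adapt during
burn-in only, and are summarized by mean, median, standard deviation and
95% highest-posterior-density intervals.  Posterior moments are condensed
into gamma distributions (``E = alpha/beta``, ``Var = alpha/beta^2``) for
sequential prior propagation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Sequence

import numpy as np

from .transport_model import ConcentrationProfile

__all__ = [
    "PriorSpec",
    "ParameterPoint",
    "PosteriorSamples",
    "ParameterSummary",
    "PosteriorSummary",
    "GammaApproximation",
    "MCMCDiagnostics",
    "log_likelihood",
    "log_posterior",
    "rw_metropolis",
    "hpd",
    "summarize",
    "fit_gamma_moments",
    "diagnostics",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("D", "u", "sigma")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior distribution for one non-negative parameter.

    Families: ``uniform(lower, upper)``, ``half_normal(scale)`` (the
    distribution of ``|Z|`` for ``Z ~ N(0, scale^2)``) and
    ``gamma(shape, rate)``.
    """

    family: str
    params: tuple[float, ...]

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(cls, lower: float, upper: float) -> "PriorSpec":
        if not lower < upper:
            raise ValueError("uniform prior needs lower < upper")
        if lower < 0:
            raise ValueError("prior support must lie in [0, inf)")
        return cls("uniform", (float(lower), float(upper)))

    @classmethod
    def half_normal(cls, scale: float) -> "PriorSpec":
        if not scale > 0:
            raise ValueError("half-normal scale must be positive")
        return cls("half_normal", (float(scale),))

    @classmethod
    def gamma(cls, shape: float, rate: float) -> "PriorSpec":
        if not (shape > 0 and rate > 0):
            raise ValueError("gamma prior needs shape > 0 and rate > 0")
        return cls("gamma", (float(shape), float(rate)))

    # -- densities and summaries ----------------------------------------
    def in_support(self, x: float) -> bool:
        if self.family == "uniform":
            lo, hi = self.params
            return lo <= x <= hi
        return x >= 0 if self.family == "half_normal" else x > 0

    def logpdf(self, x: float) -> float:
        if not self.in_support(x):
            return -math.inf
        if self.family == "uniform":
            lo, hi = self.params
            return -math.log(hi - lo)
        if self.family == "half_normal":
            (s,) = self.params
            return math.log(2.0) - 0.5 * _LOG_2PI - math.log(s) - x * x / (2.0 * s * s)
        a, b = self.params
        return a * math.log(b) - math.lgamma(a) + (a - 1.0) * math.log(x) - b * x

    @cached_property
    def _dist(self):
        from scipy import stats

        if self.family == "uniform":
            lo, hi = self.params
            return stats.uniform(lo, hi - lo)
        if self.family == "half_normal":
            return stats.halfnorm(scale=self.params[0])
        a, b = self.params
        return stats.gamma(a, scale=1.0 / b)

    def median(self) -> float:
        return float(self._dist.median())

    def mean(self) -> float:
        return float(self._dist.mean())

    def sd(self) -> float:
        return float(self._dist.std())


@dataclass(frozen=True)
class ParameterPoint:
    """One point ``theta = (D, u, sigma)`` in parameter space."""

    D: float
    u: float
    sigma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.u, self.sigma])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ParameterPoint":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws per parameter, with chain metadata."""

    draws: dict[str, np.ndarray]
    acceptance_rate: float
    seed: int
    n_iterations: int
    n_burn_in: int
    thinning: int

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.draws.values()}
        if len(lengths) != 1:
            raise ValueError("unequal draw counts across parameters")

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).size


@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    median: float
    sd: float
    hpd_low: float
    hpd_high: float


@dataclass
class PosteriorSummary:
    """Per-parameter posterior location/spread/credible-interval summary."""

    parameters: dict[str, ParameterSummary]
    hpd_mass: float = 0.95

    def __getitem__(self, name: str) -> ParameterSummary:
        return self.parameters[name]


@dataclass(frozen=True)
class GammaApproximation:
    """Gamma distribution ``Gamma(shape, rate)`` matched to sample moments."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    def as_prior(self) -> PriorSpec:
        return PriorSpec.gamma(self.shape, self.rate)


@dataclass
class MCMCDiagnostics:
    """Mixing/convergence diagnostics per parameter."""

    ess: dict[str, float]
    autocorrelations: dict[str, np.ndarray]
    split_half_discrepancy: dict[str, float]
    degenerate: dict[str, bool]


# ---------------------------------------------------------------------------
# likelihood and posterior
# ---------------------------------------------------------------------------

def log_likelihood(
    point: ParameterPoint,
    observed: ConcentrationProfile,
    predicted: ConcentrationProfile,
) -> float:
    """Gaussian log-likelihood of the observed profile given the model one.

    ``sum_i log N(observed_i; predicted_i, sigma^2)``.
    """
    if point.sigma <= 0:
        raise ValueError("sigma must be positive (degenerate likelihood)")
    if observed.positions.shape != predicted.positions.shape or not np.allclose(
        observed.positions, predicted.positions
    ):
        raise ValueError("observed and predicted profiles are on different positions")
    r = observed.values - predicted.values
    n = r.size
    s2 = point.sigma**2
    return -0.5 * n * (_LOG_2PI + math.log(s2)) - float(r @ r) / (2.0 * s2)


def log_posterior(
    point: ParameterPoint,
    priors: dict[str, PriorSpec],
    forward: Callable[[float, float], ConcentrationProfile],
    observed: ConcentrationProfile,
) -> float:
    """Unnormalized log-posterior ``log pi(data|theta) + log pi(theta)``.

    Returns ``-inf`` outside the prior support without invoking the forward
    model; forward-solver failures propagate as exceptions, never ``-inf``.
    """
    lp = 0.0
    for name, value in zip(PARAM_NAMES, point.as_array()):
        contrib = priors[name].logpdf(value)
        if contrib == -math.inf:
            return -math.inf
        lp += contrib
    predicted = forward(point.D, point.u)
    return lp + log_likelihood(point, observed, predicted)


# ---------------------------------------------------------------------------
# random-walk Metropolis-Hastings
# ---------------------------------------------------------------------------

def rw_metropolis(
    logpost: Callable[[np.ndarray], float],
    init: Sequence[float],
    n_iter: int,
    proposal_scales: Sequence[float],
    seed: int,
    *,
    burn_in: int = 0,
    thinning: int = 1,
    adapt: bool = True,
    adapt_interval: int = 50,
    param_names: Sequence[str] | None = None,
) -> PosteriorSamples:
    """Random-walk Metropolis-Hastings with burn-in-only adaptation.

    One joint Gaussian step per iteration with independent per-parameter
    scales.  During burn-in the overall scale is multiplied up/down to keep
    block acceptance inside [0.2, 0.5], and the relative scales are refreshed
    from the recent chain's per-parameter spread; adaptation is frozen after
    burn-in so the retained chain is a valid Metropolis-Hastings sample.
    Bit-reproducible for a fixed seed.
    """
    x = np.asarray(init, dtype=float)
    dim = x.size
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    names = tuple(param_names) if param_names is not None else tuple(
        f"p{i}" for i in range(dim)
    )
    lp = float(logpost(x))
    if not math.isfinite(lp):
        raise ValueError("initial point outside support (log-posterior not finite)")

    rng = np.random.default_rng(seed)
    base = np.asarray(proposal_scales, dtype=float).copy()
    if base.size != dim or np.any(base <= 0):
        raise ValueError("proposal_scales must be positive, one per parameter")
    factor = 1.0
    opt = 2.4 / math.sqrt(dim)  # classic random-walk prefactor

    chain = np.empty((n_iter, dim))
    accepted_post = 0
    accepted_block = 0
    for it in range(n_iter):
        prop = x + rng.standard_normal(dim) * (base * factor)
        lpp = float(logpost(prop))
        if lpp - lp > math.log(rng.uniform()):
            x, lp = prop, lpp
            accepted_block += 1
            if it >= burn_in:
                accepted_post += 1
        chain[it] = x
        if adapt and it < burn_in and (it + 1) % adapt_interval == 0:
            acc = accepted_block / adapt_interval
            accepted_block = 0
            if acc < 0.2:
                factor /= 1.7
            elif acc > 0.5:
                factor *= 1.7
            factor = min(max(factor, 1e-12), 1e3)
            recent = chain[max(0, it + 1 - 10 * adapt_interval): it + 1]
            sd = recent.std(axis=0)
            if np.all(sd > 0):
                base = opt * sd
                factor = min(max(factor, 0.1), 10.0)
        elif it >= burn_in:
            accepted_block = 0  # unused after burn-in; kept tidy

    kept = chain[burn_in::thinning]
    n_post = n_iter - burn_in
    acc_rate = accepted_post / n_post
    return PosteriorSamples(
        draws={name: kept[:, i].copy() for i, name in enumerate(names)},
        acceptance_rate=acc_rate,
        seed=seed,
        n_iterations=n_iter,
        n_burn_in=burn_in,
        thinning=thinning,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd(draws: Sequence[float], mass: float) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    This is the highest-posterior-density credible interval for a unimodal
    sample.  Ties between equally short windows break toward the lower
    start.
    """
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = d[m - 1:] - d[: n - m + 1]
    j = int(np.argmin(widths))  # first minimum -> lowest start on ties
    return float(d[j]), float(d[j + m - 1])


def summarize(samples: PosteriorSamples, mass: float = 0.95) -> PosteriorSummary:
    """Mean, median, sd and HPD interval for every sampled parameter."""
    out: dict[str, ParameterSummary] = {}
    for name, d in samples.draws.items():
        if d.size == 0:
            raise ValueError("no post-burn-in draws to summarize")
        if np.ptp(d) == 0:
            c = float(d[0])
            out[name] = ParameterSummary(c, c, 0.0, c, c)
            continue
        lo, hi = hpd(d, mass)
        mean = float(np.mean(d))
        med = float(np.median(d))
        if not lo <= mean <= hi:
            logger.warning(
                "posterior mean of %r outside its %g HPD interval "
                "(extremely skewed sample)", name, mass,
            )
        out[name] = ParameterSummary(mean, med, float(np.std(d)), lo, hi)
    return PosteriorSummary(parameters=out, hpd_mass=mass)


def fit_gamma_moments(mean: float, variance: float) -> GammaApproximation:
    """Gamma distribution with the given mean and variance.

    Inverts ``E = alpha/beta`` and ``Var = alpha/beta^2``:
    ``alpha = mean^2/variance``, ``beta = mean/variance``; round-trips
    exactly.
    """
    if not mean > 0:
        raise ValueError(f"gamma moment fit needs mean > 0, got {mean}")
    if not variance > 0:
        raise ValueError(f"gamma moment fit needs variance > 0, got {variance}")
    return GammaApproximation(shape=mean * mean / variance, rate=mean / variance)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _autocorrelation(d: np.ndarray, max_lag: int) -> np.ndarray:
    n = d.size
    c = d - d.mean()
    # FFT-based autocovariance
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(c, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1].real / n
    return acov / acov[0]


def diagnostics(samples: PosteriorSamples, max_lag: int = 100) -> MCMCDiagnostics:
    """Effective sample size, autocorrelations and split-half discrepancy.

    ESS uses the autocorrelation-sum estimator truncated at the first
    non-positive consecutive pair (initial positive sequence), capped at the
    number of draws.  A constant (degenerate) chain is flagged and reported
    with ESS equal to the number of draws.  The split-half discrepancy is
    the absolute difference between first- and second-half means in units
    of the whole-chain standard deviation.
    """
    ess: dict[str, float] = {}
    acfs: dict[str, np.ndarray] = {}
    split: dict[str, float] = {}
    degen: dict[str, bool] = {}
    for name, d in samples.draws.items():
        n = d.size
        if n < 100:
            raise ValueError("need at least 100 post-burn-in draws for diagnostics")
        L = min(max_lag, n - 1)
        if np.ptp(d) == 0:
            acf = np.zeros(L + 1)
            acf[0] = 1.0
            ess[name] = float(n)
            acfs[name] = acf
            split[name] = 0.0
            degen[name] = True
            continue
        acf = _autocorrelation(d, min(n - 1, max(L, 2 * (n // 2) - 1)))
        # truncate at the first non-positive consecutive pair
        tau = 1.0
        k = 1
        while k + 1 < acf.size:
            pair = acf[k] + acf[k + 1]
            if pair <= 0:
                break
            tau += 2.0 * pair
            k += 2
        ess[name] = float(min(n, n / tau))
        acfs[name] = acf[: L + 1]
        half = n // 2
        split[name] = float(abs(d[:half].mean() - d[half:].mean()) / d.std())
        degen[name] = False
    return MCMCDiagnostics(
        ess=ess, autocorrelations=acfs, split_half_discrepancy=split, degenerate=degen
    )
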