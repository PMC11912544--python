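"""Univariate distributions used as ABC priors and refitted posteriors.

Each ABC iteration refits a distribution to the accepted samples of every
variable independently.  A catalog of parametric families (normal, lognormal,
gamma, Weibull, Nakagami, Burr XII, generalized extreme value) is fitted by
maximum likelihood and the winner selected by AIC; when no parametric family
survives a Kolmogorov-Smirnov goodness-of-fit screen, or the sample is too
small or degenerate, a Gaussian kernel density estimate is used instead.
Stage 2 additionally fits two-component normal mixtures (EM) for the bimodal
pooled posteriors that arise when per-experiment calibrations disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Distribution",
    "Normal",
    "HalfNormal",
    "ParametricFit",
    "KernelDensity",
    "NormalMixture",
    "EqualMixture",
    "FAMILY_CATALOG",
    "fit_posterior",
    "fit_bimodal",
    "distribution_from_dict",
]


class Distribution:
    """Minimal sampling/density interface shared by all prior/posterior fits."""

    name: str = "distribution"

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def median(self) -> float:
        raise NotImplementedError

    def interval(self, level: float) -> tuple[float, float]:
        """Central credible interval at the given level, by quantiles."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass
class Normal(Distribution):
    mu: float
    sigma: float
    name: str = "normal"

    def sample(self, rng, size):
        return rng.normal(self.mu, self.sigma, size)

    def logpdf(self, x):
        return stats.norm.logpdf(x, self.mu, self.sigma)

    def median(self):
        return self.mu

    def interval(self, level):
        lo, hi = stats.norm.interval(level, self.mu, self.sigma)
        return float(lo), float(hi)

    def to_dict(self):
        return {"family": "normal", "mu": self.mu, "sigma": self.sigma}


@dataclass
class HalfNormal(Distribution):
    """Half-normal at zero: used for the initial endothelial activation of
    experiments whose baseline pressure gradient is zero."""

    sigma: float
    name: str = "halfnormal"

    def sample(self, rng, size):
        return np.abs(rng.normal(0.0, self.sigma, size))

    def logpdf(self, x):
        return stats.halfnorm.logpdf(x, scale=self.sigma)

    def median(self):
        return float(stats.halfnorm.median(scale=self.sigma))

    def interval(self, level):
        a = (1.0 - level) / 2.0
        return (float(stats.halfnorm.ppf(a, scale=self.sigma)),
                float(stats.halfnorm.ppf(1.0 - a, scale=self.sigma)))

    def to_dict(self):
        return {"family": "halfnormal", "sigma": self.sigma}


# scipy distribution, fit with loc fixed at 0 when the data are positive
FAMILY_CATALOG: dict[str, tuple] = {
    "normal": (stats.norm, False),
    "lognormal": (stats.lognorm, True),
    "gamma": (stats.gamma, True),
    "weibull": (stats.weibull_min, True),
    "nakagami": (stats.nakagami, True),
    "burr": (stats.burr12, True),
    "genextreme": (stats.genextreme, False),
}


@dataclass
class ParametricFit(Distribution):
    family: str
    params: tuple

    @property
    def name(self):
        return self.family

    @property
    def _dist(self):
        return FAMILY_CATALOG[self.family][0](*self.params)

    def sample(self, rng, size):
        return self._dist.rvs(size=size, random_state=rng)

    def logpdf(self, x):
        return self._dist.logpdf(x)

    def median(self):
        return float(self._dist.median())

    def interval(self, level):
        a = (1.0 - level) / 2.0
        return float(self._dist.ppf(a)), float(self._dist.ppf(1.0 - a))

    def to_dict(self):
        return {"family": self.family, "params": list(self.params)}


@dataclass
class KernelDensity(Distribution):
    """Gaussian KDE over stored samples (the fallback fit)."""

    samples: np.ndarray
    bandwidth_factor: float = 1.0
    name: str = "kernel"

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        self.samples = x
        spread = float(np.std(x))
        if spread == 0.0 or len(x) < 2:
            # degenerate sample: a narrow Gaussian around the common value
            scale = max(abs(float(np.mean(x))), 1.0) if len(x) else 1.0
            self._degenerate = Normal(float(np.mean(x)) if len(x) else 0.0,
                                      1e-6 * scale)
            self._kde = None
        else:
            self._degenerate = None
            self._kde = stats.gaussian_kde(x, bw_method="scott")
            self._kde.set_bandwidth(self._kde.factor * self.bandwidth_factor)

    def sample(self, rng, size):
        if self._degenerate is not None:
            return self._degenerate.sample(rng, size)
        idx = rng.integers(0, len(self.samples), size)
        h = np.sqrt(self._kde.covariance[0, 0])
        return self.samples[idx] + rng.normal(0.0, h, size)

    def logpdf(self, x):
        if self._degenerate is not None:
            return self._degenerate.logpdf(x)
        return np.log(np.maximum(self._kde.evaluate(np.atleast_1d(x)), 1e-300))

    def median(self):
        return float(np.median(self.samples))

    def interval(self, level):
        a = (1.0 - level) / 2.0
        return (float(np.quantile(self.samples, a)),
                float(np.quantile(self.samples, 1.0 - a)))

    def to_dict(self):
        return {"family": "kernel", "samples": self.samples.tolist(),
                "bandwidth_factor": self.bandwidth_factor}


@dataclass
class NormalMixture(Distribution):
    """Weighted mixture of two normal components."""

    w: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    name: str = "normal-mixture"

    def sample(self, rng, size):
        pick = rng.random(size) < self.w
        out = np.where(pick,
                       rng.normal(self.mu1, self.sigma1, size),
                       rng.normal(self.mu2, self.sigma2, size))
        return out

    def logpdf(self, x):
        p = (self.w * stats.norm.pdf(x, self.mu1, self.sigma1)
             + (1.0 - self.w) * stats.norm.pdf(x, self.mu2, self.sigma2))
        return np.log(np.maximum(p, 1e-300))

    def _quantile(self, q):
        lo = min(self.mu1 - 10 * self.sigma1, self.mu2 - 10 * self.sigma2)
        hi = max(self.mu1 + 10 * self.sigma1, self.mu2 + 10 * self.sigma2)
        from scipy.optimize import brentq
        cdf = lambda x: (self.w * stats.norm.cdf(x, self.mu1, self.sigma1)
                         + (1 - self.w) * stats.norm.cdf(x, self.mu2, self.sigma2) - q)
        return brentq(cdf, lo, hi)

    def median(self):
        return float(self._quantile(0.5))

    def interval(self, level):
        a = (1.0 - level) / 2.0
        return float(self._quantile(a)), float(self._quantile(1.0 - a))

    def to_dict(self):
        return {"family": "normal-mixture", "w": self.w, "mu1": self.mu1,
                "sigma1": self.sigma1, "mu2": self.mu2, "sigma2": self.sigma2}


@dataclass
class EqualMixture(Distribution):
    """Equal-probability mixture of arbitrary components (stage-2 pooling)."""

    components: Sequence[Distribution]
    name: str = "equal-mixture"

    def sample(self, rng, size):
        k = len(self.components)
        pick = rng.integers(0, k, size)
        out = np.empty(size)
        for i, comp in enumerate(self.components):
            m = pick == i
            if m.any():
                out[m] = comp.sample(rng, int(m.sum()))
        return out

    def logpdf(self, x):
        x = np.atleast_1d(x)
        p = np.mean([np.exp(c.logpdf(x)) for c in self.components], axis=0)
        return np.log(np.maximum(p, 1e-300))

    def median(self):
        rng = np.random.default_rng(0)
        return float(np.median(self.sample(rng, 4001)))

    def interval(self, level):
        rng = np.random.default_rng(0)
        x = self.sample(rng, 4001)
        a = (1.0 - level) / 2.0
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def to_dict(self):
        return {"family": "equal-mixture",
                "components": [c.to_dict() for c in self.components]}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _aic(logpdf_vals: np.ndarray, k: int) -> float:
    return 2.0 * k - 2.0 * float(np.sum(logpdf_vals))


def fit_posterior(samples: np.ndarray, min_samples: int = 30,
                  ks_alpha: float = 0.01, max_fit_n: int = 1000,
                  rng: np.random.Generator | None = None) -> Distribution:
    """Best univariate fit to posterior samples, with kernel fallback.

    Every catalog family is fitted by MLE (positive-support families with the
    location pinned at zero when the data are positive) and the winner chosen
    by AIC over the full sample; a family that fails the KS goodness-of-fit
    screen at ``ks_alpha`` is discarded.  Fewer than ``min_samples`` samples,
    degenerate samples, or no surviving family all fall back to a Gaussian
    KDE (with a widened bandwidth in the small-sample case).
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_samples or np.std(x) == 0.0:
        return KernelDensity(x, bandwidth_factor=2.0)
    if rng is None:
        rng = np.random.default_rng(0)
    x_fit = x if len(x) <= max_fit_n else rng.choice(x, max_fit_n, replace=False)

    best: tuple[float, Distribution] | None = None
    for fam, (dist, positive_support) in FAMILY_CATALOG.items():
        if positive_support and np.min(x) <= 0.0:
            continue
        try:
            with np.errstate(all="ignore"):
                if positive_support:
                    params = dist.fit(x_fit, floc=0)
                else:
                    params = dist.fit(x_fit)
                lp = dist.logpdf(x, *params)
                if not np.all(np.isfinite(lp)):
                    continue
                aic = _aic(lp, len(params))
                ks = stats.kstest(x_fit, dist.cdf, args=params)
        except Exception:
            continue
        if ks.pvalue < ks_alpha:
            continue
        if best is None or aic < best[0]:
            best = (aic, ParametricFit(fam, tuple(float(p) for p in params)))
    if best is None:
        return KernelDensity(x)
    return best[1]


def fit_bimodal(samples: np.ndarray, min_samples: int = 100,
                seed: int = 0) -> Distribution:
    """Two-component normal mixture by EM, kept only if it beats the best
    univariate fit on AIC; degenerate EM solutions fall back to univariate."""
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    univariate = fit_posterior(x)
    if len(x) < min_samples or np.std(x) == 0.0:
        return univariate
    from sklearn.mixture import GaussianMixture
    gm = GaussianMixture(n_components=2, n_init=4, random_state=seed,
                         reg_covar=1e-10)
    try:
        gm.fit(x.reshape(-1, 1))
    except Exception:
        return univariate
    w = float(gm.weights_[0])
    mus = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    if min(w, 1.0 - w) < 0.02 or np.any(sigmas < 1e-12 * max(1.0, abs(mus).max())):
        return univariate
    mixture = NormalMixture(w, float(mus[0]), float(sigmas[0]),
                            float(mus[1]), float(sigmas[1]))
    aic_mix = _aic(mixture.logpdf(x), 5)
    aic_uni = _aic(univariate.logpdf(x), _k_of(univariate))
    return mixture if aic_mix < aic_uni else univariate


def _k_of(dist: Distribution) -> int:
    if isinstance(dist, ParametricFit):
        return len(dist.params)
    if isinstance(dist, (Normal, HalfNormal)):
        return 2
    return 3  # effective complexity charged to the kernel fallback


def distribution_from_dict(d: dict) -> Distribution:
    """Inverse of ``Distribution.to_dict`` for JSON round-trips."""
    fam = d["family"]
    if fam == "normal":
        return Normal(d["mu"], d["sigma"])
    if fam == "halfnormal":
        return HalfNormal(d["sigma"])
    if fam == "kernel":
        return KernelDensity(np.asarray(d["samples"]),
                             d.get("bandwidth_factor", 1.0))
    if fam == "normal-mixture":
        return NormalMixture(d["w"], d["mu1"], d["sigma1"], d["mu2"], d["sigma2"])
    if fam == "equal-mixture":
        return EqualMixture([distribution_from_dict(c) for c in d["components"]])
    if fam in FAMILY_CATALOG:
        return ParametricFit(fam, tuple(d["params"]))
    raise ValueError(f"unknown distribution family {fam!r}")
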