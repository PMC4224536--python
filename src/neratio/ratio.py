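"""Propagation of uniform priors on (theta_n, theta_m, mu_n, mu_m) to the
posterior of the biparental-to-maternal effective-size ratio.

The effective sizes follow Ne = theta_n / (4 mu_n) for biparentally
inherited diploid loci and Nef = theta_m / (2 mu_m) for the maternally
inherited haploid locus, so the ratio is

    Ne : Nef = theta_n * mu_m / (2 * theta_m * mu_n).

All four parameters carry independent uniform priors, and the ratio is a
deterministic transform, so plain Monte-Carlo sampling targets exactly the
same posterior that an MCMC over the same priors would.  The ideal
random-mating expectation is Ne:Nef = 2; the reported "reduction" is
100 * (1 - ratio / 2) percent.

In the default "published" mode mu_m is used on its published
substitutions/locus/year scale while mu_n is per generation -- the unit
combination under which the published point estimates reproduce.  The
"adjusted" mode multiplies mu_m by the generation time first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PriorSpec",
    "RatioPosterior",
    "RatioSummary",
    "sample_ratio_posterior",
    "analytic_mean_ratio",
    "analytic_ratio_moments",
    "effective_size",
    "summarize",
]

MODES = ("published", "adjusted")


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for the four propagated parameters.

    Defaults are the published analysis inputs: theta_n ~ U[10.0, 16.5],
    theta_m ~ U[0.01, 0.05] (the 95% credible ranges of the coalescent
    theta posteriors), mu_n ~ U[1e-5, 1e-3] substitutions/locus/generation
    and mu_m ~ U[1e-8, 1e-7] substitutions/locus/year from the literature.
    Degenerate bounds (lo == hi) are allowed for point priors.
    """

    theta_n: tuple[float, float] = (10.0, 16.5)
    theta_m: tuple[float, float] = (0.01, 0.05)
    mu_n: tuple[float, float] = (1e-5, 1e-3)
    mu_m: tuple[float, float] = (1e-8, 1e-7)
    generation_time: float = 3.0

    def __post_init__(self):
        for name in ("theta_n", "theta_m", "mu_n", "mu_m"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} bounds must satisfy 0 < lo <= hi")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


@dataclass
class RatioPosterior:
    """Joint Monte-Carlo draws of the parameters and derived quantities."""

    theta_n: np.ndarray = field(repr=False)
    theta_m: np.ndarray = field(repr=False)
    mu_n: np.ndarray = field(repr=False)
    mu_m: np.ndarray = field(repr=False)
    ne: np.ndarray = field(repr=False)
    nef: np.ndarray = field(repr=False)
    ratio: np.ndarray = field(repr=False)
    reduction_pct: np.ndarray = field(repr=False)
    n_samples: int = 0
    seed: int = 0
    mode: str = "published"
    priors: PriorSpec | None = None


@dataclass
class RatioSummary:
    """Reporting summary of a ratio posterior."""

    mean: float
    sd: float
    ci95: tuple[float, float]
    reduction_mean_pct: int
    reduction_range_pct: tuple[int, int]
    ne_mean: float
    nef_mean: float
    mode: str
    n_samples: int
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(self.ci95)
        d["reduction_range_pct"] = list(self.reduction_range_pct)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _uniform(rng, bounds, size):
    lo, hi = bounds
    if lo == hi:
        return np.full(size, float(lo))
    return rng.uniform(lo, hi, size)


def sample_ratio_posterior(
    priors: PriorSpec,
    n_samples: int = 1_000_000,
    seed: int = 0,
    mode: str = "published",
) -> RatioPosterior:
    """Draw the joint posterior of (parameters, Ne, Nef, ratio, reduction).

    iid draws from the four uniform priors are pushed through the
    effective-size equations row-wise.  ``mode="adjusted"`` converts mu_m
    from per-year to per-generation using ``priors.generation_time``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    tn = _uniform(rng, priors.theta_n, n_samples)
    tm = _uniform(rng, priors.theta_m, n_samples)
    mn = _uniform(rng, priors.mu_n, n_samples)
    mm = _uniform(rng, priors.mu_m, n_samples)
    mm_eff = mm * priors.generation_time if mode == "adjusted" else mm
    ne = tn / (4.0 * mn)
    nef = tm / (2.0 * mm_eff)
    ratio = ne / nef
    return RatioPosterior(
        theta_n=tn,
        theta_m=tm,
        mu_n=mn,
        mu_m=mm,
        ne=ne,
        nef=nef,
        ratio=ratio,
        reduction_pct=100.0 * (1.0 - ratio / 2.0),
        n_samples=int(n_samples),
        seed=int(seed),
        mode=mode,
        priors=priors,
    )


def _mean_uniform(bounds) -> float:
    return 0.5 * (bounds[0] + bounds[1])


def _mean_inv_uniform(bounds) -> float:
    lo, hi = bounds
    if lo == hi:
        return 1.0 / lo
    return float(np.log(hi / lo) / (hi - lo))


def _m2_uniform(bounds) -> float:
    lo, hi = bounds
    return (lo * lo + lo * hi + hi * hi) / 3.0


def _m2_inv_uniform(bounds) -> float:
    return 1.0 / (bounds[0] * bounds[1])


def analytic_mean_ratio(priors: PriorSpec, mode: str = "published") -> float:
    """Closed-form posterior mean of the ratio (independence of the four
    uniforms: E[ratio] = E[theta_n] E[mu_m] E[1/theta_m] E[1/mu_n] / 2,
    with E[1/U(a,b)] = log(b/a)/(b-a))."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    g = priors.generation_time if mode == "adjusted" else 1.0
    return (
        _mean_uniform(priors.theta_n)
        * _mean_uniform(priors.mu_m)
        * g
        * _mean_inv_uniform(priors.theta_m)
        * _mean_inv_uniform(priors.mu_n)
        / 2.0
    )


def analytic_ratio_moments(priors: PriorSpec, mode: str = "published"):
    """Closed-form (mean, sd) of the ratio; second moments use
    E[X^2] = (a^2+ab+b^2)/3 and E[1/X^2] = 1/(ab) for X ~ U(a, b)."""
    m = analytic_mean_ratio(priors, mode)
    g = priors.generation_time if mode == "adjusted" else 1.0
    m2 = (
        _m2_uniform(priors.theta_n)
        * _m2_uniform(priors.mu_m)
        * g
        * g
        * _m2_inv_uniform(priors.theta_m)
        * _m2_inv_uniform(priors.mu_n)
        / 4.0
    )
    return m, float(np.sqrt(m2 - m * m))


def effective_size(theta: float, mu: float, ploidy_factor: int) -> float:
    """N = theta / (ploidy_factor * mu); factor 4 for biparental diploid
    loci, 2 for the maternally inherited haploid locus."""
    if ploidy_factor not in (2, 4):
        raise ValueError("ploidy_factor must be 2 or 4")
    if mu <= 0:
        raise ValueError("mu must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta / (ploidy_factor * mu)


def summarize(posterior: RatioPosterior) -> RatioSummary:
    """Mean, population SD and equal-tail 95% CI of the ratio draws, plus
    the rounded reduction percentages (range bounds come from the CI: the
    lower reduction from the CI upper bound and vice versa)."""
    r = posterior.ratio
    if r.size < 10_000:
        raise ValueError("need at least 10^4 draws for stable quantiles")
    lo, hi = np.quantile(r, [0.025, 0.975])
    mean = float(r.mean())
    return RatioSummary(
        mean=mean,
        sd=float(r.std(ddof=0)),
        ci95=(float(lo), float(hi)),
        reduction_mean_pct=int(round(100.0 * (1.0 - mean / 2.0))),
        reduction_range_pct=(
            int(round(100.0 * (1.0 - float(hi) / 2.0))),
            int(round(100.0 * (1.0 - float(lo) / 2.0))),
        ),
        ne_mean=float(posterior.ne.mean()),
        nef_mean=float(posterior.nef.mean()),
        mode=posterior.mode,
        n_samples=posterior.n_samples,
        seed=posterior.seed,
    )
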