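"""Estimators of the population-scaled mutation parameter theta.

Fast moment estimators (Watterson from segregating sites; stepwise-model
inversions from heterozygosity or allele-size variance) serve as
cross-checks for the Bayesian coalescent samplers, which integrate over
the latent genealogy by MCMC and return a posterior with a 95% credible
interval, mirroring a single-population Migrate-style analysis at desk
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .datatypes import GenotypeMatrix, SequenceAlignment
from .diversity import site_summary
from .mcmc import (
    McmcOptions,
    MicrosatelliteModel,
    SequenceModel,
    effective_sample_size,
    initial_trees,
    microsat_tip_values,
    run_sampler,
    upgma_genealogy,
)

__all__ = [
    "watterson_theta",
    "smm_theta_from_heterozygosity",
    "smm_theta_from_size_variance",
    "harmonic_number",
    "ThetaPosterior",
    "McmcOptions",
    "bayes_theta_sequences",
    "bayes_theta_microsatellites",
    "credible_interval",
]


def harmonic_number(m: int) -> float:
    """H_m = sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int, L: int | None = None) -> float:
    """Watterson's moment estimator theta = S / H_{n-1}.

    Per-locus when ``L`` is None, per site when the alignment length ``L``
    is given.
    """
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if S < 0:
        raise ValueError("S must be non-negative")
    theta = S / harmonic_number(n - 1)
    if L is not None:
        theta /= L
    return theta


def smm_theta_from_heterozygosity(H: float) -> float:
    """Invert the SMM equilibrium H = 1 - 1/sqrt(1 + 2*theta)."""
    if not (0.0 <= H < 1.0):
        raise ValueError("H must lie in [0, 1)")
    return ((1.0 / (1.0 - H)) ** 2 - 1.0) / 2.0


def smm_theta_from_size_variance(V: float) -> float:
    """SMM moment estimator from within-sample allele-size variance: 2V."""
    if V < 0:
        raise ValueError("variance must be non-negative")
    return 2.0 * V


@dataclass
class ThetaPosterior:
    """Post-burn-in theta draws with point estimates and diagnostics."""

    samples: np.ndarray = field(repr=False)
    prior_bounds: tuple[float, float]
    mean: float = field(init=False)
    mode: float = field(init=False)
    ci95: tuple[float, float] = field(init=False)
    ess: float = field(init=False)
    acceptance: dict = field(default_factory=dict)
    converged: bool = field(init=False, default=True)
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict, repr=False)
    ess_threshold: float = 50.0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        self.samples = s
        self.mean = float(s.mean())
        self.mode = _posterior_mode(s, self.prior_bounds)
        self.ci95 = credible_interval(self, 0.95)
        self.ess = effective_sample_size(s)
        self.converged = bool(self.ess >= self.ess_threshold)
        if not self.converged:
            self.flags.append("low_ess")
        lo, hi = self.prior_bounds
        if float(np.median(s)) < lo + 0.02 * (hi - lo):
            self.flags.append("piled_at_lower_bound")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "mode": self.mode,
            "ci95": list(self.ci95),
            "ess": self.ess,
            "n_samples": int(self.samples.size),
            "prior_bounds": list(self.prior_bounds),
            "acceptance": self.acceptance,
            "converged": self.converged,
            "flags": self.flags,
        }


def _posterior_mode(samples: np.ndarray, bounds: tuple[float, float]) -> float:
    if np.std(samples) == 0:
        return float(samples[0])
    kde = gaussian_kde(samples)
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def credible_interval(posterior, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail empirical credible interval from posterior samples.

    Accepts a :class:`ThetaPosterior` or a raw sample array (>= 100 draws).
    """
    samples = getattr(posterior, "samples", posterior)
    samples = np.asarray(samples, dtype=float)
    if samples.size < 100:
        raise ValueError("need at least 100 posterior samples")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [a, 1.0 - a])
    return float(lo), float(hi)


def bayes_theta_sequences(
    alignment: SequenceAlignment,
    prior_bounds: tuple[float, float] = (0.0, 0.1),
    R: float = 33.0,
    options: McmcOptions | None = None,
    prior_only: bool = False,
) -> ThetaPosterior:
    """Posterior of the per-site theta of a sequence alignment.

    Metropolis-Hastings over (genealogy, theta): node-time and
    prune-regraft updates of the latent coalescent genealogy, reflected
    random-walk updates of theta, pruning likelihood under the Ti/Tv
    substitution model with ratio ``R`` and a bounded uniform theta prior.
    Non-convergence (low ESS) is flagged, not raised.
    """
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences for the coalescent sampler")
    opts = options or McmcOptions()
    model = SequenceModel(alignment, R)
    trees = initial_trees([alignment.n_sequences], np.random.SeedSequence([opts.seed, 1]))
    lo, hi = prior_bounds
    if prior_only:
        theta0 = 0.5 * (lo + hi)
    else:
        ss = site_summary(alignment)
        theta0 = watterson_theta(
            ss["segregating_sites"], alignment.n_sequences, ss["n_sites_used"]
        )
    res = run_sampler(model, trees, prior_bounds, opts, theta0, prior_only=prior_only)
    return ThetaPosterior(
        res.samples,
        (float(lo), float(hi)),
        acceptance=res.acceptance,
        extras={"root_time_trace": res.root_time_trace},
        ess_threshold=opts.ess_threshold,
    )


def bayes_theta_microsatellites(
    genotypes: GenotypeMatrix,
    prior_bounds: tuple[float, float] = (0.0, 100.0),
    options: McmcOptions | None = None,
    prior_only: bool = False,
    max_tips_per_locus: int | None = 24,
) -> ThetaPosterior:
    """Posterior of the per-locus theta of a microsatellite dataset.

    Diploid genotypes unfold to 2n haploid tip lineages per locus, each
    locus carrying an independent latent genealogy; the tip allele sizes
    are modelled as a Brownian process (the continuous analogue of the
    stepwise mutation model) with variance theta/2 per coalescent-time
    unit, root state integrated out (REML contrasts).

    When a locus has more than ``max_tips_per_locus`` gene copies, a
    random subsample of that many is analysed (deterministic under the
    options seed).  Coalescent information about theta saturates quickly
    with sample size, while genealogy-space mixing degrades sharply, so
    desk-scale chains on very large trees return pseudo-converged,
    topology-frozen posteriors; pass ``None`` to analyse all lineages.
    """
    opts = options or McmcOptions()
    values = microsat_tip_values(genotypes)
    if max_tips_per_locus is not None:
        sub_rng = np.random.default_rng(np.random.SeedSequence([opts.seed, 3]))
        values = [
            (
                v[np.sort(sub_rng.choice(v.size, max_tips_per_locus, replace=False))]
                if v.size > max_tips_per_locus
                else v
            )
            for v in values
        ]
    sizes = [v.size for v in values]
    if any(s < 2 for s in sizes):
        raise ValueError("every locus needs at least one typed diploid")
    model = MicrosatelliteModel(values)
    if prior_only:
        trees = initial_trees(sizes, np.random.SeedSequence([opts.seed, 2]))
    else:
        # start near data-supported topologies; 2n-tip trees mix too
        # slowly from a random topology
        trees = [upgma_genealogy(v) for v in values]
    lo, hi = prior_bounds
    if prior_only:
        theta0 = 0.5 * (lo + hi)
    else:
        v = float(np.mean([np.var(x, ddof=1) for x in values]))
        theta0 = smm_theta_from_size_variance(v)
    res = run_sampler(model, trees, prior_bounds, opts, theta0, prior_only=prior_only)
    return ThetaPosterior(
        res.samples,
        (float(lo), float(hi)),
        acceptance=res.acceptance,
        extras={"root_time_trace": res.root_time_trace},
        ess_threshold=opts.ess_threshold,
    )
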