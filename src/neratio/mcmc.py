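"""Metropolis-Hastings sampler over (genealogies, theta).

The state is a set of independent per-locus genealogies plus a single
population-scaled mutation parameter theta with a bounded uniform prior.
Genealogies carry the standard Kingman coalescent prior (time in coalescent
units, so the prior does not depend on theta); theta enters only through
the data likelihood, which scales branch lengths by theta/2.  Moves:

* theta: Gaussian random walk reflected at the prior bounds (reflection
  preserves the uniform target);
* node times: uniform redraw within the (child, parent) interval, and a
  multiplicative scaling move for the root height;
* topology: a Wilson-Balding subtree prune-regraft restricted to nodes
  whose parent is not the root (the candidate-destination count is then
  identical in both directions and cancels from the Hastings ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .datatypes import GenotypeMatrix, SequenceAlignment
from .genealogy import Genealogy, coalescent_log_density, simulate_genealogy

__all__ = ["McmcOptions", "run_sampler"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class McmcOptions:
    """Chain-length and proposal-tuning knobs (all counts in sweeps).

    One sweep = ``tree_moves_per_sweep`` genealogy updates per locus
    followed by one theta update; ``n_samples`` thinned draws are recorded
    after ``burn_in`` sweeps.
    """

    burn_in: int = 500
    n_samples: int = 1500
    thin: int = 1
    tree_moves_per_sweep: int = 8
    topo_move_prob: float = 0.3
    tree_scale_prob: float = 0.15
    tree_scale_width: float = 0.3
    theta_walk_frac: float = 0.08  # RW sd as a fraction of the prior width
    root_scale_width: float = 0.4
    rescale_width: float = 0.4  # log-scale width of the joint (trees, theta) rescale
    seed: int = 0
    ess_threshold: float = 50.0

    def __post_init__(self):
        if min(self.burn_in, self.n_samples, self.thin, self.tree_moves_per_sweep) < 1:
            raise ValueError("all McmcOptions counts must be positive")
        if not (0.0 <= self.topo_move_prob <= 1.0):
            raise ValueError("topo_move_prob must be in [0, 1]")


def reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real proposal back into [lo, hi] (symmetric kernel)."""
    w = hi - lo
    y = (x - lo) % (2.0 * w)
    return lo + (y if y <= w else 2.0 * w - y)


# ---------------------------------------------------------------------------
# likelihood models


class SequenceModel:
    """Pruning likelihood of one alignment under the Ti/Tv model."""

    def __init__(self, alignment: SequenceAlignment, R: float):
        arr = alignment.to_array()
        keep = np.all(np.isin(arr, list("ACGT")), axis=0)
        arr = arr[:, keep]
        if arr.shape[1] == 0:
            raise ValueError("no ACGT-only columns available for the likelihood")
        codes = np.zeros(arr.shape, dtype=np.int64)
        for b, c in _BASE_CODE.items():
            codes[arr == b] = c
        patterns, counts = np.unique(codes, axis=1, return_counts=True)
        self.tip_codes = np.ascontiguousarray(patterns)
        self.counts = counts.astype(np.float64)
        self.R = float(R)

    def stats(self, locus: int, tree: Genealogy):
        return (tree.postorder_internal(), tree.children, tree.times)

    def loglik(self, locus: int, stats, theta: float) -> float:
        if theta < 0:
            return -np.inf
        post, children, times = stats
        return float(
            _kernels.k2p_pruning_loglik(
                post, children, times, theta, self.R, self.tip_codes, self.counts
            )
        )


class MicrosatelliteModel:
    """REML Brownian likelihood of allele sizes, one genealogy per locus.

    Tip values are the observed allele sizes (2 per typed diploid); the
    Brownian variance accumulates at theta/2 per coalescent-time unit, the
    continuous analogue of the stepwise mutation model, and the root state
    is integrated out by working with contrasts.  A nugget variance of
    1/12 per tip (the rounding variance of an integer observation) keeps
    the density bounded when tip values tie exactly; without it the
    posterior is dominated by degenerate zero-length-branch genealogies.
    """

    TIP_VARIANCE = 1.0 / 12.0

    def __init__(self, tip_values: list[np.ndarray], tip_variance: float | None = None):
        self.tip_values = [np.asarray(v, dtype=np.float64) for v in tip_values]
        self.tip_variance = self.TIP_VARIANCE if tip_variance is None else float(tip_variance)

    def stats(self, locus: int, tree: Genealogy):
        return (tree.postorder_internal(), tree.children, tree.times)

    def loglik(self, locus: int, stats, theta: float) -> float:
        post, children, times = stats
        return float(
            _kernels.brownian_reml_loglik(
                post,
                children,
                times,
                self.tip_values[locus],
                self.tip_values[locus].size,
                theta,
                self.tip_variance,
            )
        )


# ---------------------------------------------------------------------------
# proposals


def propose_node_time(tree: Genealogy, rng, root_scale_width: float):
    """Return (new_tree, log_hastings) or None if the proposal is void."""
    inner = tree.internal_nodes()
    u = int(inner[rng.integers(inner.size)])
    a, b = tree.children[u]
    lo = max(tree.times[a], tree.times[b])
    if u == tree.root:
        t_new = tree.times[u] * np.exp(rng.uniform(-root_scale_width, root_scale_width))
        if t_new <= lo:
            return None
        log_h = float(np.log(t_new / tree.times[u]))
    else:
        hi = tree.times[tree.parent[u]]
        t_new = rng.uniform(lo, hi)
        log_h = 0.0
    times = tree.times.copy()
    times[u] = t_new
    return Genealogy(tree.n_tips, tree.parent, tree.children, times), log_h


def propose_tree_scale(tree: Genealogy, rng, width: float):
    """Multiply all internal node times of one tree by exp(U(-w, w)).

    The log Hastings-Jacobian term is (n_tips - 1) * log(c): n-1 internal
    times are scaled by a multiplicative proposal.
    """
    c = float(np.exp(rng.uniform(-width, width)))
    times = tree.times.copy()
    times[tree.n_tips :] *= c
    log_h = (tree.n_tips - 1) * float(np.log(c))
    return Genealogy(tree.n_tips, tree.parent, tree.children, times), log_h


def propose_wilson_balding(tree: Genealogy, rng):
    """Prune-regraft move; returns (new_tree, log_hastings) or None.

    Only subtrees whose parent is not the root are pruned, and the pruned
    parent is always re-inserted onto an existing branch, so the root node
    and its height never change and the eligible-node count is constant.
    """
    par = tree.parent.copy()
    ch = tree.children.copy()
    tm = tree.times.copy()
    n_nodes = tree.n_nodes

    eligible = np.flatnonzero((par >= 0) & (par[np.maximum(par, 0)] >= 0) & (par != -1))
    eligible = eligible[par[par[eligible]] >= 0]
    if eligible.size == 0:
        return None
    i = int(eligible[rng.integers(eligible.size)])
    p = int(par[i])
    g = int(par[p])
    s = int(ch[p, 0] if ch[p, 1] == i else ch[p, 1])

    # detach p: its sibling edge fuses with the grandparent edge
    ch[g, 0 if ch[g, 0] == p else 1] = s
    par[s] = g
    par[p] = -2  # sentinel: detached

    mask = _kernels.subtree_mask(ch, i, n_nodes)
    cand = np.flatnonzero(
        (par >= 0) & ~mask & (np.arange(n_nodes) != i)
    )
    cand = cand[tm[par[cand]] > tm[i]]
    if cand.size == 0:
        return None
    j = int(cand[rng.integers(cand.size)])
    pj = int(par[j])
    lo = max(tm[i], tm[j])
    hi = tm[pj]
    t_new = rng.uniform(lo, hi)

    # reverse move re-attaches above the old sibling s on its (fused) edge
    rev_len = tm[g] - max(tm[i], tm[s])
    log_h = float(np.log((hi - lo) / rev_len))

    ch[pj, 0 if ch[pj, 0] == j else 1] = p
    par[p] = pj
    ch[p, 0] = i
    ch[p, 1] = j
    par[j] = p
    tm[p] = t_new
    return Genealogy(tree.n_tips, par, ch, tm), log_h


# ---------------------------------------------------------------------------
# driver


@dataclass
class SamplerResult:
    samples: np.ndarray
    acceptance: dict
    root_time_trace: np.ndarray
    final_trees: list = field(repr=False, default_factory=list)


def run_sampler(
    model,
    trees: list[Genealogy],
    prior_bounds: tuple[float, float],
    options: McmcOptions,
    theta0: float,
    prior_only: bool = False,
) -> SamplerResult:
    """Run the MH chain and return the thinned theta trace."""
    lo, hi = float(prior_bounds[0]), float(prior_bounds[1])
    if not (hi > lo >= 0.0):
        raise ValueError("prior bounds must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(options.seed)
    n_trees = len(trees)
    trees = [t.copy() for t in trees]
    theta = float(np.clip(theta0, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo)))

    if prior_only:
        stats = [None] * n_trees
        ll = np.zeros(n_trees)
    else:
        stats = [model.stats(i, trees[i]) for i in range(n_trees)]
        ll = np.array(
            [model.loglik(i, stats[i], theta) for i in range(n_trees)]
        )
    lp = np.array([coalescent_log_density(t.times, t.n_tips) for t in trees])

    walk_sd = options.theta_walk_frac * (hi - lo)
    n_sweeps = options.burn_in + options.n_samples * options.thin
    samples = np.empty(options.n_samples)
    root_trace = np.empty(options.n_samples)
    acc = {"theta": 0, "theta_try": 0}
    ndim = sum(t.n_tips - 1 for t in trees) - 1
    rescale_sd = options.rescale_width / np.sqrt(max(ndim, 1))

    # proposal scales are tuned during burn-in only (sampling is plain MH)
    adapt_window = 50
    window_acc = 0
    window_resc = [0, 0]
    k_sample = 0
    for sweep in range(n_sweeps):
        for i in range(n_trees):
            tree = trees[i]
            for _ in range(options.tree_moves_per_sweep):
                u = rng.random()
                if tree.n_tips >= 3 and u < options.topo_move_prob:
                    kind = "topo"
                    prop = propose_wilson_balding(tree, rng)
                elif u < options.topo_move_prob + options.tree_scale_prob:
                    kind = "scale"
                    prop = propose_tree_scale(tree, rng, options.tree_scale_width)
                else:
                    kind = "time"
                    prop = propose_node_time(tree, rng, options.root_scale_width)
                acc[kind + "_try"] = acc.get(kind + "_try", 0) + 1
                if prop is None:
                    continue
                new_tree, log_h = prop
                lp_new = coalescent_log_density(new_tree.times, new_tree.n_tips)
                if prior_only:
                    st_new, ll_new = None, 0.0
                else:
                    st_new = model.stats(i, new_tree)
                    ll_new = model.loglik(i, st_new, theta)
                log_a = (ll_new - ll[i]) + (lp_new - lp[i]) + log_h
                if log_a >= 0.0 or np.log(rng.random()) < log_a:
                    trees[i] = new_tree
                    tree = new_tree
                    stats[i] = st_new
                    ll[i] = ll_new
                    lp[i] = lp_new
                    acc[kind] = acc.get(kind, 0) + 1

        # joint rescale: all node times *= c, theta /= c.  The data
        # likelihood is (near-)invariant because it depends on branch
        # times essentially through theta * time, so this move decouples
        # theta from the overall tree-height scale; the coalescent prior,
        # theta prior bounds, Jacobian and any residual likelihood change
        # enter the acceptance ratio.
        acc["rescale_try"] = acc.get("rescale_try", 0) + 1
        window_resc[1] += 1
        c = float(np.exp(rng.uniform(-rescale_sd, rescale_sd)))
        theta_resc = theta / c
        if lo < theta_resc < hi:
            trees_resc = [
                Genealogy(t.n_tips, t.parent, t.children, t.times * c) for t in trees
            ]
            lp_resc = np.array(
                [coalescent_log_density(t.times, t.n_tips) for t in trees_resc]
            )
            if prior_only:
                stats_resc, ll_resc = stats, ll
            else:
                stats_resc = [model.stats(i, trees_resc[i]) for i in range(n_trees)]
                ll_resc = np.array(
                    [model.loglik(i, stats_resc[i], theta_resc) for i in range(n_trees)]
                )
            log_a = (
                float(lp_resc.sum() - lp.sum())
                + float(ll_resc.sum() - ll.sum())
                + ndim * np.log(c)
            )
            if log_a >= 0.0 or np.log(rng.random()) < log_a:
                acc["rescale"] = acc.get("rescale", 0) + 1
                window_resc[0] += 1
                theta = theta_resc
                trees = trees_resc
                stats = stats_resc
                ll = ll_resc
                lp = lp_resc

        acc["theta_try"] += 1
        theta_prop = reflect(theta + rng.normal(0.0, walk_sd), lo, hi)
        if prior_only:
            theta = theta_prop
            acc["theta"] += 1
            window_acc += 1
        else:
            ll_prop = np.array(
                [model.loglik(i, stats[i], theta_prop) for i in range(n_trees)]
            )
            log_a = float(ll_prop.sum() - ll.sum())
            if log_a >= 0.0 or np.log(rng.random()) < log_a:
                theta = theta_prop
                ll = ll_prop
                acc["theta"] += 1
                window_acc += 1

        if sweep < options.burn_in and (sweep + 1) % adapt_window == 0:
            rate = window_acc / adapt_window
            if rate < 0.2:
                walk_sd *= 0.5
            elif rate > 0.5:
                walk_sd *= 1.6
            walk_sd = float(np.clip(walk_sd, 1e-5 * (hi - lo), hi - lo))
            window_acc = 0
            resc_rate = window_resc[0] / max(window_resc[1], 1)
            if resc_rate < 0.2:
                rescale_sd *= 0.6
            elif resc_rate > 0.45:
                rescale_sd *= 1.5
            rescale_sd = float(np.clip(rescale_sd, 1e-6, 2.0))
            window_resc = [0, 0]

        if sweep >= options.burn_in and (sweep - options.burn_in) % options.thin == 0:
            if k_sample < options.n_samples:
                samples[k_sample] = theta
                root_trace[k_sample] = trees[0].tmrca
                k_sample += 1

    rates = {
        k: (acc.get(k, 0) / acc[k + "_try"] if acc.get(k + "_try") else np.nan)
        for k in ("time", "topo", "scale", "theta", "rescale")
    }
    return SamplerResult(samples, rates, root_trace, trees)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocovariance estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x) / n)
    if var == 0.0:
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sum paired correlations while the pair sums stay positive
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
    return float(n / tau)


# helpers for building initial states -------------------------------------


def microsat_tip_values(genotypes: GenotypeMatrix) -> list[np.ndarray]:
    """Per-locus haploid tip values: the 2 alleles of each typed diploid."""
    values = []
    for l in range(genotypes.n_loci):
        mask = genotypes.typed_mask(l)
        values.append(genotypes.alleles[mask, l, :].ravel().astype(np.float64))
    return values


def initial_trees(sizes: list[int], seed) -> list[Genealogy]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [
        simulate_genealogy(n, np.random.default_rng(s))
        for n, s in zip(sizes, ss.spawn(len(sizes)))
    ]


def upgma_genealogy(values: np.ndarray, height: float | None = None) -> Genealogy:
    """Average-linkage starting tree from 1-D tip values.

    Used only to initialise the MCMC near data-supported topologies (large
    trees mix far too slowly from a random topology).  Node heights are
    made strictly increasing and the tree is rescaled to the expected
    coalescent TMRCA.
    """
    from scipy.cluster.hierarchy import linkage

    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 tips")
    Z = linkage(values.reshape(-1, 1), method="average")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    for k in range(n - 1):
        u = n + k
        a, b = int(Z[k, 0]), int(Z[k, 1])
        parent[a] = parent[b] = u
        children[u] = (a, b)
        t = Z[k, 2] / 2.0
        times[u] = max(t, times[a] + 1e-4, times[b] + 1e-4)
    if height is None:
        height = 2.0 * (1.0 - 1.0 / n)
    times *= height / times[n_nodes - 1]
    return Genealogy(n, parent, children, times)
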