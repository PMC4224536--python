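"""Numba-compiled likelihood kernels used inside the MCMC inner loop.

Two likelihoods are needed per proposal: Felsenstein pruning under a
two-parameter (transition/transversion) substitution model for sequence
data, and the REML contrast likelihood of a Brownian process on the
genealogy for microsatellite allele sizes.  Both are O(n) per tree and are
compiled because they sit inside tight Metropolis-Hastings loops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# base codes: 0=A, 1=C, 2=G, 3=T; transitions are A<->G and C<->T
TRANSITION_PARTNER = np.array([2, 3, 0, 1], dtype=np.int64)


@njit(cache=True)
def brownian_reml_loglik(post_internal, children, times, tip_values, n_tips, theta, tip_var):
    """REML Brownian log-likelihood with a per-tip nugget variance.

    Variance accumulates at theta/2 per time unit along branches; each tip
    additionally carries ``tip_var`` (rounding variance of the integer
    repeat counts).  The nugget bounds the density for exactly tied tip
    values, which would otherwise favour degenerate zero-length branches.
    Works in variance units throughout, so theta does not factor out.
    """
    if theta < 0.0:
        return -np.inf
    n_nodes = children.shape[0]
    val = np.zeros(n_nodes)
    extra = np.zeros(n_nodes)
    for i in range(n_tips):
        val[i] = tip_values[i]
        extra[i] = tip_var
    half_theta = 0.5 * theta
    ll = 0.0
    for idx in range(post_internal.shape[0]):
        u = post_internal[idx]
        a = children[u, 0]
        b = children[u, 1]
        va = half_theta * (times[u] - times[a]) + extra[a]
        vb = half_theta * (times[u] - times[b]) + extra[b]
        w = va + vb
        if w <= 0.0:
            return -np.inf
        c = val[a] - val[b]
        ll += -0.5 * (np.log(2.0 * np.pi * w) + c * c / w)
        val[u] = (vb * val[a] + va * val[b]) / w
        extra[u] = va * vb / w
    return ll


@njit(cache=True)
def k2p_pruning_loglik(post_internal, children, times, theta, R, tip_codes, counts):
    """Log-likelihood of an alignment under the Kimura-type Ti/Tv model.

    ``tip_codes`` is (n_tips, P) with base codes per unique site pattern and
    ``counts`` the pattern multiplicities.  Branch lengths in expected
    substitutions per site are (theta/2) * branch time; the process is
    scaled to one expected substitution per unit so that a mutation is a
    transition with probability R/(R+1).  Base frequencies are uniform.
    """
    n_tips = tip_codes.shape[0]
    P = tip_codes.shape[1]
    n_nodes = children.shape[0]
    beta = 1.0 / (2.0 * (R + 1.0))
    alpha = R / (R + 1.0)

    partial = np.zeros((n_nodes, P, 4))
    logscale = np.zeros(P)
    for i in range(n_tips):
        for p in range(P):
            partial[i, p, tip_codes[i, p]] = 1.0

    M = np.empty((4, 4))
    msg = np.empty(4)
    for idx in range(post_internal.shape[0]):
        u = post_internal[idx]
        for slot in range(2):
            c = children[u, slot]
            nu = (times[u] - times[c]) * theta * 0.5
            e4 = np.exp(-4.0 * beta * nu)
            e2 = np.exp(-2.0 * (alpha + beta) * nu)
            p_same = 0.25 + 0.25 * e4 + 0.5 * e2
            p_ti = 0.25 + 0.25 * e4 - 0.5 * e2
            p_tv = 0.25 - 0.25 * e4
            for x in range(4):
                for y in range(4):
                    if x == y:
                        M[x, y] = p_same
                    elif (x ^ 2) == y:  # 0<->2, 1<->3: transition partner
                        M[x, y] = p_ti
                    else:
                        M[x, y] = p_tv
            for p in range(P):
                for x in range(4):
                    acc = 0.0
                    for y in range(4):
                        acc += M[x, y] * partial[c, p, y]
                    msg[x] = acc
                if slot == 0:
                    for x in range(4):
                        partial[u, p, x] = msg[x]
                else:
                    for x in range(4):
                        partial[u, p, x] *= msg[x]
        # per-pattern rescaling to avoid underflow on deep trees
        for p in range(P):
            m = partial[u, p, 0]
            for x in range(1, 4):
                if partial[u, p, x] > m:
                    m = partial[u, p, x]
            if m > 0.0 and m < 1e-40:
                for x in range(4):
                    partial[u, p, x] /= m
                logscale[p] += np.log(m)

    root = post_internal[post_internal.shape[0] - 1]
    ll = 0.0
    for p in range(P):
        site = 0.0
        for x in range(4):
            site += 0.25 * partial[root, p, x]
        if site <= 0.0:
            return -np.inf
        ll += counts[p] * (np.log(site) + logscale[p])
    return ll


@njit(cache=True)
def subtree_mask(children, node, n_nodes):
    """Boolean mask of ``node`` and all its descendants."""
    mask = np.zeros(n_nodes, dtype=np.bool_)
    stack = np.empty(n_nodes, dtype=np.int64)
    stack[0] = node
    top = 1
    while top > 0:
        top -= 1
        u = stack[top]
        mask[u] = True
        if children[u, 0] >= 0:
            stack[top] = children[u, 0]
            stack[top + 1] = children[u, 1]
            top += 2
    return mask
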