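"""Kingman-coalescent genealogies: simulation, validation, prior density.

Time is measured in coalescent units (one unit = 2N generations): while k
lineages remain, the waiting time to the next coalescence is exponential
with rate k(k-1)/2, and the merging pair is uniform among the k choose 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "coalescent_log_density",
    "as_rng",
]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class Genealogy:
    """A rooted, ultrametric, binary coalescent tree.

    Nodes are indexed 0..2n-2: tips are 0..n-1 (time 0), internal nodes
    n..2n-2.  ``parent[i]`` is -1 for the root; ``children`` rows are -1
    for tips.  ``times`` increase strictly from tips to root.
    """

    n_tips: int
    parent: np.ndarray
    children: np.ndarray
    times: np.ndarray
    _root: int = field(default=-1, repr=False)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        if self._root < 0:
            self._root = int(np.flatnonzero(self.parent == -1)[0])
        return self._root

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    def postorder_internal(self) -> np.ndarray:
        """Internal nodes ordered children-before-parents.

        Because internal times strictly exceed their children's times,
        sorting internal nodes by time yields a valid bottom-up order.
        """
        inner = self.internal_nodes()
        return inner[np.argsort(self.times[inner], kind="stable")]

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        b = np.zeros(self.n_nodes)
        non_root = self.parent >= 0
        b[non_root] = self.times[self.parent[non_root]] - self.times[non_root]
        return b

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def copy(self) -> "Genealogy":
        return Genealogy(
            self.n_tips, self.parent.copy(), self.children.copy(), self.times.copy()
        )

    def validate(self) -> None:
        """Raise ValueError if any structural invariant is broken."""
        n = self.n_tips
        if n < 2:
            raise ValueError("a genealogy needs at least 2 tips")
        if self.parent.shape != (self.n_nodes,) or self.times.shape != (self.n_nodes,):
            raise ValueError("array shapes inconsistent with n_tips")
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("exactly one root expected")
        if not np.allclose(self.times[:n], 0.0):
            raise ValueError("tree is not ultrametric: tips must sit at time 0")
        for u in self.internal_nodes():
            a, b = self.children[u]
            if a < 0 or b < 0:
                raise ValueError(f"internal node {u} lacks two children")
            if not (self.times[u] > self.times[a] and self.times[u] > self.times[b]):
                raise ValueError("node times must strictly increase toward the root")
        if np.any(self.branch_lengths() < 0):
            raise ValueError("negative branch length")

    def path_nodes_to_root(self, node: int) -> list[int]:
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path


def simulate_genealogy(n_tips: int, seed) -> Genealogy:
    """Draw a genealogy from the standard Kingman coalescent.

    Parameters
    ----------
    n_tips
        Number of sampled lineages (>= 2).
    seed
        Int seed or ``numpy.random.Generator``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = as_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    times = np.zeros(n_nodes)

    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        children[nxt] = (a, b)
        times[nxt] = t
        # replace one merged lineage by the new node, drop the other
        active[i] = nxt
        del active[j]
        nxt += 1
    return Genealogy(n_tips, parent, children, times)


def coalescent_log_density(times: np.ndarray, n_tips: int) -> float:
    """Log density of a labelled coalescent history given its node times.

    ``times`` is the full node-time array of a genealogy; tips contribute
    nothing.  With internal times 0 < t_(1) < ... < t_(n-1), the density is
    prod_k exp(-C(k,2) * dt_k) with k lineages in each inter-event interval
    (the 1/C(k,2) pair-choice factor and the rate cancel for a specific
    labelled history).
    """
    it = np.sort(times[n_tips:])
    k = np.arange(n_tips, 1, -1, dtype=np.float64)
    dt = np.diff(it, prepend=0.0)
    return float(-np.sum(k * (k - 1) / 2.0 * dt))
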