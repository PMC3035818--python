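"""Coalescent simulation of a single non-recombining locus under a
two-population isolation (no-migration) model.

Time is measured in units of 4*N0 generations throughout (the convention of
Hudson's ``ms``): a pair of lineages in one deme coalesces at rate 2 per
unit time, so j lineages coalesce at rate j*(j-1) and the expected pairwise
coalescence time is 0.5.  Both demes have constant size N0 before and after
the join; at time ``tau`` (looking backwards) the two demes merge into a
single ancestral pool of the same size.

Mutations follow the infinite-sites model: the number of segregating sites
is Poisson with mean ``theta`` times the total branch length (in 4*N0
units), and each mutation lands on a branch with probability proportional
to its length, deriving exactly the leaves subtended by that branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "IsolationModel",
    "Genealogy",
    "SimulatedLocus",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_locus",
    "years_to_tau",
    "tau_to_years",
    "write_ms_output",
]


@dataclass(frozen=True)
class IsolationModel:
    """Two-deme isolation model in ms scaling.

    Parameters
    ----------
    n1, n2 : int
        Chromosomes sampled from deme 1 and deme 2.
    theta : float
        Per-locus scaled mutation rate, 4*N0*mu_locus.
    tau : float
        Population-join time in units of 4*N0 generations.  ``tau=0`` is
        a panmictic population.  The study's null is ``theta=4``,
        ``n1=n2=200``, ``tau=1.25``.
    """

    n1: int
    n2: int
    theta: float
    tau: float

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 2:
            raise ParameterError("need at least two sampled chromosomes")
        if self.theta <= 0:
            raise ParameterError(f"theta must be positive, got {self.theta}")
        if self.tau < 0:
            raise ParameterError(f"tau must be nonnegative, got {self.tau}")


@dataclass
class Genealogy:
    """Binary coalescent tree over ``n_leaves`` sampled chromosomes.

    Nodes 0..n_leaves-1 are leaves; internal nodes are appended in
    coalescence order, so the last node is the root.  ``parent[i]`` is -1
    for the root; ``time`` holds node ages in 4*N0 units (0 for leaves).
    """

    parent: np.ndarray
    time: np.ndarray
    deme: np.ndarray  # deme index (0/1) of each leaf
    n_leaves: int
    _children: list[list[int]] | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        return self.time[self.parent[:-1]] - self.time[:-1]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent[:-1]):
                ch[p].append(i)
            self._children = ch
        return self._children

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf indices subtended by ``node`` (the node itself if a leaf)."""
        if node < self.n_leaves:
            return np.array([node], dtype=np.intp)
        ch = self.children()
        out: list[int] = []
        stack = [node]
        while stack:
            x = stack.pop()
            if x < self.n_leaves:
                out.append(x)
            else:
                stack.extend(ch[x])
        return np.asarray(out, dtype=np.intp)


@dataclass
class SimulatedLocus:
    """Infinite-sites outcome for one simulated locus.

    ``incidence`` is a (chromosome x segregating site) 0/1 matrix of
    derived-allele indicators; each column is exactly one clade of the
    genealogy.
    """

    tree: Genealogy
    site_count: int
    incidence: np.ndarray
    tmrca: float


def simulate_genealogy(model: IsolationModel, rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy under the isolation model.

    Before ``tau`` lineages coalesce only within their own deme (uniformly
    chosen pairs); any lineages remaining at ``tau`` merge into a single
    pool and coalesce to one root.
    """
    n1, n2 = model.n1, model.n2
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.intp)
    time = np.zeros(n_nodes)
    deme = np.array([0] * n1 + [1] * n2, dtype=np.int8)

    pools: list[list[int]] = [list(range(n1)), list(range(n1, n))]
    merged = model.tau == 0.0
    if merged:
        pools[0].extend(pools[1])
        pools[1] = []
    t = 0.0
    nxt = n
    while nxt < n_nodes:
        j1, j2 = len(pools[0]), len(pools[1])
        if not merged:
            r1 = j1 * (j1 - 1)
            r2 = j2 * (j2 - 1)
            rate = r1 + r2
            if rate == 0:
                t = model.tau
                pools[0].extend(pools[1])
                pools[1] = []
                merged = True
                continue
            wait = rng.exponential(1.0 / rate)
            if t + wait >= model.tau:
                t = model.tau
                pools[0].extend(pools[1])
                pools[1] = []
                merged = True
                continue
            t += wait
            pool = pools[0] if rng.random() * rate < r1 else pools[1]
        else:
            rate = j1 * (j1 - 1)
            t += rng.exponential(1.0 / rate)
            pool = pools[0]
        # uniform unordered pair from the chosen pool
        j = len(pool)
        a = int(rng.integers(j))
        b = int(rng.integers(j - 1))
        if b >= a:
            b += 1
        if a < b:
            a, b = b, a  # remove the larger index first
        ca, cb = pool[a], pool[b]
        del pool[a]
        pool[b] = nxt
        parent[ca] = nxt
        parent[cb] = nxt
        time[nxt] = t
        nxt += 1
    return Genealogy(parent=parent, time=time, deme=deme, n_leaves=n)


def drop_mutations(
    tree: Genealogy, theta: float, rng: np.random.Generator
) -> SimulatedLocus:
    """Scatter infinite-sites mutations on a genealogy.

    The segregating-site count is Poisson(theta * total branch length in
    4*N0 units); each site is assigned to a branch with probability
    proportional to its length and marks the subtended leaves as derived.
    """
    if theta <= 0:
        raise ParameterError(f"theta must be positive, got {theta}")
    lens = tree.branch_lengths()
    total = lens.sum()
    n_sites = int(rng.poisson(theta * total))
    n = tree.n_leaves
    incidence = np.zeros((n, n_sites), dtype=np.uint8)
    if n_sites:
        cum = np.cumsum(lens)
        branches = np.searchsorted(cum, rng.random(n_sites) * total, side="right")
        branches = np.minimum(branches, len(lens) - 1)
        cache: dict[int, np.ndarray] = {}
        for s, b in enumerate(branches):
            leaves = cache.get(b)
            if leaves is None:
                leaves = tree.leaves_below(int(b))
                cache[b] = leaves
            incidence[leaves, s] = 1
    return SimulatedLocus(
        tree=tree, site_count=n_sites, incidence=incidence, tmrca=tree.tmrca
    )


def simulate_locus(model: IsolationModel, rng: np.random.Generator) -> SimulatedLocus:
    """Convenience: genealogy plus mutations in one call."""
    return drop_mutations(simulate_genealogy(model, rng), model.theta, rng)


def years_to_tau(t_years: float, n0: float, gens_per_year: float) -> float:
    """Convert a divergence time in years to coalescent units of 4*N0
    generations.  250 kyr at N0=1e6 diploids and 10 generations/year gives
    tau=0.625 (note the study's printed command uses tau=1.25)."""
    if t_years < 0 or n0 <= 0 or gens_per_year <= 0:
        raise ParameterError("t_years must be >=0; n0, gens_per_year positive")
    return t_years * gens_per_year / (4.0 * n0)


def tau_to_years(tau: float, n0: float, gens_per_year: float) -> float:
    """Inverse of :func:`years_to_tau`."""
    if tau < 0 or n0 <= 0 or gens_per_year <= 0:
        raise ParameterError("tau must be >=0; n0, gens_per_year positive")
    return tau * 4.0 * n0 / gens_per_year


def write_ms_output(loci: list[SimulatedLocus], path, command: str = "introscan") -> None:
    """Write loci in Hudson's ms text dialect (segsites/positions lines).

    Positions are evenly spaced placeholders: the simulator tracks only the
    incidence matrix, which is all downstream stages consume.
    """
    with open(path, "w") as fh:
        fh.write(f"{command}\n0 0 0\n")
        for locus in loci:
            fh.write("\n//\n")
            fh.write(f"segsites: {locus.site_count}\n")
            if locus.site_count:
                pos = (np.arange(locus.site_count) + 1) / (locus.site_count + 1)
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in pos) + "\n")
                for row in locus.incidence:
                    fh.write("".join("1" if x else "0" for x in row) + "\n")
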