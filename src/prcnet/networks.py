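"""Directed-network ensembles and network-inferability theory.

A directed link s -> t in a perturbation screen is *inferable* when no
alternative route through the rest of the network can fully explain the
target's response.  With a fraction ``q`` of nodes independently perturbed,
the expected fraction of inferable links ``F(q)`` follows from counting two
motifs around each edge:

(a) the target is perturbed and every out-neighbour of the source is
    perturbed, or
(b) the target is unperturbed, every other out-neighbour of the source is
    perturbed, and every out-neighbour of the target is perturbed.

Per edge, with source out-degree ``k``, target out-degree ``l`` and ``m``
shared targets, the probability of (a) is ``q**(k+1)`` and of (b) is
``(1-q) * q**(k+l-m)``; averaging over edges gives the closed form F(q).
The area under F(q) is the network inferability I_F; replacing the joint
edge-degree distribution by the product of its out-degree marginals gives
the approximation I_F*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


class NetworkError(ValueError):
    pass


@dataclass
class DirectedNetwork:
    """Directed graph with no self-loops and no bidirectional pairs.

    ``edges`` are ordered (source, target) pairs; ``weights`` optionally
    assigns a signed strength to each edge (the direct effect of the source
    on the target).
    """

    nodes: list
    edges: set
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for s, t in self.edges:
            if s == t:
                raise NetworkError(f"self-loop {s}->{t} not allowed")
            if (t, s) in self.edges:
                raise NetworkError(f"bidirectional pair {s}<->{t} not allowed")
            if s not in node_set or t not in node_set:
                raise NetworkError(f"edge ({s},{t}) references unknown node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return self.n_edges / self.n_nodes

    def out_neighbours(self) -> dict:
        out: dict = {v: set() for v in self.nodes}
        for s, t in self.edges:
            out[s].add(t)
        return out

    def out_degree(self) -> dict:
        return {v: len(nb) for v, nb in self.out_neighbours().items()}

    def invert(self) -> "DirectedNetwork":
        """Same topology with every link direction reversed."""
        return DirectedNetwork(
            nodes=list(self.nodes),
            edges={(t, s) for s, t in self.edges},
            weights={(t, s): w for (s, t), w in self.weights.items()},
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, weight=self.weights.get(e, 1.0))
        return g

    # -- edge-list TSV -------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = []
        for s, t in sorted(self.edges, key=lambda e: (str(e[0]), str(e[1]))):
            if self.weights:
                rows.append((s, t, self.weights.get((s, t), 1.0)))
            else:
                rows.append((s, t))
        cols = ["source", "target"] + (["weight"] if self.weights else [])
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, nodes: Iterable | None = None) -> "DirectedNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        if not {"source", "target"}.issubset(df.columns):
            raise NetworkError(f"{path}: expected columns source/target")
        edges = set(zip(df["source"], df["target"]))
        weights = {}
        if "weight" in df.columns:
            weights = {
                (s, t): float(w)
                for s, t, w in zip(df["source"], df["target"], df["weight"])
            }
        if nodes is None:
            nodes = sorted({v for e in edges for v in e})
        return cls(nodes=list(nodes), edges=edges, weights=weights)


@dataclass
class PerturbedSet:
    """A realised set of perturbed nodes with its nominal fraction q."""

    perturbed: set
    q: float

    @classmethod
    def bernoulli(cls, net: DirectedNetwork, q: float, rng: np.random.Generator) -> "PerturbedSet":
        """Each node perturbed independently with probability q."""
        chosen = {v for v in net.nodes if rng.random() < q}
        return cls(perturbed=chosen, q=q)

    @classmethod
    def fixed_fraction(cls, net: DirectedNetwork, q: float, rng: np.random.Generator) -> "PerturbedSet":
        """Exactly round(q*N) nodes, uniformly chosen."""
        k = int(round(q * net.n_nodes))
        chosen = set(rng.choice(np.asarray(net.nodes, dtype=object), size=k, replace=False))
        return cls(perturbed=chosen, q=q)


@dataclass
class InferabilityCurve:
    q_grid: np.ndarray
    F_values: np.ndarray
    I_F: float
    I_F_star: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q": self.q_grid, "F": self.F_values})


# ---------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------

def _place_pairs_weighted(n: int, n_edges: int, probs: np.ndarray, rng: np.random.Generator) -> set:
    """Insert ``n_edges`` distinct unordered pairs with endpoint probs ``probs``."""
    max_pairs = n * (n - 1) // 2
    if n_edges > max_pairs:
        raise NetworkError(
            f"infeasible degree sequence: {n_edges} edges exceed {max_pairs} possible pairs"
        )
    pairs: set = set()
    attempts = 0
    limit = 200 * n_edges + 1000
    while len(pairs) < n_edges:
        k = min(4 * (n_edges - len(pairs)) + 8, 100000)
        us = rng.choice(n, size=k, p=probs)
        vs = rng.choice(n, size=k, p=probs)
        for u, v in zip(us, vs):
            if u == v:
                continue
            pair = (min(u, v), max(u, v))
            if pair not in pairs:
                pairs.add(pair)
                if len(pairs) == n_edges:
                    break
        attempts += k
        if attempts > limit and len(pairs) < n_edges:
            raise NetworkError(
                "infeasible degree sequence: could not place requested number of "
                f"edges ({len(pairs)}/{n_edges} after {attempts} attempts)"
            )
    return pairs


def generate_scale_free_network(
    n: int,
    gamma: float,
    mean_degree: float,
    hub_mode: str = "outgoing",
    seed: int | np.random.Generator = 0,
) -> DirectedNetwork:
    """Scale-free directed network with power-law exponent ``gamma``.

    Node attachment weights are drawn from a continuous power law
    p(w) ~ w**(-gamma); edges are inserted between distinct unordered pairs
    with stub probability proportional to weight, then oriented from the
    higher-degree endpoint to the lower-degree endpoint (``outgoing`` hubs)
    or the reverse (``incoming`` hubs, the same graph with all directions
    inverted).  The realised mean out-degree equals round(n*mean_degree)/n.
    """
    if n < 3:
        raise NetworkError("need n >= 3")
    if gamma <= 1:
        raise NetworkError("need gamma > 1")
    if not (0 < mean_degree < n - 1):
        raise NetworkError("need 0 < mean_degree < n-1")
    if hub_mode not in ("outgoing", "incoming"):
        raise NetworkError(f"unknown hub_mode {hub_mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_edges = int(round(n * mean_degree))
    if n_edges < 1:
        raise NetworkError("mean_degree too small: no edges requested")
    # Pareto(1, gamma-1) weights give a power-law degree sequence with
    # exponent gamma under proportional stub matching.
    w = (1.0 - rng.random(n)) ** (-1.0 / (gamma - 1.0))
    w = np.minimum(w, float(n - 1))  # truncate at the structural cutoff
    probs = w / w.sum()
    pairs = _place_pairs_weighted(n, n_edges, probs, rng)

    deg = np.zeros(n, dtype=int)
    for u, v in pairs:
        deg[u] += 1
        deg[v] += 1
    edges = set()
    for u, v in pairs:
        if deg[u] > deg[v]:
            s, t = u, v
        elif deg[v] > deg[u]:
            s, t = v, u
        else:
            s, t = (u, v) if rng.random() < 0.5 else (v, u)
        edges.add((int(s), int(t)))
    net = DirectedNetwork(nodes=list(range(n)), edges=edges)
    return net.invert() if hub_mode == "incoming" else net


def generate_random_network(
    n: int, mean_degree: float, seed: int | np.random.Generator = 0
) -> DirectedNetwork:
    """Uniform random directed network (random insertion of links)."""
    if n < 2:
        raise NetworkError("need n >= 2")
    if mean_degree >= n - 1:
        raise NetworkError("mean_degree must be < n-1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_edges = int(round(n * mean_degree))
    max_pairs = n * (n - 1) // 2
    if n_edges > max_pairs:
        raise NetworkError("too many edges requested")
    idx = rng.choice(max_pairs, size=n_edges, replace=False)
    # decode unordered pair index -> (u, v), u < v
    edges = set()
    us = np.triu_indices(n, k=1)
    for i in idx:
        u, v = int(us[0][i]), int(us[1][i])
        s, t = (u, v) if rng.random() < 0.5 else (v, u)
        edges.add((s, t))
    return DirectedNetwork(nodes=list(range(n)), edges=edges)


# ---------------------------------------------------------------------
# Inferability counting
# ---------------------------------------------------------------------

def _motif_inferable(s, t, out_s: set, out_t: set, perturbed: set) -> bool:
    if s not in perturbed:
        return False
    if t in perturbed:
        return out_s <= perturbed
    return (out_s - {t}) <= perturbed and out_t <= perturbed


def count_inferable_links(
    net: DirectedNetwork, perturbed: PerturbedSet | set, mode: str = "motif"
) -> tuple[int, dict]:
    """Count inferable links for a realised perturbed set.

    ``motif`` mode tests the two motif conditions per edge; ``refined`` mode
    additionally deletes, before testing an edge into target t, every
    out-neighbour of t whose link from t has itself been flagged inferable,
    and iterates the flags to a fixed point.
    """
    pset = perturbed.perturbed if isinstance(perturbed, PerturbedSet) else set(perturbed)
    if not pset <= set(net.nodes):
        raise NetworkError("perturbed set contains unknown nodes")
    if mode not in ("motif", "refined"):
        raise NetworkError(f"unknown mode {mode!r}")
    out = net.out_neighbours()
    flags = {e: False for e in net.edges}

    def motif_pass() -> bool:
        changed = False
        for (s, t), done in flags.items():
            if done:
                continue
            if mode == "refined":
                removable = {x for x in out[t] if flags.get((t, x), False)}
            else:
                removable = set()
            ok = _motif_inferable(s, t, out[s] - removable, out[t] - removable, pset)
            if ok:
                flags[(s, t)] = True
                changed = True
        return changed

    if mode == "motif":
        motif_pass()
    else:
        while motif_pass():
            pass
    return sum(flags.values()), flags


def expected_inferable_fraction(
    net: DirectedNetwork,
    q: float,
    n_draws: int | str = 1000,
    mode: str = "motif",
    seed: int | np.random.Generator = 0,
    perturbed_scheme: str = "bernoulli",
) -> float:
    """Expected fraction of inferable links at perturbed-node fraction q.

    ``n_draws="exhaustive"`` enumerates all perturbed sets with their
    Bernoulli(q) weights (exact; small networks only), otherwise a Monte
    Carlo average over ``n_draws`` random perturbed sets is returned.
    """
    if not (0.0 <= q <= 1.0):
        raise NetworkError("q must lie in [0,1]")
    if net.n_edges == 0:
        raise NetworkError("network has no edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_e = net.n_edges
    if n_draws == "exhaustive":
        if net.n_nodes > 20:
            raise NetworkError("exhaustive enumeration limited to n <= 20")
        total = 0.0
        for r in range(net.n_nodes + 1):
            for subset in itertools.combinations(net.nodes, r):
                w = q**r * (1 - q) ** (net.n_nodes - r)
                if w == 0.0:
                    continue
                cnt, _ = count_inferable_links(net, set(subset), mode=mode)
                total += w * cnt / n_e
        return total
    vals = []
    for _ in range(int(n_draws)):
        if perturbed_scheme == "bernoulli":
            ps = PerturbedSet.bernoulli(net, q, rng)
        else:
            ps = PerturbedSet.fixed_fraction(net, q, rng)
        cnt, _ = count_inferable_links(net, ps, mode=mode)
        vals.append(cnt / n_e)
    return float(np.mean(vals))


# ---------------------------------------------------------------------
# Closed form F(q) and inferability measures
# ---------------------------------------------------------------------

def _edge_klm(net: DirectedNetwork) -> np.ndarray:
    """Per edge: (k, l, m) = source out-degree, target out-degree, shared targets."""
    out = net.out_neighbours()
    rows = []
    for s, t in net.edges:
        k = len(out[s])
        l = len(out[t])
        m = len(out[s] & out[t])
        rows.append((k, l, m))
    return np.asarray(rows, dtype=float)


def F_closed_form(net: DirectedNetwork, q: float) -> float:
    """Closed-form F(q) with the empirical joint edge-degree distribution.

    F(q) = sum over (k,l,m) of [q**(k+1) + (1-q) q**(k+l-m)] P(k,l,m | k->l);
    with the empirical per-edge (k,l,m) this equals the exact motif-mode
    expectation under independent Bernoulli(q) perturbation.
    """
    if net.n_edges == 0:
        raise NetworkError("network has no edges")
    klm = _edge_klm(net)
    k, l, m = klm[:, 0], klm[:, 1], klm[:, 2]
    with np.errstate(invalid="ignore"):
        val = q ** (k + 1) + (1 - q) * q ** (k + l - m)
    return float(np.mean(val))


def inferability_IF(
    net: DirectedNetwork,
    q_grid: np.ndarray | None = None,
    estimator: str = "closed_form",
    n_draws: int = 200,
    mode: str = "motif",
    seed: int = 0,
) -> InferabilityCurve:
    """F(q) curve and its area I_F (trapezoid on a uniform grid)."""
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 101)
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q_grid) <= 0):
        raise NetworkError("q_grid must be strictly ascending")
    if estimator == "closed_form":
        F = np.array([F_closed_form(net, q) for q in q_grid])
    elif estimator == "monte_carlo":
        rng = np.random.default_rng(seed)
        F = np.array(
            [expected_inferable_fraction(net, q, n_draws, mode=mode, seed=rng) for q in q_grid]
        )
    else:
        raise NetworkError(f"unknown estimator {estimator!r}")
    I_F = float(np.trapezoid(F, q_grid))
    return InferabilityCurve(q_grid=q_grid, F_values=F, I_F=I_F)


def _F_star(net: DirectedNetwork, q: float) -> float:
    klm = _edge_klm(net).astype(int)
    ks = klm[:, 0]
    ls = klm[:, 1]
    n_e = len(ks)
    pk = {int(k): c / n_e for k, c in zip(*np.unique(ks, return_counts=True))}
    pl = {int(l): c / n_e for l, c in zip(*np.unique(ls, return_counts=True))}
    N = net.n_nodes
    total = 0.0
    for k, wk in pk.items():
        for l, wl in pl.items():
            mmax = min(k - 1, l)
            if mmax < 0:
                continue
            # shared-target count under independent placement of the
            # target's l out-links among the N-2 other nodes
            M = max(N - 2, 1)
            draws = min(k - 1, M)
            succ = min(l, M)
            ms = np.arange(0, mmax + 1)
            pm = hypergeom.pmf(ms, M, succ, draws)
            sm = pm.sum()
            if sm <= 0:
                pm = np.zeros_like(pm)
                pm[0] = 1.0
            else:
                pm = pm / sm
            val = q ** (k + 1) + (1 - q) * q ** (k + l - ms)
            total += wk * wl * float(np.dot(pm, val))
    return total


def inferability_IF_star(net: DirectedNetwork, q_grid: np.ndarray | None = None) -> float:
    """I_F* — the inferability under the factorised edge-degree distribution.

    The joint P(k,l,m | k->l) is replaced by the product of the empirical
    out-degree marginals of edge sources and edge targets, with the shared
    -target count m hypergeometric as implied by independent placement.
    """
    if net.n_edges == 0:
        raise NetworkError("network has no edges")
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 101)
    F = np.array([_F_star(net, q) for q in q_grid])
    return float(np.trapezoid(F, q_grid))
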