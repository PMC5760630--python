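"""Synthetic single-gene knockout screens on planted networks.

Two generative models emulate steady-state expression responses to gene
deletions:

* a linear stationary model ``0 = A (y - y_ref) + B u`` (log2 scale) whose
  responses are exact matrix solves, and
* a nonlinear ODE model with Hill-type regulation and linear degradation,
  knocked-out genes clamped to an expression floor, solved to steady state.

Both add Gaussian measurement noise, either with a standard deviation
proportional to the expression level ("expr_fraction", the default: a
multiplicative noise of the stated coefficient of variation, constant on
the log2 scale) or proportional to each entry's log2 fold change
("fc_fraction").  Wild-type replicates (pure noise around the reference)
are appended for noise-model estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .datasets import KnockoutScreen, PerturbationDesign
from .networks import DirectedNetwork, NetworkError

LOG2E = float(np.log2(np.e))
FC_NOISE_FLOOR = 0.01
EXPRESSION_FLOOR = 1e-3


class DatagenError(ValueError):
    pass


def gene_id(node) -> str:
    return f"G{node}"


def relabel_to_genes(net: DirectedNetwork) -> DirectedNetwork:
    """Relabel integer network nodes to the gene ids used in generated screens."""
    return DirectedNetwork(
        nodes=[gene_id(v) for v in net.nodes],
        edges={(gene_id(s), gene_id(t)) for s, t in net.edges},
        weights={(gene_id(s), gene_id(t)): w for (s, t), w in net.weights.items()},
    )


# ---------------------------------------------------------------------
# Interaction matrices
# ---------------------------------------------------------------------

def build_interaction_matrix(net: DirectedNetwork) -> np.ndarray:
    """A with diagonal -1 and A[t, s] = weight of edge s -> t (node order = net.nodes)."""
    idx = {v: i for i, v in enumerate(net.nodes)}
    n = net.n_nodes
    A = -np.eye(n)
    for (s, t) in net.edges:
        A[idx[t], idx[s]] = net.weights.get((s, t), 1.0)
    return A


def _is_stable(A: np.ndarray) -> bool:
    return float(np.max(np.linalg.eigvals(A).real)) < -1e-9


def assign_random_weights(
    net: DirectedNetwork,
    rng: np.random.Generator,
    weight_range: tuple[float, float] = (0.5, 1.5),
    signed: bool = True,
    max_tries: int = 100,
) -> DirectedNetwork:
    """Draw edge weights uniform in +/-[lo, hi], redrawing until A is stable."""
    lo, hi = weight_range
    edges = sorted(net.edges, key=lambda e: (str(e[0]), str(e[1])))
    for _ in range(max_tries):
        mags = rng.uniform(lo, hi, size=len(edges))
        signs = rng.choice([-1.0, 1.0], size=len(edges)) if signed else np.ones(len(edges))
        weights = {e: float(m * s) for e, m, s in zip(edges, mags, signs)}
        cand = DirectedNetwork(nodes=list(net.nodes), edges=set(net.edges), weights=weights)
        if _is_stable(build_interaction_matrix(cand)):
            return cand
    raise DatagenError(f"could not draw a stable weight assignment in {max_tries} tries")


def check_stable(A: np.ndarray) -> None:
    ev = np.linalg.eigvals(A)
    if float(np.max(ev.real)) >= -1e-9:
        raise DatagenError(
            f"interaction matrix is unstable; eigenvalue real parts in "
            f"[{ev.real.min():.3f}, {ev.real.max():.3f}]"
        )


def population_covariance(
    A: np.ndarray,
    perturbed_idx: list[int],
    sigma2: float = 0.0,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Population covariance A^-1 B B^T A^-T + sigma^2 D for unit-variance forces
    on the perturbed nodes (B the corresponding indicator columns)."""
    n = A.shape[0]
    B = np.zeros((n, n))
    for i in perturbed_idx:
        B[i, i] = 1.0
    Ainv = np.linalg.inv(A)
    D = np.diag(r) if r is not None else np.eye(n)
    return Ainv @ B @ B.T @ Ainv.T + sigma2 * D


# ---------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------

def _add_noise(
    fc: np.ndarray,
    sigma: float,
    noise_mode: str,
    rng: np.random.Generator,
    r: np.ndarray | None = None,
) -> np.ndarray:
    """Measurement noise on a genes x samples log2 fold-change block."""
    if sigma == 0:
        return fc
    if noise_mode == "expr_fraction":
        # sigma is a CV of the expression level: constant sd on log2 scale
        sd = np.full_like(fc, sigma * LOG2E)
    elif noise_mode == "fc_fraction":
        sd = np.maximum(sigma * np.abs(fc), FC_NOISE_FLOOR)
    elif noise_mode == "additive":
        sd = np.full_like(fc, sigma)
    else:
        raise DatagenError(f"unknown noise_mode {noise_mode!r}")
    if r is not None:
        sd = sd * np.sqrt(r)[:, None]
    return fc + rng.standard_normal(fc.shape) * sd


def _screen_from_blocks(
    genes: list[str],
    blocks: list[tuple[str, object, int, np.ndarray]],
) -> KnockoutScreen:
    cols, pert, rep = {}, {}, {}
    for name, perturbed, replicate, vec in blocks:
        cols[name] = vec
        pert[name] = perturbed
        rep[name] = replicate
    values = pd.DataFrame(cols, index=genes)
    return KnockoutScreen(values, pd.Series(pert, dtype=object), pd.Series(rep))


# ---------------------------------------------------------------------
# Linear steady-state model
# ---------------------------------------------------------------------

def simulate_linear_knockouts(
    net: DirectedNetwork,
    design: PerturbationDesign,
    sigma: float = 0.0,
    noise_mode: str = "additive",
    seed: int | np.random.Generator = 0,
    n_wt_replicates: int = 8,
    noise_ratios: np.ndarray | None = None,
) -> KnockoutScreen:
    """Steady-state log2 fold changes y = -A^-1 B u per single-node experiment.

    Each experiment (node, replicate, strength) applies the force
    ``u = strength * e_node``; the returned screen holds one sample per
    experiment plus ``n_wt_replicates`` wild-type replicates (pure noise).
    Perturbation forces enter relative to the reference state, whose
    sample mean is removed downstream, so the centring constraint on u is
    satisfied by construction of the covariance estimator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = build_interaction_matrix(net)
    check_stable(A)
    Ainv = np.linalg.inv(A)
    idx = {v: i for i, v in enumerate(net.nodes)}
    genes = [gene_id(v) for v in net.nodes]
    blocks = []
    for e_no, (node, replicate, strength) in enumerate(design.experiments):
        if node not in idx:
            raise DatagenError(f"experiment perturbs unknown node {node!r}")
        y = -Ainv[:, idx[node]] * strength
        blocks.append((f"ko_{node}_r{replicate}_{e_no}", gene_id(node), replicate, y))
    for r_no in range(n_wt_replicates):
        blocks.append((f"wt_r{r_no}", np.nan, r_no, np.zeros(net.n_nodes)))
    screen = _screen_from_blocks(genes, blocks)
    noisy = _add_noise(screen.values.to_numpy(), sigma, noise_mode, rng, noise_ratios)
    screen.values.iloc[:, :] = noisy
    return screen


# ---------------------------------------------------------------------
# Nonlinear ODE model
# ---------------------------------------------------------------------

@dataclass
class _HillParams:
    K: np.ndarray  # per-edge threshold
    h: np.ndarray  # per-edge Hill coefficient
    vmax: np.ndarray  # per-gene maximal regulated production
    basal: float


def _draw_hill_params(net: DirectedNetwork, rng: np.random.Generator) -> tuple[list, _HillParams]:
    edges = sorted(net.edges, key=lambda e: (str(e[0]), str(e[1])))
    K = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=len(edges)))
    h = rng.choice([1.0, 2.0], size=len(edges))
    vmax = np.exp(rng.uniform(np.log(1.0), np.log(4.0), size=net.n_nodes))
    return edges, _HillParams(K=K, h=h, vmax=vmax, basal=0.1)


def _nonlinear_rhs(net: DirectedNetwork, edges, par: _HillParams):
    idx = {v: i for i, v in enumerate(net.nodes)}
    incoming: dict[int, list[tuple[int, float, float, float]]] = {i: [] for i in range(net.n_nodes)}
    for e_no, (s, t) in enumerate(edges):
        w = net.weights.get((s, t), 1.0)
        incoming[idx[t]].append((idx[s], np.sign(w) or 1.0, par.K[e_no], par.h[e_no]))

    def rhs(x: np.ndarray, clamped: dict[int, float]) -> np.ndarray:
        x = np.maximum(x, EXPRESSION_FLOOR)
        dx = np.empty_like(x)
        for i in range(x.size):
            regs = incoming[i]
            if regs:
                terms = []
                for src, sign, K, h in regs:
                    act = x[src] ** h / (K**h + x[src] ** h)
                    terms.append(act if sign > 0 else 1.0 - act)
                prod = par.basal + par.vmax[i] * float(np.mean(terms))
            else:
                prod = par.basal + par.vmax[i] * 0.5
            dx[i] = prod - x[i]
        for i, val in clamped.items():
            dx[i] = 0.0
            x[i] = val
        return dx

    return rhs


def _steady_state(rhs, x0: np.ndarray, clamped: dict[int, float]) -> np.ndarray | None:
    x0 = x0.copy()
    for i, val in clamped.items():
        x0[i] = val
    sol = root(lambda x: rhs(x, clamped), x0, method="hybr", tol=1e-10)
    x = sol.x
    if not sol.success or np.max(np.abs(rhs(x.copy(), clamped))) > 1e-6:
        # relaxation fallback
        for _ in range(20000):
            dx = rhs(x.copy(), clamped)
            x = np.maximum(x + 0.05 * dx, EXPRESSION_FLOOR)
            for i, val in clamped.items():
                x[i] = val
            if np.max(np.abs(dx)) < 1e-10:
                break
        else:
            return None
    for i, val in clamped.items():
        x[i] = val
    return np.maximum(x, EXPRESSION_FLOOR)


def simulate_nonlinear_knockouts(
    net: DirectedNetwork,
    design: PerturbationDesign,
    noise_sd_fraction: float = 0.1,
    noise_mode: str = "expr_fraction",
    seed: int | np.random.Generator = 0,
    n_wt_replicates: int = 8,
) -> KnockoutScreen:
    """Hill-kinetics steady-state knockouts: production of the knocked-out
    gene is removed (expression clamped to the floor); output is
    log2(perturbed steady state / wild-type steady state) plus noise.

    Non-convergent experiments are excluded with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise_rng = np.random.default_rng(rng.integers(2**31))  # separated noise stream
    edges, par = _draw_hill_params(net, rng)
    rhs = _nonlinear_rhs(net, edges, par)
    idx = {v: i for i, v in enumerate(net.nodes)}
    x_wt = _steady_state(rhs, np.ones(net.n_nodes), {})
    if x_wt is None:
        raise DatagenError("wild-type steady state did not converge")
    genes = [gene_id(v) for v in net.nodes]
    blocks = []
    skipped = []
    cache: dict = {}
    for e_no, (node, replicate, _strength) in enumerate(design.experiments):
        i = idx[node]
        if node not in cache:
            cache[node] = _steady_state(rhs, x_wt, {i: EXPRESSION_FLOOR})
        x_ko = cache[node]
        if x_ko is None:
            skipped.append(node)
            continue
        fc = np.log2(x_ko / x_wt)
        blocks.append((f"ko_{node}_r{replicate}_{e_no}", gene_id(node), replicate, fc))
    if skipped:
        warnings.warn(f"excluded non-convergent knockouts: {sorted(set(skipped))}")
    for r_no in range(n_wt_replicates):
        blocks.append((f"wt_r{r_no}", np.nan, r_no, np.zeros(net.n_nodes)))
    screen = _screen_from_blocks(genes, blocks)
    noisy = _add_noise(screen.values.to_numpy(), noise_sd_fraction, noise_mode, noise_rng)
    screen.values.iloc[:, :] = noisy
    return screen


# ---------------------------------------------------------------------
# Three-node demonstration (noise-induced false positive)
# ---------------------------------------------------------------------

def three_node_chain(w21: float = 1.0, w32: float = 1.0) -> DirectedNetwork:
    """The chain 1 -> 2 -> 3 with planted strengths."""
    return DirectedNetwork(
        nodes=[1, 2, 3],
        edges={(1, 2), (2, 3)},
        weights={(1, 2): w21, (2, 3): w32},
    )


def make_three_node_demo(
    noise_grid: list[float],
    n_experiments: int = 1000,
    seed: int = 0,
    w21: float = 1.0,
    w32: float = 1.0,
) -> list[KnockoutScreen]:
    """Datasets for the chain 1 -> 2 -> 3 with nodes 1 and 2 independently
    perturbed, one screen per measurement-noise level.

    Half the experiments perturb node 1, half node 2, each with a standard
    -normal force; node 3 is never perturbed.  The absent link 1 -> 3 is
    the classic noise-induced false positive of partial-correlation
    methods.
    """
    net = three_node_chain(w21, w32)
    base_rng = np.random.default_rng(seed)
    strengths = base_rng.standard_normal(n_experiments)
    nodes = [1 if k % 2 == 0 else 2 for k in range(n_experiments)]
    screens = []
    for noise_sd in noise_grid:
        rng = np.random.default_rng(base_rng.integers(2**31))
        design = PerturbationDesign(
            n_nodes=3,
            experiments=[(nodes[k], k, float(strengths[k])) for k in range(n_experiments)],
            knockout=False,
        )
        screens.append(
            simulate_linear_knockouts(
                net, design, sigma=noise_sd, noise_mode="additive", seed=rng, n_wt_replicates=8
            )
        )
    return screens
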