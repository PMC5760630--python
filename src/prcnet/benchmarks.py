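"""Reproducible benchmark experiments on synthetic knockout screens.

These routines generate the study conditions used throughout the package's
validation: scale-free regulatory topologies (exponent 2.5, mean degree 2
or 3), strong single-gene knockouts with a small number of replicates,
10% multiplicative measurement noise, and residual-bootstrap significance.
They are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import datagen
from .datasets import KnockoutScreen, PerturbationDesign
from .evaluation import (
    noise_free_inferable_flags,
    partial_correlation_coefficients,
    true_positive_fraction,
)
from .model import PRCModel
from .networks import (
    DirectedNetwork,
    count_inferable_links,
    expected_inferable_fraction,
    F_closed_form,
    generate_random_network,
    generate_scale_free_network,
    inferability_IF,
    inferability_IF_star,
)
from .noise import ReplicateResiduals
from .prc import prc_min_strength

KNOCKOUT_STRENGTH = -5.0  # log2-scale force of a deletion (~30-fold down)
NOISE_CV = 0.1  # measurement noise: 10% of the expression level


def make_knockout_screen(
    n: int,
    q: float,
    n_replicates: int,
    seed: int,
    noise_cv: float = NOISE_CV,
    mean_degree: float = 2.0,
    gamma: float = 2.5,
    n_wt: int = 16,
    sigma_mode: str = "expr_fraction",
) -> tuple[DirectedNetwork, list, KnockoutScreen]:
    """A weighted scale-free network plus a linear knockout screen.

    A fraction q of nodes receives single-gene knockouts (fixed strong
    force, ``n_replicates`` replicates each); wild-type replicates are
    appended for the noise model.
    """
    rng = np.random.default_rng(seed)
    net = generate_scale_free_network(n, gamma, mean_degree, "outgoing", rng)
    net = datagen.assign_random_weights(net, rng)
    k = max(1, int(round(q * n)))
    perturbed = sorted(int(v) for v in rng.choice(n, size=k, replace=False))
    design = PerturbationDesign.single_knockouts(
        perturbed, n, n_replicates=n_replicates, strength=KNOCKOUT_STRENGTH, rng=rng
    )
    screen = datagen.simulate_linear_knockouts(
        net, design, sigma=noise_cv, noise_mode=sigma_mode, seed=rng, n_wt_replicates=n_wt
    )
    return net, perturbed, screen


@dataclass
class TrendPoint:
    q: float
    n_replicates: int
    method: str
    tp_all: float
    tp_inferable: float
    n_false: int
    F_q: float


def pipeline_trend_point(
    n: int,
    q: float,
    n_replicates: int,
    method: str,
    seed: int,
    n_boot: int = 200,
    noise_cv: float = NOISE_CV,
) -> TrendPoint:
    """True-positive fraction of one pipeline run against the planted truth."""
    net, perturbed, screen = make_knockout_screen(n, q, n_replicates, seed, noise_cv)
    truth = datagen.relabel_to_genes(net)
    _, flags = count_inferable_links(net, set(perturbed), mode="motif")
    gflags = {
        (datagen.gene_id(s), datagen.gene_id(t)): v for (s, t), v in flags.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = PRCModel(screen, method=method, n_boot=n_boot).fit(seed=seed)
    pred = res.significant_gene_links()
    tp_all = true_positive_fraction(pred, truth)
    denom_inf = sum(gflags.values())
    tp_inf = (
        true_positive_fraction(pred, truth, gflags, "inferable_links")
        if denom_inf
        else float("nan")
    )
    return TrendPoint(
        q=q,
        n_replicates=n_replicates,
        method=method,
        tp_all=tp_all,
        tp_inferable=tp_inf,
        n_false=len(pred - set(truth.edges)),
        F_q=F_closed_form(net, q),
    )


def noise_free_theory_check(
    n: int, q: float, seed: int, n_replicates: int = 3
) -> dict:
    """Noise-free numerical inferability vs the counting theory.

    Generates a noise-free knockout screen (random per-node forces for
    genericity), flags each true link numerically and compares with the
    refined counting flags for the same perturbed set.
    """
    rng = np.random.default_rng(seed)
    net = generate_scale_free_network(n, 2.5, 2.0, "outgoing", rng)
    net = datagen.assign_random_weights(net, rng)
    k = max(1, int(round(q * n)))
    perturbed = sorted(int(v) for v in rng.choice(n, size=k, replace=False))
    design = PerturbationDesign.single_knockouts(
        perturbed, n, n_replicates=n_replicates, rng=rng, random_strength=True
    )
    screen = datagen.simulate_linear_knockouts(
        net, design, sigma=0.0, seed=rng, n_wt_replicates=2
    )
    truth = datagen.relabel_to_genes(net)
    numeric = noise_free_inferable_flags(screen, truth)
    _, refined = count_inferable_links(net, set(perturbed), mode="refined")
    refined = {
        (datagen.gene_id(s), datagen.gene_id(t)): v for (s, t), v in refined.items()
    }
    agree = np.mean([numeric[e] == refined[e] for e in refined])
    return {
        "q": q,
        "agreement": float(agree),
        "fraction_numeric": float(np.mean(list(numeric.values()))),
        "fraction_refined": float(np.mean(list(refined.values()))),
        "F_closed_form": F_closed_form(net, q),
        "n_edges": net.n_edges,
    }


def three_node_noise_sweep(
    noise_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_experiments: int = 4000,
    seed: int = 0,
) -> dict:
    """The noise-induced false-positive demonstration on the chain 1->2->3.

    Returns, per measurement-noise level, the strength of the absent link
    1->3 relative to the true link 2->3 for PRC and for the partial
    -correlation baseline.
    """
    screens = datagen.make_three_node_demo(list(noise_grid), n_experiments, seed)
    prc_ratio, pc_ratio = [], []
    for screen in screens:
        mn13 = prc_min_strength(screen, "G3", "G1")
        mn23 = prc_min_strength(screen, "G3", "G2")
        prc_ratio.append(mn13 / mn23)
        beta = partial_correlation_coefficients(screen)
        pc_ratio.append(float(beta.loc["G3", "G1"] / beta.loc["G3", "G2"]))
    return {
        "noise_grid": list(noise_grid),
        "prc_relative_strength": prc_ratio,
        "pc_relative_strength": pc_ratio,
    }


def inferability_orderings(n: int = 300, seed: int = 0) -> dict:
    """Fig-2-style structural comparisons of network inferability."""
    rng = np.random.default_rng(seed)
    sf = generate_scale_free_network(n, 2.5, 3.0, "outgoing", rng)
    rand = generate_random_network(n, 3.0, rng)
    IF_out = inferability_IF(sf).I_F
    IF_in = inferability_IF(sf.invert()).I_F
    IF_rand = inferability_IF(rand).I_F
    by_degree = {}
    for k in (2.0, 3.0, 4.0, 6.0):
        net_k = generate_scale_free_network(n, 2.5, k, "outgoing", np.random.default_rng(seed + 17))
        by_degree[k] = inferability_IF(net_k).I_F
    return {
        "IF_outgoing_hubs": IF_out,
        "IF_random": IF_rand,
        "IF_incoming_hubs": IF_in,
        "IF_by_mean_degree": by_degree,
    }


def inferability_measure_correlation(
    n_networks: int = 24, n: int = 150, seed: int = 0
) -> float:
    """Spearman rank correlation of I_F and I_F* over a mixed ensemble."""
    rng = np.random.default_rng(seed)
    ifs, ifstars = [], []
    for i in range(n_networks):
        kind = i % 3
        gamma = float(rng.uniform(2.1, 3.5))
        k = float(rng.uniform(1.5, 5.0))
        if kind == 0:
            net = generate_scale_free_network(n, gamma, k, "outgoing", rng)
        elif kind == 1:
            net = generate_scale_free_network(n, gamma, k, "incoming", rng)
        else:
            net = generate_random_network(n, k, rng)
        ifs.append(inferability_IF(net).I_F)
        ifstars.append(inferability_IF_star(net))
    rho, _ = stats.spearmanr(ifs, ifstars)
    return float(rho)


def sigma_invariance_deviation(sigmas=(0.0, 0.5, 1.0, 5.0, 25.0)) -> float:
    """Largest change of a PRC row estimate across measurement-noise levels,
    on population covariances of a planted two-gene cascade."""
    from .prc import ppca_decompose, prc_row_single_unperturbed

    a, b = 2.0, 1.0
    rows = []
    for s2 in sigmas:
        C = np.array([[b * b, a * b * b], [a * b * b, a * a * b * b]]) + s2 * np.eye(2)
        dec = ppca_decompose(C, N0=1)
        rows.append(prc_row_single_unperturbed(dec, 1).to_numpy())
    rows = np.asarray(rows)
    return float(np.max(np.abs(rows - rows[0])))
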