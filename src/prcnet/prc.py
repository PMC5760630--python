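"""Partial response coefficients (PRC) from knockout-screen covariances.

The observed log-expression obeys a linear stationary model
``0 = A (y - y_ref) + B u`` with additive measurement noise
``y_obs = y + eps``, ``eps ~ N(0, sigma^2 D)``; ``A_ij`` is the direct
effect of gene j on gene i (``A_ii := -1`` by convention).  The covariance
of the observations is then ``C = A^-1 B B^T A^-T + sigma^2 D``, whose
maximum-likelihood decomposition is an eigenvalue problem of the noise
-whitened sample covariance: with ascending eigenvalues L_1 <= ... <= L_N
and orthonormal eigenvectors U,

* the noise variance estimate is the mean of the N0 smallest eigenvalues
  (N0 = number of unperturbed observables = zero singular values of A^-1 B),
* the signal singular values are sqrt(max(L_k - sigma^2, 0)) for k > N0.

When a single gene i is unperturbed, the i-th row of A (relative to A_ii)
is read off the smallest-eigenvalue eigenvector:
``A_ij / A_ii = (U_j1 / sqrt(r_j)) / (U_i1 / sqrt(r_i))``.
Crucially the measurement-noise level sigma shifts eigenvalues but not
eigenvectors, so the estimator is asymptotically unbiased to noise.

For several unperturbed genes, the strength of a candidate link j -> i is
bracketed between a *minimum* (variation of i unexplainable by any route
not passing through j) and a *maximum* (total effect of j on i), each a
two-node errors-in-variables problem solved by the same smallest
-eigenvector construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import KnockoutScreen

DEFAULT_EPSILON = 0.05
EIG_TIE_TOL = 1e-12
RATIO_DENOM_TOL = 1e-10


class PRCError(ValueError):
    pass


class NotIdentifiableError(PRCError):
    """The requested row/ratio carries no weight in the null direction."""


@dataclass
class NoiseRatios:
    """Scaled per-gene noise variances r_i = sigma_i^2 / sigma^2 (matrix D)."""

    r: pd.Series

    def __post_init__(self) -> None:
        if (self.r <= 0).any():
            raise PRCError("all noise ratios r_i must be positive")

    @classmethod
    def isotropic(cls, genes) -> "NoiseRatios":
        return cls(pd.Series(1.0, index=list(genes)))

    def vector(self, genes) -> np.ndarray:
        try:
            return self.r.loc[list(genes)].to_numpy(dtype=float)
        except KeyError as exc:
            raise PRCError(f"noise ratio missing for gene: {exc}") from exc


@dataclass
class SampleCovariance:
    S: np.ndarray
    genes: list
    n_samples: int
    regularised: bool
    epsilon: float


@dataclass
class CovarianceDecomposition:
    S: np.ndarray
    genes: list
    r: np.ndarray
    eigenvalues: np.ndarray  # ascending, of the whitened covariance
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    N0: int
    sigma2_hat: float
    Sigma_hat: np.ndarray  # diagonal of the signal singular values
    n_clipped: int = 0
    degenerate_nullspace: bool = False

    def reconstruct_whitened(self) -> np.ndarray:
        core = np.diag(self.Sigma_hat**2 + self.sigma2_hat)
        return self.eigenvectors @ core @ self.eigenvectors.T


def sample_covariance(
    data: KnockoutScreen | np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    genes: list | None = None,
) -> SampleCovariance:
    """Unbiased sample covariance of the log2 fold changes.

    The reference state is the sample mean; scaling is P/(P-1).  If the
    covariance is rank-deficient (fewer independent samples than genes),
    it is shrunk towards the identity, S -> (1-eps) S + eps I, and the
    regularisation is recorded.
    """
    if isinstance(data, KnockoutScreen):
        Y = data.values.to_numpy(dtype=float)
        genes = data.genes
    else:
        Y = np.asarray(data, dtype=float)
        genes = genes if genes is not None else list(range(Y.shape[0]))
    n, P = Y.shape
    if P < 2:
        raise PRCError("need at least 2 samples for a covariance estimate")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    S = (Yc @ Yc.T) / (P - 1)
    regularised = False
    # centring spends one degree of freedom; P-1 independent columns at most
    if P - 1 < n or np.linalg.matrix_rank(S) < n:
        S = (1.0 - epsilon) * S + epsilon * np.eye(n)
        regularised = True
    return SampleCovariance(S=S, genes=list(genes), n_samples=P, regularised=regularised, epsilon=epsilon)


def ppca_decompose(
    S: np.ndarray | SampleCovariance,
    N0: int,
    noise: NoiseRatios | np.ndarray | None = None,
    genes: list | None = None,
) -> CovarianceDecomposition:
    """ML decomposition of the (noise-whitened) sample covariance.

    Eigenvectors are those of ``D^(-1/2) S D^(-1/2)``; downstream
    estimators fold the un-whitening ``D^(-1/2)`` factors back in.
    """
    if isinstance(S, SampleCovariance):
        genes = S.genes
        S = S.S
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    genes = genes if genes is not None else list(range(n))
    if S.shape != (n, n) or not np.allclose(S, S.T, atol=1e-8):
        raise PRCError("S must be a symmetric square matrix")
    if not (1 <= N0 < n):
        raise PRCError(f"need 1 <= N0 < N, got N0={N0}, N={n}")
    if noise is None:
        r = np.ones(n)
    elif isinstance(noise, NoiseRatios):
        r = noise.vector(genes)
    else:
        r = np.asarray(noise, dtype=float)
    if np.any(r <= 0):
        raise PRCError("noise ratios must be positive")
    d = 1.0 / np.sqrt(r)
    Sw = S * np.outer(d, d)
    lam, U = np.linalg.eigh(Sw)  # ascending
    sigma2 = float(np.mean(lam[:N0]))
    diff = lam - sigma2
    n_clipped = int(np.sum((diff < 0) & (np.arange(n) >= N0)))
    if n_clipped:
        warnings.warn(f"{n_clipped} signal eigenvalues below noise floor were clipped to zero")
    Sigma = np.sqrt(np.clip(diff, 0.0, None))
    Sigma[:N0] = 0.0
    degenerate = bool(N0 < n and abs(lam[N0] - lam[N0 - 1]) < EIG_TIE_TOL)
    return CovarianceDecomposition(
        S=S,
        genes=list(genes),
        r=r,
        eigenvalues=lam,
        eigenvectors=U,
        N0=N0,
        sigma2_hat=sigma2,
        Sigma_hat=Sigma,
        n_clipped=n_clipped,
        degenerate_nullspace=degenerate,
    )


def prc_row_single_unperturbed(decomp: CovarianceDecomposition, i) -> pd.Series:
    """Row i of A (convention A_ii = -1) when i is the only unperturbed gene.

    Uses the smallest-eigenvalue eigenvector u of the whitened covariance:
    ``A_ij / A_ii = (u_j / sqrt(r_j)) / (u_i / sqrt(r_i))``.
    """
    if decomp.N0 != 1:
        raise PRCError(f"single-unperturbed row formula requires N0 = 1, got N0={decomp.N0}")
    genes = decomp.genes
    if i not in genes:
        raise PRCError(f"gene {i!r} not in decomposition")
    idx = genes.index(i)
    u = decomp.eigenvectors[:, 0].copy()
    if u[idx] < 0:  # fix global sign: target component positive
        u = -u
    d = 1.0 / np.sqrt(decomp.r)
    denom = u[idx] * d[idx]
    if abs(denom) < RATIO_DENOM_TOL:
        raise NotIdentifiableError(
            f"row {i!r} not identifiable: null-direction weight {denom:.2e} below tolerance"
        )
    ratio = (u * d) / denom  # A_ij / A_ii
    return pd.Series(-ratio, index=genes, name=i)  # A_ii = -1


def _pair_min_eigvec_ratio(C2: np.ndarray, d11: float, d22: float) -> float:
    """Relative strength from the smaller-eigenvalue eigenvector of the
    whitened 2x2 covariance of (target-residual, source).

    Returns -(u_src / sqrt(d_src)) / (u_resid / sqrt(d_resid)), i.e. the
    link strength under the A_ii = -1 convention.
    """
    d = np.array([1.0 / np.sqrt(d11), 1.0 / np.sqrt(d22)])
    Cw = C2 * np.outer(d, d)
    lam, U = np.linalg.eigh(Cw)
    u = U[:, 0]
    if u[0] < 0:
        u = -u
    denom = u[0] * d[0]
    if abs(denom) < RATIO_DENOM_TOL:
        raise NotIdentifiableError("two-node ratio denominator below tolerance")
    return float(-(u[1] * d[1]) / denom)


def _cov2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    m = np.vstack([x, y])
    m = m - m.mean(axis=1, keepdims=True)
    return (m @ m.T) / (m.shape[1] - 1)


def min_strength_core(
    V: np.ndarray,
    i_idx: int,
    j_idx: int,
    unperturbed_mask: np.ndarray,
    r: np.ndarray,
) -> float:
    """Minimum relative strength of the link j -> i from an array block.

    ``V`` is genes x samples with all samples perturbing gene i already
    removed; ``unperturbed_mask[g]`` marks genes with no perturbation
    experiment among the remaining samples.  Gene j is dropped from the
    observables (its perturbative effect stays in the samples); the
    reduced row coefficients ``A'_il / A'_ii`` — from the null-space
    eigenvectors of the reduced whitened covariance,
    ``(sum_{k<=N0} U_ik U_lk / sqrt(r_l)) / (sum_{k<=N0} U_ik^2 / sqrt(r_i))``
    — explain i by every route not through j; the residual of i is then
    paired with y_j in a two-node errors-in-variables problem with
    effective residual noise ratio ``r_i + sum_l (A'_il/A'_ii)^2 r_l``.

    Eigenvectors are invariant under the ridge regularisation of the
    covariance, so none is applied here.
    """
    n, P = V.shape
    if P < 2:
        raise PRCError("need at least 2 samples")
    red = np.array([g for g in range(n) if g != j_idx])
    Vr = V[red]
    i_red = int(np.searchsorted(red, i_idx))
    r_red = r[red]
    if len(red) == 1:
        # no other observables: nothing can explain i, residual is y_i
        coefs = np.ones(1)
    else:
        Vc = Vr - Vr.mean(axis=1, keepdims=True)
        S = (Vc @ Vc.T) / (P - 1)
        count = int(unperturbed_mask[red].sum())
        if count < 1:
            raise PRCError("reduced system has no unperturbed observable")
        d = 1.0 / np.sqrt(r_red)
        Sw = S * np.outer(d, d)
        lam, U = np.linalg.eigh(Sw)
        # N0: dimension of the no-signal subspace.  The design count of
        # unperturbed observables is the generic upper bound, but exact
        # alternative-route constraints make perturbation responses
        # degenerate, so the realised null space is read off the
        # spectrum: eigenvalues within a factor of the smallest (the
        # noise floor), or negligible against the largest.
        thresh = max(8.0 * lam[0], 1e-9 * max(lam[-1], 1e-30))
        spectral = int(np.sum(lam <= thresh))
        N0 = min(max(spectral, 1), count, len(red) - 1)
        U0 = U[:, :N0]
        num = (U0 @ U0[i_red]) * d
        den = num[i_red]
        if abs(den) < RATIO_DENOM_TOL:
            # the null directions carry no weight on i: no alternative
            # route explains the target, so the residual is y_i itself
            coefs = np.zeros(len(red))
            coefs[i_red] = 1.0
        else:
            coefs = num / den  # A'_il / A'_ii, with coefs[i_red] = 1
    resid = coefs @ Vr
    yj = V[j_idx]
    C2 = _cov2(resid, yj)
    others = np.arange(len(red)) != i_red
    d_resid = float(r[i_idx] + np.sum(coefs[others] ** 2 * r_red[others]))
    return _pair_min_eigvec_ratio(C2, d_resid, float(r[j_idx]))


def row_strength_core(V: np.ndarray, i_idx: int, j_idx: int, r: np.ndarray) -> float:
    """Direct strength A_ij (A_ii = -1) when i is the only unperturbed
    observable: the smallest-eigenvalue eigenvector of the full whitened
    covariance is the stationarity constraint of row i, so the link is
    identified exactly (no bracketing needed)."""
    n, P = V.shape
    if P < 2:
        raise PRCError("need at least 2 samples")
    Vc = V - V.mean(axis=1, keepdims=True)
    S = (Vc @ Vc.T) / (P - 1)
    d = 1.0 / np.sqrt(r)
    lam, U = np.linalg.eigh(S * np.outer(d, d))
    u = U[:, 0]
    if u[i_idx] < 0:
        u = -u
    den = u[i_idx] * d[i_idx]
    if abs(den) < RATIO_DENOM_TOL:
        raise NotIdentifiableError("target carries no weight in the null direction")
    return float(-(u[j_idx] * d[j_idx]) / den)


def strength_bracket_core(
    V: np.ndarray,
    i_idx: int,
    j_idx: int,
    unperturbed_mask: np.ndarray,
    r: np.ndarray,
) -> tuple[float, float]:
    """(minimum, maximum) relative strength of j -> i.

    With a single unperturbed observable (the target itself) the row
    formula identifies the strength and the bracket collapses; otherwise
    the two-node residual construction yields the lower bound and the
    plain two-node problem the upper bound.
    """
    if int(unperturbed_mask.sum()) == 1 and unperturbed_mask[i_idx]:
        s = row_strength_core(V, i_idx, j_idx, r)
        return s, s
    return (
        min_strength_core(V, i_idx, j_idx, unperturbed_mask, r),
        max_strength_core(V, i_idx, j_idx, r),
    )


def max_strength_core(V: np.ndarray, i_idx: int, j_idx: int, r: np.ndarray) -> float:
    """Maximum relative strength of j -> i (off-diagonal A' set to zero):
    the plain two-node errors-in-variables problem on (y_i, y_j)."""
    if V.shape[1] < 2:
        raise PRCError("need at least 2 samples")
    C2 = _cov2(V[i_idx], V[j_idx])
    return _pair_min_eigvec_ratio(C2, float(r[i_idx]), float(r[j_idx]))


def _screen_arrays(
    data: KnockoutScreen, i, j, noise: NoiseRatios | None
) -> tuple[np.ndarray, int, int, np.ndarray, np.ndarray]:
    work = data.drop_samples_perturbing(i)
    if not work.samples_perturbing(j):
        raise PRCError(
            f"source {j!r} has no perturbation samples after removing target experiments"
        )
    genes = work.genes
    V = work.values.to_numpy(dtype=float)
    unpert = work.unperturbed_genes()
    mask = np.array([g in unpert for g in genes])
    r = noise.vector(genes) if noise is not None else np.ones(len(genes))
    return V, genes.index(i), genes.index(j), mask, r


def prc_min_strength(
    data: KnockoutScreen,
    i,
    j,
    noise: NoiseRatios | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Minimum relative strength of the link j -> i (A_ii = -1 convention).

    Samples perturbing the target i are removed first; see
    :func:`min_strength_core` for the construction.
    """
    V, i_idx, j_idx, mask, r = _screen_arrays(data, i, j, noise)
    return min_strength_core(V, i_idx, j_idx, mask, r)


def prc_max_strength(
    data: KnockoutScreen,
    i,
    j,
    noise: NoiseRatios | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Maximum relative strength of j -> i: the total effect of j on i."""
    V, i_idx, j_idx, _mask, r = _screen_arrays(data, i, j, noise)
    return max_strength_core(V, i_idx, j_idx, r)


def link_strength_bracket(
    data: KnockoutScreen,
    i,
    j,
    noise: NoiseRatios | None = None,
) -> tuple[float, float]:
    """(minimum, maximum) relative strength of j -> i, collapsing to the
    exact row estimate when i is the only unperturbed observable."""
    V, i_idx, j_idx, mask, r = _screen_arrays(data, i, j, noise)
    return strength_bracket_core(V, i_idx, j_idx, mask, r)


def classify_link_inferability(
    min_samples: np.ndarray,
    max_samples: np.ndarray,
    alpha: float = 0.05,
) -> bool:
    """Inferability call from paired bootstrap distributions.

    A link is *non-inferable* iff (i) the bootstrap interval of
    (max - min) excludes 0 at level alpha AND (ii) the interval of the
    minimum strength includes 0 — i.e. alternative routes could fully
    explain the target's response.  Returns True when inferable.
    """
    mn = np.asarray(min_samples, dtype=float)
    mx = np.asarray(max_samples, dtype=float)
    if mn.size == 0 or mx.size == 0 or mn.size != mx.size:
        raise PRCError("need non-empty, equal-length bootstrap distributions")
    lo, hi = alpha / 2.0, 1.0 - alpha / 2.0
    diff = mx - mn
    d_lo, d_hi = np.quantile(diff, [lo, hi])
    diff_excludes_zero = (d_lo > 0) or (d_hi < 0)
    m_lo, m_hi = np.quantile(mn, [lo, hi])
    min_includes_zero = (m_lo <= 0.0 <= m_hi)
    non_inferable = diff_excludes_zero and min_includes_zero
    return not non_inferable


@dataclass
class LinkEstimate:
    """An inferred directed link with strength bracket and significance."""

    source: object
    target: object
    strength_min: float
    strength_max: float
    significance: float = np.nan  # bootstrap p-value of the minimum strength
    inferable: bool = True
    significant: bool = False
    bootstrap_min: np.ndarray = field(default_factory=lambda: np.array([]))
    bootstrap_max: np.ndarray = field(default_factory=lambda: np.array([]))
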