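"""Gene-specific biological variability from wild-type replicates.

Replicate residuals ``delta_in = log2(r_in) - <log2(r_in)>_n`` (gene i,
replicate n, ratios against the pooled reference) quantify the natural
variation among biological replicates.  They supply

* per-gene standard deviations sigma_i and scaled ratios r_i = sigma_i^2 /
  sigma^2 (the diagonal of the noise-whitening matrix D),
* the delta pool for residual bootstrapping of link strengths,
* the null distribution for the "noise cutoff": a gene responds
  significantly to a knockout when its mean log2 fold change exceeds what
  replicate variability explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import KnockoutScreen
from .prc import NoiseRatios


class NoiseModelError(ValueError):
    pass


@dataclass
class ReplicateResiduals:
    """Centred wild-type replicate residuals and the variances derived from them."""

    delta: pd.DataFrame  # genes x replicates, rows centred
    sigma: pd.Series  # per-gene sd (ddof=1); zero-variance genes get pooled sigma
    pooled_sigma2: float
    excluded_genes: list = field(default_factory=list)
    zero_variance_genes: list = field(default_factory=list)
    t_df: float | None = None

    @property
    def ratios(self) -> NoiseRatios:
        return NoiseRatios(self.sigma**2 / self.pooled_sigma2)

    def standardized_pool(self) -> np.ndarray:
        """All residuals divided by their gene's sigma (z-scores), pooled."""
        z = self.delta.div(self.sigma, axis=0)
        return z.to_numpy().ravel()

    @classmethod
    def from_screen(cls, screen: KnockoutScreen) -> "ReplicateResiduals":
        wt = screen.wild_type_samples()
        if len(wt) < 2:
            raise NoiseModelError("need at least 2 wild-type replicates for noise estimation")
        return replicate_residuals(screen.values[wt])


def replicate_residuals(wt_matrix: pd.DataFrame) -> ReplicateResiduals:
    """Centre wild-type replicate rows and estimate per-gene variability.

    Genes with fewer than 2 finite replicates are excluded (with a
    warning); genes whose replicates are exactly constant are kept but
    assigned the pooled sigma, since a zero variance is not usable as a
    whitening weight.
    """
    counts = wt_matrix.notna().sum(axis=1)
    excluded = list(wt_matrix.index[counts < 2])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} genes with <2 replicates from noise model")
    mat = wt_matrix.loc[counts >= 2]
    if mat.empty:
        raise NoiseModelError("no gene has >= 2 replicates")
    delta = mat.sub(mat.mean(axis=1), axis=0)
    sigma = mat.std(axis=1, ddof=1)
    positive = sigma[sigma > 0]
    if positive.empty:
        raise NoiseModelError("all genes have constant replicates; no variability to estimate")
    pooled_sigma2 = float((positive**2).mean())
    zero_var = list(sigma.index[sigma == 0])
    sigma = sigma.mask(sigma == 0, np.sqrt(pooled_sigma2))
    return ReplicateResiduals(
        delta=delta,
        sigma=sigma,
        pooled_sigma2=pooled_sigma2,
        excluded_genes=excluded,
        zero_variance_genes=zero_var,
    )


def fit_t_df(z: np.ndarray, min_values: int = 100) -> float:
    """ML degrees of freedom of a central t fit to pooled z-scores.

    Location is fixed at 0; the scale is free.  Heavy-tailed replicate
    variability typically yields df around 10; normal data yields a large
    df (the normal limit of the t family).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_values:
        raise NoiseModelError(f"need at least {min_values} values for a stable t fit, got {z.size}")
    df, _, _ = stats.t.fit(z, floc=0)
    return float(df)


def significant_responders(
    source,
    data: KnockoutScreen,
    noise: ReplicateResiduals,
    fdr: float = 0.05,
    correction: str = "bh",
    reference: str = "t",
) -> set:
    """Genes whose mean response to knocking out ``source`` clears the noise cutoff.

    Per gene, the mean log2 fold change over the replicates of the
    source-only knockout is tested against the gene's replicate
    -variability null (sd sigma_i / sqrt(n_rep)); reference quantiles come
    from the fitted t distribution (``reference="t"``, requires
    ``noise.t_df``) or the normal.  Multiple testing: Benjamini-Hochberg at
    ``fdr`` (default) or ``correction="bonferroni"`` at fdr/N.  The source
    gene is always included.
    """
    samples = data.samples_perturbing(source)
    if not samples:
        raise NoiseModelError(f"source {source!r} has no single-perturbation samples")
    sub = data.values[samples]
    n_rep = sub.shape[1]
    mean_fc = sub.mean(axis=1)
    sigma = noise.sigma.reindex(mean_fc.index)
    sigma = sigma.fillna(np.sqrt(noise.pooled_sigma2))
    z = mean_fc / (sigma / np.sqrt(n_rep))
    if reference == "t" and noise.t_df is not None:
        pvals = 2.0 * stats.t.sf(np.abs(z), df=noise.t_df)
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = pd.Series(pvals, index=mean_fc.index)
    mask = pvals.drop(index=[source], errors="ignore")
    if correction == "bh":
        rej, _, _, _ = multipletests(mask.to_numpy(), alpha=fdr, method="fdr_bh")
    elif correction == "bonferroni":
        rej = mask.to_numpy() < fdr / len(data.genes)
    else:
        raise NoiseModelError(f"unknown correction {correction!r}")
    responders = set(mask.index[rej])
    responders.add(source)
    return responders
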