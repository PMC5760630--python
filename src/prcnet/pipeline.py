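"""The five-step inference pipeline: clustering, subnetworks, PRC with
residual bootstrapping, two-node clusters, edge-list assembly.

Steps (the "clustering method"; skipping step 1/4 gives the "subnetwork
method", skipping the noise cutoff entirely gives plain PRC):

1. group genes co-expressed under all perturbations into clusters, treated
   as single network nodes;
2. for each perturbed source node, find the genes responding significantly
   above replicate variability — they define the source's subnetwork;
3. collect all perturbation data for subnetwork members; for each candidate
   target, remove the target's own perturbation experiments and estimate
   the minimum / maximum relative link strength by PRC, with residual
   bootstrapping over wild-type replicate residuals for significance;
4. test the directed link inside every two-gene cluster that has exactly
   one perturbed member;
5. collect significant links in an edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .datasets import KnockoutScreen
from .noise import ReplicateResiduals, significant_responders
from .prc import (
    LinkEstimate,
    NotIdentifiableError,
    PRCError,
    classify_link_inferability,
    max_strength_core,
    strength_bracket_core,
)


class PipelineError(ValueError):
    pass


# ---------------------------------------------------------------------
# Step 1: clustering
# ---------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Partition of genes into co-expression clusters."""

    assignment: dict  # gene -> cluster id

    def clusters(self) -> dict:
        out: dict = {}
        for g, c in self.assignment.items():
            out.setdefault(c, []).append(g)
        return out

    def sizes(self) -> dict:
        return {c: len(gs) for c, gs in self.clusters().items()}

    def size_of(self, gene) -> int:
        return self.sizes()[self.assignment[gene]]

    @classmethod
    def singletons(cls, genes) -> "ClusterSet":
        return cls(assignment={g: i for i, g in enumerate(genes)})


def cluster_coexpressed(data: KnockoutScreen, threshold: float = 0.995) -> ClusterSet:
    """Average-linkage hierarchical clustering on 1 - |Pearson correlation|
    across all perturbation samples, cut at distance 1 - threshold."""
    if not (0.0 < threshold <= 1.0):
        raise PipelineError("co-expression threshold must lie in (0, 1]")
    samples = data.perturbation_samples() or data.samples
    if len(samples) < 2:
        raise PipelineError("need at least 2 samples for co-expression clustering")
    X = data.values[samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance genes: uncorrelated
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - np.abs(corr), 0.0, 1.0)
    dist = (dist + dist.T) / 2.0
    if data.n_genes == 1:
        return ClusterSet.singletons(data.genes)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
    return ClusterSet(assignment=dict(zip(data.genes, (int(c) for c in labels))))


def cluster_screen(data: KnockoutScreen, clusters: ClusterSet) -> tuple[KnockoutScreen, dict]:
    """Collapse a screen to cluster-level nodes (mean of member rows).

    Returns the collapsed screen (node ids ``C<id>``) and the mapping
    cluster label -> member genes.  A sample perturbing gene g perturbs
    g's cluster.
    """
    members = clusters.clusters()
    labels = {c: f"C{c}" for c in members}
    rows = {labels[c]: data.values.loc[gs].mean(axis=0) for c, gs in members.items()}
    values = pd.DataFrame(rows).T
    values = values[data.samples]
    pert = data.perturbed.map(lambda g: np.nan if pd.isna(g) else labels[clusters.assignment[g]])
    screen = KnockoutScreen(values=values, perturbed=pert, replicate=data.replicate.copy())
    return screen, {labels[c]: gs for c, gs in members.items()}


# ---------------------------------------------------------------------
# Step 2: subnetworks
# ---------------------------------------------------------------------

def build_subnetwork(
    source,
    data: KnockoutScreen,
    noise: ReplicateResiduals,
    fdr: float = 0.05,
    correction: str = "bh",
    reference: str = "normal",
) -> KnockoutScreen:
    """Restrict the screen to the significantly responding nodes of a source.

    Node set = responders of the source's single-gene knockout (source
    included); sample set = every experiment perturbing a subnetwork
    member, plus the wild-type replicates.
    """
    responders = significant_responders(
        source, data, noise, fdr=fdr, correction=correction, reference=reference
    )
    genes = [g for g in data.genes if g in responders]
    samples = [
        s
        for s in data.samples
        if pd.isna(data.perturbed.loc[s]) or data.perturbed.loc[s] in responders
    ]
    return data.subset(genes=genes, samples=samples)


# ---------------------------------------------------------------------
# Step 3: PRC with residual bootstrapping
# ---------------------------------------------------------------------

def _delta_pools(
    genes, noise: ReplicateResiduals | None, rng: np.random.Generator
) -> list[np.ndarray]:
    pools = []
    for g in genes:
        if noise is not None and g in noise.delta.index:
            pool = noise.delta.loc[g].dropna().to_numpy(dtype=float)
        else:
            pool = np.array([])
        if pool.size < 2:
            sd = np.sqrt(noise.pooled_sigma2) if noise is not None else 0.0
            pool = rng.normal(0.0, sd, size=16) if sd > 0 else np.zeros(16)
        pools.append(pool)
    return pools


def _bootstrap_blocks(
    V: np.ndarray,
    pools: list[np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Residual bootstrap: add per-gene delta draws to the averaged log-FCs."""
    blocks = []
    for _ in range(n_boot):
        noise = np.empty_like(V)
        for g, pool in enumerate(pools):
            noise[g] = pool[rng.integers(pool.size, size=V.shape[1])]
        blocks.append(V + noise)
    return blocks


def _crossing_pvalue(samples: np.ndarray) -> float:
    """Two-sided bootstrap p-value: fraction of min-strengths crossing zero."""
    n = samples.size
    frac_le = float(np.mean(samples <= 0.0))
    frac_ge = float(np.mean(samples >= 0.0))
    p = 2.0 * min(frac_le, frac_ge)
    return float(np.clip(p, 1.0 / (n + 1), 1.0))


def infer_subnetwork_links(
    subnet: KnockoutScreen,
    source,
    noise: ReplicateResiduals | None,
    n_boot: int = 200,
    fdr: float = 0.05,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> list[LinkEstimate]:
    """Estimate source -> target links within a subnetwork.

    Uses the replicate-averaged knockout profiles; for each candidate
    target the target's own perturbation experiments are dropped, the
    minimum and maximum strengths are estimated, and their bootstrap
    distributions (delta draws added to the averaged profiles) yield a
    crossing-zero p-value (BH-corrected across the subnetwork's targets
    at ``fdr``) and the inferability call.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = subnet.genes
    if source not in genes or len(genes) < 2:
        return []
    avg = subnet.average_replicates()
    ko_cols = [s for s in avg.samples if not pd.isna(avg.perturbed.loc[s])]
    wt_count = len(subnet.wild_type_samples())
    if not ko_cols or len(ko_cols) + wt_count < 3:
        warnings.warn(f"source {source!r}: not enough profiles for covariance estimation")
        return []
    # averaged knockout profiles first, then the individual wild-type
    # replicates: the wild-type block carries independent noise in every
    # direction, so sampled response directions stay separated from the
    # no-signal subspace even with fewer knockouts than genes
    wt_cols = subnet.wild_type_samples()
    V_ko = avg.values[ko_cols].to_numpy(dtype=float)
    V_wt = subnet.values[wt_cols].to_numpy(dtype=float)
    V = np.hstack([V_ko, V_wt])
    n_ko = len(ko_cols)
    labels = [avg.perturbed.loc[s] for s in ko_cols]
    r = (
        noise.ratios.r.reindex(genes).fillna(1.0).to_numpy(dtype=float)
        if noise is not None
        else np.ones(len(genes))
    )
    pools = _delta_pools(genes, noise, rng)
    boots = []
    for Vb_ko in _bootstrap_blocks(V_ko, pools, n_boot, rng):
        boots.append(np.hstack([Vb_ko, V_wt]))
    unpert_base = np.array([g not in set(labels) for g in genes])
    j_idx = genes.index(source)

    estimates: list[LinkEstimate] = []
    for i_idx, target in enumerate(genes):
        if target == source:
            continue
        keep = [k for k, lab in enumerate(labels) if lab != target]
        if not keep or source not in [labels[k] for k in keep]:
            warnings.warn(f"target {target!r}: no usable samples after removing its experiments")
            continue
        cols = np.array(keep + list(range(n_ko, V.shape[1])))
        mask = unpert_base.copy()
        mask[i_idx] = True  # target unperturbed in the remaining samples
        try:
            mn0, mx0 = strength_bracket_core(V[:, cols], i_idx, j_idx, mask, r)
        except (NotIdentifiableError, PRCError) as exc:
            warnings.warn(f"link {source!r}->{target!r} skipped: {exc}")
            continue
        mn_b, mx_b = [], []
        for Vb in boots:
            try:
                b_mn, b_mx = strength_bracket_core(Vb[:, cols], i_idx, j_idx, mask, r)
            except (NotIdentifiableError, PRCError):
                continue
            mn_b.append(b_mn)
            mx_b.append(b_mx)
        if len(mn_b) < max(4, n_boot // 4):
            warnings.warn(f"link {source!r}->{target!r}: too few valid bootstrap samples")
            continue
        mn_b = np.asarray(mn_b)
        mx_b = np.asarray(mx_b)
        estimates.append(
            LinkEstimate(
                source=source,
                target=target,
                strength_min=mn0,
                strength_max=mx0,
                significance=_crossing_pvalue(mn_b),
                inferable=classify_link_inferability(mn_b, mx_b, alpha=alpha),
                bootstrap_min=mn_b,
                bootstrap_max=mx_b,
            )
        )
    if estimates:
        pvals = np.array([e.significance for e in estimates])
        rej, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for e, s in zip(estimates, rej):
            e.significant = bool(s)
    return estimates


# ---------------------------------------------------------------------
# Step 4: two-node clusters
# ---------------------------------------------------------------------

def two_node_cluster_links(
    clusters: ClusterSet,
    data: KnockoutScreen,
    noise: ReplicateResiduals | None,
    fdr: float = 0.05,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> list[LinkEstimate]:
    """Directed links inside two-gene clusters with exactly one perturbed member.

    The perturbed member is the source; the link is the two-node
    errors-in-variables strength over the source's knockout replicates,
    bootstrapped with replicate residuals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    estimates: list[LinkEstimate] = []
    for cid, members in clusters.clusters().items():
        if len(members) != 2:
            continue
        pert = [g for g in members if data.samples_perturbing(g)]
        if len(pert) != 1:
            continue
        source = pert[0]
        target = members[0] if members[1] == source else members[1]
        # wild-type replicates provide the contrast against the (often
        # constant-strength) knockout columns
        samples = data.samples_perturbing(source) + data.wild_type_samples()
        if len(samples) < 2:
            continue
        pair = data.subset(genes=[target, source], samples=samples)
        V = pair.values.to_numpy(dtype=float)
        r = (
            noise.ratios.r.reindex([target, source]).fillna(1.0).to_numpy(dtype=float)
            if noise is not None
            else np.ones(2)
        )
        try:
            strength = max_strength_core(V, 0, 1, r)
        except (NotIdentifiableError, PRCError):
            continue
        pools = _delta_pools([target, source], noise, rng)
        vals = []
        for Vb in _bootstrap_blocks(V, pools, n_boot, rng):
            try:
                vals.append(max_strength_core(Vb, 0, 1, r))
            except (NotIdentifiableError, PRCError):
                continue
        if len(vals) < max(4, n_boot // 4):
            continue
        vals = np.asarray(vals)
        estimates.append(
            LinkEstimate(
                source=source,
                target=target,
                strength_min=strength,
                strength_max=strength,
                significance=_crossing_pvalue(vals),
                inferable=True,
                bootstrap_min=vals,
                bootstrap_max=vals,
            )
        )
    if estimates:
        pvals = np.array([e.significance for e in estimates])
        rej, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for e, s in zip(estimates, rej):
            e.significant = bool(s)
    return estimates


# ---------------------------------------------------------------------
# Step 5: edge-list assembly
# ---------------------------------------------------------------------

@dataclass
class EdgeList:
    """Collected link estimates with the inference-method tag."""

    records: list = field(default_factory=list)
    method: str = "subnetwork"
    cluster_of: dict | None = None  # gene/cluster-node -> cluster id

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "strength_min": e.strength_min,
                "strength_max": e.strength_max,
                "significance": e.significance,
                "inferable": e.inferable,
                "significant": e.significant,
                "method": self.method,
            }
            for e in self.records
        ]
        cols = [
            "source", "target", "strength_min", "strength_max",
            "significance", "inferable", "significant", "method",
        ]
        return pd.DataFrame(rows, columns=cols)

    def significant_links(self) -> set:
        return {(e.source, e.target) for e in self.records if e.significant}

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        records = [
            LinkEstimate(
                source=row.source,
                target=row.target,
                strength_min=float(row.strength_min),
                strength_max=float(row.strength_max),
                significance=float(row.significance),
                inferable=bool(row.inferable),
                significant=bool(row.significant),
            )
            for row in df.itertuples()
        ]
        method = df["method"].iloc[0] if len(df) else "subnetwork"
        return cls(records=records, method=method)


def assemble_edge_list(
    cluster_links: list[LinkEstimate],
    subnet_links: list[LinkEstimate],
    method: str = "subnetwork",
    clusters: ClusterSet | None = None,
) -> EdgeList:
    """Merge, deduplicate (keep the most significant) and sort link estimates.

    The ``subnetwork`` method keeps only links whose source and target both
    sit in singleton clusters (links between single genes); ``clustering``
    keeps cluster-level links.
    """
    if method not in ("clustering", "subnetwork", "prc"):
        raise PipelineError(f"unknown method {method!r}")
    pool = list(subnet_links) + list(cluster_links)
    if method == "subnetwork" and clusters is not None:
        sizes = clusters.sizes()
        assign = clusters.assignment
        pool = [
            e
            for e in pool
            if sizes.get(assign.get(e.source), 1) == 1 and sizes.get(assign.get(e.target), 1) == 1
        ]
    best: dict = {}
    for e in pool:
        key = (e.source, e.target)
        if key not in best or e.significance < best[key].significance:
            best[key] = e
    records = sorted(best.values(), key=lambda e: (e.significance, str(e.source), str(e.target)))
    cluster_of = clusters.assignment if clusters is not None else None
    return EdgeList(records=records, method=method, cluster_of=cluster_of)
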