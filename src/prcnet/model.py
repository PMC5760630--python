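"""Model / Results interface for PRC network inference.

``PRCModel`` wraps a :class:`~prcnet.datasets.KnockoutScreen` and the
inference configuration; ``fit(seed)`` runs the chosen pipeline variant
("prc" — every gene is a candidate target; "subnetwork" — candidates
restricted by the noise cutoff; "clustering" — co-expressed genes merged
first) and returns a ``PRCResults`` carrying the edge list, the noise
model, the clustering and a run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import KnockoutScreen
from .noise import ReplicateResiduals
from .pipeline import (
    ClusterSet,
    EdgeList,
    PipelineError,
    assemble_edge_list,
    build_subnetwork,
    cluster_coexpressed,
    cluster_screen,
    infer_subnetwork_links,
    two_node_cluster_links,
)


class PRCModel:
    """Partial-response-coefficient network inference on a knockout screen.

    Parameters
    ----------
    screen
        The log2 fold-change matrix with perturbation annotations.
    noise
        Replicate-residual noise model; estimated from the screen's
        wild-type block when omitted.
    method
        "prc" | "subnetwork" | "clustering".
    node_fdr, link_fdr
        False-discovery rates for the responding-node cutoff and the
        link-strength significance.
    n_boot
        Residual-bootstrap sample count.
    alpha
        Level for the inferability classification intervals.
    cluster_threshold
        Minimum absolute co-expression correlation for merging genes.
    """

    def __init__(
        self,
        screen: KnockoutScreen,
        noise: ReplicateResiduals | None = None,
        method: str = "subnetwork",
        node_fdr: float = 0.05,
        link_fdr: float = 0.05,
        n_boot: int = 200,
        alpha: float = 0.05,
        cluster_threshold: float = 0.995,
        correction: str = "bh",
        reference: str = "normal",
    ) -> None:
        if method not in ("prc", "subnetwork", "clustering"):
            raise PipelineError(f"unknown method {method!r}")
        self.screen = screen
        self.noise = noise
        self.method = method
        self.node_fdr = node_fdr
        self.link_fdr = link_fdr
        self.n_boot = n_boot
        self.alpha = alpha
        self.cluster_threshold = cluster_threshold
        self.correction = correction
        self.reference = reference

    @classmethod
    def from_tsv(cls, expr_path, annot_path, **kwargs) -> "PRCModel":
        return cls(KnockoutScreen.from_tsv(expr_path, annot_path), **kwargs)

    # -- fitting -------------------------------------------------------
    def fit(self, seed: int = 0) -> "PRCResults":
        screen = self.screen
        sources = sorted(screen.perturbed_genes(), key=str)
        if not sources:
            raise PipelineError(
                "screen contains no perturbation annotations; nothing to infer"
            )
        noise = self.noise
        if noise is None and self.method in ("subnetwork", "clustering"):
            noise = ReplicateResiduals.from_screen(screen)
        if noise is None:
            try:
                noise = ReplicateResiduals.from_screen(screen)
            except Exception:
                noise = None  # plain PRC can run without a noise model

        n_warn = 0
        clusters: ClusterSet | None = None
        membership: dict | None = None
        two_node = []

        if self.method == "clustering":
            clusters = cluster_coexpressed(screen, self.cluster_threshold)
            work, membership = cluster_screen(screen, clusters)
            try:
                work_noise = ReplicateResiduals.from_screen(work)
            except Exception:
                work_noise = None
            work_sources = sorted(work.perturbed_genes(), key=str)
        else:
            work, work_noise, work_sources = screen, noise, sources

        seqs = np.random.SeedSequence(seed).spawn(len(work_sources) + 1)
        subnet_links = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for src, sq in zip(work_sources, seqs[:-1]):
                rng = np.random.default_rng(sq)
                if self.method == "prc":
                    subnet = work
                else:
                    subnet = build_subnetwork(
                        src, work, work_noise, fdr=self.node_fdr,
                        correction=self.correction, reference=self.reference,
                    )
                    if subnet.n_genes < 2:
                        continue
                subnet_links.extend(
                    infer_subnetwork_links(
                        subnet, src, work_noise, n_boot=self.n_boot,
                        fdr=self.link_fdr, seed=rng, alpha=self.alpha,
                    )
                )
            if self.method == "clustering" and clusters is not None:
                two_node = two_node_cluster_links(
                    clusters, screen, noise, fdr=self.link_fdr,
                    n_boot=self.n_boot, seed=np.random.default_rng(seqs[-1]),
                    alpha=self.alpha,
                )
            n_warn = len(caught)

        edge_list = assemble_edge_list(
            two_node, subnet_links, method=self.method if self.method != "prc" else "prc",
            clusters=None,
        )
        edge_list.cluster_of = clusters.assignment if clusters is not None else None
        run_log = {
            "method": self.method,
            "seed": seed,
            "n_genes": screen.n_genes,
            "n_samples": screen.n_samples,
            "n_sources": len(sources),
            "node_fdr": self.node_fdr,
            "link_fdr": self.link_fdr,
            "n_boot": self.n_boot,
            "n_links": len(edge_list.records),
            "n_significant": len(edge_list.significant_links()),
            "n_warnings": n_warn,
        }
        return PRCResults(
            model=self,
            edge_list=edge_list,
            noise=noise,
            clusters=clusters,
            membership=membership,
            run_log=run_log,
        )


@dataclass
class PRCResults:
    """Fit results: inferred links, noise model, clustering and run log."""

    model: PRCModel
    edge_list: EdgeList
    noise: ReplicateResiduals | None
    clusters: ClusterSet | None = None
    membership: dict | None = None
    run_log: dict = field(default_factory=dict)

    @property
    def edges(self) -> pd.DataFrame:
        return self.edge_list.to_frame()

    def significant_gene_links(self) -> set:
        """Significant directed links expanded to gene level.

        Cluster-level links (clustering method) expand to all ordered
        member pairs; two-node-cluster links are gene-level already.
        """
        links = set()
        for e in self.edge_list.records:
            if not e.significant:
                continue
            if self.membership is not None and e.source in self.membership:
                srcs = self.membership.get(e.source, [e.source])
                tgts = self.membership.get(e.target, [e.target])
                links.update((s, t) for s in srcs for t in tgts if s != t)
            else:
                links.add((e.source, e.target))
        return links

    def summary(self) -> str:
        log = self.run_log
        lines = [
            "PRC network inference results",
            "=" * 64,
            f"method:            {log.get('method')}",
            f"genes x samples:   {log.get('n_genes')} x {log.get('n_samples')}",
            f"perturbed sources: {log.get('n_sources')}",
            f"bootstrap samples: {log.get('n_boot')}",
            f"node / link FDR:   {log.get('node_fdr')} / {log.get('link_fdr')}",
            f"links tested:      {log.get('n_links')}",
            f"significant links: {log.get('n_significant')}",
            "-" * 64,
        ]
        df = self.edges
        if len(df):
            top = df[df["significant"]].head(15)
            if len(top):
                lines.append(top.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
            else:
                lines.append("(no significant links)")
        else:
            lines.append("(no links tested)")
        return "\n".join(lines)

    # -- file outputs --------------------------------------------------
    def write(self, edges_path, log_path=None, noise_path=None) -> None:
        self.edge_list.to_tsv(edges_path)
        if log_path is not None:
            with open(log_path, "w") as fh:
                json.dump(self.run_log, fh, indent=2, sort_keys=True)
        if noise_path is not None and self.noise is not None:
            pd.DataFrame(
                {
                    "gene": self.noise.sigma.index,
                    "sigma_i": self.noise.sigma.to_numpy(),
                    "r_i": (self.noise.sigma**2 / self.noise.pooled_sigma2).to_numpy(),
                }
            ).to_csv(noise_path, sep="\t", index=False)


def run_inference(data: KnockoutScreen, config: dict | None = None) -> PRCResults:
    """One-call pipeline: configure, fit and (optionally) write outputs.

    ``config`` keys: method, node_fdr, link_fdr, n_boot, alpha,
    cluster_threshold, correction, reference, seed, out_edges, out_log,
    out_noise.
    """
    config = dict(config or {})
    seed = config.pop("seed", 0)
    out_edges = config.pop("out_edges", None)
    out_log = config.pop("out_log", None)
    out_noise = config.pop("out_noise", None)
    model = PRCModel(data, **config)
    results = model.fit(seed=seed)
    if out_edges is not None:
        results.write(out_edges, out_log, out_noise)
    return results
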