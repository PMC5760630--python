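"""Data containers for knockout-screen expression data.

The central object is :class:`KnockoutScreen`: a genes x samples matrix of
log2 fold changes (M-values relative to a pooled reference) together with a
sample annotation that records, for every sample, which single gene was
knocked out (or that the sample is an unperturbed wild-type replicate) and
its replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

WT_LABEL = "WT"


class DataFormatError(ValueError):
    """Raised for malformed expression / annotation files."""


@dataclass
class KnockoutScreen:
    """Log2 fold-change expression matrix plus per-sample perturbation labels.

    Parameters
    ----------
    values
        genes x samples DataFrame of log2 fold changes.
    perturbed
        Series indexed by sample id; the knocked-out gene id, or ``None``
        (NaN) for wild-type replicates.
    replicate
        Series indexed by sample id; integer replicate index within its
        perturbation (or within the wild-type block).
    """

    values: pd.DataFrame
    perturbed: pd.Series
    replicate: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        if list(self.perturbed.index) != samples or list(self.replicate.index) != samples:
            self.perturbed = self.perturbed.reindex(samples)
            self.replicate = self.replicate.reindex(samples)
        if self.perturbed.isna().all() and len(samples) and not self.values.empty:
            # all-wild-type screens are legal (noise estimation only)
            pass

    # -- basic views ---------------------------------------------------
    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def wild_type_samples(self) -> list:
        return [s for s in self.samples if pd.isna(self.perturbed.loc[s])]

    def perturbation_samples(self) -> list:
        return [s for s in self.samples if not pd.isna(self.perturbed.loc[s])]

    def perturbed_genes(self) -> set:
        return {g for g in self.perturbed.dropna().unique()}

    def samples_perturbing(self, gene) -> list:
        return [s for s in self.samples if self.perturbed.loc[s] == gene]

    def unperturbed_genes(self, samples: Sequence | None = None) -> set:
        """Genes with no perturbation experiment among ``samples`` (default: all)."""
        if samples is None:
            samples = self.samples
        hit = {self.perturbed.loc[s] for s in samples} - {np.nan}
        hit = {g for g in hit if not pd.isna(g)}
        return set(self.genes) - hit

    def subset(self, genes: Iterable | None = None, samples: Iterable | None = None) -> "KnockoutScreen":
        genes = list(genes) if genes is not None else self.genes
        samples = list(samples) if samples is not None else self.samples
        return KnockoutScreen(
            values=self.values.loc[genes, samples].copy(),
            perturbed=self.perturbed.loc[samples].copy(),
            replicate=self.replicate.loc[samples].copy(),
        )

    def drop_samples_perturbing(self, gene) -> "KnockoutScreen":
        keep = [s for s in self.samples if self.perturbed.loc[s] != gene]
        return self.subset(samples=keep)

    def average_replicates(self) -> "KnockoutScreen":
        """Average samples that perturb the same gene (wild-types averaged too)."""
        groups: dict = {}
        for s in self.samples:
            key = self.perturbed.loc[s]
            key = WT_LABEL if pd.isna(key) else key
            groups.setdefault(key, []).append(s)
        cols, pert, rep = {}, {}, {}
        for key, ss in groups.items():
            name = f"avg_{key}"
            cols[name] = self.values[ss].mean(axis=1)
            pert[name] = np.nan if key == WT_LABEL else key
            rep[name] = 0
        values = pd.DataFrame(cols, index=self.values.index)
        return KnockoutScreen(values, pd.Series(pert), pd.Series(rep))

    # -- file I/O ------------------------------------------------------
    def to_tsv(self, expr_path, annot_path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        annot = pd.DataFrame(
            {
                "sample_id": self.samples,
                "perturbed_gene": [
                    WT_LABEL if pd.isna(self.perturbed.loc[s]) else self.perturbed.loc[s]
                    for s in self.samples
                ],
                "replicate": [int(self.replicate.loc[s]) for s in self.samples],
            }
        )
        annot.to_csv(annot_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path, annot_path) -> "KnockoutScreen":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        expr.index = expr.index.astype(str)
        expr.index.name = None
        expr.columns = expr.columns.astype(str)
        annot = pd.read_csv(annot_path, sep="\t", dtype={"sample_id": str, "perturbed_gene": str})
        required = {"sample_id", "perturbed_gene", "replicate"}
        if not required.issubset(annot.columns):
            raise DataFormatError(
                f"annotation file {annot_path} lacks columns {sorted(required - set(annot.columns))}"
            )
        for line_no, sid in enumerate(annot["sample_id"], start=2):
            if sid not in expr.columns:
                raise DataFormatError(
                    f"{annot_path} line {line_no}: sample {sid!r} not present in expression matrix"
                )
        if set(annot["sample_id"]) != set(expr.columns):
            missing = sorted(set(expr.columns) - set(annot["sample_id"]))
            raise DataFormatError(f"samples missing from annotation: {missing}")
        annot = annot.set_index("sample_id").loc[expr.columns]
        pert = annot["perturbed_gene"].where(annot["perturbed_gene"] != WT_LABEL, np.nan)
        return cls(values=expr, perturbed=pert, replicate=annot["replicate"].astype(int))


@dataclass
class PerturbationDesign:
    """Which nodes are perturbed, in which experiments, and how strongly.

    Every experiment perturbs exactly one node (single-gene screens);
    ``q`` is the fraction of distinct perturbed nodes among all nodes.
    """

    n_nodes: int
    experiments: list = field(default_factory=list)  # (node, replicate, strength)
    knockout: bool = True

    @property
    def perturbed_nodes(self) -> set:
        return {node for node, _, _ in self.experiments}

    @property
    def q(self) -> float:
        return len(self.perturbed_nodes) / self.n_nodes if self.n_nodes else 0.0

    @classmethod
    def single_knockouts(
        cls,
        nodes: Sequence,
        n_nodes: int,
        n_replicates: int = 2,
        strength: float = 1.0,
        rng: np.random.Generator | None = None,
        random_strength: bool = False,
    ) -> "PerturbationDesign":
        """One knockout experiment per node, replicated ``n_replicates`` times.

        With ``random_strength`` a single standard-normal force is drawn
        per node and shared by its replicates (replicates repeat the same
        genetic perturbation; only measurement noise differs).
        """
        rng = rng or np.random.default_rng()
        exps = []
        for node in nodes:
            s = float(rng.standard_normal()) if random_strength else strength
            for r in range(n_replicates):
                exps.append((node, r, s))
        return cls(n_nodes=n_nodes, experiments=exps)
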