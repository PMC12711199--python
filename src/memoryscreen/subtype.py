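"""Hub-gene molecular subtyping and subgroup genomic comparison.

Samples are clustered on log2(TPM + 1) hub-gene profiles with Ward's
minimum-variance criterion on Euclidean distances (the ward.D2 convention),
cut to k clusters (default 3), and the clusters are renamed 1..k by
ascending mean hub-gene expression so that label 1 is the "low" and label k
the "high" expression subtype.  Subgroups are then compared at the genomic
level: per-sample tumor mutation burden (non-silent counts) and per-gene
carrier frequencies via two-sided Fisher exact tests with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io_model import NONSILENT_CLASSES, ExpressionMatrix, MutationTable

logger = logging.getLogger(__name__)


def log_transform_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    return ExpressionMatrix(
        gene_ids=expr.gene_ids.copy(),
        sample_ids=expr.sample_ids.copy(),
        values=np.log2(expr.values + 1.0),
    )


@dataclasses.dataclass
class SubgroupAssignment:
    """Cluster label per sample; labels 1..k ordered by mean hub expression."""

    sample_ids: np.ndarray
    labels: np.ndarray  # int, 1..k
    k: int

    def __post_init__(self) -> None:
        observed = np.unique(self.labels)
        if len(observed) != self.k:
            logger.warning(
                "expected %d non-empty clusters, found %d", self.k, len(observed)
            )

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})


def cluster_by_hub_genes(transformed: ExpressionMatrix, k: int = 3) -> SubgroupAssignment:
    """Ward/Euclidean hierarchical clustering of samples on hub-gene profiles.

    ``transformed`` is the log2(M+1) hub-gene matrix (hubs x samples).  The
    dendrogram is cut to exactly ``k`` clusters, which are then renamed
    1..k by ascending mean expression across hub genes.  Deterministic: no
    randomness is involved.
    """
    n_samples = transformed.values.shape[1]
    if n_samples < k:
        raise ValueError(f"cannot form {k} clusters from {n_samples} samples")
    profiles = transformed.values.T  # samples x hubs
    linkage = hierarchy.linkage(profiles, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")

    means = {
        label: profiles[raw == label].mean() for label in np.unique(raw)
    }
    order = sorted(means, key=lambda label: means[label])
    rename = {old: new + 1 for new, old in enumerate(order)}
    labels = np.asarray([rename[l] for l in raw], dtype=int)
    return SubgroupAssignment(
        sample_ids=transformed.sample_ids.copy(), labels=labels, k=k
    )


@dataclasses.dataclass
class TmbReport:
    """Per-sample non-silent mutation count, optionally as mutations/Mb."""

    counts: pd.DataFrame  # sample_id, tmb_count [, tmb_per_mb]

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()


def compute_tmb(
    mutations: MutationTable,
    samples: Sequence[str],
    variant_filter: Iterable[str] = NONSILENT_CLASSES,
    capture_size_mb: float | None = None,
) -> TmbReport:
    """Count qualifying mutation records per sample; absent samples get 0.

    ``capture_size_mb`` (e.g. 38 for a whole-exome panel) additionally
    reports the per-megabase rate.
    """
    qualifying = mutations.filter_classes(variant_filter)
    tallies = qualifying.records.groupby("sample").size()
    counts = pd.DataFrame(
        {
            "sample_id": list(samples),
            "tmb_count": [int(tallies.get(s, 0)) for s in samples],
        }
    )
    if capture_size_mb is not None:
        if capture_size_mb <= 0:
            raise ValueError("capture size must be positive")
        counts["tmb_per_mb"] = counts["tmb_count"] / capture_size_mb
    return TmbReport(counts=counts)


@dataclasses.dataclass
class DifferentialMutationReport:
    """Per-gene carrier 2x2 comparison between two subgroups."""

    table: pd.DataFrame
    pair: tuple[int, int]
    skipped_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def differential_mutation(
    mutations: MutationTable,
    groups: SubgroupAssignment,
    pair: tuple[int, int],
    variant_filter: Iterable[str] = NONSILENT_CLASSES,
) -> DifferentialMutationReport:
    """Fisher exact comparison of per-gene carrier frequency between clusters.

    For each gene mutated in at least one of the two clusters, carriers vs
    non-carriers are tabulated per cluster; a two-sided Fisher exact test is
    applied, with Benjamini-Hochberg adjustment across the genes tested.
    Genes absent from both clusters are skipped and reported.
    """
    label_a, label_b = pair
    samples_a = groups.members(label_a)
    samples_b = groups.members(label_b)
    if not samples_a or not samples_b:
        raise ValueError(f"cluster pair {pair} includes an empty cluster")
    qualifying = mutations.filter_classes(variant_filter)

    rows = []
    skipped: list[str] = []
    set_a, set_b = set(samples_a), set(samples_b)
    for gene in qualifying.genes():
        carriers = qualifying.carriers(gene)
        n_a = len(carriers & set_a)
        n_b = len(carriers & set_b)
        if n_a == 0 and n_b == 0:
            skipped.append(gene)
            continue
        table = [[n_a, len(set_a) - n_a], [n_b, len(set_b) - n_b]]
        odds_ratio, pvalue = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "carriers_a": n_a,
                "noncarriers_a": len(set_a) - n_a,
                "carriers_b": n_b,
                "noncarriers_b": len(set_b) - n_b,
                "odds_ratio": odds_ratio,
                "p_value": pvalue,
            }
        )
    if skipped:
        logger.info("skipped %d genes absent from both clusters", len(skipped))
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "carriers_a",
            "noncarriers_a",
            "carriers_b",
            "noncarriers_b",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(frame):
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        frame = frame.sort_values(["p_value", "gene"], kind="stable").reset_index(
            drop=True
        )
    else:
        frame["q_value"] = pd.Series(dtype=float)
    return DifferentialMutationReport(table=frame, pair=pair, skipped_genes=skipped)
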