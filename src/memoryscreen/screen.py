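"""Multi-gradient permutation survival screen (MEMORY).

The screen repeatedly subsamples a cohort at a ladder of sample sizes
("gradients", roughly 10%..100% of the cohort), median-dichotomizes every
gene within each drawn subset, and records whether the two-group log-rank
test is significant.  Averaging the binary outcomes over permutations gives
the significance-probability matrix A (genes x gradients):

    A[i, j] = (1/N) * sum_n k[j, i, n]

Genes whose A exceeds a threshold (default 0.8) at the saturation gradient —
the smallest gradient at which some gene reaches probability 1 — are the
GEARs (Genes stEadily Associated with pRognosis).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, SurvivalTable
from .logrank import logrank_pvalues

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GradientPlan:
    """Ladder of subsample sizes; last entry always equals the cohort size."""

    n_total: int
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ValueError("empty gradient plan")
        if any(b < a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("gradient sizes must be non-decreasing")
        if self.sizes[-1] != self.n_total:
            raise ValueError("last gradient must cover the full cohort")

    def __len__(self) -> int:
        return len(self.sizes)


def build_gradient_plan(
    n_total: int, n_gradients: int = 10, min_size: int = 10
) -> GradientPlan:
    """Sizes round_half_up(j * n_total / n_gradients), floored at ``min_size``."""
    if n_total < min_size:
        raise ValueError(f"cohort of {n_total} is below the minimum size {min_size}")
    sizes = []
    for j in range(1, n_gradients + 1):
        k = int(math.floor(j * n_total / n_gradients + 0.5))
        sizes.append(max(k, min_size))
    sizes[-1] = n_total
    return GradientPlan(n_total=n_total, sizes=tuple(sizes))


def dichotomize_by_median(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rank-based median split: low half vs high half, ties by input position.

    Samples are stably sorted ascending; the first ceil(n/2) are labelled low
    (False), the rest high (True), so group sizes differ by at most one.

    Returns (labels, degenerate); ``degenerate`` is True when all values are
    identical, in which case the split is arbitrary and the caller should
    record the test as non-significant.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 samples to dichotomize")
    order = np.argsort(values, kind="stable")
    labels = np.zeros(n, dtype=bool)
    labels[order[-(n // 2) :]] = True
    degenerate = bool(values.max() == values.min())
    return labels, degenerate


@dataclasses.dataclass
class SignificanceTensor:
    """Binary significance outcomes k[j, i, n]: gradient x gene x permutation."""

    values: np.ndarray  # uint8, shape (J, G, N)
    gene_ids: np.ndarray
    gradient_sizes: tuple[int, ...]
    seed: int
    alpha: float
    diagnostics: pd.DataFrame  # per gradient: degenerate / undefined counts

    @property
    def n_permutations(self) -> int:
        return self.values.shape[2]

    def first_gradient_vectors(self) -> np.ndarray:
        """Gene x permutation binary matrix at the first (smallest) gradient."""
        return self.values[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            gene_ids=self.gene_ids.astype(str),
            gradient_sizes=np.asarray(self.gradient_sizes),
            seed=self.seed,
            alpha=self.alpha,
            diag_columns=self.diagnostics.columns.to_numpy(dtype=str),
            diag_values=self.diagnostics.to_numpy(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SignificanceTensor":
        with np.load(path, allow_pickle=False) as data:
            diagnostics = pd.DataFrame(
                data["diag_values"], columns=list(data["diag_columns"])
            )
            return cls(
                values=data["values"],
                gene_ids=data["gene_ids"].astype(object),
                gradient_sizes=tuple(int(s) for s in data["gradient_sizes"]),
                seed=int(data["seed"]),
                alpha=float(data["alpha"]),
                diagnostics=diagnostics,
            )


@dataclasses.dataclass
class SignificanceProbabilityMatrix:
    """A[i, j] in [0, 1]: fraction of permutations significant, genes x gradients."""

    values: np.ndarray
    gene_ids: np.ndarray
    gradient_sizes: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values,
            index=self.gene_ids,
            columns=[f"k{size}" for size in self.gradient_sizes],
        )
        frame.index.name = "gene"
        return frame

    def column_maxima(self) -> np.ndarray:
        return self.values.max(axis=0)


@dataclasses.dataclass
class SaturationResult:
    """Smallest gradient whose best gene reaches probability 1."""

    index: int  # 0-based gradient index
    saturated: bool  # False when no column attains 1 (fallback: last gradient)


@dataclasses.dataclass
class GearSet:
    """Genes steadily associated with prognosis at the chosen gradient."""

    gene_ids: np.ndarray
    probabilities: np.ndarray  # A at the saturation gradient, aligned with gene_ids
    saturation_index: int
    threshold: float
    mode: str

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "significance_probability": self.probabilities}
        )


def run_permutation_screen(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    plan: GradientPlan,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SignificanceTensor:
    """Gradient-wise permutation screen.

    For each gradient j and permutation n one subset of ``plan.sizes[j]``
    samples is drawn without replacement and shared by all genes; each gene
    is median-dichotomized within the subset and k[j, i, n] = 1 iff the
    log-rank p-value is < ``alpha``.  Degenerate genes (constant in the
    subset) and undefined tests (zero events) are coded 0 and counted in the
    diagnostics.  Fully deterministic given ``seed``: permutation (j, n) uses
    an independent substream spawned from the master seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if list(expr.sample_ids) != list(surv.sample_ids):
        raise ValueError("expression and survival must be aligned (align_samples)")

    n_samples = len(surv)
    n_genes = len(expr.gene_ids)
    n_gradients = len(plan)
    values = np.zeros((n_gradients, n_genes, n_perm), dtype=np.uint8)
    degenerate_counts = np.zeros(n_gradients, dtype=np.int64)
    undefined_counts = np.zeros(n_gradients, dtype=np.int64)

    half = None  # recomputed per gradient
    for j, k_j in enumerate(plan.sizes):
        full_draw = k_j == n_samples
        half = k_j // 2
        for n in range(n_perm):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j, n)))
            if full_draw:
                idx = np.arange(n_samples)
            else:
                idx = np.sort(rng.choice(n_samples, size=k_j, replace=False))
            sub_expr = expr.values[:, idx]
            sub_time = surv.time[idx]
            sub_event = surv.event[idx]

            # stable rank-based median split per gene: top floor(k/2) -> high
            order = np.argsort(sub_expr, axis=1, kind="stable")
            groups = np.zeros((n_genes, k_j), dtype=bool)
            np.put_along_axis(groups, order[:, -half:], True, axis=1)
            degenerate = sub_expr.max(axis=1) == sub_expr.min(axis=1)

            pvals, valid = logrank_pvalues(sub_time, sub_event, groups)
            significant = valid & ~degenerate & (pvals < alpha)
            values[j, :, n] = significant.astype(np.uint8)
            degenerate_counts[j] += int(degenerate.sum())
            undefined_counts[j] += int((~valid).sum())

    diagnostics = pd.DataFrame(
        {
            "gradient_size": list(plan.sizes),
            "degenerate_gene_tests": degenerate_counts,
            "undefined_tests": undefined_counts,
        }
    )
    logger.info(
        "screen complete: %d genes, %d gradients, %d permutations",
        n_genes,
        n_gradients,
        n_perm,
    )
    return SignificanceTensor(
        values=values,
        gene_ids=expr.gene_ids.copy(),
        gradient_sizes=plan.sizes,
        seed=seed,
        alpha=alpha,
        diagnostics=diagnostics,
    )


def significance_probability(tensor: SignificanceTensor) -> SignificanceProbabilityMatrix:
    """A[i, j] = mean over permutations of k[j, i, n], exactly."""
    if tensor.values.size == 0:
        raise ValueError("empty significance tensor")
    counts = tensor.values.sum(axis=2, dtype=np.int64)  # (J, G)
    values = counts.T / tensor.n_permutations  # (G, J)
    return SignificanceProbabilityMatrix(
        values=values,
        gene_ids=tensor.gene_ids.copy(),
        gradient_sizes=tensor.gradient_sizes,
    )


def find_saturation_gradient(A: SignificanceProbabilityMatrix) -> SaturationResult:
    """Smallest gradient whose column maximum equals 1; fallback = last, flagged."""
    maxima = A.column_maxima()
    hits = np.flatnonzero(maxima >= 1.0)
    if hits.size:
        return SaturationResult(index=int(hits[0]), saturated=True)
    logger.warning(
        "no gradient saturated (max significance probability %.3f); "
        "falling back to the largest gradient",
        float(maxima[-1]) if maxima.size else float("nan"),
    )
    return SaturationResult(index=A.values.shape[1] - 1, saturated=False)


def extract_gears(
    A: SignificanceProbabilityMatrix,
    saturation_index: int,
    threshold: float = 0.8,
    mode: Literal["saturation", "sustained"] = "saturation",
) -> GearSet:
    """Genes with significance probability strictly above ``threshold``.

    ``saturation`` (default): A[i, j*] > threshold at the saturation gradient.
    ``sustained``: the gene must first cross the threshold at some gradient
    and stay above it at every later gradient.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not 0 <= saturation_index < A.values.shape[1]:
        raise ValueError("saturation index out of range")
    if mode == "saturation":
        keep = A.values[:, saturation_index] > threshold
    elif mode == "sustained":
        above = A.values > threshold
        keep = np.zeros(A.values.shape[0], dtype=bool)
        for i in range(A.values.shape[0]):
            crossings = np.flatnonzero(above[i])
            keep[i] = crossings.size > 0 and above[i, crossings[0] :].all()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GearSet(
        gene_ids=A.gene_ids[keep].copy(),
        probabilities=A.values[keep, saturation_index].copy(),
        saturation_index=saturation_index,
        threshold=threshold,
        mode=mode,
    )
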