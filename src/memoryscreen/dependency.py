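"""Mutation effects on tumor-cell viability from CRISPR dependency scores.

For a gene g, cell lines are split into mutant and wild-type groups by their
mutation status for g.  With group means s̄_m and s̄_wt of the dependency
score the effect is summarized by

    D_m  = |s̄_m - s̄_wt|                     (absolute mean difference)
    S_dm = 2 (s̄_m - s̄_wt) / (s̄_m + s̄_wt)   (standardized difference)

together with a two-sample t-test (Welch by default).  A mutation is
"functional" when p < 0.05 and S_dm > 0.1, both strict; a functional
mutation is promoted to "subtype-associated functional" when its carrier
frequency also differs significantly across molecular subtypes.

Dependency scores are often negative (essential genes), so s̄_m + s̄_wt can
be zero or negative; S_dm is then flagged indeterminate rather than used,
because the sign of the ratio no longer tracks the sign of the difference.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import DependencyScoreTable, MutationTable

logger = logging.getLogger(__name__)

FUNCTIONAL = "functional"
SUBTYPE_FUNCTIONAL = "subtype-associated functional"
NON_FUNCTIONAL = "non-functional"


@dataclasses.dataclass
class DependencyComparison:
    """Mutant vs wild-type dependency-score contrast for one gene."""

    gene: str
    mean_mutant: float
    mean_wildtype: float
    n_mutant: int
    n_wildtype: int
    p_value: float
    d_m: float
    s_dm: float  # nan when indeterminate
    indeterminate_scale: bool


def compare_dependency(
    scores: DependencyScoreTable,
    mutant_lines: Iterable[str],
    target_gene: str,
    welch: bool = True,
) -> DependencyComparison:
    """D_m, S_dm and t-test p for one gene's mutant vs wild-type lines.

    Both groups need >= 2 lines with finite scores.  ``welch=False`` selects
    the pooled-variance Student's t-test.
    """
    if target_gene not in set(scores.gene_ids):
        raise KeyError(f"gene {target_gene!r} absent from dependency scores")
    gene_scores = scores.gene_scores(target_gene)
    mutant_lines = set(mutant_lines)
    mutant = gene_scores[gene_scores.index.isin(mutant_lines)]
    wildtype = gene_scores[~gene_scores.index.isin(mutant_lines)]
    if len(mutant) < 2 or len(wildtype) < 2:
        raise ValueError(
            f"{target_gene}: need >= 2 cell lines per group "
            f"(mutant {len(mutant)}, wild-type {len(wildtype)})"
        )
    mean_m = float(mutant.mean())
    mean_wt = float(wildtype.mean())
    d_m = abs(mean_m - mean_wt)
    denom = mean_m + mean_wt
    indeterminate = denom <= 0.0
    s_dm = float("nan") if indeterminate else 2.0 * (mean_m - mean_wt) / denom
    t_result = stats.ttest_ind(mutant, wildtype, equal_var=not welch)
    return DependencyComparison(
        gene=target_gene,
        mean_mutant=mean_m,
        mean_wildtype=mean_wt,
        n_mutant=len(mutant),
        n_wildtype=len(wildtype),
        p_value=float(t_result.pvalue),
        d_m=d_m,
        s_dm=s_dm,
        indeterminate_scale=indeterminate,
    )


def classify_mutation(
    comparison: DependencyComparison,
    subtype_enrichment_p: float | None = None,
    alpha: float = 0.05,
    s_dm_threshold: float = 0.1,
) -> str:
    """Functional iff p < alpha AND S_dm > threshold (both strict).

    Indeterminate-scale genes cannot satisfy the S_dm criterion and are
    non-functional.  A significant cross-subtype carrier-frequency test
    (``subtype_enrichment_p`` < alpha) promotes functional to
    subtype-associated functional.
    """
    functional = (
        comparison.p_value < alpha
        and not comparison.indeterminate_scale
        and comparison.s_dm > s_dm_threshold
    )
    if not functional:
        return NON_FUNCTIONAL
    if subtype_enrichment_p is not None and subtype_enrichment_p < alpha:
        return SUBTYPE_FUNCTIONAL
    return FUNCTIONAL


def screen_all_mutations(
    scores: DependencyScoreTable,
    cell_line_mutations: MutationTable,
    subtype_enrichment: dict[str, float] | None = None,
    welch: bool = True,
) -> pd.DataFrame:
    """Dependency comparison + category for every mutated gene in the screen.

    Genes failing preconditions (absent from the score matrix, fewer than 2
    lines in either group) are reported with a ``skip_reason`` instead of a
    comparison.
    """
    score_lines = set(scores.cell_line_ids)
    mutation_lines = set(cell_line_mutations.records["sample"])
    if not score_lines & mutation_lines:
        raise ValueError("no overlapping cell lines between scores and mutations")
    subtype_enrichment = subtype_enrichment or {}

    rows = []
    for gene in cell_line_mutations.genes():
        mutant_lines = cell_line_mutations.carriers(gene) & score_lines
        base = {
            "gene": gene,
            "n_mutant": len(mutant_lines),
            "n_wildtype": len(score_lines) - len(mutant_lines),
        }
        if gene not in set(scores.gene_ids):
            rows.append({**base, "skip_reason": "gene absent from score matrix"})
            continue
        try:
            cmp = compare_dependency(scores, mutant_lines, gene, welch=welch)
        except ValueError as exc:
            rows.append({**base, "skip_reason": str(exc)})
            continue
        category = classify_mutation(cmp, subtype_enrichment.get(gene))
        rows.append(
            {
                "gene": gene,
                "n_mutant": cmp.n_mutant,
                "n_wildtype": cmp.n_wildtype,
                "mean_mutant": cmp.mean_mutant,
                "mean_wildtype": cmp.mean_wildtype,
                "d_m": cmp.d_m,
                "s_dm": cmp.s_dm,
                "p_value": cmp.p_value,
                "indeterminate_scale": cmp.indeterminate_scale,
                "category": category,
                "skip_reason": "",
            }
        )
    frame = pd.DataFrame(rows)
    skipped = (frame.get("skip_reason", pd.Series(dtype=str)) != "").sum()
    if skipped:
        logger.info("skipped %d genes in the dependency screen", int(skipped))
    return frame
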