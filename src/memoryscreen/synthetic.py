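"""Synthetic TCGA-like cohorts with the structure the screen assumes.

The generator plants a known ground truth so every pipeline stage is
testable without external data:

* expression: log-normal TPM per gene with per-gene meanlog drawn uniformly
  (so some genes clear the 10-TPM hub filter and others do not).  The
  planted prognostic genes are noisy copies of one latent "program" signal
  per sample (think of a co-expressed mitosis or immune program), with
  correlation ``program_correlation`` to the latent signal; null genes are
  independent noise.
* survival: proportional hazards — samples whose latent program activity is
  above the cohort median have their baseline hazard multiplied by the
  planted hazard ratio; event times are exponential, censoring is uniform
  on (0, window].
* mutations: Bernoulli carrier status with cluster-specific probabilities,
  emitted as missense records;
* dependency screens: Gaussian scores with a planted mean shift in mutant
  lines.

Driving the hazard through the shared program (rather than through each
gene independently) is what makes the planted effect recoverable gene by
gene: every program member's above-median split approximates the program
split, so its median-split log-rank test sees close to the full hazard
ratio, and program members share correlated significance vectors — the
structure the SAS similarity is designed to detect.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io_model import DependencyScoreTable, ExpressionMatrix, MutationTable, SurvivalTable
from .subtype import SubgroupAssignment

#: default baseline hazard (events/day) and censoring window (days).  On a
#: null cohort these censor ~43% of samples (closed form below); on the
#: default planted preset (HR=3 on half the cohort) ~30%.
DEFAULT_BASELINE_HAZARD = 1.0 / 1800.0
DEFAULT_CENSORING_DAYS = 3650.0


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults give a mid-size screen."""

    n_samples: int = 300
    n_genes: int = 500
    n_prognostic: int = 20
    hazard_ratio: float = 3.0  # applied to the program-high half of the cohort
    program_correlation: float = 0.9  # planted-gene correlation with the program
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    censoring_days: float = DEFAULT_CENSORING_DAYS
    meanlog_range: tuple[float, float] = (0.5, 3.5)
    sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        if self.n_prognostic > self.n_genes:
            raise ValueError("more prognostic genes than genes")
        if not 0.0 <= self.program_correlation < 1.0:
            raise ValueError("program correlation must be in [0, 1)")
        if self.censoring_days <= 0:
            raise ValueError("censoring window must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.sdlog <= 0:
            raise ValueError("sdlog must be > 0")


@dataclasses.dataclass
class GroundTruth:
    """What was planted: prognostic genes, subtype labels, functional genes."""

    prognostic_genes: dict[str, float]  # gene -> hazard ratio
    program_activity: np.ndarray | None = None  # latent signal per sample
    subtype_labels: np.ndarray | None = None
    functional_genes: dict[str, float] | None = None  # gene -> mean shift


def expected_null_censoring_fraction(spec: CohortSpec) -> float:
    """Closed-form censoring fraction when no gene modulates the hazard.

    With exponential event times at rate λ and censoring uniform on (0, C]:
    P(event) = 1 - (1 - exp(-λC)) / (λC), so
    P(censored) = (1 - exp(-λC)) / (λC).
    """
    lc = spec.baseline_hazard * spec.censoring_days
    return (1.0 - math.exp(-lc)) / lc


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.asarray([f"GENE{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def _sample_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.asarray([f"SAMPLE{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Expression + survival with a planted prognostic program; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    gene_ids = _gene_ids(spec.n_genes)
    sample_ids = _sample_ids(spec.n_samples)

    meanlog = rng.uniform(*spec.meanlog_range, size=spec.n_genes)
    program = rng.standard_normal(spec.n_samples)  # latent prognostic signal
    noise = rng.standard_normal((spec.n_genes, spec.n_samples))

    rho = spec.program_correlation
    z = noise.copy()
    if spec.n_prognostic and spec.hazard_ratio != 1.0:
        z[: spec.n_prognostic] = (
            rho * program[None, :] + math.sqrt(1.0 - rho**2) * noise[: spec.n_prognostic]
        )
    values = np.exp(meanlog[:, None] + spec.sdlog * z)
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)

    program_high = program > np.median(program)
    hazard = spec.baseline_hazard * np.where(program_high, spec.hazard_ratio, 1.0)

    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, spec.censoring_days, size=spec.n_samples)
    observed = np.minimum(event_time, censor_time)
    observed = np.maximum(observed, 1e-6)  # follow-up must be strictly positive
    event = (event_time <= censor_time).astype(int)

    surv = SurvivalTable(sample_ids=sample_ids.copy(), time=observed, event=event)
    planted = gene_ids[: spec.n_prognostic] if spec.hazard_ratio != 1.0 else gene_ids[:0]
    truth = GroundTruth(
        prognostic_genes={g: spec.hazard_ratio for g in planted},
        program_activity=program,
    )
    return expr, surv, truth


def generate_mutation_profiles(
    groups: SubgroupAssignment,
    enriched_genes: dict[str, dict[int, float]],
    seed: int = 0,
) -> MutationTable:
    """Bernoulli carriers per (gene, sample) with cluster-specific probabilities.

    ``enriched_genes`` maps gene -> {cluster label -> carrier probability};
    missing labels default to probability 0.  Carriers are emitted as
    missense records.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    rows = []
    for gene in sorted(enriched_genes):
        probabilities = enriched_genes[gene]
        for prob in probabilities.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"carrier probability {prob} outside [0, 1]")
        for sample, label in zip(groups.sample_ids, groups.labels):
            prob = probabilities.get(int(label), 0.0)
            if rng.random() < prob:
                rows.append(
                    {"gene": gene, "sample": sample, "variant_class": "Missense_Mutation"}
                )
    records = pd.DataFrame(rows, columns=["gene", "sample", "variant_class"])
    return MutationTable(records=records)


def generate_dependency_screen(
    n_lines: int,
    genes: list[str],
    planted_effects: dict[str, float],
    noise_sd: float = 0.1,
    mutation_rate: float = 0.3,
    seed: int = 0,
) -> tuple[DependencyScoreTable, MutationTable]:
    """Cell-line dependency scores with mutation-shifted means.

    Wild-type scores are Normal(μ_g, noise_sd) with μ_g drawn once per gene;
    mutant lines (Bernoulli ``mutation_rate``) are shifted by the planted
    effect (0 for unlisted genes).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    lines = np.asarray([f"LINE{i:04d}" for i in range(1, n_lines + 1)], dtype=object)

    base_means = rng.uniform(0.2, 0.8, size=len(genes))
    scores = rng.normal(base_means[None, :], noise_sd, size=(n_lines, len(genes)))
    mutated = rng.random(size=(n_lines, len(genes))) < mutation_rate

    rows = []
    for gi, gene in enumerate(genes):
        shift = planted_effects.get(gene, 0.0)
        carriers = np.flatnonzero(mutated[:, gi])
        scores[carriers, gi] += shift
        for li in carriers:
            rows.append(
                {"gene": gene, "sample": lines[li], "variant_class": "Missense_Mutation"}
            )
    table = DependencyScoreTable(
        cell_line_ids=lines, gene_ids=np.asarray(genes, dtype=object), scores=scores
    )
    mutations = MutationTable(
        records=pd.DataFrame(rows, columns=["gene", "sample", "variant_class"])
    )
    return table, mutations
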