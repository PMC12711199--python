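"""End-to-end pipeline: screen -> network -> hubs -> subtype -> mutation stages.

A run is driven by a :class:`RunConfig` (flat YAML on disk, CLI flags
override) and produces a directory of TSV artifacts plus a JSON manifest
recording the config snapshot, software version, input checksums, per-stage
timings, diagnostics counters and an inventory of outputs with checksums.
Identical (inputs, config, seed) produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .dependency import screen_all_mutations
from .io_model import (
    align_samples,
    read_dependency_scores,
    read_expression,
    read_mutations,
    read_survival,
    write_table,
)
from .network import build_csn, compute_sas_edges, select_hub_genes
from .screen import (
    build_gradient_plan,
    extract_gears,
    find_saturation_gradient,
    run_permutation_screen,
    significance_probability,
)
from .subtype import (
    cluster_by_hub_genes,
    compute_tmb,
    differential_mutation,
    log_transform_expression,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """All knobs of a full pipeline run; defaults follow the method's standard settings."""

    expr_path: str = ""
    surv_path: str = ""
    mutations_path: str | None = None
    dependency_scores_path: str | None = None
    cell_line_mutations_path: str | None = None
    out_dir: str = "memory_out"
    n_gradients: int = 10
    n_permutations: int = 1000
    alpha: float = 0.05
    gear_threshold: float = 0.8
    gear_mode: str = "saturation"
    top_k_edges: int = 1000
    top_n_hubs: int = 10
    min_tpm: float = 10.0
    k_clusters: int = 3
    min_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if not 0.0 < self.gear_threshold <= 1.0:
            raise ConfigError(f"gear_threshold {self.gear_threshold} outside (0, 1]")
        if self.gear_mode not in ("saturation", "sustained"):
            raise ConfigError(f"unknown gear_mode {self.gear_mode!r}")
        for name in ("n_gradients", "n_permutations", "top_k_edges", "top_n_hubs", "k_clusters", "min_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.min_tpm < 0:
            raise ConfigError("min_tpm must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a flat YAML config; unknown keys and out-of-range values raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a flat mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 16), b""):
            digest.update(block)
    return digest.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_seconds: dict[str, float]
    diagnostics: dict
    outputs: dict[str, str]  # filename -> sha256
    skipped_stages: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, skipping optional stages without inputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    skipped: dict[str, str] = {}
    diagnostics: dict = {}

    input_checksums = {}
    for label, p in (
        ("expression", config.expr_path),
        ("survival", config.surv_path),
        ("mutations", config.mutations_path),
        ("dependency_scores", config.dependency_scores_path),
        ("cell_line_mutations", config.cell_line_mutations_path),
    ):
        if p and Path(p).exists():
            input_checksums[label] = _sha256(Path(p))

    def emit(name: str, obj) -> None:
        path = out_dir / name
        write_table(obj, path)
        outputs[name] = _sha256(path)

    # ---- screen -----------------------------------------------------------
    t0 = time.perf_counter()
    expr = read_expression(config.expr_path)
    surv = read_survival(config.surv_path)
    expr, surv = align_samples(expr, surv, min_samples=config.min_size)
    plan = build_gradient_plan(
        len(surv), n_gradients=config.n_gradients, min_size=config.min_size
    )
    tensor = run_permutation_screen(
        expr,
        surv,
        plan,
        n_perm=config.n_permutations,
        alpha=config.alpha,
        seed=config.seed,
    )
    a_matrix = significance_probability(tensor)
    saturation = find_saturation_gradient(a_matrix)
    gears = extract_gears(
        a_matrix,
        saturation.index,
        threshold=config.gear_threshold,
        mode=config.gear_mode,
    )
    tensor.save(out_dir / "tensor.npz")
    outputs["tensor.npz"] = _sha256(out_dir / "tensor.npz")
    emit("a_matrix.tsv", a_matrix.to_frame().reset_index())
    emit("gears.tsv", gears.to_frame())
    diagnostics["screen"] = {
        "n_samples": len(surv),
        "n_genes": len(expr.gene_ids),
        "gradient_sizes": list(plan.sizes),
        "saturated": saturation.saturated,
        "saturation_gradient_size": plan.sizes[saturation.index],
        "n_gears": len(gears),
        "per_gradient": tensor.diagnostics.to_dict(orient="list"),
    }
    timings["screen"] = time.perf_counter() - t0

    # ---- network + hubs ---------------------------------------------------
    t0 = time.perf_counter()
    hubs = None
    if len(gears):
        edges = compute_sas_edges(tensor, gears)
        csn = build_csn(edges, top_k=config.top_k_edges)
        hubs = select_hub_genes(
            csn, expr, gears, top_n=config.top_n_hubs, min_tpm=config.min_tpm
        )
        emit("edges.tsv", csn.to_frame())
        degrees = csn.degrees().rename("degree").to_frame().reset_index(names="gene")
        emit("node_degrees.tsv", degrees)
        emit("hubs.tsv", hubs.to_frame())
        diagnostics["network"] = {
            "n_candidate_edges": len(edges),
            "n_kept_edges": len(csn.edges),
            "n_hubs": len(hubs),
        }
    else:
        skipped["network"] = "empty GEAR set"
    timings["network"] = time.perf_counter() - t0

    # ---- subtype classification ------------------------------------------
    t0 = time.perf_counter()
    assignment = None
    if hubs is not None and len(hubs):
        hub_expr = log_transform_expression(expr.subset_genes(hubs.gene_ids))
        assignment = cluster_by_hub_genes(hub_expr, k=config.k_clusters)
        emit("clusters.tsv", assignment.to_frame())
        diagnostics["subtype"] = {
            "cluster_sizes": assignment.to_frame()["cluster"]
            .value_counts()
            .sort_index()
            .to_dict()
        }
    else:
        skipped["subtype"] = "no hub genes"
    timings["subtype"] = time.perf_counter() - t0

    # ---- tumor mutations: TMB + differential ------------------------------
    t0 = time.perf_counter()
    if config.mutations_path and Path(config.mutations_path).exists():
        mutations = read_mutations(config.mutations_path)
        emit("tmb.tsv", compute_tmb(mutations, list(surv.sample_ids)).to_frame())
        if assignment is not None:
            labels = sorted(set(assignment.labels))
            for a, b in [(x, y) for i, x in enumerate(labels) for y in labels[i + 1 :]]:
                report = differential_mutation(mutations, assignment, (a, b))
                emit(f"mutdiff_{a}_vs_{b}.tsv", report.to_frame())
        else:
            skipped["differential_mutation"] = "no subtype assignment"
    else:
        skipped["tumor_mutations"] = "no mutation file supplied"
    timings["tumor_mutations"] = time.perf_counter() - t0

    # ---- dependency screen -------------------------------------------------
    t0 = time.perf_counter()
    if (
        config.dependency_scores_path
        and Path(config.dependency_scores_path).exists()
        and config.cell_line_mutations_path
        and Path(config.cell_line_mutations_path).exists()
    ):
        scores = read_dependency_scores(config.dependency_scores_path)
        cl_mut = read_mutations(config.cell_line_mutations_path)
        emit("depscore.tsv", screen_all_mutations(scores, cl_mut))
    else:
        skipped["dependency"] = "no dependency inputs supplied"
    timings["dependency"] = time.perf_counter() - t0

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        input_checksums=input_checksums,
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        diagnostics=diagnostics,
        outputs=outputs,
        skipped_stages=skipped,
    )
    manifest.write(out_dir / "manifest.json")
    logger.info("pipeline complete: %d artifacts in %s", len(outputs), out_dir)
    return manifest
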