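"""Survival-analysis-similarity (SAS) network and hub-gene selection.

SAS compares two genes' binary significance vectors at the first (smallest)
sampling gradient, where significance patterns are most variable.  With
a = sum(A_i), b = sum(B_i) and c = sum(A_i * B_i) (joint significance count):

    SAS(A, B) = c / (a + b - 2c + 1)

The formula is implemented exactly as printed.  Note that it is NOT bounded
by 1: when the two vectors are identical (a = b = c) it equals c.  A
normalized Jaccard variant c / (a + b - c) is available behind a flag.

The core survival network (CSN) keeps the top-ranked edges (default 1000)
among candidate pairs formed between every GEAR and all other genes; hub
genes are the highest-degree GEAR nodes with mean expression > 10 TPM.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix
from .screen import GearSet, SignificanceTensor

logger = logging.getLogger(__name__)


def sas_score(vec_a: np.ndarray, vec_b: np.ndarray, normalized: bool = False) -> float:
    """SAS between two binary significance vectors of equal length."""
    vec_a = np.asarray(vec_a)
    vec_b = np.asarray(vec_b)
    if vec_a.shape != vec_b.shape:
        raise ValueError("significance vectors must have equal length")
    a = int(vec_a.sum())
    b = int(vec_b.sum())
    c = int((vec_a * vec_b).sum())
    if normalized:
        return c / (a + b - c) if c else 0.0
    return c / (a + b - 2 * c + 1)


def compute_sas_edges(
    tensor: SignificanceTensor, gears: GearSet, normalized: bool = False
) -> pd.DataFrame:
    """Pairwise SAS between every GEAR and all other genes (first gradient).

    Candidate pairs are deduplicated as unordered pairs; both orientations of
    a GEAR-GEAR pair count once.  Returns a frame with columns
    ``gene_u, gene_v, sas, c`` where (gene_u, gene_v) is sorted
    lexicographically within each pair.
    """
    if len(gears) == 0:
        raise ValueError("empty GEAR set: no candidate edges")
    vectors = tensor.first_gradient_vectors().astype(np.int64)  # (G, N)
    gene_ids = tensor.gene_ids
    index = {g: i for i, g in enumerate(gene_ids)}
    gear_idx = np.asarray([index[g] for g in gears.gene_ids])

    counts = vectors.sum(axis=1)  # a_i per gene
    joint = vectors[gear_idx] @ vectors.T  # (n_gears, G) joint counts c

    rows: dict[tuple[str, str], tuple[float, int]] = {}
    for k, (gi, g) in enumerate(zip(gear_idx, gears.gene_ids)):
        row = joint[k]
        for xi in range(len(gene_ids)):
            x = gene_ids[xi]
            if x == g:
                continue
            pair = (g, x) if g < x else (x, g)
            if pair in rows:
                continue
            c = int(row[xi])
            a = int(counts[gi])
            b = int(counts[xi])
            if normalized:
                sas = c / (a + b - c) if c else 0.0
            else:
                sas = c / (a + b - 2 * c + 1)
            rows[pair] = (sas, c)
    frame = pd.DataFrame(
        [(u, v, sas, c) for (u, v), (sas, c) in rows.items()],
        columns=["gene_u", "gene_v", "sas", "c"],
    )
    logger.info("computed %d candidate SAS edges from %d GEARs", len(frame), len(gears))
    return frame


def _edge_sort(frame: pd.DataFrame) -> pd.DataFrame:
    """Deterministic total order: sas desc, joint count desc, then pair id."""
    return frame.sort_values(
        by=["sas", "c", "gene_u", "gene_v"],
        ascending=[False, False, True, True],
        kind="stable",
    ).reset_index(drop=True)


@dataclasses.dataclass
class CSNGraph:
    """Core survival network: top-ranked SAS edges as an undirected graph."""

    graph: nx.Graph
    edges: pd.DataFrame  # retained edges in rank order

    def degrees(self) -> pd.Series:
        deg = pd.Series(dict(self.graph.degree()), dtype=int)
        return deg.sort_index()

    def weighted_degrees(self) -> pd.Series:
        wdeg = pd.Series(dict(self.graph.degree(weight="sas")), dtype=float)
        return wdeg.sort_index()

    def to_frame(self) -> pd.DataFrame:
        return self.edges.copy()


def build_csn(edges: pd.DataFrame, top_k: int = 1000) -> CSNGraph:
    """Keep the first ``top_k`` edges under the deterministic rank order."""
    if len(edges) == 0:
        raise ValueError("no candidate edges")
    ranked = _edge_sort(edges)
    kept = ranked.head(top_k).reset_index(drop=True)
    graph = nx.Graph()
    for row in kept.itertuples(index=False):
        graph.add_edge(row.gene_u, row.gene_v, sas=row.sas, c=row.c)
    return CSNGraph(graph=graph, edges=kept)


@dataclasses.dataclass
class HubGeneSet:
    """Top-degree GEAR nodes of the CSN passing the mean-TPM filter."""

    gene_ids: np.ndarray
    degrees: np.ndarray
    mean_tpm: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.gene_ids, "degree": self.degrees, "mean_tpm": self.mean_tpm}
        )


def select_hub_genes(
    csn: CSNGraph,
    expr: ExpressionMatrix,
    gears: GearSet,
    top_n: int = 10,
    min_tpm: float = 10.0,
) -> HubGeneSet:
    """Hub genes: GEAR nodes with mean TPM strictly > ``min_tpm``, ranked by
    (degree desc, SAS-weighted degree desc, gene id); first ``top_n`` kept."""
    mean_tpm = expr.mean_tpm()
    degrees = csn.degrees()
    weighted = csn.weighted_degrees()
    gear_set = set(gears.gene_ids)

    candidates = [
        g
        for g in degrees.index
        if g in gear_set and g in mean_tpm.index and mean_tpm[g] > min_tpm
    ]
    if not candidates:
        logger.warning("no hub-gene candidates pass the GEAR + mean-TPM filter")
    ranked = sorted(candidates, key=lambda g: (-degrees[g], -weighted[g], g))
    chosen = ranked[:top_n]
    return HubGeneSet(
        gene_ids=np.asarray(chosen, dtype=object),
        degrees=np.asarray([int(degrees[g]) for g in chosen], dtype=int),
        mean_tpm=np.asarray([float(mean_tpm[g]) for g in chosen], dtype=float),
    )
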