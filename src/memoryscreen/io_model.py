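"""Core data containers and validated readers/writers.

All tabular inputs are plain tab- or comma-delimited text: an expression
matrix (genes x samples, TPM), a survival table (sample_id/time/event), a
minimal MAF-like mutation table and a cell-line x gene dependency-score
matrix.  Containers are thin dataclasses around numpy arrays / pandas frames
that enforce the invariants the downstream screen relies on (finite
non-negative TPM, unique identifiers, positive follow-up times, binary event
codes).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataValidationError,
    DuplicateIdentifierError,
    InvalidEventError,
    MissingColumnError,
    NegativeValueError,
    NonNumericValueError,
    NonPositiveTimeError,
)

logger = logging.getLogger(__name__)

#: MAF variant classes counted as non-silent (TMB, mutation carriers).
NONSILENT_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclasses.dataclass
class ExpressionMatrix:
    """TPM expression values, genes x samples.

    Values must be finite and non-negative; gene and sample identifiers must
    be unique.  ``values[i, j]`` is the TPM of ``gene_ids[i]`` in
    ``sample_ids[j]``.
    """

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be 2-D (genes x samples)")
        n_genes, n_samples = self.values.shape
        if n_genes < 1 or n_samples < 2:
            raise DataValidationError("need at least 1 gene and 2 samples")
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise DataValidationError("identifier lengths do not match value shape")
        _check_unique(list(self.gene_ids), "gene")
        _check_unique(list(self.sample_ids), "sample")
        if not np.isfinite(self.values).all():
            raise NonNumericValueError("expression matrix contains non-finite values")
        if (self.values < 0).any():
            raise NegativeValueError("expression matrix contains negative TPM values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=np.asarray(genes, dtype=object),
            sample_ids=self.sample_ids.copy(),
            values=self.values[rows, :],
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionMatrix(
            gene_ids=self.gene_ids.copy(),
            sample_ids=np.asarray(samples, dtype=object),
            values=self.values[:, cols],
        )

    def mean_tpm(self) -> pd.Series:
        """Mean TPM per gene over the full sample set."""
        return pd.Series(self.values.mean(axis=1), index=self.gene_ids)


@dataclasses.dataclass
class SurvivalTable:
    """Right-censored follow-up: time in days (> 0), event 1=observed 0=censored."""

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise DataValidationError("survival columns have unequal lengths")
        _check_unique(list(self.sample_ids), "sample")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise NonPositiveTimeError("follow-up times must be finite and > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise InvalidEventError("event indicator must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time": self.time, "event": self.event}
        )

    def subset(self, samples: Iterable[str]) -> "SurvivalTable":
        samples = list(samples)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in samples]
        return SurvivalTable(
            sample_ids=np.asarray(samples, dtype=object),
            time=self.time[rows],
            event=self.event[rows],
        )


@dataclasses.dataclass
class MutationTable:
    """Minimal MAF: one record per (gene, sample, variant classification)."""

    records: pd.DataFrame  # columns gene, sample, variant_class

    REQUIRED = ("gene", "sample", "variant_class")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise MissingColumnError(f"mutation table lacks column {col!r}")
        if self.records[list(self.REQUIRED)].isna().any().any():
            raise DataValidationError("mutation table contains empty fields")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def filter_classes(self, allowed: Iterable[str]) -> "MutationTable":
        allowed = set(allowed)
        kept = self.records[self.records["variant_class"].isin(allowed)]
        dropped = len(self.records) - len(kept)
        if dropped:
            logger.info("filtered %d mutation records outside the allow-list", dropped)
        return MutationTable(records=kept.reset_index(drop=True))

    def carriers(self, gene: str) -> set[str]:
        sub = self.records[self.records["gene"] == gene]
        return set(sub["sample"])

    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())


@dataclasses.dataclass
class DependencyScoreTable:
    """CRISPR dependency scores, cell lines x genes; may be negative."""

    cell_line_ids: np.ndarray
    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.cell_line_ids = np.asarray(self.cell_line_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_line_ids), len(self.gene_ids)):
            raise DataValidationError("score shape does not match identifiers")
        _check_unique(list(self.cell_line_ids), "cell line")
        _check_unique(list(self.gene_ids), "gene")
        if not np.isfinite(self.scores).all():
            raise NonNumericValueError("dependency scores must be finite")

    def gene_scores(self, gene: str) -> pd.Series:
        col = int(np.flatnonzero(self.gene_ids == gene)[0])
        return pd.Series(self.scores[:, col], index=self.cell_line_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_line_ids, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# Readers


def read_expression(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples TPM matrix (first column gene ids, header samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise DuplicateIdentifierError(f"duplicate gene identifier: {dup!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[
            [not np.issubdtype(d, np.number) for d in frame.dtypes]
        ]
        raise NonNumericValueError(f"non-numeric expression column(s): {list(bad)}")
    return ExpressionMatrix(
        gene_ids=frame.index.to_numpy(dtype=object),
        sample_ids=frame.columns.to_numpy(dtype=object),
        values=values.astype(float),
    )


def read_survival(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str = "time",
    event_col: str = "event",
    delimiter: str = "\t",
) -> SurvivalTable:
    """Read a survival table; rows with missing time/event are dropped with a log line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter)
    for col in (sample_col, time_col, event_col):
        if col not in frame.columns:
            raise MissingColumnError(f"survival table lacks column {col!r}")
    complete = frame.dropna(subset=[time_col, event_col])
    if len(complete) < len(frame):
        logger.info(
            "dropped %d survival rows with missing time/event", len(frame) - len(complete)
        )
    time = pd.to_numeric(complete[time_col], errors="coerce")
    if time.isna().any():
        raise NonNumericValueError("non-numeric follow-up time")
    event = pd.to_numeric(complete[event_col], errors="coerce")
    if event.isna().any() or not event.isin((0, 1)).all():
        raise InvalidEventError("event indicator must be 0 or 1")
    return SurvivalTable(
        sample_ids=complete[sample_col].astype(str).to_numpy(dtype=object),
        time=time.to_numpy(dtype=float),
        event=event.to_numpy(dtype=int),
    )


def read_mutations(
    path: str | Path,
    allowed_classes: Iterable[str] | None = None,
    delimiter: str = "\t",
) -> MutationTable:
    """Read a MAF-minimal table (Hugo_Symbol / Tumor_Sample_Barcode / Variant_Classification).

    Records whose variant class is outside ``allowed_classes`` are kept but
    logged; filtering happens downstream (TMB, carriers) so the raw table
    stays faithful to the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=delimiter, comment="#")
    required = {
        "Hugo_Symbol": "gene",
        "Tumor_Sample_Barcode": "sample",
        "Variant_Classification": "variant_class",
    }
    for col in required:
        if col not in frame.columns:
            raise MissingColumnError(f"mutation file lacks column {col!r}")
    table = MutationTable(records=frame.rename(columns=required)[list(required.values())])
    if allowed_classes is not None:
        unknown = set(table.records["variant_class"]) - set(allowed_classes)
        if unknown:
            logger.info("mutation file contains unlisted variant classes: %s", sorted(unknown))
    return table


def read_dependency_scores(
    path: str | Path, delimiter: str | None = None
) -> DependencyScoreTable:
    """Read a cell-line x gene dependency score matrix (CSV or TSV).

    When ``delimiter`` is omitted it is inferred from the extension
    (``.csv`` -> comma, anything else -> tab).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    return DependencyScoreTable(
        cell_line_ids=frame.index.to_numpy(dtype=object),
        gene_ids=frame.columns.to_numpy(dtype=object),
        scores=frame.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Alignment and writing


def align_samples(
    expr: ExpressionMatrix, surv: SurvivalTable, min_samples: int = 10
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Inner-join expression and survival on sample id, sorted lexicographically.

    Sorting makes the aligned cohort order independent of file row order,
    which in turn fixes the stable tie-break used by the median split.
    """
    shared = sorted(set(expr.sample_ids) & set(surv.sample_ids))
    if len(shared) < min_samples:
        raise AlignmentError(
            f"only {len(shared)} shared samples between expression and survival "
            f"(need >= {min_samples})"
        )
    return expr.subset_samples(shared), surv.subset(shared)


def write_table(obj, path: str | Path) -> None:
    """Write a pipeline result as TSV; re-reading reproduces stored values exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ExpressionMatrix):
        frame = obj.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")
    elif isinstance(obj, SurvivalTable):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, MutationTable):
        out = obj.records.rename(
            columns={
                "gene": "Hugo_Symbol",
                "sample": "Tumor_Sample_Barcode",
                "variant_class": "Variant_Classification",
            }
        )
        out.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, DependencyScoreTable):
        frame = obj.to_frame()
        frame.index.name = "cell_line"
        frame.to_csv(path, sep="\t")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t")
    elif hasattr(obj, "to_frame"):
        write_table(obj.to_frame(), path)
    else:
        raise TypeError(f"don't know how to write {type(obj).__name__} as a table")
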