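"""Shared data containers for the CNV clonal-evolution pipeline.

These are deliberately thin wrappers around numpy arrays / pandas frames:
each one validates its invariants at construction time and exposes only the
accessors the pipeline stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "GenePositions",
    "CnvMatrix",
    "CnvRegionCall",
    "CloneEventSet",
    "SurvivalTable",
]

HISTOLOGY_LEVELS = ("DCIS", "IDC", "normal")


def _check_unique(ids, what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        raise ValueError(f"duplicate {what} ids")
    return arr


@dataclass
class CountMatrix:
    """Cells/spots x genes raw counts with per-cell metadata.

    ``meta`` is indexed by cell id and may carry ``sample``, ``histology``
    (DCIS / IDC / normal / NA), ``is_reference`` and optional ``x`` / ``y``
    spatial coordinates.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("shape mismatch between values and ids")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.meta = self.meta.loc[list(self.cell_ids)].copy()

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        idx = self._cell_indexer(mask_or_ids)
        return CountMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids, self.meta.iloc[idx]
        )

    def subset_genes(self, mask_or_ids) -> "CountMatrix":
        idx = self._gene_indexer(mask_or_ids)
        return CountMatrix(self.values[:, idx], self.cell_ids, self.gene_ids[idx], self.meta)

    def _cell_indexer(self, mask_or_ids) -> np.ndarray:
        return _indexer(mask_or_ids, self.cell_ids)

    def _gene_indexer(self, mask_or_ids) -> np.ndarray:
        return _indexer(mask_or_ids, self.gene_ids)


def _indexer(mask_or_ids, ids: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != ids.shape:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    lookup = {g: i for i, g in enumerate(ids)}
    try:
        return np.array([lookup[g] for g in arr], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - message only
        raise KeyError(f"unknown id {exc.args[0]!r}") from None


@dataclass
class ExpressionMatrix:
    """Cells x genes normalized (log) expression."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression must be 2-D (cells x genes)")
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("shape mismatch between values and ids")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids))
        else:
            self.meta = self.meta.loc[list(self.cell_ids)].copy()

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _indexer(mask_or_ids, self.cell_ids)
        return ExpressionMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids, self.meta.iloc[idx]
        )

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _indexer(mask_or_ids, self.gene_ids)
        return ExpressionMatrix(self.values[:, idx], self.cell_ids, self.gene_ids[idx], self.meta)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}


class GenePositions:
    """Ordered map gene -> (chromosome, start, end, cytoband).

    Coordinates are 1-based inclusive. Genes are sorted by (chromosome order,
    start); sorting defines the genome order used for smoothing and region
    calls. ``chrM`` genes are carried but excluded from CNV work via
    :meth:`cnv_genes`.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"gene", "chromosome", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"gene-position table missing columns: {sorted(missing)}")
        table = table.copy()
        if "cytoband" not in table.columns:
            table["cytoband"] = ""
        if table["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in position table")
        if (table["end"] < table["start"]).any():
            raise ValueError("zero/negative-length genes present")
        order = {c: i for i, c in enumerate(self._chromosome_order(table["chromosome"]))}
        table["_chrom_rank"] = table["chromosome"].map(order)
        table = table.sort_values(["_chrom_rank", "start"], kind="mergesort")
        table = table.drop(columns="_chrom_rank").reset_index(drop=True)
        self.table = table

    @staticmethod
    def _chromosome_order(chroms: pd.Series) -> list:
        def key(c: str):
            name = str(c)
            core = name[3:] if name.lower().startswith("chr") else name
            if core.isdigit():
                return (0, int(core), "")
            special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
            return (0, special.get(core.upper(), 99), core)

        return sorted(pd.unique(chroms), key=key)

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chromosome"]))

    def cnv_genes(self) -> np.ndarray:
        """Genes eligible for CNV inference (mitochondrial contig excluded)."""
        keep = ~self.table["chromosome"].astype(str).str.lower().isin(["chrm", "mt", "m"])
        return self.table.loc[keep, "gene"].to_numpy()

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("gene")["chromosome"]

    def ordered(self, gene_ids) -> np.ndarray:
        """Return ``gene_ids`` reordered into genome order (unknown genes dropped)."""
        present = set(gene_ids)
        return np.array([g for g in self.genes if g in present], dtype=object)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CnvMatrix:
    """Cells x genes relative-CNV values, rescaled into [-1, 1]."""

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    positions: GenePositions
    reference_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.reference_ids = np.asarray(self.reference_ids, dtype=object)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("shape mismatch")
        if np.nanmax(np.abs(self.values), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("CnvMatrix values must lie in [-1, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def row(self, cell_id) -> np.ndarray:
        idx = _indexer([cell_id], self.cell_ids)[0]
        return self.values[idx]


@dataclass(frozen=True)
class CnvRegionCall:
    """One contiguous non-neutral region called in a cell or clone profile."""

    unit_id: str
    chromosome: str
    start_index: int  # gene index within the profile's genome order, inclusive
    end_index: int  # inclusive
    start_pos: int  # genomic coordinates, 1-based inclusive
    end_pos: int
    state: str  # "amplification" | "deletion"
    mean_signal: float

    def __post_init__(self) -> None:
        if self.state not in ("amplification", "deletion"):
            raise ValueError(f"invalid region state {self.state!r}")
        if self.end_index < self.start_index:
            raise ValueError("region end before start")

    @property
    def n_genes(self) -> int:
        return self.end_index - self.start_index + 1

    def gene_span(self) -> range:
        return range(self.start_index, self.end_index + 1)


@dataclass
class CloneEventSet:
    """Per-clone discrete CNV events; the Z set of the branch-length formula."""

    clone_id: str
    events: list  # list of hashable event keys, or CnvRegionCall-like records
    members: list = field(default_factory=list)
    support: dict = field(default_factory=dict)  # event -> supporting fraction
    histology: dict = field(default_factory=dict)  # label -> fraction

    @property
    def size(self) -> int:
        return len(self.events)

    def event_set(self) -> frozenset:
        return frozenset(self.events)


@dataclass
class SurvivalTable:
    """Per-subject survival outcome plus the expression value used to stratify."""

    time: np.ndarray
    event: np.ndarray
    expression: np.ndarray
    covariates: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.expression = np.asarray(self.expression, dtype=float)
        n = len(self.time)
        if len(self.event) != n or len(self.expression) != n:
            raise ValueError("survival columns must have equal length")
        if np.any(self.time < 0):
            raise ValueError("negative survival times")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.time, "event": self.event, "expression": self.expression}
        )
        if self.covariates is not None:
            df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        return df
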