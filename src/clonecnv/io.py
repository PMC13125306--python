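"""Plain-text readers/writers for the standard exchange formats.

10x-style MTX triple (matrix.mtx / features.tsv / barcodes.tsv), dense count
TSV, gene-position TSV (1-based inclusive), annotation TSV, clone-event TSV,
BED-like region-call TSV (0-based half-open genomic coordinates) and truth
JSON. All outputs are deterministic byte-for-byte for a given input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .data import CloneEventSet, CountMatrix, GenePositions

__all__ = [
    "write_10x_dir",
    "read_10x_dir",
    "read_dense_tsv",
    "write_positions_tsv",
    "read_positions_tsv",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "write_truth_json",
    "write_events_tsv",
    "read_events_tsv",
    "write_region_calls_tsv",
]

_META_COLUMNS = ["sample", "histology", "is_reference", "region", "x", "y", "clone"]


def write_10x_dir(m: CountMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(m.values.T)  # MTX convention: genes x cells
    scio.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame({"id": m.gene_ids, "name": m.gene_ids,
                          "type": "Gene Expression"})
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_10x_dir(in_dir, meta: pd.DataFrame | None = None) -> CountMatrix:
    path = Path(in_dir)
    mat = scio.mmread(str(path / "matrix.mtx"))
    feats = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    values = np.asarray(sparse.csr_matrix(mat).todense()).T  # cells x genes
    return CountMatrix(values.astype(np.int64),
                       barcodes.to_numpy(dtype=object),
                       feats[0].to_numpy(dtype=object), meta)


def read_dense_tsv(path, meta: pd.DataFrame | None = None) -> CountMatrix:
    """Dense count table: rows = cells, columns = genes, first column = cell id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object), meta)


def write_positions_tsv(positions: GenePositions, path) -> None:
    positions.table.to_csv(path, sep="\t", index=False)


def read_positions_tsv(path) -> GenePositions:
    return GenePositions(pd.read_csv(path, sep="\t"))


def write_annotations_tsv(meta: pd.DataFrame, path) -> None:
    cols = [c for c in _META_COLUMNS if c in meta.columns]
    extra = [c for c in meta.columns if c not in cols]
    df = meta[cols + extra].copy()
    df.insert(0, "cell", meta.index)
    df.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("cell")


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_events_tsv(clone_sets: dict, path) -> None:
    """Clone-event table mirroring per-subcluster region-file semantics:
    clone, chromosome, start/end gene index (chromosome-local, inclusive),
    direction, supporting fraction."""
    rows = []
    for clone_id in sorted(clone_sets):
        c = clone_sets[clone_id]
        for ev in sorted(c.events):
            chrom, start, end, direction = ev
            rows.append((clone_id, chrom, start, end, direction,
                         round(c.support.get(ev, float("nan")), 6),
                         len(c.members)))
    pd.DataFrame(rows, columns=["clone", "chromosome", "start_gene", "end_gene",
                                "direction", "support", "n_members"]
                 ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for clone, grp in df.groupby("clone", sort=True):
        events = [(r.chromosome, int(r.start_gene), int(r.end_gene), r.direction)
                  for r in grp.itertuples()]
        support = {e: float(s) for e, s in zip(events, grp["support"])}
        out[str(clone)] = CloneEventSet(clone_id=str(clone), events=events,
                                        support=support,
                                        members=[f"{clone}_{i}" for i in
                                                 range(int(grp["n_members"].iloc[0]))])
    return out


def write_region_calls_tsv(calls: dict, path) -> None:
    """BED-like export of region calls: genomic coordinates converted from
    1-based inclusive to 0-based half-open."""
    rows = []
    for unit in sorted(calls):
        for c in calls[unit]:
            rows.append((c.chromosome, c.start_pos - 1, c.end_pos, unit, c.state,
                         c.start_index, c.end_index, round(c.mean_signal, 6)))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "unit", "state",
                                "start_gene", "end_gene", "mean_signal"]
                 ).to_csv(path, sep="\t", index=False)
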