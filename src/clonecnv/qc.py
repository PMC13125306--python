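"""Quality control, normalization, feature selection, clustering and scoring.

Covers the preprocessing applied before CNV inference: barcode-level QC
filters, library-size log normalization, vst-style highly-variable-gene
selection, PCA + SNN modularity clustering, marker-based cluster annotation,
and expression-bin-matched module scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix, ExpressionMatrix, GenePositions

__all__ = [
    "QcThresholds",
    "QcReport",
    "qc_filter",
    "normalize_log1p",
    "select_hvg_vst",
    "cluster_snn",
    "center_batches",
    "annotate_markers",
    "module_score",
    "DEFAULT_MARKERS",
]

DEFAULT_MARKERS = {
    "epithelial": ["EPCAM", "KRT8", "KRT18"],
    "fibroblast": ["PDGFRA", "COL3A1", "POSTN", "COL1A1", "COL5A2"],
    "endothelial": ["PECAM1", "CLDN5", "ITGA6", "ENG", "FLT1", "CD93", "PLVAP"],
    "myeloid": ["CD68", "APOE", "APOC1", "C1QA", "C1QC"],
    "tcell": ["CD3D", "CCL5", "TRBC2", "CD2"],
    "bcell": ["BANK1", "CD79A", "IGHM", "MS4A1"],
}


@dataclass(frozen=True)
class QcThresholds:
    min_umis: int = 200
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in (0, 1]")


@dataclass
class QcReport:
    n_input: int
    n_retained: int
    removed_low_umis: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_mito: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["input", "retained", "low_umis", "low_genes",
                              "high_genes", "high_mito"],
                "cells": [self.n_input, self.n_retained, self.removed_low_umis,
                          self.removed_low_genes, self.removed_high_genes,
                          self.removed_high_mito],
            }
        )


def mito_gene_mask(m: CountMatrix, prefix: str = "MT-",
                   positions: GenePositions | None = None) -> np.ndarray:
    """Mitochondrial genes are matched by name prefix or, when positions are
    available, by residing on the mitochondrial contig."""
    mask = np.array([str(g).upper().startswith(prefix.upper()) for g in m.gene_ids])
    if positions is not None:
        chrom = positions.chromosome_of()
        on_chrm = np.array(
            [str(chrom.get(g, "")).lower() in ("chrm", "mt", "m") for g in m.gene_ids]
        )
        mask |= on_chrm
    return mask


def qc_filter(m: CountMatrix, thresholds: QcThresholds = QcThresholds(),
              mito_prefix: str = "MT-",
              positions: GenePositions | None = None):
    """Drop low-quality barcodes. A cell is retained iff

    UMIs >= min_umis  AND  min_genes <= detected genes <= max_genes
    AND mito fraction <= max_mito_fraction.

    Returns ``(filtered CountMatrix, QcReport)``; the report counts violators
    per criterion (a cell may violate several).
    """
    umis = m.values.sum(axis=1)
    detected = (m.values > 0).sum(axis=1)
    mito = mito_gene_mask(m, mito_prefix, positions)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, m.values[:, mito].sum(axis=1) / np.maximum(umis, 1), 1.0)

    low_umis = umis < thresholds.min_umis
    low_genes = detected < thresholds.min_genes
    high_genes = detected > thresholds.max_genes
    high_mito = mito_frac > thresholds.max_mito_fraction
    keep = ~(low_umis | low_genes | high_genes | high_mito)
    if not keep.any():
        raise ValueError("QC removed every cell; thresholds too strict for this matrix")
    report = QcReport(
        n_input=m.n_cells,
        n_retained=int(keep.sum()),
        removed_low_umis=int(low_umis.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_high_genes=int(high_genes.sum()),
        removed_high_mito=int(high_mito.sum()),
    )
    return m.subset_cells(keep), report


def normalize_log1p(m: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``scale`` total counts, then log(1 + x). All-zero
    cells map to all-zero rows."""
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("cannot normalize an empty matrix")
    totals = m.values.sum(axis=1, keepdims=True).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(m.values / safe * scale)
    return ExpressionMatrix(values, m.cell_ids, m.gene_ids, m.meta)


def select_hvg_vst(m, n: int = 2000) -> np.ndarray:
    """Top-``n`` highly variable genes by vst-style standardized variance.

    The mean-variance trend is a second-degree polynomial fit of log10
    variance on log10 mean; standardized values are clipped at sqrt(N) before
    the per-gene variance is recomputed. Accepts counts or expression.
    """
    x = np.asarray(m.values, dtype=float)
    gene_ids = np.asarray(m.gene_ids, dtype=object)
    if n > x.shape[1]:
        raise ValueError(f"requested {n} genes but matrix has {x.shape[1]}")
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    ok = (var > 0) & (mean > 0)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 genes with nonzero variance")
    coeffs = np.polyfit(np.log10(mean[ok]), np.log10(var[ok]), deg=2)
    expected_sd = np.sqrt(10 ** np.polyval(coeffs, np.log10(np.maximum(mean, 1e-12))))
    expected_sd[~ok] = np.inf  # constant genes never selected
    clip = np.sqrt(x.shape[0])
    z = np.clip((x - mean[None, :]) / expected_sd[None, :], -clip, clip)
    std_var = z.var(axis=0, ddof=1)
    std_var[~ok] = -np.inf
    order = np.argsort(-std_var, kind="mergesort")
    return gene_ids[order[:n]]


def _pca(values: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.clip((values - mean) / sd, -10, 10)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(z)


def center_batches(pcs: np.ndarray, batches) -> np.ndarray:
    """Batch substitute for Harmony: per-batch mean-centering of PC
    coordinates. Never changes the number of cells."""
    pcs = np.asarray(pcs, dtype=float).copy()
    batches = np.asarray(batches)
    grand = pcs.mean(axis=0)
    for b in np.unique(batches):
        mask = batches == b
        pcs[mask] += grand - pcs[mask].mean(axis=0)
    return pcs


def cluster_snn(e: ExpressionMatrix, n_pcs: int = 30, resolution: float = 0.1,
                seed: int = 0, n_neighbors: int = 20, hvg=None,
                batch_key: str | None = None) -> np.ndarray:
    """PCA -> kNN -> Jaccard-weighted SNN graph -> Leiden modularity
    clustering at the given resolution. Deterministic under ``seed``."""
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    mat = e.subset_genes(hvg) if hvg is not None else e
    n_cells, n_genes = mat.values.shape
    if n_pcs > min(n_cells, n_genes):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(n_cells, n_genes)}")
    pcs = _pca(mat.values, n_pcs, seed)
    if batch_key is not None:
        pcs = center_batches(pcs, mat.meta[batch_key].to_numpy())

    k = min(n_neighbors, n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    idx = idx[:, 1:]  # drop self
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    for i in range(n_cells):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = shared / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)
    g = ig.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def annotate_markers(e: ExpressionMatrix, labels, marker_table: dict | None = None):
    """Assign each cluster the cell type whose marker-set mean expression
    (cluster-averaged, z-scored across clusters) is maximal.

    Returns ``(mapping cluster -> cell type, list of tied clusters)``. Ties
    are broken lexicographically and reported.
    """
    markers = marker_table if marker_table is not None else DEFAULT_MARKERS
    labels = np.asarray(labels)
    gene_pos = e.gene_index()
    missing = {t: [g for g in genes if g not in gene_pos] for t, genes in markers.items()}
    fully_missing = [t for t, lost in missing.items() if len(lost) == len(markers[t])]
    if fully_missing:
        raise ValueError(
            "no marker gene present in matrix for cell types "
            f"{fully_missing}; missing genes: "
            f"{ {t: missing[t] for t in fully_missing} }"
        )
    clusters = np.unique(labels)
    cluster_mean = np.vstack(
        [e.values[labels == c].mean(axis=0) for c in clusters]
    )  # clusters x genes
    mu = cluster_mean.mean(axis=0)
    sd = cluster_mean.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    zed = (cluster_mean - mu) / sd
    scores = {}
    for t in sorted(markers):
        cols = [gene_pos[g] for g in markers[t] if g in gene_pos]
        scores[t] = zed[:, cols].mean(axis=1)
    score_df = pd.DataFrame(scores, index=clusters)
    assignment, ties = {}, []
    for c in clusters:
        row = score_df.loc[c]
        best = row.max()
        winners = sorted(row.index[row >= best - 1e-12])
        assignment[c] = winners[0]
        if len(winners) > 1:
            ties.append(c)
    return assignment, ties


def module_score(e: ExpressionMatrix, signature, n_bins: int = 25, n_ctrl: int = 100,
                 seed: int = 0) -> np.ndarray:
    """Per-cell signature score: mean expression of the signature genes minus
    the mean of control genes sampled from expression-matched bins."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature is empty")
    gene_pos = e.gene_index()
    missing = [g for g in signature if g not in gene_pos]
    if missing:
        raise ValueError(f"signature genes missing from matrix: {missing}")
    rng = np.random.default_rng(seed)
    mean_expr = e.values.mean(axis=0)
    n_genes = len(mean_expr)
    n_bins = min(n_bins, n_genes)
    # rank-based equal-occupancy bins, as the usual module-score tools do
    ranks = pd.Series(mean_expr).rank(method="first").to_numpy() - 1
    bins = np.floor(ranks / len(ranks) * n_bins).astype(int)
    bins = np.minimum(bins, n_bins - 1)
    sig_idx = np.array([gene_pos[g] for g in signature])
    ctrl_idx: list[int] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False))
    if not ctrl_idx:  # pragma: no cover - defensive
        warnings.warn("no control genes available; score is signature mean")
        return e.values[:, sig_idx].mean(axis=1)
    ctrl = np.unique(np.asarray(ctrl_idx))
    return e.values[:, sig_idx].mean(axis=1) - e.values[:, ctrl].mean(axis=1)
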