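"""Relative-CNV inference from genome-ordered expression.

The chain mirrors the reference-based inference idiom: drop weakly expressed
genes, subtract the reference-cell per-gene mean, smooth along genome order
within chromosomes, suppress signal inside a dynamic reference band
(1.5 SD by default), rescale to [-1, 1], summarize per-cell burden, call
discrete states with a 3-state Gaussian HMM, and collapse per-cell region
calls into clone-level consensus events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CloneEventSet, CnvMatrix, CnvRegionCall, ExpressionMatrix, GenePositions

__all__ = [
    "center_on_reference",
    "smooth_genome",
    "denoise_dynamic",
    "rescale_unit",
    "cnv_score",
    "call_states_hmm",
    "consensus_clone_events",
    "infer_cnv",
    "CnvResult",
]

STATE_NAMES = ("deletion", "neutral", "amplification")


def _chromosome_blocks(positions: GenePositions, gene_ids) -> list:
    """Contiguous (chromosome, global slice, local gene table) blocks in the
    genome order induced by ``positions`` on ``gene_ids``."""
    chrom_of = positions.chromosome_of()
    chroms = [chrom_of[g] for g in gene_ids]
    blocks = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            blocks.append((chroms[start], slice(start, i)))
            start = i
    return blocks


def center_on_reference(e: ExpressionMatrix, ref_ids, cutoff: float = 0.1,
                        clip: float = 3.0) -> ExpressionMatrix:
    """Drop genes whose mean expression across all cells is below ``cutoff``,
    then subtract the reference-cell per-gene mean and clip residuals."""
    ref_ids = list(ref_ids)
    if len(ref_ids) == 0:
        raise ValueError("reference cell list is empty")
    if len(ref_ids) < 20:
        warnings.warn(f"only {len(ref_ids)} reference cells; >= 20 recommended")
    keep = e.values.mean(axis=0) >= cutoff
    if not keep.any():
        raise ValueError(f"all genes fall below the expression cutoff {cutoff}")
    e = e.subset_genes(keep)
    ref = e.subset_cells(ref_ids)
    residuals = e.values - ref.values.mean(axis=0)[None, :]
    if clip is not None:
        residuals = np.clip(residuals, -clip, clip)
    return ExpressionMatrix(residuals, e.cell_ids, e.gene_ids, e.meta)


def smooth_genome(residuals: ExpressionMatrix, positions: GenePositions,
                  window: int = 101) -> ExpressionMatrix:
    """Windowed moving average along genome order, never crossing chromosome
    boundaries; the window shrinks symmetrically at chromosome edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    order = positions.ordered(residuals.gene_ids)
    if len(order) == 0:
        raise ValueError("no gene overlaps the position table")
    mat = residuals.subset_genes(order)
    out = np.empty_like(mat.values)
    half = (window - 1) // 2
    for chrom, sl in _chromosome_blocks(positions, mat.gene_ids):
        block = mat.values[:, sl]
        length = block.shape[1]
        if window > length:
            warnings.warn(
                f"window {window} larger than chromosome {chrom} ({length} genes); capped"
            )
        h = min(half, (length - 1) // 2) if length > 1 else 0
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        idx = np.arange(length)
        lo = np.maximum(idx - h, 0)
        hi = np.minimum(idx + h, length - 1)
        out[:, sl] = (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)
    return ExpressionMatrix(out, mat.cell_ids, mat.gene_ids, mat.meta)


def center_cells_median(smoothed: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each cell's median value.

    Library-size normalization leaves a per-cell global offset in log space
    (cells with few counts shift all genes together); the per-cell median is
    a copy-neutral baseline as long as events cover a minority of the genome.
    """
    med = np.median(smoothed.values, axis=1, keepdims=True)
    return ExpressionMatrix(smoothed.values - med, smoothed.cell_ids,
                            smoothed.gene_ids, smoothed.meta)


def denoise_dynamic(smoothed: ExpressionMatrix, ref_ids, k_sd: float = 1.5,
                    mode: str = "soft"):
    """Suppress signal inside the dynamic reference band.

    Per gene, values are re-centered on the reference-cell mean; values whose
    magnitude is <= ``k_sd`` pooled reference SDs (closed band, boundary
    suppressed) become zero signal. Values outside the band either pass
    through unchanged (``mode="hard"``) or are shrunk toward zero by the band
    width (``mode="soft"``, the default) — soft shrinkage removes the
    residual noise tail that survives a hard threshold in reference cells
    while leaving genuine events, whose magnitude dwarfs the band, nearly
    untouched. Returns ``(signal ExpressionMatrix, reference SD)``.
    """
    ref = smoothed.subset_cells(list(ref_ids))
    mu = ref.values.mean(axis=0)
    centered_ref = ref.values - mu[None, :]
    sd = float(centered_ref.std(ddof=1))
    if sd == 0:
        raise ValueError(
            "reference signal has zero variance; add more (or more varied) reference cells"
        )
    # per-gene bands absorb gene-to-gene noise heteroskedasticity; genes with
    # degenerate per-gene SD fall back to the pooled value
    sd_gene = centered_ref.std(axis=0, ddof=1) if ref.values.shape[0] > 1 else None
    if sd_gene is None or np.all(sd_gene == 0):
        sd_gene = np.full(smoothed.values.shape[1], sd)
    else:
        sd_gene = np.where(sd_gene > 0, sd_gene, sd)
    band = k_sd * sd_gene[None, :]
    signal = smoothed.values - mu[None, :]
    if mode == "hard":
        signal = np.where(np.abs(signal) <= band, 0.0, signal)
    elif mode == "soft":
        signal = np.sign(signal) * np.maximum(np.abs(signal) - band, 0.0)
    else:
        raise ValueError(f"unknown denoise mode {mode!r}")
    return ExpressionMatrix(signal, smoothed.cell_ids, smoothed.gene_ids, smoothed.meta), sd


def rescale_unit(denoised: ExpressionMatrix, positions: GenePositions, ref_ids,
                 clip_percentiles: tuple | None = None) -> CnvMatrix:
    """Rescale to [-1, 1] by the matrix-wide maximum absolute value.

    Optional symmetric percentile clipping (e.g. ``(1, 99)``) is applied
    first. An all-zero matrix passes through unchanged.
    """
    values = np.asarray(denoised.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("denoised matrix contains non-finite values")
    if clip_percentiles is not None:
        lo, hi = np.percentile(values, clip_percentiles)
        bound = max(abs(lo), abs(hi))
        values = np.clip(values, -bound, bound)
    max_abs = np.abs(values).max()
    if max_abs > 0:
        values = values / max_abs
    return CnvMatrix(values, denoised.cell_ids, denoised.gene_ids, positions,
                     np.asarray(list(ref_ids), dtype=object))


def cnv_score(c: CnvMatrix, mode: str = "mean_abs") -> pd.Series:
    """Per-cell CNV burden.

    ``mean_abs`` (default) is the mean absolute rescaled signal — the sum over
    the genome normalized by gene count, so scores stay comparable across gene
    panels. ``sum_abs`` is the raw sum.
    """
    total = np.abs(c.values).sum(axis=1)
    if mode == "mean_abs":
        total = total / c.values.shape[1]
    elif mode != "sum_abs":
        raise ValueError(f"unknown score mode {mode!r}")
    return pd.Series(total, index=pd.Index(c.cell_ids), name="cnv_score")


# ---------------------------------------------------------------------------
# HMM region calls


def _viterbi_batch(x: np.ndarray, means: np.ndarray, sigma: float,
                   p_stay: float) -> np.ndarray:
    """Most likely state path for each row of ``x`` under a 3-state Gaussian
    HMM with uniform initial distribution and symmetric transitions."""
    n_units, n_genes = x.shape
    k = len(means)
    log_trans = np.full((k, k), np.log((1 - p_stay) / (k - 1)))
    np.fill_diagonal(log_trans, np.log(p_stay))

    def emit(t):
        return -0.5 * ((x[:, t, None] - means[None, :]) / sigma) ** 2 - np.log(sigma)

    v = np.log(1.0 / k) + emit(0)  # (units, k)
    ptr = np.empty((n_genes, n_units, k), dtype=np.int8)
    ptr[0] = 0
    for t in range(1, n_genes):
        cand = v[:, :, None] + log_trans[None, :, :]  # units x from x to
        ptr[t] = np.argmax(cand, axis=1)
        v = np.take_along_axis(cand, ptr[t][:, None, :], axis=1)[:, 0, :] + emit(t)
    path = np.empty((n_units, n_genes), dtype=np.int8)
    path[:, -1] = np.argmax(v, axis=1)
    for t in range(n_genes - 1, 0, -1):
        path[:, t - 1] = np.take_along_axis(ptr[t], path[:, t][:, None], axis=1)[:, 0]
    return path


def call_states_hmm(values, gene_ids, positions: GenePositions, sigma: float,
                    unit_ids=None, delta: float | None = None,
                    p_stay: float = 0.99) -> dict:
    """Call non-neutral regions per unit (cell or clone profile).

    States are deletion (mean -delta), neutral (0), amplification (+delta)
    with shared Gaussian emission SD ``sigma`` (estimated from reference
    residuals upstream). ``delta`` defaults to the median absolute nonzero
    signal (fallback 0.2). Consecutive same-state genes merge into regions;
    neutral regions are not emitted; regions never cross chromosomes.

    Returns ``{unit_id: [CnvRegionCall, ...]}`` with chromosome-local gene
    indices.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    gene_ids = np.asarray(gene_ids, dtype=object)
    if unit_ids is None:
        unit_ids = [f"unit{i}" for i in range(values.shape[0])]
    if sigma <= 0:
        raise ValueError("sigma must be positive (zero reference variance?)")
    if delta is None:
        nz = np.abs(values[values != 0])
        delta = float(np.median(nz)) if nz.size else 0.2
    means = np.array([-delta, 0.0, delta])

    pos_table = positions.table.set_index("gene")
    calls: dict = {str(u): [] for u in unit_ids}
    for chrom, sl in _chromosome_blocks(positions, gene_ids):
        block = values[:, sl]
        path = _viterbi_batch(block, means, sigma, p_stay)
        genes = gene_ids[sl]
        starts = pos_table.loc[genes, "start"].to_numpy()
        ends = pos_table.loc[genes, "end"].to_numpy()
        for ui, u in enumerate(unit_ids):
            p = path[ui]
            i = 0
            while i < len(p):
                j = i
                while j + 1 < len(p) and p[j + 1] == p[i]:
                    j += 1
                if p[i] != 1:  # non-neutral
                    calls[str(u)].append(
                        CnvRegionCall(
                            unit_id=str(u),
                            chromosome=str(chrom),
                            start_index=i,
                            end_index=j,
                            start_pos=int(starts[i]),
                            end_pos=int(ends[j]),
                            state=STATE_NAMES[p[i]],
                            mean_signal=float(block[ui, i:j + 1].mean()),
                        )
                    )
                i = j + 1
    return calls


# ---------------------------------------------------------------------------
# Clone-level consensus events


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def _small_window_mean(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(profile) < 2:
        return profile
    half = min((window - 1) // 2, (len(profile) - 1) // 2)
    csum = np.concatenate([[0.0], np.cumsum(profile)])
    idx = np.arange(len(profile))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(profile) - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _refine_region(raw: np.ndarray, smooth: np.ndarray, start: int, end: int,
                   direction: str):
    """Snap region boundaries to the clone-mean residual profile.

    Two passes: (1) a robust contiguous run on the lightly smoothed profile
    (>= 50% of the plateau, same direction) locates the region; (2) each edge
    is placed by a CUSUM step fit on the unsmoothed profile — the boundary
    maximizing the cumulative sum of (signal - plateau/2) toward the region
    midpoint — which tolerates individual low-expression genes whose
    log-ratio is compressed, yet keeps the sharpness of the raw step."""
    sign = 1.0 if direction == "amplification" else -1.0
    plateau_s = float(np.median(smooth[start:end + 1]) * sign)
    if plateau_s <= 0:
        return start, end
    mid = (start + end) // 2
    ok = sign * smooth >= 0.5 * plateau_s
    if not ok[mid]:
        inside = np.flatnonzero(ok[start:end + 1])
        if inside.size == 0:
            return start, end
        mid = start + inside[inside.size // 2]
    lo = mid
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = mid
    while hi + 1 < len(ok) and ok[hi + 1]:
        hi += 1
    h = float(np.median(raw[lo:hi + 1]) * sign)
    if h <= 0:
        return lo, hi
    g = sign * raw - 0.5 * h
    mid = (lo + hi) // 2
    # left edge: maximize sum(g[p..mid]) over p
    left_sums = np.cumsum(g[:mid + 1][::-1])[::-1]
    new_lo = int(np.argmax(left_sums))
    # right edge: maximize sum(g[mid..p])
    right_sums = np.cumsum(g[mid:])
    new_hi = mid + int(np.argmax(right_sums))
    return new_lo, new_hi


def consensus_clone_events(calls: dict, clone_labels, positions: GenePositions,
                           gene_ids, min_fraction: float = 0.75,
                           min_overlap: float = 0.5, min_cells: int = 5,
                           refine: ExpressionMatrix | None = None,
                           refine_window: int = 9,
                           histology=None) -> dict:
    """Collapse per-cell region calls into per-clone consensus event sets.

    A consensus region is a contiguous run of genes carried (same direction)
    by >= ``min_fraction`` of the clone's cells; it is emitted if that same
    fraction of cells have an individual call with >= ``min_overlap``
    reciprocal overlap. When ``refine`` (the centered, unsmoothed residual
    matrix) is supplied, boundaries are snapped to the clone-mean profile,
    undoing the smoothing blur.

    Returns ``{clone_id: CloneEventSet}`` with events keyed as
    ``(chromosome, start_index, end_index, direction)`` (chromosome-local,
    inclusive gene indices).
    """
    clone_labels = pd.Series(clone_labels)
    gene_ids = np.asarray(gene_ids, dtype=object)
    blocks = _chromosome_blocks(positions, gene_ids)
    refine_idx = None
    if refine is not None:
        refine_idx = {g: i for i, g in enumerate(refine.gene_ids)}

    out: dict = {}
    for clone in sorted(clone_labels.dropna().unique()):
        if clone == "":
            continue
        members = [str(c) for c in clone_labels.index[clone_labels == clone]]
        members = [m for m in members if m in calls]
        if len(members) < min_cells:
            warnings.warn(f"clone {clone!r} has {len(members)} cells (< {min_cells}); skipped")
            continue
        events, support = [], {}
        for chrom, sl in blocks:
            length = sl.stop - sl.start
            raw_profile = smooth_profile = None
            if refine is not None:
                cols = [refine_idx[g] for g in gene_ids[sl] if g in refine_idx]
                raw_profile = refine.values[
                    np.isin(refine.cell_ids, members)][:, cols].mean(axis=0)
                smooth_profile = _small_window_mean(raw_profile, refine_window)
            for direction in ("amplification", "deletion"):
                frac = np.zeros(length)
                per_cell = {}
                for m in members:
                    regs = [c for c in calls[m] if c.chromosome == chrom and c.state == direction]
                    per_cell[m] = regs
                    for c in regs:
                        frac[c.start_index:c.end_index + 1] += 1
                frac /= len(members)
                i = 0
                while i < length:
                    if frac[i] >= min_fraction:
                        j = i
                        while j + 1 < length and frac[j + 1] >= min_fraction:
                            j += 1
                        start, end = i, j
                        if raw_profile is not None:
                            start, end = _refine_region(raw_profile, smooth_profile,
                                                        start, end, direction)
                        n_support = sum(
                            any(_reciprocal_overlap(r.start_index, r.end_index, i, j)
                                >= min_overlap for r in per_cell[m])
                            for m in members
                        )
                        sup = n_support / len(members)
                        if sup >= min_fraction:
                            key = (str(chrom), int(start), int(end), direction)
                            events.append(key)
                            support[key] = sup
                        i = j + 1
                    else:
                        i += 1
        hist = {}
        if histology is not None:
            hseries = pd.Series(histology)
            labels = hseries.reindex(members).dropna()
            labels = labels[labels.isin(["DCIS", "IDC"])]
            if len(labels):
                hist = (labels.value_counts() / len(labels)).to_dict()
        out[str(clone)] = CloneEventSet(
            clone_id=str(clone), events=events, members=members,
            support=support, histology=hist,
        )
    return out


# ---------------------------------------------------------------------------
# Convenience pipeline


@dataclass
class CnvResult:
    residuals: ExpressionMatrix  # centered, genome-ordered, pre-smoothing
    smoothed: ExpressionMatrix
    denoised: ExpressionMatrix
    cnv: CnvMatrix
    scores: pd.Series
    reference_sd: float
    reference_ids: list = field(default_factory=list)


def infer_cnv(e: ExpressionMatrix, positions: GenePositions, ref_ids,
              cutoff: float = 0.1, window: int = 101, k_sd: float = 1.5,
              clip: float = 3.0, score_mode: str = "mean_abs") -> CnvResult:
    """Full per-cell chain: cut-off filter + reference centering ->
    genome smoothing -> dynamic denoising -> [-1, 1] rescale -> CNV score."""
    ref_ids = [str(r) for r in ref_ids]
    keep = positions.ordered(np.intersect1d(e.gene_ids, positions.cnv_genes()))
    if len(keep) == 0:
        raise ValueError("no genes overlap the CNV-eligible position table")
    e = e.subset_genes(keep)
    residuals = center_on_reference(e, ref_ids, cutoff=cutoff, clip=clip)
    residuals = residuals.subset_genes(positions.ordered(residuals.gene_ids))
    smoothed = center_cells_median(smooth_genome(residuals, positions, window=window))
    denoised, sd = denoise_dynamic(smoothed, ref_ids, k_sd=k_sd)
    cnv = rescale_unit(denoised, positions, ref_ids)
    scores = cnv_score(cnv, mode=score_mode)
    return CnvResult(residuals=residuals, smoothed=smoothed, denoised=denoised,
                     cnv=cnv, scores=scores, reference_sd=sd, reference_ids=ref_ids)


def call_clone_events(result: CnvResult, clone_labels, positions: GenePositions,
                      min_fraction: float = 0.75, min_overlap: float = 0.5,
                      min_cells: int = 5, p_stay: float = 0.99,
                      histology=None) -> dict:
    """Per-cell HMM calls followed by clone-level consensus, with boundaries
    refined against the clone-mean residual profile (which is unsmoothed and
    therefore edge-sharp).

    The HMM runs on the centered smoothed signal (pre-shrinkage): the soft
    denoise shrinkage is good for burden scores but compresses the
    state-separation the Viterbi path relies on. The denoised matrix still
    sets delta — the typical unshrunk magnitude of signal that survives
    denoising."""
    d = result.denoised
    ref_mask = np.isin(result.smoothed.cell_ids, np.asarray(result.reference_ids, dtype=object))
    mu = result.smoothed.values[ref_mask].mean(axis=0)
    centered = result.smoothed.values - mu[None, :]
    surviving = d.values != 0
    delta = float(np.median(np.abs(centered[surviving]))) if surviving.any() else 0.2
    calls = call_states_hmm(centered, d.gene_ids, positions,
                            sigma=result.reference_sd, delta=delta,
                            unit_ids=[str(c) for c in d.cell_ids], p_stay=p_stay)
    return consensus_clone_events(
        calls, clone_labels, positions, d.gene_ids,
        min_fraction=min_fraction, min_overlap=min_overlap, min_cells=min_cells,
        refine=result.residuals, histology=histology,
    )
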