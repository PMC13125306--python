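"""Synthetic multi-sample cohorts with planted clonal CNV architecture.

Every downstream stage of the pipeline is exercised against cohorts produced
here, so the generators carry full ground truth: per-cell clone and histology
labels, per-clone integer copy numbers for every gene, the planted clone tree,
and (for survival fixtures) the true hazard ratio and cutpoint.

The noise model is a pragmatic stand-in (real cohorts come with no known
generative model): counts are drawn negative binomially with a simple dosage
effect on the mean (expression multiplier = copy / 2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, GenePositions, SurvivalTable

__all__ = [
    "CnvEvent",
    "CloneSpec",
    "SimulationConfig",
    "SpatialRegion",
    "SpatialConfig",
    "GroundTruth",
    "default_config",
    "simulate_cohort",
    "simulate_spatial_sections",
    "simulate_survival_cohort",
    "simulate_marker_cohort",
    "MITO_GENES",
]

# Thirteen protein-coding mitochondrial genes; placed on a dedicated chrM so
# the QC mito filter and the CNV chrM exclusion both get exercised.
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

COPY_NEUTRAL = 2
_COPY_FLOOR_MULT = 0.05  # homozygous deletions keep ambient expression


@dataclass(frozen=True)
class CnvEvent:
    """A segmental copy-number event: ``length`` consecutive genes on one
    chromosome set to ``copy`` (0..4; 2 is a no-op)."""

    chromosome: str
    start: int  # gene index within the chromosome, 0-based
    length: int
    copy: int

    def __post_init__(self) -> None:
        if self.copy not in (0, 1, 2, 3, 4):
            raise ValueError(f"copy number must be in 0..4, got {self.copy}")
        if self.length < 1 or self.start < 0:
            raise ValueError("event must cover at least one gene at a valid start")

    @property
    def direction(self) -> str:
        if self.copy > COPY_NEUTRAL:
            return "amplification"
        if self.copy < COPY_NEUTRAL:
            return "deletion"
        return "neutral"

    @property
    def multiplier(self) -> float:
        return max(self.copy / 2.0, _COPY_FLOOR_MULT)


@dataclass(frozen=True)
class CloneSpec:
    clone_id: str
    parent_id: str | None
    events: tuple
    fraction: float
    histology: tuple = (("DCIS", 1.0),)  # label -> fraction of the clone's cells

    def histology_map(self) -> dict:
        return dict(self.histology)


@dataclass(frozen=True)
class SpatialRegion:
    region_id: str
    histology: str  # DCIS | IDC | normal
    clone_ids: tuple


@dataclass(frozen=True)
class SpatialConfig:
    n_rows: int
    n_cols: int
    regions: tuple  # of SpatialRegion, laid out in row-major blocks
    region_grid: tuple = None  # (rows, cols) of region blocks; default 1 x len(regions)
    n_spots: int = None  # defaults to the full grid


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_samples: int = 1
    cells_per_sample: int = 400
    n_reference_cells: int = 100
    genes_per_chromosome: tuple = tuple((f"chr{i}", 300) for i in range(1, 7))
    clones: tuple = ()
    nb_dispersion: float = 0.15
    library_size_lognormal: tuple = (0.0, 0.2)
    mean_counts_per_cell: float = 9000.0
    mito_fraction: float = 0.05
    include_mito: bool = True
    spatial: SpatialConfig = None

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not self.clones:
            raise ValueError("at least one clone must be specified")
        total = sum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"clone fractions must sum to 1, got {total}")
        by_id = {c.clone_id: c for c in self.clones}
        if len(by_id) != len(self.clones):
            raise ValueError("duplicate clone ids")
        for c in self.clones:
            if c.parent_id is None:
                continue
            if c.parent_id not in by_id:
                raise ValueError(f"clone {c.clone_id!r} has unknown parent {c.parent_id!r}")
            parent = by_id[c.parent_id]
            if not set(parent.events) <= set(c.events):
                raise ValueError(
                    f"clone {c.clone_id!r} violates irreversibility: its event list "
                    f"is not a superset of parent {c.parent_id!r}"
                )
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        chrom_sizes = dict(self.genes_per_chromosome)
        for c in self.clones:
            for e in c.events:
                if e.chromosome not in chrom_sizes:
                    raise ValueError(f"event on unknown chromosome {e.chromosome!r}")
                if e.start + e.length > chrom_sizes[e.chromosome]:
                    raise ValueError(f"event {e} exceeds {e.chromosome} size")


@dataclass
class GroundTruth:
    clone: pd.Series  # cell id -> clone id ("" for reference cells)
    histology: pd.Series  # cell id -> DCIS/IDC/normal
    copy_number: pd.DataFrame  # clones x genes, integer copies
    tree: dict  # clone id -> parent id (root -> None)
    clone_events: dict  # clone id -> tuple of CnvEvent
    true_hr: float = None
    true_cutpoint: float = None

    def __post_init__(self) -> None:
        parents = set(self.tree.values())
        roots = [c for c, p in self.tree.items() if p is None]
        if len(roots) != 1:
            raise ValueError("truth tree must have a single root")
        for p in parents - {None}:
            if p not in self.tree:
                raise ValueError(f"truth tree parent {p!r} is not a clone")

    def to_json_dict(self) -> dict:
        return {
            "clone": {str(k): v for k, v in self.clone.items()},
            "histology": {str(k): v for k, v in self.histology.items()},
            "tree": self.tree,
            "clone_events": {
                c: [dataclasses.asdict(e) for e in evs] for c, evs in self.clone_events.items()
            },
        }


def _make_positions(config: SimulationConfig) -> GenePositions:
    rows = []
    for chrom, n in config.genes_per_chromosome:
        num = "".join(ch for ch in chrom if ch.isdigit()) or "1"
        for i in range(n):
            start = i * 2000 + 1
            band = f"{num}q{i // 25 + 1}"
            rows.append((f"{chrom}_g{i:04d}", chrom, start, start + 999, band))
    if config.include_mito:
        for i, g in enumerate(MITO_GENES):
            start = i * 1200 + 1
            rows.append((g, "chrM", start, start + 999, "M"))
    return GenePositions(
        pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end", "cytoband"])
    )


def _clone_copy_numbers(config: SimulationConfig, positions: GenePositions) -> pd.DataFrame:
    genes = positions.genes
    gene_idx = {}
    for chrom, n in config.genes_per_chromosome:
        for i in range(n):
            gene_idx[(chrom, i)] = f"{chrom}_g{i:04d}"
    cn = pd.DataFrame(
        COPY_NEUTRAL, index=[c.clone_id for c in config.clones], columns=genes, dtype=int
    )
    for c in config.clones:
        for e in c.events:
            cols = [gene_idx[(e.chromosome, i)] for i in range(e.start, e.start + e.length)]
            cn.loc[c.clone_id, cols] = e.copy
    return cn


def _baseline_means(rng: np.random.Generator, positions: GenePositions,
                    config: SimulationConfig) -> np.ndarray:
    genes = positions.genes
    chrom = positions.table["chromosome"].to_numpy()
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    auto = chrom != "chrM"
    base[auto] *= (config.mean_counts_per_cell * (1 - config.mito_fraction)) / base[auto].sum()
    if config.include_mito and (~auto).any():
        base[~auto] = config.mean_counts_per_cell * config.mito_fraction / (~auto).sum()
    return base


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + phi * mu^2  (size r = 1/phi)
    r = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def _allocate(n: int, fractions: np.ndarray) -> np.ndarray:
    """Deterministic proportional allocation of n items (largest remainder)."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    counts[order[:remainder]] += 1
    return counts


def simulate_cohort(config: SimulationConfig):
    """Generate a multi-sample cohort; returns ``(CountMatrix, GenePositions,
    GroundTruth)``. Reference cells are copy-neutral and flagged in metadata."""
    rng = np.random.default_rng(config.seed)
    positions = _make_positions(config)
    cn = _clone_copy_numbers(config, positions)
    baseline = _baseline_means(rng, positions, config)
    genes = positions.genes
    clone_ids = [c.clone_id for c in config.clones]
    fracs = np.array([c.fraction for c in config.clones])

    mult = np.ones((len(clone_ids) + 1, len(genes)))  # last row = reference (neutral)
    for i, cid in enumerate(clone_ids):
        copies = cn.loc[cid].to_numpy()
        mult[i] = np.maximum(copies / 2.0, _COPY_FLOOR_MULT)
        mult[i][positions.table["chromosome"].to_numpy() == "chrM"] = 1.0

    cell_rows, cell_ids, meta_rows = [], [], []
    truth_clone, truth_hist = {}, {}
    for s in range(config.n_samples):
        sample = f"S{s + 1}"
        per_clone = _allocate(config.cells_per_sample, fracs)
        for ci, spec in enumerate(config.clones):
            hist_labels = list(spec.histology_map())
            hist_counts = _allocate(per_clone[ci], np.array(list(spec.histology_map().values())))
            labels = np.repeat(hist_labels, hist_counts)
            for j in range(per_clone[ci]):
                cid = f"{sample}_{spec.clone_id}_c{j:04d}"
                cell_ids.append(cid)
                cell_rows.append(ci)
                meta_rows.append((sample, labels[j], False))
                truth_clone[cid] = spec.clone_id
                truth_hist[cid] = labels[j]
        for j in range(config.n_reference_cells):
            cid = f"{sample}_ref_c{j:04d}"
            cell_ids.append(cid)
            cell_rows.append(len(clone_ids))
            meta_rows.append((sample, "normal", True))
            truth_clone[cid] = ""
            truth_hist[cid] = "normal"

    lib = rng.lognormal(*config.library_size_lognormal, size=len(cell_ids))
    mean = baseline[None, :] * mult[np.array(cell_rows)] * lib[:, None]
    counts = _sample_counts(rng, mean, config.nb_dispersion)

    meta = pd.DataFrame(meta_rows, columns=["sample", "histology", "is_reference"],
                        index=pd.Index(cell_ids))
    matrix = CountMatrix(counts, np.array(cell_ids, dtype=object), genes, meta)
    truth = GroundTruth(
        clone=pd.Series(truth_clone),
        histology=pd.Series(truth_hist),
        copy_number=cn,
        tree={c.clone_id: c.parent_id for c in config.clones},
        clone_events={c.clone_id: tuple(c.events) for c in config.clones},
    )
    return matrix, positions, truth


def simulate_spatial_sections(config: SimulationConfig):
    """Generate one spatial section: spots on a grid, regions as row-major
    blocks, each clone spatially contiguous (a strip of rows inside its
    region). Returns ``(CountMatrix, GenePositions, GroundTruth)``."""
    if config.spatial is None:
        raise ValueError("config.spatial is required for spatial simulation")
    sp = config.spatial
    n_spots = sp.n_spots if sp.n_spots is not None else sp.n_rows * sp.n_cols
    if n_spots > sp.n_rows * sp.n_cols:
        raise ValueError(
            f"grid {sp.n_rows}x{sp.n_cols} smaller than requested {n_spots} spots"
        )
    grid = sp.region_grid or (1, len(sp.regions))
    if grid[0] * grid[1] != len(sp.regions):
        raise ValueError("region_grid does not match number of regions")
    by_id = {c.clone_id: c for c in config.clones}
    for r in sp.regions:
        for cid in r.clone_ids:
            if cid not in by_id:
                raise ValueError(f"region {r.region_id!r} references unknown clone {cid!r}")

    rng = np.random.default_rng(config.seed)
    positions = _make_positions(config)
    cn = _clone_copy_numbers(config, positions)
    baseline = _baseline_means(rng, positions, config)
    genes = positions.genes
    chrom_arr = positions.table["chromosome"].to_numpy()

    block_h = sp.n_rows // grid[0]
    block_w = sp.n_cols // grid[1]
    spot_clone = {}
    spot_region = {}
    coords = []
    ids = []
    k = 0
    for y in range(sp.n_rows):
        for x in range(sp.n_cols):
            if k >= n_spots:
                break
            ri = min(y // block_h, grid[0] - 1) * grid[1] + min(x // block_w, grid[1] - 1)
            region = sp.regions[ri]
            # contiguous strips: split the region's rows among its clones
            local_y = y - min(y // block_h, grid[0] - 1) * block_h
            strip = min(local_y * len(region.clone_ids) // max(block_h, 1),
                        len(region.clone_ids) - 1)
            clone = region.clone_ids[strip]
            sid = f"spot_{y:03d}_{x:03d}"
            ids.append(sid)
            coords.append((x, y))
            spot_clone[sid] = clone
            spot_region[sid] = region
            k += 1

    clone_ids = [c.clone_id for c in config.clones]
    mult = np.ones((len(clone_ids), len(genes)))
    for i, cid in enumerate(clone_ids):
        mult[i] = np.maximum(cn.loc[cid].to_numpy() / 2.0, _COPY_FLOOR_MULT)
        mult[i][chrom_arr == "chrM"] = 1.0
    row_idx = np.array([clone_ids.index(spot_clone[s]) for s in ids])
    lib = rng.lognormal(*config.library_size_lognormal, size=len(ids))
    counts = _sample_counts(rng, baseline[None, :] * mult[row_idx] * lib[:, None],
                            config.nb_dispersion)

    meta = pd.DataFrame(
        {
            "sample": "ST1",
            "histology": [spot_region[s].histology for s in ids],
            "is_reference": [spot_region[s].histology == "normal" for s in ids],
            "region": [spot_region[s].region_id for s in ids],
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
        },
        index=pd.Index(ids),
    )
    matrix = CountMatrix(counts, np.array(ids, dtype=object), genes, meta)
    truth = GroundTruth(
        clone=pd.Series({s: spot_clone[s] for s in ids}),
        histology=pd.Series({s: spot_region[s].histology for s in ids}),
        copy_number=cn,
        tree={c.clone_id: c.parent_id for c in config.clones},
        clone_events={c.clone_id: tuple(c.events) for c in config.clones},
    )
    return matrix, positions, truth


def simulate_survival_cohort(n: int, true_hr: float, true_cutpoint: float, seed: int,
                             baseline_hazard: float = 0.1,
                             censor_upper: float = None) -> SurvivalTable:
    """Exponential event times; subjects with expression > ``true_cutpoint``
    have their hazard multiplied by ``true_hr``. Censoring is independent
    uniform on (0, censor_upper)."""
    if n < 20:
        raise ValueError("n must be >= 20 (underpowered fixture)")
    if true_hr <= 0:
        raise ValueError("true_hr must be positive")
    rng = np.random.default_rng(seed)
    expression = rng.normal(0.0, 1.0, size=n)
    hazard = np.where(expression > true_cutpoint, baseline_hazard * true_hr, baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if censor_upper is None:
        censor_upper = 3.0 / baseline_hazard
    if censor_upper <= 0:
        raise ValueError("censor_upper must be positive")
    t_cens = rng.uniform(0.0, censor_upper, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        raise ValueError("simulated cohort has no events (censoring rate 100%)")
    return SurvivalTable(time=time, event=event, expression=expression)


# ---------------------------------------------------------------------------
# Marker-expression cohort for annotation / module-score / clustering tests.

_TYPE_MARKERS = {
    "epithelial": ("EPCAM", "KRT8", "KRT18"),
    "fibroblast": ("PDGFRA", "COL3A1", "POSTN", "COL1A1", "COL5A2"),
    "endothelial": ("PECAM1", "CLDN5", "ITGA6", "ENG", "FLT1", "CD93", "PLVAP"),
    "myeloid": ("CD68", "APOE", "APOC1", "C1QA", "C1QC"),
    "tcell": ("CD3D", "CCL5", "TRBC2", "CD2"),
    "bcell": ("BANK1", "CD79A", "IGHM", "MS4A1"),
}


def simulate_marker_cohort(seed: int, cell_types=("epithelial", "tcell", "fibroblast"),
                           n_per_type: int = 100, n_filler_genes: int = 250,
                           marker_boost: float = 8.0,
                           nb_dispersion: float = 0.3) -> CountMatrix:
    """Cohort of discrete cell types with their canonical markers boosted.

    Truth is in ``meta['cell_type']``. Used to exercise clustering, marker
    annotation and module scoring, independent of the CNV machinery.
    """
    rng = np.random.default_rng(seed)
    marker_genes = [g for t in cell_types for g in _TYPE_MARKERS[t]]
    genes = np.array(marker_genes + [f"FILLER{i:04d}" for i in range(n_filler_genes)],
                     dtype=object)
    base = rng.lognormal(0.0, 1.0, size=len(genes))
    base *= 2000.0 / base.sum()
    ids, rows, types = [], [], []
    for t in cell_types:
        boost = np.ones(len(genes))
        for g in _TYPE_MARKERS[t]:
            boost[list(genes).index(g)] = marker_boost
        for j in range(n_per_type):
            ids.append(f"{t}_c{j:04d}")
            rows.append(boost)
            types.append(t)
    mean = np.array(rows) * base[None, :]
    counts = _sample_counts(rng, mean, nb_dispersion)
    meta = pd.DataFrame({"cell_type": types, "sample": "S1", "histology": "normal",
                         "is_reference": False}, index=pd.Index(ids))
    return CountMatrix(counts, np.array(ids, dtype=object), genes, meta)


def default_config(seed: int, n_samples: int = 3, cells_per_clone: int = 200,
                   n_reference_cells: int = 100) -> SimulationConfig:
    """The default 4-clone branching cohort: 6 autosomes x 300 genes, nested
    events A ⊂ B ⊂ C with D branching off A."""
    e1 = CnvEvent("chr1", 60, 70, 4)
    e2 = CnvEvent("chr2", 100, 80, 1)
    e3 = CnvEvent("chr3", 40, 70, 3)
    e4 = CnvEvent("chr4", 140, 80, 4)
    e5 = CnvEvent("chr5", 30, 50, 0)
    e6 = CnvEvent("chr6", 120, 70, 3)
    clones = (
        CloneSpec("A", None, (e1, e2), 0.25, (("DCIS", 1.0),)),
        CloneSpec("B", "A", (e1, e2, e3), 0.25, (("DCIS", 0.5), ("IDC", 0.5))),
        CloneSpec("C", "B", (e1, e2, e3, e4, e5), 0.25, (("IDC", 1.0),)),
        CloneSpec("D", "A", (e1, e2, e6), 0.25, (("IDC", 1.0),)),
    )
    return SimulationConfig(
        seed=seed,
        n_samples=n_samples,
        cells_per_sample=4 * cells_per_clone,
        n_reference_cells=n_reference_cells,
        clones=clones,
    )
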