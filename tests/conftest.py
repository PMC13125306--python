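import numpy as np
import pytest

from clonecnv import cnv, qc, sim


@pytest.fixture(scope="session")
def default_cohort():
    """The default 4-clone branching cohort at full scale (3 samples,
    200 cells/clone, 100 reference cells/sample, 6 x 300 genes + chrM)."""
    config = sim.default_config(seed=11)
    return sim.simulate_cohort(config)


@pytest.fixture(scope="session")
def default_result(default_cohort):
    matrix, positions, _ = default_cohort
    expr = qc.normalize_log1p(matrix)
    ref_ids = [c for c in matrix.cell_ids if matrix.meta.loc[c, "is_reference"]]
    return cnv.infer_cnv(expr, positions, ref_ids, window=101)


@pytest.fixture(scope="session")
def default_events(default_cohort, default_result):
    _, positions, truth = default_cohort
    clone_labels = truth.clone[truth.clone != ""]
    return cnv.call_clone_events(default_result, clone_labels, positions,
                                 histology=truth.histology)


@pytest.fixture(scope="session")
def small_cohort():
    config = sim.default_config(seed=7, n_samples=1, cells_per_clone=60,
                                n_reference_cells=40)
    return sim.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    matrix, positions, _ = small_cohort
    expr = qc.normalize_log1p(matrix)
    ref_ids = [c for c in matrix.cell_ids if matrix.meta.loc[c, "is_reference"]]
    return cnv.infer_cnv(expr, positions, ref_ids, window=101)


@pytest.fixture(scope="session")
def marker_cohort():
    return sim.simulate_marker_cohort(seed=3)


def planted_event_tuples(truth):
    """Planted events as (chromosome, start_idx, end_idx, direction) keyed by clone."""
    out = {}
    for clone, events in truth.clone_events.items():
        out[clone] = {
            (ev.chromosome, ev.direction): (ev.start, ev.start + ev.length - 1)
            for ev in events if ev.direction != "neutral"
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
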