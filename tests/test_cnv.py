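import itertools

import numpy as np
import pandas as pd
import pytest

from clonecnv import cnv, qc, sim
from clonecnv.data import CnvMatrix, CnvRegionCall, ExpressionMatrix, GenePositions

from conftest import planted_event_tuples


def _positions(chrom_sizes):
    rows = []
    for chrom, n in chrom_sizes:
        for i in range(n):
            rows.append((f"{chrom}_g{i:04d}", chrom, i * 100 + 1, i * 100 + 50, ""))
    return GenePositions(pd.DataFrame(rows, columns=["gene", "chromosome",
                                                     "start", "end", "cytoband"]))


def _expr(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    cells = [f"c{i}" for i in range(values.shape[0])]
    genes = gene_ids if gene_ids is not None else [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, np.array(cells, dtype=object),
                            np.array(list(genes), dtype=object))


class TestCenterOnReference:
    def test_reference_only_centers_to_zero(self, rng):
        values = rng.normal(2.0, 0.5, size=(30, 20))
        e = _expr(values)
        out = cnv.center_on_reference(e, list(e.cell_ids), cutoff=0.0)
        assert np.allclose(out.values.mean(axis=0), 0.0, atol=1e-12)

    def test_low_expression_gene_dropped(self):
        values = np.full((25, 3), 1.0)
        values[:, 1] = 0.05  # below cutoff 0.1
        e = _expr(values)
        out = cnv.center_on_reference(e, list(e.cell_ids), cutoff=0.1)
        assert list(out.gene_ids) == ["g0", "g2"]

    def test_empty_reference_error(self):
        e = _expr(np.ones((5, 4)))
        with pytest.raises(ValueError, match="empty"):
            cnv.center_on_reference(e, [])

    def test_all_genes_below_cutoff_error(self):
        e = _expr(np.full((25, 4), 0.01))
        with pytest.raises(ValueError, match="cutoff"):
            cnv.center_on_reference(e, list(e.cell_ids), cutoff=0.1)

    def test_planted_amplification_positive_residual(self, small_cohort, small_result):
        m, pos, truth = small_cohort
        res = small_result.residuals
        carrier = truth.clone.reindex(pd.Index(res.cell_ids)).fillna("") != ""
        block = [g for g in res.gene_ids
                 if g.startswith("chr1_") and 60 <= int(g.split("_g")[1]) <= 129]
        idx = [list(res.gene_ids).index(g) for g in block]
        is_ref = np.isin(res.cell_ids, small_result.reference_ids)
        assert res.values[np.asarray(carrier)][:, idx].mean() > 0.2
        assert abs(res.values[is_ref][:, idx].mean()) < 0.05


class TestSmoothGenome:
    def test_constant_unchanged(self):
        pos = _positions([("chr1", 10)])
        e = _expr(np.full((4, 10), 1.5), gene_ids=pos.genes)
        out = cnv.smooth_genome(e, pos, window=5)
        assert np.allclose(out.values, 1.5)

    def test_window_one_is_identity(self, rng):
        pos = _positions([("chr1", 15)])
        e = _expr(rng.normal(size=(3, 15)), gene_ids=pos.genes)
        out = cnv.smooth_genome(e, pos, window=1)
        assert np.allclose(out.values, e.values)

    def test_matches_bruteforce_window_mean(self, rng):
        pos = _positions([("chr1", 18), ("chr2", 12)])
        e = _expr(rng.normal(size=(5, 30)), gene_ids=pos.genes)
        out = cnv.smooth_genome(e, pos, window=7)
        # independent brute force, per chromosome, shrinking at the edges
        for ci, (chrom, size, off) in enumerate([("chr1", 18, 0), ("chr2", 12, 18)]):
            for i in range(size):
                lo, hi = max(0, i - 3), min(size - 1, i + 3)
                expected = e.values[:, off + lo:off + hi + 1].mean(axis=1)
                assert np.allclose(out.values[:, off + i], expected)

    def test_never_crosses_chromosomes(self):
        pos = _positions([("chr1", 6), ("chr2", 6)])
        values = np.zeros((1, 12))
        values[0, :6] = 10.0  # chr1 high, chr2 zero
        e = _expr(values, gene_ids=pos.genes)
        out = cnv.smooth_genome(e, pos, window=5)
        assert np.allclose(out.values[0, 6:], 0.0)

    def test_window_bigger_than_chromosome_warns(self, rng):
        pos = _positions([("chr1", 4)])
        e = _expr(rng.normal(size=(2, 4)), gene_ids=pos.genes)
        with pytest.warns(UserWarning, match="capped"):
            cnv.smooth_genome(e, pos, window=9)

    def test_even_window_rejected(self, rng):
        pos = _positions([("chr1", 8)])
        e = _expr(rng.normal(size=(2, 8)), gene_ids=pos.genes)
        with pytest.raises(ValueError, match="odd"):
            cnv.smooth_genome(e, pos, window=4)


class TestDenoiseDynamic:
    @staticmethod
    def _ref_matrix(rng, n_ref=50, n_genes=8):
        return _expr(rng.normal(0.0, 1.0, size=(n_ref, n_genes)))

    def test_all_inside_band_suppressed(self, rng):
        e = self._ref_matrix(rng)
        out, _ = cnv.denoise_dynamic(e, list(e.cell_ids), k_sd=50.0)
        assert np.allclose(out.values, 0.0)

    def test_closed_band_boundary(self, rng):
        e = self._ref_matrix(rng, n_ref=40, n_genes=5)
        ref = e.values
        mu = ref.mean(axis=0)
        sd_gene = (ref - mu).std(axis=0, ddof=1)
        probe = np.vstack([ref, mu + 1.5 * sd_gene, mu + 1.5 * sd_gene + 0.01])
        probe_e = _expr(probe)
        for mode in ("hard", "soft"):
            out, _ = cnv.denoise_dynamic(probe_e, [f"c{i}" for i in range(40)],
                                         k_sd=1.5, mode=mode)
            assert np.allclose(out.values[40], 0.0)  # exactly at the boundary
            assert (out.values[41] > 0).all()  # just above: retained

    def test_hard_mode_passes_through(self, rng):
        e = self._ref_matrix(rng, n_ref=40, n_genes=5)
        mu = e.values.mean(axis=0)
        probe = np.vstack([e.values, mu + 10.0])
        out, _ = cnv.denoise_dynamic(_expr(probe), [f"c{i}" for i in range(40)],
                                     k_sd=1.5, mode="hard")
        assert np.allclose(out.values[40], 10.0)

    def test_zero_variance_error(self):
        e = _expr(np.ones((30, 5)))
        with pytest.raises(ValueError, match="variance"):
            cnv.denoise_dynamic(e, list(e.cell_ids))

    def test_monotone_in_k_sd(self, rng):
        e = self._ref_matrix(rng, n_ref=60, n_genes=20)
        ref_ids = list(e.cell_ids)
        prev = None
        for k in (0.5, 1.0, 1.5, 2.0, 3.0):
            for mode in ("hard", "soft"):
                out, _ = cnv.denoise_dynamic(e, ref_ids, k_sd=k, mode=mode)
                key = (mode,)
                if prev is not None and key in prev:
                    assert (np.abs(out.values) <= prev[key] + 1e-12).all()
                prev = prev or {}
                prev[key] = np.abs(out.values)

    def test_planted_amplification_survives(self, small_cohort, small_result):
        m, pos, truth = small_cohort
        den = small_result.denoised
        # the copy-4 block on chr1 (2x expression)
        block = [g for g in den.gene_ids
                 if g.startswith("chr1_") and 70 <= int(g.split("_g")[1]) <= 119]
        idx = [list(den.gene_ids).index(g) for g in block]
        carrier = (truth.clone.reindex(pd.Index(den.cell_ids)).fillna("") != "").to_numpy()
        carrier_block = den.values[carrier][:, idx]
        surviving = (carrier_block > 0).mean(axis=1)
        assert (surviving > 0.5).mean() >= 0.95


class TestRescaleAndScore:
    def test_max_abs_maps_to_one(self):
        pos = _positions([("chr1", 3)])
        e = _expr([[2.0, -1.0, 0.5]], gene_ids=pos.genes)
        out = cnv.rescale_unit(e, pos, [])
        assert out.values[0, 0] == pytest.approx(1.0)
        assert np.abs(out.values).max() == pytest.approx(1.0)

    def test_all_zero_passthrough(self):
        pos = _positions([("chr1", 3)])
        e = _expr(np.zeros((2, 3)), gene_ids=pos.genes)
        out = cnv.rescale_unit(e, pos, [])
        assert np.allclose(out.values, 0.0)

    def test_rank_order_preserved(self, rng):
        pos = _positions([("chr1", 40)])
        vals = rng.normal(size=(5, 40))
        e = _expr(vals, gene_ids=pos.genes)
        out = cnv.rescale_unit(e, pos, [])
        assert np.array_equal(np.argsort(vals, axis=None),
                              np.argsort(out.values, axis=None))

    def test_score_zero_row(self):
        pos = _positions([("chr1", 2)])
        c = CnvMatrix(np.array([[0.0, 0.0], [0.5, -0.5]]), ["a", "b"],
                      pos.genes, pos, np.array([], dtype=object))
        s = cnv.cnv_score(c)
        assert s["a"] == 0.0
        assert s["b"] == pytest.approx(0.5)

    def test_score_sum_mode(self):
        pos = _positions([("chr1", 2)])
        c = CnvMatrix(np.array([[0.5, -0.5]]), ["a"], pos.genes, pos,
                      np.array([], dtype=object))
        assert cnv.cnv_score(c, mode="sum_abs")["a"] == pytest.approx(1.0)

    def test_score_gene_permutation_invariant(self, rng):
        pos = _positions([("chr1", 10)])
        vals = rng.uniform(-1, 1, size=(4, 10))
        c = CnvMatrix(vals, [f"c{i}" for i in range(4)], pos.genes, pos,
                      np.array([], dtype=object))
        perm = rng.permutation(10)
        c_perm = CnvMatrix(vals[:, perm], [f"c{i}" for i in range(4)],
                           pos.genes[perm], pos, np.array([], dtype=object))
        assert np.allclose(cnv.cnv_score(c).to_numpy(),
                           cnv.cnv_score(c_perm).to_numpy())

    def test_tumor_scores_exceed_normal(self, default_cohort, default_result):
        from clonecnv import compare
        m, _, truth = default_cohort
        scores = default_result.scores
        is_ref = m.meta["is_reference"].reindex(scores.index).to_numpy()
        tumor = scores[~is_ref].sample(200, random_state=0).to_numpy()
        normal = scores[is_ref].sample(200, random_state=0).to_numpy()
        res = compare.wilcoxon_compare(tumor, normal)
        assert tumor.mean() > normal.mean()
        assert res.pvalue < 0.05


def brute_force_viterbi(x, means, sigma, p_stay):
    """Exhaustive maximization over all 3^n state paths."""
    n = len(x)
    k = len(means)
    paths = np.array(list(itertools.product(range(k), repeat=n)))
    em = -0.5 * ((x[None, :] - np.asarray(means)[:, None]) / sigma) ** 2 - np.log(sigma)
    lp = np.log(1.0 / k) + em[paths[:, 0], 0].astype(float)
    for t in range(1, n):
        lp = lp + em[paths[:, t], t]
        same = paths[:, t] == paths[:, t - 1]
        lp = lp + np.where(same, np.log(p_stay), np.log((1 - p_stay) / (k - 1)))
    return paths[np.argmax(lp)]


class TestHmm:
    def test_zero_signal_no_calls(self):
        pos = _positions([("chr1", 20)])
        calls = cnv.call_states_hmm(np.zeros((2, 20)), pos.genes, pos,
                                    sigma=0.1, delta=0.3)
        assert all(len(v) == 0 for v in calls.values())

    def test_viterbi_matches_bruteforce(self, rng):
        means = np.array([-0.4, 0.0, 0.4])
        for _ in range(20):
            x = rng.normal(0, 0.5, size=8)
            path = cnv._viterbi_batch(x[None, :], means, 0.25, 0.9)[0]
            expected = brute_force_viterbi(x, means, 0.25, 0.9)
            assert np.array_equal(path, expected)

    def test_sigma_must_be_positive(self):
        pos = _positions([("chr1", 5)])
        with pytest.raises(ValueError, match="sigma"):
            cnv.call_states_hmm(np.zeros((1, 5)), pos.genes, pos, sigma=0.0)

    def test_planted_amplification_called(self, rng):
        pos = _positions([("chr1", 100)])
        signal = rng.normal(0, 0.05, size=(1, 100))
        signal[0, 30:70] += 0.5
        calls = cnv.call_states_hmm(signal, pos.genes, pos, sigma=0.05, delta=0.5)
        amps = [c for c in calls["unit0"] if c.state == "amplification"]
        assert len(amps) == 1
        overlap = (min(amps[0].end_index, 69) - max(amps[0].start_index, 30) + 1) / 40
        assert overlap >= 0.9

    def test_regions_respect_chromosomes(self, rng):
        pos = _positions([("chr1", 30), ("chr2", 30)])
        signal = np.full((1, 60), 0.5)  # one long amplification everywhere
        calls = cnv.call_states_hmm(signal, pos.genes, pos, sigma=0.05, delta=0.5)
        assert len(calls["unit0"]) == 2
        assert sorted(c.chromosome for c in calls["unit0"]) == ["chr1", "chr2"]
        for c in calls["unit0"]:
            assert (c.start_index, c.end_index) == (0, 29)


def _make_call(unit, chrom, start, end, state):
    return CnvRegionCall(unit_id=unit, chromosome=chrom, start_index=start,
                         end_index=end, start_pos=start * 100 + 1,
                         end_pos=end * 100 + 50, state=state, mean_signal=0.4)


class TestConsensus:
    def test_eight_of_ten_called(self):
        pos = _positions([("chr1", 50)])
        calls = {f"c{i}": [_make_call(f"c{i}", "chr1", 10, 20, "amplification")]
                 for i in range(8)}
        calls.update({f"c{i}": [] for i in range(8, 10)})
        labels = pd.Series({f"c{i}": "K" for i in range(10)})
        out = cnv.consensus_clone_events(calls, labels, pos, pos.genes,
                                         min_fraction=0.75)
        assert out["K"].events == [("chr1", 10, 20, "amplification")]
        assert out["K"].support[("chr1", 10, 20, "amplification")] == pytest.approx(0.8)

    def test_five_of_ten_not_called(self):
        pos = _positions([("chr1", 50)])
        calls = {f"c{i}": [_make_call(f"c{i}", "chr1", 10, 20, "amplification")]
                 for i in range(5)}
        calls.update({f"c{i}": [] for i in range(5, 10)})
        labels = pd.Series({f"c{i}": "K" for i in range(10)})
        out = cnv.consensus_clone_events(calls, labels, pos, pos.genes)
        assert out["K"].events == []

    def test_small_clone_skipped_with_warning(self):
        pos = _positions([("chr1", 50)])
        calls = {f"c{i}": [] for i in range(3)}
        labels = pd.Series({f"c{i}": "tiny" for i in range(3)})
        with pytest.warns(UserWarning, match="tiny"):
            out = cnv.consensus_clone_events(calls, labels, pos, pos.genes)
        assert "tiny" not in out

    def test_planted_events_recovered(self, default_cohort, default_events):
        _, _, truth = default_cohort
        planted = planted_event_tuples(truth)
        for clone, expected in planted.items():
            called = {(c, d): (s, e) for c, s, e, d in default_events[clone].events}
            assert set(called) == set(expected)
            for key, (ts, te) in expected.items():
                cs, ce = called[key]
                assert abs(cs - ts) <= 2 and abs(ce - te) <= 2


class TestPipelineInvariants:
    def test_cell_permutation_equivariance(self, small_cohort):
        m, pos, _ = small_cohort
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n_cells)
        m_perm = m.subset_cells(m.cell_ids[perm])
        ref = [c for c in m.cell_ids if m.meta.loc[c, "is_reference"]]
        r1 = cnv.infer_cnv(qc.normalize_log1p(m), pos, ref, window=41)
        r2 = cnv.infer_cnv(qc.normalize_log1p(m_perm), pos, ref, window=41)
        s1 = r1.scores.reindex(r2.scores.index)
        assert np.allclose(s1.to_numpy(), r2.scores.to_numpy())

    def test_reference_honesty(self, default_cohort, default_result):
        m, _, _ = default_cohort
        scores = default_result.scores
        is_ref = m.meta["is_reference"].reindex(scores.index).to_numpy()
        assert scores[is_ref].mean() < 0.1 * scores[~is_ref].mean()
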