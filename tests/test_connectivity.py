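import math

import numpy as np
import pandas as pd
import pytest

from connsim import connectivity as cn
from connsim import synthetic_data as sd


def make_scan(series, fd=None, tr=0.8, roi_ids=None):
    series = np.asarray(series, dtype=float)
    if fd is None:
        fd = np.zeros(series.shape[0])
    return cn.SubjectScan(series, fd, tr=tr, roi_ids=roi_ids)


class TestParcellation:
    def test_default_counts(self):
        par = cn.default_parcellation()
        assert par.n_rois == 352
        assert len(par.rois_in(cn.SUBCORTICAL_NETWORK)) == 19
        assert len(par.association_networks) == 8
        pool = par.rois_in_networks(
            list(par.association_networks) + [cn.SUBCORTICAL_NETWORK]
        )
        assert len(pool) == 196

    def test_duplicate_roi_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cn.Parcellation(["a", "a"], ["n1", "n1"])

    def test_tsv_round_trip(self, tmp_path):
        par = cn.default_parcellation()
        par.to_tsv(tmp_path / "p.tsv")
        back = cn.Parcellation.from_tsv(tmp_path / "p.tsv")
        assert back == par


class TestEnumerateEdges:
    @pytest.mark.parametrize("n", [2, 3, 10, 50, 197, 400])
    def test_count_identity(self, n):
        ids = [f"r{i}" for i in range(n)]
        assert len(cn.enumerate_edges(ids)) == n * (n - 1) // 2

    def test_canonical_order(self):
        assert cn.enumerate_edges(["a", "b", "c"]) == (
            ("a", "b"),
            ("a", "c"),
            ("b", "c"),
        )


class TestCensorAndConcatenate:
    def test_no_censoring_concatenates(self):
        runs = [make_scan(np.ones((100, 3)) * i) for i in (1, 2)]
        out = cn.censor_and_concatenate(runs, 0.10)
        assert out.n_frames == 200

    def test_strict_threshold(self):
        scan = make_scan(np.arange(9).reshape(3, 3), fd=[0.05, 0.15, 0.09])
        out = cn.censor_and_concatenate([scan], 0.10)
        assert out.n_frames == 2
        np.testing.assert_array_equal(out.series[:, 0], [0, 6])

    def test_boundary_frame_retained(self):
        scan = make_scan(np.zeros((2, 2)), fd=[0.10, 0.11])
        out = cn.censor_and_concatenate([scan], 0.10)
        assert out.n_frames == 1

    def test_zero_survivors_raises(self):
        scan = make_scan(np.zeros((3, 2)), fd=[0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="no frames"):
            cn.censor_and_concatenate([scan], 0.10)

    def test_synthetic_retained_fraction(self):
        rng = np.random.default_rng(0)
        scan = sd.sample_timeseries(np.eye(3), 2000, 0.3, rng)
        out = cn.censor_and_concatenate([scan], 0.10)
        assert out.n_frames / 2000 == pytest.approx(0.7, abs=0.02)

    def test_roi_mismatch_raises(self):
        a = make_scan(np.zeros((5, 3)))
        b = make_scan(np.zeros((5, 4)))
        with pytest.raises(ValueError, match="ROI ordering"):
            cn.censor_and_concatenate([a, b], 0.10)


class TestSubjectIncluded:
    def test_boundary_inclusive(self):
        scan = make_scan(np.zeros((750, 2)), tr=0.8)
        assert cn.subject_included(scan)  # 750 * 0.8 = 600 s

    def test_one_frame_short(self):
        scan = make_scan(np.zeros((749, 2)), tr=0.8)
        assert not cn.subject_included(scan)

    def test_synthetic_half_censored(self):
        rng = np.random.default_rng(1)
        scan = sd.sample_timeseries(np.eye(3), 1600, 0.5, rng, tr=0.8)
        retained = int(np.sum(scan.fd <= 0.10))
        assert cn.subject_included(scan) == (retained * 0.8 >= 600)
        assert cn.subject_included(scan)  # ~800 frames -> ~640 s


class TestComputeTsnr:
    def test_hand_example(self):
        scan = make_scan(np.array([[1.0], [2.0], [3.0]]))
        assert cn.compute_tsnr(scan).iloc[0] == pytest.approx(2.0)

    def test_zero_mean_near_zero(self):
        rng = np.random.default_rng(2)
        scan = make_scan(rng.standard_normal((5000, 1)))
        assert abs(cn.compute_tsnr(scan).iloc[0]) < 0.05

    def test_mean100_sd1(self):
        rng = np.random.default_rng(3)
        scan = make_scan(100.0 + rng.standard_normal((10000, 1)))
        assert cn.compute_tsnr(scan).iloc[0] == pytest.approx(100.0, rel=0.05)

    def test_constant_roi_raises(self):
        scan = make_scan(
            np.column_stack([np.ones(5), np.arange(5.0)]), roi_ids=("a", "b")
        )
        with pytest.raises(ValueError, match="a"):
            cn.compute_tsnr(scan)


def _tsnr_frame(values, roi_ids, n_subjects=3):
    return pd.DataFrame(
        np.tile(np.asarray(values, dtype=float), (n_subjects, 1)),
        columns=list(roi_ids),
    )


class TestSelectRois:
    @pytest.fixture
    def parc(self):
        ids = [f"r{i}" for i in range(12)]
        return cn.Parcellation(ids, ["netA"] * 6 + ["netB"] * 6,
                               {"netA": True, "netB": True})

    def test_equal_tsnr_keeps_all(self, parc):
        table = _tsnr_frame(np.full(12, 50.0), parc.roi_ids)
        assert cn.select_rois(table, parc) == parc.roi_ids

    def test_planted_outlier_dropped(self, parc):
        rng = np.random.default_rng(4)
        vals = 100.0 + rng.normal(0, 1.0, 12)
        # push one ROI to ~mean - 3 SD of the resulting distribution
        for _ in range(50):
            mean, sdv = vals.mean(), vals.std(ddof=1)
            vals[3] = mean - 3.0 * sdv
        table = _tsnr_frame(vals, parc.roi_ids)
        kept = cn.select_rois(table, parc, sd_k=2)
        assert "r3" not in kept
        assert len(kept) == 11

    def test_sd_k_monotone(self, parc):
        rng = np.random.default_rng(5)
        vals = 100.0 + rng.normal(0, 5.0, 12)
        table = _tsnr_frame(vals, parc.roi_ids)
        kept1 = set(cn.select_rois(table, parc, sd_k=1))
        kept2 = set(cn.select_rois(table, parc, sd_k=2))
        assert kept1 <= kept2

    def test_restricts_to_association_networks(self):
        ids = [f"r{i}" for i in range(8)]
        parc = cn.Parcellation(
            ids, ["assoc"] * 4 + ["motor"] * 4, {"assoc": True, "motor": False}
        )
        table = _tsnr_frame(np.full(8, 10.0), ids)
        kept = cn.select_rois(table, parc)
        assert kept == tuple(ids[:4])


class TestCorrelationEdges:
    def test_duplicated_roi_clamped_finite(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        scan = make_scan(np.column_stack([x, x]), roi_ids=("a", "b"))
        ev = cn.correlation_edges(scan)
        assert np.isfinite(ev.values).all()
        assert ev.values[0] > 10  # atanh near 1

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(7)
        scan = make_scan(rng.standard_normal((10000, 2)))
        ev = cn.correlation_edges(scan)
        assert abs(ev.values[0]) < 3.0 / np.sqrt(10000 - 3)

    def test_edge_count_352(self):
        rng = np.random.default_rng(8)
        scan = make_scan(
            rng.standard_normal((400, 352)),
            roi_ids=tuple(f"r{i}" for i in range(352)),
        )
        ev = cn.correlation_edges(scan)
        assert ev.n_edges == 61776

    def test_constant_roi_named(self):
        scan = make_scan(
            np.column_stack([np.ones(10), np.arange(10.0)]), roi_ids=("c0", "c1")
        )
        with pytest.raises(ValueError, match="c0"):
            cn.correlation_edges(scan)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((100, 5))
        a = cn.correlation_edges(make_scan(data))
        b = cn.correlation_edges(make_scan(data))
        np.testing.assert_array_equal(a.values, b.values)

    def test_roi_subset_ordering(self):
        rng = np.random.default_rng(10)
        scan = make_scan(
            rng.standard_normal((100, 4)), roi_ids=("a", "b", "c", "d")
        )
        ev = cn.correlation_edges(scan, rois=("b", "d"))
        assert ev.edges == (("b", "d"),)


def _edge_vectors_from_values(values_rows, n_rois):
    ids = [f"r{i}" for i in range(n_rois)]
    edges = cn.enumerate_edges(ids)
    return [cn.EdgeVector(edges, row) for row in values_rows]


class TestSelectHighVarianceEdges:
    def test_printed_counts(self):
        rng = np.random.default_rng(11)
        vecs = _edge_vectors_from_values(rng.standard_normal((3, 17205)), 186)
        assert len(vecs[0].edges) == 17205
        assert cn.select_high_variance_edges(vecs, 0.10).n_selected == 1721
        assert cn.select_high_variance_edges(vecs, 0.01).n_selected == 173

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.10, 0.25, 0.50, 1.0])
    def test_ceiling_rule(self, p):
        rng = np.random.default_rng(12)
        vecs = _edge_vectors_from_values(rng.standard_normal((3, 45)), 10)
        fs = cn.select_high_variance_edges(vecs, p)
        assert fs.n_selected == math.ceil(p * 45)

    def test_ties_break_by_canonical_order(self):
        rows = np.zeros((2, 6))
        rows[1, :] = 1.0  # every edge has identical variance
        vecs = _edge_vectors_from_values(rows, 4)
        fs = cn.select_high_variance_edges(vecs, 0.5)
        assert fs.edges == vecs[0].edges[:3]

    def test_selects_largest_variance(self):
        rows = np.array([[0.0, 0.0, 0.0], [0.1, 5.0, 0.2]])
        vecs = _edge_vectors_from_values(rows, 3)
        fs = cn.select_high_variance_edges(vecs, 1 / 3)
        assert fs.edges == (vecs[0].edges[1],)

    def test_invalid_fraction(self):
        rng = np.random.default_rng(13)
        vecs = _edge_vectors_from_values(rng.standard_normal((2, 3)), 3)
        for p in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                cn.select_high_variance_edges(vecs, p)

    def test_restrict_applies_training_selection(self):
        rng = np.random.default_rng(14)
        vecs = _edge_vectors_from_values(rng.standard_normal((4, 10)), 5)
        fs = cn.select_high_variance_edges(vecs[:2], 0.3)
        out = cn.restrict_to_features(vecs[3], fs)
        np.testing.assert_array_equal(out.values, vecs[3].values[fs.indices])


class TestNetworkMatrix:
    @staticmethod
    def _parc(sizes, prefix="net"):
        ids, nets = [], []
        for b, s in enumerate(sizes):
            for i in range(s):
                ids.append(f"{prefix}{b}_{i}")
                nets.append(f"{prefix}{b}")
        return cn.Parcellation(ids, nets, {f"{prefix}{b}": True for b in range(len(sizes))})

    def test_eight_networks_36_cells(self):
        parc = self._parc([2] * 8)
        rng = np.random.default_rng(15)
        ev = cn.EdgeVector(
            cn.enumerate_edges(parc.roi_ids), rng.standard_normal(16 * 15 // 2)
        )
        nm = cn.network_matrix(ev, parc)
        assert nm.n_distinct == 36
        assert nm.values_vector().shape == (36,)

    def test_constant_edges_constant_cells(self):
        parc = self._parc([3, 3])
        ev = cn.EdgeVector(
            cn.enumerate_edges(parc.roi_ids), np.full(15, 0.42)
        )
        nm = cn.network_matrix(ev, parc)
        np.testing.assert_allclose(nm.cells, 0.42)

    def test_hand_computed_cells(self):
        # 2 networks x 2 ROIs; 6 edges with hand-set z values
        parc = self._parc([2, 2])
        edges = cn.enumerate_edges(parc.roi_ids)
        values = {
            ("net0_0", "net0_1"): 0.8,   # within net0
            ("net1_0", "net1_1"): 0.4,   # within net1
            ("net0_0", "net1_0"): 0.1,
            ("net0_0", "net1_1"): 0.2,
            ("net0_1", "net1_0"): 0.3,
            ("net0_1", "net1_1"): 0.4,
        }
        ev = cn.EdgeVector(edges, np.array([values[e] for e in edges]))
        nm = cn.network_matrix(ev, parc)
        assert nm.cells[0, 0] == pytest.approx(0.8)
        assert nm.cells[1, 1] == pytest.approx(0.4)
        assert nm.cells[0, 1] == pytest.approx((0.1 + 0.2 + 0.3 + 0.4) / 4)

    def test_small_network_raises(self):
        parc = self._parc([1, 3])
        ev = cn.EdgeVector(
            cn.enumerate_edges(parc.roi_ids), np.zeros(6)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            cn.network_matrix(ev, parc)


class TestGroupAverage:
    def test_single_subject_identity(self):
        rng = np.random.default_rng(16)
        vecs = _edge_vectors_from_values(rng.standard_normal((1, 6)), 4)
        gm = cn.group_average(vecs)
        np.testing.assert_array_equal(gm.referent.values, vecs[0].values)
        assert gm.n_train == 1

    def test_symmetry_cancels(self):
        rng = np.random.default_rng(17)
        vals = rng.standard_normal(10)
        vecs = _edge_vectors_from_values([vals, -vals], 5)
        gm = cn.group_average(vecs)
        np.testing.assert_allclose(gm.referent.values, 0.0, atol=1e-15)

    def test_enumeration_mismatch(self):
        a = _edge_vectors_from_values(np.zeros((1, 3)), 3)[0]
        ids = ["x0", "x1", "x2"]
        b = cn.EdgeVector(cn.enumerate_edges(ids), np.zeros(3))
        with pytest.raises(ValueError):
            cn.group_average([a, b])

    def test_means_commute_with_network_aggregation(self, small_cohort,
                                                    small_cohort_network_items):
        edge_vectors, network_mats = small_cohort_network_items
        cohort = small_cohort
        ids = cohort.subject_ids
        gm_edges = cn.group_average([edge_vectors[s] for s in ids])
        via_edges = cn.network_matrix(gm_edges.referent, cohort.parcellation)
        via_mats = cn.group_average([network_mats[s] for s in ids]).referent
        np.testing.assert_allclose(via_edges.cells, via_mats.cells, atol=1e-12)

    def test_fig1_group_within_jitter_envelope(self):
        rng = np.random.default_rng(18)
        mats = sd.make_fig1_fixture("homogeneous", 9, 12, rng, project=False)
        group = np.mean(mats, axis=0)
        iu = np.triu_indices(12, 1)
        for m in mats:
            assert np.max(np.abs(m[iu] - group[iu])) <= 0.30
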