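import numpy as np
import pytest

import sxmerge as sx
from sxmerge.error_model import ErrorModel
from sxmerge.scaling import observation_table

from conftest import make_miniset


def cell_miniset(cell_params, ds_id, sg_number=20):
    return make_miniset(
        [[2, 2, 0], [4, 0, 0]], [100.0, 50.0],
        ds_id=ds_id, cell=sx.UnitCell(*cell_params), sg_number=sg_number,
    )


class TestIndexingConsistency:
    def test_six_percent_deviation_rejected(self):
        ref = cell_miniset((100, 50, 60, 90, 90, 90), "ref")
        bad = cell_miniset((106, 50, 60, 90, 90, 90), "bad")
        rep = sx.check_indexing_consistency([ref, bad])
        assert rep.rejected == {"bad": "bad_cell"}

    def test_five_percent_boundary_accepted(self):
        ref = cell_miniset((100, 50, 60, 90, 90, 90), "ref")
        edge = cell_miniset((105, 50, 60, 90, 90, 90), "edge")
        rep = sx.check_indexing_consistency([ref, edge])
        assert "edge" in rep.accepted

    def test_different_spacegroup_rejected(self):
        ref = cell_miniset((100, 50, 60, 90, 90, 90), "ref", sg_number=20)
        other = cell_miniset((100, 50, 60, 90, 90, 90), "other", sg_number=19)
        rep = sx.check_indexing_consistency([ref, other])
        assert rep.rejected == {"other": "bad_spacegroup"}

    def test_reference_accepts_itself(self):
        ref = cell_miniset((100, 50, 60, 90, 90, 90), "ref")
        rep = sx.check_indexing_consistency([ref])
        assert rep.accepted == ["ref"]


class TestReferenceChoice:
    def _wilson_ms(self, b, ds_id, seed=0):
        rng = np.random.default_rng(seed)
        cell = sx.UnitCell(40, 50, 60)
        sg = sx.get_spacegroup(20)
        hkl, d = sx.enumerate_asu(cell, sg, d_min=2.5)
        s2 = 1.0 / (4 * d * d)
        inten = 1000.0 * np.exp(-2 * b * s2) * rng.exponential(1.0, len(d))
        return make_miniset(hkl, inten, ds_id=ds_id, cell=cell)

    def test_lowest_wilson_b_wins(self):
        mss = [self._wilson_ms(b, f"b{b}", seed=i) for i, b in enumerate((30, 25, 40))]
        assert sx.choose_reference(mss) == "b25"

    def test_single_dataset_chooses_itself(self):
        ms = self._wilson_ms(20, "only")
        assert sx.choose_reference([ms]) == "only"

    def test_all_undefined_falls_back_to_rmeas_rank(self, sg20):
        good = make_miniset([[2, 2, 0], [-2, 2, 0]], [100.0, 101.0], ds_id="dup")
        worse = make_miniset([[2, 2, 0], [-2, 2, 0]], [60.0, 140.0], ds_id="noisy")
        assert sx.choose_reference([worse, good], sg20) == "dup"


class TestRankByRmeas:
    def test_ascending_with_inf_last(self, sg20):
        a = make_miniset([[2, 2, 0], [-2, 2, 0]], [100.0, 110.0], ds_id="mid")
        b = make_miniset([[2, 2, 0], [-2, 2, 0]], [100.0, 101.0], ds_id="best")
        c = make_miniset([[2, 2, 0], [4, 0, 0]], [100.0, 50.0], ds_id="undef")
        assert sx.rank_by_rmeas([a, b, c], sg20) == ["best", "mid", "undef"]

    def test_stable_for_ties(self, sg20):
        mss = [
            make_miniset([[2, 2, 0], [-2, 2, 0]], [100.0, 110.0], ds_id=i)
            for i in ("z", "a", "m")
        ]
        assert sx.rank_by_rmeas(mss, sg20) == ["z", "a", "m"]


class TestIsaSelect:
    def _em(self, ds, isa):
        return ErrorModel(ds, 1.0, 1.0 / isa**2, isa, 100)

    def test_below_cutoff_rejected(self):
        rep = sx.isa_select([self._em("x", 2.9), self._em("y", 3.5)])
        assert rep.rejected == {"x": "low_isa"} and rep.accepted == ["y"]

    def test_exact_cutoff_kept(self):
        rep = sx.isa_select([self._em("x", 3.0)])
        assert rep.accepted == ["x"]

    def test_zero_cutoff_keeps_all_defined(self):
        rep = sx.isa_select([self._em("x", 0.5), self._em("y", 9.0)], isa_cutoff=0.0)
        assert set(rep.accepted) == {"x", "y"}

    def test_undefined_model_rejected(self):
        rep = sx.isa_select([ErrorModel.undefined("u", "no groups"), self._em("y", 5.0)])
        assert rep.rejected == {"u": "low_isa"}


class TestCellResultantPoint:
    def test_cubic_face_diagonals(self):
        pt = sx.cell_resultant_point(sx.UnitCell(100, 100, 100))
        np.testing.assert_allclose(pt, np.sqrt(20000.0), rtol=1e-12)

    def test_oblique_law_of_cosines(self):
        pt = sx.cell_resultant_point(sx.UnitCell(50, 60, 70, 90, 90, 120))
        assert pt[0] == pytest.approx(np.sqrt(3100.0), rel=1e-12)

    def test_collinear_limit(self):
        pt = sx.cell_resultant_point(sx.UnitCell(50, 60, 70, 90, 90, 179.9))
        assert pt[0] == pytest.approx(10.0, abs=0.1)


class TestCellClusterSelect:
    def _jittered(self, base, n, jitter, rng, prefix):
        out = []
        for i in range(n):
            p = np.array(base, dtype=float)
            p[:3] += rng.normal(0, jitter, 3)
            out.append(cell_miniset(p, f"{prefix}{i:02d}"))
        return out

    def test_separated_clusters_majority_recovered(self):
        rng = np.random.default_rng(0)
        big = self._jittered((40, 50, 60, 90, 90, 90), 30, 0.1, rng, "a")
        small = self._jittered((45, 50, 60, 90, 90, 90), 10, 0.1, rng, "b")
        link, rep = sx.cell_cluster_select(big + small)
        assert set(rep.accepted) == {ms.id for ms in big}
        assert all(reason == "cell_outlier" for reason in rep.rejected.values())

    def test_identical_cells_single_cluster(self):
        mss = [cell_miniset((40, 50, 60, 90, 90, 90), f"d{i}") for i in range(5)]
        _, rep = sx.cell_cluster_select(mss)
        assert len(rep.accepted) == 5

    def test_gaussian_branch_retention_matches_theory(self):
        """n ≥ 200: per-parameter ±1.5σ filter retains ≈ P(|z|<1.5)⁶."""
        rng = np.random.default_rng(1)
        mss = []
        for i in range(250):
            p = np.concatenate([
                np.array([40, 50, 60]) + rng.normal(0, 0.5, 3),
                np.array([90, 90, 90]) + rng.normal(0, 0.3, 3),
            ])
            mss.append(cell_miniset(p, f"g{i:03d}"))
        _, rep = sx.cell_cluster_select(mss)
        assert rep.info["method"] == "gaussian"
        frac = len(rep.accepted) / 250
        expect = 0.8664**6
        assert frac == pytest.approx(expect, abs=0.05)

    def test_single_dataset_passes_through(self):
        ms = cell_miniset((40, 50, 60, 90, 90, 90), "solo")
        _, rep = sx.cell_cluster_select([ms])
        assert rep.accepted == ["solo"]


class TestPairwiseCCMatrix:
    def _pcc_minisets(self, rng, n_uniq=500):
        cell = sx.UnitCell(40, 50, 60)
        sg = sx.get_spacegroup(20)
        hkl, d = sx.enumerate_asu(cell, sg, d_min=4.0, d_max=8.0)
        idx = rng.choice(len(hkl), min(n_uniq, len(hkl)), replace=False)
        return cell, hkl[idx]

    def test_copy_and_rescaled_copy_give_unity(self, sg20):
        rng = np.random.default_rng(2)
        cell, hkl = self._pcc_minisets(rng)
        inten = rng.exponential(300, len(hkl))
        a = make_miniset(hkl, inten, ds_id="a", cell=cell)
        b = make_miniset(hkl, inten, ds_id="b", cell=cell)
        c = make_miniset(hkl, inten * 2, ds_id="c", cell=cell)
        cc, ids, flagged = sx.pairwise_cc_matrix(observation_table([a, b, c], sg20))
        assert not flagged
        np.testing.assert_allclose(cc, 1.0, atol=1e-12)
        np.testing.assert_array_equal(cc, cc.T)

    def test_independent_intensities_near_zero(self, sg20):
        rng = np.random.default_rng(3)
        cell, hkl = self._pcc_minisets(rng)
        a = make_miniset(hkl, rng.exponential(300, len(hkl)), ds_id="a", cell=cell)
        b = make_miniset(hkl, rng.exponential(300, len(hkl)), ds_id="b", cell=cell)
        cc, _, _ = sx.pairwise_cc_matrix(observation_table([a, b], sg20))
        assert abs(cc[0, 1]) < 0.15  # null bound ≈ 3/√500

    def test_too_few_common_flagged_zero(self, sg20):
        cell = sx.UnitCell(40, 50, 60)
        a = make_miniset([[0, 2, 8], [2, 0, 8]], [10.0, 20.0], ds_id="a", cell=cell)
        b = make_miniset([[0, 4, 6], [2, 2, 6]], [10.0, 20.0], ds_id="b", cell=cell)
        cc, ids, flagged = sx.pairwise_cc_matrix(observation_table([a, b], sg20))
        assert cc[0, 1] == 0.0 and flagged == [("a", "b")]


class TestPccClusterSelect:
    def _block_matrix(self, n_big=60, n_small=20, within=0.9, cross=0.2, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        n = n_big + n_small
        cc = np.full((n, n), cross)
        cc[:n_big, :n_big] = within
        cc[n_big:, n_big:] = within
        cc += rng.normal(0, noise, (n, n))
        cc = (cc + cc.T) / 2
        np.fill_diagonal(cc, 1.0)
        labels = [f"a{i:02d}" for i in range(n_big)] + [f"b{i:02d}" for i in range(n_small)]
        return cc, labels

    def test_majority_block_fully_recovered(self):
        cc, labels = self._block_matrix()
        link, rep = sx.pcc_cluster_select(cc, labels)
        assert set(rep.accepted) == {l for l in labels if l.startswith("a")}

    def test_uniform_high_cc_single_cluster(self):
        cc, labels = self._block_matrix(within=0.95, cross=0.95, noise=0.0)
        _, rep = sx.pcc_cluster_select(cc, labels)
        assert len(rep.accepted) == len(labels)

    def test_zero_cut_gives_singletons(self):
        cc, labels = self._block_matrix()
        link, rep = sx.pcc_cluster_select(cc, labels, cut=0.0)
        assert len(rep.accepted) == 1
        assert len(set(link.clusters.values())) == len(labels)

    def test_sqrt1mcc2_metric_also_recovers_blocks(self):
        cc, labels = self._block_matrix()
        _, rep = sx.pcc_cluster_select(cc, labels, cut=0.8, metric="sqrt1mcc2")
        majority = {l for l in labels if l.startswith("a")}
        assert majority.issubset(set(rep.accepted) | set(rep.rejected)) and majority <= set(
            rep.accepted
        )

    def test_dendrogram_heights_nondecreasing(self):
        cc, labels = self._block_matrix(seed=5)
        link, _ = sx.pcc_cluster_select(cc, labels)
        heights = link.merge_tree[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)
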