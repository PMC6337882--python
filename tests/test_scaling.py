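import numpy as np
import pytest

import sxmerge as sx
from sxmerge.exceptions import UndefinedModelError
from sxmerge.scaling import _rmeas, observation_table

from conftest import make_miniset


def dup_miniset(ms, ds_id, factor_i=1.0, factor_s=1.0, delta_b=0.0):
    """Clone a miniset with an optional scale/B distortion."""
    d = sx.resolution_d(ms.cell, ms.hkl)
    s2 = 1.0 / (4 * d * d)
    g = factor_i * np.exp(-2.0 * delta_b * s2)
    return sx.Miniset(
        id=ds_id,
        cell=ms.cell,
        spacegroup_number=ms.spacegroup_number,
        wavelength=ms.wavelength,
        hkl=ms.hkl.copy(),
        intensity=ms.intensity * g,
        sigma=ms.sigma * factor_s,
    )


class TestRmeasFormula:
    def test_two_observation_worked_case(self):
        # observations 90 and 110 of one unique: √2 · (10+10) / 200
        r = _rmeas(np.array([90.0, 110.0]), np.array([0, 0]), 1)
        assert r == pytest.approx(np.sqrt(2) * 20.0 / 200.0, rel=1e-12)

    def test_exact_duplicates_give_zero(self):
        r = _rmeas(np.array([50.0, 50.0, 50.0]), np.array([0, 0, 0]), 1)
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_invariant_under_global_scaling(self):
        rng = np.random.default_rng(0)
        inten = rng.exponential(100, 300)
        codes = rng.integers(0, 60, 300)
        assert _rmeas(inten, codes, 60) == pytest.approx(
            _rmeas(inten * 7.3, codes, 60), rel=1e-12
        )


class TestWilsonB:
    def _wilson_miniset(self, b_true, n=5000, seed=0, const=False):
        rng = np.random.default_rng(seed)
        cell = sx.UnitCell(40, 50, 60)
        sg = sx.get_spacegroup(20)
        hkl, d = sx.enumerate_asu(cell, sg, d_min=2.2)
        idx = rng.choice(len(hkl), size=min(n, len(hkl)), replace=False)
        hkl, d = hkl[idx], d[idx]
        s2 = 1.0 / (4 * d * d)
        e = np.ones(len(d)) if const else rng.exponential(1.0, len(d))
        inten = 1000.0 * np.exp(-2.0 * b_true * s2) * e
        return make_miniset(hkl, inten, sigma=np.maximum(np.sqrt(np.abs(inten)), 1.0))

    def test_recovers_known_b(self):
        ms = self._wilson_miniset(b_true=30.0)
        assert sx.wilson_b(ms) == pytest.approx(30.0, abs=3.0)

    def test_flat_wilson_plot_gives_zero(self):
        ms = self._wilson_miniset(b_true=0.0, const=True)
        assert sx.wilson_b(ms) == pytest.approx(0.0, abs=0.5)

    def test_invariant_under_intensity_doubling(self):
        ms = self._wilson_miniset(b_true=20.0, seed=3)
        b1 = sx.wilson_b(ms)
        ms2 = make_miniset(ms.hkl, ms.intensity * 2, sigma=ms.sigma * 2)
        assert sx.wilson_b(ms2) == pytest.approx(b1, rel=1e-9)

    def test_too_few_reflections_undefined(self):
        ms = make_miniset([[1, 2, 3], [2, 1, 1]], [10.0, 12.0])
        with pytest.raises(UndefinedModelError):
            sx.wilson_b(ms)


class TestLowResRmeas:
    def test_duplicated_observations_give_zero(self, sg20):
        hkl = np.array([[2, 2, 0], [2, 2, 0], [4, 0, 0], [4, 0, 0], [0, 2, 1] , [0, 2, 1]])
        ms = make_miniset(hkl, [100.0, 100.0, 60.0, 60.0, 30.0, 30.0])
        assert sx.low_res_rmeas(ms, sg20) == pytest.approx(0.0, abs=1e-12)

    def test_no_multiplicity_returns_inf(self, sg20):
        hkl = np.array([[2, 2, 0], [4, 0, 0], [0, 2, 1]])
        ms = make_miniset(hkl, [100.0, 60.0, 30.0])
        assert sx.low_res_rmeas(ms, sg20) == np.inf

    def test_symmetry_mates_are_grouped(self, sg20):
        # (2,2,0) and its mate (-2,2,0) observed as 90/110 → R_meas = √2·0.1
        hkl = np.array([[2, 2, 0], [-2, 2, 0]])
        ms = make_miniset(hkl, [90.0, 110.0])
        assert sx.low_res_rmeas(ms, sg20, n_shells=1) == pytest.approx(
            np.sqrt(2) * 0.1, rel=1e-12
        )


class TestScaleDatasets:
    def test_identical_datasets_selfconsistent(self, clean_ensemble, sg20):
        ms = clean_ensemble[0][0]
        twin = dup_miniset(ms, "twin")
        res = sx.scale_datasets([ms, twin], sg20, reference_id=ms.id)
        m = res.model_for("twin")
        assert m.k == pytest.approx(1.0, abs=1e-3)
        assert m.b == pytest.approx(0.0, abs=0.05)

    def test_reference_gauge_is_exact(self, clean_ensemble, sg20):
        mss, _ = clean_ensemble
        res = sx.scale_datasets(mss, sg20, reference_id=mss[0].id)
        ref = res.model_for(mss[0].id)
        assert ref.k == 1.0 and ref.b == 0.0

    def test_doubled_intensities_recover_k2(self, clean_ensemble, sg20):
        ms = clean_ensemble[0][0]
        twin = dup_miniset(ms, "twice", factor_i=2.0)
        res = sx.scale_datasets([ms, twin], sg20, reference_id=ms.id)
        assert res.model_for("twice").k == pytest.approx(2.0, rel=0.01)

    def test_b_attenuation_recovered(self, clean_ensemble, sg20):
        ms = clean_ensemble[0][0]
        twin = dup_miniset(ms, "cold", delta_b=10.0)
        res = sx.scale_datasets([ms, twin], sg20, reference_id=ms.id)
        assert res.model_for("cold").b == pytest.approx(10.0, abs=1.0)

    def test_objective_never_increases(self, noisy_ensemble, sg20):
        mss, _ = noisy_ensemble
        res = sx.scale_datasets(mss[:15], sg20)
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0))

    def test_true_scales_recovered_noise_free(self, clean_ensemble, sg20):
        mss, truth = clean_ensemble
        ref = mss[0].id
        res = sx.scale_datasets(mss, sg20, reference_id=ref)
        kref, bref = truth.k[ref], truth.b[ref]
        for m in res.models:
            assert m.k == pytest.approx(truth.k[m.dataset_id] / kref, rel=0.02)
            assert m.b == pytest.approx(truth.b[m.dataset_id] - bref, abs=1.0)

    def test_unconnected_dataset_rejected_not_fatal(self, clean_ensemble, sg20):
        mss, _ = clean_ensemble
        loner = make_miniset(
            np.array([[25, 1, 1], [25, 3, 1], [25, 5, 1]]),
            [10.0, 12.0, 9.0],
            ds_id="loner",
            cell=mss[0].cell,
        )
        res = sx.scale_datasets(mss + [loner], sg20, reference_id=mss[0].id)
        assert res.rejected == {"loner": "unconnected"}
        assert all(m.dataset_id != "loner" for m in res.models)


class TestMerge:
    def test_single_observation_passthrough(self, sg20):
        ms = make_miniset([[2, 2, 0]], [42.0], sigma=[3.0])
        table = observation_table([ms], sg20)
        merged = sx.merge(table)
        assert merged.n_unique == 1
        assert merged.table["intensity"][0] == pytest.approx(42.0)
        assert merged.table["multiplicity"][0] == 1

    def test_weighted_mean_worked_case(self, sg20):
        a = make_miniset([[2, 2, 0]], [10.0], sigma=[1.0], ds_id="a")
        b = make_miniset([[2, 2, 0]], [20.0], sigma=[2.0], ds_id="b")
        table = observation_table([a, b], sg20)
        merged = sx.merge(table)
        assert merged.table["intensity"][0] == pytest.approx(12.0, rel=1e-12)
        assert merged.table["sigma"][0] == pytest.approx(1.25 ** -0.5, rel=1e-12)

    def test_multiplicity_conserved(self, noisy_ensemble, sg20):
        mss, _ = noisy_ensemble
        table = observation_table(mss[:8], sg20)
        merged = sx.merge(table)
        assert merged.total_observations == len(table)


class TestComputeStats:
    def test_duplicate_everything_perfect_stats(self, sg20):
        rng = np.random.default_rng(4)
        cell = sx.UnitCell(40, 50, 60)
        hkl, d = sx.enumerate_asu(cell, sg20, d_min=4.0)
        inten = rng.exponential(500, len(hkl))
        kw = dict(cell=cell)
        a = make_miniset(hkl, inten, ds_id="a", **kw)
        b = make_miniset(hkl, inten, ds_id="b", **kw)
        table = observation_table([a, b], sg20)
        merged = sx.merge(table)
        st = sx.compute_stats(merged, table, cell, sg20)
        assert st.overall["r_meas"] == pytest.approx(0.0, abs=1e-12)
        assert st.overall["cc_half"] == pytest.approx(1.0, abs=1e-9)

    def test_full_sphere_is_complete(self, sg20):
        cell = sx.UnitCell(40, 50, 60)
        hkl, d = sx.enumerate_asu(cell, sg20, d_min=4.0)
        inten = np.linspace(10, 500, len(hkl))
        a = make_miniset(hkl, inten, ds_id="a", cell=cell)
        b = make_miniset(hkl, inten + 1, ds_id="b", cell=cell)
        table = observation_table([a, b], sg20)
        st = sx.compute_stats(sx.merge(table), table, cell, sg20)
        assert st.overall["completeness"] == pytest.approx(1.0, abs=1e-9)

    def test_cc_half_null_for_pure_noise(self, sg20):
        rng = np.random.default_rng(6)
        cell = sx.UnitCell(40, 50, 60)
        hkl, _ = sx.enumerate_asu(cell, sg20, d_min=3.0)
        mss = [
            make_miniset(hkl, rng.normal(100, 30, len(hkl)), sigma=np.full(len(hkl), 30.0),
                         ds_id=f"n{i}", cell=cell)
            for i in range(4)
        ]
        table = observation_table(mss, sg20)
        st = sx.compute_stats(sx.merge(table), table, cell, sg20, n_shells=1)
        n = st.overall["n_unique"]
        assert abs(st.overall["cc_half"]) < 3.0 / np.sqrt(n)

    def test_stats_invariant_under_dataset_order(self, noisy_ensemble, sg20):
        mss, _ = noisy_ensemble
        sub = mss[:6]
        t1 = observation_table(sub, sg20)
        t2 = observation_table(sub[::-1], sg20, cell=sub[0].cell)
        s1 = sx.compute_stats(sx.merge(t1), t1, sub[0].cell, sg20)
        s2 = sx.compute_stats(sx.merge(t2), t2, sub[0].cell, sg20)
        assert s1.overall["r_meas"] == pytest.approx(s2.overall["r_meas"], rel=1e-9)
        assert s1.overall["completeness"] == pytest.approx(s2.overall["completeness"])
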