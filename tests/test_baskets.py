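"""Basket detection criterion and the chi-square association test."""

import numpy as np
import pytest
from scipy import stats

from varishell.baskets import (
    BasketConfig,
    ContingencyTable,
    angular_coverage,
    basket_summary,
    chisq_association,
    detect_baskets,
    fibonacci_directions,
)
from varishell.celltypes import CellType, TypedCell
from varishell.scene import GanglionScene, VaricositySet
from varishell.synthetic import _sample_on_surface_shell, make_sphere_fixture


def _hand_chi2(counts):
    counts = np.asarray(counts, float)
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    return float(((counts - expected) ** 2 / expected).sum())


class TestFibonacciBins:
    def test_unit_vectors(self):
        d = fibonacci_directions(64)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform(self):
        # every direction of a dense random sample lands in some bin, and bin
        # occupancy is roughly balanced
        rng = np.random.default_rng(0)
        v = rng.standard_normal((20000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        from scipy.spatial import cKDTree

        _, idx = cKDTree(fibonacci_directions(64)).query(v)
        occupancy = np.bincount(idx, minlength=64)
        assert occupancy.min() > 0.5 * occupancy.mean()


class TestCoverage:
    def test_empty_is_zero(self):
        assert angular_coverage(np.empty((0, 3))) == 0.0

    def test_full_sphere_coverage_high(self, rng):
        v = rng.standard_normal((500, 3))
        assert angular_coverage(v) > 0.9

    def test_octant_coverage_low(self, rng):
        # positive octant only: ~1/8 of bins plus a ring of boundary bins,
        # well below the 1/3 basket threshold
        v = np.abs(rng.standard_normal((200, 3)))
        assert angular_coverage(v) <= 0.25


class TestDetectBaskets:
    def _scene_and_types(self):
        scene = make_sphere_fixture(radius=5.0, n_spots_in_shell=0, seed=0)
        typed = [TypedCell("C001", CellType.CHAT_ONLY)]
        return scene, typed

    def test_no_spots_no_basket(self):
        scene, typed = self._scene_and_types()
        attributed = {"TH": {"C001": np.empty((0, 3))}}
        [call] = detect_baskets(typed, scene, attributed)
        assert not call.is_basket and call.coverage == 0.0 and call.shell_count == 0

    def test_encircling_spots_called_basket(self, rng):
        scene, typed = self._scene_and_types()
        cell = scene.cells[0]
        pts = _sample_on_surface_shell(cell, 100, 1.0, rng)
        [call] = detect_baskets(typed, scene, {"TH": {"C001": pts}})
        assert call.is_basket and call.coverage > 0.33 and call.shell_count == 100

    def test_single_octant_cluster_not_basket(self, rng):
        scene, typed = self._scene_and_types()
        center = scene.cells[0].mesh.center_mass
        dirs = np.abs(rng.standard_normal((20, 3)))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = center + dirs * 5.0
        [call] = detect_baskets(typed, scene, {"TH": {"C001": pts}})
        assert not call.is_basket
        assert call.coverage < 0.33

    def test_manual_flag_overrides(self, rng):
        scene, _ = self._scene_and_types()
        typed = [TypedCell("C001", CellType.CHAT_ONLY, basket_th=True)]
        [call] = detect_baskets(typed, scene, {"TH": {"C001": np.empty((0, 3))}})
        assert call.is_basket and call.source == "manual"

    def test_monotone_in_thresholds(self, rng):
        scene, typed = self._scene_and_types()
        cell = scene.cells[0]
        pts = _sample_on_surface_shell(cell, 30, 1.0, rng)[:18]
        attributed = {"TH": {"C001": pts}}
        base = detect_baskets(typed, scene, attributed, BasketConfig())[0].is_basket
        for cfg in (BasketConfig(n_min=25), BasketConfig(c_min=0.95)):
            stricter = detect_baskets(typed, scene, attributed, cfg)[0].is_basket
            assert not (stricter and not base)


class TestChiSquare:
    def test_uniform_table_is_zero(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], [[10, 10], [10, 10]])
        chi2, df, p = chisq_association(table)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_textbook_hand_formula(self):
        counts = [[20, 5], [5, 20]]
        chi2, df, p = chisq_association(ContingencyTable(["a", "b"], ["x", "y"], counts))
        assert df == 1
        assert chi2 == pytest.approx(_hand_chi2(counts), abs=1e-12)

    def test_matches_hand_formula_on_random_tables(self, rng):
        for _ in range(100):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            counts = rng.integers(1, 80, size=shape)
            table = ContingencyTable(
                [f"r{i}" for i in range(shape[0])],
                [f"c{j}" for j in range(shape[1])],
                counts,
            )
            chi2, df, p = chisq_association(table)
            assert chi2 == pytest.approx(_hand_chi2(counts), abs=1e-9)
            assert df == (shape[0] - 1) * (shape[1] - 1)
            assert p == pytest.approx(stats.chi2.sf(chi2, df), rel=1e-9)

    def test_permutation_invariance(self, rng):
        counts = rng.integers(1, 50, size=(2, 4))
        t1 = ContingencyTable(["a", "b"], list("wxyz"), counts)
        t2 = ContingencyTable(["b", "a"], list("zyxw"), counts[::-1, ::-1])
        assert chisq_association(t1)[0] == pytest.approx(chisq_association(t2)[0], rel=1e-12)

    def test_zero_margin_raises(self):
        table = ContingencyTable(["a", "b"], ["x", "y"], [[0, 5], [0, 10]])
        with pytest.raises(ValueError, match="margin"):
            chisq_association(table)

    def test_study_basket_table_is_strongly_associated(self):
        """ENK baskets vs the four ChAT/NOS types: df=3, p far below 0.01."""
        baskets = np.array([53, 0, 5, 3])
        totals = np.array([190, 205, 58, 33])
        table = ContingencyTable(
            ["basket", "no_basket"],
            [t.value for t in CellType],
            np.vstack([baskets, totals - baskets]),
        )
        chi2, df, p = chisq_association(table)
        assert df == 3
        assert p < 0.01


class TestBasketSummary:
    @staticmethod
    def _typed_with_baskets(th_baskets, enk_baskets, totals):
        typed, calls = [], []
        i = 0
        for t, n, n_th, n_enk in zip(CellType, totals, th_baskets, enk_baskets):
            for j in range(n):
                cid = f"C{i:04d}"
                typed.append(TypedCell(cid, t))
                for marker, flag in (("TH", j < n_th), ("ENK", j < n_enk)):
                    from varishell.baskets import BasketCall

                    calls.append(BasketCall(cid, marker, flag, 0, 0.0))
                i += 1
        return typed, calls

    def test_study_percentages(self):
        typed, calls = self._typed_with_baskets(
            th_baskets=(10, 0, 0, 0),
            enk_baskets=(53, 0, 5, 3),
            totals=(190, 205, 58, 33),
        )
        table_th, pct_th = basket_summary(calls, typed, "TH")
        assert pct_th["ChAT+/NOS-"] == 100.0
        table_enk, pct_enk = basket_summary(calls, typed, "ENK")
        assert round(pct_enk["ChAT+/NOS-"]) == 87
        assert pct_enk["ChAT-/NOS+"] == 0.0
        assert round(pct_enk["ChAT+/NOS+"]) == 8
        assert round(pct_enk["ChAT-/NOS-"]) == 5
        assert table_enk.counts[0].sum() == 61
        assert table_enk.counts.sum() == 486

    def test_no_baskets_all_zero(self):
        typed, calls = self._typed_with_baskets((0,) * 4, (0,) * 4, (5, 5, 5, 5))
        table, pct = basket_summary(calls, typed, "ENK")
        assert table.counts[0].sum() == 0
        assert all(v == 0.0 for v in pct.values())

    def test_id_mismatch_raises(self):
        typed, calls = self._typed_with_baskets((0,) * 4, (0,) * 4, (2, 2, 2, 2))
        with pytest.raises(ValueError, match="basket call"):
            basket_summary(calls[:-2], typed, "ENK")
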