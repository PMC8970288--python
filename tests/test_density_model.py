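"""NB mixed model: input building, posterior transforms, gradient
correctness, cross-checks against an independent fixed-effects fit, offset
behaviour, shape submodel and the morphometric ANOVA."""

import warnings

import numpy as np
import pytest

from varishell.celltypes import CellType, TypedCell
from varishell.density_model import (
    DensityRatioResult,
    ModelInputRow,
    ModelSettings,
    PosteriorSummary,
    _NBGLMMTarget,
    build_model_input,
    density_ratio,
    fit_nb_glmm,
    mean_density,
    morphometric_anova,
)
from varishell.geometry import CellMorphometry, ShellDensityRecord
from varishell.synthetic import GeneratorParams, simulate_model_rows

warnings.filterwarnings("ignore", category=FutureWarning)

FAST = ModelSettings(chains=2, warmup=300, draws=300, rhat_threshold=np.inf)


def _record(i, cell_type, marker="TH", count=5, volume=1000.0, subj="S01", gang="G1"):
    return ShellDensityRecord(
        cell_id=f"C{i:04d}",
        marker=marker,
        count=count,
        shell_volume=volume,
        density=1000.0 * count / volume,
        subject_id=subj,
        ganglion_id=gang,
        cell_type=cell_type,
    )


class TestBuildModelInput:
    def test_study_scale_row_count(self):
        """486 included cells, 33 ChAT-/NOS-: 453 cells x 2 markers = 906 rows."""
        records = []
        types = (
            ["ChAT+/NOS-"] * 190 + ["ChAT-/NOS+"] * 205 + ["ChAT+/NOS+"] * 58 + ["ChAT-/NOS-"] * 33
        )
        for i, t in enumerate(types):
            for m in ("TH", "ENK"):
                records.append(_record(i, t, marker=m))
        rows = build_model_input(records)
        assert len(rows) == 906

    def test_empty_input(self):
        assert build_model_input([]) == []

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            ModelInputRow(count=1, cell_type="ChAT+/NOS-", marker="TH", volume=0.0,
                          subject="S01", ganglion="G1")

    def test_missing_type_rejected(self):
        with pytest.raises(ValueError, match="no cell type"):
            build_model_input([_record(0, "")])


class TestTargetGradient:
    def test_matches_finite_differences(self, rng):
        rows, _ = simulate_model_rows(
            GeneratorParams(n_subjects=3, ganglia_per_subject=2, cells_per_ganglion=5),
            seed=4,
        )
        target = _NBGLMMTarget(rows)
        theta = target.initial_point(rng) + 0.3 * rng.standard_normal(target.dim)
        lp, g = target.logp_and_grad(theta)
        assert np.isfinite(lp)
        h = 1e-6
        idx = rng.choice(target.dim, 30, replace=False)
        for k in idx:
            e = np.zeros(target.dim)
            e[k] = h
            fd = (target.logp_and_grad(theta + e)[0] - target.logp_and_grad(theta - e)[0]) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_degenerate_design_rejected(self):
        rows = [
            ModelInputRow(3, "ChAT+/NOS-", "TH", 1000.0, "S01", "G1"),
            ModelInputRow(3, "ChAT-/NOS+", "TH", 1000.0, "S02", "G1"),
        ]
        with pytest.raises(ValueError, match="degenerate"):
            _NBGLMMTarget(rows)


def _degenerate_posterior(beta_values, n_draws=1):
    """PosteriorSummary with constant draws, for transform checks."""
    cells = [(t.value, m) for t in (CellType.CHAT_ONLY, CellType.NOS_ONLY, CellType.CHAT_NOS)
             for m in ("TH", "ENK")]
    beta = np.tile(np.asarray(beta_values, float), (1, n_draws, 1))
    zeros = np.zeros_like(beta)
    return PosteriorSummary(
        cells=cells, beta=beta, gamma=zeros, sigma_subj=zeros, sigma_gang=zeros,
        rhat={}, ess={}, divergences=0, accept_rate=1.0, step_sizes=[0.1],
        seed=0, settings=ModelSettings(), n_rows=0,
    )


class TestPosteriorTransforms:
    def test_mean_density_scale(self):
        post = _degenerate_posterior([np.log(0.00743)] * 6)
        md = mean_density(post, "ChAT+/NOS-", "TH")
        assert md["median"] == pytest.approx(7.43)
        assert md["ci_low"] == md["ci_high"] == pytest.approx(7.43)

    def test_ratio_identity_and_shift(self):
        beta = [np.log(0.002)] * 6
        post = _degenerate_posterior(beta)
        r = density_ratio(post, "TH", "ChAT+/NOS-", "ChAT-/NOS+")
        assert r.median == 1.0 and (r.ci_low, r.ci_high) == (1.0, 1.0)
        beta2 = list(beta)
        beta2[0] = beta[0] + np.log(2.0)  # TH x ChAT+/NOS-
        r2 = density_ratio(_degenerate_posterior(beta2), "TH", "ChAT+/NOS-", "ChAT-/NOS+")
        assert r2.median == pytest.approx(2.0)

    def test_same_type_ratio_is_one(self):
        post = _degenerate_posterior([np.log(0.002)] * 6)
        r = density_ratio(post, "TH", "ChAT+/NOS-", "ChAT+/NOS-")
        assert r.median == 1.0

    def test_unknown_type_raises(self):
        post = _degenerate_posterior([0.0] * 6)
        with pytest.raises(KeyError):
            mean_density(post, "ChAT-/NOS-", "TH")

    def test_significance_flag(self):
        r = DensityRatioResult("TH", "a", "b", 1.3, 1.05, 1.6, 0.99)
        assert r.significant
        r2 = DensityRatioResult("TH", "a", "b", 1.2, 0.95, 1.6, 0.9)
        assert not r2.significant


class TestFit:
    @pytest.fixture(scope="class")
    def fixed_effect_rows(self):
        """No group variation: comparable to a fixed-effects NB fit."""
        params = GeneratorParams(
            n_subjects=4,
            ganglia_per_subject=2,
            cells_per_ganglion=25,
            subject_sd=0.0,
            ganglion_sd=0.0,
            basket_prob={},
            nb_shape={"TH": 8.0, "ENK": 8.0},
        )
        return simulate_model_rows(params, seed=21)[0]

    @pytest.fixture(scope="class")
    def fixed_effect_posterior(self, fixed_effect_rows):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_nb_glmm(fixed_effect_rows, FAST, seed=9)

    def test_against_statsmodels_nb_glm(self, fixed_effect_rows, fixed_effect_posterior):
        """Posterior medians track an independent maximum-likelihood fit of
        the fixed-effects NB GLM with offset (statsmodels)."""
        import statsmodels.api as sm

        post = fixed_effect_posterior
        y = np.array([r.count for r in fixed_effect_rows])
        X = np.zeros((len(fixed_effect_rows), 6))
        for i, r in enumerate(fixed_effect_rows):
            X[i, post.cells.index((r.cell_type, r.marker))] = 1.0
        offset = np.log([r.volume for r in fixed_effect_rows])
        glm = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1 / 8.0), offset=offset
        ).fit()
        for k in range(6):
            bayes = np.median(post.beta[:, :, k])
            assert bayes == pytest.approx(glm.params[k], abs=0.12)

    def test_seed_determinism(self, fixed_effect_rows):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_nb_glmm(fixed_effect_rows, FAST, seed=3)
            b = fit_nb_glmm(fixed_effect_rows, FAST, seed=3)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.gamma, b.gamma)

    def test_offset_property(self, fixed_effect_rows, fixed_effect_posterior):
        """Doubling all shell volumes with counts fixed halves every mean
        density and leaves ratios unchanged (up to Monte Carlo error)."""
        doubled = [
            ModelInputRow(r.count, r.cell_type, r.marker, 2.0 * r.volume, r.subject, r.ganglion)
            for r in fixed_effect_rows
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post2 = fit_nb_glmm(doubled, FAST, seed=9)
        post1 = fixed_effect_posterior
        for ct, m in post1.cells:
            d1 = mean_density(post1, ct, m)["median"]
            d2 = mean_density(post2, ct, m)["median"]
            assert d2 / d1 == pytest.approx(0.5, rel=0.08)
        r1 = density_ratio(post1, "TH", "ChAT+/NOS-", "ChAT-/NOS+")
        r2 = density_ratio(post2, "TH", "ChAT+/NOS-", "ChAT-/NOS+")
        assert r2.median == pytest.approx(r1.median, abs=0.12)

    def test_shape_submodel_ordering(self):
        """Marker-specific overdispersion is recovered in sign: TH simulated
        with much larger NB shape (less dispersion) than ENK."""
        params = GeneratorParams(
            n_subjects=4,
            ganglia_per_subject=2,
            cells_per_ganglion=30,
            subject_sd=0.0,
            ganglion_sd=0.0,
            basket_prob={},
            nb_shape={"TH": 25.0, "ENK": 2.0},
        )
        rows, _ = simulate_model_rows(params, seed=31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_nb_glmm(rows, FAST, seed=13)
        for t in ("ChAT+/NOS-", "ChAT-/NOS+"):
            g_th = np.median(post.gamma[:, :, post.cell_index(t, "TH")])
            g_enk = np.median(post.gamma[:, :, post.cell_index(t, "ENK")])
            assert g_th > g_enk

    def test_requires_two_subjects(self):
        rows = [
            ModelInputRow(3, t, m, 1000.0, "S01", "G1")
            for t in ("ChAT+/NOS-", "ChAT-/NOS+", "ChAT+/NOS+")
            for m in ("TH", "ENK")
        ]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_nb_glmm(rows, FAST, seed=0)


class TestMorphometricAnova:
    @staticmethod
    def _cells(groups):
        cells = []
        i = 0
        for ctype, values in groups.items():
            for v in values:
                cells.append(
                    TypedCell(
                        f"C{i}",
                        CellType(ctype),
                        morphometry=CellMorphometry(f"C{i}", v, v, np.zeros(3)),
                    )
                )
                i += 1
        return cells

    def test_known_shift_recovered_by_tukey(self, rng):
        base = 1000 + rng.normal(0, 1.0, 12)
        shifted = base + 500.0
        cells = self._cells({"ChAT+/NOS-": base, "ChAT-/NOS+": shifted})
        res = morphometric_anova(cells, measure="volume", unit_of_analysis="cell")
        assert res.p_value < 1e-6
        [pair] = res.tukey
        assert abs(pair.mean_diff) == pytest.approx(500.0, abs=2.0)

    def test_constant_groups_rejected(self):
        cells = self._cells({"ChAT+/NOS-": [5.0, 5.0], "ChAT-/NOS+": [5.0, 5.0]})
        with pytest.raises(ValueError, match="zero variance"):
            morphometric_anova(cells, measure="volume", unit_of_analysis="cell")

    def test_null_calibration(self, rng):
        """Groups drawn from one distribution: p > 0.05 in most replicates."""
        hits = 0
        for _ in range(12):
            cells = self._cells(
                {t.value: rng.normal(2000, 300, 10) for t in CellType}
            )
            res = morphometric_anova(cells, measure="surface_area", unit_of_analysis="cell")
            hits += res.p_value > 0.05
        assert hits >= 9

    def test_ganglion_unit_of_analysis(self, rng):
        cells = self._cells(
            {"ChAT+/NOS-": rng.normal(3000, 100, 8), "ChAT-/NOS+": rng.normal(2000, 100, 8)}
        )
        groups = {c.cell_id: ("S01", f"G{i % 4}") for i, c in enumerate(cells)}
        res = morphometric_anova(
            cells, measure="volume", unit_of_analysis="ganglion", groups=groups
        )
        assert res.df_within == 6  # 8 ganglion-level means, 2 groups
        assert res.p_value < 0.01
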