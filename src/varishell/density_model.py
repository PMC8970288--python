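"""Bayesian negative-binomial mixed model of perisomatic varicosity counts.

The count of varicosities in the ±1 um shell of cell *i* is modelled as

    Count_i ~ NegativeBinomial(mean mu_i, shape phi_i)
    log mu_i  = beta[cell(i)] + u[subj(i), cell(i)] + w[gang(i), cell(i)] + log V_i
    log phi_i = gamma[cell(i)]

where ``cell(i)`` indexes the six cell-type x marker combinations
(cell-mean coding: one coefficient per combination, no global intercept, so
``exp(beta)`` is directly a mean density), ``V_i`` is the shell volume (um^3,
multiplicative offset), and the negative binomial uses the mean/shape
convention Var = mu + mu^2/phi.  Random-effect vectors over the six
combinations are drawn, non-centrally, from multivariate normals at the
subject and subject:ganglion levels with half-normal(0, 1) scales and
LKJ(2) correlation priors; fixed coefficients and log-shapes have
normal(anchor, 1) priors whose anchors are located at the pooled log density
and a moment-based pooled log shape (the cell-mean analogue of giving the
intercept a data-located prior while contrast-scale coefficients get
normal(0, 1)).  Posteriors are explored with the in-house HMC sampler
(:mod:`varishell.hmc`); 4 chains x (1,000 warmup + 1,000 retained) by
default.

Reported quantities: population mean densities per cell type x marker
(``exp(beta) x 1,000`` per 1,000 um^3, random effects at zero) and pairwise
density ratios with equal-tailed 95% credible intervals.

Also hosts the classical morphometric comparison (one-way ANOVA with Tukey
HSD) of cell surface area and volume between the four ChAT/NOS types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .celltypes import MODELLED_TYPES, CellType
from .geometry import ShellDensityRecord
from .hmc import HMCSettings, sample_chains
from .lkj import chol_corr_backward, chol_corr_forward, n_corr_params
from .scene import MARKERS

__all__ = [
    "ModelInputRow",
    "ModelSettings",
    "PosteriorSummary",
    "DensityRatioResult",
    "build_model_input",
    "fit_nb_glmm",
    "mean_density",
    "density_ratio",
    "morphometric_anova",
]


@dataclass(frozen=True)
class ModelInputRow:
    count: int
    cell_type: str  # one of the three modelled type values
    marker: str  # TH | ENK
    volume: float  # shell volume, um^3
    subject: str
    ganglion: str

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.volume <= 0:
            raise ValueError(
                f"cell in {self.subject}/{self.ganglion}: shell volume must be > 0"
            )


@dataclass(frozen=True)
class ModelSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    lkj_eta: float = 2.0
    rhat_threshold: float = 1.05
    abort_on_rhat: bool = False
    max_leapfrog: int = 128
    integration_time: float = 1.5


@dataclass
class DensityRatioResult:
    marker: str
    numerator: str
    denominator: str
    median: float
    ci_low: float
    ci_high: float
    prob_gt_1: float

    @property
    def significant(self) -> bool:
        """True when the 95% credible interval excludes 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


@dataclass
class PosteriorSummary:
    cells: list[tuple[str, str]]  # (cell_type value, marker) per coefficient
    beta: np.ndarray  # (chains, draws, n_cells) log mean density x volume
    gamma: np.ndarray  # (chains, draws, n_cells) log NB shape
    sigma_subj: np.ndarray  # (chains, draws, n_cells)
    sigma_gang: np.ndarray
    rhat: dict[str, np.ndarray]
    ess: dict[str, np.ndarray]
    divergences: int
    accept_rate: float
    step_sizes: list[float]
    seed: int
    settings: ModelSettings
    n_rows: int
    subjects: list[str] = field(default_factory=list)

    @property
    def max_rhat(self) -> float:
        return float(max(np.nanmax(v) for v in self.rhat.values()))

    def cell_index(self, cell_type: str, marker: str) -> int:
        key = (cell_type, marker)
        if key not in self.cells:
            raise KeyError(f"no coefficient for cell type {cell_type!r}, marker {marker!r}")
        return self.cells.index(key)


# --------------------------------------------------------------------------- #
def build_model_input(records: list[ShellDensityRecord]) -> list[ModelInputRow]:
    """Model rows from density records: drop ChAT-/NOS- cells, carry the
    shell volume as the offset variable."""
    modelled = {t.value for t in MODELLED_TYPES}
    rows = []
    for r in records:
        if not r.cell_type:
            raise ValueError(f"cell {r.cell_id!r} has a density record but no cell type")
        if r.cell_type == CellType.NEITHER.value:
            continue
        if r.cell_type not in modelled:
            raise ValueError(f"cell {r.cell_id!r}: unknown cell type {r.cell_type!r}")
        rows.append(
            ModelInputRow(
                count=int(r.count),
                cell_type=r.cell_type,
                marker=r.marker,
                volume=float(r.shell_volume),
                subject=r.subject_id,
                ganglion=r.ganglion_id,
            )
        )
    return rows


class _NBGLMMTarget:
    """Unconstrained log-posterior and gradient for the NB mixed model."""

    def __init__(self, rows: list[ModelInputRow], eta: float = 2.0):
        types = [t.value for t in MODELLED_TYPES]
        self.cells = [(t, m) for t in types for m in MARKERS]
        cell_index = {tm: k for k, tm in enumerate(self.cells)}
        self.subjects = sorted({r.subject for r in rows})
        self.gangs = sorted({(r.subject, r.ganglion) for r in rows})
        s_index = {s: i for i, s in enumerate(self.subjects)}
        g_index = {g: i for i, g in enumerate(self.gangs)}
        self.y = np.array([r.count for r in rows], dtype=float)
        self.c = np.array([cell_index[(r.cell_type, r.marker)] for r in rows])
        self.s = np.array([s_index[r.subject] for r in rows])
        self.g = np.array([g_index[(r.subject, r.ganglion)] for r in rows])
        self.logV = np.log([r.volume for r in rows])
        self.C = len(self.cells)
        self.S = len(self.subjects)
        self.G = len(self.gangs)
        self.eta = eta
        present = np.bincount(self.c, minlength=self.C)
        if (present == 0).any():
            missing = [self.cells[k] for k in np.flatnonzero(present == 0)]
            raise ValueError(f"degenerate design: no rows for {missing}")
        self.ncorr = n_corr_params(self.C)
        self.dim = 4 * self.C + 2 * self.ncorr + self.C * (self.S + self.G)
        self._lgam_y = special.gammaln(self.y + 1.0)
        self._tril = np.tril(np.ones((self.C, self.C)))
        # Priors: normal(0, 1) deviations around data-located anchors, the
        # counterpart of the reference fitting package's handling of the
        # intercept (its normal(0,1) applies to contrast-scale coefficients,
        # not to the absolute log density, which is far from 0 with a um^3
        # offset).  beta is anchored at the pooled log density, gamma at a
        # moment-based pooled log shape.
        V = np.exp(self.logV)
        self.beta_anchor = float(np.log((self.y.sum() + 0.5) / V.sum()))
        mu_hat = np.exp(self.beta_anchor) * V
        excess = float(np.sum((self.y - mu_hat) ** 2 - mu_hat))
        denom = float(np.sum(mu_hat**2))
        phi_hat = denom / excess if excess > 0 else 50.0
        self.gamma_anchor = float(np.log(np.clip(phi_hat, 0.5, 50.0)))

    # parameter vector layout
    def unpack(self, theta: np.ndarray):
        C, nc = self.C, self.ncorr
        o = 0
        beta = theta[o : o + C]; o += C
        gamma = theta[o : o + C]; o += C
        ls_u = theta[o : o + C]; o += C
        ls_v = theta[o : o + C]; o += C
        y_u = theta[o : o + nc]; o += nc
        y_v = theta[o : o + nc]; o += nc
        z_u = theta[o : o + C * self.S].reshape(self.S, C); o += C * self.S
        z_v = theta[o : o + C * self.G].reshape(self.G, C)
        return beta, gamma, ls_u, ls_v, y_u, y_v, z_u, z_v

    def logp_and_grad(self, theta: np.ndarray):
        # extreme proposals overflow exp() harmlessly (they are rejected via
        # the non-finite log-density); keep the console clean
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_and_grad(theta)

    def _logp_and_grad(self, theta: np.ndarray):
        beta, gamma, ls_u, ls_v, y_u, y_v, z_u, z_v = self.unpack(theta)
        C = self.C
        sig_u, sig_v = np.exp(ls_u), np.exp(ls_v)

        L_u, logp_corr_u, cache_u = chol_corr_forward(y_u, C, self.eta)
        L_v, logp_corr_v, cache_v = chol_corr_forward(y_v, C, self.eta)

        u = (z_u @ L_u.T) * sig_u  # (S, C)
        v = (z_v @ L_v.T) * sig_v  # (G, C)

        eta_lin = beta[self.c] + u[self.s, self.c] + v[self.g, self.c] + self.logV
        gam_c = gamma[self.c]
        phi = np.exp(gam_c)
        log_phi_mu = np.logaddexp(gam_c, eta_lin)  # log(phi + mu)

        ll = np.sum(
            special.gammaln(self.y + phi)
            - special.gammaln(phi)
            - self._lgam_y
            + phi * (gam_c - log_phi_mu)
            + self.y * (eta_lin - log_phi_mu)
        )

        # gradients of the likelihood
        mu_frac = np.exp(eta_lin - log_phi_mu)  # mu / (mu + phi)
        g_eta = self.y - (self.y + phi) * mu_frac
        g_loggphi = phi * (
            special.digamma(self.y + phi)
            - special.digamma(phi)
            + gam_c
            - log_phi_mu
            + 1.0
            - (self.y + phi) * np.exp(-log_phi_mu)
        )

        g_beta = np.bincount(self.c, weights=g_eta, minlength=C) - (beta - self.beta_anchor)
        g_gamma = np.bincount(self.c, weights=g_loggphi, minlength=C) - (
            gamma - self.gamma_anchor
        )

        A_u = np.bincount(self.s * C + self.c, weights=g_eta, minlength=self.S * C).reshape(
            self.S, C
        )
        A_v = np.bincount(self.g * C + self.c, weights=g_eta, minlength=self.G * C).reshape(
            self.G, C
        )

        g_z_u = (A_u * sig_u) @ L_u - z_u
        g_z_v = (A_v * sig_v) @ L_v - z_v
        g_ls_u = np.sum(A_u * u, axis=0) + (1.0 - sig_u**2)
        g_ls_v = np.sum(A_v * v, axis=0) + (1.0 - sig_v**2)

        gL_u = ((A_u * sig_u).T @ z_u) * self._tril
        gL_v = ((A_v * sig_v).T @ z_v) * self._tril
        g_y_u = chol_corr_backward(cache_u, gL_u)
        g_y_v = chol_corr_backward(cache_v, gL_v)

        logp = (
            ll
            - 0.5 * np.sum((beta - self.beta_anchor) ** 2)
            - 0.5 * np.sum((gamma - self.gamma_anchor) ** 2)
            - 0.5 * np.sum(z_u**2)
            - 0.5 * np.sum(z_v**2)
            + np.sum(-0.5 * sig_u**2 + ls_u)
            + np.sum(-0.5 * sig_v**2 + ls_v)
            + logp_corr_u
            + logp_corr_v
        )
        grad = np.concatenate(
            [g_beta, g_gamma, g_ls_u, g_ls_v, g_y_u, g_y_v, g_z_u.ravel(), g_z_v.ravel()]
        )
        return float(logp), grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        beta0 = np.empty(self.C)
        for k in range(self.C):
            sel = self.c == k
            rate = (self.y[sel].sum() + 0.5) / np.exp(self.logV[sel]).sum()
            beta0[k] = np.log(rate)
        theta = np.concatenate(
            [
                beta0 + 0.05 * rng.standard_normal(self.C),
                self.gamma_anchor + 0.1 * rng.standard_normal(self.C),
                np.log(0.1) + 0.1 * rng.standard_normal(2 * self.C),  # scales
                0.01 * rng.standard_normal(2 * self.ncorr),
                0.01 * rng.standard_normal(self.C * (self.S + self.G)),
            ]
        )
        return theta


def fit_nb_glmm(
    rows: list[ModelInputRow],
    settings: ModelSettings = ModelSettings(),
    seed: int = 0,
) -> PosteriorSummary:
    """Fit the NB mixed model by HMC and summarise the posterior.

    Requires at least two subjects and at least two cell types present.
    Emits a warning (or raises, with ``abort_on_rhat``) if any monitored
    Rhat exceeds the threshold.
    """
    if not rows:
        raise ValueError("no model input rows")
    if len({r.subject for r in rows}) < 2:
        raise ValueError("model requires at least 2 subjects")
    if len({r.cell_type for r in rows}) < 2:
        raise ValueError("model requires at least 2 cell types present")

    target = _NBGLMMTarget(rows, eta=settings.lkj_eta)
    hmc = HMCSettings(
        n_warmup=settings.warmup,
        n_draws=settings.draws,
        target_accept=settings.target_accept,
        max_leapfrog=settings.max_leapfrog,
        integration_time=settings.integration_time,
    )
    chains = sample_chains(
        target.logp_and_grad, target.initial_point, settings.chains, hmc, seed
    )

    C = target.C
    draws = np.stack([ch.draws for ch in chains])  # (chains, draws, dim)
    beta = draws[:, :, :C]
    gamma = draws[:, :, C : 2 * C]
    sigma_subj = np.exp(draws[:, :, 2 * C : 3 * C])
    sigma_gang = np.exp(draws[:, :, 3 * C : 4 * C])

    monitored = {
        "beta": beta,
        "gamma": gamma,
        "sigma_subj": sigma_subj,
        "sigma_gang": sigma_gang,
    }
    rhat, ess = _diagnostics(monitored)

    summary = PosteriorSummary(
        cells=target.cells,
        beta=beta,
        gamma=gamma,
        sigma_subj=sigma_subj,
        sigma_gang=sigma_gang,
        rhat=rhat,
        ess=ess,
        divergences=int(sum(ch.divergences for ch in chains)),
        accept_rate=float(np.mean([ch.accept_rate for ch in chains])),
        step_sizes=[ch.step_size for ch in chains],
        seed=seed,
        settings=settings,
        n_rows=len(rows),
        subjects=target.subjects,
    )
    if summary.max_rhat > settings.rhat_threshold:
        msg = (
            f"convergence warning: max Rhat {summary.max_rhat:.3f} exceeds "
            f"{settings.rhat_threshold} (chains={settings.chains}, draws={settings.draws})"
        )
        if settings.abort_on_rhat:
            raise RuntimeError(msg)
        warnings.warn(msg, RuntimeWarning)
    return summary


def _diagnostics(monitored: dict[str, np.ndarray]):
    import arviz as az

    rhat: dict[str, np.ndarray] = {}
    ess: dict[str, np.ndarray] = {}
    for name, arr in monitored.items():
        if arr.shape[0] < 2:
            rhat[name] = np.full(arr.shape[-1], np.nan)
            ess[name] = np.full(arr.shape[-1], np.nan)
            continue
        rhat[name] = np.array(
            [float(az.rhat(arr[:, :, j])) for j in range(arr.shape[-1])]
        )
        ess[name] = np.array(
            [float(az.ess(arr[:, :, j])) for j in range(arr.shape[-1])]
        )
    return rhat, ess


# --------------------------------------------------------------------------- #
def mean_density(posterior: PosteriorSummary, cell_type: str, marker: str) -> dict:
    """Posterior median and equal-tailed 95% CI of the population mean
    density (per 1,000 um^3) for one cell type x marker (random effects at
    zero): ``exp(beta) x 1,000`` under cell-mean coding with a um^3 offset."""
    k = posterior.cell_index(cell_type, marker)
    d = np.exp(posterior.beta[:, :, k].ravel()) * 1000.0
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {
        "cell_type": cell_type,
        "marker": marker,
        "median": float(np.median(d)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "draws": d,
    }


def density_ratio(
    posterior: PosteriorSummary, marker: str, type_a: str, type_b: str
) -> DensityRatioResult:
    """Posterior of the density ratio type_a / type_b for one marker."""
    ka = posterior.cell_index(type_a, marker)
    kb = posterior.cell_index(type_b, marker)
    ratio = np.exp(posterior.beta[:, :, ka].ravel() - posterior.beta[:, :, kb].ravel())
    lo, hi = np.percentile(ratio, [2.5, 97.5])
    return DensityRatioResult(
        marker=marker,
        numerator=type_a,
        denominator=type_b,
        median=float(np.median(ratio)),
        ci_low=float(lo),
        ci_high=float(hi),
        prob_gt_1=float(np.mean(ratio > 1.0)),
    )


# --------------------------------------------------------------------------- #
@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass
class AnovaResult:
    measure: str
    unit_of_analysis: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: list[TukeyPair]
    group_means: dict[str, float]


def morphometric_anova(
    cells,
    measure: str = "volume",
    unit_of_analysis: str = "ganglion",
    groups: dict[str, tuple[str, str]] | None = None,
) -> AnovaResult:
    """One-way ANOVA + Tukey HSD of a morphometric measure across cell types.

    ``cells`` is a list of TypedCell with morphometry attached.  With the
    default ``unit_of_analysis='ganglion'`` the observations are per-ganglion
    type means (``groups`` must then map cell_id -> (subject, ganglion));
    with ``'cell'`` every included cell is an observation.
    """
    if measure not in ("surface_area", "volume"):
        raise ValueError("measure must be 'surface_area' or 'volume'")
    values: dict[str, list[float]] = {}
    if unit_of_analysis == "cell":
        for tc in cells:
            if not tc.included or tc.morphometry is None:
                continue
            values.setdefault(tc.cell_type.value, []).append(
                getattr(tc.morphometry, measure)
            )
    elif unit_of_analysis == "ganglion":
        if groups is None:
            raise ValueError("unit_of_analysis='ganglion' requires a cell->ganglion map")
        acc: dict[tuple[str, tuple[str, str]], list[float]] = {}
        for tc in cells:
            if not tc.included or tc.morphometry is None:
                continue
            key = (tc.cell_type.value, tuple(groups[tc.cell_id]))
            acc.setdefault(key, []).append(getattr(tc.morphometry, measure))
        for (ctype, _), vals in acc.items():
            values.setdefault(ctype, []).append(float(np.mean(vals)))
    else:
        raise ValueError("unit_of_analysis must be 'cell' or 'ganglion'")

    groups_present = {k: v for k, v in values.items() if len(v) >= 2}
    if len(groups_present) < 2:
        raise ValueError("ANOVA requires >=2 types with >=2 observations each")
    labels = sorted(groups_present)
    samples = [np.asarray(groups_present[k], dtype=float) for k in labels]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        raise ValueError("all observations identical: ANOVA undefined (zero variance)")
    f_stat, p_val = stats.f_oneway(*samples)
    df_between = len(labels) - 1
    df_within = sum(len(s) for s in samples) - len(labels)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    endog = np.concatenate(samples)
    grp = np.concatenate([[lab] * len(s) for lab, s in zip(labels, samples)])
    tk = pairwise_tukeyhsd(endog, grp, alpha=0.05)
    pairs = [
        TukeyPair(
            group_a=str(a),
            group_b=str(b),
            mean_diff=float(diff),
            ci_low=float(lo),
            ci_high=float(hi),
            p_adj=float(p),
        )
        for (a, b, diff, p, lo, hi, _) in tk.summary().data[1:]
    ]
    return AnovaResult(
        measure=measure,
        unit_of_analysis=unit_of_analysis,
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p_val),
        tukey=pairs,
        group_means={k: float(np.mean(v)) for k, v in groups_present.items()},
    )
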