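"""Bayesian negative-binomial hierarchical trend model.

Counts y_{p,t} for province p (region r(p)) and training year t follow

    y_{p,t} ~ NegBin(mean mu_{p,t}, dispersion theta),  Var = mu + mu^2/theta
    log mu_{p,t} = alpha + u_{r(p)} + v_p + beta * (t - t0) + gamma_t

with region effects u (sum-to-zero), province effects v (sum-to-zero within
region for the nested structure, globally for province-only), a linear
year trend beta, and a first-order random-walk year effect gamma anchored at
gamma_{t0} = 0.  Priors are weakly informative and overridable via
:class:`PriorSpec`.

Posterior inference is a self-contained adaptive Metropolis-within-Gibbs
sampler (:mod:`huntwatch._sampler`), run as >= 2 independent chains;
convergence is summarised with split-R-hat and bulk/tail effective sample
sizes, and a fit with any R-hat above 1.05 is flagged unusable rather than
silently accepted.

Counterfactual forecasts for post-training years extend the random walk
forward (gamma_{T+k} = gamma_{T+k-1} + Normal(0, sigma_gamma)), extrapolate
the linear trend, and draw new counts from the negative binomial, so the
reported median and central 95% interval are full posterior-predictive
quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator

from ._sampler import run_chain
from .panel import LicensePanel, PanelValidationError, SplitSpec

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorDraws",
    "FitDiagnostics",
    "NegativeBinomialTrendModel",
    "fit",
    "predict",
    "log_pointwise_density",
    "loglik_matrix",
    "nb_logpmf",
]

_STRUCTURES = ("region", "province", "nested")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate spatiotemporal structure."""

    label: str = "rw_linear_nested"
    include_linear_trend: bool = True
    rw_order: int = 1
    intercept_structure: str = "nested"

    def __post_init__(self) -> None:
        if self.rw_order not in (0, 1):
            raise ValueError("rw_order must be 0 or 1")
        if self.intercept_structure not in _STRUCTURES:
            raise ValueError(f"intercept_structure must be one of {_STRUCTURES}")

    @property
    def degenerate(self) -> bool:
        """True for the intercept-only baseline (no trend of either kind)."""
        return not self.include_linear_trend and self.rw_order == 0


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative default priors; all overridable.

    ``mu_alpha=None`` centres the intercept prior at the log grand-mean count
    of the training data at fit time.  sigma hyperpriors are half-Normal
    scales; the dispersion prior is Exponential(``inv_dispersion_rate``) on
    1/theta, which is near-flat over the inverse dispersion and admits
    near-Poisson panels.
    """

    mu_alpha: float | None = None
    sd_alpha: float = 1.5
    sd_beta: float = 0.2
    hn_sigma_region: float = 1.0
    hn_sigma_province: float = 1.0
    hn_sigma_rw: float = 0.5
    inv_dispersion_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sd_alpha", "sd_beta", "hn_sigma_region", "hn_sigma_province",
                     "hn_sigma_rw", "inv_dispersion_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (priors must be proper)")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 2
    draws: int = 2500
    warmup: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0:
            raise ValueError("invalid sampler configuration")


@dataclass(frozen=True)
class PosteriorDraws:
    """Posterior draws of all model parameters, with chain layout.

    Arrays have shape (chains, draws) for scalars and (chains, draws, k)
    for vectors; ``gamma`` covers every training year (anchor included),
    ``u``/``v`` are the constrained effect vectors.  The intercept is
    reported in the first-training-year parameterisation
    (log mu = alpha + ... + beta * (t - t0) + gamma_t).
    """

    alpha: np.ndarray
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    sigma_u: np.ndarray
    sigma_v: np.ndarray
    sigma_gamma: np.ndarray
    theta: np.ndarray
    provinces: tuple[str, ...]
    regions: tuple[str, ...]
    region_index: np.ndarray = field(repr=False)
    training_years: tuple[int, ...]
    model_spec: ModelSpec
    seed: int

    @property
    def n_draws_total(self) -> int:
        return int(self.alpha.size)

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    # -- persistence ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        C, S = self.alpha.shape
        cols: dict[str, np.ndarray] = {
            "chain": np.repeat(np.arange(C), S),
            "draw": np.tile(np.arange(S), C),
            "alpha": self.flat("alpha"),
            "beta": self.flat("beta"),
        }
        for i, r in enumerate(self.regions):
            cols[f"u_{r}"] = self.flat("u")[:, i]
        for i, p in enumerate(self.provinces):
            cols[f"v_{p}"] = self.flat("v")[:, i]
        for i, yr in enumerate(self.training_years):
            cols[f"gamma_{yr}"] = self.flat("gamma")[:, i]
        for name in ("sigma_u", "sigma_v", "sigma_gamma", "theta"):
            cols[name] = self.flat(name)
        return pd.DataFrame(cols)

    def meta(self) -> dict:
        return {
            "provinces": list(self.provinces),
            "regions": list(self.regions),
            "region_index": [int(i) for i in self.region_index],
            "training_years": list(self.training_years),
            "model_spec": asdict(self.model_spec),
            "seed": int(self.seed),
        }

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: Mapping) -> "PosteriorDraws":
        C = int(df["chain"].max()) + 1
        S = int(df["draw"].max()) + 1
        regions = tuple(meta["regions"])
        provinces = tuple(meta["provinces"])
        years = tuple(int(y) for y in meta["training_years"])

        def grab(names: Sequence[str]) -> np.ndarray:
            a = df.loc[:, list(names)].to_numpy()
            return a.reshape(C, S, len(names)) if len(names) > 1 or names[0].startswith(("u_", "v_", "gamma_")) else a.reshape(C, S)

        return cls(
            alpha=df["alpha"].to_numpy().reshape(C, S),
            beta=df["beta"].to_numpy().reshape(C, S),
            u=grab([f"u_{r}" for r in regions]),
            v=grab([f"v_{p}" for p in provinces]),
            gamma=grab([f"gamma_{y}" for y in years]),
            sigma_u=df["sigma_u"].to_numpy().reshape(C, S),
            sigma_v=df["sigma_v"].to_numpy().reshape(C, S),
            sigma_gamma=df["sigma_gamma"].to_numpy().reshape(C, S),
            theta=df["theta"].to_numpy().reshape(C, S),
            provinces=provinces,
            regions=regions,
            region_index=np.asarray(meta["region_index"], dtype=np.int64),
            training_years=years,
            model_spec=ModelSpec(**meta["model_spec"]),
            seed=int(meta["seed"]),
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """Split-R-hat / ESS summaries; ``usable`` is False if any R-hat > 1.05."""

    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    acceptance: dict[str, float]
    max_rhat: float
    min_ess_bulk: float
    usable: bool

    def summary(self) -> dict:
        return {
            "max_rhat": self.max_rhat,
            "min_ess_bulk": self.min_ess_bulk,
            "usable": self.usable,
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "ess_tail": self.ess_tail,
            "acceptance": self.acceptance,
        }


# ----------------------------------------------------------------------


def nb_logpmf(y, mu, theta):
    """Negative-binomial log-pmf in the (mean, dispersion) parameterisation."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _as_panel(X) -> LicensePanel:
    if isinstance(X, LicensePanel):
        return X
    if isinstance(X, pd.DataFrame):
        return LicensePanel.from_frame(X)
    raise TypeError(f"expected LicensePanel or DataFrame, got {type(X).__name__}")


def _vgroups(spec: ModelSpec, region_index: np.ndarray, n_regions: int):
    """Free province indices and their absorbing partner for the sum-to-zero
    constraint groups of v."""
    P = region_index.shape[0]
    if spec.intercept_structure == "region" or P == 1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    free, partner = [], []
    if spec.intercept_structure == "nested":
        for r in range(n_regions):
            members = np.flatnonzero(region_index == r)
            if members.size < 2:
                continue
            for p in members[:-1]:
                free.append(p)
                partner.append(members[-1])
    else:  # province-only: one global group
        for p in range(P - 1):
            free.append(p)
            partner.append(P - 1)
    return np.asarray(free, dtype=np.int64), np.asarray(partner, dtype=np.int64)


def _moment_theta(y: np.ndarray, obs: np.ndarray) -> float:
    """Rough pooled method-of-moments dispersion for initialisation."""
    ests = []
    for p in range(y.shape[0]):
        yy = y[p][obs[p]]
        if yy.size < 3:
            continue
        m, s2 = yy.mean(), yy.var(ddof=1)
        if s2 > m > 0:
            ests.append(m * m / (s2 - m))
    if not ests:
        return 500.0
    return float(np.clip(np.median(ests), 2.0, 5000.0))


class NegativeBinomialTrendModel(BaseEstimator):
    """Sklearn-style estimator for the hierarchical NB trend model.

    Parameters
    ----------
    include_linear_trend, rw_order, intercept_structure
        Candidate structure (see :class:`ModelSpec`).
    training_cutoff
        Last training year; panel years after it are held out for
        counterfactual prediction.  ``None`` trains on all panel years.
    priors
        :class:`PriorSpec`; ``None`` uses the documented defaults.
    chains, draws, warmup
        MCMC layout; ``draws`` are post-warmup retained draws per chain.
    pred_reps
        Predictive count replicates drawn per posterior draw (Monte-Carlo
        smoothing of predictive quantiles).
    seed
        Master seed; fixes fit and (by default) prediction randomness.

    Attributes
    ----------
    draws_ : PosteriorDraws
    diagnostics_ : FitDiagnostics
    split_ : SplitSpec
    panel_ : LicensePanel
    """

    def __init__(
        self,
        include_linear_trend: bool = True,
        rw_order: int = 1,
        intercept_structure: str = "nested",
        training_cutoff: int | None = None,
        priors: PriorSpec | None = None,
        chains: int = 2,
        draws: int = 2500,
        warmup: int = 2000,
        pred_reps: int = 5,
        seed: int = 0,
        label: str | None = None,
    ):
        self.include_linear_trend = include_linear_trend
        self.rw_order = rw_order
        self.intercept_structure = intercept_structure
        self.training_cutoff = training_cutoff
        self.priors = priors
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.pred_reps = pred_reps
        self.seed = seed
        self.label = label

    # ------------------------------------------------------------------
    def model_spec(self) -> ModelSpec:
        label = self.label
        if label is None:
            parts = []
            if self.rw_order:
                parts.append("rw")
            if self.include_linear_trend:
                parts.append("linear")
            parts.append(self.intercept_structure)
            label = "_".join(parts) if parts[:-1] else f"intercept_{self.intercept_structure}"
        return ModelSpec(
            label=label,
            include_linear_trend=self.include_linear_trend,
            rw_order=self.rw_order,
            intercept_structure=self.intercept_structure,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y=None, split: SplitSpec | None = None, cells_mask=None):
        """Fit on the training years of the panel.

        Parameters
        ----------
        X
            :class:`LicensePanel` or long-format frame.
        split
            Overrides ``training_cutoff``.
        cells_mask
            Optional boolean (province, training-year) array; False cells are
            treated as unobserved (used for exact leave-one-out refits).
        """
        panel = _as_panel(X)
        if split is None:
            cutoff = self.training_cutoff
            if cutoff is None:
                cutoff = max(panel.years)
            split = SplitSpec.from_cutoff(panel.years, cutoff)
        spec = self.model_spec()
        priors = self.priors if self.priors is not None else PriorSpec()

        years = [y_ for y_ in split.sorted_training if y_ in panel.years]
        if len(years) < 3:
            raise PanelValidationError("need at least 3 training years")
        provinces = panel.provinces
        regions = panel.regions
        r_of = {r: i for i, r in enumerate(regions)}
        region_index = np.asarray(
            [r_of[panel.region_of[p]] for p in provinces], dtype=np.int64
        )
        P, T, R = len(provinces), len(years), len(regions)

        ymat = np.zeros((P, T))
        obs = np.zeros((P, T), dtype=np.bool_)
        for i, p in enumerate(provinces):
            for j, yr in enumerate(years):
                c = panel.get(p, yr)
                if c is not None:
                    ymat[i, j] = c
                    obs[i, j] = True
        if cells_mask is not None:
            obs = obs & np.asarray(cells_mask, dtype=bool)
        short = [provinces[i] for i in range(P) if obs[i].sum() < 3]
        if short:
            raise PanelValidationError(
                f"provinces with fewer than 3 observed training years: {short}"
            )

        t_idx = np.arange(T, dtype=float)
        tbar = t_idx.mean()
        tc = t_idx - tbar

        use_linear = bool(spec.include_linear_trend)
        use_rw = spec.rw_order == 1 and T > 1
        use_u = spec.intercept_structure in ("region", "nested") and R > 1
        vfree, vpartner = _vgroups(spec, region_index, R)
        use_v = vfree.size > 0

        mu_alpha = (
            priors.mu_alpha
            if priors.mu_alpha is not None
            else float(np.log(max(ymat[obs].mean(), 1.0)))
        )
        theta0 = _moment_theta(ymat, obs)

        # flat province list per region for the kernel
        order = np.argsort(region_index, kind="stable")
        region_rows_flat = order.astype(np.int64)
        counts_per_region = np.bincount(region_index, minlength=R)
        region_rows_off = np.concatenate([[0], np.cumsum(counts_per_region)]).astype(
            np.int64
        )

        ss = np.random.SeedSequence(int(self.seed))
        chain_seeds = [int(s) for s in ss.generate_state(self.chains, dtype=np.uint32) >> 1]
        jit_rng = np.random.default_rng(ss.spawn(1)[0])

        dim = 2 + R + P + T + 4
        chain_draws = []
        acc_rates = []
        for c in range(self.chains):
            init = np.zeros(dim)
            init[0] = mu_alpha + (0.0 if c == 0 else jit_rng.normal(0.0, 0.3))
            init[1] = 0.0 if (c == 0 or not use_linear) else jit_rng.normal(0.0, 0.05)
            init[dim - 4] = 0.1 * np.exp(jit_rng.normal(0.0, 0.3) if c else 0.0)
            init[dim - 3] = 0.1 * np.exp(jit_rng.normal(0.0, 0.3) if c else 0.0)
            init[dim - 2] = 0.05 * np.exp(jit_rng.normal(0.0, 0.3) if c else 0.0)
            init[dim - 1] = theta0 * np.exp(0.0 if c == 0 else jit_rng.normal(0.0, 0.5))
            d, rates = run_chain(
                ymat,
                obs,
                region_index,
                region_rows_flat,
                region_rows_off,
                vfree,
                vpartner,
                tc,
                use_linear,
                use_u,
                use_v,
                use_rw,
                mu_alpha,
                priors.sd_alpha,
                priors.sd_beta,
                priors.hn_sigma_region,
                priors.hn_sigma_province,
                priors.hn_sigma_rw,
                priors.inv_dispersion_rate,
                int(self.warmup),
                int(self.draws),
                chain_seeds[c],
                init,
            )
            chain_draws.append(d)
            acc_rates.append(rates)

        arr = np.stack(chain_draws)  # (C, S, dim)
        alpha_int = arr[:, :, 0]
        beta = arr[:, :, 1]
        alpha = alpha_int - beta * tbar  # first-training-year parameterisation
        u = arr[:, :, 2 : 2 + R]
        v = arr[:, :, 2 + R : 2 + R + P]
        gamma = arr[:, :, 2 + R + P : 2 + R + P + T]
        sig = arr[:, :, 2 + R + P + T :]

        self.draws_ = PosteriorDraws(
            alpha=alpha,
            beta=beta,
            u=u,
            v=v,
            gamma=gamma,
            sigma_u=sig[:, :, 0],
            sigma_v=sig[:, :, 1],
            sigma_gamma=sig[:, :, 2],
            theta=sig[:, :, 3],
            provinces=tuple(provinces),
            regions=tuple(regions),
            region_index=region_index,
            training_years=tuple(years),
            model_spec=spec,
            seed=int(self.seed),
        )
        self.panel_ = panel
        self.split_ = split
        self.diagnostics_ = _diagnostics(
            self.draws_,
            active=dict(
                beta=use_linear, u=use_u, v=use_v, gamma=use_rw,
                sigma_u=use_u, sigma_v=use_v, sigma_gamma=use_rw,
            ),
            acceptance=np.mean(acc_rates, axis=0),
        )
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted; call fit() first")

    def predictive_draws(
        self,
        years: Iterable[int],
        seed: int | None = None,
        pred_reps: int | None = None,
    ) -> tuple[np.ndarray, tuple[str, ...], tuple[int, ...]]:
        """Posterior-predictive count draws for the panel's provinces.

        Returns (draws, provinces, years) with draws of shape
        (S * pred_reps, P, K).
        """
        self._check_fitted()
        return predictive_draws(
            self.draws_,
            years,
            seed=self.seed if seed is None else seed,
            pred_reps=self.pred_reps if pred_reps is None else pred_reps,
        )

    def predictive_summary(
        self,
        years: Iterable[int] | None = None,
        seed: int | None = None,
        pred_reps: int | None = None,
    ) -> pd.DataFrame:
        """Per (province, year) counterfactual median and central 95% interval."""
        self._check_fitted()
        if years is None:
            years = self.split_.sorted_evaluation
        years = tuple(int(y) for y in years)
        if not years:
            raise ValueError("no evaluation years requested or available")
        sims, provinces, years = self.predictive_draws(years, seed=seed, pred_reps=pred_reps)
        lo, med, hi = np.percentile(sims, [2.5, 50.0, 97.5], axis=0)
        rows = []
        region_of = self.panel_.region_of
        for j, yr in enumerate(years):
            for i, p in enumerate(provinces):
                rows.append(
                    (p, region_of[p], yr, float(med[i, j]), float(lo[i, j]), float(hi[i, j]))
                )
        return pd.DataFrame(
            rows, columns=["province", "region", "year", "median", "lo95", "hi95"]
        )

    def predict(self, X) -> np.ndarray:
        """Predictive median counts for rows of X (province, year columns)."""
        self._check_fitted()
        df = X.to_frame() if isinstance(X, LicensePanel) else pd.DataFrame(X)
        years = tuple(sorted(set(int(y) for y in df["year"])))
        summ = self.predictive_summary(years=years)
        key = summ.set_index(["province", "year"])["median"]
        return np.asarray(
            [key.loc[(str(p), int(y))] for p, y in zip(df["province"], df["year"])]
        )

    def log_pointwise_density(self, cells: Iterable[tuple[str, int]] | None = None):
        self._check_fitted()
        return log_pointwise_density(self.draws_, self.panel_, cells)


# ----------------------------------------------------------------------
# functional API (thin wrappers; PosteriorDraws is self-describing)


def fit(
    panel: LicensePanel,
    split: SplitSpec,
    model_spec: ModelSpec | None = None,
    prior_spec: PriorSpec | None = None,
    sampler_config: SamplerConfig | None = None,
) -> tuple[PosteriorDraws, FitDiagnostics]:
    spec = model_spec or ModelSpec()
    cfg = sampler_config or SamplerConfig()
    est = NegativeBinomialTrendModel(
        include_linear_trend=spec.include_linear_trend,
        rw_order=spec.rw_order,
        intercept_structure=spec.intercept_structure,
        priors=prior_spec,
        chains=cfg.chains,
        draws=cfg.draws,
        warmup=cfg.warmup,
        seed=cfg.seed,
        label=spec.label,
    )
    est.fit(panel, split=split)
    return est.draws_, est.diagnostics_


def predictive_draws(
    draws: PosteriorDraws,
    years: Iterable[int],
    seed: int = 0,
    pred_reps: int = 5,
) -> tuple[np.ndarray, tuple[str, ...], tuple[int, ...]]:
    """Forward-simulate posterior-predictive counts for post-training years."""
    years = tuple(int(y) for y in years)
    last = max(draws.training_years)
    t0 = min(draws.training_years)
    bad = [y for y in years if y <= last]
    if bad:
        raise ValueError(
            f"evaluation years {bad} do not lie after the last training year {last}"
        )
    spec = draws.model_spec
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))

    alpha = draws.flat("alpha")
    beta = draws.flat("beta") if spec.include_linear_trend else 0.0
    u = draws.flat("u")
    v = draws.flat("v")
    sigma_g = draws.flat("sigma_gamma")
    theta = draws.flat("theta")
    S = alpha.shape[0]
    P = len(draws.provinces)
    K = len(years)

    max_step = max(y - last for y in years)
    if spec.rw_order == 1:
        g_last = draws.flat("gamma")[:, -1]
        eps = rng.normal(0.0, 1.0, size=(S, max_step)) * sigma_g[:, None]
        g_path = g_last[:, None] + np.cumsum(eps, axis=1)  # (S, max_step)
        g_future = np.stack([g_path[:, y - last - 1] for y in years], axis=1)
    else:
        g_future = np.zeros((S, K))

    t_rel = np.asarray([y - t0 for y in years], dtype=float)
    eta = (
        alpha[:, None, None]
        + u[:, draws.region_index][:, :, None]
        + v[:, :, None]
        + (beta[:, None, None] * t_rel[None, None, :] if spec.include_linear_trend else 0.0)
        + g_future[:, None, :]
    )
    mu = np.exp(eta)  # (S, P, K)
    reps = int(pred_reps)
    mu_r = np.repeat(mu, reps, axis=0)
    th_r = np.repeat(theta, reps)[:, None, None]
    sims = rng.negative_binomial(th_r, th_r / (th_r + mu_r))
    return sims, draws.provinces, years


def predict(
    draws: PosteriorDraws,
    evaluation_years: Iterable[int],
    seed: int = 0,
    pred_reps: int = 5,
    region_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """PredictiveSummary frame: province, region, year, median, lo95, hi95."""
    sims, provinces, years = predictive_draws(
        draws, evaluation_years, seed=seed, pred_reps=pred_reps
    )
    lo, med, hi = np.percentile(sims, [2.5, 50.0, 97.5], axis=0)
    if region_of is None:
        region_of = {
            p: draws.regions[draws.region_index[i]] for i, p in enumerate(provinces)
        }
    rows = [
        (p, region_of[p], yr, float(med[i, j]), float(lo[i, j]), float(hi[i, j]))
        for j, yr in enumerate(years)
        for i, p in enumerate(provinces)
    ]
    return pd.DataFrame(
        rows, columns=["province", "region", "year", "median", "lo95", "hi95"]
    )


def loglik_matrix(
    draws: PosteriorDraws,
    panel: LicensePanel,
    cells: Sequence[tuple[str, int]] | None = None,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """(S, N) matrix of per-draw NB log-pmf at the requested training cells."""
    spec = draws.model_spec
    p_of = {p: i for i, p in enumerate(draws.provinces)}
    t0 = min(draws.training_years)
    y_of = {yr: j for j, yr in enumerate(draws.training_years)}
    if cells is None:
        cells = [
            (p, yr)
            for p in draws.provinces
            for yr in draws.training_years
            if panel.get(p, yr) is not None
        ]
    kept: list[tuple[str, int]] = []
    skipped: list[tuple[str, int]] = []
    for p, yr in cells:
        if yr not in y_of or p not in p_of or panel.get(p, yr) is None:
            skipped.append((p, yr))
        else:
            kept.append((p, int(yr)))
    if skipped:
        warnings.warn(f"cells excluded from log-density: {skipped}", stacklevel=2)
    if not kept:
        raise ValueError("no usable cells for log-density evaluation")

    alpha = draws.flat("alpha")
    beta = draws.flat("beta")
    u = draws.flat("u")
    v = draws.flat("v")
    gamma = draws.flat("gamma")
    theta = draws.flat("theta")

    pi = np.asarray([p_of[p] for p, _ in kept])
    ti = np.asarray([y_of[yr] for _, yr in kept])
    yy = np.asarray([panel.get(p, yr) for p, yr in kept], dtype=float)

    eta = alpha[:, None] + u[:, draws.region_index[pi]] + v[:, pi]
    if spec.include_linear_trend:
        t_rel = np.asarray([yr - t0 for _, yr in kept], dtype=float)
        eta = eta + beta[:, None] * t_rel[None, :]
    if spec.rw_order == 1:
        eta = eta + gamma[:, ti]
    mu = np.exp(eta)
    return nb_logpmf(yy[None, :], mu, theta[:, None]), kept


def log_pointwise_density(
    draws: PosteriorDraws,
    panel: LicensePanel,
    cells: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-cell log predictive density, log-mean-exp over posterior draws."""
    ll, kept = loglik_matrix(draws, panel, cells)
    lpd = logsumexp(ll, axis=0) - np.log(ll.shape[0])
    return pd.DataFrame(
        {
            "province": [p for p, _ in kept],
            "year": [yr for _, yr in kept],
            "lpd": lpd,
        }
    )


# ----------------------------------------------------------------------


def _diagnostics(
    draws: PosteriorDraws, active: Mapping[str, bool], acceptance: np.ndarray
) -> FitDiagnostics:
    import arviz as az

    post = {"alpha": draws.alpha, "theta": draws.theta}
    if active.get("beta"):
        post["beta"] = draws.beta
    if active.get("u"):
        post["u"] = draws.u
        post["sigma_u"] = draws.sigma_u
    if active.get("v"):
        post["v"] = draws.v
        post["sigma_v"] = draws.sigma_v
    if active.get("gamma"):
        post["gamma"] = draws.gamma[:, :, 1:]  # anchor is constant
        post["sigma_gamma"] = draws.sigma_gamma
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=post)
        rhat = az.rhat(idata)
        essb = az.ess(idata, method="bulk")
        esst = az.ess(idata, method="tail")

    def collapse(ds, fn):
        return {k: float(fn(ds[k].values)) for k in post}

    rh = collapse(rhat, np.nanmax)
    eb = collapse(essb, np.nanmin)
    et = collapse(esst, np.nanmin)
    if draws.alpha.shape[0] < 2:
        # single chain: split-rhat still defined by arviz; keep as-is
        pass
    max_rhat = float(np.nanmax(list(rh.values())))
    min_ess = float(np.nanmin(list(eb.values())))
    return FitDiagnostics(
        rhat=rh,
        ess_bulk=eb,
        ess_tail=et,
        acceptance={"mean_site_acceptance": float(np.nanmean(acceptance))},
        max_rhat=max_rhat,
        min_ess_bulk=min_ess,
        usable=bool(max_rhat <= 1.05),
    )
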