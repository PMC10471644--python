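"""Hierarchical Bayesian ANCOVA for community PUFA responses.

The model explains a per-site community response C_ij (site i nested in lake
j) with a linear predictor

    η_ij = β_0i(j) + β_1k(ij) + β_2l(ij) + β_3m(ij) + Σ_n β_n · ln X_nij

where β_0i(j) is a site intercept drawn from a lake-level normal
N(β_0j, σ²_0j), the lake means β_0j are drawn from N(μ_0, τ²_0), the
categorical blocks (lake type k, vegetation l, substrate m) are constrained
to sum to zero, and the continuous covariates X_n (latitude, color, pH, TP,
TN) enter on the natural-log scale.  Three observation families are
supported:

* ``normal-on-log`` — ln(C_ij) ~ N(η_ij, σ²), for positive responses;
* ``poisson`` — C_ij ~ Poisson(exp(η_ij)), for counts;
* ``binomial-logit`` — C_ij ~ Bin(logit⁻¹(η_ij), Richness_ij), for counts of
  PUFA-rich taxa relative to site richness.

Priors: all location effects N(0, 10⁴); all precisions Gamma(0.001, 0.001)
(shape, rate).  Sampling uses component-wise random-walk Metropolis with a
symmetric normal proposal whose standard deviation is tuned during an initial
adaptation phase toward a 20–40% acceptance rate, combined with conjugate
Gibbs draws for the pure-hierarchy nodes (lake means, variances and
hyperparameters), the classical sampler assignment for this model class.
Convergence is monitored with the Brooks–Gelman corrected potential
scale-reduction factor and the Monte-Carlo error relative to the posterior
SD; model comparison uses DIC = D̄(θ) + pD with pD = D̄(θ) − D(θ̄).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data_model import SurveySample

__all__ = [
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_TERMS",
    "ModelSpec",
    "ParameterState",
    "FitResult",
    "ModelRanking",
    "linear_predictor",
    "log_likelihood",
    "fit",
    "gelman_rubin",
    "mc_error_ratio",
    "dic",
    "select_model",
]

CONTINUOUS_COVARIATES = ("latitude", "color", "ph", "tp", "tn")
CATEGORICAL_TERMS = ("lake_type", "vegetation", "substrate")
FAMILIES = ("normal-on-log", "poisson", "binomial-logit")

_PRIOR_VAR = 1.0e4  # N(0, 10000) on every location effect
_GAMMA_A = 0.001  # Gamma(shape, rate) on every precision
_GAMMA_B = 0.001
_ADAPT_BATCH = 50
_ADAPT_FACTOR = 1.1
_TARGET_LOW, _TARGET_HIGH = 0.2, 0.4


@dataclass(frozen=True)
class ModelSpec:
    """Which response is modelled, under which family, with which terms."""

    response: str
    family: str
    categorical_terms: tuple[str, ...] = ()
    continuous_terms: tuple[str, ...] = ()
    binomial_size_field: str = "richness"
    pooled_intercept: bool = False
    shared_lake_variance: bool = False
    log_latitude: bool = True
    center_covariates: bool = True
    fixed_sigma2: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        for term in self.categorical_terms:
            if term not in CATEGORICAL_TERMS:
                raise ValueError(f"unknown categorical term {term!r}")
        for term in self.continuous_terms:
            if term not in CONTINUOUS_COVARIATES:
                raise ValueError(f"unknown continuous term {term!r}")
        if self.fixed_sigma2 is not None and self.fixed_sigma2 <= 0:
            raise ValueError("fixed_sigma2 must be positive")
        object.__setattr__(self, "categorical_terms", tuple(self.categorical_terms))
        object.__setattr__(self, "continuous_terms", tuple(self.continuous_terms))


@dataclass(frozen=True)
class ParameterState:
    """A full set of model parameters, keyed by domain labels.

    Used for forward simulation and for oracle evaluation of the linear
    predictor; the sampler works on an equivalent packed representation.
    ``cat_effects`` maps term → level → effect and each block should sum to
    zero; ``sigma2_0lake`` may be a single shared variance or a per-lake map.
    """

    beta0_site: Mapping[tuple[str, str], float] = field(default_factory=dict)
    beta0_lake: Mapping[str, float] = field(default_factory=dict)
    sigma2_0lake: Mapping[str, float] | float = 1.0
    mu0: float = 0.0
    tau2_0: float = 1.0
    cat_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    beta_cont: Mapping[str, float] = field(default_factory=dict)
    sigma2: float | None = None

    def zero_sum_residuals(self) -> dict[str, float]:
        """Absolute block sums of the categorical effects (0 when constrained)."""
        return {
            term: abs(float(sum(levels.values())))
            for term, levels in self.cat_effects.items()
        }


def _covariate_value(spec: ModelSpec, sample: SurveySample, name: str) -> float:
    x = float(getattr(sample, name))
    if name == "latitude" and not spec.log_latitude:
        return x
    return math.log(x)


def linear_predictor(state: ParameterState, spec: ModelSpec, sample: SurveySample) -> float:
    """η for one site under the model block (no covariate centring)."""
    key = (sample.lake_id, sample.site_id)
    if spec.pooled_intercept:
        eta = state.mu0
    else:
        try:
            eta = float(state.beta0_site[key])
        except KeyError as exc:
            raise KeyError(f"no site intercept for {key}") from exc
    for term in spec.categorical_terms:
        block = state.cat_effects.get(term)
        if block is None:  # term carries no effects in this state
            continue
        level = getattr(sample, term)
        try:
            eta += float(block[level])
        except KeyError as exc:
            raise KeyError(f"unknown {term} level {level!r}") from exc
    for name in spec.continuous_terms:
        eta += float(state.beta_cont.get(name, 0.0)) * _covariate_value(spec, sample, name)
    return eta


def _family_loglik(family: str, y, eta, sigma2=None, size=None):
    """Element-wise observation log-density (includes all constants)."""
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if family == "normal-on-log":
        z = np.log(y)
        return -0.5 * np.log(2.0 * np.pi * sigma2) - (z - eta) ** 2 / (2.0 * sigma2)
    if family == "poisson":
        return y * eta - np.exp(eta) - gammaln(y + 1.0)
    if family == "binomial-logit":
        size = np.asarray(size, dtype=float)
        log_binom = gammaln(size + 1.0) - gammaln(y + 1.0) - gammaln(size - y + 1.0)
        return log_binom + y * eta - size * np.logaddexp(0.0, eta)
    raise ValueError(f"unknown family {family!r}")


def log_likelihood(
    state: ParameterState,
    spec: ModelSpec,
    samples: Sequence[SurveySample],
    responses: Mapping[tuple[str, str], float] | pd.DataFrame,
) -> float:
    """Total observation log-likelihood of ``responses`` under ``state``."""
    values = _response_lookup(responses, spec.response)
    total = 0.0
    for sample in samples:
        y = values[(sample.lake_id, sample.site_id)]
        eta = linear_predictor(state, spec, sample)
        size = None
        if spec.family == "binomial-logit":
            size = _binomial_size(spec, sample, responses)
            if not (0 <= y <= size):
                raise ValueError("binomial response must satisfy 0 <= y <= size")
        if spec.family == "normal-on-log" and y <= 0:
            raise ValueError("normal-on-log family requires strictly positive responses")
        sigma2 = spec.fixed_sigma2 if state.sigma2 is None else state.sigma2
        total += float(
            _family_loglik(spec.family, [y], [eta], sigma2=sigma2, size=[size] if size is not None else None)[0]
        )
    return total


def _response_lookup(responses, column: str) -> dict[tuple[str, str], float]:
    if isinstance(responses, pd.DataFrame):
        if column not in responses.columns:
            raise KeyError(f"responses table has no column {column!r}")
        return {
            (str(r.lake_id), str(r.site_id)): float(getattr(r, column))
            for r in responses.itertuples(index=False)
        }
    return {k: float(v) for k, v in responses.items()}


def _binomial_size(spec: ModelSpec, sample: SurveySample, responses) -> float:
    if isinstance(responses, pd.DataFrame) and spec.binomial_size_field in responses.columns:
        lookup = _response_lookup(responses, spec.binomial_size_field)
        return lookup[(sample.lake_id, sample.site_id)]
    return float(getattr(sample, spec.binomial_size_field))


# ---------------------------------------------------------------------------
# Packed model data
# ---------------------------------------------------------------------------


class _ModelData:
    """Arrays aligned to the site rows, plus the parameter-vector layout."""

    def __init__(self, spec: ModelSpec, samples: Sequence[SurveySample], responses):
        self.spec = spec
        values = _response_lookup(responses, spec.response)
        missing = [
            (s.lake_id, s.site_id)
            for s in samples
            if (s.lake_id, s.site_id) not in values
        ]
        if missing:
            raise KeyError(f"responses missing for sites: {missing[:5]}")
        self.site_keys = [(s.lake_id, s.site_id) for s in samples]
        self.y = np.array([values[k] for k in self.site_keys], dtype=float)
        self.n = len(samples)

        lakes: list[str] = []
        for s in samples:
            if s.lake_id not in lakes:
                lakes.append(s.lake_id)
        self.lake_labels = lakes
        self.n_lakes = len(lakes)
        lake_pos = {l: i for i, l in enumerate(lakes)}
        self.lake_idx = np.array([lake_pos[s.lake_id] for s in samples], dtype=int)
        if not spec.pooled_intercept and self.n_lakes < 2:
            raise ValueError("need at least 2 lakes for the nested-intercept model")

        self.size = None
        if spec.family == "binomial-logit":
            self.size = np.array(
                [_binomial_size(spec, s, responses) for s in samples], dtype=float
            )
            if np.any(self.y < 0) or np.any(self.y > self.size):
                raise ValueError("binomial response must satisfy 0 <= y <= size")
        if spec.family == "normal-on-log" and np.any(self.y <= 0):
            raise ValueError("normal-on-log family requires strictly positive responses")
        if spec.family in ("poisson", "binomial-logit") and np.any(self.y != np.round(self.y)):
            raise ValueError(f"{spec.family} family requires integer responses")

        # categorical blocks
        self.cat_levels: dict[str, list[str]] = {}
        self.cat_idx: dict[str, np.ndarray] = {}
        for term in spec.categorical_terms:
            labels = sorted({str(getattr(s, term)) for s in samples})
            if len(labels) < 2:
                raise ValueError(f"categorical term {term!r} has fewer than 2 levels")
            pos = {l: i for i, l in enumerate(labels)}
            self.cat_levels[term] = labels
            self.cat_idx[term] = np.array(
                [pos[str(getattr(s, term))] for s in samples], dtype=int
            )

        # continuous covariates, on the (log) model scale, optionally centred
        self.cont_names = list(spec.continuous_terms)
        X = np.empty((self.n, len(self.cont_names)))
        for p, name in enumerate(self.cont_names):
            X[:, p] = [_covariate_value(spec, s, name) for s in samples]
        self.x_means = X.mean(axis=0) if (spec.center_covariates and X.size) else np.zeros(X.shape[1])
        self.X = X - self.x_means
        # per-lake covariate means, used by the ridge-shift sampler moves
        counts = np.bincount(self.lake_idx, minlength=self.n_lakes).astype(float)
        self.x_lake_mean = np.empty((self.n_lakes, self.X.shape[1]))
        for p in range(self.X.shape[1]):
            self.x_lake_mean[:, p] = (
                np.bincount(self.lake_idx, weights=self.X[:, p], minlength=self.n_lakes)
                / counts
            )

        # observation scale for the normal family
        self.z = np.log(self.y) if spec.family == "normal-on-log" else None

        # parameter-vector layout
        names: list[str] = []
        if spec.pooled_intercept:
            names.append("beta0")
        else:
            names += [f"beta0_site[{l}:{s}]" for l, s in self.site_keys]
            names += [f"beta0_lake[{l}]" for l in lakes]
            if spec.shared_lake_variance:
                names.append("sigma2_0lake")
            else:
                names += [f"sigma2_0lake[{l}]" for l in lakes]
            names += ["mu0", "tau2_0"]
        for term in spec.categorical_terms:
            names += [f"beta_{term}[{lvl}]" for lvl in self.cat_levels[term]]
        names += [f"beta_{name}" for name in self.cont_names]
        self.estimate_sigma2 = spec.family == "normal-on-log" and spec.fixed_sigma2 is None
        if self.estimate_sigma2:
            names.append("sigma2")
        self.param_names = names

    # -- likelihood helpers -------------------------------------------------

    def loglik(self, eta: np.ndarray, sigma2: float | None, rows=None) -> np.ndarray:
        y = self.y if rows is None else self.y[rows]
        size = None if self.size is None else (self.size if rows is None else self.size[rows])
        if self.spec.family == "normal-on-log":
            z = self.z if rows is None else self.z[rows]
            return -0.5 * np.log(2.0 * np.pi * sigma2) - (z - eta) ** 2 / (2.0 * sigma2)
        return _family_loglik(self.spec.family, y, eta, sigma2=sigma2, size=size)

    def initial_eta_scale(self) -> np.ndarray:
        """Crude per-site location on the linear-predictor scale, for inits."""
        if self.spec.family == "normal-on-log":
            return self.z.copy()
        if self.spec.family == "poisson":
            return np.log(self.y + 0.5)
        p = (self.y + 0.5) / (self.size + 1.0)
        return np.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Posterior draws, diagnostics and DIC components for one fitted model."""

    spec: ModelSpec
    param_names: list[str]
    chains: list[np.ndarray]  # each (n_draws, n_params)
    deviances: list[np.ndarray]
    acceptance_rates: dict[str, float]
    gelman_rubin: np.ndarray | None
    mc_error_ratio: np.ndarray
    dbar: float
    d_at_mean: float
    pd: float
    dic: float
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return sum(c.shape[0] for c in self.chains)

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.chains, axis=0)

    def draws(self, name: str) -> np.ndarray:
        try:
            col = self.param_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc
        return self.pooled()[:, col]

    def posterior_mean(self, name: str) -> float:
        return float(self.draws(name).mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        d = self.draws(name)
        return float(np.quantile(d, lo)), float(np.quantile(d, 1.0 - lo))

    def summary(self) -> pd.DataFrame:
        pooled = self.pooled()
        frame = pd.DataFrame(
            {
                "mean": pooled.mean(axis=0),
                "sd": pooled.std(axis=0, ddof=1),
                "q2.5": np.quantile(pooled, 0.025, axis=0),
                "q50": np.quantile(pooled, 0.5, axis=0),
                "q97.5": np.quantile(pooled, 0.975, axis=0),
                "mc_error_ratio": self.mc_error_ratio,
            },
            index=pd.Index(self.param_names, name="parameter"),
        )
        if self.gelman_rubin is not None:
            frame["rhat"] = self.gelman_rubin
        return frame


def dic(fit_result: FitResult) -> tuple[float, float, float]:
    """(D̄, pD, DIC) of a fitted model."""
    return fit_result.dbar, fit_result.pd, fit_result.dic


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


class _Chain:
    """One MCMC chain over the packed state."""

    def __init__(self, data: _ModelData, rng: np.random.Generator, n_adapt: int):
        self.data = data
        self.spec = data.spec
        self.rng = rng
        self.n_adapt = n_adapt
        n, J = data.n, data.n_lakes
        base = data.initial_eta_scale()

        # crude least-squares starting values for the covariate coefficients
        # (chains start near the mode; jitter keeps them overdispersed)
        self.beta = np.zeros(len(data.cont_names))
        if self.beta.size:
            centred = base - base.mean()
            sol, *_ = np.linalg.lstsq(data.X, centred, rcond=None)
            self.beta = sol + rng.normal(0.0, 0.1 + 0.05 * np.abs(sol))
            base = base - data.X @ self.beta

        if self.spec.pooled_intercept:
            self.b0 = float(base.mean() + rng.normal(0.0, 0.3))
        else:
            self.b_site = base + rng.normal(0.0, 0.1, size=n)
            self.b_lake = np.array(
                [self.b_site[data.lake_idx == j].mean() for j in range(J)]
            ) + rng.normal(0.0, 0.1, size=J)
            self.mu0 = float(self.b_lake.mean() + rng.normal(0.0, 0.1))
            # start the variance hyperparameters at the init residual scales so
            # the chain begins at a coherent point of the hierarchy
            self.tau2 = float(max(self.b_lake.var(), 1e-3))
            within = float(max((self.b_site - self.b_lake[data.lake_idx]).var(), 1e-3))
            self.s2_lake = (
                np.array([within])
                if self.spec.shared_lake_variance
                else np.full(J, within)
            )
        self.cat_free = {
            t: np.zeros(len(data.cat_levels[t]) - 1) for t in self.spec.categorical_terms
        }
        self.cat_full = {
            t: np.zeros(len(data.cat_levels[t])) for t in self.spec.categorical_terms
        }
        if self.spec.family == "normal-on-log":
            if self.spec.fixed_sigma2 is not None:
                self.sigma2 = float(self.spec.fixed_sigma2)
            else:
                resid = data.z - base
                self.sigma2 = float(max(resid.var() + 0.05, 0.05))
        else:
            self.sigma2 = None

        # adaptation state
        self.sd_site = np.full(n, 0.2) if not self.spec.pooled_intercept else None
        self.acc_site = np.zeros(n) if not self.spec.pooled_intercept else None
        self.sd_b0 = 0.2
        self.acc_b0 = 0.0
        self.sd_cat = {t: np.full(v.size, 0.2) for t, v in self.cat_free.items()}
        self.acc_cat = {t: np.zeros(v.size) for t, v in self.cat_free.items()}
        self.sd_beta = np.full(self.beta.size, 0.1)
        self.acc_beta = np.zeros(self.beta.size)
        self.sd_shift = np.full(self.beta.size, 1.0)
        self.acc_shift = np.zeros(self.beta.size)
        self.total_acc: dict[str, float] = {}
        self.total_n: dict[str, float] = {}

        self.cat_rows = {
            t: [np.flatnonzero(data.cat_idx[t] == k) for k in range(len(data.cat_levels[t]))]
            for t in self.spec.categorical_terms
        }

    # -- helpers ------------------------------------------------------------

    def eta(self) -> np.ndarray:
        data = self.data
        if self.spec.pooled_intercept:
            out = np.full(data.n, self.b0)
        else:
            out = self.b_site.copy()
        for t in self.spec.categorical_terms:
            out += self.cat_full[t][data.cat_idx[t]]
        if self.beta.size:
            out += data.X @ self.beta
        return out

    def _count(self, key: str, accepted: float, proposed: float) -> None:
        self.total_acc[key] = self.total_acc.get(key, 0.0) + accepted
        self.total_n[key] = self.total_n.get(key, 0.0) + proposed

    def _site_prior_moments(self) -> tuple[np.ndarray, np.ndarray]:
        data = self.data
        mean = self.b_lake[data.lake_idx]
        if self.spec.shared_lake_variance:
            var = np.full(data.n, self.s2_lake[0])
        else:
            var = self.s2_lake[data.lake_idx]
        return mean, var

    # -- one iteration ------------------------------------------------------

    def step(self, iteration: int) -> None:
        data, rng = self.data, self.rng
        eta = self.eta()
        ll = data.loglik(eta, self.sigma2)
        adapting = iteration <= self.n_adapt

        # 1. intercepts (Metropolis)
        if self.spec.pooled_intercept:
            delta = rng.normal(0.0, self.sd_b0)
            new_eta = eta + delta
            new_ll = data.loglik(new_eta, self.sigma2)
            dlp = new_ll.sum() - ll.sum() + (self.b0**2 - (self.b0 + delta) ** 2) / (2 * _PRIOR_VAR)
            if math.log(rng.uniform()) < dlp:
                self.b0 += delta
                eta, ll = new_eta, new_ll
                self.acc_b0 += 1
                self._count("beta0", 1, 1)
            else:
                self._count("beta0", 0, 1)
        else:
            prior_mean, prior_var = self._site_prior_moments()
            eps = rng.normal(0.0, self.sd_site)
            new_eta = eta + eps
            new_ll = data.loglik(new_eta, self.sigma2)
            dprior = (
                (self.b_site - prior_mean) ** 2 - (self.b_site + eps - prior_mean) ** 2
            ) / (2.0 * prior_var)
            accept = np.log(rng.uniform(size=data.n)) < (new_ll - ll + dprior)
            self.b_site += eps * accept
            eta = np.where(accept, new_eta, eta)
            ll = np.where(accept, new_ll, ll)
            self.acc_site += accept
            self._count("beta0_site", float(accept.sum()), data.n)

            # 2. lake means (Gibbs)
            J = data.n_lakes
            n_j = np.bincount(data.lake_idx, minlength=J).astype(float)
            sum_j = np.bincount(data.lake_idx, weights=self.b_site, minlength=J)
            s2 = np.full(J, self.s2_lake[0]) if self.spec.shared_lake_variance else self.s2_lake
            prec = n_j / s2 + 1.0 / self.tau2
            mean = (sum_j / s2 + self.mu0 / self.tau2) / prec
            self.b_lake = mean + rng.standard_normal(J) / np.sqrt(prec)

            # 3. lake variances (Gibbs)
            resid2 = np.bincount(
                data.lake_idx,
                weights=(self.b_site - self.b_lake[data.lake_idx]) ** 2,
                minlength=J,
            )
            if self.spec.shared_lake_variance:
                shape = _GAMMA_A + 0.5 * data.n
                rate = _GAMMA_B + 0.5 * resid2.sum()
                self.s2_lake = np.array([1.0 / rng.gamma(shape, 1.0 / rate)])
            else:
                shape = _GAMMA_A + 0.5 * n_j
                rate = _GAMMA_B + 0.5 * resid2
                self.s2_lake = 1.0 / rng.gamma(shape, 1.0 / rate)

            # 4. hypermean and hypervariance (Gibbs)
            prec0 = J / self.tau2 + 1.0 / _PRIOR_VAR
            mean0 = (self.b_lake.sum() / self.tau2) / prec0
            self.mu0 = float(mean0 + rng.standard_normal() / math.sqrt(prec0))
            shape = _GAMMA_A + 0.5 * J
            rate = _GAMMA_B + 0.5 * float(np.sum((self.b_lake - self.mu0) ** 2))
            self.tau2 = float(1.0 / rng.gamma(shape, 1.0 / rate))

        # 5. zero-sum categorical effects (Metropolis on the free components)
        for term in self.spec.categorical_terms:
            rows = self.cat_rows[term]
            free = self.cat_free[term]
            full = self.cat_full[term]
            last = len(rows) - 1
            for c in range(free.size):
                delta = rng.normal(0.0, self.sd_cat[term][c])
                rc, rl = rows[c], rows[last]
                new_eta_c = eta[rc] + delta
                new_eta_l = eta[rl] - delta
                dll = (
                    data.loglik(new_eta_c, self.sigma2, rows=rc).sum()
                    - ll[rc].sum()
                    + data.loglik(new_eta_l, self.sigma2, rows=rl).sum()
                    - ll[rl].sum()
                )
                dlp = dll + (free[c] ** 2 - (free[c] + delta) ** 2) / (2 * _PRIOR_VAR)
                if math.log(rng.uniform()) < dlp:
                    free[c] += delta
                    full[c] += delta
                    full[last] = -free.sum()
                    eta[rc] = new_eta_c
                    eta[rl] = new_eta_l
                    ll[rc] = data.loglik(new_eta_c, self.sigma2, rows=rc)
                    ll[rl] = data.loglik(new_eta_l, self.sigma2, rows=rl)
                    self.acc_cat[term][c] += 1
                    self._count(f"beta_{term}", 1, 1)
                else:
                    self._count(f"beta_{term}", 0, 1)

        # 6. continuous coefficients (Metropolis)
        for p in range(self.beta.size):
            delta = rng.normal(0.0, self.sd_beta[p])
            new_eta = eta + delta * data.X[:, p]
            new_ll = data.loglik(new_eta, self.sigma2)
            dlp = (
                new_ll.sum()
                - ll.sum()
                + (self.beta[p] ** 2 - (self.beta[p] + delta) ** 2) / (2 * _PRIOR_VAR)
            )
            if math.log(rng.uniform()) < dlp:
                self.beta[p] += delta
                eta, ll = new_eta, new_ll
                self.acc_beta[p] += 1
                self._count(f"beta_{data.cont_names[p]}", 1, 1)
            else:
                self._count(f"beta_{data.cont_names[p]}", 0, 1)

        # 6b. ridge-shift moves: β_p → β_p + δ with all intercepts shifted by
        # −δ·x, a likelihood-invariant shear that traverses the posterior
        # ridge between a (near-)lake-level covariate and the nested random
        # intercepts; the Metropolis ratio involves only the priors.
        if not self.spec.pooled_intercept:
            for p in range(self.beta.size):
                delta = rng.normal(0.0, self.sd_shift[p])
                x = data.X[:, p]
                xbar = data.x_lake_mean[:, p]
                new_beta = self.beta[p] + delta
                new_b_site = self.b_site - delta * x
                new_b_lake = self.b_lake - delta * xbar
                _, prior_var = self._site_prior_moments()
                site_resid_old = self.b_site - self.b_lake[data.lake_idx]
                site_resid_new = new_b_site - new_b_lake[data.lake_idx]
                dlp = (
                    (self.beta[p] ** 2 - new_beta**2) / (2 * _PRIOR_VAR)
                    + np.sum((site_resid_old**2 - site_resid_new**2) / (2.0 * prior_var))
                    + np.sum(
                        (self.b_lake - self.mu0) ** 2 - (new_b_lake - self.mu0) ** 2
                    )
                    / (2.0 * self.tau2)
                )
                if math.log(rng.uniform()) < dlp:
                    self.beta[p] = new_beta
                    self.b_site = new_b_site
                    self.b_lake = new_b_lake
                    self.acc_shift[p] += 1
                    self._count(f"shift_{data.cont_names[p]}", 1, 1)
                else:
                    self._count(f"shift_{data.cont_names[p]}", 0, 1)

        # 7. observation variance (Gibbs, normal family)
        if data.estimate_sigma2:
            resid2 = float(np.sum((data.z - eta) ** 2))
            shape = _GAMMA_A + 0.5 * data.n
            rate = _GAMMA_B + 0.5 * resid2
            self.sigma2 = float(1.0 / rng.gamma(shape, 1.0 / rate))

        # adaptation of proposal scales in fixed-size batches
        if adapting and iteration % _ADAPT_BATCH == 0:
            def tune(sd, acc):
                rate = acc / _ADAPT_BATCH
                sd = np.where(rate > _TARGET_HIGH, sd * _ADAPT_FACTOR, sd)
                sd = np.where(rate < _TARGET_LOW, sd / _ADAPT_FACTOR, sd)
                return sd

            if self.spec.pooled_intercept:
                self.sd_b0 = float(tune(np.array(self.sd_b0), np.array(self.acc_b0)))
                self.acc_b0 = 0.0
            else:
                self.sd_site = tune(self.sd_site, self.acc_site)
                self.acc_site[:] = 0.0
            for term in self.spec.categorical_terms:
                self.sd_cat[term] = tune(self.sd_cat[term], self.acc_cat[term])
                self.acc_cat[term][:] = 0.0
            self.sd_beta = tune(self.sd_beta, self.acc_beta)
            self.acc_beta[:] = 0.0
            if not self.spec.pooled_intercept:
                self.sd_shift = tune(self.sd_shift, self.acc_shift)
                self.acc_shift[:] = 0.0

    # -- packing ------------------------------------------------------------

    def pack(self) -> np.ndarray:
        parts: list[np.ndarray] = []
        if self.spec.pooled_intercept:
            parts.append(np.array([self.b0]))
        else:
            parts += [self.b_site, self.b_lake, self.s2_lake, np.array([self.mu0, self.tau2])]
        for term in self.spec.categorical_terms:
            parts.append(self.cat_full[term])
        parts.append(self.beta)
        if self.data.estimate_sigma2:
            parts.append(np.array([self.sigma2]))
        return np.concatenate(parts) if parts else np.empty(0)


def _deviance_from_vector(data: _ModelData, vec: np.ndarray) -> float:
    """Deviance −2·log L at an arbitrary packed parameter vector."""
    spec = data.spec
    pos = 0
    if spec.pooled_intercept:
        eta = np.full(data.n, vec[pos])
        pos += 1
    else:
        eta = vec[pos : pos + data.n].copy()
        pos += data.n
        pos += data.n_lakes  # lake means
        pos += 1 if spec.shared_lake_variance else data.n_lakes
        pos += 2  # mu0, tau2
    for term in spec.categorical_terms:
        k = len(data.cat_levels[term])
        eta += vec[pos : pos + k][data.cat_idx[term]]
        pos += k
    p = len(data.cont_names)
    if p:
        eta += data.X @ vec[pos : pos + p]
        pos += p
    sigma2 = spec.fixed_sigma2
    if data.estimate_sigma2:
        sigma2 = float(vec[pos])
    return float(-2.0 * data.loglik(eta, sigma2).sum())


def fit(
    spec: ModelSpec,
    samples: Sequence[SurveySample],
    responses,
    *,
    n_iter: int = 50_000,
    n_chains: int = 2,
    n_adapt: int = 4_000,
    burn_in: int = 5_000,
    thin: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    check_acceptance: bool = True,
) -> FitResult:
    """Sample the posterior of ``spec`` given survey samples and responses.

    Draws are retained every ``thin`` iterations after ``burn_in``; proposal
    scales adapt for the first ``n_adapt`` iterations and are frozen after.
    Identical ``seed``/spec/data give a bit-identical draw sequence.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if thin < 1 or n_chains < 1:
        raise ValueError("thin and n_chains must be >= 1")
    data = _ModelData(spec, samples, responses)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)

    chains: list[np.ndarray] = []
    deviances: list[np.ndarray] = []
    acc_tot: dict[str, float] = {}
    acc_n: dict[str, float] = {}
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        chain = _Chain(data, rng, n_adapt)
        kept_states: list[np.ndarray] = []
        kept_dev: list[float] = []
        for iteration in range(1, n_iter + 1):
            chain.step(iteration)
            if iteration > burn_in and (iteration - burn_in) % thin == 0:
                vec = chain.pack()
                kept_states.append(vec)
                kept_dev.append(_deviance_from_vector(data, vec))
        chains.append(np.array(kept_states))
        deviances.append(np.array(kept_dev))
        for key in chain.total_acc:
            acc_tot[key] = acc_tot.get(key, 0.0) + chain.total_acc[key]
            acc_n[key] = acc_n.get(key, 0.0) + chain.total_n[key]

    if not kept_states:
        raise ValueError("no draws retained; increase n_iter or reduce burn_in/thin")

    acceptance = {k: acc_tot[k] / acc_n[k] for k in acc_tot}
    if check_acceptance:
        off = {k: round(v, 3) for k, v in acceptance.items() if not 0.1 <= v <= 0.6}
        if off:
            warnings.warn(
                f"Metropolis acceptance rates outside the tuning window after "
                f"adaptation: {off}",
                stacklevel=2,
            )

    rhat = gelman_rubin(chains) if n_chains >= 2 else None
    pooled = np.concatenate(chains, axis=0)
    mc_ratio = mc_error_ratio(pooled)

    dbar = float(np.concatenate(deviances).mean())
    theta_bar = pooled.mean(axis=0)
    d_at_mean = _deviance_from_vector(data, theta_bar)
    p_d = dbar - d_at_mean
    return FitResult(
        spec=spec,
        param_names=data.param_names,
        chains=chains,
        deviances=deviances,
        acceptance_rates=acceptance,
        gelman_rubin=rhat,
        mc_error_ratio=mc_ratio,
        dbar=dbar,
        d_at_mean=d_at_mean,
        pd=p_d,
        dic=dbar + p_d,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(chains: Sequence[np.ndarray]) -> np.ndarray:
    """Brooks–Gelman corrected potential scale-reduction factor per parameter.

    ``chains`` is a sequence of (n_draws, n_params) arrays (1-D accepted for a
    single parameter).  Requires at least two chains.
    """
    arrays = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in chains]
    if len(arrays) < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    n = min(a.shape[0] for a in arrays)
    if n < 2:
        raise ValueError("need at least 2 draws per chain")
    stacked = np.stack([a[:n] for a in arrays])  # (m, n, p)
    m = stacked.shape[0]
    means = stacked.mean(axis=1)  # (m, p)
    within = stacked.var(axis=1, ddof=1).mean(axis=0)  # W
    b_over_n = means.var(axis=0, ddof=1)  # B/n
    var_hat = (n - 1) / n * within + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (m + 1) / m * var_hat / within - (n - 1) / (m * n)
    r2 = np.where(within <= 0, np.where(b_over_n <= 0, 1.0, np.inf), r2)
    return np.sqrt(np.maximum(r2, 0.0))


def mc_error_ratio(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte-Carlo standard error over posterior SD, per parameter.

    Parameters with zero posterior SD return ``nan`` (flagged as undefined).
    Ratios at or above 0.05 indicate too few effective draws.
    """
    arr = np.asarray(draws, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    n = arr.shape[0]
    nb = min(n_batches, n)
    if nb < 2:
        raise ValueError("need at least 2 batches")
    size = n // nb
    trimmed = arr[: nb * size].reshape(nb, size, arr.shape[1])
    batch_means = trimmed.mean(axis=1)
    se = batch_means.std(axis=0, ddof=1) / math.sqrt(nb)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, se / sd, np.nan)
    return float(ratio[0]) if squeeze else ratio


# ---------------------------------------------------------------------------
# DIC model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelRanking:
    """DIC-ranked candidate models; entries within 2 units tie with the top."""

    entries: list[dict]
    complete: bool = True

    @property
    def best(self) -> dict:
        return self.entries[0]

    def tied_with_best(self) -> list[dict]:
        top = self.entries[0]["dic"]
        return [e for e in self.entries if e["dic"] - top < 2.0]


def select_model(
    spec_template: ModelSpec,
    samples: Sequence[SurveySample],
    responses,
    candidate_continuous: Sequence[str] | None = None,
    candidate_categorical: Sequence[str] | None = None,
    *,
    budget: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    **fit_kwargs,
) -> ModelRanking:
    """Exhaustive DIC search over inclusion patterns of candidate terms.

    Every subset of ``candidate_continuous`` × ``candidate_categorical`` is
    fitted (the intercept structure of ``spec_template`` is always kept) and
    models are ranked by ascending DIC.  ``budget`` caps the number of fits;
    exceeding it yields a partial ranking with a warning.
    """
    cont = tuple(candidate_continuous if candidate_continuous is not None else spec_template.continuous_terms)
    cat = tuple(candidate_categorical if candidate_categorical is not None else spec_template.categorical_terms)
    combos = [
        (tuple(cs), tuple(ks))
        for cs in _subsets(cont)
        for ks in _subsets(cat)
    ]
    complete = True
    if budget is not None and len(combos) > budget:
        warnings.warn(
            f"model-selection budget {budget} below candidate count {len(combos)}; "
            "returning a partial ranking",
            stacklevel=2,
        )
        combos = combos[:budget]
        complete = False
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    model_seeds = ss.spawn(len(combos))
    entries = []
    for (cs, ks), mseed in zip(combos, model_seeds):
        spec = replace(spec_template, continuous_terms=cs, categorical_terms=ks)
        result = fit(spec, samples, responses, seed=mseed, **fit_kwargs)
        entries.append(
            {
                "spec": spec,
                "continuous_terms": cs,
                "categorical_terms": ks,
                "dic": result.dic,
                "dbar": result.dbar,
                "pd": result.pd,
            }
        )
    entries.sort(key=lambda e: e["dic"])
    return ModelRanking(entries=entries, complete=complete)


def _subsets(items: Sequence[str]):
    for r in range(len(items) + 1):
        yield from itertools.combinations(items, r)
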