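"""Hierarchical Bayesian fitting of power-law learning curves.

Day-one performance of subject *s* on trial *t* is modelled as

    y_{s,t} ~ Normal( I_s + C_s * (1 - R_s**(t-1)),  sigma_obs[g(s)] )

with subject parameters drawn from group-level normal populations,

    I_s ~ N(mu_I[g], sigma_I[g]),  C_s ~ N(mu_C[g], sigma_C[g]),
    R_s ~ N(mu_R[g], sigma_R[g])   restricted to (0, 1),

where g(s) is the subject's design cell (or a coarser grouping).  The
hierarchy shrinks noisy individual fits toward their group and makes the
fit robust to starting values.  Hyperpriors are weakly informative on the
scale of finger-tapping counts (tens of sequences per 30 s trial):
mu_I, mu_C ~ N(0, 10^2), mu_R ~ Uniform(0, 1), all standard deviations
half-normal with scale 5.

The posterior is sampled with an adaptive random-walk Metropolis-within-
Gibbs scheme.  Subject-level parameters are conditionally independent
given the hyperparameters, and group-level parameters are conditionally
independent given the subject parameters, so each update sweeps a whole
block with vectorized, coordinate-wise accept/reject steps.  R_s and
mu_R are updated on the logit scale and standard deviations on the log
scale (with the corresponding Jacobians), which avoids boundary
rejections.  Proposal scales adapt toward ~0.44 acceptance during
burn-in and are frozen afterwards, preserving the stationary
distribution of the retained draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DiagnosticsError,
    IdentifiabilityError,
    InitializationError,
)

__all__ = [
    "CurveParams",
    "PriorSpec",
    "McmcConfig",
    "ParamState",
    "HierarchicalCurveModel",
    "PosteriorDraws",
    "learning_curve",
    "log_density",
    "mcmc_fit",
    "summarize",
    "subject_estimates",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class CurveParams:
    """Power-law learning-curve parameters for one subject.

    I is the initial performance at trial one, C the change in
    performance over day one (the asymptote is I + C) and R the learning
    rate: the closer R is to 0, the faster the plateau is reached.
    """

    I: float
    C: float
    R: float


def learning_curve(I, C, R, t):
    """Expected correct sequences on trial t: ``I + C * (1 - R**(t-1))``.

    ``t`` is 1-based and may be an array; at t = 1 the value is exactly I.
    """
    t = np.asarray(t)
    if np.any(t < 1):
        raise ValueError("trial index t must be >= 1")
    return I + C * (1.0 - np.power(R, t - 1))


# ---------------------------------------------------------------------------
# Priors and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior scales (see module docstring)."""

    mu_loc: float = 0.0
    mu_scale: float = 10.0
    sigma_scale: float = 5.0


@dataclass
class McmcConfig:
    """Sampler settings.

    ``grouping`` selects which factor columns define the hyperparameter
    groups: "cell" uses every design factor (16 groups in the main
    scenario), "piano_age" coarsens to the four experience-by-age groups;
    a list of column names or an explicit subject_id -> group mapping is
    also accepted.  ``fixed_r`` pins every subject's R (no R updates) and
    ``hierarchical=False`` drops the group level entirely, leaving flat
    priors on the subject parameters; together with ``fixed_sigma_obs``
    this reduces the model to independent linear-Gaussian regressions,
    which is used as an analytic cross-check.
    """

    n_chains: int = 2
    n_iterations: int = 3000
    n_burnin: int = 1000
    thinning: int = 1
    seed: int = 0
    adapt_window: int = 50
    priors: PriorSpec = field(default_factory=PriorSpec)
    grouping: object = "cell"
    hierarchical: bool = True
    fixed_r: float | Mapping[str, float] | None = None
    fixed_sigma_obs: float | None = None

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if not self.hierarchical and self.fixed_sigma_obs is None:
            raise ValueError(
                "non-hierarchical fits need fixed_sigma_obs (no sigma prior)"
            )


@dataclass
class ParamState:
    """Natural-scale parameter state: subject arrays (S,) + group arrays (G,)."""

    I: np.ndarray
    C: np.ndarray
    R: np.ndarray
    mu_I: np.ndarray
    mu_C: np.ndarray
    mu_R: np.ndarray
    sigma_I: np.ndarray
    sigma_C: np.ndarray
    sigma_R: np.ndarray
    sigma_obs: np.ndarray

    def copy(self) -> "ParamState":
        return ParamState(**{k: np.array(v, dtype=float) for k, v in vars(self).items()})


def _normal_logpdf(x, mu, sd):
    return -np.log(sd) - 0.5 * _LOG_2PI - 0.5 * ((x - mu) / sd) ** 2


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def resolve_grouping(factors: pd.DataFrame, grouping) -> pd.Series:
    """Subject_id -> group label series for a grouping specification."""
    factors = factors.reset_index(drop=True)
    canonical = [c for c in ("piano", "age_group", "intelligence", "gender")
                 if c in factors.columns]
    if isinstance(grouping, str):
        if grouping == "cell":
            cols = canonical
        elif grouping == "piano_age":
            cols = [c for c in ("piano", "age_group") if c in factors.columns]
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        if not cols:
            labels = pd.Series("all", index=factors.index)
        else:
            labels = factors[cols].astype(str).agg("|".join, axis=1)
    elif isinstance(grouping, (list, tuple)):
        labels = factors[list(grouping)].astype(str).agg("|".join, axis=1)
    elif isinstance(grouping, pd.Series):
        labels = factors["subject_id"].map(grouping)
    elif isinstance(grouping, Mapping):
        labels = factors["subject_id"].map(dict(grouping))
    else:
        raise TypeError(f"cannot interpret grouping {grouping!r}")
    if labels.isna().any():
        missing = factors.loc[labels.isna(), "subject_id"].tolist()
        raise KeyError(f"no group assigned for subjects {missing}")
    return pd.Series(labels.values, index=factors["subject_id"].values)


class HierarchicalCurveModel:
    """Joint density of day-one data and the hierarchical curve model."""

    def __init__(
        self,
        trials: pd.DataFrame,
        factors: pd.DataFrame,
        grouping="cell",
        priors: PriorSpec | None = None,
        hierarchical: bool = True,
    ):
        self.priors = priors or PriorSpec()
        self.hierarchical = hierarchical
        self.subject_ids = list(factors["subject_id"])
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject_id in factors")

        day1 = trials[trials["session"] == "day1"]
        unknown = set(day1["subject_id"]) - set(self.subject_ids)
        if unknown:
            raise KeyError(f"trials reference unknown subjects: {sorted(unknown)}")
        wide = day1.pivot_table(
            index="subject_id", columns="trial", values="correct_sequences"
        ).reindex(self.subject_ids)
        self.t = np.asarray(sorted(wide.columns), dtype=float)
        wide = wide[sorted(wide.columns)]
        self.y = wide.to_numpy(dtype=float)  # (S, T), NaN where absent
        self.mask = ~np.isnan(self.y)
        self.n_obs = self.mask.sum(axis=1)
        if np.any(self.n_obs < 3):
            bad = [s for s, n in zip(self.subject_ids, self.n_obs) if n < 3]
            raise IdentifiabilityError(
                f"subjects with fewer than 3 day-1 trials: {bad}"
            )
        self.y0 = np.where(self.mask, self.y, 0.0)

        glabels = resolve_grouping(factors, grouping)
        self.group_names = list(dict.fromkeys(glabels.values))
        gindex = {g: i for i, g in enumerate(self.group_names)}
        self.group_idx = np.array([gindex[glabels[s]] for s in self.subject_ids])
        self.n_subjects = len(self.subject_ids)
        self.n_groups = len(self.group_names)

    def check_group_sizes(self) -> None:
        """Hierarchical fitting needs >= 2 subjects per group."""
        counts = np.bincount(self.group_idx, minlength=self.n_groups)
        if np.any(counts < 2):
            bad = [g for g, c in zip(self.group_names, counts) if c < 2]
            raise IdentifiabilityError(
                f"groups with fewer than 2 subjects: {bad}"
            )

    # -- likelihood ---------------------------------------------------------

    def curve_mean(self, I, C, R) -> np.ndarray:
        return I[:, None] + C[:, None] * (1.0 - np.power(R[:, None], self.t - 1.0))

    def sse(self, I, C, R) -> np.ndarray:
        resid = np.where(self.mask, self.y0 - self.curve_mean(I, C, R), 0.0)
        return np.einsum("ij,ij->i", resid, resid)

    def log_likelihood_per_subject(self, state: ParamState) -> np.ndarray:
        sig = state.sigma_obs[self.group_idx]
        sse = self.sse(state.I, state.C, state.R)
        return (
            -0.5 * self.n_obs * _LOG_2PI
            - self.n_obs * np.log(sig)
            - 0.5 * sse / sig**2
        )

    def log_likelihood(self, state: ParamState) -> float:
        """Normal log-likelihood of the day-1 data around the curves."""
        return float(np.sum(self.log_likelihood_per_subject(state)))

    # -- priors -------------------------------------------------------------

    def _subject_prior(self, state: ParamState) -> float:
        g = self.group_idx
        lp = _normal_logpdf(state.I, state.mu_I[g], state.sigma_I[g])
        lp = lp + _normal_logpdf(state.C, state.mu_C[g], state.sigma_C[g])
        lp = lp + _normal_logpdf(state.R, state.mu_R[g], state.sigma_R[g])
        return float(np.sum(lp))

    def _hyperprior(self, state: ParamState) -> float:
        pr = self.priors
        lp = np.sum(_normal_logpdf(state.mu_I, pr.mu_loc, pr.mu_scale))
        lp += np.sum(_normal_logpdf(state.mu_C, pr.mu_loc, pr.mu_scale))
        if np.any(state.mu_R <= 0.0) or np.any(state.mu_R >= 1.0):
            return -np.inf
        for sig in (state.sigma_I, state.sigma_C, state.sigma_R, state.sigma_obs):
            lp += np.sum(stats.halfnorm.logpdf(sig, scale=pr.sigma_scale))
        return float(lp)

    def log_density(self, state: ParamState) -> float:
        """Unnormalized log posterior on the natural scale.

        Returns -inf whenever any R_s leaves (0, 1) or any standard
        deviation is non-positive.
        """
        if len(state.I) != self.n_subjects:
            raise ValueError(
                f"state has {len(state.I)} subjects, data has {self.n_subjects}"
            )
        if np.any(state.R <= 0.0) or np.any(state.R >= 1.0):
            return -np.inf
        for sig in (state.sigma_I, state.sigma_C, state.sigma_R, state.sigma_obs):
            if np.any(np.asarray(sig) <= 0.0):
                return -np.inf
        total = self.log_likelihood(state)
        if self.hierarchical:
            total += self._subject_prior(state)
            hp = self._hyperprior(state)
            if not np.isfinite(hp):
                return -np.inf
            total += hp
        return float(total)

    # -- initialization -----------------------------------------------------

    def least_squares_init(self) -> ParamState:
        """Per-subject grid search over R with closed-form (I, C) given R."""
        grid = np.linspace(0.05, 0.95, 19)
        I = np.empty(self.n_subjects)
        C = np.empty(self.n_subjects)
        R = np.empty(self.n_subjects)
        resvar = np.empty(self.n_subjects)
        for s in range(self.n_subjects):
            m = self.mask[s]
            y = self.y[s, m]
            tt = self.t[m]
            best = (np.inf, 0.0, 0.0, 0.5)
            for r in grid:
                X = np.column_stack([np.ones_like(tt), 1.0 - r ** (tt - 1.0)])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse = float(np.sum((y - X @ beta) ** 2))
                if sse < best[0]:
                    best = (sse, beta[0], beta[1], r)
            sse, i0, c0, r0 = best
            I[s] = max(i0, 1e-3)
            C[s] = max(c0, 1e-3)
            R[s] = min(max(r0, 0.03), 0.97)
            resvar[s] = sse / max(self.n_obs[s] - 3, 1)

        G = self.n_groups
        mu_I = np.empty(G); mu_C = np.empty(G); mu_R = np.empty(G)
        sigma_I = np.empty(G); sigma_C = np.empty(G); sigma_R = np.empty(G)
        sigma_obs = np.empty(G)
        for g in range(G):
            sel = self.group_idx == g
            mu_I[g] = I[sel].mean()
            mu_C[g] = C[sel].mean()
            mu_R[g] = min(max(R[sel].mean(), 0.05), 0.95)
            sigma_I[g] = max(I[sel].std(ddof=1), 0.2)
            sigma_C[g] = max(C[sel].std(ddof=1), 0.2)
            sigma_R[g] = min(max(R[sel].std(ddof=1), 0.02), 0.3)
            sigma_obs[g] = max(np.sqrt(resvar[sel].mean()), 0.05)
        return ParamState(I, C, R, mu_I, mu_C, mu_R,
                          sigma_I, sigma_C, sigma_R, sigma_obs)


def log_density(
    state: ParamState,
    trials: pd.DataFrame,
    factors: pd.DataFrame,
    grouping="cell",
    priors: PriorSpec | None = None,
    hierarchical: bool = True,
) -> float:
    """Log posterior density (up to a constant) of a full parameter state."""
    model = HierarchicalCurveModel(trials, factors, grouping, priors, hierarchical)
    return model.log_density(state)


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Retained MCMC draws: array (chain, draw, parameter) on natural scale."""

    draws: np.ndarray
    param_names: list[str]
    subject_ids: list[str]
    group_names: list[str]
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def extract(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chain, draw)."""
        return self.draws[:, :, self.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        ch, dr, P = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(ch), dr * P),
                "iteration": np.tile(np.repeat(np.arange(dr), P), ch),
                "parameter": np.tile(self.param_names, ch * dr),
                "value": self.draws.reshape(-1),
            }
        )

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "draws.csv"
        self.to_dataframe().to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class _TransformedState:
    """Sampler-side state: R and mu_R on logit scale, sigmas on log scale."""

    __slots__ = ("I", "C", "zR", "mu_I", "mu_C", "zmu_R",
                 "lsig_I", "lsig_C", "lsig_R", "lsig_obs")

    def __init__(self, state: ParamState):
        self.I = np.array(state.I, dtype=float)
        self.C = np.array(state.C, dtype=float)
        self.zR = _logit(np.array(state.R, dtype=float))
        self.mu_I = np.array(state.mu_I, dtype=float)
        self.mu_C = np.array(state.mu_C, dtype=float)
        self.zmu_R = _logit(np.array(state.mu_R, dtype=float))
        self.lsig_I = np.log(np.array(state.sigma_I, dtype=float))
        self.lsig_C = np.log(np.array(state.sigma_C, dtype=float))
        self.lsig_R = np.log(np.array(state.sigma_R, dtype=float))
        self.lsig_obs = np.log(np.array(state.sigma_obs, dtype=float))

    def natural(self) -> ParamState:
        return ParamState(
            I=self.I.copy(), C=self.C.copy(), R=_expit(self.zR),
            mu_I=self.mu_I.copy(), mu_C=self.mu_C.copy(), mu_R=_expit(self.zmu_R),
            sigma_I=np.exp(self.lsig_I), sigma_C=np.exp(self.lsig_C),
            sigma_R=np.exp(self.lsig_R), sigma_obs=np.exp(self.lsig_obs),
        )


class _ChainSampler:
    def __init__(self, model: HierarchicalCurveModel, config: McmcConfig,
                 init: ParamState, rng: np.random.Generator):
        self.m = model
        self.cfg = config
        self.rng = rng
        self.s = _TransformedState(init)
        self.update_r = config.fixed_r is None
        self.update_sig_obs = (
            config.fixed_sigma_obs is None and config.hierarchical
        )
        S, G = model.n_subjects, model.n_groups
        self.scales = {
            "I": np.full(S, 0.5), "C": np.full(S, 0.5), "zR": np.full(S, 0.3),
            "IC": np.full(S, 0.5),
            "mu_I": np.full(G, 0.4), "mu_C": np.full(G, 0.4),
            "zmu_R": np.full(G, 0.2), "lsig_I": np.full(G, 0.3),
            "lsig_C": np.full(G, 0.3), "lsig_R": np.full(G, 0.3),
            "lsig_obs": np.full(G, 0.2),
            "tmu_I": np.full(G, 0.3), "tmu_C": np.full(G, 0.3),
            "tmu_R": np.full(G, 0.1), "ssig_I": np.full(G, 0.3),
            "ssig_C": np.full(G, 0.3), "ssig_R": np.full(G, 0.3),
        }
        self.group_n = np.bincount(model.group_idx, minlength=G).astype(float)
        self._refresh_cache()

    # cached quantities -----------------------------------------------------
    def _refresh_cache(self):
        self.R = _expit(self.s.zR)
        self.B = 1.0 - np.power(self.R[:, None], self.m.t - 1.0)  # (S, T)
        mean = self.s.I[:, None] + self.s.C[:, None] * self.B
        self.resid = np.where(self.m.mask, self.m.y0 - mean, 0.0)
        self.sse = np.einsum("ij,ij->i", self.resid, self.resid)

    def _sigma_obs_per_subject(self):
        return np.exp(self.s.lsig_obs)[self.m.group_idx]

    def _adapt(self, key, accept_prob, it):
        gamma = (it + 1.0) ** -0.6
        self.scales[key] *= np.exp(gamma * (accept_prob - 0.44))
        np.clip(self.scales[key], 1e-4, 50.0, out=self.scales[key])

    # subject-level blocks --------------------------------------------------
    def _accept_subject(self, d_logpost, key, it, adapting):
        logu = np.log(self.rng.uniform(size=d_logpost.shape))
        acc = logu < d_logpost
        if adapting:
            self._adapt(key, np.minimum(1.0, np.exp(np.minimum(d_logpost, 0.0))), it)
        return acc

    def update_I(self, it, adapting):
        s, m = self.s, self.m
        delta = self.rng.normal(size=m.n_subjects) * self.scales["I"]
        resid_new = self.resid - delta[:, None] * m.mask
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = -0.5 * (sse_new - self.sse) / sig2
        if self.cfg.hierarchical:
            g = m.group_idx
            sd = np.exp(s.lsig_I)[g]
            mu = s.mu_I[g]
            d += (
                _normal_logpdf(s.I + delta, mu, sd) - _normal_logpdf(s.I, mu, sd)
            )
        acc = self._accept_subject(d, "I", it, adapting)
        s.I[acc] += delta[acc]
        self.resid[acc] = resid_new[acc]
        self.sse[acc] = sse_new[acc]

    def update_C(self, it, adapting):
        s, m = self.s, self.m
        delta = self.rng.normal(size=m.n_subjects) * self.scales["C"]
        resid_new = self.resid - delta[:, None] * (self.B * m.mask)
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = -0.5 * (sse_new - self.sse) / sig2
        if self.cfg.hierarchical:
            g = m.group_idx
            sd = np.exp(s.lsig_C)[g]
            mu = s.mu_C[g]
            d += (
                _normal_logpdf(s.C + delta, mu, sd) - _normal_logpdf(s.C, mu, sd)
            )
        acc = self._accept_subject(d, "C", it, adapting)
        s.C[acc] += delta[acc]
        self.resid[acc] = resid_new[acc]
        self.sse[acc] = sse_new[acc]

    def update_R(self, it, adapting):
        s, m = self.s, self.m
        z_new = s.zR + self.rng.normal(size=m.n_subjects) * self.scales["zR"]
        R_new = _expit(z_new)
        B_new = 1.0 - np.power(R_new[:, None], m.t - 1.0)
        mean_new = s.I[:, None] + s.C[:, None] * B_new
        resid_new = np.where(m.mask, m.y0 - mean_new, 0.0)
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = -0.5 * (sse_new - self.sse) / sig2
        # logit-scale Jacobian: log R(1-R)
        jac = np.log(R_new) + np.log1p(-R_new) - np.log(self.R) - np.log1p(-self.R)
        d += jac
        if self.cfg.hierarchical:
            g = m.group_idx
            sd = np.exp(s.lsig_R)[g]
            mu = _expit(s.zmu_R)[g]
            d += _normal_logpdf(R_new, mu, sd) - _normal_logpdf(self.R, mu, sd)
        acc = self._accept_subject(d, "zR", it, adapting)
        s.zR[acc] = z_new[acc]
        self.R[acc] = R_new[acc]
        self.B[acc] = B_new[acc]
        self.resid[acc] = resid_new[acc]
        self.sse[acc] = sse_new[acc]

    def update_IC_seesaw(self, it, adapting):
        # joint move I' = I + d, C' = C - d: the plateau I + C is tightly
        # identified while the split is not, so this traverses the
        # anti-correlated (I, C) ridge that single-site steps cross slowly
        s, m = self.s, self.m
        delta = self.rng.normal(size=m.n_subjects) * self.scales["IC"]
        # mean shift is d * R**(t-1) = d * (1 - B)
        resid_new = self.resid - delta[:, None] * ((1.0 - self.B) * m.mask)
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = -0.5 * (sse_new - self.sse) / sig2
        if self.cfg.hierarchical:
            g = m.group_idx
            sd_I, mu_I = np.exp(s.lsig_I)[g], s.mu_I[g]
            sd_C, mu_C = np.exp(s.lsig_C)[g], s.mu_C[g]
            d += (
                _normal_logpdf(s.I + delta, mu_I, sd_I)
                - _normal_logpdf(s.I, mu_I, sd_I)
                + _normal_logpdf(s.C - delta, mu_C, sd_C)
                - _normal_logpdf(s.C, mu_C, sd_C)
            )
        acc = self._accept_subject(d, "IC", it, adapting)
        s.I[acc] += delta[acc]
        s.C[acc] -= delta[acc]
        self.resid[acc] = resid_new[acc]
        self.sse[acc] = sse_new[acc]

    # group-level blocks ----------------------------------------------------
    def _group_sums(self, per_subject):
        return np.bincount(self.m.group_idx, weights=per_subject,
                           minlength=self.m.n_groups)

    def _accept_group(self, d, key, it, adapting):
        logu = np.log(self.rng.uniform(size=d.shape))
        acc = logu < d
        if adapting:
            self._adapt(key, np.minimum(1.0, np.exp(np.minimum(d, 0.0))), it)
        return acc

    def _update_mu(self, key, values, it, adapting):
        # key in {"mu_I", "mu_C"}; values = subject-level I or C
        s, m = self.s, self.m
        cur = getattr(s, key)
        prop = cur + self.rng.normal(size=m.n_groups) * self.scales[key]
        sd = np.exp(getattr(s, "lsig_" + key[-1]))
        g = m.group_idx
        d = self._group_sums(
            _normal_logpdf(values, prop[g], sd[g])
            - _normal_logpdf(values, cur[g], sd[g])
        )
        pr = self.cfg.priors
        d += (
            _normal_logpdf(prop, pr.mu_loc, pr.mu_scale)
            - _normal_logpdf(cur, pr.mu_loc, pr.mu_scale)
        )
        acc = self._accept_group(d, key, it, adapting)
        cur[acc] = prop[acc]

    def _update_zmu_R(self, it, adapting):
        s, m = self.s, self.m
        prop = s.zmu_R + self.rng.normal(size=m.n_groups) * self.scales["zmu_R"]
        mu_new, mu_old = _expit(prop), _expit(s.zmu_R)
        sd = np.exp(s.lsig_R)
        g = m.group_idx
        d = self._group_sums(
            _normal_logpdf(self.R, mu_new[g], sd[g])
            - _normal_logpdf(self.R, mu_old[g], sd[g])
        )
        # Uniform(0,1) prior on mu_R => only the logit Jacobian remains
        d += (
            np.log(mu_new) + np.log1p(-mu_new)
            - np.log(mu_old) - np.log1p(-mu_old)
        )
        acc = self._accept_group(d, "zmu_R", it, adapting)
        s.zmu_R[acc] = prop[acc]

    def _update_lsig(self, key, values, mu_key, it, adapting):
        # key in {"lsig_I", "lsig_C", "lsig_R"}
        s, m = self.s, self.m
        cur = getattr(s, key)
        prop = cur + self.rng.normal(size=m.n_groups) * self.scales[key]
        sd_new, sd_old = np.exp(prop), np.exp(cur)
        mu = getattr(s, mu_key)
        if mu_key == "zmu_R":
            mu = _expit(mu)
        g = m.group_idx
        d = self._group_sums(
            _normal_logpdf(values, mu[g], sd_new[g])
            - _normal_logpdf(values, mu[g], sd_old[g])
        )
        scale2 = 2.0 * self.cfg.priors.sigma_scale**2
        # half-normal prior plus the log-scale Jacobian
        d += -(sd_new**2 - sd_old**2) / scale2 + (prop - cur)
        acc = self._accept_group(d, key, it, adapting)
        cur[acc] = prop[acc]

    def _update_lsig_obs(self, it, adapting):
        s, m = self.s, self.m
        cur = s.lsig_obs
        prop = cur + self.rng.normal(size=m.n_groups) * self.scales["lsig_obs"]
        g = m.group_idx
        dl = (
            -m.n_obs * (prop[g] - cur[g])
            - 0.5 * self.sse * (np.exp(-2.0 * prop[g]) - np.exp(-2.0 * cur[g]))
        )
        d = self._group_sums(dl)
        sd_new, sd_old = np.exp(prop), np.exp(cur)
        scale2 = 2.0 * self.cfg.priors.sigma_scale**2
        d += -(sd_new**2 - sd_old**2) / scale2 + (prop - cur)
        acc = self._accept_group(d, "lsig_obs", it, adapting)
        cur[acc] = prop[acc]

    # joint group moves -----------------------------------------------------
    # Translation shifts a group mean together with all its subjects'
    # values; scaling multiplies the subject deviations from the mean
    # while moving log sigma by the same amount.  Standardized deviations
    # (x - mu)/sigma are invariant under both maps, so the subject-prior
    # terms cancel against the proposal Jacobians and the acceptance
    # ratio reduces to the likelihood change plus (for scaling) the
    # half-normal hyperprior change and the log-scale Jacobian.  These
    # moves decorrelate the hierarchy's location/scale funnels, which
    # coordinate-wise updates alone traverse very slowly.

    def _shift_subjects(self, delta_s, key, d_extra, it, adapting):
        m = self.m
        resid_new = self.resid - delta_s[:, None] * m.mask
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = self._group_sums(-0.5 * (sse_new - self.sse) / sig2) + d_extra
        acc = self._accept_group(d, key, it, adapting)
        smask = acc[m.group_idx]
        self.resid[smask] = resid_new[smask]
        self.sse[smask] = sse_new[smask]
        return acc, smask

    def _translate_IC(self, which, it, adapting):
        s, m = self.s, self.m
        key = "tmu_" + which
        d_g = self.rng.normal(size=m.n_groups) * self.scales[key]
        mu = getattr(s, "mu_" + which)
        pr = self.cfg.priors
        d_extra = (
            _normal_logpdf(mu + d_g, pr.mu_loc, pr.mu_scale)
            - _normal_logpdf(mu, pr.mu_loc, pr.mu_scale)
        )
        acc, smask = self._shift_subjects(
            d_g[m.group_idx], key, d_extra, it, adapting
        )
        mu[acc] += d_g[acc]
        vals = getattr(s, which)
        vals[smask] += d_g[m.group_idx][smask]

    def _scale_IC(self, which, it, adapting):
        s, m = self.s, self.m
        key = "ssig_" + which
        eps = self.rng.normal(size=m.n_groups) * self.scales[key]
        lsig = getattr(s, "lsig_" + which)
        sig_old, sig_new = np.exp(lsig), np.exp(lsig + eps)
        scale2 = 2.0 * self.cfg.priors.sigma_scale**2
        d_extra = -(sig_new**2 - sig_old**2) / scale2 + eps
        mu = getattr(s, "mu_" + which)[m.group_idx]
        vals = getattr(s, which)
        new_vals = mu + (vals - mu) * np.exp(eps)[m.group_idx]
        acc, smask = self._shift_subjects(
            new_vals - vals, key, d_extra, it, adapting
        )
        lsig[acc] += eps[acc]
        vals[smask] = new_vals[smask]

    def _group_move_R(self, kind, it, adapting):
        s, m = self.s, self.m
        key = "tmu_R" if kind == "translate" else "ssig_R"
        step = self.rng.normal(size=m.n_groups) * self.scales[key]
        mu_old = _expit(s.zmu_R)
        g = m.group_idx
        if kind == "translate":
            R_new = self.R + step[g]
            mu_new = mu_old + step
            d_extra = np.zeros(m.n_groups)
        else:
            R_new = mu_old[g] + (self.R - mu_old[g]) * np.exp(step)[g]
            mu_new = mu_old
            sig_old, sig_new = np.exp(s.lsig_R), np.exp(s.lsig_R + step)
            scale2 = 2.0 * self.cfg.priors.sigma_scale**2
            d_extra = -(sig_new**2 - sig_old**2) / scale2 + step
        bad_subj = (R_new <= 1e-12) | (R_new >= 1.0 - 1e-12)
        invalid = np.bincount(g, weights=bad_subj, minlength=m.n_groups) > 0
        invalid |= (mu_new <= 1e-12) | (mu_new >= 1.0 - 1e-12)
        R_new = np.clip(R_new, 1e-12, 1.0 - 1e-12)
        B_new = 1.0 - np.power(R_new[:, None], m.t - 1.0)
        mean_new = s.I[:, None] + s.C[:, None] * B_new
        resid_new = np.where(m.mask, m.y0 - mean_new, 0.0)
        sse_new = np.einsum("ij,ij->i", resid_new, resid_new)
        sig2 = self._sigma_obs_per_subject() ** 2
        d = self._group_sums(-0.5 * (sse_new - self.sse) / sig2) + d_extra
        d[invalid] = -np.inf
        acc = self._accept_group(d, key, it, adapting)
        smask = acc[g]
        if kind == "translate":
            s.zmu_R[acc] = _logit(mu_new[acc])
        else:
            s.lsig_R[acc] += step[acc]
        self.R[smask] = R_new[smask]
        s.zR[smask] = _logit(R_new[smask])
        self.B[smask] = B_new[smask]
        self.resid[smask] = resid_new[smask]
        self.sse[smask] = sse_new[smask]

    # one sweep -------------------------------------------------------------
    def sweep(self, it: int, adapting: bool):
        self.update_I(it, adapting)
        self.update_C(it, adapting)
        self.update_IC_seesaw(it, adapting)
        if self.update_r:
            self.update_R(it, adapting)
        if self.cfg.hierarchical:
            self._update_mu("mu_I", self.s.I, it, adapting)
            self._update_mu("mu_C", self.s.C, it, adapting)
            self._update_zmu_R(it, adapting)
            self._update_lsig("lsig_I", self.s.I, "mu_I", it, adapting)
            self._update_lsig("lsig_C", self.s.C, "mu_C", it, adapting)
            self._update_lsig("lsig_R", self.R, "zmu_R", it, adapting)
            if self.update_sig_obs:
                self._update_lsig_obs(it, adapting)
            self._translate_IC("I", it, adapting)
            self._translate_IC("C", it, adapting)
            self._scale_IC("I", it, adapting)
            self._scale_IC("C", it, adapting)
            if self.update_r:
                self._group_move_R("translate", it, adapting)
                self._group_move_R("scale", it, adapting)

    def flat_draw(self) -> np.ndarray:
        st = self.s
        parts = [st.I, st.C, self.R]
        if self.cfg.hierarchical:
            parts += [
                st.mu_I, st.mu_C, _expit(st.zmu_R),
                np.exp(st.lsig_I), np.exp(st.lsig_C), np.exp(st.lsig_R),
                np.exp(st.lsig_obs),
            ]
        return np.concatenate(parts)


def _param_names(model: HierarchicalCurveModel, hierarchical: bool) -> list[str]:
    names = [f"I[{s}]" for s in model.subject_ids]
    names += [f"C[{s}]" for s in model.subject_ids]
    names += [f"R[{s}]" for s in model.subject_ids]
    if hierarchical:
        for stem in ("mu_I", "mu_C", "mu_R",
                     "sigma_I", "sigma_C", "sigma_R", "sigma_obs"):
            names += [f"{stem}[{g}]" for g in model.group_names]
    return names


def _apply_fixed(init: ParamState, model: HierarchicalCurveModel,
                 config: McmcConfig) -> ParamState:
    if config.fixed_r is not None:
        fr = config.fixed_r
        if isinstance(fr, Mapping):
            init.R = np.array([float(fr[s]) for s in model.subject_ids])
        else:
            init.R = np.full(model.n_subjects, float(fr))
    if config.fixed_sigma_obs is not None:
        init.sigma_obs = np.full(model.n_groups, float(config.fixed_sigma_obs))
    return init


def mcmc_fit(
    trials: pd.DataFrame,
    factors: pd.DataFrame,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the hierarchical learning-curve model.

    Chains are initialized from per-subject least-squares fits (grid
    search over R with closed-form I, C), with group hyperparameters at
    the moments of those fits, then jittered per chain.  The run is
    deterministic given ``config.seed``.
    """
    config = config or McmcConfig()
    config.validate()
    model = HierarchicalCurveModel(
        trials, factors, config.grouping, config.priors, config.hierarchical
    )
    if config.hierarchical:
        model.check_group_sizes()
    base_init = _apply_fixed(model.least_squares_init(), model, config)

    n_keep = (config.n_iterations - config.n_burnin) // config.thinning
    names = _param_names(model, config.hierarchical)
    all_draws = np.empty((config.n_chains, n_keep, len(names)))

    for chain in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(int(config.seed), int(chain), 7))
        )
        init = None
        for _ in range(10):
            cand = base_init.copy()
            cand.I = np.maximum(cand.I + rng.normal(0, 0.2, model.n_subjects), 1e-3)
            cand.C = np.maximum(cand.C + rng.normal(0, 0.2, model.n_subjects), 1e-3)
            if config.fixed_r is None:
                cand.R = _expit(
                    _logit(cand.R) + rng.normal(0, 0.1, model.n_subjects)
                )
            if config.hierarchical:
                cand.mu_I = cand.mu_I + rng.normal(0, 0.1, model.n_groups)
                cand.mu_C = cand.mu_C + rng.normal(0, 0.1, model.n_groups)
                cand.mu_R = _expit(
                    _logit(cand.mu_R) + rng.normal(0, 0.05, model.n_groups)
                )
            if np.isfinite(model.log_density(cand)):
                init = cand
                break
        if init is None:
            raise InitializationError(
                "could not find a finite initial density after 10 attempts"
            )

        sampler = _ChainSampler(model, config, init, rng)
        kept = 0
        for it in range(config.n_iterations):
            sampler.sweep(it, adapting=it < config.n_burnin)
            if it >= config.n_burnin:
                j = it - config.n_burnin
                if j % config.thinning == 0 and kept < n_keep:
                    all_draws[chain, kept] = sampler.flat_draw()
                    kept += 1

    return PosteriorDraws(
        draws=all_draws,
        param_names=names,
        subject_ids=model.subject_ids,
        group_names=model.group_names,
        config=config,
    )


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------

def summarize(draws: PosteriorDraws) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Posterior summary plus per-subject point estimates.

    Returns ``(summary, estimates)``: a table with posterior mean, sd,
    central 95% interval, split-chain rank-normalized R-hat and bulk
    effective sample size per parameter (computed with arviz), and a
    per-subject table of posterior-mean curve parameters suitable as
    dependent variables for the downstream factorial analyses.
    """
    if draws.n_chains < 2 or draws.n_draws < 100:
        raise DiagnosticsError(
            "diagnostics need >= 2 chains with >= 100 retained draws each"
        )
    import arviz as az

    arr = draws.draws  # (chain, draw, P)
    with np.errstate(invalid="ignore", divide="ignore"):
        idata = az.convert_to_dataset({"theta": arr})
        rhat = np.asarray(az.rhat(idata)["theta"])
        ess = np.asarray(az.ess(idata)["theta"])
    # constant chains have undefined R-hat/ESS; report the ideal values
    flat = arr.reshape(-1, arr.shape[2])
    const = flat.std(axis=0) == 0.0
    rhat = np.where(const, 1.0, rhat)
    ess = np.where(const, float(flat.shape[0]), ess)

    summary = pd.DataFrame(
        {
            "parameter": draws.param_names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else 0.0,
            "q2.5": np.percentile(flat, 2.5, axis=0),
            "q97.5": np.percentile(flat, 97.5, axis=0),
            "rhat": rhat,
            "ess": ess,
        }
    )
    return summary, subject_estimates(draws)


def subject_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior-mean (I, C, R) per subject."""
    means = draws.draws.reshape(-1, draws.draws.shape[2]).mean(axis=0)
    lookup = dict(zip(draws.param_names, means))
    rows = [
        {
            "subject_id": s,
            "I": lookup[f"I[{s}]"],
            "C": lookup[f"C[{s}]"],
            "R": lookup[f"R[{s}]"],
        }
        for s in draws.subject_ids
    ]
    return pd.DataFrame(rows)
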