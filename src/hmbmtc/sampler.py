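"""MCMC for the hierarchical binomial-logit model.

The published analysis ran three parallel chains with 60,000 burn-in and
60,000 saved iterations in a Gibbs-style sampler; the algorithm itself is
not part of the model contract, so this module implements an adaptive
Metropolis-within-Gibbs scheme with exact conjugate updates where the full
conditionals are tractable:

* ``alpha0``, ``eta_i``, ``theta_ij``, ``gamma_jt``: per-coordinate
  Gaussian random-walk Metropolis.  Coordinates within each block touch
  disjoint observation sets, so the whole block is proposed and
  accepted/rejected elementwise in one vectorized step.
* ``delta_j``, ``alpha1`` (truncated), imputed ``x_ij``: conjugate normal
  draws given the ``theta`` layer.
* ``1/sigma_eta^2``: conjugate gamma draw.
* ``tau_j``: random-walk Metropolis on the log scale.

Proposal scales adapt toward a 0.44 acceptance rate in batches during
burn-in (Roberts-Rosenthal) and are frozen afterwards, so the saved draws
come from a fixed-kernel chain.  All randomness flows from a single seed
via ``numpy.random.SeedSequence``; identical seed + config gives identical
draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special

from .model import (
    ALPHA1_BOUND,
    PRIOR_VAR_ALPHA0,
    PRIOR_VAR_DELTA,
    PRIOR_VAR_GAMMA,
    SIGMA_ETA_GAMMA_RATE,
    SIGMA_ETA_GAMMA_SHAPE,
    TAU_UPPER,
    ModelParameters,
    MTCModel,
)

__all__ = ["SamplerConfig", "PosteriorDraws", "run_sampler", "adaptive_metropolis"]

_TARGET_ACCEPT = 0.44
_BATCH = 50


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 3
    burn_in: int = 2000
    draws: int = 2000
    seed: int = 0
    prior_only: bool = False
    init_retries: int = 10

    @classmethod
    def preset(cls, name: str) -> "SamplerConfig":
        if name == "paper":
            return cls(chains=3, burn_in=60000, draws=60000)
        if name == "desk":
            return cls(chains=3, burn_in=2000, draws=2000)
        raise ValueError(f"unknown preset {name!r}; use 'paper' or 'desk'")


@dataclass
class PosteriorDraws:
    """Saved posterior draws, shaped (chains, draws_per_chain, ...) per block."""

    values: dict[str, np.ndarray]
    labels: dict[str, list[str]]
    chains: int
    draws_per_chain: int
    burn_in: int
    seed: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """Chain-pooled draws, shape (chains*draws, ...)."""
        v = self.values[name]
        return v.reshape((-1,) + v.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Flat columnar table with chain/iteration indices, for persistence."""
        cols: dict[str, np.ndarray] = {}
        c = np.repeat(np.arange(self.chains), self.draws_per_chain)
        it = np.tile(np.arange(self.draws_per_chain), self.chains)
        cols["chain"] = c
        cols["iteration"] = it
        for name, v in self.values.items():
            flat = v.reshape((self.chains * self.draws_per_chain, -1))
            labs = self.labels.get(name)
            for k in range(flat.shape[1]):
                col = name if flat.shape[1] == 1 and not labs else f"{name}[{labs[k]}]"
                cols[col] = flat[:, k]
        return pd.DataFrame(cols)


def _init_params(model: MTCModel, rng: np.random.Generator) -> ModelParameters:
    """Random overdispersed start: prior draws truncated to [-2, 2] on locations."""
    def loc(size=None):
        return rng.uniform(-2.0, 2.0, size=size)

    return ModelParameters(
        alpha0=float(loc()),
        alpha1=float(loc()),
        eta=loc(model.n_studies),
        theta=loc(model.n_arms),
        gamma=np.where(model.gamma_free, loc(model.n_gamma), 0.0),
        delta=np.where(model.delta_free, loc(model.n_classes), 0.0),
        tau=rng.uniform(0.5, 2.0, size=model.n_classes),
        sigma_eta=float(rng.uniform(0.5, 2.0)),
        x_missing=np.clip(rng.standard_normal(model.n_missing), -2.0, 2.0),
    )


class _Chain:
    """One chain's state and update sweep."""

    def __init__(self, model: MTCModel, cfg: SamplerConfig, rng: np.random.Generator):
        self.m = model
        self.rng = rng
        if cfg.prior_only:
            self.y = np.zeros_like(model.y)
            self.n = np.zeros_like(model.n)
        else:
            self.y = model.y
            self.n = model.n
        for attempt in range(cfg.init_retries):
            self.p = _init_params(model, rng)
            if math.isfinite(self._full_logpost()):
                break
        else:
            raise RuntimeError("non-finite log-density at initialization after retries")
        self.lp = self._lin_pred()
        # adaptive proposal log-scales, per coordinate
        self.ls_alpha0 = 0.0
        self.ls_eta = np.zeros(model.n_studies)
        self.ls_theta = np.zeros(model.n_arms)
        self.ls_gamma = np.zeros(model.n_gamma)
        self.ls_tau = np.zeros(model.n_classes)
        self.ls_cshift = np.zeros(model.n_classes)
        self.ls_ridge = 0.0
        self.adapting = True
        self._acc = {k: 0.0 for k in ("alpha0", "eta", "theta", "gamma", "tau", "cshift", "ridge")}
        self._acc_batch = {
            "alpha0": 0.0,
            "eta": np.zeros(model.n_studies),
            "theta": np.zeros(model.n_arms),
            "gamma": np.zeros(model.n_gamma),
            "tau": np.zeros(model.n_classes),
            "cshift": np.zeros(model.n_classes),
            "ridge": 0.0,
        }
        self._batch_count = 0
        self._n_batches = 0
        self._steps = 0

    # -- density pieces ------------------------------------------------- #
    def _lin_pred(self) -> np.ndarray:
        m, p = self.m, self.p
        return p.alpha0 + p.eta[m.obs_i] + p.theta[m.obs_arm] + p.gamma[m.obs_g]

    def _obs_ll(self, lp: np.ndarray) -> np.ndarray:
        pr = special.expit(lp)
        pr = np.clip(pr, 1e-12, 1.0 - 1e-12)
        return self.y * np.log(pr) + (self.n - self.y) * np.log1p(-pr)

    def _full_logpost(self) -> float:
        lp = self.m.log_prior(self.p)
        if not math.isfinite(lp):
            return -math.inf
        pred = self._lin_pred()
        return lp + float(self._obs_ll(pred).sum())

    def _mu_theta(self) -> np.ndarray:
        m, p = self.m, self.p
        x = m.covariate_values(p)
        return p.delta[m.arm_class] + p.alpha1 * x, x

    # -- updates --------------------------------------------------------- #
    def _mh_block(self, name, values, ls, obs_idx, prior_delta, free=None):
        """Vectorized elementwise random-walk MH for one block.

        Coordinates map to disjoint observation subsets, so conditional
        acceptance factorizes and can be decided per coordinate.
        """
        k = values.size
        if k == 0:
            return values
        step = np.exp(ls) * self.rng.standard_normal(k)
        if free is not None:
            step = np.where(free, step, 0.0)
        ll_old = self._obs_ll(self.lp)
        lp_new = self.lp + step[obs_idx]
        ll_new = self._obs_ll(lp_new)
        dll = np.bincount(obs_idx, weights=ll_new - ll_old, minlength=k)
        dpost = dll + prior_delta(values + step) - prior_delta(values)
        accept = np.log(self.rng.uniform(size=k)) < dpost
        if free is not None:
            accept &= free
        values = np.where(accept, values + step, values)
        acc_d = np.where(accept, step, 0.0)
        self.lp = self.lp + acc_d[obs_idx]
        self._acc_batch[name] += accept
        self._acc[name] += float(accept.mean()) if free is None else float(accept[free].mean()) if free.any() else 0.0
        return values

    def _update_alpha0(self):
        step = math.exp(self.ls_alpha0) * self.rng.standard_normal()
        new = self.p.alpha0 + step
        dll = float((self._obs_ll(self.lp + step) - self._obs_ll(self.lp)).sum())
        dprior = -0.5 * (new**2 - self.p.alpha0**2) / PRIOR_VAR_ALPHA0
        if math.log(self.rng.uniform()) < dll + dprior:
            self.p.alpha0 = new
            self.lp = self.lp + step
            self._acc_batch["alpha0"] += 1.0
            self._acc["alpha0"] += 1.0

    def _update_eta(self):
        s2 = self.p.sigma_eta**2
        self.p.eta = self._mh_block(
            "eta", self.p.eta, self.ls_eta, self.m.obs_i,
            lambda v: -0.5 * v**2 / s2,
        )

    def _update_theta(self):
        mu, _ = self._mu_theta()
        t2 = self.p.tau[self.m.arm_class] ** 2
        self.p.theta = self._mh_block(
            "theta", self.p.theta, self.ls_theta, self.m.obs_arm,
            lambda v: -0.5 * (v - mu) ** 2 / t2,
        )

    def _update_gamma(self):
        self.p.gamma = self._mh_block(
            "gamma", self.p.gamma, self.ls_gamma, self.m.obs_g,
            lambda v: -0.5 * v**2 / PRIOR_VAR_GAMMA,
            free=self.m.gamma_free,
        )

    def _update_delta(self):
        m, p = self.m, self.p
        x = m.covariate_values(p)
        resid = p.theta - p.alpha1 * x
        t2 = p.tau**2
        n_j = np.bincount(m.arm_class, minlength=m.n_classes)
        s_j = np.bincount(m.arm_class, weights=resid, minlength=m.n_classes)
        prec = 1.0 / PRIOR_VAR_DELTA + n_j / t2
        mean = (s_j / t2) / prec
        draw = mean + self.rng.standard_normal(m.n_classes) / np.sqrt(prec)
        p.delta = np.where(m.delta_free, draw, 0.0)

    def _update_alpha1(self):
        m, p = self.m, self.p
        x = m.covariate_values(p)
        t2 = p.tau[m.arm_class] ** 2
        r = p.theta - p.delta[m.arm_class]
        prec = float(np.sum(x * x / t2))
        if prec < 1e-12:
            p.alpha1 = float(self.rng.uniform(-ALPHA1_BOUND, ALPHA1_BOUND))
            return
        mean = float(np.sum(x * r / t2)) / prec
        sd = prec**-0.5
        lo = special.ndtr((-ALPHA1_BOUND - mean) / sd)
        hi = special.ndtr((ALPHA1_BOUND - mean) / sd)
        u = self.rng.uniform(lo, hi)
        u = min(max(u, 1e-15), 1 - 1e-15)
        p.alpha1 = float(mean + sd * special.ndtri(u))

    def _update_tau(self):
        m, p = self.m, self.p
        mu, _ = self._mu_theta()
        ss = np.bincount(m.arm_class, weights=(p.theta - mu) ** 2, minlength=m.n_classes)
        n_j = np.bincount(m.arm_class, minlength=m.n_classes)
        logt = np.log(p.tau)
        prop = logt + np.exp(self.ls_tau) * self.rng.standard_normal(m.n_classes)
        tau_new = np.exp(prop)
        ok = tau_new < TAU_UPPER
        # N(theta | mu, tau^2) product + Uniform(0,100) prior + log-scale Jacobian
        d = (
            -n_j * (prop - logt)
            - 0.5 * ss * (tau_new**-2 - p.tau**-2)
            + (prop - logt)
        )
        accept = ok & (np.log(self.rng.uniform(size=m.n_classes)) < d)
        p.tau = np.where(accept, tau_new, p.tau)
        self._acc_batch["tau"] += accept
        self._acc["tau"] += float(accept.mean())

    def _update_class_shift(self):
        """Joint translation of (delta_j, theta_.j): decorrelates the class
        effect from its arm effects, leaving the theta-prior kernel fixed."""
        m, p = self.m, self.p
        c = np.exp(self.ls_cshift) * self.rng.standard_normal(m.n_classes)
        c = np.where(m.delta_free, c, 0.0)
        cls_obs = m.arm_class[m.obs_arm]
        ll_old = self._obs_ll(self.lp)
        lp_new = self.lp + c[cls_obs]
        dll = np.bincount(cls_obs, weights=self._obs_ll(lp_new) - ll_old, minlength=m.n_classes)
        dprior = -0.5 * ((p.delta + c) ** 2 - p.delta**2) / PRIOR_VAR_DELTA
        accept = np.log(self.rng.uniform(size=m.n_classes)) < dll + dprior
        accept &= m.delta_free
        c_acc = np.where(accept, c, 0.0)
        p.delta = p.delta + c_acc
        p.theta = p.theta + c_acc[m.arm_class]
        self.lp = self.lp + c_acc[cls_obs]
        self._acc_batch["cshift"] += accept
        self._acc["cshift"] += float(accept[m.delta_free].mean()) if m.delta_free.any() else 0.0

    def _update_ridge(self):
        """Translation along the intercept/class-effect ridge: alpha0+c with
        theta-c and (free) delta-c leaves the likelihood unchanged.  In the
        faithful parameterization the theta prior is also invariant and only
        the vague margins decide; under the corner constraint the pinned
        class's theta-prior kernel enters the ratio."""
        m, p = self.m, self.p
        c = math.exp(self.ls_ridge) * self.rng.standard_normal()
        d = -0.5 * ((p.alpha0 + c) ** 2 - p.alpha0**2) / PRIOR_VAR_ALPHA0
        d += float(
            np.sum(-0.5 * ((p.delta[m.delta_free] - c) ** 2 - p.delta[m.delta_free] ** 2) / PRIOR_VAR_DELTA)
        )
        pinned_arms = ~m.delta_free[m.arm_class]
        if pinned_arms.any():
            mu, _ = self._mu_theta()
            r = (p.theta - mu)[pinned_arms]
            t2 = (p.tau[m.arm_class] ** 2)[pinned_arms]
            d += float(np.sum(-0.5 * ((r - c) ** 2 - r**2) / t2))
        if math.log(self.rng.uniform()) < d:
            p.alpha0 += c
            p.theta = p.theta - c
            p.delta = np.where(m.delta_free, p.delta - c, p.delta)
            self._acc_batch["ridge"] += 1.0
            self._acc["ridge"] += 1.0

    def _update_sigma_eta(self):
        p = self.p
        shape = SIGMA_ETA_GAMMA_SHAPE + 0.5 * p.eta.size
        rate = SIGMA_ETA_GAMMA_RATE + 0.5 * float(np.sum(p.eta**2))
        lam = self.rng.gamma(shape, 1.0 / rate)
        p.sigma_eta = float(lam**-0.5)

    def _update_x_missing(self):
        m, p = self.m, self.p
        if m.n_missing == 0:
            return
        cls = m.arm_class[m.missing_arms]
        t2 = p.tau[cls] ** 2
        r = p.theta[m.missing_arms] - p.delta[cls]
        prec = 1.0 + p.alpha1**2 / t2
        mean = (p.alpha1 * r / t2) / prec
        p.x_missing = mean + self.rng.standard_normal(m.n_missing) / np.sqrt(prec)

    def _adapt(self):
        self._n_batches += 1
        gain = min(0.5, self._n_batches**-0.5)

        def nudge(ls, rate):
            return ls + np.where(rate > _TARGET_ACCEPT, gain, -gain)

        b = self._batch_count
        self.ls_alpha0 += gain if self._acc_batch["alpha0"] / b > _TARGET_ACCEPT else -gain
        self.ls_eta = nudge(self.ls_eta, self._acc_batch["eta"] / b)
        self.ls_theta = nudge(self.ls_theta, self._acc_batch["theta"] / b)
        self.ls_gamma = nudge(self.ls_gamma, self._acc_batch["gamma"] / b)
        self.ls_tau = nudge(self.ls_tau, self._acc_batch["tau"] / b)
        self.ls_cshift = nudge(self.ls_cshift, self._acc_batch["cshift"] / b)
        self.ls_ridge += gain if self._acc_batch["ridge"] / b > _TARGET_ACCEPT else -gain
        for k in self._acc_batch:
            self._acc_batch[k] = self._acc_batch[k] * 0.0
        self._batch_count = 0

    def sweep(self):
        self._update_alpha0()
        self._update_eta()
        self._update_theta()
        self._update_gamma()
        self._update_delta()
        self._update_class_shift()
        self._update_ridge()
        self._update_alpha1()
        self._update_tau()
        self._update_sigma_eta()
        self._update_x_missing()
        self._steps += 1
        self._batch_count += 1
        if self.adapting and self._batch_count == _BATCH:
            self._adapt()


def run_sampler(model: MTCModel, config: SamplerConfig) -> PosteriorDraws:
    """Run the full MCMC protocol and return saved (post burn-in) draws."""
    m = model
    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(config.chains)
    C, N = config.chains, config.draws
    out = {
        "alpha0": np.empty((C, N)),
        "alpha1": np.empty((C, N)),
        "sigma_eta": np.empty((C, N)),
        "eta": np.empty((C, N, m.n_studies)),
        "theta": np.empty((C, N, m.n_arms)),
        "gamma": np.empty((C, N, m.n_gamma)),
        "delta": np.empty((C, N, m.n_classes)),
        "tau": np.empty((C, N, m.n_classes)),
        "x_missing": np.empty((C, N, m.n_missing)),
    }
    acc_total: dict[str, float] = {}
    for c in range(C):
        rng = np.random.default_rng(child_seeds[c])
        chain = _Chain(m, config, rng)
        for _ in range(config.burn_in):
            chain.sweep()
        chain.adapting = False
        for k in range(N):
            chain.sweep()
            p = chain.p
            out["alpha0"][c, k] = p.alpha0
            out["alpha1"][c, k] = p.alpha1
            out["sigma_eta"][c, k] = p.sigma_eta
            out["eta"][c, k] = p.eta
            out["theta"][c, k] = p.theta
            out["gamma"][c, k] = p.gamma
            out["delta"][c, k] = p.delta
            out["tau"][c, k] = p.tau
            out["x_missing"][c, k] = p.x_missing
        for k, v in chain._acc.items():
            acc_total[k] = acc_total.get(k, 0.0) + v / max(chain._steps, 1) / C

    labels = {
        "eta": list(m.study_ids),
        "theta": [f"{s}:{c}" for s, c in m.arm_labels],
        "gamma": [f"{c}@{t}" for c, t in m.gamma_labels],
        "delta": [c.value for c in m.classes],
        "tau": [c.value for c in m.classes],
        "x_missing": [f"{m.arm_labels[a][0]}:{m.arm_labels[a][1]}" for a in m.missing_arms],
    }
    return PosteriorDraws(
        values=out,
        labels=labels,
        chains=C,
        draws_per_chain=N,
        burn_in=config.burn_in,
        seed=config.seed,
        acceptance=acc_total,
    )


def adaptive_metropolis(
    logpdf: Callable[[np.ndarray], float],
    x0: np.ndarray,
    *,
    draws: int = 5000,
    burn_in: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Generic joint random-walk Metropolis with burn-in scale adaptation.

    Utility for small targets (closed-form cross-checks, toy posteriors);
    the full model uses :func:`run_sampler`.
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    d = x.size
    ls = 0.0
    cur = logpdf(x)
    if not math.isfinite(cur):
        raise ValueError("non-finite log-density at x0")
    out = np.empty((draws, d))
    acc = 0
    n_batches = 0
    for k in range(burn_in + draws):
        prop = x + math.exp(ls) * rng.standard_normal(d)
        new = logpdf(prop)
        if math.log(rng.uniform()) < new - cur:
            x, cur = prop, new
            acc += 1
        if k < burn_in and (k + 1) % _BATCH == 0:
            n_batches += 1
            gain = min(0.1, n_batches**-0.5)
            ls += gain if acc / _BATCH > 0.3 else -gain
            acc = 0
        if k >= burn_in:
            out[k - burn_in] = x
    return out
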