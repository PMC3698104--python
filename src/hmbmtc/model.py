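"""Arm-based hierarchical binomial-logit model for the treatment network.

For study i, treatment class j and follow-up time t, the (effective) count
of women below the blood-loss threshold is modelled as

    y_ijt ~ Binomial(n_ijt, p_ijt)
    logit(p_ijt) = alpha0 + eta_i + theta_ij + gamma_jt

with study effects eta_i ~ N(0, sigma_eta^2), class-by-study effects
theta_ij ~ N(delta_j + alpha1 * x_ij, tau_j^2) conditional on the class
effect delta_j and the standardized baseline mean blood loss x_ij, and
gamma_jt a class-specific follow-up-time increment.  A study observed at
several times shares eta_i and theta_ij across times and differs only
through gamma_jt.

Priors (variance parameterization):
    alpha0 ~ N(0, 1e4);  delta_j ~ N(0, 1e4) iid;  gamma_jt ~ N(0, 100) iid
    alpha1 ~ Uniform(-5, 5);  tau_j ~ Uniform(0, 100) iid
    1/sigma_eta^2 ~ Gamma(0.1, 0.1)  (shape-rate, the BUGS convention)
    missing x_ij ~ N(0, 1)  (missing at random)

gamma_jt exists only for (class, time) pairs actually observed; there is no
extrapolation to unobserved combinations.  The parameterization carries a
well-known translation ridge — (alpha0+c, theta-c, delta-c) leaves the
likelihood and the theta prior kernel unchanged — so only sums such as
alpha0 + delta_j + gamma_jt are reported.  An optional corner constraint
(delta for the reference class and each class's earliest gamma pinned at 0)
is available for better mixing; it changes no identifiable functional.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .network import EvidenceNetwork, Scale, TreatmentClass
from .proportions import (
    EffectiveObservation,
    ProportionConfig,
    Provenance,
    estimate_proportions,
)

__all__ = [
    "ModelParameters",
    "StandardizedCovariate",
    "MTCModel",
    "Identifiability",
    "standardize_baselines",
    "pool_same_class_arms",
]

_CLIP = 1e-12  # probability guard inside the likelihood

# prior hyperparameters (variances)
PRIOR_VAR_ALPHA0 = 1e4
PRIOR_VAR_DELTA = 1e4
PRIOR_VAR_GAMMA = 100.0
ALPHA1_BOUND = 5.0
TAU_UPPER = 100.0
SIGMA_ETA_GAMMA_SHAPE = 0.1
SIGMA_ETA_GAMMA_RATE = 0.1


class Identifiability(str, enum.Enum):
    FAITHFUL = "faithful"  # the model exactly as published: no constraint
    CORNER = "corner"      # delta_ref = 0 and gamma_{j, earliest t} = 0


@dataclass
class StandardizedCovariate:
    """Standardized baseline mean MBL per (study, class) arm."""

    values: np.ndarray        # standardized x_ij; entries at missing_mask are placeholders
    missing_mask: np.ndarray  # True where baseline was not reported
    center: float             # mL, mean of non-missing raw values
    scale: float              # mL, SD of non-missing raw values

    def standardize(self, raw_ml: float) -> float:
        return (raw_ml - self.center) / self.scale


def standardize_baselines(raw: Sequence[float | None]) -> StandardizedCovariate:
    """Center and scale baseline MBL by the mean/SD over non-missing arms."""
    arr = np.array([np.nan if v is None else float(v) for v in raw], dtype=float)
    mask = np.isnan(arr)
    obs = arr[~mask]
    if obs.size < 2:
        raise ValueError("need >= 2 non-missing baseline values to standardize")
    center = float(obs.mean())
    scale = float(obs.std(ddof=1))
    if scale <= 0:
        raise ValueError("zero spread in baseline values")
    values = np.where(mask, 0.0, (arr - center) / scale)
    return StandardizedCovariate(values=values, missing_mask=mask, center=center, scale=scale)


@dataclass
class ModelParameters:
    """One joint configuration of all model unknowns."""

    alpha0: float
    alpha1: float
    eta: np.ndarray        # (n_studies,)
    theta: np.ndarray      # (n_arms,) one per (study, class)
    gamma: np.ndarray      # (n_gamma,) one per observed (class, time)
    delta: np.ndarray      # (n_classes,)
    tau: np.ndarray        # (n_classes,) > 0
    sigma_eta: float       # > 0
    x_missing: np.ndarray  # imputed standardized baselines, one per missing arm

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.alpha0, self.alpha1, self.eta.copy(), self.theta.copy(),
            self.gamma.copy(), self.delta.copy(), self.tau.copy(),
            self.sigma_eta, self.x_missing.copy(),
        )


def pool_same_class_arms(obs: list[EffectiveObservation]) -> list[EffectiveObservation]:
    """Merge arms sharing (study, class, time, scale) by summing effective counts.

    Trials comparing two regimens of the same class (e.g. two ablation
    techniques) contribute no between-class edge but their arms are kept
    for the likelihood as one pooled class arm.  The pooled proportion is
    the count-weighted mean, so it always lies between the constituents'.
    """
    groups: dict[tuple, list[EffectiveObservation]] = {}
    order: list[tuple] = []
    for o in obs:
        k = (o.study_id, o.treatment, o.time_months, o.scale)
        if k not in groups:
            order.append(k)
        groups.setdefault(k, []).append(o)
    out: list[EffectiveObservation] = []
    for k in order:
        members = groups[k]
        if len(members) == 1:
            out.append(members[0])
            continue
        y = sum(m.y_eff for m in members)
        n = sum(m.n_eff for m in members)
        # same boundary continuity rule as direct counts
        p = (y + 0.5) / (n + 1.0) if y <= 0 or y >= n else y / n
        se = math.sqrt(p * (1 - p) / n)
        bl = [ (m.baseline_mean, m.n_eff) for m in members if m.baseline_mean is not None ]
        baseline = sum(b * w for b, w in bl) / sum(w for _, w in bl) if bl else None
        out.append(
            EffectiveObservation(
                study_id=k[0], treatment=k[1], time_months=k[2], scale=k[3],
                p_hat=p, se=se, n_eff=n, y_eff=y,
                provenance=Provenance.POOLED, baseline_mean=baseline,
            )
        )
    return out


class MTCModel:
    """The mixed-treatment-comparison model bound to a set of observations.

    Build with :meth:`from_network` (runs proportion estimation, pools
    same-class arms and standardizes baselines) or directly from effective
    observations.  :meth:`fit` runs MCMC and returns an
    :class:`~hmbmtc.results.MTCResults`.
    """

    def __init__(
        self,
        observations: list[EffectiveObservation],
        *,
        covariate: StandardizedCovariate | None = None,
        identifiability: Identifiability | str = Identifiability.FAITHFUL,
        reference_class: TreatmentClass = TreatmentClass.PLACEBO,
        design: dict | None = None,
    ):
        self.observations = list(observations)
        self.identifiability = Identifiability(identifiability)
        self.reference_class = reference_class
        self._build_index(design)
        if covariate is None:
            raw = [self._arm_baseline(i_arm) for i_arm in range(self.n_arms)]
            if sum(v is not None for v in raw) >= 2:
                covariate = standardize_baselines(raw)
            else:
                covariate = StandardizedCovariate(
                    values=np.zeros(self.n_arms),
                    missing_mask=np.ones(self.n_arms, dtype=bool),
                    center=170.0, scale=55.0,
                )
        self.covariate = covariate
        self._build_masks()

    # ------------------------------------------------------------------ #
    def _arm_baseline(self, i_arm: int) -> float | None:
        sid, tc = self.arm_labels[i_arm]
        vals = [
            (o.baseline_mean, o.n_eff)
            for o in self.observations
            if o.study_id == sid and o.treatment == tc and o.baseline_mean is not None
        ]
        if not vals:
            return None
        return sum(b * w for b, w in vals) / sum(w for _, w in vals)

    def _build_index(self, design: dict | None) -> None:
        if design is not None:
            self.study_ids = list(design["studies"])
            self.classes = [TreatmentClass(c) for c in design["classes"]]
            self.arm_labels = [(s, TreatmentClass(c)) for s, c in design["arms"]]
            self.gamma_labels = [(TreatmentClass(c), int(t)) for c, t in design["gammas"]]
        else:
            self.study_ids = sorted({o.study_id for o in self.observations})
            self.classes = sorted({o.treatment for o in self.observations}, key=lambda c: c.value)
            self.arm_labels = sorted(
                {(o.study_id, o.treatment) for o in self.observations},
                key=lambda k: (k[0], k[1].value),
            )
            self.gamma_labels = sorted(
                {(o.treatment, o.time_months) for o in self.observations},
                key=lambda k: (k[0].value, k[1]),
            )
        self.n_studies = len(self.study_ids)
        self.n_classes = len(self.classes)
        self.n_arms = len(self.arm_labels)
        self.n_gamma = len(self.gamma_labels)

        study_idx = {s: k for k, s in enumerate(self.study_ids)}
        class_idx = {c: k for k, c in enumerate(self.classes)}
        arm_idx = {a: k for k, a in enumerate(self.arm_labels)}
        gamma_idx = {g: k for k, g in enumerate(self.gamma_labels)}
        self.class_index = class_idx
        self.gamma_index = gamma_idx
        self.arm_index = arm_idx

        self.obs_i = np.array([study_idx[o.study_id] for o in self.observations], dtype=int)
        self.obs_arm = np.array(
            [arm_idx[(o.study_id, o.treatment)] for o in self.observations], dtype=int
        )
        self.obs_g = np.array(
            [gamma_idx[(o.treatment, o.time_months)] for o in self.observations], dtype=int
        )
        self.arm_class = np.array([class_idx[tc] for _, tc in self.arm_labels], dtype=int)
        self.y = np.array([o.y_eff for o in self.observations], dtype=float)
        self.n = np.array([o.n_eff for o in self.observations], dtype=float)
        # continuous-binomial normalizer, constant across parameter values
        self._log_binom = (
            special.gammaln(self.n + 1)
            - special.gammaln(self.y + 1)
            - special.gammaln(self.n - self.y + 1)
        )

    def _build_masks(self) -> None:
        """Free-parameter masks implementing the optional corner constraint."""
        self.delta_free = np.ones(self.n_classes, dtype=bool)
        self.gamma_free = np.ones(self.n_gamma, dtype=bool)
        if self.identifiability is Identifiability.CORNER:
            if self.reference_class in self.class_index:
                self.delta_free[self.class_index[self.reference_class]] = False
            earliest: dict[TreatmentClass, int] = {}
            for k, (tc, t) in enumerate(self.gamma_labels):
                if tc not in earliest or t < self.gamma_labels[earliest[tc]][1]:
                    earliest[tc] = k
            for k in earliest.values():
                self.gamma_free[k] = False
        self.missing_arms = np.flatnonzero(self.covariate.missing_mask)
        self.n_missing = int(self.missing_arms.size)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_network(
        cls,
        net: EvidenceNetwork,
        *,
        proportion_config: ProportionConfig | None = None,
        identifiability: Identifiability | str = Identifiability.FAITHFUL,
        reference_class: TreatmentClass = TreatmentClass.PLACEBO,
    ) -> "MTCModel":
        obs = pool_same_class_arms(estimate_proportions(net, proportion_config))
        return cls(obs, identifiability=identifiability, reference_class=reference_class)

    # ------------------------------------------------------------------ #
    def covariate_values(self, params: ModelParameters) -> np.ndarray:
        """Per-arm standardized baselines with imputed values filled in."""
        x = self.covariate.values.copy()
        if self.n_missing:
            x[self.missing_arms] = params.x_missing
        return x

    def linear_predictor(self, params: ModelParameters, i=None, j=None, t=None) -> np.ndarray | float:
        """logit p = alpha0 + eta_i + theta_ij + gamma_jt.

        Without arguments, returns the vector over all observations; with
        (i, j, t) — study id, class, time — a single indexed value.
        """
        if i is None:
            return (
                params.alpha0
                + params.eta[self.obs_i]
                + params.theta[self.obs_arm]
                + params.gamma[self.obs_g]
            )
        sid = self.study_ids.index(i) if not isinstance(i, (int, np.integer)) else i
        arm = self.arm_index.get((self.study_ids[sid], j))
        g = self.gamma_index.get((j, t))
        if arm is None or g is None:
            raise KeyError(f"(study={i}, class={j}, time={t}) is not indexed in the design")
        return float(params.alpha0 + params.eta[sid] + params.theta[arm] + params.gamma[g])

    def log_likelihood(self, params: ModelParameters) -> float:
        """Continuous-binomial log likelihood summed over observations."""
        if len(self.observations) == 0:
            return 0.0
        lp = self.linear_predictor(params)
        p = special.expit(lp)
        p = np.clip(p, _CLIP, 1.0 - _CLIP)
        ll = self._log_binom + self.y * np.log(p) + (self.n - self.y) * np.log1p(-p)
        return float(ll.sum())

    def log_prior(self, params: ModelParameters) -> float:
        """Joint log prior, -inf outside the support."""
        if not (-ALPHA1_BOUND < params.alpha1 < ALPHA1_BOUND):
            return -math.inf
        if np.any(params.tau <= 0) or np.any(params.tau >= TAU_UPPER):
            return -math.inf
        if params.sigma_eta <= 0:
            return -math.inf
        lp = 0.0
        lp += -0.5 * params.alpha0**2 / PRIOR_VAR_ALPHA0 - 0.5 * math.log(2 * math.pi * PRIOR_VAR_ALPHA0)
        lp += float(
            np.sum(-0.5 * params.delta**2 / PRIOR_VAR_DELTA - 0.5 * math.log(2 * math.pi * PRIOR_VAR_DELTA))
        )
        lp += float(
            np.sum(-0.5 * params.gamma**2 / PRIOR_VAR_GAMMA - 0.5 * math.log(2 * math.pi * PRIOR_VAR_GAMMA))
        )
        lp += -math.log(2 * ALPHA1_BOUND)  # Uniform(-5,5)
        lp += -self.n_classes * math.log(TAU_UPPER)  # Uniform(0,100) each
        prec = params.sigma_eta**-2
        lp += float(stats.gamma.logpdf(prec, a=SIGMA_ETA_GAMMA_SHAPE, scale=1.0 / SIGMA_ETA_GAMMA_RATE))
        s2 = params.sigma_eta**2
        lp += float(np.sum(-0.5 * params.eta**2 / s2 - 0.5 * np.log(2 * math.pi * s2)))
        x = self.covariate_values(params)
        mu_theta = params.delta[self.arm_class] + params.alpha1 * x
        t2 = params.tau[self.arm_class] ** 2
        lp += float(np.sum(-0.5 * (params.theta - mu_theta) ** 2 / t2 - 0.5 * np.log(2 * math.pi * t2)))
        if self.n_missing:
            lp += float(np.sum(-0.5 * params.x_missing**2 - 0.5 * math.log(2 * math.pi)))
        return lp

    def log_posterior(self, params: ModelParameters) -> float:
        lp = self.log_prior(params)
        if not math.isfinite(lp):
            return -math.inf
        return lp + self.log_likelihood(params)

    # ------------------------------------------------------------------ #
    def fit(
        self,
        *,
        preset: str = "desk",
        chains: int | None = None,
        burn_in: int | None = None,
        draws: int | None = None,
        seed: int = 0,
        prior_only: bool = False,
        progress: bool = False,
    ):
        """Sample the posterior and return an :class:`MTCResults`.

        ``preset="paper"`` reproduces the published protocol (3 chains,
        60,000 burn-in, 60,000 saved); ``preset="desk"`` is the fast
        profile (3 chains, 2,000 + 2,000) for interactive and test use.
        Explicit ``chains``/``burn_in``/``draws`` override the preset.
        """
        from .results import MTCResults
        from .sampler import SamplerConfig, run_sampler

        cfg = SamplerConfig.preset(preset)
        if chains is not None:
            cfg = replace(cfg, chains=chains)
        if burn_in is not None:
            cfg = replace(cfg, burn_in=burn_in)
        if draws is not None:
            cfg = replace(cfg, draws=draws)
        cfg = replace(cfg, seed=seed, prior_only=prior_only)
        posterior = run_sampler(self, cfg)
        return MTCResults(self, posterior)

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        """Serializable specification: index maps + prior hyperparameters."""
        return json.dumps(
            {
                "studies": self.study_ids,
                "classes": [c.value for c in self.classes],
                "arms": [[s, c.value] for s, c in self.arm_labels],
                "gammas": [[c.value, t] for c, t in self.gamma_labels],
                "identifiability": self.identifiability.value,
                "reference_class": self.reference_class.value,
                "covariate": {
                    "center": self.covariate.center,
                    "scale": self.covariate.scale,
                    "missing": self.covariate.missing_mask.tolist(),
                },
                "priors": {
                    "var_alpha0": PRIOR_VAR_ALPHA0,
                    "var_delta": PRIOR_VAR_DELTA,
                    "var_gamma": PRIOR_VAR_GAMMA,
                    "alpha1_bound": ALPHA1_BOUND,
                    "tau_upper": TAU_UPPER,
                    "sigma_eta_gamma": [SIGMA_ETA_GAMMA_SHAPE, SIGMA_ETA_GAMMA_RATE],
                },
            },
            indent=2,
        )
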