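"""Posterior summaries: efficacy tables with credible intervals.

The deliverable of the analysis is, per treatment class and follow-up
time, the posterior median (with equal-tailed 95% credible interval) of
the percentage of women below the blood-loss threshold, evaluated at a
reference baseline MBL.  Per draw the predicted probability is

    p = inverse-logit(alpha0 + delta_j + alpha1 * x_ref + gamma_jt)

with x_ref the standardized reference baseline (0 at the stored center,
the all-study average of reported baseline means) and the study-level
random effects at their conditional means ("typical study" plug-in:
eta = 0, theta centered at delta_j + alpha1*x_ref).  A marginal mode
instead adds new-study noise N(0, sigma_eta^2) + N(0, tau_j^2) per draw.
Only the identifiable sum alpha0 + delta_j + gamma_jt enters predictions,
so they are invariant to the intercept/class-effect translation ridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .model import MTCModel
from .network import TreatmentClass
from .sampler import PosteriorDraws

__all__ = [
    "EfficacyEstimate",
    "MTCResults",
    "predict_efficacy",
    "efficacy_table",
    "cri_width_report",
    "NoParameterError",
]

#: reference baseline: all-study average of reported baseline mean MBL (mL)
DEFAULT_REFERENCE_BASELINE = 169.64


class NoParameterError(KeyError):
    """Requested (class, time) pair has no follow-up parameter in the model."""


@dataclass(frozen=True)
class EfficacyEstimate:
    """Posterior efficacy of one class at one time, in percent."""

    treatment: TreatmentClass
    time_months: int
    median_pct: float
    cri_low_pct: float
    cri_high_pct: float
    reference_baseline: float

    def __post_init__(self):
        if not (self.cri_low_pct <= self.median_pct <= self.cri_high_pct):
            raise ValueError("credible interval must bracket the median")

    @property
    def width_pct(self) -> float:
        return self.cri_high_pct - self.cri_low_pct

    def render(self) -> str:
        """Table-style rendering, e.g. ``87.5 (77.6-93.9)``."""
        return f"{self.median_pct:.1f} ({self.cri_low_pct:.1f}-{self.cri_high_pct:.1f})"


def _efficacy_draws(
    model: MTCModel,
    draws: PosteriorDraws,
    j: TreatmentClass,
    t: int,
    baseline: float | None,
    mode: str,
    rng: np.random.Generator | None,
) -> np.ndarray:
    if (j, t) not in model.gamma_index:
        raise NoParameterError(
            f"no follow-up parameter for ({j}, {t} months): the pair was never "
            "observed and the model does not extrapolate"
        )
    if baseline is None:
        baseline = model.covariate.center
    x_ref = model.covariate.standardize(baseline)
    jx = model.class_index[j]
    g = model.gamma_index[(j, t)]
    a0 = draws.stacked("alpha0")
    a1 = draws.stacked("alpha1")
    dj = draws.stacked("delta")[:, jx]
    gj = draws.stacked("gamma")[:, g]
    lp = a0 + dj + a1 * x_ref + gj
    if mode == "marginal":
        if rng is None:
            rng = np.random.default_rng(0)
        sig = draws.stacked("sigma_eta")
        tau = draws.stacked("tau")[:, jx]
        lp = lp + sig * rng.standard_normal(lp.size) + tau * rng.standard_normal(lp.size)
    elif mode != "plugin":
        raise ValueError("mode must be 'plugin' or 'marginal'")
    return special.expit(lp)


def predict_efficacy(
    model: MTCModel,
    draws: PosteriorDraws,
    j: TreatmentClass,
    t: int,
    baseline: float | None = None,
    *,
    mode: str = "plugin",
    rng: np.random.Generator | None = None,
) -> EfficacyEstimate:
    """Posterior median and equal-tailed 95% CrI of % below threshold.

    Percentiles use linear interpolation (type 7), matching the 2.5/50/97.5
    percentage points of the posterior distribution.
    """
    p = _efficacy_draws(model, draws, j, t, baseline, mode, rng)
    lo, med, hi = np.percentile(p, [2.5, 50.0, 97.5])
    return EfficacyEstimate(
        treatment=j,
        time_months=t,
        median_pct=100.0 * float(med),
        cri_low_pct=100.0 * float(lo),
        cri_high_pct=100.0 * float(hi),
        reference_baseline=float(baseline if baseline is not None else model.covariate.center),
    )


def efficacy_table(
    model: MTCModel,
    draws: PosteriorDraws,
    times: Sequence[int],
    baseline: float | None = None,
    *,
    mode: str = "plugin",
    rng: np.random.Generator | None = None,
) -> list[EfficacyEstimate]:
    """Efficacy estimates for every class observed at each requested time.

    Within each time, rows are sorted by descending posterior median.
    """
    out: list[EfficacyEstimate] = []
    for t in times:
        rows = [
            predict_efficacy(model, draws, j, t, baseline, mode=mode, rng=rng)
            for (j, tt) in model.gamma_labels
            if tt == t
        ]
        rows.sort(key=lambda e: (-e.median_pct, e.treatment.value))
        out.extend(rows)
    return out


def cri_width_report(table: Iterable[EfficacyEstimate]) -> pd.DataFrame:
    """Credible-interval widths (percentage points) per table row."""
    return pd.DataFrame(
        [
            {
                "class": e.treatment.value,
                "time_months": e.time_months,
                "width_pct": e.width_pct,
            }
            for e in table
        ]
    )


def efficacy_frame(table: Iterable[EfficacyEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": e.treatment.value,
                "time_months": e.time_months,
                "median_pct": e.median_pct,
                "cri_low_pct": e.cri_low_pct,
                "cri_high_pct": e.cri_high_pct,
                "width_pct": e.width_pct,
                "reference_baseline": e.reference_baseline,
            }
            for e in table
        ]
    )


def render_markdown(table: Iterable[EfficacyEstimate]) -> str:
    """Markdown table in the publication's layout."""
    lines = ["| Treatment | Time (months) | % below threshold (95% CrI) |", "|---|---|---|"]
    for e in table:
        lines.append(f"| {e.treatment.value} | {e.time_months} | {e.render()} |")
    return "\n".join(lines)


class MTCResults:
    """Fitted-model results: draws, diagnostics and efficacy summaries."""

    def __init__(self, model: MTCModel, posterior: PosteriorDraws):
        self.model = model
        self.posterior = posterior

    # -- efficacy ------------------------------------------------------- #
    def predict_efficacy(self, j, t, baseline=None, *, mode="plugin", rng=None) -> EfficacyEstimate:
        return predict_efficacy(self.model, self.posterior, j, t, baseline, mode=mode, rng=rng)

    def efficacy_table(self, times, baseline=None, *, mode="plugin", rng=None) -> list[EfficacyEstimate]:
        return efficacy_table(self.model, self.posterior, times, baseline, mode=mode, rng=rng)

    def efficacy_frame(self, times, baseline=None, **kw) -> pd.DataFrame:
        return efficacy_frame(self.efficacy_table(times, baseline, **kw))

    def identifiable_sum_draws(self, j: TreatmentClass, t: int) -> np.ndarray:
        """Pooled draws of alpha0 + delta_j + gamma_jt (logit scale)."""
        if (j, t) not in self.model.gamma_index:
            raise NoParameterError(f"({j}, {t}) not in design")
        return (
            self.posterior.stacked("alpha0")
            + self.posterior.stacked("delta")[:, self.model.class_index[j]]
            + self.posterior.stacked("gamma")[:, self.model.gamma_index[(j, t)]]
        )

    # -- diagnostics ---------------------------------------------------- #
    def psrf(self, param_selector=None) -> dict[str, float]:
        from .diagnostics import gelman_rubin

        return gelman_rubin(self.posterior, param_selector)

    def trace_summary(self, param_selector=None) -> pd.DataFrame:
        from .diagnostics import trace_summary

        return trace_summary(self.posterior, param_selector)

    # -- reporting ------------------------------------------------------ #
    def summary(self, times: Sequence[int] | None = None, baseline: float | None = None) -> str:
        """Human-readable fit summary: efficacy table + convergence flags."""
        times = list(times) if times is not None else sorted({t for _, t in self.model.gamma_labels})
        table = self.efficacy_table(times, baseline)
        lines = [
            "Mixed-treatment-comparison fit",
            f"  studies: {self.model.n_studies}  classes: {self.model.n_classes}  "
            f"observations: {len(self.model.observations)}",
            f"  chains: {self.posterior.chains}  draws/chain: {self.posterior.draws_per_chain}  "
            f"burn-in: {self.posterior.burn_in}",
            f"  reference baseline MBL: "
            f"{baseline if baseline is not None else self.model.covariate.center:.2f} mL",
            "",
            render_markdown(table),
        ]
        if self.posterior.chains >= 2:
            rh = self.psrf(["alpha0", "alpha1", "delta", "gamma"])
            finite = {k: v for k, v in rh.items() if not math.isnan(v)}
            worst = max(finite, key=finite.get) if finite else None
            if worst is not None:
                lines += ["", f"  max PSRF (Brooks-Gelman): {finite[worst]:.3f} [{worst}]"]
                flagged = sorted(k for k, v in finite.items() if v > 1.1)
                if flagged:
                    lines.append(f"  PSRF > 1.1: {', '.join(flagged)}")
        return "\n".join(lines)
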