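"""Empirical precursor ("source") time courses.

The compartment models are fed by transitional (T1, T2) or FM B cells whose
size, donor chimerism and Ki67-high fraction are described empirically as
functions of host age, fitted independently of the main inference and then
frozen (two-stage estimation).  Functional forms:

* adult precursor size: ``S(t) = exp(s0 + s1 * exp(-s2 * t))`` — smooth,
  saturating, nearly flat over 75-600 days for T1;
* young-mouse T1 size: ``S(t) = A * t^p * exp(-t / tau) + B`` — rises to a
  peak near 20 days of age, declines over the next few weeks, then plateaus;
* donor chimerism: ``chi(t) = chi_stable * (1 - exp(-k (t - t_bmt)))`` —
  zero at transplant, saturating at the stable bone-marrow chimerism;
* Ki67-high fraction: constant in host age (transitional Ki67 is residual
  from bone-marrow precursor divisions and does not vary with age).

All forms are replaceable defaults; the fitting machinery only requires the
``size / chimerism / ki67 / chi_stable`` interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = [
    "SourceModel",
    "SourceFit",
    "eval_source",
    "fit_source",
    "young_t1_timecourse",
    "adult_size_curve",
]

_EPS = 1e-4


def adult_size_curve(t, s0, s1, s2):
    """Saturating adult precursor size, ``exp(s0 + s1 * exp(-s2 t))`` cells."""
    t = np.asarray(t, float)
    return np.exp(s0 + s1 * np.exp(-s2 * t))


def young_t1_timecourse(t, amplitude, power, tau, plateau):
    """Unimodal young-mouse T1 numbers: ``A t^p exp(-t/tau) + B`` cells.

    Peaks at ``t = p * tau`` (near 20 days for the default fixture), then
    declines to the adult plateau ``B`` over the following weeks.
    """
    t = np.asarray(t, float)
    return amplitude * t**power * np.exp(-t / tau) + plateau


@dataclass(frozen=True)
class SourceModel:
    """Frozen empirical description of a precursor population.

    ``size_fn`` maps host age (days) to cell numbers; chimerism rises from 0
    at the transplant age to ``chi_stable`` at rate ``chi_rate``; the
    Ki67-high fraction is ``ki67_fn`` of host age (constant by default).
    ``t_min``/``t_max`` bound the supported host-age range.
    """

    size_fn: Callable
    chi_stable: float = 0.8
    chi_rate: float = 0.107
    ki67_fn: Callable = field(default=lambda t: np.full_like(np.asarray(t, float), 0.8))
    t_min: float = 0.0
    t_max: float = 750.0
    label: str = "T1"

    def _check_range(self, t):
        t = np.asarray(t, float)
        if np.any(t < self.t_min) or np.any(t > self.t_max):
            raise ValueError(
                f"host age outside supported range [{self.t_min}, {self.t_max}] for source {self.label}"
            )
        return t

    def size(self, t):
        return self.size_fn(self._check_range(t))

    def chimerism(self, t, t_bmt):
        t = self._check_range(t)
        dt = np.asarray(t, float) - t_bmt
        if np.any(dt < -1e-9):
            raise ValueError("chimerism requested before the transplant age")
        return self.chi_stable * -np.expm1(-self.chi_rate * np.clip(dt, 0.0, None))

    def ki67(self, t):
        return np.clip(self.ki67_fn(self._check_range(t)), 0.0, 1.0)


def eval_source(src: SourceModel, t, t_bmt):
    """Evaluate (size, donor fraction, Ki67-high fraction) at host age ``t``."""
    return src.size(t), src.chimerism(t, t_bmt), src.ki67(t)


@dataclass
class SourceFit:
    """Result of independently fitting the source component curves."""

    params: dict
    residual_sd: dict
    source: SourceModel


def _fit_log_size(t, y, young):
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    logy = np.log(y)
    if young:
        # A t^p exp(-t/tau) + B on the log scale
        def resid(q):
            a, p, tau, b = np.exp(q[0]), q[1], np.exp(q[2]), np.exp(q[3])
            return np.log(young_t1_timecourse(t, a, p, tau, b)) - logy

        peak = t[np.argmax(y)]
        q0 = np.array([np.log(y.max() / max(peak, 1.0) ** 2), 2.0, np.log(max(peak / 2.0, 2.0)), np.log(y.min())])
        sol = least_squares(resid, q0, method="lm", max_nfev=20000)
        a, p, tau, b = np.exp(sol.x[0]), sol.x[1], np.exp(sol.x[2]), np.exp(sol.x[3])
        params = {"amplitude": a, "power": p, "tau": tau, "plateau": b}
        fn = lambda tt, a=a, p=p, tau=tau, b=b: young_t1_timecourse(tt, a, p, tau, b)
    else:
        def resid(q):
            return q[0] + q[1] * np.exp(-np.exp(q[2]) * t) - logy

        q0 = np.array([logy[np.argmax(t)], logy[np.argmin(t)] - logy[np.argmax(t)], np.log(0.01)])
        sol = least_squares(resid, q0, method="lm", max_nfev=20000)
        s0, s1, s2 = sol.x[0], sol.x[1], np.exp(sol.x[2])
        params = {"s0": s0, "s1": s1, "s2": s2}
        fn = lambda tt, s0=s0, s1=s1, s2=s2: adult_size_curve(tt, s0, s1, s2)
    sd = float(np.std(sol.fun, ddof=min(len(sol.x), len(t) - 1)))
    return params, fn, sd


def _fit_chimerism(days_post_bmt, y):
    d = np.asarray(days_post_bmt, float)
    y = np.clip(np.asarray(y, float), _EPS, 1.0 - _EPS)
    ly = logit(y)

    def resid(q):
        chi, k = expit(q[0]), np.exp(q[1])
        pred = np.clip(chi * -np.expm1(-k * d), _EPS, 1.0 - _EPS)
        return logit(pred) - ly

    q0 = np.array([logit(np.clip(y.max(), 0.05, 0.98)), np.log(0.1)])
    sol = least_squares(resid, q0, max_nfev=20000)
    chi, k = float(expit(sol.x[0])), float(np.exp(sol.x[1]))
    sd = float(np.std(sol.fun, ddof=1))
    return {"chi_stable": chi, "chi_rate": k}, sd


def fit_source(
    size_obs=None,
    chimerism_obs=None,
    ki67_obs=None,
    young: bool = False,
    label: str = "T1",
    t_max: float = 750.0,
) -> SourceFit:
    """Fit the empirical source curves by least squares on transformed scales.

    Each observation set is a ``(x, y)`` pair of arrays: host age vs cell
    numbers for ``size_obs`` (fitted on the log scale), days post transplant
    vs donor fraction for ``chimerism_obs`` (logit scale), and host age vs
    Ki67-high fraction for ``ki67_obs`` (logit scale, constant model).
    Requires at least 4 observations per supplied component.
    """
    params: dict = {}
    resid_sd: dict = {}

    size_fn = lambda t: np.full_like(np.asarray(t, float), np.nan)
    chi_stable, chi_rate = 0.8, 0.107
    kappa = 0.8

    if size_obs is not None:
        t, y = map(np.asarray, size_obs)
        if t.size < 4 or np.unique(t).size < 2:
            raise ValueError("size fit needs >= 4 observations at >= 2 distinct ages")
        p, size_fn, sd = _fit_log_size(t, y, young)
        params["size"] = p
        resid_sd["size"] = sd
    if chimerism_obs is not None:
        d, y = map(np.asarray, chimerism_obs)
        if d.size < 4 or np.unique(d).size < 2:
            raise ValueError("chimerism fit needs >= 4 observations at >= 2 distinct times")
        p, sd = _fit_chimerism(d, y)
        chi_stable, chi_rate = p["chi_stable"], p["chi_rate"]
        params["chimerism"] = p
        resid_sd["chimerism"] = sd
    if ki67_obs is not None:
        t, y = map(np.asarray, ki67_obs)
        if t.size < 4:
            raise ValueError("ki67 fit needs >= 4 observations")
        y = np.clip(np.asarray(y, float), _EPS, 1.0 - _EPS)
        kappa = float(expit(np.mean(logit(y))))
        params["ki67"] = {"kappa": kappa}
        resid_sd["ki67"] = float(np.std(logit(y), ddof=1))

    src = SourceModel(
        size_fn=size_fn,
        chi_stable=chi_stable,
        chi_rate=chi_rate,
        ki67_fn=lambda t, kappa=kappa: np.full_like(np.asarray(t, float), kappa),
        t_min=0.0,
        t_max=t_max,
        label=label,
    )
    return SourceFit(params=params, residual_sd=resid_sd, source=src)
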