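"""Age-structured FM model, GFP fluorescence mapping, young-mouse variants.

The unstructured compartment model has an equivalent formulation in terms of
the density ``u(a, t)`` of cells over cell age ``a`` (time since entry into
the FM compartment) at host age ``t``:

    u(a, t) = E(t - a) * exp(-int_{t-a}^{t} lambda(s) ds),   a < t - t0,

by the method of characteristics, where ``E(s) = phi(s) m(s) S(s)`` is the
entry rate and ``lambda = delta + extra_death - rho`` the net loss rate
(division leaves a lineage's entry time unchanged on average, so the density
thins at the *net* rate).  Cells already present at the starting age ``t0``
form a boundary cohort carried as an atom with an assumed steady-state
exponential age profile.

Rag2-GFP fluorescence decays exponentially with cell age,
``g(a) = g0 exp(-gamma a)``, which maps age distributions onto measurable
mean fluorescence intensities (MFI) of all FM cells and of the
"GFP-positive" subset above a gating threshold.  Two competing extensions
reconcile the adult model with young-mouse FM counts: a per-capita influx
that ramps up with host age (``rising_influx``) or an excess early-life
death rate (``early_death``); they predict different age distributions and
hence different GFP readouts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .models import KineticParams, T_REF

__all__ = [
    "GFPMap",
    "YoungVariant",
    "AgeDensity",
    "solve_age_density",
    "predict_gfp",
    "solve_young_counts",
    "fit_young_variants",
]


@dataclass(frozen=True)
class GFPMap:
    """Map from cell age to GFP fluorescence: ``g(a) = g0 exp(-gamma a)``.

    ``threshold`` is the gate above which a cell scores GFP-positive; cells
    are positive while younger than ``ln(g0 / threshold) / gamma`` days.
    """

    g0: float
    gamma: float
    threshold: float

    def __post_init__(self):
        if self.g0 <= 0 or self.gamma < 0:
            raise ValueError("need g0 > 0 and gamma >= 0")
        if not 0.0 < self.threshold < self.g0:
            raise ValueError("threshold must lie in (0, g0)")

    def fluorescence(self, age):
        return self.g0 * np.exp(-self.gamma * np.asarray(age, float))

    @property
    def age_cut(self) -> float:
        if self.gamma == 0.0:
            return np.inf
        return float(np.log(self.g0 / self.threshold) / self.gamma)


@dataclass(frozen=True)
class YoungVariant:
    """Young-mouse extension of the adult FM model.

    ``rising_influx``: per-capita recruitment from T1 is multiplied by a
    logistic ramp in host age, ``1 / (1 + exp(-(t - t_mid) / width))``.
    ``early_death``: the loss rate gains an additive excess
    ``d_young * exp(-w_decay * t)``.  Both reduce to the adult model at
    large host age.
    """

    kind: str = "rising_influx"
    t_mid: float = 30.0
    width: float = 15.0
    d_young: float = 0.15
    w_decay: float = 0.03

    def __post_init__(self):
        if self.kind not in ("rising_influx", "early_death", "adult"):
            raise ValueError("kind must be 'rising_influx', 'early_death' or 'adult'")
        if self.width <= 0 or self.w_decay < 0 or self.d_young < 0:
            raise ValueError("invalid young-variant parameters")

    def influx_multiplier(self, t):
        t = np.asarray(t, float)
        if self.kind != "rising_influx":
            return np.ones_like(t)
        return 1.0 / (1.0 + np.exp(-(t - self.t_mid) / self.width))

    def extra_death(self, t):
        t = np.asarray(t, float)
        if self.kind != "early_death":
            return np.zeros_like(t)
        return self.d_young * np.exp(-self.w_decay * t)


def _entry_rate(variant, params, source, s):
    return params.phi(s, T_REF) * variant.influx_multiplier(s) * np.asarray(source.size(s), float)


def _net_loss(variant, params, s):
    return params.delta(s, T_REF) + variant.extra_death(s) - params.rho(s, T_REF)


def solve_young_counts(
    variant: YoungVariant,
    params: KineticParams,
    source,
    t_grid,
    t_start: float = 10.0,
    n0: float = 1.0e6,
):
    """Total FM numbers in young mice: ``N' = E(t) - (delta + eps - rho) N``."""
    from .models import _linear_forced_path

    t_grid = np.atleast_1d(np.asarray(t_grid, float))
    grid = np.union1d(np.arange(t_start, t_grid[-1] + 0.25, 0.25), t_grid)
    mid = 0.5 * (grid[:-1] + grid[1:])
    path = _linear_forced_path(
        _net_loss(variant, params, mid), _entry_rate(variant, params, source, mid), grid, n0
    )
    return np.interp(t_grid, grid, path)


@dataclass
class AgeDensity:
    """Cell-age density at one host age, plus the boundary-cohort atom.

    ``ages``/``u`` give the density (cells per day of age) for cells that
    entered after the tracking start; the boundary cohort (cells already
    present at ``t_start``) is an atom of mass ``atom_mass`` whose ages are
    ``atom_age_offset`` plus an exponential with rate ``atom_rate``.
    """

    t: float
    ages: np.ndarray
    u: np.ndarray
    atom_mass: float
    atom_age_offset: float
    atom_rate: float

    def total(self) -> float:
        return float(np.trapezoid(self.u, self.ages) + self.atom_mass)

    def mean_age(self) -> float:
        m_new = np.trapezoid(self.u * self.ages, self.ages)
        m_atom = self.atom_mass * (self.atom_age_offset + 1.0 / self.atom_rate)
        return float((m_new + m_atom) / self.total())

    def cdf(self, a):
        """Fraction of cells with age <= a."""
        a = np.atleast_1d(np.asarray(a, float))
        tot = self.total()
        out = np.empty_like(a)
        cum = np.concatenate(([0.0], np.cumsum(np.diff(self.ages) * 0.5 * (self.u[:-1] + self.u[1:]))))
        for i, ai in enumerate(a):
            new_part = np.interp(ai, self.ages, cum)
            if ai <= self.atom_age_offset:
                atom_part = 0.0
            else:
                atom_part = self.atom_mass * -np.expm1(-self.atom_rate * (ai - self.atom_age_offset))
            out[i] = (new_part + atom_part) / tot
        return out if out.size > 1 else float(out[0])


def solve_age_density(
    variant: YoungVariant,
    params: KineticParams,
    source,
    t: float,
    t_start: float = 10.0,
    n0: float = 1.0e6,
    da: float = 0.25,
) -> AgeDensity:
    """Cell-age density of the FM pool at host age ``t`` by characteristics.

    Cells of age ``a < t - t_start`` entered at time ``t - a`` at rate
    ``E(t - a)`` and survived with probability
    ``exp(-int (delta + eps - rho))`` along the characteristic; older cells
    belong to the boundary cohort, whose mass decays by the same survival
    factor from ``t_start`` and whose internal age profile is the
    steady-state exponential at the starting age.
    """
    if t < t_start:
        raise ValueError("t must be >= t_start")
    # entry-time grid s in [t_start, t]; ages a = t - s
    s = np.union1d(np.arange(t_start, t + da, da), [t])
    lam = _net_loss(variant, params, s)
    # cumulative net loss integral from s to t (trapezoid, reversed)
    seg = np.diff(s) * 0.5 * (lam[:-1] + lam[1:])
    cum_from_start = np.concatenate(([0.0], np.cumsum(seg)))
    integral_s_to_t = cum_from_start[-1] - cum_from_start
    u_entry = _entry_rate(variant, params, source, s) * np.exp(-integral_s_to_t)
    ages = t - s[::-1]
    u = u_entry[::-1]

    atom_rate = max(float(_net_loss(variant, params, t_start)), 1e-6)
    atom_mass = n0 * float(np.exp(-integral_s_to_t[0]))
    return AgeDensity(
        t=float(t),
        ages=ages,
        u=u,
        atom_mass=atom_mass,
        atom_age_offset=float(t - t_start),
        atom_rate=atom_rate,
    )


def predict_gfp(density: AgeDensity, gfp: GFPMap):
    """(MFI of all cells, MFI of GFP-positive cells, GFP-positive fraction).

    The GFP-positive set is ``{a < age_cut}``; if no cells fall in it, the
    positive-set MFI is reported missing (NaN).
    """
    g = gfp.fluorescence(density.ages)
    total = density.total()
    atom_extra = 1.0 / (1.0 + gfp.gamma / density.atom_rate)  # E[e^{-gamma * exp age}]
    atom_g = gfp.fluorescence(density.atom_age_offset) * atom_extra
    mfi_total = (np.trapezoid(g * density.u, density.ages) + density.atom_mass * atom_g) / total

    cut = gfp.age_cut
    in_pos = density.ages <= cut
    pos_mass = np.trapezoid(density.u[in_pos], density.ages[in_pos]) if in_pos.sum() > 1 else 0.0
    pos_fluo = (
        np.trapezoid((g * density.u)[in_pos], density.ages[in_pos]) if in_pos.sum() > 1 else 0.0
    )
    if cut > density.atom_age_offset:
        # part of the boundary cohort still gates positive
        w = -np.expm1(-density.atom_rate * (cut - density.atom_age_offset))
        pos_mass += density.atom_mass * w
        r, gam, a0 = density.atom_rate, gfp.gamma, density.atom_age_offset
        z = r + gam
        pos_fluo += (
            density.atom_mass
            * gfp.fluorescence(a0)
            * r / z * -np.expm1(-z * (cut - a0))
        )
    if pos_mass <= 0.0:
        return float(mfi_total), float("nan"), 0.0
    return float(mfi_total), float(pos_fluo / pos_mass), float(pos_mass / total)


def _fit_variant_to_counts(kind, params, source, counts_df, t_start, n0):
    t = counts_df["age_d"].to_numpy(float)
    y = np.log(counts_df["counts"].to_numpy(float))

    if kind == "rising_influx":
        def make(q):
            return YoungVariant(kind=kind, t_mid=q[0], width=np.exp(q[1]))
        q0 = np.array([35.0, np.log(8.0)])
    else:
        def make(q):
            return YoungVariant(kind=kind, d_young=np.exp(q[0]), w_decay=np.exp(q[1]))
        q0 = np.array([np.log(0.1), np.log(0.03)])

    def resid(q):
        v = make(q)
        pred = solve_young_counts(v, params, source, t, t_start=t_start, n0=n0)
        return np.log(np.clip(pred, 1e-300, None)) - y

    sol = least_squares(resid, q0, max_nfev=4000)
    return make(sol.x), float(np.sum(sol.fun**2))


def _fit_gfp_map(variant, params, source, mfi_df, threshold, t_start, n0):
    t = mfi_df["age_d"].to_numpy(float)
    y = np.log(mfi_df["mfi_total"].to_numpy(float))
    dens = [solve_age_density(variant, params, source, ti, t_start=t_start, n0=n0) for ti in t]

    def resid(q):
        gmap = GFPMap(g0=np.exp(q[0]), gamma=np.exp(q[1]), threshold=threshold)
        pred = np.array([predict_gfp(d, gmap)[0] for d in dens])
        return np.log(np.clip(pred, 1e-300, None)) - y

    q0 = np.array([np.log(np.exp(y.max()) * 2.0), np.log(0.1)])
    sol = least_squares(resid, q0, max_nfev=2000)
    return GFPMap(g0=float(np.exp(sol.x[0])), gamma=float(np.exp(sol.x[1])), threshold=threshold)


def fit_young_variants(
    counts_df,
    mfi_df,
    adult_params: KineticParams,
    source_young,
    threshold: float = 50.0,
    t_start: float = 10.0,
    n0: float = 1.0e6,
) -> dict:
    """Fit both young-mouse variants and discriminate them with GFP data.

    Stage 1 fits each variant's two extension parameters to young FM counts
    (adult kinetics frozen).  Stage 2 fits the two GFP parameters (initial
    fluorescence and decay rate) to the total-FM MFI series.  Each fitted
    variant then *predicts* the held-out MFI of GFP-positive cells; the
    variant with the smaller squared error on that prediction is preferred.

    ``counts_df`` needs columns (age_d, counts); ``mfi_df`` needs
    (age_d, mfi_total, mfi_pos).
    """
    results = {}
    for kind in ("rising_influx", "early_death"):
        variant, sse_counts = _fit_variant_to_counts(
            kind, adult_params, source_young, counts_df, t_start, n0
        )
        gmap = _fit_gfp_map(variant, adult_params, source_young, mfi_df, threshold, t_start, n0)
        t = mfi_df["age_d"].to_numpy(float)
        obs_pos = mfi_df["mfi_pos"].to_numpy(float)
        pred_pos = np.array(
            [
                predict_gfp(
                    solve_age_density(variant, adult_params, source_young, ti, t_start=t_start, n0=n0),
                    gmap,
                )[1]
                for ti in t
            ]
        )
        ok = np.isfinite(obs_pos) & np.isfinite(pred_pos)
        sse_pos = float(np.sum((np.log(pred_pos[ok]) - np.log(obs_pos[ok])) ** 2))
        results[kind] = {
            "variant": variant,
            "gfp_map": gmap,
            "sse_counts": sse_counts,
            "sse_pos_mfi": sse_pos,
            "pred_pos_mfi": pred_pos,
        }
    results["preferred"] = min(
        ("rising_influx", "early_death"), key=lambda k: results[k]["sse_pos_mfi"]
    )
    return results
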