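"""Ki67-structured compartment models of peripheral B cell maintenance.

Each model tracks a B cell compartment (e.g. follicular mature, FM, or
germinal center, GC, B cells) fed by a precursor population whose size
``S(t)``, donor chimerism ``chi(t)`` and Ki67-high fraction ``kappa(t)`` are
empirical functions of host age (see :mod:`bcellfate.sources`).  Within the
compartment, cells are stratified by lineage (host / donor) and by Ki67
status (high / low).  For every subset and lineage the dynamics are

    dK_hi/dt = a * phi(t) S(t) chi(t) kappa(t) + rho (K_hi + 2 K_lo)
               - (beta + delta(t)) K_hi
    dK_lo/dt = a * phi(t) S(t) chi(t) (1 - kappa(t)) + beta K_hi
               - (rho + delta(t)) K_lo

where ``phi`` is the per-capita recruitment rate from the precursor, ``a``
the subset's share of the influx, ``delta`` the loss rate (death plus onward
differentiation), ``rho`` the division rate and ``beta`` the rate at which
Ki67 decays below the detection gate (transit time ``1/beta``).  Division
sends both daughters to the Ki67-high pool, hence the ``2 K_lo`` term.
Summing the pair gives ``dN/dt = a phi S chi + (rho - delta) N``.

Model families differ in which single rate is allowed to vary exponentially
with host age (turnover, division or recruitment), whether the compartment
splits into two kinetically distinct subsets, or whether a fixed host-only
"incumbent" population exists that is never replaced.

Two integration backends are available.  The default (``backend="exp"``)
advances each linear forced equation with its exact integrating-factor
solution over each step, evaluating coefficients at the step midpoint; it is
unconditionally stable, strictly non-negative, and exact whenever rates and
forcing are constant.  ``backend="lsoda"`` wraps :func:`scipy.integrate.solve_ivp`
around :func:`rhs` and is used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FAMILIES",
    "ModelConfig",
    "KineticParams",
    "Trajectory",
    "ObservableSeries",
    "rhs",
    "solve_trajectory",
    "predict_observables",
    "closed_form_constant",
    "steady_state_ki67",
]

FAMILIES = (
    "homogeneous",
    "time_turnover",
    "time_division",
    "time_recruitment",
    "kinetic_heterogeneity",
    "incumbent",
)

PRECURSORS = ("T1", "T2", "T1+T2", "FM")

#: host age (days) at which base rates are quoted and time modifiers are anchored
T_REF = 75.0


@dataclass(frozen=True)
class ModelConfig:
    """Structural choices: model family, precursor population, subset count.

    ``clock`` records which time variable the exponential rate modifiers run
    on; all groups of mice are fitted jointly on host age, so this is
    ``"host_age"`` (kept explicit so the assumption is visible).
    """

    family: str = "homogeneous"
    precursor: str = "T1"
    n_subsets: int = 1
    clock: str = "host_age"
    t_ref: float = T_REF

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.precursor not in PRECURSORS:
            raise ValueError(f"unknown precursor {self.precursor!r}")
        if self.n_subsets not in (1, 2):
            raise ValueError("n_subsets must be 1 or 2")
        if (self.family == "kinetic_heterogeneity") != (self.n_subsets == 2):
            raise ValueError("n_subsets == 2 exactly when family == 'kinetic_heterogeneity'")
        if self.clock != "host_age":
            raise ValueError("rate modifiers run on host age")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic rates (per day) and their exponential time modifiers.

    Rates are quoted at host age ``t_ref`` (default 75 days); a nonzero
    modifier ``r_x`` scales the corresponding rate as
    ``x(t) = x0 * exp(r_x * (t - t_ref))``.  At most one modifier may be
    nonzero, and it must match the model family.  For two-subset models,
    subset 2 has its own loss and division rates (``delta0_2``, ``rho0_2``)
    and receives a fraction ``1 - alpha`` of the influx; the Ki67 transit
    rate ``beta`` is shared.
    """

    phi0: float = 0.01
    delta0: float = 0.03
    rho0: float = 0.005
    beta: float = 0.25
    r_delta: float = 0.0
    r_rho: float = 0.0
    r_phi: float = 0.0
    alpha: float = 1.0
    delta0_2: float = 0.0
    rho0_2: float = 0.0
    incumbent_size: float = 0.0

    def validate(self, config: ModelConfig) -> None:
        for name in ("phi0", "delta0", "rho0", "beta", "delta0_2", "rho0_2", "incumbent_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        active = {"r_delta": self.r_delta, "r_rho": self.r_rho, "r_phi": self.r_phi}
        nonzero = [k for k, v in active.items() if v != 0.0]
        allowed = {
            "homogeneous": [],
            "kinetic_heterogeneity": [],
            "incumbent": [],
            "time_turnover": ["r_delta"],
            "time_division": ["r_rho"],
            "time_recruitment": ["r_phi"],
        }[config.family]
        if any(k not in allowed for k in nonzero):
            raise ValueError(
                f"time modifiers {nonzero} not allowed for family {config.family!r}"
            )
        if config.family == "incumbent" and self.incumbent_size < 0:
            raise ValueError("incumbent_size must be >= 0")
        if config.family != "incumbent" and self.incumbent_size != 0:
            raise ValueError("incumbent_size requires family == 'incumbent'")
        if config.n_subsets == 2 and (self.delta0_2 <= 0 or self.rho0_2 < 0):
            raise ValueError("two-subset model needs delta0_2 > 0 and rho0_2 >= 0")

    # -- rates as functions of host age -------------------------------------
    def delta(self, t, t_ref=T_REF, subset=0):
        base = self.delta0 if subset == 0 else self.delta0_2
        return base * np.exp(self.r_delta * (np.asarray(t, float) - t_ref))

    def rho(self, t, t_ref=T_REF, subset=0):
        base = self.rho0 if subset == 0 else self.rho0_2
        return base * np.exp(self.r_rho * (np.asarray(t, float) - t_ref))

    def phi(self, t, t_ref=T_REF):
        return self.phi0 * np.exp(self.r_phi * (np.asarray(t, float) - t_ref))

    def influx_share(self, subset: int) -> float:
        return self.alpha if subset == 0 else 1.0 - self.alpha


def steady_state_ki67(delta, rho, beta, kappa_source):
    """Equilibrium Ki67-high fraction of a subset at constant rates.

    Setting the structured equations to zero and eliminating pool size gives
    ``k* = ((delta - rho) * kappa_S + 2 rho) / (beta + delta + rho)``: Ki67
    is fed both by inheritance from the precursor (at the net replacement
    rate ``delta - rho``) and by division.
    """
    return ((delta - rho) * kappa_source + 2.0 * rho) / (beta + delta + rho)


# ---------------------------------------------------------------------------
# state layout: per subset s, lineage l (0 = host, 1 = donor): [K_hi, K_lo]
# flattened as state[((s * 2) + l) * 2 + {0: hi, 1: lo}]; incumbent appended.
# ---------------------------------------------------------------------------


def _state_size(config: ModelConfig) -> int:
    n = config.n_subsets * 2 * 2
    if config.family == "incumbent":
        n += 1
    return n


def rhs(t, state, params: KineticParams, source, config: ModelConfig, t_bmt: float):
    """Time derivative of the flattened population state at host age ``t``.

    ``source`` must expose ``size(t)``, ``chimerism(t, t_bmt)`` and
    ``ki67(t)``.  The incumbent pool, when present, is constant (zero
    derivative).  Raises on negative state entries (beyond a tiny numerical
    tolerance) or if the source is not evaluable at ``t``.
    """
    state = np.asarray(state, float)
    if state.min() < -1e-6 * (1.0 + abs(state).max()):
        raise ValueError(f"negative population state at t={t}: min={state.min()}")
    S = float(source.size(t))
    chi_d = float(source.chimerism(t, t_bmt))
    kappa = float(source.ki67(t))
    tr = config.t_ref
    out = np.empty_like(state)
    for s in range(config.n_subsets):
        a = params.influx_share(s)
        dlt = float(params.delta(t, tr, subset=s))
        rho = float(params.rho(t, tr, subset=s))
        phi = float(params.phi(t, tr))
        for lineage, chi in ((0, 1.0 - chi_d), (1, chi_d)):
            i = ((s * 2) + lineage) * 2
            k_hi, k_lo = state[i], state[i + 1]
            influx = a * phi * S * chi
            out[i] = influx * kappa + rho * (k_hi + 2.0 * k_lo) - (params.beta + dlt) * k_hi
            out[i + 1] = influx * (1.0 - kappa) + params.beta * k_hi - (rho + dlt) * k_lo
    if config.family == "incumbent":
        out[-1] = 0.0
    return out


@dataclass
class Trajectory:
    """Solution of a compartment model on a monotone host-age grid.

    ``n`` and ``k_hi`` have shape ``(n_subsets, 2, n_times)`` with lineage
    axis ordered (host, donor); ``incumbent`` is the constant host-only pool
    (0 unless the incumbent family is used).
    """

    t: np.ndarray
    n: np.ndarray
    k_hi: np.ndarray
    incumbent: float
    config: ModelConfig
    params: KineticParams
    t_bmt: float

    @property
    def k_lo(self) -> np.ndarray:
        return self.n - self.k_hi

    def total(self) -> np.ndarray:
        return self.n.sum(axis=(0, 1)) + self.incumbent


def _phi1(z):
    """(exp(z) - 1) / z, stable near 0."""
    z = np.asarray(z, float)
    out = np.ones_like(z)
    nz = np.abs(z) > 1e-12
    out[nz] = np.expm1(z[nz]) / z[nz]
    return out


def _linear_forced_path(lam_mid, f_mid, tgrid, x0):
    """Solve ``x' = f(t) - lam(t) x`` on ``tgrid`` given midpoint coefficients.

    Uses the exact constant-coefficient propagator on each step and a
    numerically stable cumulative (log-sum-exp) form of the variation-of-
    constants sum, so arbitrarily stiff ``lam`` cannot overflow.  Requires
    ``f >= 0``; the result is then non-negative for ``x0 >= 0``.
    """
    dt = np.diff(tgrid)
    lam_dt = lam_mid * dt
    Lambda = np.concatenate(([0.0], np.cumsum(lam_dt)))
    # per-step forced increment, referenced to the step's right edge
    b = f_mid * dt * _phi1(-lam_dt)
    with np.errstate(divide="ignore"):
        logc = np.where(b > 0.0, np.log(np.where(b > 0.0, b, 1.0)), -np.inf) + Lambda[1:]
    log_cum = np.logaddexp.accumulate(logc)
    x = np.empty_like(tgrid, dtype=float)
    x[0] = x0
    with np.errstate(over="ignore"):
        hom = x0 * np.exp(-Lambda[1:])
    x[1:] = hom + np.exp(log_cum - Lambda[1:])
    return x


def _quasi_steady_state(params, source, config, t0):
    """Pre-transplant host state: pool at steady state under the source at t0.

    Returns per-subset (N*, k*).  Requires delta(t0) > rho(t0) in every
    subset, otherwise no finite steady state exists.
    """
    S = float(source.size(t0))
    kappa = float(source.ki67(t0))
    out = []
    for s in range(config.n_subsets):
        dlt = float(params.delta(t0, config.t_ref, subset=s))
        rho = float(params.rho(t0, config.t_ref, subset=s))
        phi = float(params.phi(t0, config.t_ref))
        if dlt <= rho:
            raise ValueError(
                "host steady state undefined: delta <= rho at the transplant age"
            )
        n_star = params.influx_share(s) * phi * S / (dlt - rho)
        k_star = steady_state_ki67(dlt, rho, params.beta, kappa)
        out.append((n_star, k_star))
    return out


def solve_trajectory(
    config: ModelConfig,
    params: KineticParams,
    source,
    t_bmt: float,
    t_grid,
    backend: str = "exp",
    dt: float = 0.5,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate a model from the transplant age over ``t_grid`` (host ages).

    Initial condition: donor compartments empty at ``t_bmt``; host
    compartments at the model's quasi-steady state under the source at
    ``t_bmt`` with Ki67 split at its equilibrium fraction.  ``t_grid`` must
    lie in ``[t_bmt, inf)`` and within the source's supported range.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, float))
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be non-decreasing")
    if t_grid[0] < t_bmt:
        raise ValueError("t_grid must start at or after t_bmt")
    params.validate(config)
    t_max = t_grid[-1]

    qss = _quasi_steady_state(params, source, config, t_bmt)

    if backend == "lsoda":
        return _solve_lsoda(config, params, source, t_bmt, t_grid, qss, rtol)
    if backend != "exp":
        raise ValueError(f"unknown backend {backend!r}")

    # internal grid: uniform spacing plus every requested output time
    grid = np.union1d(np.arange(t_bmt, t_max + dt, dt), t_grid)
    grid = grid[grid <= t_max + 1e-12]
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    mid = 0.5 * (grid[:-1] + grid[1:])
    tr = config.t_ref

    S_m = np.asarray(source.size(mid), float)
    chi_m = np.asarray(source.chimerism(mid, t_bmt), float)
    kap_m = np.asarray(source.ki67(mid), float)
    phi_m = params.phi(mid, tr)

    n_out = np.empty((config.n_subsets, 2, t_grid.size))
    khi_out = np.empty_like(n_out)
    sel = np.searchsorted(grid, t_grid)

    for s in range(config.n_subsets):
        a = params.influx_share(s)
        dlt_m = params.delta(mid, tr, subset=s)
        rho_m = params.rho(mid, tr, subset=s)
        n0, k0 = qss[s]
        for lineage in (0, 1):
            chi_l = (1.0 - chi_m) if lineage == 0 else chi_m
            x0 = n0 if lineage == 0 else 0.0
            f_n = a * phi_m * S_m * chi_l
            n_path = _linear_forced_path(dlt_m - rho_m, f_n, grid, x0)
            n_mid = 0.5 * (n_path[:-1] + n_path[1:])
            f_k = f_n * kap_m + 2.0 * rho_m * n_mid
            k_path = _linear_forced_path(params.beta + dlt_m + rho_m, f_k, grid, x0 * k0)
            n_out[s, lineage] = n_path[sel]
            khi_out[s, lineage] = k_path[sel]

    return Trajectory(
        t=t_grid,
        n=n_out,
        k_hi=khi_out,
        incumbent=params.incumbent_size if config.family == "incumbent" else 0.0,
        config=config,
        params=params,
        t_bmt=t_bmt,
    )


def _solve_lsoda(config, params, source, t_bmt, t_grid, qss, rtol):
    y0 = np.zeros(_state_size(config))
    for s, (n0, k0) in enumerate(qss):
        i = (s * 2) * 2  # host lineage
        y0[i] = n0 * k0
        y0[i + 1] = n0 * (1.0 - k0)
    if config.family == "incumbent":
        y0[-1] = params.incumbent_size

    sol = solve_ivp(
        rhs,
        (t_bmt, t_grid[-1]),
        y0,
        t_eval=t_grid,
        args=(params, source, config, t_bmt),
        method="LSODA",
        rtol=rtol,
        atol=1e-2,
    )
    if not sol.success:
        raise RuntimeError(f"LSODA integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    n = np.empty((config.n_subsets, 2, t_grid.size))
    k_hi = np.empty_like(n)
    for s in range(config.n_subsets):
        for lineage in (0, 1):
            i = ((s * 2) + lineage) * 2
            k_hi[s, lineage] = y[i]
            n[s, lineage] = y[i] + y[i + 1]
    return Trajectory(
        t=np.asarray(t_grid, float),
        n=n,
        k_hi=k_hi,
        incumbent=params.incumbent_size if config.family == "incumbent" else 0.0,
        config=config,
        params=params,
        t_bmt=t_bmt,
    )


@dataclass
class ObservableSeries:
    """Model observables on a host-age grid.

    ``norm_chimerism`` is the donor fraction of the compartment divided by
    the stable chimerism of the precursor, so 1 means the compartment has
    attained its ancestor's chimerism (complete replacement).  Ki67
    fractions are per lineage; where a lineage is empty they are NaN
    (missing), never 0.
    """

    t: np.ndarray
    total_counts: np.ndarray
    norm_chimerism: np.ndarray
    ki67_host: np.ndarray
    ki67_donor: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age_d": self.t,
                "counts": self.total_counts,
                "norm_chimerism": self.norm_chimerism,
                "ki67_host": self.ki67_host,
                "ki67_donor": self.ki67_donor,
            }
        )


def predict_observables(traj: Trajectory, source) -> ObservableSeries:
    """Map a trajectory onto the three fitted observable series.

    The incumbent pool counts toward total size and the host lineage; it is
    treated as Ki67-low (a long-established resting population).
    """
    chi_stable = float(source.chi_stable)
    if chi_stable <= 0:
        raise ValueError("source stable chimerism must be > 0")
    n_host = traj.n[:, 0, :].sum(axis=0) + traj.incumbent
    n_donor = traj.n[:, 1, :].sum(axis=0)
    total = n_host + n_donor
    with np.errstate(invalid="ignore", divide="ignore"):
        chim = np.where(total > 0, n_donor / np.where(total > 0, total, 1.0), np.nan)
        k_host = np.where(
            n_host > 0, traj.k_hi[:, 0, :].sum(axis=0) / np.where(n_host > 0, n_host, 1.0), np.nan
        )
        k_donor = np.where(
            n_donor > 0, traj.k_hi[:, 1, :].sum(axis=0) / np.where(n_donor > 0, n_donor, 1.0), np.nan
        )
    return ObservableSeries(
        t=traj.t,
        total_counts=total,
        norm_chimerism=chim / chi_stable,
        ki67_host=k_host,
        ki67_donor=k_donor,
    )


def closed_form_constant(phi_s, delta, rho, n0, t):
    """Pool size under constant rates and constant total influx ``phi_s``.

    ``N(t) = phi_s/(delta-rho) + (N0 - phi_s/(delta-rho)) exp(-(delta-rho) t)``
    with the degenerate case ``delta == rho`` handled as linear growth.
    Serves as the analytic oracle for the numerical integrators.
    """
    t = np.asarray(t, float)
    lam = delta - rho
    if abs(lam) < 1e-14:
        return n0 + phi_s * t
    n_inf = phi_s / lam
    return n_inf + (n0 - n_inf) * np.exp(-lam * t)
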