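"""Synthetic busulfan-chimera cohorts and reporter-mouse datasets.

Emulates the statistical structure of the fate-mapping experiments: mice
transplanted in three age-at-BMT groups, each destructively sampled once at
some later age; cell counts carry lognormal noise, and the fraction-valued
observables (normalized chimerism, Ki67-high fractions) carry logit-normal
noise clamped to [0, 1].  All randomness flows from a single integer seed
which is expanded into independent substreams per mouse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .models import ModelConfig, KineticParams, solve_trajectory, predict_observables

__all__ = [
    "NoiseModel",
    "CohortDesign",
    "simulate_cohort",
    "simulate_gfp_cohort",
    "simulate_yfp_experiment",
]

_EPS = 1e-4
#: donor pools below this normalized chimerism yield no measurable donor Ki67
_DONOR_DETECTION = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: sd of log counts and of logit-scale fractions."""

    sd_log_counts: float = 0.3
    sd_logit_chimerism: float = 0.3
    sd_logit_ki67: float = 0.2

    def __post_init__(self):
        if min(self.sd_log_counts, self.sd_logit_chimerism, self.sd_logit_ki67) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout: age-at-BMT windows with group sizes, candidate sampling ages.

    ``groups`` is a sequence of ``(bmt_age_lo, bmt_age_hi, n_mice)``.  Each
    mouse receives a transplant age drawn from its window (rounded to whole
    weeks, mirroring batched experimental cohorts) and one sampling age
    drawn from ``sampling_ages`` at least 14 days post transplant.
    """

    groups: Sequence = ((35.0, 56.0, 15), (56.0, 84.0, 14), (84.0, 126.0, 12))
    sampling_ages: np.ndarray = field(default_factory=lambda: np.arange(77.0, 601.0, 7.0))
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    def __post_init__(self):
        for lo, hi, n in self.groups:
            if n < 1:
                raise ValueError("each group needs at least one mouse")
            if hi < lo:
                raise ValueError("age-at-BMT window inverted")


def _logit_noise(x, sd, rng):
    x = np.clip(x, _EPS, 1.0 - _EPS)
    return float(np.clip(expit(logit(x) + sd * rng.standard_normal()), 0.0, 1.0))


def _draw_mice(design: CohortDesign):
    """Per-mouse (t_bmt, t_sample) draws, deterministic given the design seed."""
    mice = []
    idx = 0
    for lo, hi, n in design.groups:
        for _ in range(int(n)):
            rng = np.random.default_rng([design.seed, idx])
            t_bmt = float(np.round(rng.uniform(lo, hi) / 7.0) * 7.0)
            t_bmt = min(max(t_bmt, lo), hi)
            ages = np.asarray(design.sampling_ages, float)
            ages = ages[ages >= t_bmt + 14.0]
            if ages.size == 0:
                raise ValueError("no sampling age at least 14 d after BMT")
            t_sample = float(rng.choice(ages))
            mice.append((idx, t_bmt, t_sample, rng))
            idx += 1
    return mice


def simulate_cohort(
    design: CohortDesign,
    config: ModelConfig,
    params: KineticParams,
    source,
    subset_label: str = "FM",
) -> pd.DataFrame:
    """Simulate one destructive-sampling chimera cohort.

    Solves the model once per distinct transplant age, reads the observables
    at each mouse's sampling age and applies the design's noise model.  With
    all noise sds zero, the returned table equals the model predictions
    exactly.  Donor Ki67 is missing (NaN) while the donor pool is below the
    detection fraction.
    """
    mice = _draw_mice(design)
    noise = design.noise

    by_bmt: dict = {}
    for idx, t_bmt, t_sample, _ in mice:
        by_bmt.setdefault(t_bmt, []).append(t_sample)
    pred = {}
    for t_bmt, ages in by_bmt.items():
        grid = np.unique(np.asarray(sorted(ages), float))
        obs = predict_observables(
            solve_trajectory(config, params, source, t_bmt, grid), source
        )
        pred[t_bmt] = {a: i for i, a in enumerate(grid)}, obs

    rows = []
    for idx, t_bmt, t_sample, rng in mice:
        index, obs = pred[t_bmt]
        i = index[t_sample]
        counts = float(obs.total_counts[i]) * float(
            np.exp(noise.sd_log_counts * rng.standard_normal())
        )
        chim = _logit_noise(obs.norm_chimerism[i], noise.sd_logit_chimerism, rng)
        k_host = _logit_noise(obs.ki67_host[i], noise.sd_logit_ki67, rng)
        if obs.norm_chimerism[i] < _DONOR_DETECTION or np.isnan(obs.ki67_donor[i]):
            k_donor = np.nan
            rng.standard_normal()  # keep the stream length fixed
        else:
            k_donor = _logit_noise(obs.ki67_donor[i], noise.sd_logit_ki67, rng)
        rows.append(
            {
                "mouse_id": f"m{idx:03d}",
                "age_bmt_d": t_bmt,
                "age_d": t_sample,
                "subset": subset_label,
                "counts": counts,
                "norm_chimerism": chim,
                "ki67_host": k_host,
                "ki67_donor": k_donor,
            }
        )
    return pd.DataFrame(rows)


def simulate_gfp_cohort(
    variant,
    params: KineticParams,
    source_young,
    gfp_map,
    ages,
    seed: int = 0,
    sd_log_mfi: float = 0.05,
    n0: float = 1.0e6,
    t_start: float = 10.0,
) -> pd.DataFrame:
    """Simulate Rag2-GFP fluorescence readouts of young-mouse FM B cells.

    For each host age, the age-structured model gives the GFP mean
    fluorescence intensity of all FM cells and of the GFP-positive subset;
    multiplicative lognormal noise is applied to both MFIs.
    """
    from .agestructure import solve_age_density, predict_gfp

    rows = []
    for i, age in enumerate(np.asarray(ages, float)):
        rng = np.random.default_rng([seed, i])
        dens = solve_age_density(variant, params, source_young, age, t_start=t_start, n0=n0)
        mfi_total, mfi_pos, pos_frac = predict_gfp(dens, gfp_map)
        rows.append(
            {
                "age_d": float(age),
                "mfi_total": mfi_total * float(np.exp(sd_log_mfi * rng.standard_normal())),
                "mfi_pos": (
                    np.nan
                    if np.isnan(mfi_pos)
                    else mfi_pos * float(np.exp(sd_log_mfi * rng.standard_normal()))
                ),
                "gfp_pos_frac": pos_frac,
            }
        )
    return pd.DataFrame(rows)


def simulate_yfp_experiment(
    f0: float,
    net_loss: float,
    sampling_days,
    seed: int = 0,
    n_cells: int = 150,
    site: str = "spleen",
) -> pd.DataFrame:
    """Simulate a Ki67-reporter (YFP) label-dilution time course.

    After an instantaneous tamoxifen pulse labels a fraction ``f0`` of GC B
    cells, heritable label is diluted by unlabeled immigrants at the net
    loss rate: ``E[f](t) = f0 * exp(-net_loss * t)``.  Each sampled mouse
    contributes a binomial draw of ``n_cells`` scored cells.
    """
    if not 0.0 < f0 <= 1.0:
        raise ValueError("f0 must lie in (0, 1]")
    if net_loss < 0.0:
        raise ValueError("net_loss must be >= 0")
    rows = []
    for i, day in enumerate(np.asarray(sampling_days, float)):
        rng = np.random.default_rng([seed, i])
        f = f0 * float(np.exp(-net_loss * day))
        rows.append(
            {
                "day": float(day),
                "labeled_fraction": rng.binomial(n_cells, f) / n_cells,
                "site": site,
            }
        )
    return pd.DataFrame(rows)
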