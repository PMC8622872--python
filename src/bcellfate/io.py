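"""Tabular I/O, run configuration, and the end-to-end pipeline."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_cohort_csv", "write_cohort_csv", "load_run_config", "run_pipeline"]

REQUIRED_COLUMNS = [
    "mouse_id",
    "age_bmt_d",
    "age_d",
    "subset",
    "counts",
    "norm_chimerism",
    "ki67_host",
    "ki67_donor",
]
_NUMERIC = REQUIRED_COLUMNS[1:3] + REQUIRED_COLUMNS[4:]

#: precursor candidates considered per compartment
ALLOWED_PRECURSORS = {
    "FM": ("T1", "T2", "T1+T2"),
    "GC_spleen": ("T1", "T2", "FM"),
    "GC_LN": ("T2", "FM"),
}


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort observation table.

    Required columns: mouse_id, age_bmt_d, age_d, subset, counts,
    norm_chimerism, ki67_host, ki67_donor (fractions may be empty =
    missing).  Rows violating the invariants (counts <= 0, fractions
    outside [0, 1], sampling before transplant) are dropped with a logged
    warning naming their line numbers; unknown extra columns are ignored
    with a warning.  A missing required column or a non-numeric cell raises.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
        df = df[REQUIRED_COLUMNS]
    for c in _NUMERIC:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric value in column {c!r} at line {line}")
        df[c] = converted

    ok = (
        (df["counts"] > 0)
        & (df["age_d"] > df["age_bmt_d"])
        & (df["norm_chimerism"].isna() | (df["norm_chimerism"] >= 0))
        & (df["ki67_host"].isna() | df["ki67_host"].between(0, 1))
        & (df["ki67_donor"].isna() | df["ki67_donor"].between(0, 1))
    )
    if (~ok).any():
        lines = [int(i) + 2 for i in df.index[~ok]]
        logger.warning("%s: dropped %d invalid row(s) at line(s) %s", path, len(lines), lines)
        df = df[ok]
    return df.reset_index(drop=True)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=REQUIRED_COLUMNS)


@dataclass
class RunConfig:
    """Configuration of one fitting run (YAML or JSON on disk)."""

    subset: str = "FM"
    families: Sequence[str] = ("time_turnover",)
    precursor: str = "T1"
    cohort_file: Optional[str] = None
    seed: int = 0
    output_dir: str = "bcellfate_out"
    sample: bool = False
    n_starts: int = 16
    n_steps: int = 500
    n_burn: int = 200
    noise: dict = field(default_factory=dict)
    yfp_prior_file: Optional[str] = None

    def __post_init__(self):
        if self.subset not in ALLOWED_PRECURSORS:
            raise ValueError(f"subset must be one of {sorted(ALLOWED_PRECURSORS)}")
        if self.precursor not in ALLOWED_PRECURSORS[self.subset]:
            raise ValueError(
                f"precursor {self.precursor!r} is not considered for subset {self.subset!r}"
            )


def load_run_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    cfg = RunConfig(**data)
    if cfg.cohort_file is not None and not Path(cfg.cohort_file).exists():
        raise FileNotFoundError(cfg.cohort_file)
    return cfg


def _default_source(subset, precursor):
    from . import presets

    if precursor == "T1":
        return presets.adult_t1_source()
    if precursor in ("T2", "T1+T2"):
        return presets.adult_t2_source()
    return presets.fm_as_source()


def run_pipeline(cfg: RunConfig) -> dict:
    """Fit each requested model family to a cohort and compare them.

    Writes, under ``cfg.output_dir``: a kinetic-summary parameter table per
    family (with 95% intervals), a model-weight table when more than one
    family is requested, predicted-vs-observed series for the best family,
    and a run log.  Fully deterministic given the seed.
    """
    from .models import ModelConfig, solve_trajectory, predict_observables
    from .priors import default_priors
    from .inference import fit_map, sample_posterior, compare_models
    from .summaries import summarize_kinetics
    from .simulate import NoiseModel
    from .reporter import build_net_loss_prior
    from . import presets

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("bcellfate")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if cfg.cohort_file is None:
            raise ValueError("run_pipeline needs a cohort_file (use `bcellfate simulate` first)")
        cohort = read_cohort_csv(cfg.cohort_file)
        cohort = cohort[cohort["subset"] == cfg.subset].reset_index(drop=True)
        if cohort.empty:
            raise ValueError(f"no rows with subset == {cfg.subset!r} in {cfg.cohort_file}")
        noise = NoiseModel(**cfg.noise) if cfg.noise else presets.DEFAULT_NOISE
        source = _default_source(cfg.subset, cfg.precursor)
        scale = "FM" if cfg.subset == "FM" else "GC"
        net_loss_prior = None
        if cfg.yfp_prior_file:
            net_loss_prior = build_net_loss_prior(pd.read_csv(cfg.yfp_prior_file))
            root.info(
                "YFP net-loss prior: median %.4g/d scale %.2f",
                net_loss_prior.median_value, net_loss_prior.sdlog,
            )

        fits, summaries = {}, {}
        for fam in cfg.families:
            n_sub = 2 if fam == "kinetic_heterogeneity" else 1
            mconfig = ModelConfig(family=fam, precursor=cfg.precursor, n_subsets=n_sub)
            priors = default_priors(mconfig, scale=scale)
            root.info("fitting family %s", fam)
            if cfg.sample:
                fit = sample_posterior(
                    cohort, mconfig, source, priors, noise,
                    seed=cfg.seed, n_steps=cfg.n_steps, n_burn=cfg.n_burn,
                    net_loss_prior=net_loss_prior, map_starts=cfg.n_starts,
                )
            else:
                fit = fit_map(
                    cohort, mconfig, source, priors, noise,
                    n_starts=cfg.n_starts, seed=cfg.seed, net_loss_prior=net_loss_prior,
                )
            fits[fam] = fit
            summ = summarize_kinetics(fit, mconfig, source, t_ref=75.0)
            summaries[fam] = summ
            frame = summ.to_frame()
            counts_like = frame["quantity"].isin(["influx_cells_per_day", "pool_size"])
            frame.loc[counts_like, ["estimate", "ci_lo", "ci_hi"]] /= 1e6  # report as x1e6 cells
            frame.loc[counts_like, "quantity"] += "_x1e6"
            frame.to_csv(out / f"params_{fam}.csv", index=False, float_format="%.6g")

            best_traj = {}
            for tb in np.unique(cohort["age_bmt_d"]):
                ages = np.linspace(tb + 1.0, cohort["age_d"].max(), 80)
                obs = predict_observables(
                    solve_trajectory(mconfig, fit.map_params, source, float(tb), ages), source
                )
                frame_fit = obs.to_frame()
                frame_fit.insert(0, "age_bmt_d", tb)
                best_traj[tb] = frame_fit
            pd.concat(best_traj.values()).to_csv(
                out / f"predicted_{fam}.csv", index=False, float_format="%.6g"
            )

        result = {"fits": fits, "summaries": summaries, "comparison": None}
        if len(cfg.families) > 1 and cfg.sample:
            comp = compare_models([fits[f] for f in cfg.families], names=list(cfg.families))
            comp.table.to_csv(out / "model_weights.csv", float_format="%.6g")
            root.info("model comparison (%s):\n%s", comp.method, comp.table)
            result["comparison"] = comp
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
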