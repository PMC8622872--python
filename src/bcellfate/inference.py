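"""Joint likelihood, MAP estimation, posterior sampling, model comparison.

The three observable series are fitted jointly with Gaussian likelihoods on
transformed scales: log total counts, logit normalized chimerism, and logit
Ki67-high fractions of host and donor cells.  Each mouse contributes up to
four independent observation components evaluated at the model prediction
for its own (transplant age, sampling age) pair; missing components (NaN)
are skipped.  Pointwise log-likelihoods are retained per component so that
models can be compared with PSIS-LOO (leave-one-out) and pseudo-BMA weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from .models import ModelConfig, KineticParams, solve_trajectory, predict_observables
from .priors import Prior, PriorSpec
from .simulate import NoiseModel

__all__ = [
    "FitResult",
    "ModelComparison",
    "log_likelihood",
    "fit_map",
    "sample_posterior",
    "compare_models",
    "params_from_working",
    "working_from_params",
]

logger = logging.getLogger(__name__)

_EPS = 1e-4
_COMPONENTS = ("counts", "norm_chimerism", "ki67_host", "ki67_donor")


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def params_from_working(z: Dict[str, float], config: ModelConfig, relabel: bool = True) -> KineticParams:
    """Build :class:`KineticParams` from working-scale values.

    For two-subset models, subsets are relabelled so that subset 1 has the
    larger loss rate (the transient subset), breaking the label-switching
    symmetry of the likelihood.
    """
    kw = dict(
        phi0=np.exp(z["phi0"]),
        delta0=np.exp(z["delta0"]),
        rho0=np.exp(z["rho0"]),
        beta=np.exp(z["beta"]),
        r_delta=z.get("r_delta", 0.0),
        r_rho=z.get("r_rho", 0.0),
        r_phi=z.get("r_phi", 0.0),
    )
    if config.n_subsets == 2:
        kw["alpha"] = float(expit(z["alpha"]))
        kw["delta0_2"] = np.exp(z["delta0_2"])
        kw["rho0_2"] = np.exp(z["rho0_2"])
        if relabel and kw["delta0"] < kw["delta0_2"]:
            kw["delta0"], kw["delta0_2"] = kw["delta0_2"], kw["delta0"]
            kw["rho0"], kw["rho0_2"] = kw["rho0_2"], kw["rho0"]
            kw["alpha"] = 1.0 - kw["alpha"]
    if config.family == "incumbent":
        kw["incumbent_size"] = np.exp(z["incumbent_size"])
    return KineticParams(**kw)


def working_from_params(params: KineticParams, config: ModelConfig) -> Dict[str, float]:
    z = {
        "phi0": np.log(params.phi0),
        "delta0": np.log(params.delta0),
        "rho0": np.log(params.rho0),
        "beta": np.log(params.beta),
    }
    if config.n_subsets == 2:
        z["alpha"] = float(logit(np.clip(params.alpha, 1e-9, 1 - 1e-9)))
        z["delta0_2"] = np.log(params.delta0_2)
        z["rho0_2"] = np.log(params.rho0_2)
    if config.family == "time_turnover":
        z["r_delta"] = params.r_delta
    elif config.family == "time_division":
        z["r_rho"] = params.r_rho
    elif config.family == "time_recruitment":
        z["r_phi"] = params.r_phi
    elif config.family == "incumbent":
        z["incumbent_size"] = np.log(max(params.incumbent_size, 1e-12))
    return z


def net_loss_at_ref(params: KineticParams, config: ModelConfig) -> float:
    """Net loss rate delta - rho at the reference age (influx-weighted for two subsets)."""
    t = config.t_ref
    d1 = float(params.delta(t, config.t_ref, 0) - params.rho(t, config.t_ref, 0))
    if config.n_subsets == 1:
        return d1
    d2 = float(params.delta(t, config.t_ref, 1) - params.rho(t, config.t_ref, 1))
    return params.alpha * d1 + (1.0 - params.alpha) * d2


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class _CohortEval:
    """Pre-indexed cohort table for repeated likelihood evaluation."""

    def __init__(self, cohort: pd.DataFrame, config, source, noise: NoiseModel):
        cohort = cohort.reset_index(drop=True)
        self.config, self.source, self.noise = config, source, noise
        self.n_rows = len(cohort)
        self.t_bmt = cohort["age_bmt_d"].to_numpy(float)
        self.t_obs = cohort["age_d"].to_numpy(float)
        self.obs = {
            "counts": cohort["counts"].to_numpy(float),
            "norm_chimerism": cohort["norm_chimerism"].to_numpy(float),
            "ki67_host": cohort["ki67_host"].to_numpy(float),
            "ki67_donor": cohort["ki67_donor"].to_numpy(float),
        }
        self.groups = []
        for tb in np.unique(self.t_bmt):
            idx = np.flatnonzero(self.t_bmt == tb)
            ages = np.unique(self.t_obs[idx])
            pos = np.searchsorted(ages, self.t_obs[idx])
            self.groups.append((float(tb), idx, ages, pos))
        self.labels: List[str] = []
        self._label_sets = []
        for i in range(self.n_rows):
            comps = [c for c in _COMPONENTS if np.isfinite(self.obs[c][i])]
            self._label_sets.append(comps)
            self.labels.extend(f"{i}:{c}" for c in comps)
        self.n_points = len(self.labels)
        # vectorisation index: component -> (cohort rows, slots in the pointwise vector)
        self._slots = {}
        slot_of = {lbl: j for j, lbl in enumerate(self.labels)}
        for c in _COMPONENTS:
            rows = np.array(
                [i for i in range(self.n_rows) if c in self._label_sets[i]], dtype=int
            )
            slots = np.array([slot_of[f"{i}:{c}"] for i in rows], dtype=int)
            self._slots[c] = (rows, slots)
        self._y_t = {
            "counts": np.log(np.clip(self.obs["counts"], 1e-300, None)),
            "norm_chimerism": logit(np.clip(self.obs["norm_chimerism"], _EPS, 1 - _EPS)),
            "ki67_host": logit(np.clip(self.obs["ki67_host"], _EPS, 1 - _EPS)),
            "ki67_donor": logit(np.clip(self.obs["ki67_donor"], _EPS, 1 - _EPS)),
        }

    def predictions(self, params: KineticParams):
        pred = {c: np.full(self.n_rows, np.nan) for c in _COMPONENTS}
        for tb, idx, ages, pos in self.groups:
            obs = predict_observables(
                solve_trajectory(self.config, params, self.source, tb, ages),
                self.source,
            )
            pred["counts"][idx] = obs.total_counts[pos]
            pred["norm_chimerism"][idx] = obs.norm_chimerism[pos]
            pred["ki67_host"][idx] = obs.ki67_host[pos]
            pred["ki67_donor"][idx] = obs.ki67_donor[pos]
        return pred

    def pointwise(self, params: KineticParams) -> np.ndarray:
        try:
            pred = self.predictions(params)
        except (ValueError, RuntimeError, FloatingPointError):
            return np.full(self.n_points, -np.inf)
        sd = {
            "counts": self.noise.sd_log_counts,
            "norm_chimerism": self.noise.sd_logit_chimerism,
            "ki67_host": self.noise.sd_logit_ki67,
            "ki67_donor": self.noise.sd_logit_ki67,
        }
        out = np.empty(self.n_points)
        log2pi = np.log(2.0 * np.pi)
        for c in _COMPONENTS:
            rows, slots = self._slots[c]
            if rows.size == 0:
                continue
            mu = pred[c][rows]
            with np.errstate(invalid="ignore", divide="ignore"):
                if c == "counts":
                    mu_t = np.log(np.clip(mu, 1e-300, None))
                else:
                    mu_t = logit(np.clip(mu, _EPS, 1.0 - _EPS))
                z = (self._y_t[c][rows] - mu_t) / sd[c]
                lp = -0.5 * z * z - np.log(sd[c]) - 0.5 * log2pi
            out[slots] = np.where(np.isfinite(mu), lp, -np.inf)
        return out


def log_likelihood(
    params: KineticParams,
    cohort: pd.DataFrame,
    config: ModelConfig,
    source,
    noise: NoiseModel,
):
    """Joint log likelihood of a cohort table; returns (total, pointwise).

    The pointwise vector holds one entry per non-missing observation
    component, ordered by cohort row then by component (counts, chimerism,
    Ki67 host, Ki67 donor); its sum is the total.
    """
    ev = _CohortEval(cohort, config, source, noise)
    pw = ev.pointwise(params)
    return float(pw.sum()), pw


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """MAP fit, optional posterior samples, and pointwise log-likelihoods."""

    config: ModelConfig
    param_names: List[str]
    map_working: Dict[str, float]
    map_params: KineticParams
    log_post: float
    laplace_cov: Optional[np.ndarray] = None
    samples_working: Optional[np.ndarray] = None  # (chains, draws, ndim)
    pointwise: Optional[np.ndarray] = None        # (kept draws, n_obs)
    obs_labels: Optional[List[str]] = None
    diagnostics: Dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def natural_samples(self) -> pd.DataFrame:
        """Posterior (or Laplace) draws mapped to natural-scale parameters."""
        if self.samples_working is None:
            raise ValueError("no samples available; run sample_posterior or use laplace_draws")
        flat = self.samples_working.reshape(-1, len(self.param_names))
        rows = [
            params_from_working(dict(zip(self.param_names, zrow)), self.config)
            for zrow in flat
        ]
        return pd.DataFrame([r.__dict__ for r in rows])

    def laplace_draws(self, n: int = 4000, seed: int = 0) -> pd.DataFrame:
        """Draws from the Gaussian (observed-information) approximation at the MAP."""
        if self.laplace_cov is None:
            raise ValueError("no Laplace covariance stored")
        rng = np.random.default_rng(seed)
        mean = np.array([self.map_working[k] for k in self.param_names])
        z = rng.multivariate_normal(mean, self.laplace_cov, size=n, method="svd")
        rows = [
            params_from_working(dict(zip(self.param_names, zrow)), self.config)
            for zrow in z
        ]
        return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# MAP
# ---------------------------------------------------------------------------


def _make_log_posterior(ev: _CohortEval, priors: PriorSpec, config, net_loss_prior):
    names = list(priors)

    def logpost(zvec: np.ndarray) -> float:
        z = dict(zip(names, zvec))
        lp = priors.logpdf_working(z)
        if not np.isfinite(lp):
            return -np.inf
        params = params_from_working(z, config, relabel=False)
        if net_loss_prior is not None:
            nl = net_loss_at_ref(params, config)
            if nl <= 0:
                return -np.inf
            lp += float(net_loss_prior.logpdf_working(np.log(nl)))
        pw = ev.pointwise(params)
        ll = pw.sum()
        if not np.isfinite(ll):
            return -np.inf
        return float(lp + ll)

    return names, logpost


def _hessian_fd(f, x0, step=1e-3):
    """Central finite-difference Hessian of a scalar function."""
    n = x0.size
    h = step * (1.0 + np.abs(x0))
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H, f0


def fit_map(
    cohort: pd.DataFrame,
    config: ModelConfig,
    source,
    priors: PriorSpec,
    noise: NoiseModel,
    n_starts: int = 16,
    seed: int = 0,
    net_loss_prior: Optional[Prior] = None,
    start_params: Optional[KineticParams] = None,
    maxiter: int = 2000,
) -> FitResult:
    """Maximum a posteriori fit by multistart derivative-free optimisation.

    Starts are drawn from the prior (plus the prior median and, optionally,
    a user-supplied starting point); each runs Nelder-Mead followed by an
    L-BFGS-B polish, and the best local optimum is kept.  The observed
    information at the MAP is stored as a Laplace covariance for interval
    construction.
    """
    ev = _CohortEval(cohort, config, source, noise)
    names, logpost = _make_log_posterior(ev, priors, config, net_loss_prior)

    def neg(zv):
        lp = logpost(zv)
        # large finite penalty keeps gradient-based polishing well-defined
        return -lp if np.isfinite(lp) else 1e12

    rng = np.random.default_rng(seed)

    candidates = [np.array([priors[k]._loc for k in names])]  # prior medians (working scale)
    if start_params is not None:
        z0 = working_from_params(start_params, config)
        candidates.append(np.array([z0[k] for k in names]))
    # prior draws can violate delta > rho (no pre-BMT steady state); keep
    # sampling until enough feasible starts are found
    starts, n_fail, attempts = [], 0, 0
    for z0 in candidates:
        if np.isfinite(logpost(z0)):
            starts.append(z0)
        else:
            n_fail += 1
    while len(starts) < max(n_starts, 1) and attempts < 100 * n_starts:
        zs = priors.sample(rng)
        z0 = np.array([zs[k] for k in names])
        attempts += 1
        if np.isfinite(logpost(z0)):
            starts.append(z0)
        else:
            n_fail += 1

    best = None
    for z0 in starts:
        try:
            res = minimize(
                neg, z0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-7, "adaptive": True},
            )
            res = minimize(neg, res.x, method="L-BFGS-B", options={"maxiter": 200})
        except (ValueError, RuntimeError):
            n_fail += 1
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimisation starts failed ({n_fail} rejected outright)"
        )

    H, _ = _hessian_fd(neg, best.x)
    try:
        cov = np.linalg.inv(H + 1e-9 * np.eye(H.shape[0]))
        # fall back to a diagonal pseudo-covariance if H is not PD
        if not np.all(np.linalg.eigvalsh(cov) > 0):
            cov = np.linalg.pinv(H)
            ev_min = np.linalg.eigvalsh(cov).min()
            if ev_min <= 0:
                cov = cov + (1e-6 - min(ev_min, 0.0)) * np.eye(H.shape[0])
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(len(names), 0.25))

    z_map = dict(zip(names, best.x))
    return FitResult(
        config=config,
        param_names=names,
        map_working=z_map,
        map_params=params_from_working(z_map, config),
        log_post=-float(best.fun),
        laplace_cov=cov,
        obs_labels=ev.labels,
        diagnostics={"n_starts": len(starts), "n_failed_starts": n_fail},
    )


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------


def sample_posterior(
    cohort: pd.DataFrame,
    config: ModelConfig,
    source,
    priors: PriorSpec,
    noise: NoiseModel,
    seed: int = 0,
    n_walkers: Optional[int] = None,
    n_steps: int = 500,
    n_burn: int = 200,
    net_loss_prior: Optional[Prior] = None,
    map_result: Optional[FitResult] = None,
    n_pointwise: int = 400,
    map_starts: int = 6,
) -> FitResult:
    """Sample the posterior with an affine-invariant ensemble sampler.

    Walkers are initialised in a small Gaussian ball around the MAP (which
    is computed first if not supplied).  Convergence is summarised by the
    split-chain R-hat across walkers; a fit with max R-hat > 1.1 is flagged
    (``converged = False``), never silently returned as clean.  A thinned
    pointwise log-likelihood matrix (one column per observation component)
    is stored for LOO model comparison.
    """
    import emcee

    if map_result is None:
        map_result = fit_map(
            cohort, config, source, priors, noise,
            n_starts=map_starts, seed=seed, net_loss_prior=net_loss_prior,
        )
    ev = _CohortEval(cohort, config, source, noise)
    names, logpost = _make_log_posterior(ev, priors, config, net_loss_prior)
    ndim = len(names)
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 16)
    if n_walkers < 2 * ndim:
        raise ValueError("need at least 2 * ndim walkers")

    rng = np.random.default_rng(seed)
    center = np.array([map_result.map_working[k] for k in names])
    scale = np.sqrt(np.clip(np.diag(map_result.laplace_cov), 1e-6, 4.0))
    p0 = center + 0.5 * scale * rng.standard_normal((n_walkers, ndim))
    for i in range(n_walkers):  # ensure finite starting log-probabilities
        for _ in range(50):
            if np.isfinite(logpost(p0[i])):
                break
            p0[i] = center + 0.1 * scale * rng.standard_normal(ndim)

    np.random.seed(seed)  # emcee draws its internal RandomState from the global state
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logpost)
    sampler.run_mcmc(p0, n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=n_burn)  # (draws, walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (walkers, draws, ndim)

    try:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_da = az.rhat(az.convert_to_dataset(chain))
            rhat = float(rhat_da["x"].max())
    except Exception:  # pragma: no cover - diagnostic only
        rhat = np.nan
    accept = float(np.mean(sampler.acceptance_fraction))
    converged = bool(np.isfinite(rhat) and rhat < 1.1 and 0.05 < accept < 0.95)
    if not converged:
        logger.warning("sampler flagged: rhat=%.3f acceptance=%.2f", rhat, accept)

    flat = chain.reshape(-1, ndim)
    keep = np.linspace(0, flat.shape[0] - 1, min(n_pointwise, flat.shape[0])).astype(int)
    pointwise = np.empty((keep.size, ev.n_points))
    for j, i in enumerate(keep):
        pointwise[j] = ev.pointwise(
            params_from_working(dict(zip(names, flat[i])), config, relabel=False)
        )

    return FitResult(
        config=config,
        param_names=names,
        map_working=map_result.map_working,
        map_params=map_result.map_params,
        log_post=map_result.log_post,
        laplace_cov=map_result.laplace_cov,
        samples_working=chain,
        pointwise=pointwise,
        obs_labels=ev.labels,
        diagnostics={
            "rhat": rhat,
            "acceptance_fraction": accept,
            "converged": converged,
            "n_steps": n_steps,
            "n_burn": n_burn,
        },
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelComparison:
    """Per-model LOO-IC and pseudo-BMA weights (summing to 1)."""

    table: pd.DataFrame
    method: str  # "loo" or "waic" (fallback, flagged)

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]


def compare_models(fits: Sequence[FitResult], names: Optional[Sequence[str]] = None) -> ModelComparison:
    """Rank models by LOO-IC computed from pointwise log-likelihoods.

    All fits must carry pointwise matrices over the identical observation
    set.  The expected log pointwise predictive density is estimated by
    Pareto-smoothed importance sampling (PSIS-LOO via arviz); if PSIS fails
    outright, WAIC is used instead and the result is flagged.  Weights are
    pseudo-Bayesian-model-averaging weights ``exp(-0.5 dLOOIC)`` normalized.
    """
    import arviz as az

    if names is None:
        names = [f.config.family for f in fits]
    ref = fits[0].obs_labels
    for f in fits[1:]:
        if f.obs_labels != ref:
            raise ValueError("fits were not computed on the identical observation set")
    if any(f.pointwise is None for f in fits):
        raise ValueError("fits need pointwise log-likelihoods; run sample_posterior")

    elpds, method = [], "loo"
    for f in fits:
        ll = f.pointwise[None, :, :]  # (chain, draw, obs)
        idata = az.from_dict(
            posterior={"placeholder": np.zeros(ll.shape[:2])},
            log_likelihood={"obs": ll},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = az.loo(idata, pointwise=False)
                elpds.append(float(res["elpd_loo"]))
            except Exception:
                res = az.waic(idata, pointwise=False)
                elpds.append(float(res["elpd_waic"]))
                method = "waic"
    looic = -2.0 * np.asarray(elpds)
    d = looic - looic.min()
    w = np.exp(-0.5 * d)
    w /= w.sum()
    table = pd.DataFrame({"looic": looic, "d_looic": d, "weight": w}, index=list(names))
    table = table.sort_values("looic")
    return ModelComparison(table=table, method=method)
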