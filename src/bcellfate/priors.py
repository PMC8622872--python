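"""Prior distributions on kinetic parameters.

Priors are specified on the scale the sampler works on: positive rates are
sampled as logs (lognormal priors), proportions as logits (logit-normal),
and the signed exponential time modifiers on their natural scale (normal).
Defaults are weakly informative and centred on plausible lymphocyte scales:
slow-turnover (FM-like) compartments have loss/division medians of weeks to
months, germinal-center compartments of about a day, and the Ki67-high
transit time is centred on 4 days (Ki67 persists for roughly 3-4 days after
mitosis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "Prior",
    "LogNormalPrior",
    "NormalPrior",
    "LogitNormalPrior",
    "PriorSpec",
    "default_priors",
]


class Prior:
    """A proper univariate prior with an unconstrained working coordinate."""

    def to_natural(self, z):
        raise NotImplementedError

    def to_working(self, x):
        raise NotImplementedError

    def logpdf_working(self, z):
        """Log density in the working coordinate (Jacobian included)."""
        raise NotImplementedError

    def sample_working(self, rng, size=None):
        raise NotImplementedError

    def median(self):
        return self.to_natural(self._loc)


@dataclass
class LogNormalPrior(Prior):
    """Lognormal prior: natural value x > 0, working coordinate log x."""

    median_value: float
    sdlog: float

    def __post_init__(self):
        if self.median_value <= 0 or self.sdlog <= 0:
            raise ValueError("lognormal prior needs median > 0 and sdlog > 0")
        self._loc = np.log(self.median_value)

    def to_natural(self, z):
        return np.exp(z)

    def to_working(self, x):
        return np.log(x)

    def logpdf_working(self, z):
        return norm.logpdf(z, self._loc, self.sdlog)

    def sample_working(self, rng, size=None):
        return rng.normal(self._loc, self.sdlog, size=size)


@dataclass
class NormalPrior(Prior):
    """Normal prior on an unconstrained natural value (e.g. a rate modifier)."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("normal prior needs sd > 0")
        self._loc = self.mean

    def to_natural(self, z):
        return z

    def to_working(self, x):
        return x

    def logpdf_working(self, z):
        return norm.logpdf(z, self.mean, self.sd)

    def sample_working(self, rng, size=None):
        return rng.normal(self.mean, self.sd, size=size)


@dataclass
class LogitNormalPrior(Prior):
    """Logit-normal prior: natural value in (0, 1), working coordinate logit x."""

    mean_logit: float
    sd_logit: float

    def __post_init__(self):
        if self.sd_logit <= 0:
            raise ValueError("logit-normal prior needs sd > 0")
        self._loc = self.mean_logit

    def to_natural(self, z):
        return expit(z)

    def to_working(self, x):
        return logit(x)

    def logpdf_working(self, z):
        return norm.logpdf(z, self.mean_logit, self.sd_logit)

    def sample_working(self, rng, size=None):
        return rng.normal(self.mean_logit, self.sd_logit, size=size)


class PriorSpec(dict):
    """Ordered mapping of parameter name -> :class:`Prior`."""

    def logpdf_working(self, z_dict: Dict[str, float]) -> float:
        return float(sum(self[k].logpdf_working(z_dict[k]) for k in self))

    def sample(self, rng) -> Dict[str, float]:
        """One joint draw, returned in working coordinates."""
        return {k: float(p.sample_working(rng)) for k, p in self.items()}

    def medians(self) -> Dict[str, float]:
        return {k: float(p.median()) for k, p in self.items()}


def default_priors(config, scale: str = "FM") -> PriorSpec:
    """Weakly informative priors for a model family.

    ``scale`` selects the centring of the loss/division priors: ``"FM"`` for
    slow naive-like compartments (median residence ~1 month), ``"GC"`` for
    rapidly cycling germinal-center compartments (median residence ~1 day).
    """
    if scale not in ("FM", "GC"):
        raise ValueError("scale must be 'FM' or 'GC'")
    slow = scale == "FM"
    delta_prior = LogNormalPrior(0.03 if slow else 1.0, 1.5)
    rho_prior = LogNormalPrior(0.005 if slow else 1.0, 1.5)
    spec = PriorSpec()
    spec["phi0"] = LogNormalPrior(0.01, 2.0)
    if config.n_subsets == 2:
        spec["alpha"] = LogitNormalPrior(0.0, 1.25)
    spec["delta0"] = delta_prior
    spec["rho0"] = rho_prior
    if config.n_subsets == 2:
        spec["delta0_2"] = LogNormalPrior(delta_prior.median_value, 1.5)
        spec["rho0_2"] = LogNormalPrior(rho_prior.median_value, 1.5)
    spec["beta"] = LogNormalPrior(0.25, 0.5)  # Ki67 transit time centred on 4 d
    if config.family == "time_turnover":
        spec["r_delta"] = NormalPrior(0.0, 0.01)
    elif config.family == "time_division":
        spec["r_rho"] = NormalPrior(0.0, 0.01)
    elif config.family == "time_recruitment":
        spec["r_phi"] = NormalPrior(0.0, 0.01)
    elif config.family == "incumbent":
        spec["incumbent_size"] = LogNormalPrior(1.0e5, 3.0)
    return spec
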