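"""USEPA-style soil exposure dose and risk equations.

Average daily dose per pathway (mg/kg/day) for a soil concentration C
(mg/kg):

* ingestion:  ``ADD = C * IR_ing * EF * ED * CF / (BW * AT)``
* dermal:     ``ADD = C * SA * AF * ABS * EF * ED * CF / (BW * AT)``
* inhalation: ``ADD = C * IR_inh * EF * ED / (PEF * BW * AT)``

with ``AT = ED * 365`` days for non-carcinogenic endpoints and
``AT = 70 * 365`` days for carcinogenic endpoints. Hazard quotients are
``HQ = ADD/RfD`` summed to the hazard index HI; carcinogenic risks are
``CR = ADD * SF`` summed to TCR over the elements carrying slope
factors. Both HI and TCR are linear (degree-1 homogeneous) in the
concentration vector — the property the source-apportionment stage
relies on.

Parameters may be scalars or equal-length numpy arrays, so the same
kernel serves deterministic evaluation and vectorised Monte Carlo.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .data import ValidationError


class ConfigError(ValueError):
    """Scenario/catalogue configuration is incomplete or inconsistent."""


@dataclasses.dataclass
class Distribution:
    """One exposure parameter's distribution.

    Families: ``point(value)``, ``normal(mean, sd)`` truncated at zero,
    ``lognormal(mean, sd)`` parameterised by its arithmetic mean/SD,
    ``uniform(low, high)``, ``triangular(left, mode, right)``.
    """

    kind: str
    params: dict

    def mean(self) -> float:
        p = self.params
        if self.kind == "point":
            return float(p["value"])
        if self.kind in ("normal", "lognormal"):
            return float(p["mean"])
        if self.kind == "uniform":
            return (p["low"] + p["high"]) / 2.0
        if self.kind == "triangular":
            return (p["left"] + p["mode"] + p["right"]) / 3.0
        raise ConfigError(f"unknown distribution family {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.kind == "point":
            return np.full(n, float(p["value"]))
        if self.kind == "normal":
            # truncated at zero so physical parameters stay positive
            a = (0.0 - p["mean"]) / p["sd"]
            return stats.truncnorm.rvs(a, np.inf, loc=p["mean"], scale=p["sd"],
                                       size=n, random_state=rng)
        if self.kind == "lognormal":
            m, s = p["mean"], p["sd"]
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.kind == "triangular":
            return rng.triangular(p["left"], p["mode"], p["right"], size=n)
        raise ConfigError(f"unknown distribution family {self.kind!r}")

    @classmethod
    def from_config(cls, cfg) -> "Distribution":
        if isinstance(cfg, (int, float)):
            return cls("point", {"value": float(cfg)})
        cfg = dict(cfg)
        kind = cfg.pop("dist")
        return cls(kind, cfg)


@dataclasses.dataclass
class ExposureScenario:
    """Receptor, exposure pathways, and one Distribution per parameter."""

    receptor: str
    parameters: dict[str, Distribution]
    pathways: tuple = defaults.PATHWAYS
    at_carcinogenic_years: float = defaults.AT_CARCINOGENIC_YEARS

    REQUIRED = {
        "ingestion": ("IR_ing", "EF", "ED", "BW", "CF"),
        "dermal": ("SA", "AF", "ABS", "EF", "ED", "BW", "CF"),
        "inhalation": ("IR_inh", "EF", "ED", "BW", "PEF"),
    }

    def __post_init__(self):
        for pathway in self.pathways:
            for name in self.REQUIRED[pathway]:
                if name not in self.parameters:
                    raise ConfigError(
                        f"parameter {name!r} required for pathway {pathway!r} "
                        f"is missing from scenario {self.receptor!r}")

    def point_values(self) -> dict[str, float]:
        return {name: d.mean() for name, d in self.parameters.items()}

    def sample(self, rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
        return {name: d.sample(rng, n) for name, d in self.parameters.items()}

    @classmethod
    def default(cls, receptor: str, pathways: tuple = defaults.PATHWAYS
                ) -> "ExposureScenario":
        if receptor not in defaults.EXPOSURE_CATALOGUE:
            raise ConfigError(f"no default catalogue for receptor {receptor!r}")
        params = {name: Distribution.from_config(cfg)
                  for name, cfg in defaults.EXPOSURE_CATALOGUE[receptor].items()}
        return cls(receptor, params, pathways)

    @classmethod
    def from_config(cls, receptor: str, cfg: Mapping,
                    pathways: tuple = defaults.PATHWAYS) -> "ExposureScenario":
        params = {name: Distribution.from_config(c) for name, c in cfg.items()}
        return cls(receptor, params, pathways)


def _averaging_time(params: Mapping, horizon: str, at_ca_years: float):
    if horizon == "nc":
        return np.asarray(params["ED"]) * 365.0
    return at_ca_years * 365.0


def pathway_kernel(params: Mapping, pathway: str, horizon: str,
                   at_ca_years: float = defaults.AT_CARCINOGENIC_YEARS):
    """Dose per unit soil concentration for one pathway (kg soil/kg bw/day
    equivalent); multiply by C (mg/kg) to get ADD. Accepts scalar or
    array-valued parameters."""
    at = _averaging_time(params, horizon, at_ca_years)
    bw = np.asarray(params["BW"])
    ef, ed = np.asarray(params["EF"]), np.asarray(params["ED"])
    if pathway == "ingestion":
        return (np.asarray(params["IR_ing"]) * ef * ed
                * np.asarray(params["CF"]) / (bw * at))
    if pathway == "dermal":
        return (np.asarray(params["SA"]) * np.asarray(params["AF"])
                * np.asarray(params["ABS"]) * ef * ed
                * np.asarray(params["CF"]) / (bw * at))
    if pathway == "inhalation":
        return (np.asarray(params["IR_inh"]) * ef * ed
                / (np.asarray(params["PEF"]) * bw * at))
    raise ConfigError(f"unknown pathway {pathway!r}")


def average_daily_dose(conc: pd.Series, scenario: ExposureScenario,
                       pathway: str, horizon: str = "nc") -> pd.Series:
    """Per-element ADD for one pathway at the scenario's point values."""
    if pathway not in scenario.pathways:
        raise ConfigError(f"pathway {pathway!r} not enabled in scenario")
    params = scenario.point_values()
    for name in ExposureScenario.REQUIRED[pathway]:
        if name not in params:
            raise ConfigError(f"missing parameter {name!r} for {pathway!r}")
    k = pathway_kernel(params, pathway, horizon, scenario.at_carcinogenic_years)
    return conc * float(k)


@dataclasses.dataclass
class RiskResult:
    """Deterministic kernel output: dose/HQ/CR matrices and HI/TCR totals."""

    add_nc: pd.DataFrame   # element x pathway, mg/kg/day (AT_nc)
    add_ca: pd.DataFrame   # element x pathway, mg/kg/day (AT_ca)
    hq: pd.DataFrame
    cr: pd.DataFrame
    hi: float
    tcr: float

    def summary(self) -> pd.Series:
        return pd.Series({"HI": self.hi, "TCR": self.tcr})


def risk_from_dose(add_nc: pd.DataFrame, add_ca: pd.DataFrame,
                   ref) -> RiskResult:
    """HQ/HI from non-carcinogenic doses and CR/TCR from carcinogenic
    doses; elements without a slope factor are skipped in TCR."""
    pathways = list(add_nc.columns)
    rfd = ref.rfd.reindex(index=add_nc.index)[pathways]
    if rfd.isna().any().any():
        missing = rfd.stack(future_stack=True)
        missing = list(missing[missing.isna()].index[:3])
        raise ValidationError(f"missing RfD for {missing}")
    if (rfd == 0).any().any():
        raise ValidationError("RfD must be nonzero")
    hq = add_nc / rfd
    sf = ref.slope_factor.reindex(index=add_ca.index)[list(add_ca.columns)]
    cr = (add_ca * sf).fillna(0.0)
    return RiskResult(add_nc=add_nc, add_ca=add_ca, hq=hq, cr=cr,
                      hi=float(hq.values.sum()), tcr=float(cr.values.sum()))


def assess(conc: pd.Series, scenario: ExposureScenario, ref) -> RiskResult:
    """Full deterministic evaluation for one concentration vector."""
    add_nc = pd.DataFrame(
        {p: average_daily_dose(conc, scenario, p, "nc") for p in scenario.pathways})
    add_ca = pd.DataFrame(
        {p: average_daily_dose(conc, scenario, p, "ca") for p in scenario.pathways})
    return risk_from_dose(add_nc, add_ca, ref)


def weighted_concentration_sums(conc: pd.DataFrame, ref,
                                pathways=defaults.PATHWAYS):
    """Per-sample, per-pathway toxicity-weighted concentration sums.

    ``w_hq[s, p] = sum_e C[s, e] / RfD[e, p]`` and
    ``w_cr[s, p] = sum_e C[s, e] * SF[e, p]`` — the concentration side of
    the factored linear kernel used by the Monte Carlo engines.
    """
    pathways = list(pathways)
    rfd = ref.rfd.reindex(index=conc.columns)[pathways]
    if rfd.isna().any().any():
        raise ValidationError("missing RfD entries for weighted sums")
    sf = ref.slope_factor.reindex(index=conc.columns)[pathways].fillna(0.0)
    w_hq = conc.values @ (1.0 / rfd.values)
    w_cr = conc.values @ sf.values
    return (pd.DataFrame(w_hq, index=conc.index, columns=pathways),
            pd.DataFrame(w_cr, index=conc.index, columns=pathways))
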