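"""Source-oriented risk: per-source shares of ecological and health risk.

The receptor model attributes to each source a fraction of every
element's mean concentration; because the ecological-risk sum and the
health-risk kernels are linear in concentration, pushing each source's
concentration vector through the risk models yields an exact additive
decomposition of RI-type ecological risk, HI and TCR. Shares of the
non-additive Nemerow comprehensive index (NIRI) are reported on the
additive sum-of-Er surrogate, since a quadratic-mean index has no unique
exact decomposition; the NIRI itself is reported for the totals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import ConcentrationTable, ElementReference, ValidationError
from .health import ExposureScenario, pathway_kernel
from .indices import _nemerow
from .pmf import PMFResults


def source_concentrations(solution: PMFResults, table: ConcentrationTable
                          ) -> pd.DataFrame:
    """Each source's share of each element's observed mean concentration
    (sources x elements, mg/kg); columns sum to the observed means."""
    loading = solution.factor_loading_pct() / 100.0  # elements x factors
    mean_obs = table.data.mean()
    zero = loading.sum(axis=1) <= 0
    conc = loading.T * mean_obs  # factors x elements
    if zero.any():
        conc.loc[:, zero[zero].index] = np.nan
    return conc


@dataclasses.dataclass
class SourceRiskShare:
    """Per-source percentage shares per risk metric, plus the per-source,
    per-element risk-weight matrices behind them."""

    eco_shares: pd.Series | None = None            # % per source
    eco_weights: pd.DataFrame | None = None        # sources x elements, Er
    eco_niri_total: float | None = None
    hi_shares: dict | None = None                  # receptor -> % per source
    tcr_shares: dict | None = None
    hi_weights: dict | None = None                 # receptor -> sources x elements
    tcr_weights: dict | None = None

    def summary(self) -> pd.DataFrame:
        blocks = {}
        if self.eco_shares is not None:
            blocks["NIRI"] = self.eco_shares
        for receptor, s in (self.hi_shares or {}).items():
            blocks[f"HI ({receptor})"] = s
        for receptor, s in (self.tcr_shares or {}).items():
            blocks[f"TCR ({receptor})"] = s
        return pd.DataFrame(blocks)


def ecological_risk_by_source(source_conc: pd.DataFrame, ref: ElementReference
                              ) -> SourceRiskShare:
    """Per-source Er matrices and shares of the summed ecological risk."""
    elements = [el for el in source_conc.columns if el in ref.eco_elements()]
    if not elements:
        raise ValidationError("no ecological-risk elements in attribution")
    er = (source_conc[elements] / ref.background[elements]
          * ref.toxicity[elements])
    totals = er.sum(axis=1)
    shares = totals / totals.sum() * 100.0
    mean_er = er.sum(axis=0)
    niri_total = float(_nemerow(mean_er.mean(), mean_er.max()))
    return SourceRiskShare(eco_shares=shares, eco_weights=er,
                           eco_niri_total=niri_total)


def health_risk_by_source(source_conc: pd.DataFrame,
                          scenarios: dict[str, ExposureScenario],
                          ref: ElementReference,
                          mode: str = "deterministic",
                          n_iter: int = 10_000,
                          seed: int | None = None) -> SourceRiskShare:
    """Per-source HI and TCR shares per receptor.

    ``mcs`` mode evaluates mean risks under shared parameter draws across
    sources (common random numbers); by linearity in concentration this
    reduces to weighting pathways by their mean kernels, which differs
    from the deterministic point-value weighting only through the mild
    nonlinearity of the dose equations in the exposure parameters.
    """
    hi_shares, tcr_shares, hi_w, tcr_w = {}, {}, {}, {}
    for receptor, scenario in scenarios.items():
        if mode == "mcs":
            # mean risk over realizations; parameter draws are shared
            # across sources (common random numbers), so by linearity
            # only the mean pathway kernels matter
            rng = np.random.default_rng(seed)
            draws = scenario.sample(rng, n_iter)
            k_nc = {p: float(np.mean(pathway_kernel(
                draws, p, "nc", scenario.at_carcinogenic_years)))
                for p in scenario.pathways}
            k_ca = {p: float(np.mean(pathway_kernel(
                draws, p, "ca", scenario.at_carcinogenic_years)))
                for p in scenario.pathways}
        elif mode == "deterministic":
            point = scenario.point_values()
            k_nc = {p: float(pathway_kernel(
                point, p, "nc", scenario.at_carcinogenic_years))
                for p in scenario.pathways}
            k_ca = {p: float(pathway_kernel(
                point, p, "ca", scenario.at_carcinogenic_years))
                for p in scenario.pathways}
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        his, tcrs, hw, tw = {}, {}, {}, {}
        for source in source_conc.index:
            c = source_conc.loc[source].dropna()
            hq_el = sum(c / ref.rfd.loc[c.index, p] * k_nc[p]
                        for p in scenario.pathways)
            cr_el = sum(c * ref.slope_factor.loc[c.index, p].fillna(0.0)
                        * k_ca[p] for p in scenario.pathways)
            his[source] = float(hq_el.sum())
            tcrs[source] = float(cr_el.sum())
            hw[source] = hq_el
            tw[source] = cr_el
        his = pd.Series(his)
        tcrs = pd.Series(tcrs)
        hi_shares[receptor] = his / his.sum() * 100.0
        tcr_shares[receptor] = tcrs / tcrs.sum() * 100.0
        hi_w[receptor] = pd.DataFrame(hw).T
        tcr_w[receptor] = pd.DataFrame(tw).T
    return SourceRiskShare(hi_shares=hi_shares, tcr_shares=tcr_shares,
                           hi_weights=hi_w, tcr_weights=tcr_w)


def combine_shares(eco: SourceRiskShare, health: SourceRiskShare
                   ) -> SourceRiskShare:
    return SourceRiskShare(
        eco_shares=eco.eco_shares, eco_weights=eco.eco_weights,
        eco_niri_total=eco.eco_niri_total,
        hi_shares=health.hi_shares, tcr_shares=health.tcr_shares,
        hi_weights=health.hi_weights, tcr_weights=health.tcr_weights)


def priority_ranking(shares: SourceRiskShare) -> dict:
    """Control priorities per metric: sources ordered by share (ties keep
    factor order), and within the top source the elements ordered by
    their risk weight. Returns one record per metric with the full
    ordering and the headline (source, element) pair."""
    out = {}

    def _rank(share: pd.Series, weights: pd.DataFrame) -> dict:
        order = share.sort_values(ascending=False, kind="stable").index
        top = order[0]
        tied = list(share.index[share == share[top]])
        elements = weights.loc[top].sort_values(ascending=False, kind="stable")
        return {
            "source_order": list(order),
            "shares": share.round(4).to_dict(),
            "top_sources": tied,
            "top_source": tied[0],
            "key_element": elements.index[0],
            "element_weights": elements.round(6).to_dict(),
        }

    if shares.eco_shares is not None:
        out["NIRI"] = _rank(shares.eco_shares, shares.eco_weights)
    for receptor in (shares.hi_shares or {}):
        out[f"HI:{receptor}"] = _rank(shares.hi_shares[receptor],
                                      shares.hi_weights[receptor])
    for receptor in (shares.tcr_shares or {}):
        out[f"TCR:{receptor}"] = _rank(shares.tcr_shares[receptor],
                                       shares.tcr_weights[receptor])
    return out


def apportion_risk(solution: PMFResults, table: ConcentrationTable,
                   ref: ElementReference,
                   scenarios: dict[str, ExposureScenario],
                   mode: str = "deterministic") -> SourceRiskShare:
    """End-to-end coupling: attribution, ecological and health shares."""
    conc = source_concentrations(solution, table)
    eco = ecological_risk_by_source(conc, ref)
    health = health_risk_by_source(conc, scenarios, ref, mode=mode)
    return combine_shares(eco, health)
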