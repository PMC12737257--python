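"""Deterministic pollution and ecological risk indices.

Single-element pollution index PI = C/S (S the regional background),
integrated per sample by the Nemerow index
``NIPI = sqrt((PI_ave^2 + PI_max^2) / 2)``.

Hakanson single-element ecological risk ``Er = Tr * C/B`` with toxicity
coefficient Tr, summed to RI per sample, and combined Nemerow-style as
``NIRI = sqrt((Er_ave^2 + Er_max^2) / 2)`` so that one extreme element
is not diluted by the panel size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import (ClassificationScheme, ConcentrationTable, ElementReference,
                   ValidationError, default_schemes)


def _nemerow(ave: pd.Series, mx: pd.Series) -> pd.Series:
    return np.sqrt((ave**2 + mx**2) / 2.0)


@dataclasses.dataclass
class PollutionResult:
    """Per-cell PI plus per-sample PI_ave / PI_max / NIPI and grades."""

    pi: pd.DataFrame
    pi_ave: pd.Series
    pi_max: pd.Series
    nipi: pd.Series
    cell_grades: pd.DataFrame
    sample_grades: pd.Series

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"PI_ave": self.pi_ave, "PI_max": self.pi_max,
                             "NIPI": self.nipi, "grade": self.sample_grades})


@dataclasses.dataclass
class EcoRiskResult:
    """Per-cell Er plus per-sample RI / Er_ave / Er_max / NIRI and grades."""

    er: pd.DataFrame
    ri: pd.Series
    er_ave: pd.Series
    er_max: pd.Series
    niri: pd.Series
    cell_grades: pd.DataFrame
    ri_grades: pd.Series
    niri_grades: pd.Series

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"RI": self.ri, "Er_ave": self.er_ave,
                             "Er_max": self.er_max, "NIRI": self.niri,
                             "RI_grade": self.ri_grades,
                             "NIRI_grade": self.niri_grades})


def pollution_index(table: ConcentrationTable, ref: ElementReference,
                    schemes: dict[str, ClassificationScheme] | None = None
                    ) -> PollutionResult:
    schemes = schemes or default_schemes()
    background = ref.background.reindex(table.elements)
    if background.isna().any() or (background <= 0).any():
        missing = background.index[background.isna() | (background <= 0)]
        raise ValidationError(f"missing/nonpositive background for {list(missing)}")
    pi = table.data / background
    pi_ave = pi.mean(axis=1)
    pi_max = pi.max(axis=1)
    nipi = _nemerow(pi_ave, pi_max)
    return PollutionResult(
        pi=pi, pi_ave=pi_ave, pi_max=pi_max, nipi=nipi,
        cell_grades=pi.apply(schemes["PI"].classify),
        sample_grades=schemes["NIPI"].classify(nipi),
    )


def ecological_risk(table: ConcentrationTable, ref: ElementReference,
                    schemes: dict[str, ClassificationScheme] | None = None
                    ) -> EcoRiskResult:
    """Hakanson risk over the elements carrying a toxicity coefficient
    (Fe is excluded by the shipped defaults)."""
    schemes = schemes or default_schemes()
    elements = [el for el in table.elements if el in ref.eco_elements()]
    if not elements:
        raise ValidationError("no elements with toxicity coefficients in table")
    tox = ref.toxicity.reindex(elements)
    background = ref.background.reindex(elements)
    if background.isna().any():
        raise ValidationError("missing background for ecological-risk elements")
    er = table.data[elements] / background * tox
    ri = er.sum(axis=1)
    er_ave = er.mean(axis=1)
    er_max = er.max(axis=1)
    niri = _nemerow(er_ave, er_max)
    return EcoRiskResult(
        er=er, ri=ri, er_ave=er_ave, er_max=er_max, niri=niri,
        cell_grades=er.apply(schemes["Er"].classify),
        ri_grades=schemes["RI"].classify(ri),
        niri_grades=schemes["NIRI"].classify(niri),
    )


def classify(values, scheme: ClassificationScheme):
    """Grade lookup with the half-open break convention."""
    return scheme.classify(values)


def mean_single_element_risk(mean_conc: pd.Series, ref: ElementReference
                             ) -> pd.Series:
    """Mean-concentration Er per element, the survey-level ranking statistic."""
    elements = [el for el in mean_conc.index if el in ref.eco_elements()]
    return (mean_conc[elements] / ref.background[elements]
            * ref.toxicity[elements])
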