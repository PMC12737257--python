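"""Shared data model: concentration tables, element reference data,
grade schemes and descriptive statistics.

All concentrations are held internally in mg/kg. Elements reported in
g/kg (typically Fe) are converted at load time through an explicit unit
declaration; nothing downstream ever sees mixed units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import defaults


class SchemaError(ValueError):
    """An input file does not have the declared columns/keys."""


class ValidationError(ValueError):
    """Input values violate a data-model invariant."""


def round_half_up(x, ndigits: int = 2):
    """Round half away from zero (report convention, matches 2-dp tables).

    numpy's ``round`` is banker's rounding; survey tables are presented
    half-up, so report formatting goes through this helper.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out.item() if out.ndim == 0 else out


@dataclasses.dataclass
class ConcentrationTable:
    """Samples x elements concentration matrix with land-use strata.

    Parameters
    ----------
    data : DataFrame
        Rows indexed by sample id, one column per element, mg/kg.
    land_use : Series
        Land-use label per sample, from :data:`sorisk.defaults.LAND_USES`.
    """

    data: pd.DataFrame
    land_use: pd.Series
    land_use_categories: tuple = defaults.LAND_USES

    def __post_init__(self):
        self.data = self.data.astype(float)
        self.land_use = self.land_use.reindex(self.data.index)
        if self.land_use.isna().any():
            raise ValidationError("every sample needs a land-use label")
        bad_use = set(self.land_use) - set(self.land_use_categories)
        if bad_use:
            raise ValidationError(f"unknown land-use categories: {sorted(bad_use)}")
        if self.data.isna().any().any():
            cell = self._first_bad_cell(self.data.isna())
            raise ValidationError(f"non-numeric concentration at {cell}")
        if (self.data.values < 0).any():
            cell = self._first_bad_cell(self.data < 0)
            raise ValidationError(f"negative concentration at {cell}")

    def _first_bad_cell(self, mask: pd.DataFrame) -> str:
        stacked = mask.stack()
        sample, element = stacked[stacked].index[0]
        return f"sample {sample!r}, element {element!r}"

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def subset(self, land_use: str) -> "ConcentrationTable":
        mask = self.land_use == land_use
        if not mask.any():
            raise ValidationError(f"no samples with land use {land_use!r}")
        return ConcentrationTable(self.data.loc[mask], self.land_use.loc[mask],
                                  self.land_use_categories)

    def describe(self) -> pd.DataFrame:
        return describe(self)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "land_use", self.land_use)
        out.index.name = "sample_id"
        out.to_csv(path, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, elements: Sequence[str] | None = None,
                 units: Mapping[str, str] | None = None,
                 strict: bool = True) -> "ConcentrationTable":
        return load_concentration_table(path, elements=elements, units=units,
                                        strict=strict)


def load_concentration_table(path, elements: Sequence[str] | None = None,
                             units: Mapping[str, str] | None = None,
                             strict: bool = True) -> ConcentrationTable:
    """Read a sample-by-element CSV into a validated table.

    The CSV carries ``sample_id`` and ``land_use`` columns plus one column
    per element. ``units`` may declare ``{"Fe": "g/kg"}`` to convert that
    column to mg/kg (x1000) at load. With ``strict=False`` rows holding
    negative or non-numeric concentrations are dropped instead of raising;
    the rejected sample ids are recorded on the returned table as
    ``table.rejected``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path)
    if "sample_id" not in raw.columns or "land_use" not in raw.columns:
        raise SchemaError("CSV must have 'sample_id' and 'land_use' columns")
    raw = raw.set_index("sample_id")
    if elements is None:
        elements = [c for c in raw.columns if c != "land_use"]
    missing = [el for el in elements if el not in raw.columns]
    if missing:
        raise SchemaError(f"missing element columns: {missing}")
    values = raw[list(elements)].apply(pd.to_numeric, errors="coerce")
    for el, unit in (units or {}).items():
        if unit not in ("mg/kg", "g/kg"):
            raise SchemaError(f"unknown unit {unit!r} for {el}")
        if unit == "g/kg":
            values[el] = values[el] * 1000.0
    bad = values.isna().any(axis=1) | (values < 0).any(axis=1)
    if bad.any() and not strict:
        rejected = list(values.index[bad])
        table = ConcentrationTable(values.loc[~bad], raw.loc[~bad, "land_use"])
        table.rejected = rejected
        return table
    table = ConcentrationTable(values, raw["land_use"])
    table.rejected = []
    return table


def describe(table: ConcentrationTable) -> pd.DataFrame:
    """Per-element mean / max / min / SD / CV (rows) as in survey tables.

    SD is the sample standard deviation (n-1 denominator); CV = SD/mean.
    Requires at least two samples.
    """
    if table.n_samples < 2:
        raise ValidationError("descriptive statistics need >= 2 samples")
    x = table.data
    mean = x.mean()
    sd = x.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sd / mean).where(mean != 0, 0.0)
    return pd.DataFrame(
        {"mean": mean, "max": x.max(), "min": x.min(), "sd": sd, "cv": cv}
    ).T


@dataclasses.dataclass
class ElementReference:
    """Per-element reference data: backgrounds, toxicity coefficients,
    detection limits, analytical error fractions, reference doses and
    carcinogenic slope factors.

    ``toxicity`` may be NaN for elements excluded from ecological risk
    (Fe by default). ``slope_factor`` is NaN for non-carcinogens.
    """

    background: pd.Series
    toxicity: pd.Series
    mdl: pd.Series
    error_fraction: pd.Series
    rfd: pd.DataFrame           # elements x pathways, mg/kg/day
    slope_factor: pd.DataFrame  # elements x pathways, (mg/kg/day)^-1

    def __post_init__(self):
        if (self.background <= 0).any():
            raise ValidationError("background values must be positive")
        tox = self.toxicity.dropna()
        if (tox < 1).any():
            raise ValidationError("toxicity coefficients must be >= 1")
        if (self.mdl <= 0).any():
            raise ValidationError("MDLs must be positive")
        ef = self.error_fraction
        if ((ef <= 0) | (ef >= 1)).any():
            raise ValidationError("error fractions must lie in (0, 1)")

    @property
    def elements(self) -> list[str]:
        return list(self.background.index)

    def eco_elements(self) -> list[str]:
        """Elements that enter ecological risk (toxicity defined)."""
        return list(self.toxicity.dropna().index)

    @classmethod
    def default(cls, elements: Iterable[str] = defaults.ELEMENTS) -> "ElementReference":
        elements = list(elements)
        idx = pd.Index(elements, name="element")
        rfd = pd.DataFrame({p: pd.Series(defaults.RFD[p]) for p in defaults.PATHWAYS}
                           ).reindex(idx)
        sf = pd.DataFrame({p: pd.Series(defaults.SLOPE_FACTOR[p]) for p in defaults.PATHWAYS}
                          ).reindex(idx)
        return cls(
            background=pd.Series(defaults.HENAN_BACKGROUND).reindex(idx),
            toxicity=pd.Series(defaults.HAKANSON_TOXICITY).reindex(idx),
            mdl=pd.Series(defaults.DEFAULT_MDL).reindex(idx),
            error_fraction=pd.Series(defaults.DEFAULT_ERROR_FRACTION).reindex(idx),
            rfd=rfd,
            slope_factor=sf,
        )

    @classmethod
    def from_yaml(cls, path) -> "ElementReference":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        for key in ("background", "mdl", "error_fraction"):
            if key not in cfg:
                raise SchemaError(f"element reference file missing {key!r}")
        elements = list(cfg["background"])
        idx = pd.Index(elements, name="element")
        rfd = pd.DataFrame(cfg.get("rfd", {})).reindex(idx)
        sf = pd.DataFrame(cfg.get("slope_factor", {})).reindex(idx)
        return cls(
            background=pd.Series(cfg["background"]).reindex(idx).astype(float),
            toxicity=pd.Series(cfg.get("toxicity", {})).reindex(idx).astype(float),
            mdl=pd.Series(cfg["mdl"]).reindex(idx).astype(float),
            error_fraction=pd.Series(cfg["error_fraction"]).reindex(idx).astype(float),
            rfd=rfd,
            slope_factor=sf,
        )

    def to_yaml(self, path) -> None:
        cfg = {
            "background": self.background.to_dict(),
            "toxicity": self.toxicity.dropna().to_dict(),
            "mdl": self.mdl.to_dict(),
            "error_fraction": self.error_fraction.to_dict(),
            "rfd": {p: self.rfd[p].dropna().to_dict() for p in self.rfd.columns},
            "slope_factor": {p: self.slope_factor[p].dropna().to_dict()
                             for p in self.slope_factor.columns},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclasses.dataclass
class ClassificationScheme:
    """Ordered grade break points; half-open [lower, next lower) intervals.

    A value exactly on a break point is assigned to the higher grade.
    """

    name: str
    grades: list  # list of (label, lower_bound)

    def __post_init__(self):
        bounds = [b for _, b in self.grades]
        if bounds[0] > 0:
            raise ValidationError("lowest bound must cover 0")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError("break points must be strictly increasing")
        self._bounds = np.array(bounds)
        self._labels = np.array([lab for lab, _ in self.grades], dtype=object)

    def classify(self, values):
        """Map index values to grade labels."""
        arr = np.asarray(values, dtype=float)
        idx = np.searchsorted(self._bounds, arr, side="right") - 1
        idx = np.clip(idx, 0, len(self._labels) - 1)
        if np.ndim(values) == 0:
            return self._labels[int(idx)]
        out = self._labels[idx]
        if isinstance(values, pd.Series):
            return pd.Series(out, index=values.index)
        return out

    @classmethod
    def default(cls, name: str) -> "ClassificationScheme":
        return cls(name, [tuple(g) for g in defaults.GRADE_SCHEMES[name]])


def default_schemes() -> dict[str, ClassificationScheme]:
    return {name: ClassificationScheme.default(name) for name in defaults.GRADE_SCHEMES}
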