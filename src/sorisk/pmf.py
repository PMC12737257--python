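"""Uncertainty-weighted positive matrix factorization (PMF).

The receptor model decomposes a samples-by-elements concentration matrix
as ``x_ij = sum_k g_ik f_kj + e_ij`` with nonnegative source
contributions ``g`` and source profiles ``f``, minimising

    Q = sum_ij ((x_ij - sum_k g_ik f_kj) / u_ij)^2

where ``u_ij`` is the measurement uncertainty built from the method
detection limit (MDL) and the analytical error fraction:

* concentration above the MDL:
  ``u = sqrt((error_fraction * concentration)^2 + (0.5 * MDL)^2)``
* otherwise: ``u = 5/6 * MDL``

Optimisation uses weighted multiplicative nonnegative-matrix-factorization
updates (weight matrix ``1/u^2``), which keep nonnegativity and never
increase Q; the best of several random initialisations is kept. The scale
ambiguity is resolved by normalising every contribution column to unit
mean. ``Q_robust`` recomputes Q after inflating the uncertainty of cells
with |scaled residual| > 4 to the residual magnitude, so a handful of
outlying cells cannot dominate the objective.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .data import ConcentrationTable, ElementReference, ValidationError

_EPS = 1e-12


def compute_uncertainty(table: ConcentrationTable, ref: ElementReference
                        ) -> pd.DataFrame:
    """Cell-wise uncertainty matrix u_ij from MDL and error fraction.

    The above-MDL branch applies strictly for concentration > MDL; a
    concentration exactly at the MDL uses the below-MDL value (5/6 MDL).
    """
    mdl = ref.mdl.reindex(table.elements)
    ef = ref.error_fraction.reindex(table.elements)
    if mdl.isna().any() or (mdl <= 0).any():
        raise ValidationError("MDL must be positive for every element")
    if ef.isna().any():
        raise ValidationError("error fraction missing for some elements")
    x = table.data
    above = np.sqrt((ef * x) ** 2 + (0.5 * mdl) ** 2)
    below = pd.DataFrame(np.broadcast_to((5.0 / 6.0) * mdl.values, x.shape),
                         index=x.index, columns=x.columns)
    return above.where(x.gt(mdl, axis=1), below)


def _q_value(x, u, g, f):
    return float((((x - g @ f) / u) ** 2).sum())


def _loading_entropy(f):
    """Entropy of per-element loading fractions; lower = sparser profiles."""
    frac = f / (f.sum(axis=0, keepdims=True) + _EPS)
    frac = np.clip(frac, _EPS, 1.0)
    return float(-(frac * np.log(frac)).sum())


def _multiplicative_fit(x, w, g, f, max_iter, tol):
    """Weighted multiplicative updates; returns (g, f, q_history, converged)."""
    wx = w * x
    q_hist = [float((w * (x - g @ f) ** 2).sum())]
    converged = False
    for _ in range(max_iter):
        gf = g @ f
        g = g * (wx @ f.T) / ((w * gf) @ f.T + _EPS)
        gf = g @ f
        f = f * (g.T @ wx) / (g.T @ (w * gf) + _EPS)
        q = float((w * (x - g @ f) ** 2).sum())
        q_hist.append(q)
        if abs(q_hist[-2] - q) <= tol * max(q_hist[-2], _EPS):
            converged = True
            break
    return g, f, np.array(q_hist), converged


class PMF:
    """Receptor model for one concentration table.

    Parameters
    ----------
    x : DataFrame
        Samples x elements concentrations (mg/kg).
    uncertainty : DataFrame
        Cell-wise uncertainties, same shape, all positive.
    n_factors : int
        Number of latent sources (at most min of the matrix dimensions).
    """

    def __init__(self, x: pd.DataFrame, uncertainty: pd.DataFrame,
                 n_factors: int):
        if isinstance(x, ConcentrationTable):
            x = x.data
        self.x = pd.DataFrame(x).astype(float)
        self.u = pd.DataFrame(uncertainty).reindex_like(self.x).astype(float)
        if (self.u <= 0).any().any() or self.u.isna().any().any():
            raise ValidationError("uncertainties must be positive everywhere")
        if not 1 <= n_factors <= min(self.x.shape):
            raise ValidationError("n_factors must lie in [1, min(dims)]")
        self.n_factors = int(n_factors)

    @classmethod
    def from_table(cls, table: ConcentrationTable, ref: ElementReference,
                   n_factors: int) -> "PMF":
        return cls(table.data, compute_uncertainty(table, ref), n_factors)

    def fit(self, n_starts: int = 20, seed: int | None = None,
            max_iter: int = 5000, tol: float = 1e-8,
            tie_tol: float = 0.005) -> "PMFResults":
        """Best-of-``n_starts`` weighted multiplicative-update fit.

        When several starts reach the same minimum Q (within ``tie_tol``
        relative), the factorization is rotationally ambiguous along a
        flat ridge; the tie is broken toward the solution with the
        lowest loading-fraction entropy, i.e. the sparsest profiles —
        the physically expected shape of source profiles, each dominated
        by its tracer elements.
        """
        rng = np.random.default_rng(seed)
        x, u = self.x.values, self.u.values
        w = 1.0 / u**2
        n, m = x.shape
        k = self.n_factors
        col_scale = x.mean(axis=0) / k
        solutions = []
        for _ in range(n_starts):
            g0 = rng.uniform(0.5, 1.5, size=(n, k))
            f0 = col_scale * rng.uniform(0.5, 1.5, size=(k, m))
            g, f, q_hist, conv = _multiplicative_fit(x, w, g0, f0, max_iter, tol)
            solutions.append((g, f, q_hist, conv))
        q_min = min(s[2][-1] for s in solutions)
        ties = [s for s in solutions if s[2][-1] <= q_min * (1.0 + tie_tol)]
        g, f, q_hist, conv = min(ties, key=lambda s: _loading_entropy(s[1]))
        if not conv:
            warnings.warn("PMF did not meet the convergence tolerance within "
                          "the iteration cap; returning best solution found")
        # resolve scale ambiguity: unit-mean contribution columns
        scale = g.mean(axis=0)
        scale[scale == 0] = 1.0
        g = g / scale
        f = f * scale[:, None]
        return PMFResults(model=self, _g=g, _f=f, q_history=q_hist,
                          converged=conv, seed=seed, n_starts=n_starts)


@dataclasses.dataclass
class PMFResults:
    """Fitted factorization with the standard receptor-model diagnostics."""

    model: PMF
    _g: np.ndarray
    _f: np.ndarray
    q_history: np.ndarray
    converged: bool
    seed: object
    n_starts: int

    def __post_init__(self):
        self.factor_names = [f"F{k + 1}" for k in range(self.model.n_factors)]

    @property
    def contributions(self) -> pd.DataFrame:
        return pd.DataFrame(self._g, index=self.model.x.index,
                            columns=self.factor_names)

    @property
    def profiles(self) -> pd.DataFrame:
        return pd.DataFrame(self._f, index=self.factor_names,
                            columns=self.model.x.columns)

    @property
    def reconstruction(self) -> pd.DataFrame:
        return pd.DataFrame(self._g @ self._f, index=self.model.x.index,
                            columns=self.model.x.columns)

    @property
    def scaled_residuals(self) -> pd.DataFrame:
        return (self.model.x - self.reconstruction) / self.model.u

    @property
    def q_true(self) -> float:
        return _q_value(self.model.x.values, self.model.u.values,
                        self._g, self._f)

    @property
    def q_robust(self) -> float:
        e = (self.model.x - self.reconstruction).values
        u = self.model.u.values
        r2 = (e / u) ** 2
        return float(np.where(r2 > 16.0, 1.0, r2).sum())

    def r2_per_element(self) -> pd.Series:
        """Coefficient of determination between observed and reconstructed
        concentrations, per element."""
        x = self.model.x
        xhat = self.reconstruction
        ss_res = ((x - xhat) ** 2).sum()
        ss_tot = ((x - x.mean()) ** 2).sum()
        return (1.0 - ss_res / ss_tot.where(ss_tot > 0)).rename("r2")

    def factor_loading_pct(self) -> pd.DataFrame:
        """Percent of each element's reconstructed mass carried by each
        factor (elements x factors, rows sum to 100)."""
        mass = self.contributions.mean(axis=0).values[:, None] * self._f
        total = mass.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total > 0, mass / total * 100.0, 0.0)
        if (total <= 0).any():
            warnings.warn("element(s) with zero reconstructed mass; "
                          "loading percentages reported as 0")
        return pd.DataFrame(pct.T, index=self.model.x.columns,
                            columns=self.factor_names)

    def factor_contribution_pct(self) -> pd.Series:
        """Percent of total sources per factor: each element's reconstructed
        mass is first normalised to 1 so no single high-concentration
        element dominates; sums to 100."""
        loading = self.factor_loading_pct()
        return loading.mean(axis=0).rename("contribution_pct")

    def diagnostics(self) -> dict:
        """Q ratio, scaled-residual coverage of [-3, 3], per-element R2."""
        r = self.scaled_residuals.values
        return {
            "q_true": self.q_true,
            "q_robust": self.q_robust,
            "q_ratio": self.q_robust / self.q_true if self.q_true > 0 else 1.0,
            "residuals_within_3": float((np.abs(r) <= 3.0).mean()),
            "r2": self.r2_per_element().to_dict(),
            "converged": self.converged,
        }

    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            f"PMF solution: {self.model.n_factors} factors, "
            f"{self.model.x.shape[0]} samples x {self.model.x.shape[1]} elements",
            f"  Q(true) = {d['q_true']:.4g}   Q(robust) = {d['q_robust']:.4g}"
            f"   ratio = {d['q_ratio']:.3f}",
            f"  scaled residuals in [-3, 3]: {100 * d['residuals_within_3']:.1f}%"
            f"   converged: {d['converged']}",
            "  factor contributions (%): "
            + ", ".join(f"{k}: {v:.1f}"
                        for k, v in self.factor_contribution_pct().items()),
        ]
        return "\n".join(lines)


def match_factors(estimated: pd.DataFrame, truth: pd.DataFrame,
                  on: str = "loadings"):
    """Optimal factor pairing via Hungarian assignment on cosine
    similarity of profile rows.

    With ``on="loadings"`` (default) the assignment is computed on
    per-element loading fractions (each element column normalised to sum
    1 across factors), which discriminates factors even when raw
    profiles are dominated by a few high-concentration elements; the
    returned similarities are always cosines of the raw profile rows.
    Returns ``(perm, sims)`` with ``estimated.iloc[perm[k]]``
    corresponding to ``truth.iloc[k]``.
    """
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)

    def _cos_rows(a, b):
        an = a / (np.linalg.norm(a, axis=1, keepdims=True) + _EPS)
        bn = b / (np.linalg.norm(b, axis=1, keepdims=True) + _EPS)
        return bn @ an.T  # truth x estimated

    if on == "loadings":
        est_l = est / (est.sum(axis=0, keepdims=True) + _EPS)
        tru_l = tru / (tru.sum(axis=0, keepdims=True) + _EPS)
        sim_assign = _cos_rows(est_l, tru_l)
    elif on == "profiles":
        sim_assign = _cos_rows(est, tru)
    else:
        raise ValueError("on must be 'loadings' or 'profiles'")
    rows, cols = linear_sum_assignment(-sim_assign)
    sim_profiles = _cos_rows(est, tru)
    return cols, sim_profiles[rows, cols]


def factor_number_scan(x: pd.DataFrame, u: pd.DataFrame, k_values,
                       n_starts: int = 10, seed: int | None = None,
                       **fit_kwargs) -> pd.DataFrame:
    """Q statistics across candidate factor numbers (selection is left to
    inspection, never automated)."""
    rows = []
    for k in k_values:
        res = PMF(x, u, k).fit(n_starts=n_starts, seed=seed, **fit_kwargs)
        rows.append({"k": k, "q_true": res.q_true, "q_robust": res.q_robust,
                     "q_ratio": res.q_robust / res.q_true
                     if res.q_true > 0 else 1.0})
    return pd.DataFrame(rows).set_index("k")


def correlation_matrix(table: ConcentrationTable):
    """Spearman rank correlations with two-sided p-values (diagnostic).

    Constant columns yield NaN correlations, reported as missing.
    """
    if table.n_samples < 5:
        raise ValidationError("correlation diagnostic needs >= 5 samples")
    x = table.data
    cols = list(x.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if x[a].nunique() < 2 or x[b].nunique() < 2:
                continue
            res = stats.spearmanr(x[a], x[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p
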