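"""Power-law species--area model fitting and between-bin slope contrasts.

The nested SAR is the power law ``S = c * A**z``, fitted on log--log axes by
ordinary least squares: ``log10(S) = log10(c) + z * log10(A)`` where ``A`` is
the summed MST length in km of a nested region and ``S`` its (coverage-
standardized or face-value) richness.  The slope ``z`` is the log--log rate
of richness increase with spatial extent -- an average beta diversity over
the measured scales -- and is invariant to the logarithm base.  The
intercept is reported at the smallest measured scale of 100 km
(``c100 = 10**fit(log10 100)``), never at zero: changing the slope would
otherwise masquerade as a change in local richness.

Usage follows the statsmodels convention::

    model = SpeciesAreaModel(area_km, richness)
    res = model.fit()          # -> SpeciesAreaResults
    print(res.summary())

Slope differences between successive time bins use a pooled
slope-by-bin interaction model with t-contrasts on the pooled residual
degrees of freedom and a multivariate-t (simulation based) multiplicity
adjustment over the contrast family, mirroring the estimated-marginal-trends
("emtrends") approach.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SpeciesAreaModel", "SpeciesAreaResults", "SlopeContrast",
           "compare_slopes", "contrasts_to_frame"]

_LOG100 = 2.0  # log10 of the 100 km reference scale


class SpeciesAreaModel:
    """OLS power-law SAR model for one bin x group point cloud.

    Parameters
    ----------
    area_km : array-like
        Spatial extent of each nested region (summed MST length, km > 0).
    richness : array-like
        Richness estimate per region (>= 1; SQS or face-value).
    bin_name, group : str, optional
        Labels carried through to results and summaries.
    """

    def __init__(self, area_km, richness, bin_name: str = "", group: str = ""):
        area = np.asarray(area_km, dtype=float)
        rich = np.asarray(richness, dtype=float)
        ok = np.isfinite(area) & np.isfinite(rich) & (area > 0) & (rich >= 1.0)
        self.n_excluded = int(len(area) - ok.sum())
        self.area_km = area[ok]
        self.richness = rich[ok]
        self.bin_name = bin_name
        self.group = group
        if len(self.area_km) < 3:
            raise ValueError(
                f"need >= 3 usable points to fit a SAR, got {len(self.area_km)}")
        if np.ptp(np.log10(self.area_km)) == 0.0:
            raise ValueError("singular design: all regions share one area")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, area_col: str = "mst_km",
                       richness_col: str = "richness", bin_name: str = "",
                       group: str = "") -> "SpeciesAreaModel":
        return cls(df[area_col], df[richness_col], bin_name=bin_name, group=group)

    def fit(self) -> "SpeciesAreaResults":
        x = np.log10(self.area_km)
        y = np.log10(self.richness)
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        return SpeciesAreaResults(self, res)


class SpeciesAreaResults:
    """Fitted SAR: slope ``z``, intercept at 100 km, uncertainties and
    diagnostics.  Thin wrapper around a statsmodels OLS results object
    (available as ``.ols``)."""

    def __init__(self, model: SpeciesAreaModel, ols_results):
        self.model = model
        self.ols = ols_results
        b0, b1 = ols_results.params
        self.slope_z = float(b1)
        self.se_slope = float(ols_results.bse[1])
        ci = ols_results.conf_int(alpha=0.05)
        self.ci95_slope = (float(ci[1, 0]), float(ci[1, 1]))
        # mean-prediction (normal-theory) interval at log10(100 km)
        xref = np.array([1.0, _LOG100])
        yref = float(xref @ ols_results.params)
        se_ref = float(np.sqrt(xref @ ols_results.cov_params() @ xref))
        tcrit = stats.t.ppf(0.975, ols_results.df_resid)
        self.log10_c100 = yref
        self.se_log10_c100 = se_ref
        self.intercept_c100 = float(10.0 ** yref)
        self.ci95_c100 = (float(10.0 ** (yref - tcrit * se_ref)),
                          float(10.0 ** (yref + tcrit * se_ref)))
        self.r2 = float(ols_results.rsquared)
        self.n_points = int(ols_results.nobs)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.ols.resid)

    def predict(self, area_km) -> np.ndarray:
        """Fitted richness at the given spatial extents (back-transformed)."""
        a = np.asarray(area_km, dtype=float)
        return 10.0 ** (self.ols.params[0] + self.ols.params[1] * np.log10(a))

    def summary(self) -> str:
        label = " ".join(s for s in (self.model.group, self.model.bin_name) if s)
        lines = [
            f"Species-area relationship (power law){': ' + label if label else ''}",
            f"  n regions        {self.n_points}",
            f"  slope z          {self.slope_z:8.4f}  (SE {self.se_slope:.4f}, "
            f"95% CI {self.ci95_slope[0]:.4f} .. {self.ci95_slope[1]:.4f})",
            f"  intercept c100   {self.intercept_c100:8.3f}  species at 100 km  "
            f"(95% CI {self.ci95_c100[0]:.3f} .. {self.ci95_c100[1]:.3f})",
            f"  R^2              {self.r2:8.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **scatter_kw):
        """Log--log scatter of the points with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.area_km, self.model.richness, s=12, alpha=0.6,
                   **scatter_kw)
        grid = np.geomspace(self.model.area_km.min(), self.model.area_km.max(), 64)
        ax.plot(grid, self.predict(grid), color="black",
                label=f"z={self.slope_z:.3f}, c100={self.intercept_c100:.1f}")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("summed MST length (km)")
        ax.set_ylabel("species richness")
        ax.legend(frameon=False)
        return ax

    def to_dict(self) -> dict:
        return {
            "bin": self.model.bin_name, "group": self.model.group,
            "slope": self.slope_z, "se_slope": self.se_slope,
            "ci95_slope_lo": self.ci95_slope[0], "ci95_slope_hi": self.ci95_slope[1],
            "c100": self.intercept_c100,
            "ci95_c100_lo": self.ci95_c100[0], "ci95_c100_hi": self.ci95_c100[1],
            "r2": self.r2, "n_points": self.n_points,
        }


@dataclass(frozen=True)
class SlopeContrast:
    """Difference in SAR slope between two bins from the pooled model."""

    pair: tuple
    estimate: float
    se: float
    df: int
    t_stat: float
    p_value: float
    p_adj: float


def _pooled_interaction_fit(log_area, log_rich, bin_codes, n_bins):
    """Cell-means OLS: one intercept and one slope per bin.

    Returns (beta, cov, df_resid); slope of bin b is beta[n_bins + b].
    """
    n = len(log_area)
    X = np.zeros((n, 2 * n_bins))
    rows = np.arange(n)
    X[rows, bin_codes] = 1.0
    X[rows, n_bins + bin_codes] = log_area
    beta, _, rank, _ = np.linalg.lstsq(X, log_rich, rcond=None)
    if rank < 2 * n_bins:
        raise ValueError("singular pooled design (a bin with constant area?)")
    resid = log_rich - X @ beta
    df = n - 2 * n_bins
    if df <= 0:
        raise ValueError("no residual degrees of freedom in pooled model")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov, df


def compare_slopes(area_km, richness, bins, pairs=None, adjust: str = "mvt",
                   nsim: int = 20000, seed: int = 0):
    """Test SAR slope differences between bins from one pooled model.

    Fits ``log10(S) ~ log10(A) x bin`` (separate intercept and slope per
    bin), then t-tests each requested slope difference on the pooled residual
    degrees of freedom.  ``pairs`` defaults to consecutive bins in order of
    first appearance.  Multiplicity over the contrast family is adjusted by
    simulation from the joint multivariate-t distribution of the contrast
    statistics (``adjust="mvt"``), or by Bonferroni, or not at all.

    Returns a list of :class:`SlopeContrast`.
    """
    area = np.asarray(area_km, dtype=float)
    rich = np.asarray(richness, dtype=float)
    bins = np.asarray(bins, dtype=object)
    ok = np.isfinite(area) & np.isfinite(rich) & (area > 0) & (rich >= 1.0)
    area, rich, bins = area[ok], rich[ok], bins[ok]

    order = list(dict.fromkeys(bins))       # first-appearance order
    code_of = {b: i for i, b in enumerate(order)}
    codes = np.array([code_of[b] for b in bins])
    for b in order:
        if np.sum(codes == code_of[b]) < 3:
            raise ValueError(f"bin {b!r} has fewer than 3 points")
    if pairs is None:
        pairs = list(zip(order[:-1], order[1:]))
    for a, b in pairs:
        if a not in code_of or b not in code_of:
            missing = a if a not in code_of else b
            raise ValueError(f"requested bin {missing!r} absent from points")

    nb = len(order)
    beta, cov, df = _pooled_interaction_fit(np.log10(area), np.log10(rich), codes, nb)

    L = np.zeros((len(pairs), 2 * nb))
    for k, (a, b) in enumerate(pairs):
        L[k, nb + code_of[a]] = 1.0
        L[k, nb + code_of[b]] = -1.0
    est = L @ beta
    vcv = L @ cov @ L.T
    se = np.sqrt(np.diag(vcv))
    tstat = est / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)

    k = len(pairs)
    if k == 1 or adjust == "none":
        p_adj = p.copy()
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, p * k)
    elif adjust == "mvt":
        corr = vcv / np.outer(se, se)
        rng = np.random.default_rng(seed)
        try:
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError:
            p_adj = np.minimum(1.0, p * k)          # Bonferroni fallback
        else:
            z = rng.standard_normal((nsim, k)) @ chol.T
            scale = np.sqrt(rng.chisquare(df, size=nsim) / df)
            maxt = np.max(np.abs(z), axis=1) / scale
            p_adj = np.array([(np.sum(maxt >= abs(t)) + 1.0) / (nsim + 1.0)
                              for t in tstat])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return [SlopeContrast(pair=(a, b), estimate=float(est[i]), se=float(se[i]),
                          df=int(df), t_stat=float(tstat[i]),
                          p_value=float(p[i]), p_adj=float(p_adj[i]))
            for i, (a, b) in enumerate(pairs)]


def contrasts_to_frame(contrasts) -> pd.DataFrame:
    """Tabulate contrasts with the conventional column names."""
    return pd.DataFrame([{
        "Contrast": f"{a} - {b}", "Null.value": 0, "Estimate": c.estimate,
        "SE": c.se, "df": c.df, "Statistic": c.t_stat, "P value": c.p_adj,
    } for c in contrasts for a, b in [c.pair]])
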