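"""Range-equilibrium diagnostics.

Two questions about a species' gradient range: (1) does per-locus genetic
diversity (theta) decline toward the range limits? — tested by a linear
mixed model of per-locus theta on distance from the mean sampling
elevation, with a random intercept per locus and a 1-df likelihood-ratio
test; and (2) how large is Wright's neighborhood size Nw = 4 pi rho sigma^2?
— estimated following Rousset as the reciprocal of the slope of
F_ST/(1-F_ST) on ln(geographic distance).  Negative F_ST values and
negative slopes are corrected to zero, in which case Nw is infinite
(panmixia at the sampled scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import LocalityTable

__all__ = [
    "RangeLimitTestResult",
    "NeighborhoodEstimate",
    "ThetaRangeLimitModel",
    "RoussetRegression",
    "theta_range_lrt",
    "rousset_neighborhood",
]


@dataclass
class RangeLimitTestResult:
    """1-df LRT of theta against distance-from-range-center."""

    chi2: float
    p_value: float
    slope: float
    n_loci: int
    n_populations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "statistic": "LRT chi2 (1 df)",
                    "value": self.chi2,
                    "p_value": self.p_value,
                    "slope_theta_per_m": self.slope,
                }
            ]
        )


def theta_range_lrt(
    theta_table: pd.DataFrame, localities: LocalityTable
) -> RangeLimitTestResult:
    """Mixed-model LRT of per-locus theta on elevation distance.

    ``theta_table`` needs columns locus, population, theta_hat (one row per
    locus x population).  The covariate is the population's absolute
    elevation distance (m) from the mean sampling elevation; the model has
    a random intercept per locus, and the test compares maximum-likelihood
    fits with and without the covariate.
    """
    if localities.n_localities < 3:
        raise ValueError("need at least 3 localities")
    pops = theta_table["population"].unique()
    if theta_table["locus"].nunique() < 20:
        warnings.warn("fewer than 20 loci: the LRT may be unreliable")
    elev = dict(zip(localities.ids, localities.elevation))
    center = localities.elevation.mean()
    d_of = {p: abs(elev[p] - center) for p in pops}
    df = theta_table.copy()
    df["d"] = df["population"].map(d_of).astype(float)
    y = df["theta_hat"].to_numpy(float)
    groups = df["locus"].to_numpy()
    x_alt = sm.add_constant(df["d"].to_numpy(float))
    x_null = np.ones((len(df), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_alt = sm.MixedLM(y, x_alt, groups=groups).fit(reml=False)
        fit_null = sm.MixedLM(y, x_null, groups=groups).fit(reml=False)
    chi2 = max(0.0, 2.0 * (fit_alt.llf - fit_null.llf))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return RangeLimitTestResult(
        chi2=float(chi2),
        p_value=p,
        slope=float(fit_alt.params[1]),
        n_loci=int(theta_table["locus"].nunique()),
        n_populations=len(pops),
    )


@dataclass
class NeighborhoodEstimate:
    """Wright's neighborhood size from Rousset's regression.

    ``nw`` is 1/slope when the slope of F_ST/(1-F_ST) on ln(distance) is
    positive, infinite otherwise; rho (density) and sigma (parent-offspring
    distance) are not separately estimable, only the composite 4 pi rho
    sigma^2.
    """

    slope: float
    intercept: float
    nw: float
    finite: bool
    n_pairs: int
    n_fst_corrected: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "neighborhood_size": self.nw,
                    "finite": self.finite,
                    "n_pairs": self.n_pairs,
                }
            ]
        )


def rousset_neighborhood(fst_pairs: np.ndarray, distances_km: np.ndarray) -> NeighborhoodEstimate:
    """Estimate Nw = 4 pi rho sigma^2 from pairwise F_ST and distances.

    Negative F_ST values are set to 0 before the transformation and a
    non-positive regression slope is corrected to 0, yielding an infinite
    neighborhood size.  Zero distances are an error (ln undefined); exclude
    same-locality pairs upstream.
    """
    fst = np.asarray(fst_pairs, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if fst.shape != d.shape:
        raise ValueError("fst_pairs and distances must align")
    if len(fst) < 3:
        raise ValueError("need at least 3 population pairs")
    if (d <= 0).any():
        raise ValueError("distances must be positive (ln undefined at 0)")
    n_corrected = int((fst < 0).sum())
    fst = np.clip(fst, 0.0, None)
    if (fst >= 1).any():
        raise ValueError("F_ST must be below 1")
    y = fst / (1.0 - fst)
    x = np.log(d)
    slope, intercept = np.polyfit(x, y, 1)
    corrected_slope = max(0.0, float(slope))
    finite = corrected_slope > 0
    return NeighborhoodEstimate(
        slope=corrected_slope,
        intercept=float(intercept),
        nw=1.0 / corrected_slope if finite else float("inf"),
        finite=finite,
        n_pairs=len(fst),
        n_fst_corrected=n_corrected,
    )


class ThetaRangeLimitModel:
    """Model object: per-locus theta against range position."""

    def __init__(self, theta_table: pd.DataFrame, localities: LocalityTable):
        self.theta_table = theta_table
        self.localities = localities

    def fit(self) -> RangeLimitTestResult:
        return theta_range_lrt(self.theta_table, self.localities)


class RoussetRegression:
    """Model object: pairwise F_ST against log distance.

    Accepts a square F_ST matrix plus the matching distance matrix (zero
    -distance pairs are excluded, as are the diagonals) or flat pair
    arrays.
    """

    def __init__(self, fst, distances_km):
        fst = np.asarray(fst, dtype=float)
        d = np.asarray(distances_km, dtype=float)
        if fst.ndim == 2:
            iu = np.triu_indices(fst.shape[0], k=1)
            fst, d = fst[iu], d[iu]
            keep = d > 0
            if (~keep).any():
                warnings.warn(f"excluding {(~keep).sum()} zero-distance pairs")
            fst, d = fst[keep], d[keep]
        self.fst = fst
        self.distances_km = d

    def fit(self) -> NeighborhoodEstimate:
        return rousset_neighborhood(self.fst, self.distances_km)
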