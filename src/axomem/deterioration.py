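"""Exponential deterioration-rate law R(p) = A - B * e^p.

The decline of the recognition score with injury level p is summarized by
an exponential law, fit by ordinary least squares of R on the regressor
e^p (the model is linear in (A, B), so the fit is exact and the usual OLS
standard errors apply).  B is the deterioration rate: larger B means the
network loses recall performance faster as the injured fraction grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["DeteriorationFit", "fit_rate", "predict", "fit_from_sweep"]


@dataclass(frozen=True)
class DeteriorationFit:
    A: float
    B: float
    se_A: float
    se_B: float
    n_points: int
    rmse: float
    noise_level: float | str = "pooled"

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("a fit needs at least 2 points")

    def predict(self, p):
        return predict(self, p)

    def to_dict(self) -> dict:
        return dict(
            A=self.A, B=self.B, se_A=self.se_A, se_B=self.se_B,
            n_points=self.n_points, rmse=self.rmse, noise_level=self.noise_level,
        )


def fit_rate(points, noise_level: float | str = "pooled") -> DeteriorationFit:
    """Fit R = A - B * e^p by OLS over (p, R) pairs.

    ``points`` is a sequence of (p, R) pairs or a 2-column array.  Requires
    at least two distinct p values (otherwise the design is singular).
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an n x 2 array of (p, R)")
    arr = arr[~np.isnan(arr).any(axis=1)]  # cells without a usable score
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 valid (p, R) points")
    p, r = arr[:, 0], arr[:, 1]
    if np.ptp(p) == 0:
        raise ValueError("all p values identical: singular design")
    x = sm.add_constant(np.exp(p))
    with np.errstate(divide="ignore", invalid="ignore"):  # saturated 2-point fit
        res = sm.OLS(r, x).fit()
        a, minus_b = res.params
        se_a, se_b = res.bse
        rmse = float(np.sqrt(np.mean(res.resid**2)))
    return DeteriorationFit(
        A=float(a), B=float(-minus_b), se_A=float(se_a), se_B=float(se_b),
        n_points=len(r), rmse=rmse, noise_level=noise_level,
    )


def predict(fit: DeteriorationFit, p):
    """Predicted recognition score A - B * e^p."""
    p = np.asarray(p, dtype=float)
    out = fit.A - fit.B * np.exp(p)
    return float(out) if out.ndim == 0 else out


def fit_from_sweep(aggregate: pd.DataFrame, pooled: bool = True) -> list[DeteriorationFit]:
    """Fit the deterioration law to an aggregated sweep table.

    With ``pooled=True`` a single fit uses every (noise, injury) cell's
    normalized score; otherwise one fit is produced per cue-noise level.
    """
    fits = []
    if pooled:
        pts = aggregate[["injury_level", "score"]].to_numpy()
        fits.append(fit_rate(pts, noise_level="pooled"))
    else:
        for noise, grp in aggregate.groupby("noise_level", sort=True):
            pts = grp[["injury_level", "score"]].to_numpy()
            fits.append(fit_rate(pts, noise_level=float(noise)))
    return fits
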