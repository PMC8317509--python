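"""Whale- and species-level aggregation and log-log scaling fits.

Allometric relations of the form y = b * L^m appear as straight lines on
log10-log10 axes; ordinary least squares on the transformed variables
returns the scaling exponent m as the slope. (Species random effects and
GAM smoothers are deliberately out of scope; OLS on whale-level means and
binned means are the implemented analogues.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InvalidInputError

__all__ = [
    "ScalingFit",
    "summarize_deployments",
    "loglog_scaling_fit",
    "efficiency_speed_curve",
]


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit on log10-transformed axes; ``slope`` is the allometric exponent."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    predictor_name: str
    response_name: str
    slope_se: float
    slope_conf_int: tuple[float, float]

    def summary(self) -> str:
        lo, hi = self.slope_conf_int
        return (
            f"log10({self.response_name}) ~ log10({self.predictor_name}), n={self.n}\n"
            f"  slope     {self.slope:+.4f} (SE {self.slope_se:.4f}, "
            f"95% CI [{lo:+.4f}, {hi:+.4f}])\n"
            f"  intercept {self.intercept:+.4f}\n"
            f"  R^2       {self.r_squared:.4f}"
        )


def summarize_deployments(records: pd.DataFrame) -> pd.DataFrame:
    """One summary row per (whale_id, species, mode) with mean and s.e.m.

    ``records`` must carry ``whale_id``, ``species`` and ``mode`` columns;
    every numeric column is summarised. Beats with mode ``excluded`` are
    dropped before aggregation.
    """
    for col in ("whale_id", "species", "mode"):
        if col not in records.columns:
            raise InvalidInputError(f"records must contain a {col!r} column")
    use = records[records["mode"] != "excluded"]
    numeric = use.select_dtypes(include=[np.number]).columns
    grouped = use.groupby(["whale_id", "species", "mode"], sort=True)
    out = []
    for key, grp in grouped:
        row: dict = dict(zip(["whale_id", "species", "mode"], key))
        row["n_beats"] = len(grp)
        for col in numeric:
            vals = grp[col].dropna().to_numpy()
            row[f"mean_{col}"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"sem_{col}"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        out.append(row)
    return pd.DataFrame(out)


def loglog_scaling_fit(
    x, y, predictor_name: str = "x", response_name: str = "y"
) -> ScalingFit:
    """OLS of log10(y) on log10(x); the slope is the scaling exponent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need at least 3 paired observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidInputError("log-log fit requires strictly positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    model = sm.OLS(ly, sm.add_constant(lx))
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    return ScalingFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared) if np.isfinite(res.rsquared) else 1.0,
        n=int(x.size),
        predictor_name=predictor_name,
        response_name=response_name,
        slope_se=float(res.bse[1]),
        slope_conf_int=(float(ci[1, 0]), float(ci[1, 1])),
    )


def efficiency_speed_curve(
    eta,
    u,
    bin_width: float = 0.25,
    speed_range: tuple[float, float] = (1.0, 5.0),
    min_count: int = 5,
) -> pd.DataFrame:
    """Binned mean Froude efficiency over swimming speed.

    Returns one row per speed bin with the bin centre, mean efficiency,
    beat count and a ``low_n`` flag for bins thinner than ``min_count``.
    """
    eta = np.asarray(eta, dtype=float)
    u = np.asarray(u, dtype=float)
    if eta.size == 0:
        return pd.DataFrame(columns=["speed_mid", "mean_eta", "n", "low_n"])
    lo, hi = speed_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (u >= a) & (u < b)
        n = int(np.sum(sel))
        if n == 0:
            continue
        rows.append(
            {
                "speed_mid": (a + b) / 2,
                "mean_eta": float(np.mean(eta[sel])),
                "n": n,
                "low_n": n < min_count,
            }
        )
    return pd.DataFrame(rows)
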