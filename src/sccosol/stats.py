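"""Fit statistics: objective function, AARD, R2, AIC/AICc, model comparison.

All models in the package are regressed by minimizing the sum of absolute
relative deviations

    OF = sum_i |y2_exp,i - y2_calc,i| / y2_exp,i,
    AARD% = 100 * OF / N,

while the goodness-of-fit and information criteria are computed on raw mole-
fraction residuals: SSE = sum (y_exp - y_calc)^2, AIC = N ln(SSE/N) + 2Q and
AICc = AIC + 2Q(Q+1)/(N-Q-1).  The two objectives differ; the comparison
table deliberately reports the raw-residual statistics so that models fitted
on relative deviations can still be ranked by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "objective_of",
    "aard_percent",
    "r_squared",
    "adjusted_r_squared",
    "information_criteria",
    "ComparisonRow",
    "comparison_table",
    "sample_std",
    "expanded_uncertainty",
    "combined_relative_uncertainty",
]


def _as_arrays(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if np.any(obs <= 0):
        raise ValueError("observed values must be strictly positive")
    return obs, pred


def objective_of(observed, predicted) -> float:
    """Sum of absolute relative deviations (the regression objective)."""
    obs, pred = _as_arrays(observed, predicted)
    return float(np.sum(np.abs(obs - pred) / obs))


def aard_percent(observed, predicted) -> float:
    """Average absolute relative deviation, in percent."""
    obs, _ = _as_arrays(observed, predicted)
    return 100.0 * objective_of(observed, predicted) / obs.size


def r_squared(observed, predicted) -> float:
    """R2 = 1 - SSE/SStot on the mole fractions."""
    obs, pred = _as_arrays(observed, predicted)
    sse = float(np.sum((obs - pred) ** 2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    return 1.0 - sse / sstot


def adjusted_r_squared(r2: float, n: int, q: int) -> float:
    """R2_adj = 1 - (1 - R2)(N - 1)/(N - Q - 1)."""
    if n - q - 1 <= 0:
        raise ValueError("need N > Q + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def information_criteria(sse: float, n: int, q: int) -> tuple[float, float]:
    """(AIC, AICc) from the error sum of squares.

    AIC = N ln(SSE/N) + 2Q;  AICc adds the small-sample correction
    2Q(Q+1)/(N-Q-1), appropriate whenever N < 40.
    """
    if sse <= 0:
        raise ValueError("sse must be > 0")
    if n <= q + 1:
        raise ValueError("AICc undefined for N <= Q + 1")
    aic = n * math.log(sse / n) + 2 * q
    aicc = aic + 2 * q * (q + 1) / (n - q - 1)
    return aic, aicc


@dataclass(frozen=True)
class ComparisonRow:
    model_name: str
    sse: float
    rmse: float
    n_points: int
    n_params: int
    aic: float
    aicc: float
    aard_percent: float
    r2: float
    r2_adj: float


def comparison_table(fits: Sequence) -> pd.DataFrame:
    """Model-comparison table, rows sorted ascending by AICc.

    ``fits`` is a sequence of fitted results (any object exposing
    ``model_name``, ``observed``, ``fittedvalues`` and ``k_params``).
    All fits must be on the same dataset.
    """
    if not fits:
        raise ValueError("no fits given")
    ref = np.asarray(fits[0].observed, dtype=float)
    rows = []
    for fit in fits:
        obs = np.asarray(fit.observed, dtype=float)
        if obs.shape != ref.shape or not np.allclose(obs, ref):
            raise ValueError(
                f"{fit.model_name}: fitted on a different dataset"
            )
        pred = np.asarray(fit.fittedvalues, dtype=float)
        n, q = obs.size, fit.k_params
        sse = float(np.sum((obs - pred) ** 2))
        aic, aicc = information_criteria(sse, n, q)
        r2 = r_squared(obs, pred)
        rows.append(
            ComparisonRow(
                model_name=fit.model_name,
                sse=sse,
                rmse=math.sqrt(sse / n),
                n_points=n,
                n_params=q,
                aic=aic,
                aicc=aicc,
                aard_percent=aard_percent(obs, pred),
                r2=r2,
                r2_adj=adjusted_r_squared(r2, n, q),
            )
        )
    rows.sort(key=lambda r: r.aicc)
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("model_name")


def sample_std(values) -> float:
    """Bessel-corrected (n-1) sample standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.sqrt(np.sum((arr - arr.mean()) ** 2) / (arr.size - 1)))


def expanded_uncertainty(u_combined: float, k: float = 2.0) -> float:
    """U = k * u_combined (k=2 ~ 95% confidence)."""
    if not k > 0:
        raise ValueError("coverage factor k must be > 0")
    return k * u_combined


def combined_relative_uncertainty(
    sensitivities: Sequence[float],
    rel_uncertainties: Sequence[float],
) -> float:
    """u_combined/y = sqrt(sum (P_i * u(x_i)/x_i)^2).

    Generic propagation utility; the sensitivity coefficients P_i are
    measurement-chain specific and must be supplied by the caller.
    """
    s = np.asarray(sensitivities, dtype=float)
    u = np.asarray(rel_uncertainties, dtype=float)
    if s.shape != u.shape:
        raise ValueError("sensitivities and uncertainties must align")
    return float(np.sqrt(np.sum((s * u) ** 2)))
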