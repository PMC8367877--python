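"""Blind-challenge evaluation statistics.

Error metrics over aligned predicted/experimental pairs — root mean square
error (RMSE), mean absolute error (MAE) and mean signed error (MSE, the
bias) — plus a *descriptive* ordinary least squares regression of the
predictions on the experimental values, reported as slope m', intercept b'
and the coefficient of determination R^2 (squared Pearson correlation).

"Descriptive" means the regression characterizes the scatter plot; it is
not used to recalibrate predictions.  Rows without an experimental value
are dropped (with a logged count) before any statistic is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["PredictionTable", "MetricsReport", "error_metrics",
           "descriptive_regression", "evaluate"]


@dataclass(frozen=True)
class PredictionTable:
    """Aligned predicted vs. experimental values for one property."""

    data: pd.DataFrame  # columns: compound_id, predicted, experimental
    property_label: str = ""

    REQUIRED = ("compound_id", "predicted", "experimental")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"prediction table missing columns: {missing}")
        if df["compound_id"].duplicated().any():
            dups = sorted(df.loc[df["compound_id"].duplicated(), "compound_id"])
            raise ValueError(f"duplicate compound ids: {dups}")
        n_missing = int(df["experimental"].isna().sum())
        if n_missing:
            logger.info(
                "%s: dropping %d row(s) without experimental values",
                self.property_label or "prediction table", n_missing,
            )
            df = df.dropna(subset=["experimental"])
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, float, float | None]],
        property_label: str = "",
    ) -> "PredictionTable":
        df = pd.DataFrame(pairs, columns=list(cls.REQUIRED))
        return cls(df, property_label)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def predicted(self) -> np.ndarray:
        return self.data["predicted"].to_numpy(dtype=float)

    @property
    def experimental(self) -> np.ndarray:
        return self.data["experimental"].to_numpy(dtype=float)


@dataclass(frozen=True)
class MetricsReport:
    """One row of challenge statistics for one prediction table."""

    n: int
    rmse: float
    mae: float
    mse: float
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    property_label: str = ""

    def to_dict(self) -> dict:
        return {
            "property": self.property_label, "n": self.n, "rmse": self.rmse,
            "mae": self.mae, "mse": self.mse, "slope": self.slope,
            "intercept": self.intercept, "r2": self.r2,
        }

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation rounding; internal values stay full precision."""
        out = self.to_dict()
        for k, v in out.items():
            if isinstance(v, float):
                out[k] = round(v, ndigits)
        return out


def error_metrics(table: PredictionTable) -> MetricsReport:
    """RMSE, MAE and mean signed error of predicted - experimental."""
    if len(table) < 2:
        raise ValueError(f"need at least 2 rows, got {len(table)}")
    e = table.predicted - table.experimental
    return MetricsReport(
        n=len(table),
        rmse=float(np.sqrt(np.mean(e**2))),
        mae=float(np.mean(np.abs(e))),
        mse=float(np.mean(e)),
        property_label=table.property_label,
    )


def descriptive_regression(table: PredictionTable) -> tuple[float, float, float]:
    """OLS of predicted (response) on experimental (regressor).

    Returns (slope, intercept, r2) with r2 the squared Pearson correlation
    — identical whichever variable is treated as response.
    """
    if len(table) < 3:
        raise ValueError(f"need at least 3 rows for regression, got {len(table)}")
    x = table.experimental
    if math.isclose(float(np.var(x)), 0.0, abs_tol=1e-300):
        raise ValueError("experimental values have zero variance")
    fit = sps.linregress(x, table.predicted)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def evaluate(table: PredictionTable) -> MetricsReport:
    """Full statistics row: error metrics plus descriptive regression."""
    base = error_metrics(table)
    slope, intercept, r2 = descriptive_regression(table)
    return MetricsReport(
        n=base.n, rmse=base.rmse, mae=base.mae, mse=base.mse,
        slope=slope, intercept=intercept, r2=r2,
        property_label=table.property_label,
    )
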