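"""Regressions of demographic and physico-ecological predictors on the
morphological response variables.

With only a handful of crater lakes, each predictor-response combination is
fitted as a separate simple OLS regression (no multivariate models).  The
divergence-rate response is the Mahalanobis distance of a crater lake to
its source divided by colonization time in generations, a multivariate
analogue of the haldane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import LakeTable

__all__ = [
    "RegressionFit",
    "divergence_rate",
    "ols_fit",
    "LakeRegressionSuite",
    "RegressionSuiteResults",
    "run_regression_suite",
]

RESPONSES = ("procrustes_dist", "shape_variance", "cv_ei", "rate")
PREDICTORS = (
    "n_founder",
    "t_col",
    "admix",
    "ne_longterm",
    "mean_depth",
    "littoral_area",
)
# predictors log10-transformed by default (large dynamic range)
LOG_PREDICTORS = ("n_founder",)
# additional "exponential" (log10-predictor) variants fitted alongside the
# linear ones
EXPONENTIAL_VARIANTS = (("shape_variance", "mean_depth"), ("rate", "t_col"))


@dataclass
class RegressionFit:
    predictor: str
    response: str
    transform: str  # "none" | "log10_x"
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return dict(
            predictor=self.predictor,
            response=self.response,
            transform=self.transform,
            slope=self.slope,
            intercept=self.intercept,
            r2=self.r2,
            adj_r2=self.adj_r2,
            p=self.p,
            n=self.n,
        )


def divergence_rate(mahalanobis_dist: float, t_col_generations: float) -> float:
    """Morphological change per generation: distance / colonization time."""
    if t_col_generations <= 0:
        raise ValueError("colonization time must be positive")
    return float(mahalanobis_dist) / float(t_col_generations)


def ols_fit(x, y, transform: str = "none",
            predictor: str = "x", response: str = "y") -> RegressionFit:
    """Simple OLS of y on (optionally log10-transformed) x.

    Reports r2, adjusted r2 = 1 - (1 - r2)(n - 1)/(n - 2), and the
    two-sided F-test p-value (equal to the squared-t p-value for a simple
    regression).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if transform == "log10_x":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive x")
        x = np.log10(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        # constant response: flat fit, no explained variance
        return RegressionFit(predictor, response, transform,
                             slope=0.0, intercept=float(y[0]),
                             r2=0.0, adj_r2=0.0, p=1.0, n=n)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    return RegressionFit(
        predictor=predictor,
        response=response,
        transform=transform,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        p=float(model.f_pvalue),
        n=n,
    )


@dataclass
class RegressionSuiteResults:
    fits: list[RegressionFit]
    skipped: list[tuple[str, str, str]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([f.to_dict() for f in self.fits])
        df["significant"] = df["p"] < 0.05
        df["p_bonferroni"] = np.minimum(1.0, df["p"] * len(df))
        return df

    def significant(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Per-lake regression suite (separate simple OLS fits)",
            f"  fits: {len(df)}   significant at 0.05: {int(df.significant.sum())}",
        ]
        if self.skipped:
            lines.append(f"  skipped (missing data): {len(self.skipped)}")
        lines.append(
            df.sort_values("p")
            .to_string(index=False, float_format=lambda v: f"{v:.4g}")
        )
        return "\n".join(lines)


class LakeRegressionSuite:
    """Model: every response x predictor combination of a lake table as a
    separate simple regression.

    Founder size is log10-transformed; an "exponential" (log10-predictor)
    variant is additionally fitted for shape variance against mean depth
    and rate against colonization time.  Surface area is deliberately not
    part of the default predictor set (collinear with mean depth).
    Combinations with missing values are skipped and listed.
    """

    def __init__(
        self,
        table: LakeTable,
        responses=RESPONSES,
        predictors=PREDICTORS,
    ):
        self.table = table
        self.responses = tuple(responses)
        self.predictors = tuple(predictors)
        missing = [
            c
            for c in self.responses + self.predictors
            if c not in table.frame.columns
        ]
        if missing:
            raise ValueError(f"lake table is missing columns: {missing}")
        if len(table.frame) < 3:
            raise ValueError("need at least 3 lakes")

    def fit(self) -> RegressionSuiteResults:
        df = self.table.frame
        fits: list[RegressionFit] = []
        skipped: list[tuple[str, str, str]] = []
        combos = [
            (resp, pred, "log10_x" if pred in LOG_PREDICTORS else "none")
            for resp in self.responses
            for pred in self.predictors
        ]
        combos += [
            (resp, pred, "log10_x")
            for resp, pred in EXPONENTIAL_VARIANTS
            if resp in self.responses and pred in self.predictors
        ]
        for resp, pred, transform in combos:
            sub = df[[pred, resp]].dropna()
            if len(sub) < 3:
                skipped.append((resp, pred, transform))
                continue
            try:
                fits.append(
                    ols_fit(
                        sub[pred].to_numpy(),
                        sub[resp].to_numpy(),
                        transform=transform,
                        predictor=pred,
                        response=resp,
                    )
                )
            except ValueError:
                skipped.append((resp, pred, transform))
        return RegressionSuiteResults(fits=fits, skipped=skipped)


def run_regression_suite(table: LakeTable) -> RegressionSuiteResults:
    """Functional entry point over :class:`LakeRegressionSuite`."""
    return LakeRegressionSuite(table).fit()
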