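"""Pooled multi-predictor volume regression and summary-statistics ANOVA.

Two pieces of machinery:

* :func:`fit_volume_model` — OLS of each regional volume on age, sex,
  ethnicity, education, and ICV, reporting standardized and raw
  coefficients with a Bonferroni significance flag.
* :func:`twoway_anova_from_summaries` — a 2x2 ethnicity-by-sex ANOVA
  reconstructed exactly from per-cell (n, mean, sd) summaries using
  sequential (Type I) sums of squares, for when only the published cell
  summaries are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .cohort import CohortTable

__all__ = [
    "RegressionResult",
    "CellSummary",
    "AnovaRow",
    "AnovaTable",
    "PREDICTORS",
    "fit_volume_model",
    "bonferroni_threshold",
    "twoway_anova_from_summaries",
    "expand_cell_summary",
]

PREDICTORS = ("age", "sex", "ethnicity", "education", "icv")

# Binary codings: chosen so a negative ethnicity coefficient means the
# second-listed level has smaller volumes.
DEFAULT_SEX_CODING: Mapping[str, float] = {"female": 0.0, "male": 1.0}
DEFAULT_ETHNICITY_CODING: Mapping[str, float] = {"korean": 0.0, "caucasian": 1.0}


@dataclass(frozen=True)
class PredictorEffect:
    b_std: float
    b_raw: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    region: str
    effects: Mapping[str, PredictorEffect]
    r2: float
    n: int
    p_threshold: float

    def significant(self, predictor: str) -> bool:
        return self.effects[predictor].p < self.p_threshold


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test p threshold controlling family-wise error at ``alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate design: constant predictor or outcome")
    return (x - x.mean()) / sd


def fit_volume_model(
    cohort: CohortTable,
    region: str,
    alpha: float = 0.05,
    m: int = 15,
    sex_coding: Mapping[str, float] = DEFAULT_SEX_CODING,
    ethnicity_coding: Mapping[str, float] = DEFAULT_ETHNICITY_CODING,
    standardize_binary: bool = True,
) -> RegressionResult:
    """OLS of a region's absolute volume on the five standard predictors.

    Standardized coefficients come from the fully z-scored model (binary
    predictors coded 0/1, then z-scored by default; set
    ``standardize_binary=False`` to keep them as dummies).  Raw
    coefficients and p-values come from the unscaled fit; p-values are
    identical between the two parameterizations.
    """
    if region not in cohort.region_set:
        raise KeyError(f"unknown region {region!r}")
    if len(cohort) < 10:
        raise ValueError("need at least 10 records")
    raw = {
        "age": np.array([r.age for r in cohort], dtype=float),
        "sex": np.array([sex_coding[r.sex] for r in cohort], dtype=float),
        "ethnicity": np.array([ethnicity_coding[r.ethnicity] for r in cohort], dtype=float),
        "education": np.array([r.education for r in cohort], dtype=float),
        "icv": np.array([r.icv for r in cohort], dtype=float),
    }
    y = np.array([r.volumes[region] for r in cohort], dtype=float)

    for name, x in raw.items():
        if x.std(ddof=1) == 0:
            raise ValueError(f"degenerate design: predictor {name!r} is constant")
    if y.std(ddof=1) == 0:
        raise ValueError("degenerate design: outcome is constant")

    X_raw = sm.add_constant(np.column_stack([raw[p] for p in PREDICTORS]))
    fit_raw = sm.OLS(y, X_raw).fit()

    cols_std = []
    for p in PREDICTORS:
        x = raw[p]
        if p in ("sex", "ethnicity") and not standardize_binary:
            cols_std.append(x)
        else:
            cols_std.append(_zscore(x))
    X_std = sm.add_constant(np.column_stack(cols_std))
    fit_std = sm.OLS(_zscore(y), X_std).fit()

    effects = {
        p: PredictorEffect(
            b_std=float(fit_std.params[i + 1]),
            b_raw=float(fit_raw.params[i + 1]),
            p=float(fit_raw.pvalues[i + 1]),
        )
        for i, p in enumerate(PREDICTORS)
    }
    return RegressionResult(
        region=region,
        effects=effects,
        r2=float(fit_raw.rsquared),
        n=len(cohort),
        p_threshold=bonferroni_threshold(alpha, m),
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA from cell summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSummary:
    ethnicity: str
    sex: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each cell needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaRow:
    term: str
    ss: float
    df: int
    F: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple[AnovaRow, ...]
    ss_error: float
    df_error: int

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)


def _weighted_rss(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = (y - X @ beta) * sw
    return float(resid @ resid)


def twoway_anova_from_summaries(cells: Sequence[CellSummary]) -> AnovaTable:
    """2x2 ANOVA (ethnicity, sex, interaction) from per-cell summaries.

    Uses sequential (Type I) sums of squares with ethnicity entered first,
    then sex, then the interaction; in a 2x2 design the interaction SS is
    invariant to the SS type.  Equivalent to the subject-level ANOVA: the
    between-cell part depends only on cell ns and means, and the error SS
    is the pooled within-cell sum of squares ``sum((n_i - 1) * sd_i^2)``.
    """
    if len(cells) != 4:
        raise ValueError("exactly four cells (2x2 design) required")
    combos = {(c.ethnicity, c.sex) for c in cells}
    eth_levels = sorted({c.ethnicity for c in cells})
    sex_levels = sorted({c.sex for c in cells})
    if len(eth_levels) != 2 or len(sex_levels) != 2 or len(combos) != 4:
        raise ValueError("cells must form a complete 2x2 ethnicity-by-sex design")

    n = np.array([c.n for c in cells], dtype=float)
    m = np.array([c.mean for c in cells], dtype=float)
    s = np.array([c.sd for c in cells], dtype=float)
    eth = np.array([float(eth_levels.index(c.ethnicity)) for c in cells])
    sex = np.array([float(sex_levels.index(c.sex)) for c in cells])

    one = np.ones(4)
    designs = [
        np.column_stack([one]),
        np.column_stack([one, eth]),
        np.column_stack([one, eth, sex]),
        np.column_stack([one, eth, sex, eth * sex]),
    ]
    rss = [_weighted_rss(X, m, n) for X in designs]
    ss_terms = [rss[i] - rss[i + 1] for i in range(3)]

    ss_error = float(((n - 1.0) * s**2).sum())
    df_error = int(n.sum()) - 4
    if df_error < 1:
        raise ValueError("no error degrees of freedom")
    mse = ss_error / df_error

    rows = []
    for term, ss in zip(("ethnicity", "sex", "ethnicity:sex"), ss_terms):
        F = ss / mse
        rows.append(AnovaRow(term=term, ss=ss, df=1, F=F, p=float(sps.f.sf(F, 1, df_error))))
    return AnovaTable(rows=tuple(rows), ss_error=ss_error, df_error=df_error)


def expand_cell_summary(cell: CellSummary) -> np.ndarray:
    """Construct a sample with exactly the cell's n, mean, and sd.

    Two points sit at mean +/- sd*sqrt((n-1)/2) and the rest at the mean;
    used as the subject-level oracle for the summary ANOVA.
    """
    delta = cell.sd * np.sqrt((cell.n - 1) / 2.0)
    values = np.full(cell.n, cell.mean, dtype=float)
    values[0] += delta
    values[1] -= delta
    return values


def regression_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Tidy per-predictor table mirroring the published regression layout."""
    rows = []
    for res in results:
        for predictor in PREDICTORS:
            eff = res.effects[predictor]
            rows.append(
                {
                    "region": res.region,
                    "predictor": predictor,
                    "b_std": eff.b_std,
                    "b_raw": eff.b_raw,
                    "p": eff.p,
                    "significant_bonferroni": eff.p < res.p_threshold,
                    "r2": res.r2,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
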