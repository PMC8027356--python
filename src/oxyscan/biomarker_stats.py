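"""Cohort statistics: biomarker/curve-parameter correlations and summaries.

Reproduces the published analysis surface: pairwise Pearson correlations of
the extracted curve parameters (EI_min, EI_max, PoS) with %HbF, %F-cells and
%DRBCs (with two-sided p-values from the t transform and Fisher-z 95%
confidence intervals), ordinary-least-squares fits with pointwise confidence
bands for the scatter panels, cohort summary tables, and the
point-of-sickling threshold observation (very high %HbF and %F-cells are
required for PoS to fall reliably below 25 mmHg).

Samples with an undefined PoS (non-sickling curves) are excluded pairwise,
with the excluded count reported — never silently dropped.  The correlation
machinery is implemented directly from the product-moment formulas so the
analysis is self-contained; tests cross-check it against scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

BIOMARKER_ROWS = ("hbf_pct", "fcells_pct", "drbc_pct")
PARAMETER_COLS = ("ei_min", "ei_max", "pos_mmHg")


class DegenerateVariableError(ValueError):
    """A correlation input has zero variance."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one biomarker x parameter pair."""

    biomarker: str
    parameter: str
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n_used: int
    n_excluded: int = 0


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of y on x with a pointwise 95% CI band for the mean response."""

    slope: float
    intercept: float
    slope_se: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep], int((~keep).sum())


def _t_sf(t: float, df: int) -> float:
    """Two-sided p from Student's t via the regularised incomplete beta."""
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def pearson_r(
    x, y, biomarker: str = "x", parameter: str = "y"
) -> CorrelationResult:
    """Product-moment correlation with t-transform p-value and Fisher-z CI.

    Undefined entries are deleted pairwise; requires n >= 3 complete pairs
    and non-zero variance in both vectors.
    """
    xv, yv, n_excluded = _clean_pair(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateVariableError("degenerate_variable: zero variance input")
    r = float(xc @ yc / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = _t_sf(abs(t), n - 2)
    if abs(r) == 1.0:
        ci_low = ci_high = r
    elif n <= 3:
        ci_low, ci_high = -1.0, 1.0
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(
        biomarker=biomarker,
        parameter=parameter,
        r=r,
        p_value=p,
        ci_low=ci_low,
        ci_high=ci_high,
        n_used=n,
        n_excluded=n_excluded,
    )


def _records_to_frame(cohort) -> pd.DataFrame:
    """Accept a DataFrame or a list of PatientRecord with params filled."""
    if isinstance(cohort, pd.DataFrame):
        return cohort
    rows = []
    for rec in cohort:
        if rec.params is None:
            raise ValueError(
                f"{rec.sample_id}: curve parameters not extracted yet"
            )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "hbf_pct": rec.hbf_pct,
                "fcells_pct": rec.fcells_pct,
                "drbc_pct": rec.drbc_pct,
                "hb_g_dl": rec.hb_g_dl,
                "rbc_count_1e6_ul": rec.rbc_count_1e6_ul,
                "ei_max": rec.params.ei_max,
                "ei_min": rec.params.ei_min,
                "pos_mmHg": rec.params.pos_mmHg,
                "recovery_pct": rec.params.recovery_pct,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(cohort) -> list[CorrelationResult]:
    """The nine biomarker x parameter correlations (3 biomarkers x EI_min,
    EI_max, PoS).  ``cohort`` is a DataFrame with the named columns or a list
    of PatientRecord with extracted parameters."""
    frame = _records_to_frame(cohort)
    results = []
    for bio in BIOMARKER_ROWS:
        for param in PARAMETER_COLS:
            results.append(
                pearson_r(frame[bio], frame[param], biomarker=bio, parameter=param)
            )
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation results as the documented nine-row table."""
    return pd.DataFrame(
        [
            {
                "biomarker": c.biomarker,
                "parameter": c.parameter,
                "r": c.r,
                "p": c.p_value,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "n_used": c.n_used,
                "n_excluded": c.n_excluded,
            }
            for c in results
        ]
    )


def fit_linear_with_ci(x, y) -> tuple[LinearFit, "np.ndarray"]:
    """OLS of y on x; returns the fit and a function-ready CI band.

    The second element is the (n,) array of pointwise 95% half-widths for
    the mean response evaluated at the (cleaned, sorted) x values; use
    :func:`ci_band` to evaluate the band on an arbitrary grid.
    """
    xv, yv, _ = _clean_pair(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(xv) == 0:
        raise DegenerateVariableError("degenerate_variable: x is constant")
    xm = xv.mean()
    sxx = float(((xv - xm) ** 2).sum())
    slope = float(((xv - xm) * (yv - yv.mean())).sum() / sxx)
    intercept = float(yv.mean() - slope * xm)
    resid = yv - (intercept + slope * xv)
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    fit = LinearFit(slope=slope, intercept=intercept,
                    slope_se=float(np.sqrt(s2 / sxx)), n=n)
    half = ci_band(fit, xv, xm, sxx, s2)
    return fit, half


def ci_band(fit: LinearFit, grid, x_mean: float, sxx: float, s2: float) -> np.ndarray:
    """Pointwise 95% half-width of the mean-response CI at ``grid``."""
    from scipy.stats import t as t_dist

    grid = np.asarray(grid, dtype=float)
    tcrit = float(t_dist.ppf(0.975, fit.n - 2))
    se_mean = np.sqrt(s2 * (1.0 / fit.n + (grid - x_mean) ** 2 / sxx))
    return tcrit * se_mean


@dataclass(frozen=True)
class CohortSummary:
    """Per-variable mean, sd (n-1 denominator), min, max and n."""

    table: pd.DataFrame

    def rendered(self) -> pd.Series:
        """Rows formatted as ``mean +/- sd [min-max]`` for reports."""
        t = self.table
        return pd.Series(
            {
                var: f"{row['mean']:.1f} ± {row['sd']:.1f} "
                f"[{row['min']:.1f}–{row['max']:.1f}]"
                for var, row in t.iterrows()
            }
        )


def cohort_summary(cohort, variables: tuple[str, ...] | None = None) -> CohortSummary:
    """Mean, sd, min, max and n per biomarker/parameter column present."""
    frame = _records_to_frame(cohort)
    if len(frame) == 0:
        raise ValueError("empty cohort")
    if variables is None:
        candidates = (
            "hbf_pct", "fcells_pct", "drbc_pct", "hb_g_dl", "rbc_count_1e6_ul",
            "ei_max", "ei_min", "pos_mmHg", "recovery_pct",
        )
        variables = tuple(v for v in candidates if v in frame.columns)
    rows = {}
    for var in variables:
        vals = frame[var].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        if n == 0:
            continue
        rows[var] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else float("nan"),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": n,
        }
    return CohortSummary(table=pd.DataFrame(rows).T)


def pos_threshold_rule(
    cohort,
    hbf_cut: float = 30.0,
    fcell_cut: float = 80.0,
    pos_cut_mmHg: float = 25.0,
) -> pd.DataFrame:
    """Proportion of patients with PoS below ``pos_cut_mmHg`` in the group
    above both biomarker cuts versus the rest.

    An undefined PoS on a curve that never sickles counts as below-cut (its
    sickling threshold is below any measurable pO2) and is also tallied
    separately in ``n_pos_undefined``.  Empty groups yield NaN proportions
    with ``group_empty`` flagged.
    """
    frame = _records_to_frame(cohort)
    above = (frame["hbf_pct"] > hbf_cut) & (frame["fcells_pct"] > fcell_cut)
    rows = []
    for label, mask in (("above_both_cuts", above), ("not_above", ~above)):
        sub = frame[mask]
        n = len(sub)
        undefined = sub["pos_mmHg"].isna()
        below = (sub["pos_mmHg"] < pos_cut_mmHg) | undefined
        rows.append(
            {
                "group": label,
                "n": n,
                "n_below_cut": int(below.sum()),
                "n_pos_undefined": int(undefined.sum()),
                "proportion_below_cut": float(below.mean()) if n else float("nan"),
                "flags": "" if n else "group_empty",
            }
        )
    return pd.DataFrame(rows)
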