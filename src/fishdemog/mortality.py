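"""Age-based catch-curve estimation of total mortality.

Under equilibrium assumptions (stable recruitment, constant fishing and
natural mortality over the analysed ages, constant selectivity beyond full
recruitment) the log of numbers-at-age declines linearly with age at rate
``Z``, the instantaneous total mortality (1/yr). A linear model fitted to the
descending limb of the catch curve therefore estimates ``Z`` as minus its
slope, and the annual mortality rate is ``A = (1 - exp(-Z)) * 100`` percent.

The descending limb runs from one year older than the modal age (assumed
full selectivity) up to the oldest age class preceded by no more than two
consecutive zero-frequency age classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .records import FishRecord
from .alk import age_frequency

__all__ = [
    "select_descending_limb",
    "CatchCurve",
    "CatchCurveResults",
    "fit_catch_curve",
    "z_to_annual_mortality",
    "chapman_robson_z",
    "compare_catch_curves",
    "CatchCurveComparison",
    "cohort_catch_curves",
]


def _as_series(freq) -> pd.Series:
    s = pd.Series(freq).astype(float)
    s.index = s.index.astype(int)
    return s.sort_index()


def select_descending_limb(freq) -> tuple[int, int]:
    """Inclusive (start, end) age range of the descending limb.

    start: one year older than the age of maximum catch frequency (modal-age
    ties resolve to the oldest mode — the conservative full-selectivity
    choice). end: the oldest age whose immediately preceding run of
    consecutive zero-frequency ages is at most 2; ages beyond a run of 3+
    zeros are excluded.
    """
    s = _as_series(freq)
    if s.empty:
        raise ValueError("empty age frequency")
    modal_age = int(s[s == s.max()].index.max())
    start = modal_age + 1
    tail = s.loc[start:]
    end = None
    zero_run = 0
    for age, count in tail.items():
        if count > 0:
            if zero_run <= 2:
                end = int(age)
            else:
                break
            zero_run = 0
        else:
            zero_run += 1
    if end is None:
        raise ValueError("insufficient data: no positive-count ages beyond the modal age")
    return start, end


def z_to_annual_mortality(z: float) -> float:
    """Annual mortality A (percent) from instantaneous total mortality Z (1/yr)."""
    if z < 0:
        raise ValueError(f"Z must be >= 0, got {z}")
    return (1.0 - math.exp(-z)) * 100.0


class CatchCurve:
    """Catch-curve model over an age-frequency vector.

    Parameters
    ----------
    freq : mapping or Series of counts per integer age (dense, interior
        zeros included).

    Examples
    --------
    >>> cc = CatchCurve(age_frequency(records))
    >>> res = cc.fit()          # limb selected by the standard rule
    >>> res.z, res.a_percent
    """

    def __init__(self, freq):
        self.freq = _as_series(freq)
        if (self.freq < 0).any():
            raise ValueError("age frequencies must be non-negative")

    def fit(self, limb: tuple[int, int] | None = None) -> "CatchCurveResults":
        """OLS of ln(count) on age over the limb's positive-count ages.

        Interior zero counts inside the limb are dropped from the regression
        (their log is undefined) but retained in ``plot_data``. A positive
        slope yields a result flagged ``ascending=True`` rather than an error.
        """
        if limb is None:
            limb = select_descending_limb(self.freq)
        start, end = limb
        if start < self.freq.index.min() or end > self.freq.index.max():
            raise ValueError(f"limb {limb} outside observed ages")
        window = self.freq.loc[start:end]
        pos = window[window > 0]
        if len(pos) < 3:
            raise ValueError("insufficient data: need >= 3 positive counts in limb")
        x = sm.add_constant(pos.index.to_numpy(dtype=float))
        y = np.log(pos.to_numpy())
        ols = sm.OLS(y, x).fit()
        slope = float(ols.params[1])
        z = -slope
        return CatchCurveResults(
            freq=self.freq, limb_ages=(int(start), int(end)),
            z=z, z_se=float(ols.bse[1]), intercept=float(ols.params[0]),
            r2=float(ols.rsquared) if len(pos) > 2 else float("nan"),
            n_points=len(pos),
            a_percent=z_to_annual_mortality(max(z, 0.0)),
            ascending=slope > 0, sm_results=ols,
        )


@dataclass
class CatchCurveResults:
    """Fitted descending-limb regression and derived mortality rates."""

    freq: pd.Series = field(repr=False)
    limb_ages: tuple
    z: float
    z_se: float
    intercept: float
    r2: float
    n_points: int
    a_percent: float
    ascending: bool = False
    sm_results: object = field(repr=False, default=None)

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.sm_results.conf_int(alpha=1 - level)[1]
        return (-hi, -lo)

    @property
    def plot_data(self) -> pd.DataFrame:
        """ln(count) by age including limb zeros (as NaN), for diagnostics."""
        with np.errstate(divide="ignore"):
            logn = np.log(self.freq.replace(0, np.nan))
        in_limb = (self.freq.index >= self.limb_ages[0]) & \
                  (self.freq.index <= self.limb_ages[1])
        return pd.DataFrame({"count": self.freq, "log_count": logn,
                             "in_limb": in_limb})

    def summary(self) -> str:
        lines = [
            "Catch-curve fit",
            f"  limb ages {self.limb_ages[0]}-{self.limb_ages[1]} "
            f"({self.n_points} positive age classes)",
            f"  Z = {self.z:.3f} +/- {self.z_se:.3f} /yr   r^2 = {self.r2:.3f}",
            f"  A = {self.a_percent:.1f}% per year",
        ]
        if self.ascending:
            lines.append("  warning: ascending limb (positive slope); Z not interpretable")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        d = self.plot_data
        ax.scatter(d.index, d["log_count"], c=np.where(d["in_limb"], "C3", "C7"))
        xs = np.array(self.limb_ages, dtype=float)
        ax.plot(xs, self.intercept - self.z * xs, "C3--",
                label=f"Z = {self.z:.2f}")
        ax.set_xlabel("age (yr)")
        ax.set_ylabel("ln(count)")
        ax.legend()
        return ax


def fit_catch_curve(freq, limb: tuple[int, int] | None = None) -> CatchCurveResults:
    """Functional wrapper around :class:`CatchCurve`."""
    return CatchCurve(freq).fit(limb=limb)


def chapman_robson_z(freq, limb: tuple[int, int] | None = None) -> float:
    """Chapman-Robson survival estimator of Z over the same limb (cross-check).

    Uses the recoded-age mean: S = T / (n + T - 1) with T the sum of recoded
    ages, Z = -ln(S). Offered as an independent check on the regression
    estimator, not the headline method.
    """
    s = _as_series(freq)
    if limb is None:
        limb = select_descending_limb(s)
    window = s.loc[limb[0]:limb[1]]
    ages = window.index.to_numpy(dtype=float) - limb[0]
    counts = window.to_numpy()
    n = counts.sum()
    t = float((ages * counts).sum())
    surv = t / (n + t - 1.0)
    return -math.log(surv)


@dataclass
class CatchCurveComparison:
    """Pooled test of Z homogeneity across groups (age x group interaction)."""

    per_group: dict  # group -> CatchCurveResults
    f_stat: float
    p_value: float
    df: tuple
    r2: float
    n_points: int
    sm_results: object = field(repr=False, default=None)

    @property
    def z_by_group(self) -> dict:
        return {g: res.z for g, res in self.per_group.items()}

    def summary(self) -> str:
        lines = ["Catch-curve comparison (common-slope test)"]
        for g, res in self.per_group.items():
            lines.append(f"  {g}: Z = {res.z:.3f} +/- {res.z_se:.3f} "
                         f"(limb {res.limb_ages[0]}-{res.limb_ages[1]})")
        lines.append(f"  age x group interaction: F = {self.f_stat:.3f} "
                     f"(df {self.df[0]:g}, {self.df[1]:g}), p = {self.p_value:.4g}, "
                     f"pooled r^2 = {self.r2:.3f}")
        return "\n".join(lines)


def compare_catch_curves(freqs: dict) -> CatchCurveComparison:
    """Test whether total mortality differs between groups.

    Fits the pooled model ``ln(count) ~ age * group`` over each group's own
    descending limb (positive counts only) and F-tests the interaction: a
    significant age x group term means the slopes — hence the Z estimates —
    differ. With full interaction coding, per-group slopes equal the separate
    single-group fits.
    """
    if len(freqs) < 2:
        raise ValueError("need >= 2 groups to compare")
    per_group = {}
    rows = []
    for g, freq in freqs.items():
        try:
            res = fit_catch_curve(freq)
        except ValueError as exc:
            raise ValueError(f"group {g!r}: {exc}") from exc
        per_group[g] = res
        window = _as_series(freq).loc[res.limb_ages[0]:res.limb_ages[1]]
        pos = window[window > 0]
        for age, count in pos.items():
            rows.append({"group": str(g), "age": float(age),
                         "log_count": math.log(count)})
    df = pd.DataFrame(rows)
    full = smf.ols("log_count ~ age * C(group)", data=df).fit()
    reduced = smf.ols("log_count ~ age + C(group)", data=df).fit()
    ftest = full.compare_f_test(reduced)
    # a perfect log-linear fit leaves ~0/0; clamp to the null
    from scipy import stats as _st
    f_stat = max(float(ftest[0]), 0.0)
    p_value = float(_st.f.sf(f_stat, ftest[2], full.df_resid))
    return CatchCurveComparison(
        per_group=per_group, f_stat=f_stat, p_value=p_value,
        df=(float(ftest[2]), float(full.df_resid)),
        r2=float(full.rsquared), n_points=len(df), sm_results=full,
    )


def cohort_catch_curves(records: Iterable[FishRecord],
                        min_age_classes: int = 4,
                        cohorts: Iterable[int] | None = None):
    """Per-birth-cohort catch curves from multi-year sampling.

    A fish sampled in calendar year ``y`` at age ``a`` belongs to cohort
    ``y - a``; pooling each cohort's counts across sampling years gives a
    longitudinal catch curve per cohort. Cohorts with fewer than
    ``min_age_classes`` positive age classes, or where limb selection fails,
    are skipped and reported.

    Returns ``(fits, skipped)``: dict cohort -> CatchCurveResults and dict
    cohort -> reason.
    """
    by_cohort: dict[int, list[int]] = {}
    for rec in records:
        if rec.age_yr is None:
            raise ValueError("all records must be aged for cohort analysis")
        cohort = rec.capture_year - rec.age_yr
        by_cohort.setdefault(cohort, []).append(rec.age_yr)
    fits: dict[int, CatchCurveResults] = {}
    skipped: dict[int, str] = {}
    for cohort in sorted(by_cohort):
        if cohorts is not None and cohort not in cohorts:
            continue
        ages = np.asarray(by_cohort[cohort])
        if len(np.unique(ages)) < min_age_classes:
            skipped[cohort] = (f"only {len(np.unique(ages))} positive age classes "
                               f"(need >= {min_age_classes})")
            continue
        idx = np.arange(ages.min(), ages.max() + 1)
        freq = pd.Series(0, index=idx)
        vals, counts = np.unique(ages, return_counts=True)
        freq.loc[vals] = counts
        try:
            fits[cohort] = fit_catch_curve(freq)
        except ValueError as exc:
            skipped[cohort] = str(exc)
    return fits, skipped
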