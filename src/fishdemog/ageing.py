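"""Ageing-validation statistics: increment periodicity, seasonal edge and
marginal-increment cycles, otolith-fish allometry, and reader precision.

Validating an ageing protocol requires showing that (1) otoliths grow
throughout life (allometry of otolith metrics on fish age/length), (2) visible
increments form on a determinable schedule (chemical-marking periodicity,
marginal-increment and edge-type seasonality), and (3) repeated readings are
precise (index of average percent error, percent agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .records import FishRecord, ReadingPair, records_to_frame
from .simulate import OTCRecord

__all__ = [
    "compute_periodicity",
    "summarize_periodicity",
    "PeriodicitySummary",
    "iape",
    "percent_agreement",
    "confidence_code_counts",
    "monthly_marginal_increment",
    "monthly_edge_percent",
    "fit_allometry",
    "AllometryResults",
]


def compute_periodicity(rec: OTCRecord) -> float:
    """Days per increment cycle from one chemically marked otolith.

    The mark-to-edge distance ``x`` spans ``x / y`` increment cycles, where
    ``y`` is the width of the last complete increment; those cycles were laid
    down over the known growth period ``G`` days, so the formation period is
    ``G * y / x`` days per annulus. A value near 365 d validates annual
    deposition.
    """
    if rec.y_mm == 0:
        raise ZeroDivisionError("last-complete-increment width y_mm is zero")
    if rec.x_mm <= 0 or rec.y_mm <= 0 or rec.g_days <= 0:
        raise ValueError("x_mm, y_mm and g_days must be positive")
    return rec.g_days * rec.y_mm / rec.x_mm


@dataclass
class PeriodicitySummary:
    """Mean and spread of per-fish increment-formation periods (days)."""

    per_fish_days: list
    mean_days: float
    sd_days: float  # sample sd (ddof=1)
    sd_population_days: float  # population sd (ddof=0)
    n: int

    def __str__(self) -> str:
        return f"periodicity {self.mean_days:.0f} +/- {self.sd_days:.0f} d (n={self.n})"


def summarize_periodicity(values: Sequence[float]) -> PeriodicitySummary:
    """Summarise per-fish periodicities; both sd conventions are reported."""
    values = [float(v) for v in values]
    if not values:
        raise ValueError("no periodicity values supplied")
    if any(v <= 0 for v in values):
        raise ValueError("periodicities must be positive")
    arr = np.asarray(values)
    return PeriodicitySummary(
        per_fish_days=values,
        mean_days=float(arr.mean()),
        sd_days=float(arr.std(ddof=1)) if len(values) > 1 else 0.0,
        sd_population_days=float(arr.std(ddof=0)),
        n=len(values),
    )


def iape(pairs: Iterable[ReadingPair]) -> float:
    """Index of average percent error (Beamish-Fournier) across fish, in percent.

    For fish *j* with reads :math:`x_{ij}` and mean read :math:`\\bar x_j`,

    .. math:: IAPE = \\frac{100}{N} \\sum_j \\frac{1}{R_j}
              \\sum_i \\frac{|x_{ij} - \\bar x_j|}{\\bar x_j}

    Fish whose reads average zero carry an undefined relative error and are
    excluded. Zero iff every retained fish's reads agree exactly.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no reading pairs supplied")
    per_fish = []
    for p in pairs:
        reads = np.asarray(p.reads, dtype=float)
        mean = reads.mean()
        if mean == 0:
            continue  # relative error undefined at mean age 0
        per_fish.append(np.abs(reads - mean).mean() / mean)
    if not per_fish:
        raise ValueError("all fish had mean read 0; IAPE undefined")
    return 100.0 * float(np.mean(per_fish))


def percent_agreement(pairs: Iterable[ReadingPair], tolerance_yr: int = 0) -> float:
    """Share of fish (percent) whose reads all fall within ``tolerance_yr``."""
    if tolerance_yr < 0:
        raise ValueError("tolerance_yr must be >= 0")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no reading pairs supplied")
    agree = sum(1 for p in pairs if max(p.reads) - min(p.reads) <= tolerance_yr)
    return 100.0 * agree / len(pairs)


def confidence_code_counts(pairs: Iterable[ReadingPair]) -> pd.Series:
    """Tabulate reader confidence codes (good to poor); no model is fitted."""
    from .records import CONFIDENCE_CODES
    codes = [p.confidence_code for p in pairs if p.confidence_code is not None]
    return pd.Series(codes, dtype=object).value_counts().reindex(
        CONFIDENCE_CODES, fill_value=0)


def monthly_marginal_increment(records: Iterable[FishRecord],
                               age_classes: set | None = None) -> pd.DataFrame:
    """Monthly mean/sd of otolith marginal increment for selected age classes.

    Returns a 12-row table indexed by month with columns ``mean``, ``sd`` and
    ``n`` (months without data hold NaN). The month of minimum mean — where
    most otoliths have just completed an annulus — is stored in
    ``table.attrs["min_month"]``.
    """
    rows = []
    for rec in records:
        if rec.marginal_increment_mm is None or rec.age_yr is None:
            continue
        if age_classes is not None and rec.age_yr not in age_classes:
            continue
        rows.append((rec.capture_month, rec.marginal_increment_mm))
    if not rows:
        raise ValueError("no records with marginal increment in the requested age classes")
    df = pd.DataFrame(rows, columns=["month", "mi"])
    g = df.groupby("month")["mi"]
    table = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n": g.size()})
    table = table.reindex(range(1, 13))
    table.index.name = "month"
    table.attrs["min_month"] = int(table["mean"].idxmin())
    return table


def monthly_edge_percent(records: Iterable[FishRecord],
                         ages=range(3, 13)) -> pd.DataFrame:
    """Monthly percent of otoliths with a translucent margin.

    Indeterminate edges are excluded before computing; only the requested age
    range is retained. Columns: ``percent_translucent``, ``n_translucent``,
    ``n_opaque``, ``n``. The month of maximum percent is stored in
    ``table.attrs["max_month"]``.
    """
    ages = set(ages)
    rows = []
    for rec in records:
        if rec.edge_type is None or rec.edge_type == "indeterminate":
            continue
        if rec.age_yr is None or rec.age_yr not in ages:
            continue
        rows.append((rec.capture_month, rec.edge_type == "translucent"))
    df = pd.DataFrame(rows, columns=["month", "translucent"])
    if df.empty:
        table = pd.DataFrame(index=pd.RangeIndex(1, 13, name="month"),
                             columns=["percent_translucent", "n_translucent",
                                      "n_opaque", "n"], dtype=float)
        return table
    g = df.groupby("month")["translucent"]
    table = pd.DataFrame({
        "n_translucent": g.sum().astype(int),
        "n": g.size().astype(int),
    })
    table["n_opaque"] = table["n"] - table["n_translucent"]
    table["percent_translucent"] = 100.0 * table["n_translucent"] / table["n"]
    table = table.reindex(range(1, 13))[
        ["percent_translucent", "n_translucent", "n_opaque", "n"]]
    table.index.name = "month"
    table.attrs["max_month"] = int(table["percent_translucent"].idxmax())
    return table


# Candidate mean structures for otolith allometry, simplest first so that AIC
# ties resolve toward fewer parameters. `cov` is age (otolith weight) or fish
# length (otolith length); `female`/`spotted` are 0/1 against the male/plain
# reference levels.
_CANDIDATES = [
    "{resp} ~ {cov}",
    "{resp} ~ {cov} + spotted",
    "{resp} ~ {cov} + female",
    "{resp} ~ {cov} + spotted + female",
    "{resp} ~ {cov} + spotted + {cov}:spotted",
    "{resp} ~ {cov} + spotted + female + {cov}:spotted",
]


def _gaussian_aic(result) -> float:
    """n*ln(RSS/n) + 2p with RSS floored to stay finite on noiseless data."""
    n = result.nobs
    rss = max(float(result.ssr), n * 1e-20)
    p = result.df_model + 2  # coefficients incl. intercept, plus sigma
    return n * math.log(rss / n) + 2 * p


def _select_parsimonious(fitted, delta: float = 2.0):
    """Smallest model within ``delta`` AIC units of the minimum.

    Models closer than ~2 AIC units are effectively equivalent, so the
    selection prefers parsimony among them rather than chasing noise-level
    AIC differences.
    """
    min_aic = min(aic for _, aic, _ in fitted)
    eligible = [f for f in fitted if f[1] <= min_aic + delta]
    return min(eligible, key=lambda f: f[2].df_model)


@dataclass
class AllometryResults:
    """Selected linear model of an otolith metric on a fish metric."""

    response: str
    covariate: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    aic: float
    n: int
    sm_results: object = field(repr=False, default=None)
    candidate_aics: dict = field(repr=False, default_factory=dict)

    def summary(self):
        return self.sm_results.summary()


def fit_allometry(records: Iterable[FishRecord], response: str = "oto_weight",
                  include_factors: bool = True) -> AllometryResults:
    """Fit and select (by AIC) a linear otolith-fish allometry model.

    ``response="oto_weight"`` regresses otolith weight (mg) on fish age with
    morph/sex candidate terms; ``response="oto_length"`` regresses otolith
    length (mm) on fish total length. Reference levels are the plain morph
    and males. A strong positive relationship indicates the otolith accretes
    material throughout life and is therefore usable for ageing.
    """
    if response not in ("oto_weight", "oto_length"):
        raise ValueError(f"unknown response {response!r}")
    df = records_to_frame(records)
    resp_col = "oto_weight_mg" if response == "oto_weight" else "oto_length_mm"
    cov = "age_yr" if response == "oto_weight" else "tl_cm"
    df = df.dropna(subset=[resp_col, cov, "sex", "morph"])
    df = df[df["sex"].isin(["female", "male"]) & df["morph"].isin(["plain", "spotted"])]
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    work = pd.DataFrame({
        "resp": df[resp_col].astype(float),
        "cov": df[cov].astype(float),
        "female": (df["sex"] == "female").astype(float),
        "spotted": (df["morph"] == "spotted").astype(float),
    })
    if include_factors and (work["spotted"].nunique() < 2 or work["female"].nunique() < 2):
        raise ValueError("factor terms requested but sex or morph has a single level")
    candidates = _CANDIDATES if include_factors else _CANDIDATES[:1]
    fitted = []
    aics = {}
    for template in candidates:
        formula = template.format(resp="resp", cov="cov")
        res = smf.ols(formula, data=work).fit()
        aic = _gaussian_aic(res)
        aics[formula] = aic
        fitted.append((formula, aic, res))
    formula, aic, res = _select_parsimonious(fitted)
    pretty = formula.replace("resp", response).replace("cov", cov)
    return AllometryResults(
        response=response, covariate=cov, formula=pretty,
        params=res.params.rename(lambda s: s.replace("cov", cov)),
        bse=res.bse.rename(lambda s: s.replace("cov", cov)),
        pvalues=res.pvalues.rename(lambda s: s.replace("cov", cov)),
        r2=float(res.rsquared), aic=float(aic), n=int(res.nobs),
        sm_results=res, candidate_aics=aics,
    )
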