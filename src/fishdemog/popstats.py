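"""Population summaries: length-weight allometry, longevity and mean maximum
size (oldest-decile means), and two-group comparison tests."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .records import FishRecord, records_to_frame

__all__ = [
    "fit_length_weight",
    "LengthWeightResults",
    "oldest_decile_summary",
    "OldestDecile",
    "compare_groups",
    "GroupComparison",
]

# Candidate mean structures for ln(TW) ~ ln(TL), simplest first; female and
# spotted are 0/1 dummies against the male/plain reference levels.
_LW_CANDIDATES = [
    "log_tw ~ log_tl",
    "log_tw ~ log_tl + spotted",
    "log_tw ~ log_tl + female",
    "log_tw ~ log_tl + spotted + female",
    "log_tw ~ log_tl + female + log_tl:female",
    "log_tw ~ log_tl + spotted + female + log_tl:female",
]


def _gaussian_aic(result) -> float:
    n = result.nobs
    rss = max(float(result.ssr), n * 1e-20)
    return n * math.log(rss / n) + 2 * (result.df_model + 2)


@dataclass
class LengthWeightResults:
    """Selected log-log length-weight model TW = a * TL^b (natural logs)."""

    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    aic: float
    n: int
    sm_results: object = field(repr=False, default=None)
    candidate_aics: dict = field(repr=False, default_factory=dict)

    @property
    def log_a(self) -> float:
        return float(self.params["Intercept"])

    @property
    def b(self) -> float:
        """Allometric exponent; 3 is isometric growth."""
        return float(self.params["log_tl"])

    def predict_weight(self, tl_cm, female: bool = False, spotted: bool = False):
        """Back-transformed weight (g) at length for the reference or a group."""
        log_tl = np.log(np.asarray(tl_cm, dtype=float))
        eta = self.log_a + self.b * log_tl
        eta += self.params.get("female", 0.0) * female
        eta += self.params.get("spotted", 0.0) * spotted
        eta += self.params.get("log_tl:female", 0.0) * female * log_tl
        return np.exp(eta)

    def summary(self):
        return self.sm_results.summary()


def fit_length_weight(records: Iterable[FishRecord],
                      include_factors: bool = True) -> LengthWeightResults:
    """Fit ln(TW) on ln(TL) with sex/morph candidate terms, selected by AIC.

    Reference levels are the plain morph and males; the ln(TL) x sex
    interaction allows the allometric exponent to differ between sexes.
    Raises on non-positive lengths or weights, listing the offending fish.
    """
    records = [r for r in records if r.tw_g is not None]
    bad = [r.fish_id for r in records if r.tl_cm <= 0 or r.tw_g <= 0]
    if bad:
        raise ValueError(f"non-positive TL or TW for fish: {bad[:10]}")
    df = records_to_frame(records)
    if len(df) < 10:
        raise ValueError(f"need >= 10 records with weight, got {len(df)}")
    work = pd.DataFrame({
        "log_tw": np.log(df["tw_g"].to_numpy(dtype=float)),
        "log_tl": np.log(df["tl_cm"].to_numpy(dtype=float)),
        "female": (df["sex"] == "female").astype(float),
        "spotted": (df["morph"] == "spotted").astype(float),
    })
    use_factors = include_factors and work["female"].nunique() > 1 \
        and work["spotted"].nunique() > 1
    candidates = _LW_CANDIDATES if use_factors else _LW_CANDIDATES[:1]
    from .ageing import _select_parsimonious
    fitted = []
    aics = {}
    for formula in candidates:
        res = smf.ols(formula, data=work).fit()
        aic = _gaussian_aic(res)
        aics[formula] = aic
        fitted.append((formula, aic, res))
    formula, aic, res = _select_parsimonious(fitted)
    return LengthWeightResults(
        formula=formula, params=res.params, bse=res.bse, pvalues=res.pvalues,
        r2=float(res.rsquared), aic=float(aic), n=int(res.nobs),
        sm_results=res, candidate_aics=aics,
    )


@dataclass
class OldestDecile:
    """Longevity and mean maximum size from the oldest 10% of the sample."""

    longevity_yr: float
    mean_max_size_cm: float
    subset_ids: list
    n_total: int

    @property
    def n_subset(self) -> int:
        return len(self.subset_ids)

    def __str__(self) -> str:
        return (f"oldest {self.n_subset}/{self.n_total}: mean age "
                f"{self.longevity_yr:.2f} yr, mean TL {self.mean_max_size_cm:.2f} cm")


def oldest_decile_summary(records: Iterable[FishRecord]) -> OldestDecile:
    """Mean age (longevity) and mean TL of the oldest 10% of aged fish.

    The subset holds the ceil(n/10) oldest fish, ranked by age with ties
    broken by length (longer first) and then fish_id for determinism.
    """
    recs = [r for r in records if r.age_yr is not None]
    n = len(recs)
    if n < 10:
        raise ValueError(f"need >= 10 aged records, got {n}")
    k = math.ceil(n / 10)
    ranked = sorted(recs, key=lambda r: (-r.age_yr, -r.tl_cm, str(r.fish_id)))
    subset = ranked[:k]
    return OldestDecile(
        longevity_yr=float(np.mean([r.age_yr for r in subset])),
        mean_max_size_cm=float(np.mean([r.tl_cm for r in subset])),
        subset_ids=[r.fish_id for r in subset],
        n_total=n,
    )


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    df: float | None
    test: str

    def __str__(self) -> str:
        df = f", df = {self.df:.1f}" if self.df is not None else ""
        return f"{self.test}: stat = {self.statistic:.3f}{df}, p = {self.p_value:.4g}"


def compare_groups(a, b, test: str = "welch_t") -> GroupComparison:
    """Two-sided two-group comparison.

    ``welch_t`` is the unequal-variance t-test (fractional Welch degrees of
    freedom); ``wilcoxon`` is the rank-sum (Mann-Whitney) test used for
    quantities like longevity where normality is doubtful.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               df=float(res.df), test="welch_t")
    if test == "wilcoxon":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            raise ValueError(
                "degenerate case: both groups constant and identical; "
                "rank-sum test is undefined")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison(statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               df=None, test="wilcoxon_rank_sum")
    raise ValueError(f"unknown test {test!r}")
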