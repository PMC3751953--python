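"""Von Bertalanffy growth modelling with bootstrap uncertainty.

The von Bertalanffy growth function (VBGF)

.. math:: L_t = L_\\infty \\left(1 - e^{-K (t - t_0)}\\right)

describes mean length at age with asymptotic length :math:`L_\\infty` (cm),
rate :math:`K` (1/yr) at which that asymptote is approached, and
:math:`t_0` (yr), the theoretical age at zero length. Because parameter
estimates are sensitive to the sampled age range (small fish are rarely
captured by the gear), the default fit constrains the curve through the
origin (:math:`t_0 = 0`); the unconstrained three-parameter fit and the
Francis reparametrisation in terms of mean lengths at chosen reference ages
are also available.

Parameter uncertainty comes from a nonparametric bootstrap (resampling fish
with replacement and refitting); group comparisons use bivariate confidence
ellipses around the :math:`(L_\\infty, K)` clouds — non-overlapping ellipses
indicate different growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VBGFParams",
    "vbgf_predict",
    "VonBertalanffyModel",
    "VBGFResults",
    "FrancisResults",
    "fit_vbgf",
    "bootstrap_vbgf",
    "fit_rvbgf",
    "EllipseRegion",
    "confidence_ellipse",
    "ellipses_overlap",
]


@dataclass(frozen=True)
class VBGFParams:
    """VBGF parameter triple (l_inf cm, k 1/yr, t0 yr)."""

    l_inf: float
    k: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.l_inf <= 0 or self.k <= 0:
            raise ValueError("l_inf and k must be positive")

    def predict(self, t):
        return vbgf_predict(self, t)


def vbgf_predict(params: VBGFParams, t):
    """Mean length at age ``t``; monotone increasing, asymptoting at l_inf."""
    t = np.asarray(t, dtype=float)
    out = params.l_inf * (1.0 - np.exp(-params.k * (t - params.t0)))
    return float(out) if out.ndim == 0 else out


class ConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge; carries the best point found."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


def _fit_arrays(age: np.ndarray, length: np.ndarray, constrained: bool,
                x0: np.ndarray | None = None):
    """Least-squares VBGF fit on raw arrays.

    Multi-start over a small k grid with l_inf initialised just above the
    largest observed fish; returns (params_vector, rss). ``x0`` short-circuits
    the grid (used for warm-started bootstrap refits).
    """
    lmax = float(length.max())

    if constrained:
        def resid(p):
            return length - p[0] * (1.0 - np.exp(-p[1] * age))
        bounds = ([1e-6, 1e-6], [np.inf, np.inf])
        starts = [np.array([lmax * 1.05, k0]) for k0 in (0.1, 0.3, 0.6)]
    else:
        def resid(p):
            return length - p[0] * (1.0 - np.exp(-p[1] * (age - p[2])))
        bounds = ([1e-6, 1e-6, -10.0], [np.inf, np.inf, 10.0])
        starts = [np.array([lmax * 1.05, k0, t00])
                  for k0 in (0.1, 0.3, 0.6) for t00 in (-0.5, 0.0)]
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)] + starts

    best = None
    for start in starts:
        try:
            sol = optimize.least_squares(resid, start, bounds=bounds, method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = 2.0 * sol.cost
        if best is None or rss < best[1]:
            best = (sol.x, rss, sol.status > 0)
        if x0 is not None and best is not None and best[2]:
            break  # warm start succeeded; skip the grid
    if best is None or not best[2]:
        raise ConvergenceError(
            "VBGF fit did not converge from any start",
            best_params=None if best is None else best[0])
    return best[0], best[1]


@dataclass
class EllipseRegion:
    """Elliptical confidence region for (l_inf, k).

    Defined by ``(p - center)' cov^-1 (p - center) <= chi2_2(level)``, the
    bivariate-Gaussian approximation of a bootstrap cloud.
    """

    center: np.ndarray
    cov: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(self.cov, self.cov.T, rtol=1e-8, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.cov)
        if np.any(eigvals < -1e-12 * max(1.0, eigvals.max())):
            raise ValueError("covariance must be positive semi-definite")
        if eigvals.min() <= 1e-15 * max(1.0, eigvals.max()):
            raise ValueError("degenerate covariance (rank < 2)")

    @property
    def radius2(self) -> float:
        return float(stats.chi2.ppf(self.level, df=2))

    @property
    def semi_axes(self) -> np.ndarray:
        """Lengths of the two semi-axes."""
        return np.sqrt(np.linalg.eigvalsh(self.cov) * self.radius2)

    def mahalanobis2(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        sol = np.linalg.solve(self.cov, d.T)
        return np.einsum("ij,ji->i", d, sol)

    def contains(self, points) -> np.ndarray:
        """Boolean membership for one point or an (n, 2) array of points."""
        inside = self.mahalanobis2(points) <= self.radius2
        return bool(inside[0]) if np.ndim(points) == 1 else inside

    def boundary(self, n: int = 360) -> np.ndarray:
        """(n, 2) points on the ellipse boundary."""
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        eigval, eigvec = np.linalg.eigh(self.cov)
        transform = eigvec @ np.diag(np.sqrt(eigval * self.radius2))
        return (transform @ circle).T + self.center


def confidence_ellipse(cloud, level: float = 0.95) -> EllipseRegion:
    """Gaussian-approximation confidence ellipse of an (n, 2) parameter cloud."""
    cloud = np.asarray(cloud, dtype=float)
    if cloud.ndim != 2 or cloud.shape[1] != 2:
        raise ValueError("cloud must be an (n, 2) array of (l_inf, k) pairs")
    if len(cloud) < 10:
        raise ValueError(f"need >= 10 replicates to build an ellipse, got {len(cloud)}")
    return EllipseRegion(center=cloud.mean(axis=0),
                         cov=np.cov(cloud, rowvar=False), level=level)


def ellipses_overlap(a: EllipseRegion, b: EllipseRegion, n_boundary: int = 1440) -> bool:
    """True iff the two elliptical disks intersect.

    Checked numerically: mutual centre containment plus membership of each
    ellipse's boundary (sampled at ``n_boundary`` points) in the other. The
    discretisation resolves overlaps down to ~2*pi/n_boundary of the boundary
    arc, ample for bootstrap-cloud comparisons.
    """
    if a.contains(b.center) or b.contains(a.center):
        return True
    if bool(np.any(a.contains(b.boundary(n_boundary)))):
        return True
    return bool(np.any(b.contains(a.boundary(n_boundary))))


class VonBertalanffyModel:
    """Nonlinear least-squares VBGF model of length at age.

    Parameters
    ----------
    age, length : array-like
        Per-fish integer (or fractional) ages in years and total lengths
        in cm.
    mode : {"constrained", "unconstrained"}
        ``constrained`` fixes t0 = 0 (curve through the origin).

    Examples
    --------
    >>> model = VonBertalanffyModel(ages, lengths, mode="constrained")
    >>> res = model.fit(n_boot=1000, seed=1)
    >>> res.params.l_inf, res.conf_int().loc["l_inf"]
    """

    def __init__(self, age, length, mode: str = "constrained"):
        if mode not in ("constrained", "unconstrained"):
            raise ValueError(f"unknown mode {mode!r}")
        age = np.asarray(age, dtype=float)
        length = np.asarray(length, dtype=float)
        if age.shape != length.shape or age.ndim != 1:
            raise ValueError("age and length must be 1-d arrays of equal length")
        if np.any(age < 0):
            raise ValueError("ages must be >= 0")
        if np.any(length <= 0):
            raise ValueError("lengths must be positive")
        n_distinct = len(np.unique(age))
        if n_distinct < 3:
            raise ValueError(
                f"VBGF is not identifiable from {n_distinct} distinct age class(es); need >= 3")
        self.age = age
        self.length = length
        self.mode = mode

    @classmethod
    def from_records(cls, records, mode: str = "constrained",
                     sex: str | None = None, morph: str | None = None):
        """Build from aged fish records, optionally restricted to a sex/morph."""
        age, length = [], []
        for rec in records:
            if rec.age_yr is None:
                continue
            if sex is not None and rec.sex != sex:
                continue
            if morph is not None and rec.morph != morph:
                continue
            age.append(rec.age_yr)
            length.append(rec.tl_cm)
        return cls(np.array(age, dtype=float), np.array(length, dtype=float), mode=mode)

    def fit(self, n_boot: int = 0, seed: int | None = None,
            level: float = 0.95, ci_method: str = "percentile") -> "VBGFResults":
        """Fit the model; with ``n_boot > 0`` also bootstrap (l_inf, k) CIs.

        Bootstrap replicates resample fish with replacement and refit
        warm-started at the full-data estimates; replicates that fail to
        converge are dropped and counted (an error is raised if more than
        half fail).
        """
        constrained = self.mode == "constrained"
        x, rss = _fit_arrays(self.age, self.length, constrained)
        params = VBGFParams(l_inf=float(x[0]), k=float(x[1]),
                            t0=0.0 if constrained else float(x[2]))
        n = len(self.age)
        p = len(x) + 1  # plus residual sigma
        aic = n * math.log(max(rss, n * 1e-20) / n) + 2 * p

        cloud = None
        n_failed = 0
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                try:
                    xb, _ = _fit_arrays(self.age[idx], self.length[idx],
                                        constrained, x0=x)
                except (ConvergenceError, ValueError):
                    n_failed += 1
                    continue
                rows.append(xb)
            if n_failed > n_boot // 2:
                raise ConvergenceError(
                    f"{n_failed}/{n_boot} bootstrap replicates failed to converge")
            cloud = np.asarray(rows)
        return VBGFResults(model=self, params=params, rss=float(rss), n=n,
                           aic=float(aic), mode=self.mode, bootstrap_cloud=cloud,
                           n_failed=n_failed, level=level, ci_method=ci_method)


@dataclass
class VBGFResults:
    """Fitted VBGF with optional bootstrap parameter cloud."""

    model: VonBertalanffyModel = field(repr=False)
    params: VBGFParams
    rss: float
    n: int
    aic: float
    mode: str
    bootstrap_cloud: np.ndarray | None = field(repr=False, default=None)
    n_failed: int = 0
    level: float = 0.95
    ci_method: str = "percentile"

    def predict(self, t):
        return vbgf_predict(self.params, t)

    @property
    def sigma(self) -> float:
        """Residual standard deviation (cm)."""
        return math.sqrt(self.rss / self.n)

    def _param_table(self) -> pd.DataFrame:
        names = ["l_inf", "k"] + ([] if self.mode == "constrained" else ["t0"])
        est = [getattr(self.params, nm) for nm in names]
        return pd.DataFrame({"estimate": est}, index=names)

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        """Bootstrap confidence intervals per parameter (default percentile)."""
        if self.bootstrap_cloud is None or not len(self.bootstrap_cloud):
            raise ValueError("no bootstrap cloud; refit with n_boot > 0")
        level = self.level if level is None else level
        alpha = (1.0 - level) / 2.0
        table = self._param_table()
        cloud = self.bootstrap_cloud
        lo = np.quantile(cloud, alpha, axis=0)
        hi = np.quantile(cloud, 1.0 - alpha, axis=0)
        if self.ci_method == "basic":
            est = table["estimate"].to_numpy()[: cloud.shape[1]]
            lo, hi = 2 * est - hi, 2 * est - lo
        table["lower"] = lo[: len(table)]
        table["upper"] = hi[: len(table)]
        return table

    def ellipse(self, level: float = 0.95) -> EllipseRegion:
        """Bivariate confidence ellipse around (l_inf, k)."""
        if self.bootstrap_cloud is None:
            raise ValueError("no bootstrap cloud; refit with n_boot > 0")
        return confidence_ellipse(self.bootstrap_cloud[:, :2], level=level)

    def summary(self) -> str:
        lines = [
            "Von Bertalanffy growth fit",
            f"  mode: {self.mode}   n = {self.n}   AIC = {self.aic:.1f}",
            f"  residual sd = {self.sigma:.2f} cm",
        ]
        try:
            ci = self.conf_int()
            for name, row in ci.iterrows():
                lines.append(f"  {name:>6s} = {row['estimate']:8.3f}  "
                             f"[{row['lower']:.3f}, {row['upper']:.3f}] "
                             f"({int(self.level * 100)}% bootstrap {self.ci_method})")
            lines.append(f"  bootstrap replicates: {len(self.bootstrap_cloud)} "
                         f"({self.n_failed} failed)")
        except ValueError:
            for name, row in self._param_table().iterrows():
                lines.append(f"  {name:>6s} = {row['estimate']:8.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Length-at-age scatter with the fitted curve."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.age, self.model.length, s=8, alpha=0.4, label="data")
        grid = np.linspace(0, self.model.age.max() * 1.05, 200)
        ax.plot(grid, self.predict(grid), color="C3", label="VBGF fit")
        ax.set_xlabel("age (yr)")
        ax.set_ylabel("total length (cm)")
        ax.legend()
        return ax


def fit_vbgf(records, mode: str = "constrained", **filters) -> VBGFResults:
    """Convenience wrapper: fit a VBGF to aged fish records (no bootstrap)."""
    return VonBertalanffyModel.from_records(records, mode=mode, **filters).fit()


def bootstrap_vbgf(records, mode: str = "constrained", iterations: int = 1000,
                   seed: int | None = None, **filters) -> VBGFResults:
    """Fit a VBGF with ``iterations`` bootstrap replicates and percentile CIs."""
    model = VonBertalanffyModel.from_records(records, mode=mode, **filters)
    return model.fit(n_boot=iterations, seed=seed)


@dataclass
class FrancisResults:
    """Francis-reparametrised VBGF: mean lengths at three reference ages.

    The fitted curve is identical to the ordinary (unconstrained) VBGF; the
    parameters are the mean lengths ``l1 <= l2 <= l3`` at ``tau1``,
    ``(tau1+tau3)/2`` and ``tau3``, which are better determined by the data
    and directly comparable across populations.
    """

    ref_ages: tuple
    l_ref: np.ndarray  # (l1, l2, l3)
    se: np.ndarray
    rss: float
    n: int
    warnings: list = field(default_factory=list)

    @property
    def l1(self): return float(self.l_ref[0])

    @property
    def l2(self): return float(self.l_ref[1])

    @property
    def l3(self): return float(self.l_ref[2])

    def to_vbgf(self) -> VBGFParams:
        """Back-transform to (l_inf, k, t0)."""
        tau1, tau3 = self.ref_ages
        l1, l2, l3 = self.l_ref
        r = (l3 - l2) / (l2 - l1)
        k = -2.0 * math.log(r) / (tau3 - tau1)
        l_inf = l1 + (l3 - l1) / (1.0 - r * r)
        t0 = tau1 + math.log(1.0 - l1 / l_inf) / k
        return VBGFParams(l_inf=float(l_inf), k=float(k), t0=float(t0))

    def predict(self, t):
        return vbgf_predict(self.to_vbgf(), t)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        tau1, tau3 = self.ref_ages
        idx = [f"L(tau1={tau1:g})", f"L(mid={0.5 * (tau1 + tau3):g})", f"L(tau3={tau3:g})"]
        return pd.DataFrame({
            "estimate": self.l_ref,
            "lower": self.l_ref - z * self.se,
            "upper": self.l_ref + z * self.se,
        }, index=idx)

    def summary(self) -> str:
        lines = [f"Francis rVBGF fit (n = {self.n})"]
        for name, row in self.conf_int().iterrows():
            lines.append(f"  {name:>12s} = {row['estimate']:7.2f} cm "
                         f"[{row['lower']:.2f}, {row['upper']:.2f}]")
        back = self.to_vbgf()
        lines.append(f"  back-transformed: l_inf = {back.l_inf:.2f} cm, "
                     f"k = {back.k:.3f}/yr, t0 = {back.t0:.3f} yr")
        lines.extend(f"  warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def fit_rvbgf(records_or_age, length=None, ref_ages: tuple = (2.0, 10.0)) -> FrancisResults:
    """Fit the Francis reparametrised VBGF.

    Accepts either aged fish records or explicit (age, length) arrays.
    ``ref_ages = (tau1, tau3)`` are the outer reference ages; the middle age
    is their midpoint. Reference ages outside the observed age range are
    recorded as warnings on the result, not errors.
    """
    if length is None:
        age = np.array([r.age_yr for r in records_or_age if r.age_yr is not None], float)
        length = np.array([r.tl_cm for r in records_or_age if r.age_yr is not None], float)
    else:
        age = np.asarray(records_or_age, dtype=float)
        length = np.asarray(length, dtype=float)
    tau1, tau3 = ref_ages
    if not tau1 < tau3:
        raise ValueError("require tau1 < tau3")
    warnings = []
    if tau1 < age.min() or tau3 > age.max():
        warnings.append(
            f"reference ages ({tau1:g}, {tau3:g}) extend beyond observed ages "
            f"[{age.min():g}, {age.max():g}]")

    dtau = tau3 - tau1

    def curve(p, t):
        l1, l2, l3 = p
        r = (l3 - l2) / (l2 - l1)
        theta = 2.0 * (t - tau1) / dtau
        return l1 + (l3 - l1) * (1.0 - np.power(r, theta)) / (1.0 - r * r)

    def resid(p):
        return length - curve(p, age)

    # start from the empirical means near the reference ages
    fit0, _ = _fit_arrays(age, length, constrained=False)
    p0 = VBGFParams(fit0[0], fit0[1], fit0[2])
    start = np.array([vbgf_predict(p0, tau1), vbgf_predict(p0, 0.5 * (tau1 + tau3)),
                      vbgf_predict(p0, tau3)])
    sol = optimize.least_squares(resid, start, method="lm")
    if not np.all(np.isfinite(sol.x)):
        raise ConvergenceError("rVBGF fit did not converge")
    rss = 2.0 * sol.cost
    n = len(age)
    sigma2 = rss / max(n - 3, 1)
    jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
    se = np.sqrt(np.clip(np.diag(jtj_inv) * sigma2, 0.0, None))
    return FrancisResults(ref_ages=(float(tau1), float(tau3)), l_ref=sol.x,
                          se=se, rss=float(rss), n=n, warnings=warnings)
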