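"""Quantitative-assay statistics: equilibrium binding fits, plate
densitometry, logistic growth fits, the growth-efficiency statistic and the
efficiency-affinity correlation.

The two curve fits follow a statsmodels-style layout: a model object built
from data whose ``fit()`` returns a results object carrying the estimates,
bootstrap confidence intervals, diagnostics and a ``summary()`` table.

Single-site (Langmuir) binding:  R([A]) = Rmax * [A] / (Kd + [A])
Logistic growth:                 D(t)  = K / (1 + exp(-r (t - t50)))

Growth efficiency is the slope of the growth curve at the half-maximum
density divided by the time of half-maximum; for the logistic model the
slope at t50 is r*K/4 in closed form, so efficiency = (r*K/4)/t50.  An
alternative "plateau" definition (K/t50, maximum density over time of half
max) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import FitError, UbrecError, UndefinedEfficiencyError

BOOTSTRAP_REPS = 500

# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class BindingSeries:
    """Equilibrium SPR responses at ascending analyte concentrations."""

    concentrations: tuple  # uM, strictly increasing
    responses: tuple       # RU
    replicate: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        r = np.asarray(self.responses, float)
        if c.size != r.size:
            raise ValueError("concentrations and responses must have equal length")
        if (c <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if not np.isfinite(r).all():
            raise ValueError("responses must be finite")

    @property
    def conc(self) -> np.ndarray:
        return np.asarray(self.concentrations, float)

    @property
    def resp(self) -> np.ndarray:
        return np.asarray(self.responses, float)


@dataclass(frozen=True)
class GrowthSeries:
    """Background-subtracted integrated spot density over time."""

    times: tuple     # hours, strictly increasing
    densities: tuple  # arbitrary units
    spot: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        d = np.asarray(self.densities, float)
        if t.size != d.size:
            raise ValueError("times and densities must have equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(d).all():
            raise ValueError("densities must be finite")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.densities, float)


# ---------------------------------------------------------------------------
# Model functions


def single_site(conc, kd, rmax):
    conc = np.asarray(conc, float)
    return rmax * conc / (kd + conc)


def logistic(t, K, r, t50):
    from scipy.special import expit

    t = np.asarray(t, float)
    return K * expit(r * (t - t50))


# ---------------------------------------------------------------------------
# Single-site binding


class SingleSiteBinding:
    """Single-site equilibrium binding model for one concentration series.

    Parameters
    ----------
    series : BindingSeries
        Must contain at least 4 distinct concentrations.
    """

    def __init__(self, series: BindingSeries):
        if len(set(series.concentrations)) < 4:
            raise FitError("need >= 4 distinct concentrations for a binding fit")
        self.series = series

    @classmethod
    def from_dataframe(cls, df, conc_col="concentration_uM", resp_col="response_RU",
                       replicate: str = "") -> "SingleSiteBinding":
        d = df.sort_values(conc_col)
        return cls(BindingSeries(tuple(d[conc_col]), tuple(d[resp_col]), replicate))

    def _fit_once(self, conc, resp):
        cmax = conc.max()
        rmax0 = max(resp.max(), 1e-9)
        best = None
        # multi-start damped least squares; Kd starts bracket the tested range
        for kd0 in (0.1 * cmax, cmax, 10.0 * cmax):
            try:
                res = optimize.least_squares(
                    lambda p: single_site(conc, p[0], p[1]) - resp,
                    x0=[kd0, rmax0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.isfinite(best.x).all():
            return None
        return best

    def fit(self, bootstrap: int = BOOTSTRAP_REPS, seed: int = 0) -> "SingleSiteBindingResults":
        """Least-squares fit with a seeded residual bootstrap for the CI."""
        conc, resp = self.series.conc, self.series.resp
        best = self._fit_once(conc, resp)
        if best is None:
            return SingleSiteBindingResults(
                model=self, kd=np.nan, rmax=np.nan, residual_norm=np.nan,
                converged=False, kd_ci=(np.nan, np.nan), rmax_ci=(np.nan, np.nan),
                diagnostics={"reason": "optimizer failed to converge"})
        kd, rmax = best.x
        fitted = single_site(conc, kd, rmax)
        residuals = resp - fitted
        # asymptotic standard errors from the jacobian at the optimum
        dof = max(conc.size - 2, 1)
        sigma2 = float((residuals ** 2).sum() / dof)
        try:
            cov = sigma2 * np.linalg.inv(best.jac.T @ best.jac)
            kd_se, rmax_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            kd_se = rmax_se = np.nan
        rng = np.random.default_rng(seed)
        kds, rmaxs = [], []
        for _ in range(bootstrap):
            boot = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            b = self._fit_once(conc, boot)
            if b is not None:
                kds.append(b.x[0])
                rmaxs.append(b.x[1])
        kd_ci = tuple(np.percentile(kds, [2.5, 97.5])) if kds else (np.nan, np.nan)
        rmax_ci = tuple(np.percentile(rmaxs, [2.5, 97.5])) if rmaxs else (np.nan, np.nan)
        return SingleSiteBindingResults(
            model=self, kd=float(kd), rmax=float(rmax),
            residual_norm=float(np.linalg.norm(residuals)), converged=True,
            kd_ci=kd_ci, rmax_ci=rmax_ci, kd_se=kd_se, rmax_se=rmax_se,
            diagnostics={"bootstrap_reps": len(kds), "seed": seed},
        )


@dataclass
class SingleSiteBindingResults:
    """Fitted Kd/Rmax with bootstrap CIs and the binding classification."""

    model: SingleSiteBinding
    kd: float          # uM
    rmax: float        # RU
    residual_norm: float
    converged: bool
    kd_ci: tuple = (np.nan, np.nan)
    rmax_ci: tuple = (np.nan, np.nan)
    kd_se: float = np.nan
    rmax_se: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    @property
    def ka(self) -> float:
        """Association constant 1/Kd (1/uM)."""
        return 1.0 / self.kd

    @property
    def classification(self) -> str:
        """"no-binding" when the fitted plateau is indistinguishable from
        noise (Rmax < 3x residual SD, dof-corrected), when Rmax is not
        statistically resolved from zero (estimate < 2x its standard
        error), or when Kd lies far beyond the tested range (> 10x the
        maximum concentration); otherwise "binding"."""
        series = self.model.series
        if not self.converged:
            return "no-binding"
        dof = max(series.resp.size - 2, 1)
        noise_sd = self.residual_norm / np.sqrt(dof)
        if self.rmax < 3.0 * noise_sd:
            return "no-binding"
        if np.isfinite(self.rmax_se) and self.rmax_se > 0 \
                and self.rmax < 2.0 * self.rmax_se:
            return "no-binding"
        if self.kd > 10.0 * series.conc.max():
            return "no-binding"
        return "binding"

    def predict(self, conc) -> np.ndarray:
        return single_site(conc, self.kd, self.rmax)

    def scaled_responses(self, rmax_target: float = 100.0) -> np.ndarray:
        """Responses rescaled so the fitted plateau equals ``rmax_target``
        (the convention used for overlay plots)."""
        return self.model.series.resp * (rmax_target / self.rmax)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            "Single-site binding fit",
            "=" * 43,
            f"n concentrations     {s.conc.size:>10d}",
            f"conc range (uM)      {s.conc.min():>10.3g} - {s.conc.max():.3g}",
            f"Kd (uM)              {self.kd:>10.4g}  CI95 [{self.kd_ci[0]:.4g}, {self.kd_ci[1]:.4g}]",
            f"Rmax (RU)            {self.rmax:>10.4g}  CI95 [{self.rmax_ci[0]:.4g}, {self.rmax_ci[1]:.4g}]",
            f"residual norm        {self.residual_norm:>10.4g}",
            f"classification       {self.classification:>10s}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Logistic growth


class LogisticGrowth:
    """Three-parameter logistic growth model for one spot's density series."""

    def __init__(self, series: GrowthSeries):
        if series.t.size < 6:
            raise FitError("need >= 6 time points for a logistic growth fit")
        self.series = series

    @classmethod
    def from_dataframe(cls, df, time_col="time_h", density_col="density",
                       spot: str = "") -> "LogisticGrowth":
        d = df.sort_values(time_col)
        return cls(GrowthSeries(tuple(d[time_col]), tuple(d[density_col]), spot))

    def _starts(self):
        t, d = self.series.t, self.series.d
        K0 = max(d.max(), 1e-9)
        span = t.max() - t.min()
        # crude t50 guess: first crossing of half max
        half = K0 / 2.0
        above = np.nonzero(d >= half)[0]
        t50_0 = t[above[0]] if above.size else t.mean()
        r0 = 4.0 / max(span / 4.0, 1e-6)
        return [(K0, r0, t50_0), (K0, r0 / 4.0, t.mean()),
                (1.2 * K0, 2.0 * r0, t50_0)]

    def fit(self, nsg_snr: float = 3.0) -> "LogisticGrowthResults":
        """Damped least-squares fit with 3 starts.

        The spot is flagged NSG (no significant growth) when the fit fails,
        the fitted dynamic range is below ``nsg_snr`` times the residual SD,
        or the fitted parameters are non-positive/unidentifiable.
        """
        t, d = self.series.t, self.series.d
        best = None
        for K0, r0, t50_0 in self._starts():
            try:
                res = optimize.least_squares(
                    lambda p: logistic(t, *p) - d, x0=[K0, r0, t50_0],
                    bounds=([1e-12, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                    method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            return LogisticGrowthResults(self, np.nan, np.nan, np.nan, np.nan, True,
                                         {"reason": "optimizer failed"})
        K, r, t50 = best.x
        residuals = d - logistic(t, K, r, t50)
        noise_sd = float(residuals.std())
        dynamic = float(logistic(t.max(), K, r, t50) - logistic(t.min(), K, r, t50))
        # a spot is NSG when the fitted rise is indistinguishable from noise
        # or negligible relative to the signal scale (catches exactly flat
        # noiseless series, where both the rise and the noise are ~0)
        scale = max(float(np.abs(d).max()), 1e-6)
        nsg = bool(
            not np.isfinite([K, r, t50]).all()
            or K <= 0 or r <= 0 or t50 <= 0
            or dynamic < nsg_snr * max(noise_sd, 1e-12)
            or dynamic < 0.05 * scale
        )
        return LogisticGrowthResults(
            self, float(K), float(r), float(t50),
            float(np.linalg.norm(residuals)), nsg,
            {"noise_sd": noise_sd, "dynamic_range": dynamic},
        )


@dataclass
class LogisticGrowthResults:
    """Fitted logistic parameters and the NSG (no significant growth) flag."""

    model: LogisticGrowth
    K: float       # plateau density, AU
    r: float       # rate, 1/h
    t50: float     # time of half-maximum, h
    residual_norm: float
    nsg: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def efficiency(self) -> float:
        """Slope at half-max density over its time index: (r*K/4)/t50."""
        return growth_efficiency(self)

    @property
    def efficiency_plateau(self) -> float:
        """Alternative definition: maximum density over time of half max."""
        if self.nsg:
            raise UndefinedEfficiencyError("efficiency undefined for an NSG spot")
        return self.K / self.t50

    def predict(self, t) -> np.ndarray:
        return logistic(t, self.K, self.r, self.t50)

    def summary(self) -> str:
        lines = [
            "Logistic growth fit",
            "=" * 38,
            f"n time points     {self.model.series.t.size:>10d}",
            f"K (AU)            {self.K:>10.4g}",
            f"r (1/h)           {self.r:>10.4g}",
            f"t50 (h)           {self.t50:>10.4g}",
            f"residual norm     {self.residual_norm:>10.4g}",
            f"NSG               {str(self.nsg):>10s}",
        ]
        if not self.nsg:
            lines.append(f"efficiency (AU/h^2){self.efficiency:>9.4g}")
        return "\n".join(lines)


def growth_efficiency(fit: LogisticGrowthResults) -> float:
    """Growth efficiency = slope of the growth curve at the half-maximum
    density, divided by the time of half maximum.

    For the logistic model the slope at t50 is r*K/4 exactly, so the
    statistic is (r*K/4)/t50 (AU/h^2).  Undefined for NSG spots.
    """
    if fit.nsg:
        raise UndefinedEfficiencyError("efficiency undefined for an NSG spot")
    return (fit.r * fit.K / 4.0) / fit.t50


# ---------------------------------------------------------------------------
# Image densitometry


def oval_mask(shape: tuple[int, int], center: tuple[float, float],
              size: tuple[float, float] = (20.0, 20.0)) -> np.ndarray:
    """Boolean mask of an axis-aligned oval ROI.

    A pixel belongs to the ROI when its center satisfies the ellipse
    inequality ((x-cx)/a)^2 + ((y-cy)/b)^2 <= 1 with semi-axes a = w/2,
    b = h/2.  ``center`` is (row, col).
    """
    h, w = shape
    b, a = size[0] / 2.0, size[1] / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    return ((cc - center[1]) / a) ** 2 + ((rr - center[0]) / b) ** 2 <= 1.0


def integrate_rois(stack: np.ndarray, centers, roi_size: tuple[float, float] = (20.0, 20.0),
                   times=None) -> list[GrowthSeries]:
    """Integrate oval ROIs over an image stack with background subtraction.

    ``stack`` is (n_frames, H, W).  For each frame the background level is
    the median of all pixels outside every ROI; each spot's value is the sum
    of its ROI pixels minus background x ROI pixel count.  ROIs clipped by
    the image edge are an error.  Returns one :class:`GrowthSeries` per
    center (frame index as time when ``times`` is None).
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, H, W)")
    n, h, w = stack.shape
    masks = []
    for (r, c) in centers:
        if r - roi_size[0] / 2 < 0 or r + roi_size[0] / 2 > h - 1 \
                or c - roi_size[1] / 2 < 0 or c + roi_size[1] / 2 > w - 1:
            raise UbrecError(f"ROI at ({r}, {c}) is clipped by the image edge")
        masks.append(oval_mask((h, w), (r, c), roi_size))
    outside = ~np.logical_or.reduce(masks) if masks else np.ones((h, w), bool)
    if not outside.any():
        raise UbrecError("no pixels left outside the ROIs for background estimation")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    series = []
    for k, mask in enumerate(masks):
        npix = int(mask.sum())
        vals = []
        for f in range(n):
            bg = float(np.median(stack[f][outside]))
            vals.append(float(stack[f][mask].sum() - bg * npix))
        series.append(GrowthSeries(tuple(t), tuple(vals), spot=str(k)))
    return series


# ---------------------------------------------------------------------------
# Correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation out of [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


def correlate(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise UbrecError("correlation needs at least 3 points")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise UbrecError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))
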