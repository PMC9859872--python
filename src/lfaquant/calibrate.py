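"""Four-parameter logistic calibration with confidence-band detection limits.

The dose-response of the competitive assay is fitted with

    y = A2 + (A1 - A2) / (1 + (x/x0)^p)

on raw concentrations (y(0) = A1 is the p > 0 limit of the curve).  The
pointwise 95% confidence band of the fitted curve is built with the delta
method, t(n-4) quantiles and the Jacobian-based parameter covariance; a
parametric bootstrap band is available as a cross-check.  Detection limits
follow the band-intersection construction for a decreasing curve:

* critical level  y_crit = lower band at concentration zero,
* MDC (minimum detectable concentration): smallest x with  yhat(x) = y_crit,
* RDL (reliable detection limit): smallest x with  upper_band(x) = y_crit,

both located by coarse log-grid bracketing plus bisection.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (BandError, DomainError, FitError, LimitError,
                     NormalizationError)
from .simulate import fourpl_response

__all__ = [
    "CalibrationPoint", "FourPLFit", "DetectionLimits", "calibration_table",
    "normalize", "fit_4pl", "confidence_band", "bootstrap_band",
    "detection_limits", "compare_conjugates",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate signals at one concentration, raw and blank-normalized."""

    concentration: float
    signals: tuple[float, ...]
    normalized: tuple[float, ...]


def calibration_table(signals: pd.DataFrame, mode: str = "ratio") -> pd.DataFrame:
    """Collapse per-channel signals to one row per strip.

    ``signals`` is the quantification table (columns strip_id, channel,
    test_signal, control_signal, ratio, concentration_ug_per_l).  ``mode``
    selects the evaluated quantity: "ratio" (test/control, the preferred
    evaluation) or "test" (plain test-line signal).  The strip value is the
    mean over its channels.
    """
    if mode not in ("ratio", "test"):
        raise DomainError(f"unknown calibration mode {mode!r}")
    col = "ratio" if mode == "ratio" else "test_signal"
    g = signals.groupby("strip_id", sort=False).agg(
        concentration=("concentration_ug_per_l", "first"),
        signal=(col, "mean"),
        signal_sd=(col, lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n_channels=(col, "size"),
    ).reset_index()
    return g


def normalize(table: pd.DataFrame, signal_col: str = "signal") -> pd.DataFrame:
    """Divide every signal by the mean blank (zero-concentration) signal.

    Returns a copy with a ``normalized`` column; the blank rows average to
    exactly 1 by construction.

    Raises
    ------
    NormalizationError
        No zero-concentration rows, or blank mean <= 0.
    """
    if "concentration" not in table.columns:
        raise NormalizationError("table lacks a 'concentration' column")
    blank = table.loc[table["concentration"] == 0, signal_col]
    if blank.empty:
        raise NormalizationError("no zero-concentration (blank) entry")
    s0 = float(blank.mean())
    if s0 <= 0:
        raise NormalizationError(f"degenerate blank signal {s0!r}")
    out = table.copy()
    out["normalized"] = out[signal_col] / s0
    return out


def to_points(table: pd.DataFrame) -> list[CalibrationPoint]:
    pts = []
    for conc, grp in table.groupby("concentration", sort=True):
        pts.append(CalibrationPoint(float(conc),
                                    tuple(grp["signal"]),
                                    tuple(grp["normalized"])))
    return pts


# ---------------------------------------------------------------------------
# 4PL fit
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    """Fitted 4PL with parameter covariance and the data it was fitted to.

    ``covariance`` is the Jacobian-based estimate scaled by the residual
    variance; ``residual_variance`` is the reduced chi-square of the
    unweighted fit.  ``dof = n_points - 4``.
    """

    a1: float
    a2: float
    x0: float
    p: float
    covariance: np.ndarray
    residual_variance: float
    n_points: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def dof(self) -> int:
        return self.n_points - 4

    @property
    def ec50(self) -> float:
        return self.x0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.x0, self.p])

    def predict(self, x) -> np.ndarray:
        return fourpl_response(x, self.a1, self.a2, self.x0, self.p)

    def gradient(self, x) -> np.ndarray:
        """d y / d (a1, a2, x0, p), shape (len(x), 4); y(0) handled as limit."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        g = np.zeros((x.size, 4))
        pos = x > 0
        u = np.zeros_like(x)
        u[pos] = (x[pos] / self.x0) ** self.p
        denom = (1.0 + u) ** 2
        g[:, 0] = 1.0 / (1.0 + u)
        g[:, 1] = u / (1.0 + u)
        g[:, 2] = (self.a1 - self.a2) * self.p * u / (self.x0 * denom)
        g[pos, 3] = -(self.a1 - self.a2) * u[pos] * np.log(x[pos] / self.x0) \
            / denom[pos]
        return g

    def stderr(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def to_dict(self) -> dict:
        return {
            "A1": self.a1, "A2": self.a2, "x0": self.x0, "p": self.p,
            "EC50": self.ec50,
            "stderr": dict(zip(("A1", "A2", "x0", "p"), self.stderr())),
            "covariance": self.covariance.tolist(),
            "residual_variance": self.residual_variance,
            "n_points": self.n_points,
        }


def _start_values(x: np.ndarray, y: np.ndarray) -> dict:
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    a1 = float(ys[xs == xs.min()].mean())
    a2 = float(ys[xs == xs.max()].mean())
    if a1 == a2:
        a2 = a1 - max(1e-3, abs(a1) * 0.1)
    mid = (a1 + a2) / 2.0
    pos = xs > 0
    # concentration whose mean response is closest to the midpoint
    xi = xs[pos]
    yi = ys[pos]
    x0 = float(xi[np.argmin(np.abs(yi - mid))]) if xi.size else 1.0
    return {"a1": a1, "a2": a2, "x0": max(x0, 1e-6), "p": 1.0}


def fit_4pl(concentration, y, weights=None) -> FourPLFit:
    """Least-squares 4PL fit with covariance from the Jacobian.

    Parameters
    ----------
    concentration, y
        Concentrations (>= 0, at least 5 distinct values including 0) and
        responses, replicates as repeated concentrations.
    weights
        Optional per-point weights multiplying the residuals (e.g. 1/SD);
        default unweighted.

    Raises
    ------
    FitError
        Optimizer failure or missing covariance.

    Warns when the fitted slope exponent is not positive (curve orientation
    opposite to a decreasing inhibition assay).
    """
    x = np.asarray(concentration, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.shape != yv.shape or x.ndim != 1:
        raise DomainError("concentration and y must be equal-length 1-D")
    if np.any(x < 0):
        raise DomainError("negative concentrations")
    if np.unique(x).size < 5 or 0.0 not in x:
        raise DomainError("need >= 5 distinct concentrations including 0")
    model = lmfit.Model(fourpl_response, independent_vars=["x"])
    start = _start_values(x, yv)
    params = model.make_params(**start)
    params["x0"].set(min=1e-12)
    params["p"].set(min=-50, max=50)
    result = model.fit(yv, params, x=x, weights=weights)
    if not result.success:
        raise FitError(f"4PL fit did not converge: {result.message}")
    if result.covar is None:
        raise FitError("4PL fit converged without a covariance estimate")
    names = ["a1", "a2", "x0", "p"]
    vals = {n: float(result.params[n].value) for n in names}
    if vals["p"] <= 0 or vals["a1"] < vals["a2"]:
        warnings.warn("fitted curve has increasing orientation "
                      "(p <= 0 or A1 < A2): not an inhibition response",
                      stacklevel=2)
    # reorder covariance rows/cols into (a1, a2, x0, p)
    var_names = result.var_names
    idx = [var_names.index(n) for n in names]
    cov = np.asarray(result.covar)[np.ix_(idx, idx)]
    return FourPLFit(
        a1=vals["a1"], a2=vals["a2"], x0=vals["x0"], p=vals["p"],
        covariance=cov, residual_variance=float(result.redchi),
        n_points=x.size, x=x.copy(), y=yv.copy(),
    )


# ---------------------------------------------------------------------------
# confidence bands and detection limits
# ---------------------------------------------------------------------------

def _band_halfwidth(fit: FourPLFit, x: np.ndarray, level: float,
                    kind: str) -> np.ndarray:
    if not (0 <= level < 1):
        raise DomainError("confidence level must lie in [0, 1)")
    if fit.dof <= 0:
        raise BandError("no residual degrees of freedom for a band")
    cov = fit.covariance
    if not np.all(np.isfinite(cov)):
        raise BandError("covariance contains non-finite entries")
    g = fit.gradient(x)
    var_mean = np.einsum("ij,jk,ik->i", g, cov, g)
    if np.any(var_mean < -1e-12):
        raise BandError("covariance not positive semi-definite")
    var_mean = np.clip(var_mean, 0.0, None)
    if kind == "confidence":
        var = var_mean
    elif kind == "prediction":
        var = var_mean + fit.residual_variance
    else:
        raise DomainError(f"unknown band kind {kind!r}")
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    return tq * np.sqrt(var)


def confidence_band(fit: FourPLFit, x, level: float = 0.95,
                    kind: str = "confidence") -> tuple[np.ndarray, np.ndarray]:
    """Pointwise band ``yhat ± t(level, n-4) * SE(yhat)`` (delta method).

    ``kind="prediction"`` adds the residual variance to the delta-method
    variance of the mean response.  ``level=0`` collapses the band onto the
    fitted curve, as does a zero residual variance.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    yhat = fit.predict(x)
    hw = _band_halfwidth(fit, x, level, kind)
    return yhat - hw, yhat + hw


def bootstrap_band(fit: FourPLFit, x, level: float = 0.95,
                   n_boot: int = 2000, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Parametric-bootstrap band: refit on Gaussian-resampled responses.

    Draws ``n_boot`` synthetic data sets ``yhat(x_i) + N(0, s)`` with ``s``
    the fitted residual SD, refits each, and returns pointwise percentile
    bands of the refitted curves.  Serves as an independent cross-check of
    the delta-method band.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    rng = np.random.default_rng(seed)
    s = np.sqrt(fit.residual_variance)
    base = fit.predict(fit.x)
    curves = np.empty((n_boot, x.size))
    kept = 0
    for _ in range(n_boot):
        yb = base + rng.normal(0.0, s, size=base.shape)
        try:
            fb = fit_4pl(fit.x, yb)
        except (FitError, DomainError):
            continue
        curves[kept] = fb.predict(x)
        kept += 1
    if kept < n_boot // 2:
        raise BandError("parametric bootstrap: too many refits failed")
    lo = np.percentile(curves[:kept], 100 * (0.5 - level / 2), axis=0)
    hi = np.percentile(curves[:kept], 100 * (0.5 + level / 2), axis=0)
    return lo, hi


@dataclass(frozen=True)
class DetectionLimits:
    """MDC/RDL from the confidence-band construction, both in ug/l."""

    mdc: float
    rdl: float
    ec50: float
    level: float = 0.95
    y_crit: float = float("nan")

    def to_dict(self) -> dict:
        return {"MDC_ug_per_l": self.mdc, "RDL_ug_per_l": self.rdl,
                "EC50_ug_per_l": self.ec50, "level": self.level,
                "y_crit": self.y_crit}


def _bisect_log(f, lo: float, hi: float, rtol: float) -> float:
    """Bisection on log-concentration for a sign change f(lo) > 0 > f(hi)."""
    llo, lhi = np.log(lo), np.log(hi)
    flo = f(lo)
    for _ in range(200):
        lmid = 0.5 * (llo + lhi)
        mid = np.exp(lmid)
        fm = f(mid)
        if np.sign(fm) == np.sign(flo):
            llo = lmid
        else:
            lhi = lmid
        if (lhi - llo) < rtol:
            break
    return float(np.exp(0.5 * (llo + lhi)))


def _first_downcross(f, grid: np.ndarray) -> tuple[float, float]:
    vals = np.array([f(g) for g in grid])
    sign = vals > 0
    if not sign[0]:
        return grid[0], grid[0]
    idx = np.nonzero(~sign)[0]
    if idx.size == 0:
        raise LimitError("limit beyond calibrated range "
                         f"[{grid[0]:g}, {grid[-1]:g}] ug/l")
    i = idx[0]
    return grid[i - 1], grid[i]


def detection_limits(fit: FourPLFit, level: float = 0.95,
                     bracket: tuple[float, float] = (1e-3, 1e5),
                     rtol: float = 1e-6, n_grid: int = 400,
                     kind: str = "confidence") -> DetectionLimits:
    """MDC and RDL of a decreasing calibration curve.

    The critical response is the lower band limit at zero concentration;
    the MDC is where the fitted curve crosses it and the RDL where the
    upper band does.  Roots are bracketed on a log grid spanning
    ``bracket`` and refined by bisection to relative tolerance ``rtol``.
    ``kind`` selects a confidence band of the mean response (default) or a
    prediction band for single future measurements.

    Raises
    ------
    LimitError
        The criterion has no crossing inside ``bracket``.
    """
    if fit.a1 <= fit.a2:
        raise DomainError("detection limits need a decreasing curve (A1 > A2)")
    y_crit = float(confidence_band(fit, 0.0, level, kind)[0][0])
    if y_crit <= fit.a2:
        raise LimitError("zero-concentration band reaches below the lower "
                         "asymptote; assay has no dynamic range at this level")
    grid = np.geomspace(bracket[0], bracket[1], n_grid)

    def curve_excess(x):
        return float(fit.predict(x) - y_crit)

    def upper_excess(x):
        return float(confidence_band(fit, x, level, kind)[1][0] - y_crit)

    lo, hi = _first_downcross(curve_excess, grid)
    mdc = lo if lo == hi else _bisect_log(curve_excess, lo, hi, rtol)
    lo, hi = _first_downcross(upper_excess, grid)
    rdl = lo if lo == hi else _bisect_log(upper_excess, lo, hi, rtol)
    return DetectionLimits(mdc=mdc, rdl=max(rdl, mdc), ec50=fit.x0,
                           level=level, y_crit=y_crit)


# ---------------------------------------------------------------------------
# conjugate comparison
# ---------------------------------------------------------------------------

def compare_conjugates(results: dict[str, list[tuple[FourPLFit, DetectionLimits]]]
                       ) -> pd.DataFrame:
    """Rank conjugates by calibration performance.

    ``results`` maps a conjugate label to its (triplicate) batch fits.
    Returns one row per label with EC50 mean and standard error over
    batches, and mean MDC/RDL.  Warns when labels were calibrated on
    different concentration grids (limited comparability).
    """
    if len(results) < 1:
        raise DomainError("need at least one calibration")
    grids = {lab: tuple(np.unique(np.concatenate([f.x for f, _ in batch])))
             for lab, batch in results.items()}
    if len(set(grids.values())) > 1:
        warnings.warn("conjugates calibrated on different concentration "
                      "grids; comparison is indicative only", stacklevel=2)
    rows = []
    for label, batch in results.items():
        ec50 = np.array([f.ec50 for f, _ in batch])
        mdc = np.array([d.mdc for _, d in batch])
        rdl = np.array([d.rdl for _, d in batch])
        n = len(batch)
        rows.append({
            "label": label,
            "n_batches": n,
            "ec50_mean": ec50.mean(),
            "ec50_se": ec50.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "mdc_mean": mdc.mean(),
            "rdl_mean": rdl.mean(),
        })
    df = pd.DataFrame(rows).sort_values("mdc_mean").reset_index(drop=True)
    return df
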