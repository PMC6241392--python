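"""Analyte quantification: MFI summaries, standard dilution series,
log-logistic standard curves, and inverse concentration estimation.

The standard curve is the five-parameter log-logistic model

    y = c + (d - c) / (1 + exp(b * (x - e)))**f

fitted with the dose on the log10-concentration scale and the response
as log10 MFI (both axes log, as is conventional for bead immunoassays).
``c`` and ``d`` are the lower and upper asymptotes, ``e`` the dose at
the inflection (log10 concentration), ``b`` the slope (negative for an
increasing curve in this parameterization), and ``f`` the asymmetry;
``f = 1`` recovers the symmetric four-parameter model widely used for
ELISA data. The extra asymmetry parameter usually fits real assay data
better, so 5PL is the default.

Concentrations are estimated by inverting the fitted curve,

    x_hat = e + (1 / b) * ln(((d - c) / (y - c))**(1 / f) - 1)

and reported as ``10**x_hat``. The estimation error is the delta-method
standard error of ``x_hat`` with respect to the curve parameters,
back-transformed to a multiplicative factor ``10**se``; responses
outside the open asymptote interval cannot be inverted and are reported
missing with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, FitError

MEAN_FUNCTIONS = ("geometric", "harmonic", "arithmetic")


# ---------------------------------------------------------------------------
# MFI
# ---------------------------------------------------------------------------


def calc_analyte_mfi(
    events: pd.DataFrame,
    parameter: str,
    column_name: str = "analyte_id",
    mean_fun: str = "geometric",
    sample_column: str = "sample_id",
) -> pd.DataFrame:
    """Mean fluorescence intensity of the reporter channel per
    (sample, analyte).

    Events with a missing analyte ID are excluded. ``geometric``
    (``exp(mean(ln x))``, the default since intensities live on a log
    scale), ``harmonic`` (``n / sum(1/x)``) and ``arithmetic`` means are
    available; the first two require strictly positive intensities.
    """
    if mean_fun not in MEAN_FUNCTIONS:
        raise DataError(
            f"unknown mean_fun {mean_fun!r}; choose one of {MEAN_FUNCTIONS}"
        )
    for col in (parameter, column_name, sample_column):
        if col not in events.columns:
            raise DataError(
                f"column {col!r} not present; available: {list(events.columns)}"
            )
    sub = events.loc[events[column_name].notna(), [sample_column, column_name, parameter]]
    rows = []
    for (sample, analyte), grp in sub.groupby(
        [sample_column, column_name], sort=True
    ):
        x = grp[parameter].to_numpy(dtype=float)
        if mean_fun in ("geometric", "harmonic") and np.any(x <= 0):
            raise DataError(
                f"{mean_fun} mean undefined: non-positive intensity in "
                f"sample {sample!r}, analyte {analyte!r}"
            )
        if mean_fun == "geometric":
            mfi = float(np.exp(np.mean(np.log(x))))
        elif mean_fun == "harmonic":
            mfi = float(len(x) / np.sum(1.0 / x))
        else:
            mfi = float(np.mean(x))
        rows.append(
            {sample_column: sample, column_name: analyte, "n_events": len(x), "mfi": mfi}
        )
    return pd.DataFrame(rows, columns=[sample_column, column_name, "n_events", "mfi"])


# ---------------------------------------------------------------------------
# standard dilution series
# ---------------------------------------------------------------------------


def calc_std_conc(
    sample_numbers: Sequence[int],
    start_conc: float,
    dilution_factor: float = 4.0,
) -> np.ndarray:
    """Assign concentrations to a dilution series of standard samples.

    Samples are ordered numerically from high to low; the highest gets
    the start concentration C0, the i-th thereafter ``C0 / D**i``, and
    the very last sample 0 -- it is assumed to be the blank (background)
    measurement. The result is aligned with the input order. Sample
    numbers must be distinct.
    """
    nums = np.asarray(list(sample_numbers))
    if len(nums) != len(np.unique(nums)):
        raise DataError(f"duplicate standard sample numbers in {nums.tolist()}")
    if not start_conc > 0:
        raise DataError(f"start concentration must be > 0, got {start_conc}")
    if not dilution_factor > 1:
        raise DataError(f"dilution factor must be > 1, got {dilution_factor}")
    order = np.argsort(nums, kind="stable")[::-1]  # high -> low
    conc = np.empty(len(nums), dtype=float)
    for i, pos in enumerate(order):
        conc[pos] = 0.0 if i == len(nums) - 1 else start_conc / dilution_factor**i
    return conc


# ---------------------------------------------------------------------------
# log-logistic model
# ---------------------------------------------------------------------------

_PARAM_NAMES_5PL = ("b", "c", "d", "e", "f")


@dataclass
class StandardCurve:
    """Fitted 5PL/4PL standard curve on the log10-dose, log10-response
    scale. ``covariance`` is ordered (b, c, d, e[, f])."""

    b: float
    c: float
    d: float
    e: float
    f: float = 1.0
    model: str = "5PL"  # "5PL" | "4PL"
    covariance: np.ndarray | None = None
    residual_sd: float = 0.0
    converged: bool = True
    dose_scale: str = "log10"
    response_scale: str = "log10"

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES_5PL if self.model == "5PL" else _PARAM_NAMES_5PL[:4]

    @property
    def theta(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in self.param_names])


def _l5(x, b, c, d, e, f):
    with np.errstate(over="ignore"):
        return c + (d - c) * (1.0 + np.exp(b * (np.asarray(x, dtype=float) - e))) ** (
            -f
        )


def logistic5(x, curve: StandardCurve) -> np.ndarray:
    """Evaluate the (4/5)PL response at log10-dose ``x``."""
    return _l5(x, curve.b, curve.c, curve.d, curve.e, curve.f)


def _inv_l5(y, b, c, d, e, f):
    """Inverse of the 5PL on the open response interval between the
    asymptotes; NaN outside."""
    y = np.asarray(y, dtype=float)
    lo, hi = (c, d) if c < d else (d, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = ((d - c) / (y - c)) ** (1.0 / f) - 1.0
        x = e + np.log(ratio) / b
    return np.where((y > lo) & (y < hi), x, np.nan)


def inverse_logistic5(y, curve: StandardCurve) -> np.ndarray:
    """Log10 dose at which the curve attains response ``y`` (NaN when
    ``y`` lies outside the open asymptote interval)."""
    return _inv_l5(y, curve.b, curve.c, curve.d, curve.e, curve.f)


def fit_standard_curve(
    standards: pd.DataFrame,
    model: str = "5PL",
    concentration_column: str = "concentration",
    response_column: str = "log10_mfi",
) -> StandardCurve:
    """Nonlinear least-squares fit of log10 MFI on log10 concentration.

    Blank rows (concentration 0) are excluded -- their dose is undefined
    on the log scale; they serve only as QC context. At least 5 (4PL) or
    6 (5PL) distinct non-blank concentrations are recommended. The
    parameter covariance is computed from the Jacobian at the optimum
    and the residual variance.
    """
    if model not in ("5PL", "4PL"):
        raise DataError(f"model must be '5PL' or '4PL', got {model!r}")
    for col in (concentration_column, response_column):
        if col not in standards.columns:
            raise DataError(
                f"column {col!r} not present; available: {list(standards.columns)}"
            )
    df = standards.loc[standards[concentration_column] > 0]
    x = np.log10(df[concentration_column].to_numpy(dtype=float))
    y = df[response_column].to_numpy(dtype=float)
    if len(x) < 4:
        raise FitError(f"need at least 4 non-blank standard points, got {len(x)}")
    if np.ptp(y) < 1e-10:
        raise FitError("flat response: standard MFIs are constant, cannot fit")

    span = np.ptp(y)
    c0 = y.min() - 0.05 * span
    d0 = y.max() + 0.05 * span
    increasing = np.corrcoef(x, y)[0, 1] >= 0
    # in this parameterization an increasing curve has b < 0
    sign = -1.0 if increasing else 1.0
    e0 = float(x[np.argmin(np.abs(y - (c0 + d0) / 2))])

    n_par = 5 if model == "5PL" else 4

    def residuals(theta):
        b, c, d, e = theta[:4]
        f = theta[4] if n_par == 5 else 1.0
        return _l5(x, b, c, d, e, f) - y

    lower = [-np.inf, -np.inf, -np.inf, -np.inf, 1e-3][:n_par]
    upper = [np.inf, np.inf, np.inf, np.inf, 1e3][:n_par]
    best = None
    for b0 in (0.5, 1.0, 2.0, 4.0, 8.0):
        theta0 = [sign * b0, c0, d0, e0, 1.0][:n_par]
        try:
            res = least_squares(
                residuals,
                theta0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("standard-curve fit did not converge for any start value")

    theta = best.x
    n, p = len(x), n_par
    dof = max(n - p, 1)
    residual_sd = float(np.sqrt(2 * best.cost / dof))
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.pinv(jtj) * residual_sd**2
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    b, c, d, e = theta[:4]
    f = float(theta[4]) if n_par == 5 else 1.0
    return StandardCurve(
        b=float(b),
        c=float(c),
        d=float(d),
        e=float(e),
        f=f,
        model=model,
        covariance=cov,
        residual_sd=residual_sd,
        converged=True,
    )


# ---------------------------------------------------------------------------
# inverse estimation
# ---------------------------------------------------------------------------


def _xhat_and_se(y: np.ndarray, curve: StandardCurve) -> tuple[np.ndarray, np.ndarray]:
    theta = curve.theta
    names = curve.param_names

    def inv_at(th):
        kw = dict(zip(names, th))
        kw.setdefault("f", curve.f)
        return _inv_l5(y, **kw)

    xhat = inv_at(theta)
    if curve.covariance is None or not np.all(np.isfinite(curve.covariance)):
        return xhat, np.full_like(xhat, np.nan)
    grad = np.empty((len(theta), len(y)))
    for i in range(len(theta)):
        h = 1e-6 * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (inv_at(up) - inv_at(dn)) / (2 * h)
    var = np.einsum("in,ij,jn->n", grad, curve.covariance, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    return xhat, se


def calculate_concentration(
    samples: pd.DataFrame,
    curve: StandardCurve,
    mfi_column: str = "mfi",
) -> pd.DataFrame:
    """Back-calculate concentrations from MFIs through a fitted curve.

    Adds ``log10_mfi``, ``calc_conc`` (``10**x_hat``),
    ``calc_conc_error`` (multiplicative delta-method factor ``10**se``)
    and ``flag`` (``"ok"`` or ``"out_of_range"`` for responses at or
    beyond the curve asymptotes, which are reported missing rather than
    extrapolated).
    """
    if not curve.converged:
        raise FitError("standard curve did not converge; refusing to estimate")
    if mfi_column not in samples.columns:
        raise DataError(
            f"column {mfi_column!r} not present; available: {list(samples.columns)}"
        )
    out = samples.copy()
    mfi = out[mfi_column].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(mfi > 0, np.log10(np.where(mfi > 0, mfi, np.nan)), np.nan)
    xhat, se = _xhat_and_se(y, curve)
    out["log10_mfi"] = y
    with np.errstate(over="ignore"):  # se blows up near the asymptotes
        out["calc_conc"] = 10.0**xhat
        out["calc_conc_error"] = 10.0**se
    out["flag"] = np.where(np.isfinite(xhat), "ok", "out_of_range")
    return out
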