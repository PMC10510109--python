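"""Assay-curve metrics: DSF melting temperature, DLS critical aggregation
concentration, and FLIM single-exponential lifetime.

Tm is the temperature of the maximum of the first derivative of the
max-normalized melt curve, refined by parabolic interpolation through the
derivative peak. The CAC is the "origin of slope" of a scattering-vs-
log-concentration series, operationalized as the breakpoint of a continuous
two-segment linear fit chosen by exhaustive search over interior grid
positions. Fluorescence lifetime is a single-component exponential tailfit
I(t) = I0 exp(-t/tau) + offset restricted to times past ``tail_start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .core import CurveTrace

logger = logging.getLogger("memnano")


@dataclass
class TmResult:
    tm: float  # degC
    derivative_peak_value: float  # AU / degC
    local_maxima: list[float] = field(default_factory=list)  # all derivative peaks


@dataclass
class CacResult:
    cac: float  # nM
    slope_below: float
    slope_above: float
    fit_error: float  # residual sum of squares


@dataclass
class LifetimeResult:
    tau: float  # ns
    I0: float
    offset: float
    residual: float
    n_points: int


def fit_tm(melt: CurveTrace) -> TmResult:
    """Melting temperature from the first-derivative maximum of a melt curve.

    The signal is normalized to its maximum, differentiated by central
    differences on the temperature grid, and the derivative peak refined by
    a parabola through the peak and its two neighbors (the 0.5 degC grid
    would otherwise quantize Tm). All local derivative maxima are reported
    as diagnostics; a curve with no positive derivative anywhere raises
    "no melting transition".
    """
    if melt.kind not in ("", "melt"):
        raise ValueError(f"expected a melt curve, got kind {melt.kind!r}")
    if len(melt) < 10:
        raise ValueError("melt curve needs at least 10 points")
    x = melt.x
    y = melt.y / np.max(melt.y)
    steps = np.diff(x)
    if np.allclose(steps, steps[0], rtol=1e-6) and x.size >= 9:
        # Savitzky-Golay derivative: the symmetric window suppresses
        # measurement noise without shifting a symmetric transition
        from scipy.signal import savgol_filter

        window = min(15, x.size if x.size % 2 else x.size - 1)
        dy = savgol_filter(y, window, polyorder=3, deriv=1, delta=float(steps[0]))
    else:
        dy = np.gradient(y, x)
    i = int(np.argmax(dy))
    if dy[i] <= 0:
        raise ValueError("no melting transition: derivative never positive")
    tm, peak = _parabolic_peak(x, dy, i)
    interior = np.arange(1, x.size - 1)
    local = interior[(dy[interior] > dy[interior - 1]) & (dy[interior] >= dy[interior + 1]) & (dy[interior] > 0)]
    return TmResult(
        tm=tm, derivative_peak_value=peak, local_maxima=[float(x[j]) for j in local]
    )


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:  # not locally concave; keep the grid point
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = x[i + 1] - x[i]
    return float(x[i] + delta * h), float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)


def fit_cac(dls: CurveTrace, min_p_value: float = 0.05) -> CacResult:
    """Critical aggregation concentration from a two-segment breakpoint fit.

    ``dls.x`` is log10(concentration / nM). A continuous hinge model
    y = a + b x + c max(0, x - xb) is fit by least squares for every
    interior grid candidate xb; the candidate minimizing the residual sum
    of squares wins and CAC = 10^xb. The fit must beat a single straight
    line by an F-test at ``min_p_value`` and must steepen (c > 0), else
    "no aggregation onset detected".
    """
    if dls.kind not in ("", "dls"):
        raise ValueError(f"expected a dls curve, got kind {dls.kind!r}")
    x, y = dls.x, dls.y
    n = x.size
    if n < 6:
        raise ValueError("dls series needs at least 6 points")
    best = None
    for k in range(2, n - 2):  # >= 2 points strictly on each side
        xb = x[k]
        design = np.column_stack([np.ones(n), x, np.clip(x - xb, 0.0, None)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ssr = float((((design @ coef) - y) ** 2).sum())
        if best is None or ssr < best[0] - 1e-15 * abs(best[0]):
            best = (ssr, xb, coef)
    ssr_seg, xb, coef = best
    line = np.polyfit(x, y, 1)
    ssr_line = float(((np.polyval(line, x) - y) ** 2).sum())
    scale = max(float((y**2).sum()), 1e-300)
    if ssr_line <= 1e-20 * scale:
        raise ValueError("no aggregation onset detected: data fit a single line")
    if ssr_seg <= 1e-20 * scale:
        p = 0.0  # segmented fit is exact; unambiguous breakpoint
    else:
        f_stat = ((ssr_line - ssr_seg) / 2.0) / (ssr_seg / (n - 4))
        p = float(f_dist.sf(max(f_stat, 0.0), 2, n - 4))
    slope_below = float(coef[1])
    slope_above = float(coef[1] + coef[2])
    if p > min_p_value or coef[2] <= 0:
        raise ValueError(
            "no aggregation onset detected: two-segment fit not better than a line"
        )
    return CacResult(
        cac=float(10.0**xb),
        slope_below=slope_below,
        slope_above=slope_above,
        fit_error=ssr_seg,
    )


def fit_lifetime(decay: CurveTrace, tail_start: float = 0.0) -> LifetimeResult:
    """Single-component exponential tailfit of a fluorescence decay (ns).

    Restricted to t >= ``tail_start``; a flat (offset-only) trace or a
    non-convergent optimizer raises with the residual in the message.
    """
    sel = decay.x >= tail_start
    t, y = decay.x[sel], decay.y[sel]
    if t.size < 10:
        raise ValueError("lifetime fit needs at least 10 points after tail_start")
    if (y < 0).any():
        raise ValueError("decay counts must be non-negative")
    amp0 = float(y.max() - y.min())
    span = float(y.max())
    if span <= 0 or amp0 <= 1e-9 * span:
        raise ValueError(
            f"lifetime fit did not converge: trace is flat "
            f"(amplitude {amp0:.3g} over offset {y.min():.3g})"
        )
    tau0 = max((t[-1] - t[0]) / 5.0, 1e-6)

    def model(t, i0, tau, off):
        return i0 * np.exp(-t / tau) + off

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[amp0, tau0, float(y.min())],
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        resid = float(((model(t, amp0, tau0, y.min()) - y) ** 2).sum())
        raise ValueError(
            f"lifetime fit did not converge (residual {resid:.3g}): {exc}"
        ) from exc
    i0, tau, off = (float(v) for v in popt)
    resid = float(((model(t, *popt) - y) ** 2).sum())
    if tau > 100.0 * (t[-1] - t[0]):
        raise ValueError(
            f"lifetime fit did not converge: tau {tau:.3g} far exceeds the "
            f"observation window (residual {resid:.3g})"
        )
    return LifetimeResult(tau=tau, I0=i0, offset=off, residual=resid, n_points=int(t.size))
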