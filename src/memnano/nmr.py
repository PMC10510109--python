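"""NMR-derived metrics: PRE intensity ratios, chemical-shift perturbation,
and TRACT rotational-correlation-time estimation.

CSP combines the amide 1H and 15N shift changes between two states as

    CSP (ppm) = sqrt((dN^2 / 25 + dH^2) / 2),

down-weighting 15N by its larger shift dispersion. PRE ratios are
tagged/untagged peak intensities normalized so the least-attenuated residue
is exactly 1. TRACT fits mono-exponential decays of the TROSY (alpha) and
anti-TROSY (beta) 15N doublet components; their rate difference
dR = R_beta - R_alpha equals twice the 15N CSA / N-H dipole transverse
cross-correlation rate, which is inverted numerically to the rotational
correlation time tau_c for an isotropically tumbling rigid rotor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .core import CurveTrace

logger = logging.getLogger("memnano")

# physical constants for the dipole/CSA cross-correlation rate
_H_PLANCK = 6.62607015e-34  # J s
_MU0 = 4.0e-7 * np.pi  # T m / A
_GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
_GAMMA_N = -2.7126e7  # rad s^-1 T^-1 (15N, negative)
_R_NH = 1.02e-10  # m, amide N-H bond length
_CSA_N = 160e-6  # 15N chemical shift anisotropy magnitude
_THETA = np.deg2rad(17.0)  # angle between the CSA axis and the N-H bond


@dataclass
class TractResult:
    R_alpha: float  # s^-1
    R_beta: float  # s^-1
    delta_R: float  # s^-1
    tau_c_ns: float
    field_MHz: float


def compute_csp(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-residue combined 1H/15N chemical-shift perturbation in ppm.

    Expects columns ``residue, H_ref_ppm, N_ref_ppm, H_alt_ppm, N_alt_ppm``;
    residues missing either state are skipped with a log entry.
    """
    required = {"residue", "H_ref_ppm", "N_ref_ppm", "H_alt_ppm", "N_alt_ppm"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")
    ok = pairs[sorted(required - {"residue"})].notna().all(axis=1)
    if not ok.all():
        logger.info("compute_csp: skipped %d residue(s) missing a state", int((~ok).sum()))
    sub = pairs[ok]
    dh = sub["H_alt_ppm"].to_numpy() - sub["H_ref_ppm"].to_numpy()
    dn = sub["N_alt_ppm"].to_numpy() - sub["N_ref_ppm"].to_numpy()
    csp = np.sqrt((dn**2 / 25.0 + dh**2) / 2.0)
    return pd.DataFrame({"residue": sub["residue"].to_numpy(), "csp_ppm": csp})


def compute_pre_ratios(
    pairs: pd.DataFrame, reference_residues: list[int] | None = None
) -> pd.DataFrame:
    """Per-residue PRE intensity ratios I_tagged/I_untagged, normalized to 1.

    By default every raw ratio is divided by the maximum raw ratio so the
    least-attenuated residue reads exactly 1; alternatively a set of
    ``reference_residues`` known to be unaffected can define the
    normalization via their mean raw ratio. Residues with non-positive
    untagged intensity are excluded with a log entry.
    """
    required = {"residue", "I_tagged", "I_untagged"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"intensity table missing column(s): {sorted(missing)}")
    ok = pairs["I_untagged"].to_numpy() > 0
    if not ok.all():
        logger.info(
            "compute_pre_ratios: excluded %d residue(s) with non-positive "
            "untagged intensity",
            int((~ok).sum()),
        )
    sub = pairs[ok]
    raw = sub["I_tagged"].to_numpy() / sub["I_untagged"].to_numpy()
    if reference_residues is not None:
        sel = np.isin(sub["residue"].to_numpy(), reference_residues)
        if not sel.any():
            raise ValueError("no reference residue present in the table")
        norm = raw[sel].mean()
    else:
        norm = raw.max()
    if not norm > 0:
        raise ValueError("normalization constant is non-positive")
    return pd.DataFrame({"residue": sub["residue"].to_numpy(), "pre_ratio": raw / norm})


# ---------------------------------------------------------------------------
# TRACT


def _spectral_density(omega: float, tau_c: float) -> float:
    """Lorentzian spectral density J(w) = (2/5) tau / (1 + (w tau)^2)."""
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def tract_delta_r(tau_c_ns: float, field_MHz: float) -> float:
    """Predicted R_beta - R_alpha (s^-1) for an isotropic rotor.

    dR = 2 eta_xy with eta_xy = 2 p dN P2(cos theta) [4 J(0) + 3 J(wN)],
    p = mu0 gammaH gammaN h / (16 pi^2 sqrt(2) r^3) and
    dN = gammaN B0 dSigma / (3 sqrt(2)). Strictly increasing in tau_c at
    fixed field (J(0) dominates), so the inversion is well-posed.
    """
    tau = tau_c_ns * 1e-9
    b0 = 2.0 * np.pi * field_MHz * 1e6 / _GAMMA_H
    omega_n = abs(_GAMMA_N) * b0
    p = _MU0 * _GAMMA_H * _GAMMA_N * _H_PLANCK / (
        16.0 * np.pi**2 * np.sqrt(2.0) * _R_NH**3
    )
    d_n = _GAMMA_N * b0 * _CSA_N / (3.0 * np.sqrt(2.0))
    p2 = 0.5 * (3.0 * np.cos(_THETA) ** 2 - 1.0)
    eta_xy = (
        2.0
        * p
        * d_n
        * p2
        * (4.0 * _spectral_density(0.0, tau) + 3.0 * _spectral_density(omega_n, tau))
    )
    return 2.0 * eta_xy


def tau_c_from_delta_r(delta_r: float, field_MHz: float) -> float:
    """Invert the TRACT rate difference to tau_c (ns) by Brent root-finding."""
    if not delta_r > 0:
        raise ValueError("delta_R must be positive to yield a physical tau_c")
    lo, hi = 1e-3, 1e3
    f = lambda tc: tract_delta_r(tc, field_MHz) - delta_r
    if f(hi) < 0:
        raise ValueError(f"delta_R = {delta_r:.3g} s^-1 exceeds the model range")
    return float(brentq(f, lo, hi, xtol=1e-9))


def _fit_monoexp(trace: CurveTrace, with_offset: bool = False) -> tuple[float, float]:
    """Least-squares I(t) = I0 exp(-R t) (+ offset); returns (I0, R)."""
    t, y = trace.x, trace.y
    if t.size < 5:
        raise ValueError("decay needs at least 5 points")
    if y[0] <= 0 or (y <= 0).all():
        raise ValueError("decay intensities must be positive at t = 0")
    pos = y > 0
    r0 = max(1e-3, -np.polyfit(t[pos], np.log(y[pos]), 1)[0])
    try:
        if with_offset:
            popt, _ = curve_fit(
                lambda t, i0, r, c: i0 * np.exp(-r * t) + c,
                t, y, p0=[y[0], r0, 0.0], maxfev=10000,
            )
        else:
            popt, _ = curve_fit(
                lambda t, i0, r: i0 * np.exp(-r * t),
                t, y, p0=[y[0], r0], maxfev=10000,
            )
    except RuntimeError as exc:
        raise ValueError(f"exponential fit did not converge: {exc}") from exc
    return float(popt[0]), float(popt[1])


def fit_tract(
    decay_alpha: CurveTrace,
    decay_beta: CurveTrace,
    field_MHz: float = 900.0,
    with_offset: bool = False,
) -> TractResult:
    """Fit both TRACT state decays and convert dR to tau_c.

    Delays are in seconds. The alpha (TROSY) state relaxes more slowly than
    beta; identical traces give dR = 0 and no tau_c (reported as nan).
    """
    _, r_alpha = _fit_monoexp(decay_alpha, with_offset)
    _, r_beta = _fit_monoexp(decay_beta, with_offset)
    delta_r = r_beta - r_alpha
    if delta_r <= 0:
        logger.warning("fit_tract: non-positive delta_R = %.3g s^-1", delta_r)
        tau = float("nan")
    else:
        tau = tau_c_from_delta_r(delta_r, field_MHz)
    return TractResult(
        R_alpha=r_alpha,
        R_beta=r_beta,
        delta_R=delta_r,
        tau_c_ns=tau,
        field_MHz=field_MHz,
    )
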