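"""Synthetic-data generators for every analysis stage.

Each generator emulates the statistical structure its downstream analysis
assumes — clustered immunogold point patterns on plasma-membrane sheets,
Brownian single-particle trajectories with localization noise and blinking,
paired NMR peak tables with and without a paramagnetic tag, and the assay
curves (TRACT decays, thermal melts, scattering-vs-concentration series,
fluorescence-lifetime decays). Ground truth is always returned alongside
the observables so recovery can be tested without re-simulation.

Every function takes one integer ``seed`` that feeds a single NumPy
Generator; sub-streams are derived deterministically from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .core import CurveTrace, PointPattern, Region, Track, TrackSet

logger = logging.getLogger("memnano")

#: TRACT relaxation-delay schedule for the slowly relaxing (TROSY, alpha)
#: 15N state, in milliseconds.
TRACT_ALPHA_DELAYS_MS = (0, 5, 10, 16, 22, 30, 40, 50, 64, 80, 100, 130, 170, 240)
#: Delay schedule for the faster-relaxing (anti-TROSY, beta) state, ms.
TRACT_BETA_DELAYS_MS = (0, 1, 2, 4, 7, 11, 15, 20, 26, 32, 39, 47, 56, 70)

#: Default thermal-melt temperature grid: 25-95 degC in 0.5 degC steps.
MELT_GRID_C = tuple(np.arange(25.0, 95.0 + 1e-9, 0.5))


@dataclass(frozen=True)
class ClusterModel:
    """Thomas-style cluster process on a rectangular sheet.

    ``points_per_cluster`` is an inclusive integer range; each parent emits a
    uniformly drawn count from it, defaulting to the 4-6 proteins per
    nanocluster occupancy. ``cluster_sd`` (the isotropic Gaussian offspring
    dispersion) is artifact-chosen — no cluster radius is established for
    K-Ras nanoclusters — and defaults to 20 nm.
    """

    n_clusters: int
    points_per_cluster: tuple[int, int] = (4, 6)
    cluster_sd: float = 20.0
    region: Region = field(default_factory=lambda: Region(1000.0, 1000.0))

    def __post_init__(self) -> None:
        lo, hi = self.points_per_cluster
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if not (1 <= lo <= hi):
            raise ValueError("points_per_cluster must satisfy 1 <= lower <= upper")
        if not self.cluster_sd > 0:
            raise ValueError("cluster_sd must be positive")


@dataclass(frozen=True)
class DiffusionModel:
    """Free 2-D Brownian motion imaged at fixed frame rate.

    Defaults mirror a TIRF acquisition: 10 ms frame interval in a
    16 x 16 um field of view.
    """

    diffusion_coefficient: float  # um^2/s
    frame_interval: float = 0.010  # s
    n_frames: int = 200
    localization_sd: float = 0.0  # um
    blink_probability: float = 0.0
    region: Region = field(default_factory=lambda: Region(16.0, 16.0))  # um

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if not 0 <= self.blink_probability < 1:
            raise ValueError("blink_probability must be in [0, 1)")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be >= 0")


def gen_csr_pattern(
    n: int, region: Region, seed: int, sheet_id: str = "csr"
) -> PointPattern:
    """Draw ``n`` points independently uniform on ``region`` (the CSR null)."""
    if n < 0:
        raise ValueError(f"number of points must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    pts = rng.uniform((0.0, 0.0), (region.width, region.height), size=(n, 2))
    return PointPattern(points=pts, region=region, sheet_id=sheet_id)


def gen_cluster_pattern(
    model: ClusterModel, seed: int, sheet_id: str = "thomas"
) -> tuple[PointPattern, np.ndarray]:
    """Simulate a clustered pattern; returns (pattern, parent index per point).

    Parent centers are uniform on the region; offspring are displaced by an
    isotropic Gaussian of sd ``cluster_sd`` and re-drawn until they land
    inside the region (keeps the per-cluster count exact without torus
    wrapping or clipping).
    """
    rng = np.random.default_rng(seed)
    region = model.region
    lo, hi = model.points_per_cluster
    parents = rng.uniform(
        (0.0, 0.0), (region.width, region.height), size=(model.n_clusters, 2)
    )
    counts = rng.integers(lo, hi + 1, size=model.n_clusters)
    pts: list[np.ndarray] = []
    labels: list[int] = []
    for k in range(model.n_clusters):
        need = int(counts[k])
        got: list[np.ndarray] = []
        while len(got) < need:
            cand = parents[k] + rng.normal(0.0, model.cluster_sd, size=(need, 2))
            inside = region.contains(cand)
            got.extend(cand[inside])
        pts.append(np.asarray(got[:need]))
        labels.extend([k] * need)
    points = np.vstack(pts) if pts else np.empty((0, 2))
    pattern = PointPattern(points=points, region=region, sheet_id=sheet_id)
    return pattern, np.asarray(labels, dtype=int)


def gen_brownian_tracks(
    model: DiffusionModel, n_tracks: int, seed: int
) -> TrackSet:
    """Simulate Brownian trajectories with localization noise and blinking.

    Per-frame displacement components are N(0, 2*D*dt) per axis; trajectories
    reflect off the region boundary so every position stays inside the field
    of view. Reported positions add independent Gaussian localization error.
    With probability ``blink_probability`` a frame's observation is dropped,
    but never two in a row, so single-gap linking can in principle recover
    every track. The returned TrackSet carries the observed tracks plus the
    noiseless, gapless truth in ``.truth``.
    """
    if n_tracks < 0:
        raise ValueError("n_tracks must be >= 0")
    rng = np.random.default_rng(seed)
    region = model.region
    step_sd = float(np.sqrt(2.0 * model.diffusion_coefficient * model.frame_interval))
    observed: list[Track] = []
    truth: list[Track] = []
    for tid in range(n_tracks):
        start = rng.uniform((0.0, 0.0), (region.width, region.height))
        steps = rng.normal(0.0, step_sd, size=(model.n_frames - 1, 2))
        path = np.vstack([start, start + np.cumsum(steps, axis=0)])
        path = _reflect(path, region)
        frames = np.arange(model.n_frames)
        truth.append(Track(id=tid, frames=frames.copy(), xy=path.copy()))
        noisy = path + rng.normal(0.0, model.localization_sd, size=path.shape)
        keep = np.ones(model.n_frames, dtype=bool)
        if model.blink_probability > 0:
            u = rng.uniform(size=model.n_frames)
            for f in range(model.n_frames):
                if u[f] < model.blink_probability and (f == 0 or keep[f - 1]):
                    keep[f] = False
        observed.append(Track(id=tid, frames=frames[keep], xy=noisy[keep]))
    return TrackSet(
        tracks=observed,
        frame_interval=model.frame_interval,
        unit="um",
        region=region,
        truth=truth,
        n_frames=model.n_frames,
    )


def _reflect(path: np.ndarray, region: Region) -> np.ndarray:
    """Fold coordinates back into the rectangle by mirror reflection."""
    out = path.copy()
    for axis, side in ((0, region.width), (1, region.height)):
        v = np.mod(out[:, axis], 2.0 * side)
        out[:, axis] = np.where(v > side, 2.0 * side - v, v)
    return out


@dataclass
class FrameStack:
    """A rendered image sequence plus the calibration used to make it."""

    frames: np.ndarray  # (n_frames, ny, nx) float counts
    pixel_size: float  # um / px
    psf_sigma: float  # px
    n_clipped: int = 0

    def as_uint16(self) -> np.ndarray:
        return np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)


def render_frames(
    tracks: TrackSet,
    psf_sigma: float = 1.3,
    pixel_size: float = 0.16,
    photons: float = 1000.0,
    background: float = 10.0,
    seed: int = 0,
    poisson_noise: bool = True,
) -> FrameStack:
    """Render observed localizations into a synthetic TIRF movie.

    Each localization becomes an integrated symmetric 2-D Gaussian (total
    intensity ``photons``) on a uniform ``background``; Poisson counting
    noise is applied unless ``poisson_noise`` is False. Frame dimensions
    derive from the track region and the pixel size (16 x 16 um at
    0.16 um/px gives the default 100 x 100 px field). Pixel centers sit at
    integer coordinates. Emitters outside the frame are clipped and counted.
    """
    if not psf_sigma > 0:
        raise ValueError("psf_sigma must be positive")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    region = tracks.region or Region(16.0, 16.0)
    nx = int(round(region.width / pixel_size))
    ny = int(round(region.height / pixel_size))
    n_frames = tracks.n_frames or (
        1 + max((int(t.frames.max()) for t in tracks.tracks if len(t)), default=0)
    )
    rng = np.random.default_rng(seed)
    stack = np.full((n_frames, ny, nx), float(background))
    xs = np.arange(nx)
    ys = np.arange(ny)
    n_clipped = 0
    root2sig = np.sqrt(2.0) * psf_sigma
    for track in tracks.tracks:
        for f, (x_um, y_um) in zip(track.frames, track.xy):
            xc = x_um / pixel_size
            yc = y_um / pixel_size
            if not (-0.5 <= xc < nx - 0.5 and -0.5 <= yc < ny - 0.5):
                n_clipped += 1
                continue
            gx = 0.5 * (erf((xs - xc + 0.5) / root2sig) - erf((xs - xc - 0.5) / root2sig))
            gy = 0.5 * (erf((ys - yc + 0.5) / root2sig) - erf((ys - yc - 0.5) / root2sig))
            stack[f] += photons * np.outer(gy, gx)
    if n_clipped:
        logger.info("render_frames: clipped %d localization(s) outside the frame", n_clipped)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return FrameStack(
        frames=stack, pixel_size=pixel_size, psf_sigma=psf_sigma, n_clipped=n_clipped
    )


class NmrTables(NamedTuple):
    peaks: pd.DataFrame  # residue, H_ref_ppm, N_ref_ppm, H_alt_ppm, N_alt_ppm
    intensities: pd.DataFrame  # residue, I_tagged, I_untagged
    truth: pd.DataFrame  # residue, perturbed, delta_h, delta_n, pre_effect


def gen_nmr_tables(
    n_residues: int,
    perturbed: set[int] | frozenset[int] = frozenset(),
    csp_effect: tuple[float, float] = (0.1, 0.5),
    pre_effect: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> NmrTables:
    """Build paired peak-position and peak-intensity tables.

    ``csp_effect`` is the (delta_H, delta_N) offset in ppm applied to each
    perturbed residue; ``pre_effect`` in [0, 1) is the fractional intensity
    loss of perturbed residues in the paramagnetically tagged spectrum.
    Multiplicative Gaussian noise of fractional sd ``noise_sd`` perturbs
    shifts (scaled down 100x, shifts are precise) and intensities.
    """
    perturbed = set(perturbed)
    if not perturbed <= set(range(1, n_residues + 1)):
        raise ValueError("perturbed residues must lie in 1..n_residues")
    if not 0 <= pre_effect < 1:
        raise ValueError("pre_effect must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    h_ref = rng.uniform(7.0, 9.5, size=n_residues)
    n_ref = rng.uniform(105.0, 130.0, size=n_residues)
    is_pert = np.isin(residues, sorted(perturbed))
    dh = np.where(is_pert, csp_effect[0], 0.0)
    dn = np.where(is_pert, csp_effect[1], 0.0)
    h_alt = h_ref + dh + rng.normal(0.0, noise_sd * 0.01, size=n_residues)
    n_alt = n_ref + dn + rng.normal(0.0, noise_sd * 0.01, size=n_residues)
    i_untag = rng.uniform(0.8, 1.2, size=n_residues)
    ratio = np.where(is_pert, 1.0 - pre_effect, 1.0)
    i_tag = i_untag * ratio * (1.0 + rng.normal(0.0, noise_sd, size=n_residues))
    peaks = pd.DataFrame(
        {
            "residue": residues,
            "H_ref_ppm": h_ref,
            "N_ref_ppm": n_ref,
            "H_alt_ppm": h_alt,
            "N_alt_ppm": n_alt,
        }
    )
    intensities = pd.DataFrame(
        {"residue": residues, "I_tagged": i_tag, "I_untagged": i_untag}
    )
    truth = pd.DataFrame(
        {
            "residue": residues,
            "perturbed": is_pert,
            "delta_h": dh,
            "delta_n": dn,
            "pre_effect": np.where(is_pert, pre_effect, 0.0),
        }
    )
    return NmrTables(peaks=peaks, intensities=intensities, truth=truth)


_CURVE_UNITS = {"tract": "s", "melt": "degC", "dls": "log10_nM", "flim": "ns"}


def gen_curve(
    kind: str,
    params: dict,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CurveTrace:
    """Generate one assay curve of the given ``kind`` on ``grid``.

    kinds and their params
    ----------------------
    tract : ``I0``, ``R`` (s^-1); grid in seconds (defaults to the alpha-state
        delay schedule). I(t) = I0 exp(-R t).
    melt : ``tm`` (degC), ``width`` (degC), optional ``low``, ``high``,
        ``decline`` (AU/degC post-transition linear loss); grid in degC
        (defaults to 25-95 in 0.5 steps). Rising logistic in temperature.
    dls : ``cac`` (nM), ``slope_below``, ``slope_above``, optional
        ``intercept``; grid in log10(concentration/nM). Continuous
        two-segment line with the slope break at log10(cac).
    flim : ``I0``, ``tau`` (ns), optional ``offset``; grid in ns.
        I(t) = I0 exp(-t/tau) + offset.

    Gaussian noise proportional to the signal (fractional sd ``noise_sd``)
    is added on top.
    """
    rng = np.random.default_rng(seed)
    if kind == "tract":
        x = np.asarray(
            grid if grid is not None else np.asarray(TRACT_ALPHA_DELAYS_MS) / 1e3,
            dtype=float,
        )
        y = params["I0"] * np.exp(-params["R"] * x)
    elif kind == "melt":
        x = np.asarray(grid if grid is not None else MELT_GRID_C, dtype=float)
        low = params.get("low", 0.1)
        high = params.get("high", 1.0)
        y = low + (high - low) / (1.0 + np.exp(-(x - params["tm"]) / params["width"]))
        decline = params.get("decline", 0.0)
        if decline:
            onset = params["tm"] + 4.0 * params["width"]
            y = y - decline * np.clip(x - onset, 0.0, None)
    elif kind == "dls":
        x = np.asarray(
            grid if grid is not None else np.linspace(0.5, 4.0, 29), dtype=float
        )
        xb = np.log10(params["cac"])
        y = (
            params.get("intercept", 1.0)
            + params["slope_below"] * x
            + (params["slope_above"] - params["slope_below"]) * np.clip(x - xb, 0.0, None)
        )
    elif kind == "flim":
        x = np.asarray(grid if grid is not None else np.linspace(0.0, 25.0, 251), dtype=float)
        y = params["I0"] * np.exp(-x / params["tau"]) + params.get("offset", 0.0)
    else:
        raise ValueError(f"unknown curve kind {kind!r}; expected tract|melt|dls|flim")
    if not (np.diff(x) > 0).all():
        raise ValueError("grid must be strictly increasing")
    if noise_sd:
        y = y * (1.0 + rng.normal(0.0, noise_sd, size=y.shape))
    return CurveTrace(x=x, y=y, kind=kind, x_unit=_CURVE_UNITS[kind])
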