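"""Barrier transport assays: vascular permeability and FRAP diffusivity.

Permeability uses the standard microvessel-on-chip estimator: dye flux
across the wall of a cylindrical vessel of effective diameter d gives

    P = (d/4) · (dI/dt) / (I1 − I0)        [length/time]

where I(t) is the background-subtracted intensity integrated over the
measurement window (vessel plus perivascular band) normalized to vessel
area, I1 the initial mean intravascular intensity, I0 the background, and
d/4 the volume-to-surface ratio of a cylinder. The ratio form makes the
estimate invariant to affine intensity rescaling.

FRAP diffusivity fits the uniform-disc instantaneous-bleach recovery
closed form (Soumpasis):

    f(t) = M · exp(−2τ_D/t) · [I₀(2τ_D/t) + I₁(2τ_D/t)],   D = w²/(4τ_D)

with w the bleach-spot radius, M the mobile fraction, and I₀, I₁ modified
Bessel functions. A model-free half-time estimate D = 0.224·w²/t_half is
reported alongside as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.special import ive

from .images import ImageStack, RasterImage


@dataclass
class PermeabilityResult:
    P: float                      # cm/s
    window: tuple[float, float]   # (t_start, t_end) seconds
    I0: float                     # background AU
    I1: float                     # initial mean intravascular AU
    slope: float                  # dI/dt, AU/s (vessel-area normalized)
    d_eff: float                  # μm


@dataclass
class FrapFit:
    D: float                 # μm²/s, closed-form fit
    spot_radius: float       # μm
    tau_D: float             # s
    mobile_fraction: float
    residual: float          # RMS of fit residuals
    D_half: float            # μm²/s, half-time cross-check
    low_confidence: bool = False


def estimate_permeability(stack: ImageStack, vessel_mask: RasterImage,
                          d_eff: float | None = None,
                          background: float | None = None,
                          band_width: float = 30.0,
                          t_start: float = 0.0) -> PermeabilityResult:
    """Permeability (cm/s) from a dye time-lapse and a vessel mask.

    ``d_eff`` defaults to the morphometric effective diameter of the
    supplied mask; ``background`` defaults to the mean intensity of the
    perivascular band in the first frame. Frames before ``t_start``
    (seconds) are excluded, matching a post-convection stabilization
    window.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames for a slope estimate")
    m = vessel_mask.as_bool()
    if m.shape != stack.frames.shape[1:]:
        raise ValueError("vessel mask not aligned with the stack")
    px = stack.pixel_size
    if d_eff is None:
        from .morphometry import skeletonize_network
        graph = skeletonize_network(vessel_mask)
        if graph.total_length == 0:
            raise ValueError("cannot derive d_eff from an empty skeleton")
        d_eff = m.sum() * px**2 / graph.total_length

    it = max(int(np.ceil(band_width / px)), 1)
    band = ndi.binary_dilation(m, iterations=it) & ~m
    window = m | band

    sel = stack.times >= t_start
    if sel.sum() < 3:
        raise ValueError("fewer than 3 frames in the measurement window")
    times = stack.times[sel]
    frames = stack.frames[sel]

    I0 = float(frames[0][band].mean()) if background is None else float(background)
    I1 = float(frames[0][m].mean())
    if I1 <= I0:
        raise ValueError(f"no dye signal: intravascular {I1:.3g} ≤ "
                         f"background {I0:.3g}")

    A_v = m.sum() * px**2
    # window intensity normalized to vessel area, AU
    I_t = np.array([(f[window] - I0).sum() * px**2 / A_v for f in frames])
    slope = float(np.polyfit(times, I_t, 1)[0])  # AU/s
    P_um_s = (d_eff / 4.0) * slope / (I1 - I0)
    return PermeabilityResult(P=P_um_s / 1e4, window=(times[0], times[-1]),
                              I0=I0, I1=I1, slope=slope, d_eff=float(d_eff))


def _soumpasis(t: np.ndarray, tau_d: float, mobile: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        x = np.where(t > 0, 2.0 * tau_d / np.maximum(t, 1e-30), np.inf)
    val = np.where(np.isinf(x), 0.0, ive(0, x) + ive(1, x))
    return mobile * val


def fit_frap_diffusivity(movie: ImageStack, roi_center: tuple[float, float] | None = None,
                         roi_radius: float | None = None,
                         n_prebleach: int | None = None) -> FrapFit:
    """Diffusion coefficient from a bleach-spot recovery movie.

    ROI center/radius and the pre-bleach frame count default to the movie
    metadata. Requires pre-bleach frames and ≥10 post-bleach frames.
    The bleach-spot radius is taken from metadata (not estimated from the
    image), matching a hard-edged bleach ROI protocol.
    """
    meta = movie.meta
    if n_prebleach is None:
        n_prebleach = int(meta.get("n_prebleach", 1))
    if roi_center is None:
        roi_center = meta.get("bleach_center_um")
    if roi_radius is None:
        roi_radius = meta.get("spot_radius_um")
    if roi_center is None or roi_radius is None:
        raise ValueError("bleach ROI not in metadata; pass roi_center/roi_radius")
    if n_prebleach < 1:
        raise ValueError("need at least one pre-bleach frame")
    n_post = movie.n_frames - n_prebleach
    if n_post < 10:
        raise ValueError("need at least 10 post-bleach frames")

    ny, nx = movie.frames.shape[1:]
    px = movie.pixel_size
    xs = np.arange(nx) * px
    ys = np.arange(ny) * px
    xx, yy = np.meshgrid(xs, ys)
    cx, cy = roi_center
    if not (0 <= cx <= xs[-1] and 0 <= cy <= ys[-1]):
        raise ValueError("bleach ROI outside the field")
    roi = np.hypot(xx - cx, yy - cy) <= roi_radius

    I_pre = float(movie.frames[:n_prebleach][:, roi].mean())
    post = movie.frames[n_prebleach:]
    t = movie.times[n_prebleach:] - movie.times[n_prebleach]
    I_t = post[:, roi].mean(axis=1)
    I_bleach = float(I_t[0])
    if I_pre <= I_bleach:
        raise ValueError("no bleach detected in the ROI")
    f = (I_t - I_bleach) / (I_pre - I_bleach)

    low_confidence = bool(f.max() < 0.2)
    # init from the half-recovery time of the observed plateau
    plateau = max(float(f[-5:].mean()), 1e-6)
    tau0 = max(1.1 * _crossing_time(t, f, 0.5 * plateau), float(t[1]))
    try:
        popt, _ = curve_fit(_soumpasis, t[1:], f[1:], p0=[tau0, min(plateau, 1.0)],
                            bounds=([1e-9, 0.0], [np.inf, 1.0]), maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"FRAP fit did not converge: {exc}") from exc
    tau_d, mobile = float(popt[0]), float(popt[1])
    D = roi_radius**2 / (4.0 * tau_d)
    resid = float(np.sqrt(np.mean((f[1:] - _soumpasis(t[1:], *popt)) ** 2)))
    # model-free cross-check; the half level is referenced to the fitted
    # mobile fraction since a finite movie need not reach its plateau
    t_half = _crossing_time(t, f, 0.5 * max(mobile, 1e-6))
    D_half = 0.224 * roi_radius**2 / t_half if t_half > 0 else float("nan")
    return FrapFit(D=D, spot_radius=float(roi_radius), tau_D=tau_d,
                   mobile_fraction=mobile, residual=resid, D_half=D_half,
                   low_confidence=low_confidence)


def _crossing_time(t: np.ndarray, f: np.ndarray, level: float) -> float:
    above = np.nonzero(f >= level)[0]
    if above.size == 0 or above[0] == 0:
        return float(t[1]) if len(t) > 1 else 0.0
    i = above[0]
    t0, t1 = t[i - 1], t[i]
    f0, f1 = f[i - 1], f[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (level - f0) * (t1 - t0) / (f1 - f0))
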