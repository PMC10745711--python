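"""Hertzian spherical-contact fitting of nanoindentation load–depth curves.

The loading segment is fit to the classical Hertz model for a rigid
sphere of radius R on an incompressible elastic half-space,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

after contact-point detection and optional cantilever-compliance
correction (δ_sample = δ_piezo − F/k_probe for raw piezo curves).
Defaults match a soft-tissue nanoindenter probe: R = 25 μm,
k_probe = 0.027 N/m, ν = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_R = 25.0              # μm
DEFAULT_NU = 0.5
DEFAULT_PROBE_STIFFNESS = 0.027  # N/m


@dataclass
class HertzFit:
    E: float                        # Pa
    contact_point: float            # μm offset applied to depths
    r_squared: float
    depth_range: tuple[float, float]  # μm, re-zeroed fit range
    reliable: bool = True


def find_contact_point(curve: pd.DataFrame, baseline_fraction: float = 0.15,
                       persistence: int = 5) -> float:
    """Depth offset (μm) where the load leaves the pre-contact baseline.

    Baseline statistics come from the first ``baseline_fraction`` of the
    samples; contact is the first depth where the load exceeds
    mean + 3·sd for ``persistence`` consecutive samples. A curve already
    in contact at its start returns 0 with a warning; a curve that never
    leaves its baseline (pure noise) is an error.
    """
    z = curve["depth_um"].to_numpy(float)
    F = curve["load_uN"].to_numpy(float)
    n = len(z)
    if n < 3 * persistence:
        raise ValueError("curve too short for contact detection")
    nb = max(int(baseline_fraction * n), persistence)
    base = F[:nb]
    eps = 1e-9 * max(np.abs(F).max(), 1e-30)
    # a "baseline" that rises well beyond its own scatter means the probe
    # was already in contact at the first sample
    slope, icpt = np.polyfit(z[:nb], base, 1)
    rise = slope * (z[nb - 1] - z[0])
    resid_sd = float(np.std(base - (slope * z[:nb] + icpt)))
    if rise > 3.0 * max(resid_sd, eps):
        warnings.warn("curve starts in contact; offset set to 0", stacklevel=2)
        return 0.0
    thr = base.mean() + 3.0 * max(base.std(), eps)

    above = F > thr
    idx = None
    for i in range(n - persistence + 1):
        if above[i:i + persistence].all():
            idx = i
            break
    if idx is None or F.max() < base.mean() + 5.0 * max(base.std(), 1e-30):
        raise ValueError("no contact detected: load never leaves the baseline")
    if idx == 0:
        warnings.warn("curve starts in contact; offset set to 0", stacklevel=2)
        return 0.0
    return float(z[idx - 1])


def fit_hertz(curve: pd.DataFrame, depth_fraction: float = 1.0,
              R: float = DEFAULT_R, nu: float = DEFAULT_NU,
              contact_offset: float | None = None,
              correct_compliance: bool = False,
              probe_stiffness: float = DEFAULT_PROBE_STIFFNESS,
              min_points: int = 10) -> HertzFit:
    """Effective Young's modulus from a loading curve.

    ``contact_offset`` (μm) re-zeroes the depth axis; None runs
    :func:`find_contact_point` first. The fit covers the loading segment
    up to ``depth_fraction`` of the maximum re-zeroed depth and is linear
    in F vs δ^{3/2}, so it is exact on noiseless Hertzian data. Fits with
    non-positive E or R² < 0.8 are flagged unreliable with a warning.
    """
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must be in (0, 1]")
    z = curve["depth_um"].to_numpy(float)
    F = curve["load_uN"].to_numpy(float)
    if contact_offset is None:
        contact_offset = find_contact_point(curve)
    delta = z - contact_offset
    if correct_compliance:
        # piezo travel minus cantilever deflection: δ = z − F/k
        delta = delta - (F * 1e-6) / probe_stiffness * 1e6
    sel = delta > 0
    delta, Fs = delta[sel], F[sel]
    if len(delta) and depth_fraction < 1:
        sel2 = delta <= depth_fraction * delta.max()
        delta, Fs = delta[sel2], Fs[sel2]
    if len(delta) < min_points:
        raise ValueError(f"insufficient points in fit range "
                         f"({len(delta)} < {min_points})")

    x = delta**1.5               # μm^{3/2}
    a = float(np.sum(Fs * x) / np.sum(x * x))   # μN/μm^{3/2}
    pred = a * x
    ss_res = float(np.sum((Fs - pred) ** 2))
    ss_tot = float(np.sum((Fs - Fs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # a [μN/μm^{3/2}] → SI [N/m^{3/2}]: 1e-6 / (1e-6)^{3/2} = 1e3
    E = 0.75 * (a * 1e3) * (1 - nu**2) / np.sqrt(R * 1e-6)
    reliable = E > 0 and r2 >= 0.8
    if not reliable:
        warnings.warn(f"unreliable Hertz fit: E = {E:.3g} Pa, R² = {r2:.3f}",
                      stacklevel=2)
    return HertzFit(E=float(E), contact_point=float(contact_offset),
                    r_squared=r2, depth_range=(float(delta.min()),
                                               float(delta.max())),
                    reliable=reliable)
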