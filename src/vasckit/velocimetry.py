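"""Flow velocimetry: bleach-spot centroid drift, bead tracking, pressure decay.

Interstitial velocities (~0.1–1.5 μm/s) are measured from the drift of a
bleached spot's intensity-deficit centroid; luminal velocities from
Laplacian-of-Gaussian bead detection plus greedy nearest-neighbor
linking with gap closing (the sparse, non-crossing regime of tracer-bead
perfusion movies); hydraulic decay constants from a single-exponential
fit to reservoir pressure-drop series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit

from .images import ImageStack, RasterImage


@dataclass
class Track:
    """One linked particle trajectory (times in s, positions in μm)."""

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track timestamps must be strictly increasing")

    @property
    def displacement(self) -> float:
        return float(np.hypot(self.xs[-1] - self.xs[0], self.ys[-1] - self.ys[0]))

    @property
    def path_length(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.xs), np.diff(self.ys))))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def mean_speed(self) -> float:
        return self.path_length / self.duration if self.duration > 0 else 0.0


@dataclass
class DriftResult:
    speed: float                     # μm/s
    velocity: tuple[float, float]    # (vx, vy) μm/s
    times: np.ndarray                # s (post-bleach)
    centroids: np.ndarray            # (n, 2) μm
    r_squared: float


@dataclass
class DecayFit:
    dP0: float        # mmH2O
    tau: float        # hours
    residual: float   # RMS, mmH2O
    decaying: bool = True


# ---------------------------------------------------------------------------
# FRAP centroid-drift velocimetry

def estimate_if_velocity_frap(movie: ImageStack,
                              bleach_roi: tuple[float, float, float] | None = None,
                              n_prebleach: int | None = None,
                              min_frames: int = 5,
                              smooth_sigma: float = 2.0,
                              signal_gate: float = 15.0) -> DriftResult:
    """Interstitial flow speed from the drift of the bleached-spot centroid.

    The per-frame intensity deficit (mean pre-bleach frame minus current
    frame) is Gaussian-smoothed by ``smooth_sigma`` pixels — a symmetric
    kernel shifts no centroid but suppresses the shot-noise floor, which
    keeps the fading spot detectable late into the movie — then
    thresholded at 3× the (smoothed) pre-bleach noise sd and its weighted
    centroid tracked; speed is the magnitude of the linear displacement
    slope. Frames whose deficit falls below the noise floor are dropped;
    fewer than ``min_frames`` usable frames is an error.

    ``bleach_roi`` is (cx μm, cy μm, radius μm) and defaults to metadata;
    it seeds the first centroid window. Each frame's centroid is iterated
    mean-shift style inside a window centered on itself, so the estimate
    stays unbiased when the spreading deficit tail reaches the field edge
    (the window truncates it symmetrically).
    """
    meta = movie.meta
    if n_prebleach is None:
        n_prebleach = int(meta.get("n_prebleach", 1))
    if bleach_roi is None:
        c = meta.get("bleach_center_um")
        r = meta.get("spot_radius_um")
        bleach_roi = (c[0], c[1], r) if c is not None and r is not None else None
    if n_prebleach < 1:
        raise ValueError("need at least one pre-bleach frame")

    def smooth(a):
        return ndi.gaussian_filter(a, smooth_sigma) if smooth_sigma > 0 else a

    pre = np.stack([smooth(f) for f in movie.frames[:n_prebleach]])
    ref = pre.mean(axis=0)
    noise_sd = float(np.std(pre - ref)) if n_prebleach > 1 \
        else float(np.std(np.diff(ref, axis=1))) / np.sqrt(2)
    post = movie.frames[n_prebleach:]
    times = movie.times[n_prebleach:]

    px = movie.pixel_size
    ny, nx = ref.shape
    xs = np.arange(nx) * px
    ys = np.arange(ny) * px
    xx, yy = np.meshgrid(xs, ys)

    if bleach_roi is not None:
        cur = np.array([bleach_roi[0], bleach_roi[1]])
        win = max(2.5 * bleach_roi[2], 25.0)
    else:
        cur, win = None, max(0.15 * min(nx * px, ny * px), 25.0)

    cents, used_t, masses = [], [], []
    thr = 3.0 * noise_sd
    # detection needs the peak deficit to clear both the expected extreme
    # of the noise field and a contrast gate: frames where the washed-out
    # spot barely tops the noise floor contribute bias (the static
    # reference-noise pattern masquerades as deficit), so they are dropped
    detect_thr = noise_sd * max(3.0 + np.sqrt(2.0 * np.log(ref.size)),
                                signal_gate)
    for f, t in zip(post, times):
        deficit = ref - smooth(f)
        deficit = np.where(deficit > thr, deficit, 0.0)
        if deficit.sum() <= 0 or deficit.max() < max(detect_thr, 1e-12):
            continue
        if cur is None:  # seed from the full-field centroid once
            mass = deficit.sum()
            cur = np.array([(deficit * xx).sum() / mass,
                            (deficit * yy).sum() / mass])
        c = cur.copy()
        ok = True
        for _ in range(8):
            sel = np.hypot(xx - c[0], yy - c[1]) <= win
            mass = deficit[sel].sum()
            if mass <= 0:
                ok = False
                break
            new = np.array([(deficit * sel * xx).sum() / mass,
                            (deficit * sel * yy).sum() / mass])
            if np.hypot(*(new - c)) < 0.01 * px:
                c = new
                break
            c = new
        if not ok:
            continue
        cur = c
        cents.append((float(c[0]), float(c[1])))
        used_t.append(t)
        masses.append(float(mass))
    if len(cents) < min_frames:
        raise ValueError(
            f"bleached region detectable in only {len(cents)} frames "
            f"(deficit below 3× background sd)")
    cents = np.array(cents)
    used_t = np.array(used_t)
    # the centroid sd of frame k scales as 1/mass_k, so weight the linear
    # fit by mass² — late, washed-out frames contribute almost nothing
    w = np.array(masses) ** 2

    vx, x0 = np.polyfit(used_t, cents[:, 0], 1, w=np.sqrt(w))
    vy, y0 = np.polyfit(used_t, cents[:, 1], 1, w=np.sqrt(w))
    pred = np.column_stack([x0 + vx * used_t, y0 + vy * used_t])
    ss_res = float(np.sum((cents - pred) ** 2))
    ss_tot = float(np.sum((cents - cents.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DriftResult(speed=float(np.hypot(vx, vy)), velocity=(float(vx), float(vy)),
                       times=used_t, centroids=cents, r_squared=r2)


# ---------------------------------------------------------------------------
# bead detection and linking

def detect_beads(frame: RasterImage, blob_diameter: float = 5.0,
                 intensity_threshold: float = 2.0) -> np.ndarray:
    """Laplacian-of-Gaussian blob detection with subpixel centers.

    The scale-normalized LoG response (−σ²·∇²G⊛I at σ = blob_diameter/2
    converted to pixels) is searched for local maxima above
    ``intensity_threshold`` AU; centers are refined by per-axis quadratic
    interpolation. Returns an (n, 3) array of (x μm, y μm, response AU);
    an empty frame gives an empty array.
    """
    px = frame.pixel_size
    sigma = (blob_diameter / 2.0) / px / np.sqrt(2.0)  # matched LoG scale, px
    img = np.asarray(frame.pixels, float)
    resp = -(sigma**2) * ndi.gaussian_laplace(img, sigma)
    maxed = ndi.maximum_filter(resp, size=3, mode="nearest")
    peaks = (resp == maxed) & (resp > intensity_threshold)
    # suppress plateau duplicates
    rows, cols = np.nonzero(peaks)
    out = []
    ny, nx = img.shape
    for r, c in zip(rows, cols):
        dr = dc = 0.0
        if 0 < r < ny - 1:
            denom = resp[r - 1, c] - 2 * resp[r, c] + resp[r + 1, c]
            if denom < 0:
                dr = 0.5 * (resp[r - 1, c] - resp[r + 1, c]) / denom
        if 0 < c < nx - 1:
            denom = resp[r, c - 1] - 2 * resp[r, c] + resp[r, c + 1]
            if denom < 0:
                dc = 0.5 * (resp[r, c - 1] - resp[r, c + 1]) / denom
        dr = float(np.clip(dr, -0.5, 0.5))
        dc = float(np.clip(dc, -0.5, 0.5))
        out.append(((c + dc) * px, (r + dr) * px, resp[r, c]))
    if not out:
        return np.empty((0, 3))
    return np.array(sorted(out, key=lambda s: (s[0], s[1])))


def link_tracks(spots_per_frame: list[np.ndarray], times: np.ndarray,
                max_link: float = 15.0, max_gap_frames: int = 2,
                min_displacement: float = 5.0) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking with gap closing.

    Candidate (track, spot) pairs within ``max_link`` μm are assigned in
    order of increasing distance (ties broken by coordinates, so linking
    is independent of spot-list order); a track missing from up to
    ``max_gap_frames`` consecutive frames can be re-linked at the same
    radius. Tracks with net displacement below ``min_displacement`` μm
    are discarded (nonmoving-object filter).
    """
    if len(spots_per_frame) < 2:
        raise ValueError("need at least 2 frames to link")
    times = np.asarray(times, float)
    active: list[dict] = []
    done: list[dict] = []
    for fi, spots in enumerate(spots_per_frame):
        spots = np.asarray(spots, float).reshape(-1, spots.shape[-1] if np.ndim(spots) == 2 else 3)
        pairs = []
        for ti, tr in enumerate(active):
            if fi - tr["last_frame"] > max_gap_frames + 1:
                continue
            for si in range(len(spots)):
                d = float(np.hypot(spots[si, 0] - tr["xs"][-1],
                                   spots[si, 1] - tr["ys"][-1]))
                if d <= max_link:
                    pairs.append((d, spots[si, 0], spots[si, 1],
                                  tr["xs"][-1], tr["ys"][-1], ti, si))
        taken_t: set[int] = set()
        taken_s: set[int] = set()
        for d, sx, sy, tx, ty, ti, si in sorted(pairs, key=lambda p: p[:5]):
            if ti in taken_t or si in taken_s:
                continue
            taken_t.add(ti)
            taken_s.add(si)
            tr = active[ti]
            tr["ts"].append(times[fi])
            tr["xs"].append(float(sx))
            tr["ys"].append(float(sy))
            tr["last_frame"] = fi
        for si in range(len(spots)):
            if si not in taken_s:
                active.append({"ts": [times[fi]], "xs": [float(spots[si, 0])],
                               "ys": [float(spots[si, 1])], "last_frame": fi})
        still = []
        for tr in active:
            if fi - tr["last_frame"] > max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    tracks = []
    for tr in done:
        if len(tr["ts"]) < 2:
            continue
        t = Track(np.array(tr["ts"]), np.array(tr["xs"]), np.array(tr["ys"]))
        if t.displacement >= min_displacement:
            tracks.append(t)
    tracks.sort(key=lambda t: (t.times[0], t.xs[0], t.ys[0]))
    return tracks


def track_bead_movie(movie: ImageStack, blob_diameter: float = 5.0,
                     intensity_threshold: float = 2.0, max_link: float = 15.0,
                     max_gap_frames: int = 2,
                     min_displacement: float = 5.0) -> list[Track]:
    """Detect-and-link convenience wrapper over a whole movie."""
    spots = [detect_beads(movie.frame(i), blob_diameter, intensity_threshold)
             for i in range(movie.n_frames)]
    return link_tracks(spots, movie.times, max_link, max_gap_frames,
                       min_displacement)


def mean_bead_speed(tracks: list[Track]) -> float:
    """Mean of per-track mean speeds (μm/s); NaN with no tracks."""
    if not tracks:
        return float("nan")
    return float(np.mean([t.mean_speed for t in tracks]))


# ---------------------------------------------------------------------------
# reservoir pressure decay

def fit_pressure_decay(series: pd.DataFrame | tuple[np.ndarray, np.ndarray]) -> DecayFit:
    """Single-exponential fit ΔP(t) = dP0·exp(−t/τ) to a pressure series.

    Accepts a DataFrame with columns ``t_hours``/``dP_mmH2O`` or a
    (t, dP) tuple. τ is a descriptive hydraulic relaxation constant
    (resistance × reservoir capacitance). A series that does not decay is
    flagged (``decaying=False``) rather than rejected.
    """
    if isinstance(series, pd.DataFrame):
        t = series["t_hours"].to_numpy(float)
        dP = series["dP_mmH2O"].to_numpy(float)
    else:
        t, dP = (np.asarray(a, float) for a in series)
    if t.size < 4:
        raise ValueError("need at least 4 samples")
    if np.any(dP <= 0):
        raise ValueError("pressure values must be positive")

    # log-linear seed, then nonlinear refinement
    b, a = np.polyfit(t, np.log(dP), 1)
    decaying = b < 0
    p0 = [float(np.exp(a)), float(-1.0 / b) if decaying else float(t[-1] * 10)]

    def model(t, dp0, tau):
        return dp0 * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(model, t, dP, p0=p0, maxfev=10000,
                            bounds=([0, 1e-9], [np.inf, np.inf]))
        dp0, tau = float(popt[0]), float(popt[1])
        resid = float(np.sqrt(np.mean((dP - model(t, *popt)) ** 2)))
    except RuntimeError:
        dp0, tau, resid = p0[0], p0[1], float("inf")
    # non-decaying when the fitted time constant exceeds the record many-fold
    if tau > 50 * (t[-1] - t[0]):
        decaying = False
    return DecayFit(dP0=dp0, tau=tau, residual=resid, decaying=decaying)
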