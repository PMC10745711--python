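"""Synthetic fixtures with known ground truth for every assay in the toolkit.

Each generator emulates one experimental readout of a microvessel-on-chip
culture — vessel-reporter images, dye-leakage time lapses, FRAP movies,
bead perfusion movies, nanoindentation load–depth curves, reservoir
pressure decays — and attaches a :class:`SyntheticTruth` carrying the
parameters used, so the paired estimator can be tested closed-loop.

Determinism: every stochastic generator takes a seed and is bit-reproducible
for the same seed and parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .images import ImageStack, RasterImage

# Default imaging calibration: 0.64 μm/pixel, the bead-tracking camera
# resolution; all generators accept an override.
DEFAULT_PIXEL_SIZE = 0.64

TRUTH_KINDS = ("network", "permeability", "frap", "beads", "indentation", "decay")


@dataclass
class SyntheticTruth:
    """Ground-truth parameter record attached to every generated fixture."""

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in TRUTH_KINDS:
            raise ValueError(f"unknown truth kind {self.kind!r}")

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(
            {"kind": self.kind, "params": self.params}, default=_default, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["kind"], d["params"])


@dataclass
class SyntheticNetworkSpec:
    """Parameters of a random planar vessel network.

    Widths are drawn per branch from N(width_mean, width_sd) and clipped
    so every stroke stays rasterizable. The default width scale matches
    mature on-chip lumens (~40 μm diameter).
    """

    seed: int = 0
    domain_size: tuple[float, float] = (500.0, 500.0)  # (width, height) μm
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_nodes: int = 12
    width_mean: float = 40.0
    width_sd: float = 4.0
    target_coverage: float | None = None

    def validate(self) -> None:
        w, h = self.domain_size
        if min(w, h) < 100:
            raise ValueError("domain must be at least 100 μm per side")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not self.width_mean > 2 * self.pixel_size:
            raise ValueError("width_mean must exceed 2 pixels")
        margin = self.width_mean
        if 2 * margin >= min(w, h):
            raise ValueError("strokes cannot fit the domain at this width")
        if self.target_coverage is not None and not 0 < self.target_coverage < 1:
            raise ValueError("target_coverage must be a fraction in (0,1)")


# ---------------------------------------------------------------------------
# geometry helpers

def _relative_neighborhood_edges(points: np.ndarray) -> list[tuple[int, int]]:
    """Relative-neighborhood graph edges (subset of the Delaunay graph).

    Edge (p, q) survives iff no third point r satisfies
    max(d(p,r), d(q,r)) < d(p,q) — the classic 'lune empty' rule, which
    yields sparse, loopy, biologically plausible planar networks.
    """
    n = len(points)
    if n == 2:
        return [(0, 1)]
    cand: set[tuple[int, int]] = set()
    try:
        tri = Delaunay(points)
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                cand.add((i, j))
    except Exception:  # degenerate (collinear) point sets
        cand = {(i, j) for i in range(n) for j in range(i + 1, n)}
    d = np.linalg.norm(points[:, None] - points[None], axis=-1)
    edges = []
    for i, j in sorted(cand):
        dij = d[i, j]
        ok = True
        for r in range(n):
            if r != i and r != j and max(d[i, r], d[j, r]) < dij:
                ok = False
                break
        if ok:
            edges.append((i, j))
    return edges


def rasterize_strokes(segments, widths, domain_size, pixel_size,
                      cap_style: str = "round") -> RasterImage:
    """Union of constant-width strokes → binary mask.

    A pixel belongs to the mask iff its *center* lies within width/2 of a
    stroke centerline (no anti-aliasing), which keeps area and length
    analytically checkable. ``cap_style='round'`` (default) measures
    distance to the segment (stadium shape); ``'butt'`` clips to the
    segment's perpendicular band half-open on one side, so an
    axis-aligned bar of length L and width w covers exactly L·w.

    Pixel centers sit at (col·pixel_size, row·pixel_size), origin at the
    top-left pixel center.
    """
    w_um, h_um = domain_size
    nx = int(round(w_um / pixel_size))
    ny = int(round(h_um / pixel_size))
    mask = np.zeros((ny, nx), dtype=bool)
    for (p, q), width in zip(segments, widths):
        p = np.asarray(p, float)
        q = np.asarray(q, float)
        r = width / 2.0
        lo = np.minimum(p, q) - r - pixel_size
        hi = np.maximum(p, q) + r + pixel_size
        c0 = max(int(np.floor(lo[0] / pixel_size)), 0)
        c1 = min(int(np.ceil(hi[0] / pixel_size)) + 1, nx)
        r0 = max(int(np.floor(lo[1] / pixel_size)), 0)
        r1 = min(int(np.ceil(hi[1] / pixel_size)) + 1, ny)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = np.arange(c0, c1) * pixel_size
        ys = np.arange(r0, r1) * pixel_size
        xx, yy = np.meshgrid(xs, ys)
        d = q - p
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.hypot(xx - p[0], yy - p[1])
            inside = dist <= r
        else:
            t = ((xx - p[0]) * d[0] + (yy - p[1]) * d[1]) / L2
            tc = np.clip(t, 0.0, 1.0)
            dist = np.hypot(xx - (p[0] + tc * d[0]), yy - (p[1] + tc * d[1]))
            if cap_style == "butt":
                L = np.sqrt(L2)
                perp = ((xx - p[0]) * (-d[1]) + (yy - p[1]) * d[0]) / L
                inside = (perp >= -r) & (perp < r) & (t >= 0.0) & (t < 1.0)
            else:
                inside = dist <= r
        mask[r0:r1, c0:c1] |= inside
    return RasterImage(mask, pixel_size)


def bar_mask(length: float, width: float, pixel_size: float = 1.0,
             pad: float = 20.0) -> RasterImage:
    """Axis-aligned rectangular bar (flat caps): area = length·width."""
    seg = [((pad, pad + width / 2), (pad + length, pad + width / 2))]
    return rasterize_strokes(seg, [width],
                             (length + 2 * pad, width + 2 * pad),
                             pixel_size, cap_style="butt")


def h_mask(height: float = 400.0, span: float = 200.0, width: float = 20.0,
           pixel_size: float = 1.0, pad: float = 30.0) -> RasterImage:
    """H-shaped fixture: two verticals plus a crossbar.

    By construction: 2 junctions, 4 endpoints, 5 branches.
    """
    x1, x2 = pad, pad + span
    y0, y1 = pad, pad + height
    ym = (y0 + y1) / 2
    segs = [((x1, y0), (x1, y1)), ((x2, y0), (x2, y1)), ((x1, ym), (x2, ym))]
    return rasterize_strokes(segs, [width] * 3,
                             (span + 2 * pad, height + 2 * pad), pixel_size)


# ---------------------------------------------------------------------------
# generators

def generate_vessel_network(spec: SyntheticNetworkSpec) -> tuple[RasterImage, SyntheticTruth]:
    """Random branched vessel-bed mask with per-branch width ground truth.

    Nodes are seeded uniformly (with a dart-throwing minimum spacing),
    connected by the relative-neighborhood rule, and the largest connected
    component is stroked at constant width per branch.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.domain_size
    margin = spec.width_mean
    min_sep = max((min(w_um, h_um) - 2 * margin) / max(spec.n_nodes ** 0.5, 2.0),
                  2 * spec.pixel_size)
    pts: list[np.ndarray] = []
    for _ in range(spec.n_nodes * 50):
        if len(pts) == spec.n_nodes:
            break
        p = rng.uniform([margin, margin], [w_um - margin, h_um - margin])
        if not pts or cKDTree(np.array(pts)).query(p)[0] >= min_sep:
            pts.append(p)
    points = np.array(pts)
    if len(points) < 2:
        raise ValueError("could not place nodes in the domain")

    edges = _relative_neighborhood_edges(points)
    # keep largest connected component
    import networkx as nx
    g = nx.Graph(edges)
    g.add_nodes_from(range(len(points)))
    comp = max(nx.connected_components(g), key=len)
    edges = [(i, j) for i, j in edges if i in comp]
    if not edges:
        raise ValueError("network generation produced no edges")

    widths = rng.normal(spec.width_mean, spec.width_sd, size=len(edges))
    widths = np.clip(widths, 2.2 * spec.pixel_size, None)
    segments = [(points[i], points[j]) for i, j in edges]

    mask = rasterize_strokes(segments, widths, spec.domain_size, spec.pixel_size)
    if spec.target_coverage is not None:
        for _ in range(6):
            cov = mask.pixels.mean()
            if abs(cov - spec.target_coverage) / spec.target_coverage < 0.02:
                break
            widths = np.clip(widths * spec.target_coverage / max(cov, 1e-9),
                             2.2 * spec.pixel_size, min(w_um, h_um) / 3)
            mask = rasterize_strokes(segments, widths, spec.domain_size,
                                     spec.pixel_size)

    deg = np.zeros(len(points), int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    used = sorted({i for e in edges for i in e})
    lengths = [float(np.linalg.norm(points[j] - points[i])) for i, j in edges]
    truth = SyntheticTruth("network", {
        "seed": spec.seed,
        "branch_widths_um": [float(w) for w in widths],
        "branch_lengths_um": lengths,
        "total_length_um": float(np.sum(lengths)),
        "n_junctions": int(np.sum(deg[used] >= 3)),
        "n_endpoints": int(np.sum(deg[used] == 1)),
        "area_coverage": float(mask.pixels.mean()),
        "width_mean_um": float(np.mean(widths)),
        "nodes_um": points[used].tolist(),
    })
    return mask, truth


def _poissonish(rng: np.random.Generator, signal: np.ndarray,
                noise_scale: float) -> np.ndarray:
    """Poisson-like read noise: variance proportional to the signal."""
    if noise_scale == 0:
        return signal
    return signal + noise_scale * np.sqrt(np.clip(signal, 0, None)) * \
        rng.standard_normal(signal.shape)


def render_fluorescence(mask: RasterImage, blur_sigma: float = 1.0,
                        background: float = 10.0, noise_scale: float = 1.0,
                        amplitude: float = 100.0, seed: int = 0) -> RasterImage:
    """Render a binary mask as a fluorescence-like intensity image.

    intensity = background + amplitude·(mask ⊛ Gaussian(blur_sigma μm))
    plus Poisson-like noise scaled by ``noise_scale``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    from scipy.ndimage import gaussian_filter
    sig = np.asarray(mask.as_bool(), float)
    if blur_sigma > 0:
        sig = gaussian_filter(sig, blur_sigma / mask.pixel_size)
    img = background + amplitude * sig
    img = _poissonish(np.random.default_rng(seed), img, noise_scale)
    return RasterImage(img, mask.pixel_size)


def simulate_permeability_stack(mask: RasterImage, P_true: float,
                                d_eff: float | None = None,
                                frame_interval: float = 300.0,
                                n_frames: int = 4,
                                I1: float = 100.0, I0: float = 5.0,
                                band_width: float = 30.0,
                                noise_scale: float = 0.0,
                                seed: int = 0) -> tuple[ImageStack, SyntheticTruth]:
    """Dye-leakage time lapse across a vessel wall of known permeability.

    The intravascular signal stays at ``I1`` while dye accumulates in a
    perivascular band. Treating each branch as a cylinder of diameter
    ``d_eff``, the background-subtracted image intensity integrated over
    the field grows at rate

        dΣ/dt = 4 · (A_v / d_eff) · (I1 − I0) · P,

    which is the image-domain form of the wall flux J = P·S·ΔC for a
    cylinder (S/V = 4/d) rendered at uniform luminal intensity. P_true is
    in cm/s; 70-kDa dextran assays sit near 1e-6 cm/s.
    """
    if P_true < 0:
        raise ValueError("P_true must be non-negative")
    from scipy.ndimage import binary_dilation

    m = mask.as_bool()
    px = mask.pixel_size
    if d_eff is None:
        from .morphometry import skeletonize_network
        graph = skeletonize_network(mask)
        d_eff = m.sum() * px**2 / graph.total_length
    A_v = m.sum() * px**2  # μm²
    L_eq = A_v / d_eff     # centerline length consistent with d_eff, μm
    P_um = P_true * 1e4    # cm/s → μm/s
    rate_total = 4.0 * L_eq * (I1 - I0) * P_um  # AU·μm²/s

    it = int(np.ceil(band_width / px))
    band = binary_dilation(m, iterations=max(it, 1)) & ~m
    n_band = int(band.sum())
    if n_band == 0:
        raise ValueError("mask leaves no extravascular band in the field")
    per_pixel_rate = rate_total / (n_band * px**2)  # AU/s per band pixel

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * float(frame_interval)
    frames = np.empty((n_frames, *m.shape), float)
    for k, t in enumerate(times):
        f = np.full(m.shape, float(I0))
        f[m] = I1
        f[band] += per_pixel_rate * t
        frames[k] = _poissonish(rng, f, noise_scale)
    truth = SyntheticTruth("permeability", {
        "P_true_cm_s": float(P_true), "d_eff_um": float(d_eff),
        "I1": I1, "I0": I0, "band_width_um": band_width,
        "frame_interval_s": frame_interval,
    })
    stack = ImageStack(frames, px, times,
                       meta={"assay": "permeability", "d_eff_um": float(d_eff)})
    return stack, truth


def simulate_frap(D_true: float, v_true: float = 0.0,
                  spot_diameter: float = 30.0, frame_interval: float = 0.4,
                  n_frames: int = 100, noise_scale: float = 0.0,
                  pixel_size: float = DEFAULT_PIXEL_SIZE,
                  field_size: tuple[int, int] = (256, 256),
                  bleach_depth: float = 0.8, I_pre: float = 100.0,
                  n_prebleach: int = 10, drift_angle: float = 0.0,
                  seed: int = 0) -> tuple[ImageStack, SyntheticTruth]:
    """Bleach-spot recovery movie under known diffusion and uniform drift.

    The post-bleach frames are the exact advection–diffusion evolution of
    a uniform-disc bleach profile: the intensity deficit is convolved with
    a Gaussian kernel of variance 2·D·t, shifted by v·t, evaluated
    spectrally on a zero-padded grid (no PDE time stepping, so the movie
    doubles as its own oracle). Defaults mirror a 30-μm-Ø bleach imaged
    every 0.4 s.
    """
    if not D_true > 0:
        raise ValueError("D_true must be positive")
    if v_true < 0:
        raise ValueError("v_true must be non-negative")
    w = spot_diameter / 2.0
    t_half = 0.224 * w**2 / D_true  # disc-FRAP half time
    if t_half < 2 * frame_interval:
        warnings.warn("frame interval too coarse to resolve recovery "
                      f"(t_half = {t_half:.3g} s)", stacklevel=2)

    ny, nx = field_size
    cx = (nx // 2) * pixel_size
    cy = (ny // 2) * pixel_size
    xs = np.arange(nx) * pixel_size
    ys = np.arange(ny) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    disc = np.hypot(xx - cx, yy - cy) <= w
    deficit0 = bleach_depth * I_pre * disc.astype(float)

    # zero-padded spectral propagator: exact for free diffusion + drift
    pad_y, pad_x = ny, nx
    big = np.zeros((ny + 2 * pad_y, nx + 2 * pad_x))
    big[pad_y:pad_y + ny, pad_x:pad_x + nx] = deficit0
    F0 = np.fft.fft2(big)
    ky = 2 * np.pi * np.fft.fftfreq(big.shape[0], d=pixel_size)
    kx = 2 * np.pi * np.fft.fftfreq(big.shape[1], d=pixel_size)
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    vx = v_true * np.cos(drift_angle)
    vy = v_true * np.sin(drift_angle)

    rng = np.random.default_rng(seed)
    times = np.concatenate([
        -frame_interval * np.arange(n_prebleach, 0, -1),
        np.arange(n_frames) * float(frame_interval),
    ])
    frames = np.empty((n_prebleach + n_frames, ny, nx))
    for i in range(n_prebleach):
        frames[i] = _poissonish(rng, np.full((ny, nx), I_pre), noise_scale)
    for k in range(n_frames):
        t = k * frame_interval
        if t == 0:
            d = deficit0
        else:
            prop = np.exp(-k2 * D_true * t - 1j * (KX * vx + KY * vy) * t)
            d = np.real(np.fft.ifft2(F0 * prop))[pad_y:pad_y + ny,
                                                 pad_x:pad_x + nx]
        frames[n_prebleach + k] = _poissonish(rng, I_pre - d, noise_scale)

    truth = SyntheticTruth("frap", {
        "D_true_um2_s": float(D_true), "v_true_um_s": float(v_true),
        "spot_radius_um": float(w), "bleach_depth": bleach_depth,
        "I_pre": I_pre, "drift_angle": drift_angle,
    })
    stack = ImageStack(frames, pixel_size, times, meta={
        "assay": "frap", "n_prebleach": n_prebleach,
        "bleach_center_um": (cx, cy), "spot_radius_um": float(w),
    })
    return stack, truth


def simulate_bead_movie(v_mean: float, n_beads: int = 10,
                        bead_diameter: float = 2.0, frame_rate: float = 16.67,
                        n_frames: int = 40, seed: int = 0,
                        pixel_size: float = DEFAULT_PIXEL_SIZE,
                        field_size: tuple[int, int] = (192, 320),
                        v_sd_frac: float = 0.05, amplitude: float = 10.0,
                        background: float = 0.2,
                        noise_scale: float = 0.0,
                        max_link: float = 15.0) -> tuple[ImageStack, SyntheticTruth]:
    """Movie of fluorescent tracer beads advected along +x.

    Per-bead speeds are drawn around ``v_mean``; beads occupy separated
    y-lanes so tracks never cross (the regime the greedy linker targets).
    Defaults mirror 2-μm beads imaged at 0.64 μm/pixel and ~16.7 Hz.
    """
    dt = 1.0 / frame_rate
    if v_mean * dt >= max_link:
        raise ValueError("frame rate does not resolve motion: per-frame "
                         f"displacement {v_mean * dt:.1f} μm ≥ link radius")
    rng = np.random.default_rng(seed)
    ny, nx = field_size
    Lx = nx * pixel_size
    Ly = ny * pixel_size
    T = (n_frames - 1) * dt
    sigma = bead_diameter / 2.0  # μm, rendered blob scale

    lane_gap = max(2.5 * bead_diameter, Ly / (n_beads + 1))
    ys0 = lane_gap * (np.arange(n_beads) + 0.7)
    ys0 = ys0[ys0 < Ly - 2 * bead_diameter]
    n_beads = len(ys0)
    speeds = np.abs(rng.normal(v_mean, v_sd_frac * max(v_mean, 1e-12), n_beads)) \
        if v_mean > 0 else np.zeros(n_beads)
    travel = speeds * T
    x0_hi = np.clip(Lx - travel - 4 * bead_diameter, 4 * bead_diameter + 1e-6, None)
    xs0 = rng.uniform(4 * bead_diameter, x0_hi)

    xs_grid = np.arange(nx) * pixel_size
    ys_grid = np.arange(ny) * pixel_size
    frames = np.empty((n_frames, ny, nx))
    tracks = []
    times = np.arange(n_frames) * dt
    pos_x = np.empty((n_beads, n_frames))
    for b in range(n_beads):
        pos_x[b] = xs0[b] + speeds[b] * times
        tracks.append({"t_s": times.tolist(),
                       "x_um": pos_x[b].tolist(),
                       "y_um": [float(ys0[b])] * n_frames})
    for k in range(n_frames):
        f = np.full((ny, nx), background)
        for b in range(n_beads):
            xb, yb = pos_x[b, k], ys0[b]
            c0 = max(int((xb - 5 * sigma) / pixel_size), 0)
            c1 = min(int((xb + 5 * sigma) / pixel_size) + 2, nx)
            r0 = max(int((yb - 5 * sigma) / pixel_size), 0)
            r1 = min(int((yb + 5 * sigma) / pixel_size) + 2, ny)
            if c0 >= c1 or r0 >= r1:
                continue
            gx = np.exp(-((xs_grid[c0:c1] - xb) ** 2) / (2 * sigma**2))
            gy = np.exp(-((ys_grid[r0:r1] - yb) ** 2) / (2 * sigma**2))
            f[r0:r1, c0:c1] += amplitude * gy[:, None] * gx[None, :]
        frames[k] = _poissonish(rng, f, noise_scale)
    truth = SyntheticTruth("beads", {
        "v_mean_um_s": float(v_mean), "speeds_um_s": speeds.tolist(),
        "mean_speed_um_s": float(speeds.mean()) if n_beads else 0.0,
        "bead_diameter_um": bead_diameter, "tracks": tracks,
    })
    stack = ImageStack(frames, pixel_size, times,
                       meta={"assay": "beads", "frame_rate_hz": frame_rate})
    return stack, truth


def simulate_indentation(E_true: float, R: float = 25.0, nu: float = 0.5,
                         max_depth: float = 12.0, noise_scale: float = 0.0,
                         precontact: float = 2.0, n_points: int = 240,
                         probe_stiffness: float = 0.027,
                         compliance: bool = False,
                         seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Hertzian spherical-indentation loading curve.

    F(δ) = (4/3)·E/(1−ν²)·√R·δ^{3/2} for δ past the contact point, with a
    flat pre-contact segment of length ``precontact`` and multiplicative
    noise of fractional scale ``noise_scale``. Depths in μm, loads in μN.
    With ``compliance=True`` the depth column is the raw piezo travel
    δ_piezo = δ_sample + F/k_probe (k_probe in N/m).
    """
    if not 0 < nu <= 0.5:
        raise ValueError("Poisson ratio must be in (0, 0.5]")
    if not E_true > 0 or not R > 0:
        raise ValueError("E_true and R must be positive")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, precontact + max_depth, n_points)  # μm
    delta = np.clip(z - precontact, 0.0, None)
    # SI: Pa · m^{1/2} · m^{3/2} = N; report μN
    F = (4.0 / 3.0) * (E_true / (1 - nu**2)) * np.sqrt(R * 1e-6) \
        * (delta * 1e-6) ** 1.5 * 1e6
    if noise_scale > 0:
        F = F * (1 + noise_scale * rng.standard_normal(F.shape))
    if compliance:
        z = z + (F * 1e-6) / probe_stiffness * 1e6  # deflection in μm
    curve = pd.DataFrame({"depth_um": z, "load_uN": F})
    truth = SyntheticTruth("indentation", {
        "E_true_Pa": float(E_true), "R_um": R, "nu": nu,
        "contact_offset_um": precontact, "max_depth_um": max_depth,
        "probe_stiffness_N_m": probe_stiffness, "compliance": compliance,
    })
    return curve, truth


def simulate_pressure_decay(dP0: float = 7.0, tau: float = 24.0,
                            sample_interval: float = 4.0, n_samples: int = 24,
                            noise_scale: float = 0.0,
                            seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Reservoir pressure-drop decay ΔP(t) = dP0·exp(−t/tau).

    dP0 in mmH2O (7 mmH2O is the high-flow condition), tau and the
    sampling interval in hours (reservoirs are read every ~4 hours).
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * float(sample_interval)
    dP = dP0 * np.exp(-t / tau)
    if noise_scale > 0:
        dP = dP + noise_scale * dP0 * rng.standard_normal(t.shape)
    series = pd.DataFrame({"t_hours": t, "dP_mmH2O": dP})
    truth = SyntheticTruth("decay", {
        "dP0_mmH2O": float(dP0), "tau_hours": float(tau),
    })
    return series, truth
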