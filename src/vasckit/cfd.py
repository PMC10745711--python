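"""Steady Stokes–Brinkman flow on segmented microvessel masks.

The open lumen (cell-culture media) and the porous extravascular gel are
solved as one unified Brinkman problem on a 2D staggered (MAC) grid:

    ∇·u = 0
    −∇p + ∇·(μ(x)∇u) − χ_gel(x)·(μ_gel/k)·u = 0

with μ(x) the media viscosity in the lumen and the gel (Brinkman
effective) viscosity in the gel, k the hydraulic permeability, a
Dirichlet pressure drop between the left (inlet) and right (outlet)
edges, and no-slip top/bottom walls. Inertia is dropped (Stokes regime:
Re ≲ 1 at the device's velocities and scales), which makes the problem
linear in the applied pressure — scaling ΔP scales every velocity and
shear exactly.

In the gel the solution is the superficial (Darcy) velocity; the pore
velocity is superficial/porosity and region statistics report both.
The scalar shear stress is μ(x)·γ̇ with γ̇ = √(2 E:E) from the symmetric
strain-rate tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .images import RasterImage

LUMEN, GEL, WALL = 0, 1, 2


@dataclass
class CfdParams:
    """Physical parameters; defaults are the device's media/fibrin values."""

    media_density: float = 998.2      # kg/m³
    media_viscosity: float = 9.4e-4   # Pa·s
    gel_density: float = 985.0        # kg/m³
    gel_viscosity: float = 1e-2       # Pa·s (Brinkman effective viscosity)
    porosity: float = 0.3
    k: float = 1e-13                  # hydraulic permeability, m²
    dP: float = 70.0                  # Pa (7 mmH2O), inlet minus outlet
    channel_length: float = 3e-3      # m, device central channel

    def __post_init__(self) -> None:
        for name in ("media_density", "media_viscosity", "gel_density",
                     "gel_viscosity", "k", "channel_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "CfdParams":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class DomainGrid:
    labels: np.ndarray          # (ny, nx) of {LUMEN, GEL, WALL}
    cell_size: tuple[float, float]   # (dx, dy) μm

    def __post_init__(self) -> None:
        dx, dy = self.cell_size
        if not (dx > 0 and dy > 0):
            raise ValueError("cell sizes must be positive")
        fluid = self.labels != WALL
        if not fluid[:, 0].any() or not fluid[:, -1].any():
            raise ValueError("no inlet or outlet cells on the left/right edges")
        lab, _ = ndi.label(fluid)
        inlet_ids = set(np.unique(lab[:, 0])) - {0}
        outlet_ids = set(np.unique(lab[:, -1])) - {0}
        if not (inlet_ids & outlet_ids):
            raise ValueError("no inlet-to-outlet fluid path")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def length(self) -> float:
        """Physical inlet→outlet length, μm."""
        return self.labels.shape[1] * self.cell_size[0]


@dataclass
class FlowField:
    u: np.ndarray               # (ny, nx) cell-centered x-velocity, m/s
    v: np.ndarray               # (ny, nx) cell-centered y-velocity, m/s
    p: np.ndarray               # (ny, nx) pressure, Pa
    shear: np.ndarray           # (ny, nx) scalar shear stress, Pa
    divergence_residual: float  # max cell divergence / characteristic rate
    u_face: np.ndarray = field(repr=False, default=None)  # (ny, nx+1)
    v_face: np.ndarray = field(repr=False, default=None)  # (ny+1, nx)
    grid: DomainGrid = field(repr=False, default=None)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class RegionStats:
    """Mean ± sd of speed (mm/s) and shear (Pa) per region."""

    velocity: dict       # region → (mean, sd) mm/s, superficial in gel
    shear: dict          # region → (mean, sd) Pa
    gel_pore_velocity: tuple[float, float] | None = None  # mm/s, superficial/porosity

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in ("tissue", "vessel", "gel"):
            if region in self.velocity:
                rows.append({
                    "region": region,
                    "velocity_mean_mm_s": self.velocity[region][0],
                    "velocity_sd_mm_s": self.velocity[region][1],
                    "shear_mean_Pa": self.shear[region][0],
                    "shear_sd_Pa": self.shear[region][1],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def build_domains(vessel_mask: RasterImage, gel_extent=None,
                  coarsen_factor: int = 1) -> DomainGrid:
    """Label a binary vessel mask as lumen/gel cells.

    Vessel pixels become lumen, everything else gel; the channel walls are
    the top/bottom domain edges (no-slip) and the inlet/outlet are the
    left/right edges. ``coarsen_factor`` block-averages the mask with
    majority vote (ties favor lumen, preserving thin vessels).
    ``gel_extent`` optionally restricts to a (row0, row1, col0, col1)
    sub-window before coarsening.
    """
    m = vessel_mask.as_bool()
    if gel_extent is not None:
        r0, r1, c0, c1 = gel_extent
        m = m[r0:r1, c0:c1]
    px = vessel_mask.pixel_size
    f = int(coarsen_factor)
    if f < 1:
        raise ValueError("coarsen_factor must be ≥ 1")
    if f > 1:
        ny, nx = m.shape
        m = m[:ny - ny % f, :nx - nx % f]
        blocks = m.reshape(m.shape[0] // f, f, m.shape[1] // f, f)
        m = blocks.mean(axis=(1, 3)) >= 0.5
        px = px * f
    labels = np.where(m, LUMEN, GEL).astype(np.int8)
    return DomainGrid(labels, (px, px))


def solve_brinkman(grid: DomainGrid, params: CfdParams) -> FlowField:
    """Direct sparse solve of the steady Stokes–Brinkman system.

    Viscosity at staggered flux points is harmonically averaged across
    the lumen–gel interface; the Darcy drag at a face is the arithmetic
    mean of the adjacent cell drags (a harmonic mean would vanish at the
    interface since the lumen drag is zero). Raises on a singular system;
    the returned field carries the discrete divergence residual.
    """
    ny, nx = grid.shape
    dx = grid.cell_size[0] * 1e-6  # m
    dy = grid.cell_size[1] * 1e-6
    lab = grid.labels
    mu = np.where(lab == LUMEN, params.media_viscosity, params.gel_viscosity)
    drag = np.where(lab == GEL, params.gel_viscosity / params.k, 0.0)
    solid = lab == WALL
    p_in, p_out = params.dP, 0.0

    Nu = ny * (nx + 1)
    Nv = (ny - 1) * nx if ny > 1 else 0
    Np = ny * nx
    N = Nu + Nv + Np

    def iu(j, i):
        return j * (nx + 1) + i

    def iv(j, i):  # interior v rows j = 1..ny-1
        return Nu + (j - 1) * nx + i

    def ip(j, i):
        return Nu + Nv + j * nx + i

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    def hmean(ms):
        ms = [m for m in ms if m is not None]
        return len(ms) / sum(1.0 / m for m in ms)

    inv_dx2, inv_dy2 = 1.0 / dx**2, 1.0 / dy**2

    # ---- x-momentum over u faces -------------------------------------
    for j in range(ny):
        for i in range(nx + 1):
            r = iu(j, i)
            west = lab[j, i - 1] if i > 0 else None
            east = lab[j, i] if i < nx else None
            if (west == WALL) or (east == WALL):
                add(r, r, 1.0)
                continue
            aP = 0.0
            # east/west viscous fluxes (zero-gradient ghost at open ends)
            if i < nx:
                cE = mu[j, i] * inv_dx2
                add(r, iu(j, i + 1), cE)
                aP -= cE
            if i > 0:
                cW = mu[j, i - 1] * inv_dx2
                add(r, iu(j, i - 1), cW)
                aP -= cW
            # north (j-1 side) / south (j+1 side) with wall mirror ghosts
            cells_n = [mu[j - 1, max(i - 1, 0)], mu[j - 1, min(i, nx - 1)],
                       mu[j, max(i - 1, 0)], mu[j, min(i, nx - 1)]] if j > 0 else None
            cells_s = [mu[j, max(i - 1, 0)], mu[j, min(i, nx - 1)],
                       mu[j + 1, max(i - 1, 0)], mu[j + 1, min(i, nx - 1)]] \
                if j < ny - 1 else None
            if j > 0:
                cN = hmean(cells_n) * inv_dy2
                add(r, iu(j - 1, i), cN)
                aP -= cN
            else:
                aP -= 2.0 * hmean([mu[j, max(i - 1, 0)], mu[j, min(i, nx - 1)]]) * inv_dy2
            if j < ny - 1:
                cS = hmean(cells_s) * inv_dy2
                add(r, iu(j + 1, i), cS)
                aP -= cS
            else:
                aP -= 2.0 * hmean([mu[j, max(i - 1, 0)], mu[j, min(i, nx - 1)]]) * inv_dy2
            # Darcy drag (arithmetic face mean)
            dvals = [drag[j, i - 1] if i > 0 else None,
                     drag[j, i] if i < nx else None]
            dvals = [d for d in dvals if d is not None]
            aP -= float(np.mean(dvals))
            add(r, r, aP)
            # pressure gradient with Dirichlet ghosts at inlet/outlet
            if 0 < i < nx:
                add(r, ip(j, i), -1.0 / dx)
                add(r, ip(j, i - 1), 1.0 / dx)
            elif i == 0:
                add(r, ip(j, 0), -2.0 / dx)
                b[r] = -2.0 * p_in / dx
            else:
                add(r, ip(j, nx - 1), 2.0 / dx)
                b[r] = 2.0 * p_out / dx

    # ---- y-momentum over interior v faces ----------------------------
    for j in range(1, ny):
        for i in range(nx):
            r = iv(j, i)
            if lab[j - 1, i] == WALL or lab[j, i] == WALL:
                add(r, r, 1.0)
                continue
            aP = 0.0
            if j + 1 <= ny - 1:
                cS = mu[j, i] * inv_dy2
                add(r, iv(j + 1, i), cS)
                aP -= cS
            else:
                aP -= mu[j, i] * inv_dy2  # v at bottom wall is 0
            if j - 1 >= 1:
                cN = mu[j - 1, i] * inv_dy2
                add(r, iv(j - 1, i), cN)
                aP -= cN
            else:
                aP -= mu[j - 1, i] * inv_dy2  # v at top wall is 0
            if i < nx - 1:
                cE = hmean([mu[j - 1, i], mu[j - 1, i + 1],
                            mu[j, i], mu[j, i + 1]]) * inv_dx2
                add(r, iv(j, i + 1), cE)
                aP -= cE
            if i > 0:
                cW = hmean([mu[j - 1, i - 1], mu[j - 1, i],
                            mu[j, i - 1], mu[j, i]]) * inv_dx2
                add(r, iv(j, i - 1), cW)
                aP -= cW
            # at inlet/outlet columns: zero-gradient tangential ghost (no flux)
            aP -= 0.5 * (drag[j - 1, i] + drag[j, i])
            add(r, r, aP)
            add(r, ip(j, i), -1.0 / dy)
            add(r, ip(j - 1, i), 1.0 / dy)

    # ---- continuity over cells ---------------------------------------
    for j in range(ny):
        for i in range(nx):
            r = ip(j, i)
            if solid[j, i]:
                add(r, r, 1.0)
                continue
            add(r, iu(j, i + 1), 1.0 / dx)
            add(r, iu(j, i), -1.0 / dx)
            if j + 1 <= ny - 1:
                add(r, iv(j + 1, i), 1.0 / dy)
            if j >= 1:
                add(r, iv(j, i), -1.0 / dy)

    A = sparse.csc_matrix((vals, (rows, cols)), shape=(N, N))
    try:
        lu = sparse.linalg.splu(A)
    except RuntimeError as exc:
        raise RuntimeError(f"Brinkman solve failed: {exc}") from exc
    x = lu.solve(b)
    x += lu.solve(b - A @ x)  # one step of iterative refinement
    if not np.all(np.isfinite(x)):
        raise RuntimeError("Brinkman solve failed: non-finite solution "
                           "(singular system)")

    u_face = x[:Nu].reshape(ny, nx + 1)
    v_face = np.zeros((ny + 1, nx))
    if Nv:
        v_face[1:ny] = x[Nu:Nu + Nv].reshape(ny - 1, nx)
    p = x[Nu + Nv:].reshape(ny, nx)

    u_c = 0.5 * (u_face[:, :-1] + u_face[:, 1:])
    v_c = 0.5 * (v_face[:-1, :] + v_face[1:, :])

    div = (u_face[:, 1:] - u_face[:, :-1]) / dx + (v_face[1:] - v_face[:-1]) / dy
    char = max(np.abs(u_face).max() / dx, np.abs(v_face).max() / dy, 1e-300)
    resid = float(np.abs(div[~solid]).max() / char) if (~solid).any() else 0.0

    fieldv = FlowField(u=u_c, v=v_c, p=p, shear=np.zeros_like(u_c),
                       divergence_residual=resid, u_face=u_face,
                       v_face=v_face, grid=grid)
    fieldv.shear = shear_field(fieldv, params)
    return fieldv


def shear_field(flow: FlowField, params: CfdParams) -> np.ndarray:
    """Scalar shear stress μ(x)·√(2 E:E) from cell-centered gradients, Pa."""
    grid = flow.grid
    dx = grid.cell_size[0] * 1e-6
    dy = grid.cell_size[1] * 1e-6
    eo = 2 if min(grid.shape) >= 3 else 1
    dudy, dudx = np.gradient(flow.u, dy, dx, edge_order=eo)
    dvdy, dvdx = np.gradient(flow.v, dy, dx, edge_order=eo)
    Exx, Eyy = dudx, dvdy
    Exy = 0.5 * (dudy + dvdx)
    gamma = np.sqrt(2.0 * (Exx**2 + Eyy**2 + 2.0 * Exy**2))
    mu = np.where(grid.labels == LUMEN, params.media_viscosity,
                  params.gel_viscosity)
    return mu * gamma


def section_fluxes(flow: FlowField) -> np.ndarray:
    """Volumetric flux (m²/s per unit depth) through every vertical section."""
    dy = flow.grid.cell_size[1] * 1e-6
    return flow.u_face.sum(axis=0) * dy


def region_stats(flow: FlowField, grid: DomainGrid,
                 params: CfdParams | None = None) -> RegionStats:
    """Area-weighted mean ± sd of speed and shear per region.

    Regions: tissue (lumen ∪ gel), vessel (lumen only), gel only.
    Velocities in mm/s; the gel figure is the superficial velocity, with
    the pore velocity (superficial / porosity) reported separately when
    params are supplied. Empty regions are omitted with a warning.
    """
    import warnings

    speed = flow.speed * 1e3  # m/s → mm/s
    shear = flow.shear
    masks = {"tissue": grid.labels != WALL,
             "vessel": grid.labels == LUMEN,
             "gel": grid.labels == GEL}
    vel, sh = {}, {}
    for name, m in masks.items():
        if not m.any():
            warnings.warn(f"region {name!r} is empty; omitted", stacklevel=2)
            continue
        vel[name] = (float(speed[m].mean()), float(speed[m].std()))
        sh[name] = (float(shear[m].mean()), float(shear[m].std()))
    pore = None
    if params is not None and "gel" in vel:
        pore = (vel["gel"][0] / params.porosity, vel["gel"][1] / params.porosity)
    return RegionStats(velocity=vel, shear=sh, gel_pore_velocity=pore)


# ---------------------------------------------------------------------------
# dimensionless transport metrics

def compute_peclet(v: float, L: float, D: float) -> float:
    """Peclet number Pe = v·L/D.

    v in μm/s, L in mm, D in μm²/s (units reconciled internally).
    Pe > 10 is the commonly quoted threshold for a vasculogenic response
    to interstitial flow. v = 0 gives Pe = 0; L and D must be positive.
    """
    if not (L > 0 and D > 0):
        raise ValueError("L and D must be positive")
    if v < 0:
        raise ValueError("v must be non-negative")
    return v * (L * 1e3) / D


@dataclass
class ShearEstimate:
    tau: float       # Pa
    formula: str


def interstitial_shear(v: float, mu: float, k: float) -> ShearEstimate:
    """Brinkman boundary-layer shear scaling τ = μ·v/√k on cells in gel.

    v in μm/s, μ in Pa·s, k in m². The result is labeled with the formula
    used, since alternative interstitial-shear conventions exist.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    if not mu > 0 or v < 0:
        raise ValueError("mu must be positive and v non-negative")
    tau = mu * (v * 1e-6) / np.sqrt(k)
    return ShearEstimate(tau=float(tau), formula="tau = mu * v / sqrt(k)")
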