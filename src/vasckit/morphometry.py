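"""Vessel segmentation, skeletonization, and network morphometrics.

The metric definitions follow standard microvascular image analysis:

* connectivity — junction count / endpoint count of the skeleton graph
  (more looped networks score higher);
* branch density — branches per mm² of region of interest;
* effective diameter — total vessel area / total skeleton length, which
  equals the true width for a constant-width vessel;
* area coverage — percent of the ROI occupied by vessel.

Two numerical details matter for the ±5% effective-diameter contract and
are handled explicitly here. Branch lengths are measured on simplified
polylines (Ramer–Douglas–Peucker, 1-px tolerance) rather than raw
8-connected chains, removing the up-to-8% staircase overestimate on
diagonal branches. And terminal branches are extended from the thinned
skeleton's retracted tip to the mask boundary along the local branch
direction, compensating the ~half-width end retraction of topological
thinning on capped strokes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters
from skimage.morphology import skeletonize

from .images import ImageStack, RasterImage

_NEI8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonNode:
    x: float           # μm
    y: float           # μm
    kind: str          # 'junction' | 'endpoint'


@dataclass
class Branch:
    polyline: np.ndarray      # (N, 2) array of (x, y) μm
    length: float             # μm, after simplification/extension
    node_a: int               # node index, -1 for closed loops
    node_b: int


@dataclass
class SkeletonGraph:
    nodes: list[SkeletonNode]
    branches: list[Branch]
    skeleton: np.ndarray      # boolean skeleton pixel grid
    pixel_size: float

    @property
    def n_junctions(self) -> int:
        return sum(n.kind == "junction" for n in self.nodes)

    @property
    def n_endpoints(self) -> int:
        return sum(n.kind == "endpoint" for n in self.nodes)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))


@dataclass
class MorphologyMetrics:
    connectivity: float               # junctions/endpoints; nan if undefined
    connectivity_defined: bool
    branch_density: float             # branches / mm²
    effective_diameter: float         # μm
    area_coverage: float              # % of ROI
    mean_branch_length: float         # μm
    total_vessel_area: float          # μm²
    total_skeleton_length: float      # μm
    n_junctions: int = 0
    n_endpoints: int = 0
    n_branches: int = 0


# ---------------------------------------------------------------------------
# segmentation

def segment_vessels(image: RasterImage | ImageStack, sigma: float = 2.0,
                    outlier_radius: float = 2.0,
                    outlier_threshold: float | None = None,
                    threshold_method: str = "otsu",
                    keep_largest: bool = False) -> RasterImage:
    """Binary vessel mask from a fluorescence image (or stack, max-projected).

    Pipeline: maximum projection (stacks) → Gaussian smoothing (``sigma``
    μm) → median-based outlier replacement within ``outlier_radius`` μm →
    global threshold. ``outlier_threshold`` defaults to 5× the robust sd
    of the median residual. Raises when the threshold degenerates to an
    all-foreground or all-background mask.
    """
    if isinstance(image, ImageStack):
        image = RasterImage(image.frames.max(axis=0), image.pixel_size)
    px = image.pixel_size
    data = np.asarray(image.pixels, float)
    if np.unique(data).size < 2:
        raise ValueError("degenerate image: fewer than 2 gray levels")

    if sigma > 0:
        data = ndi.gaussian_filter(data, sigma / px)
    if outlier_radius > 0:
        size = 2 * max(int(round(outlier_radius / px)), 1) + 1
        med = ndi.median_filter(data, size=size)
        resid = data - med
        thr = outlier_threshold
        if thr is None:
            thr = 5.0 * 1.4826 * np.median(np.abs(resid))
        data = np.where(np.abs(resid) > thr, med, data)

    methods = {"otsu": filters.threshold_otsu,
               "isodata": filters.threshold_isodata,
               "mean": filters.threshold_mean,
               "li": filters.threshold_li}
    if threshold_method not in methods:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    try:
        t = methods[threshold_method](data)
    except ValueError as exc:
        raise ValueError(f"degenerate threshold: {exc}") from exc
    mask = data > t
    if mask.all() or not mask.any():
        raise ValueError(
            f"degenerate threshold {t:.4g}: mask is all "
            f"{'foreground' if mask.all() else 'background'}")
    if keep_largest:
        lab, n = ndi.label(mask)
        if n > 1:
            sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    return RasterImage(mask, px)


# ---------------------------------------------------------------------------
# skeleton graph extraction

def _neighbor_degrees(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), int)
    kernel[1, 1] = 0
    return ndi.convolve(sk.astype(int), kernel, mode="constant")


def _rdp(points: np.ndarray, eps: float) -> np.ndarray:
    """Ramer–Douglas–Peucker polyline simplification (iterative)."""
    n = len(points)
    if n < 3:
        return points
    keep = np.zeros(n, bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        seg = points[j] - points[i]
        L = np.hypot(*seg)
        pts = points[i + 1:j]
        if L == 0:
            d = np.linalg.norm(pts - points[i], axis=1)
        else:
            rel = pts - points[i]
            d = np.abs(seg[0] * rel[:, 1] - seg[1] * rel[:, 0]) / L
        kmax = int(np.argmax(d))
        if d[kmax] > eps:
            k = i + 1 + kmax
            keep[k] = True
            stack.append((i, k))
            stack.append((k, j))
    return points[keep]


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _extract_graph(sk: np.ndarray, pixel_size: float) -> SkeletonGraph:
    """Contract a 1-px skeleton into nodes (junctions/endpoints) + branches."""
    rows, cols = np.nonzero(sk)
    if rows.size == 0:
        return SkeletonGraph([], [], sk, pixel_size)
    deg = _neighbor_degrees(sk)

    junction_px = sk & (deg >= 3)
    node_label = np.zeros(sk.shape, int)  # 0 = not a node pixel
    nodes: list[SkeletonNode] = []
    # merge 8-adjacent junction pixels into single junction nodes
    lab, n_j = ndi.label(junction_px, structure=np.ones((3, 3)))
    for jid in range(1, n_j + 1):
        rr, cc = np.nonzero(lab == jid)
        nodes.append(SkeletonNode(float(cc.mean() * pixel_size),
                                  float(rr.mean() * pixel_size), "junction"))
        node_label[rr, cc] = len(nodes)
    # endpoints and isolated pixels
    for r, c in zip(*np.nonzero(sk & (deg <= 1))):
        nodes.append(SkeletonNode(float(c * pixel_size),
                                  float(r * pixel_size), "endpoint"))
        node_label[r, c] = len(nodes)

    ny, nx = sk.shape

    def neighbors(r, c):
        for dr, dc in _NEI8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and sk[rr, cc]:
                yield rr, cc

    visited_chain = np.zeros(sk.shape, bool)
    used_edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    branches: list[Branch] = []

    def add_branch(path, na, nb):
        poly = np.array([(c * pixel_size, r * pixel_size) for r, c in path])
        simp = _rdp(poly, 1.0 * pixel_size)
        branches.append(Branch(simp, _polyline_length(simp), na - 1, nb - 1))

    node_pixels = list(zip(*np.nonzero(node_label > 0)))
    for r0, c0 in node_pixels:
        for r1, c1 in neighbors(r0, c0):
            if node_label[r1, c1] > 0:
                # direct node-node adjacency; same junction cluster is internal
                if node_label[r1, c1] == node_label[r0, c0]:
                    continue
                ekey = tuple(sorted([(r0, c0), (r1, c1)]))
                if ekey in used_edges:
                    continue
                used_edges.add(ekey)
                add_branch([(r0, c0), (r1, c1)],
                           node_label[r0, c0], node_label[r1, c1])
                continue
            if visited_chain[r1, c1]:
                continue
            # walk the degree-2 chain until the next node pixel
            path = [(r0, c0), (r1, c1)]
            visited_chain[r1, c1] = True
            prev, cur = (r0, c0), (r1, c1)
            while True:
                nxt = [(rr, cc) for rr, cc in neighbors(*cur)
                       if (rr, cc) != prev
                       and not (node_label[rr, cc] == 0 and visited_chain[rr, cc])]
                # prefer an unvisited chain pixel; otherwise a node pixel
                chain_next = [p for p in nxt if node_label[p] == 0]
                node_next = [p for p in nxt if node_label[p] > 0]
                if chain_next:
                    prev, cur = cur, chain_next[0]
                    visited_chain[cur] = True
                    path.append(cur)
                elif node_next:
                    # avoid stepping back into the very cluster we left when a
                    # shorter route inside the cluster exists
                    end = node_next[0]
                    path.append(end)
                    add_branch(path, node_label[r0, c0], node_label[end])
                    break
                else:
                    # dead end without node pixel (shouldn't happen) — endpoint
                    add_branch(path, node_label[r0, c0], 0)
                    break

    # pure cycles: remaining unvisited degree-2 pixels with no node contact
    rem = sk & ~visited_chain & (node_label == 0) & (deg == 2)
    lab, n_c = ndi.label(rem, structure=np.ones((3, 3)))
    for cid in range(1, n_c + 1):
        rr, cc = np.nonzero(lab == cid)
        start = (rr[0], cc[0])
        path = [start]
        visited_chain[start] = True
        prev, cur = None, start
        while True:
            nxt = [p for p in neighbors(*cur) if p != prev and not visited_chain[p]]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited_chain[cur] = True
            path.append(cur)
        path.append(start)  # close the loop
        add_branch(path, 0, 0)

    return SkeletonGraph(nodes, branches, sk, pixel_size)


def _prune_spurs(sk: np.ndarray, pixel_size: float, prune_length: float,
                 max_iter: int = 5) -> tuple[np.ndarray, SkeletonGraph]:
    graph = _extract_graph(sk, pixel_size)
    for _ in range(max_iter):
        to_remove = []
        for b in graph.branches:
            terms = [graph.nodes[i].kind for i in (b.node_a, b.node_b) if i >= 0]
            if "endpoint" in terms and b.length < prune_length:
                to_remove.append(b)
        if not to_remove:
            break
        sk = sk.copy()
        deg = _neighbor_degrees(sk)
        for b in to_remove:
            for x, y in b.polyline:
                r = int(round(y / pixel_size))
                c = int(round(x / pixel_size))
                # keep junction-cluster pixels so surviving branches stay joined
                if 0 <= r < sk.shape[0] and 0 <= c < sk.shape[1] and deg[r, c] < 3:
                    sk[r, c] = False
        graph = _extract_graph(sk, pixel_size)
    return sk, graph


def _extend_terminals(graph: SkeletonGraph, mask: np.ndarray) -> None:
    """Extend terminal branches along their end direction to the mask edge.

    Thinning retracts branch tips by roughly half the local vessel width;
    marching the tip outward until it leaves the mask restores centerline
    length without touching the skeleton pixel set (so skeleton ⊆ mask
    stays exact).
    """
    px = graph.pixel_size
    dt = ndi.distance_transform_edt(mask) * px
    ny, nx = mask.shape

    def inside(pt):
        c = int(round(pt[0] / px))
        r = int(round(pt[1] / px))
        return 0 <= r < ny and 0 <= c < nx and mask[r, c]

    for b in graph.branches:
        for end in (0, 1):
            nid = b.node_a if end == 0 else b.node_b
            if nid < 0 or graph.nodes[nid].kind != "endpoint":
                continue
            poly = b.polyline if end == 1 else b.polyline[::-1]
            if len(poly) < 2:
                continue
            k = min(5, len(poly) - 1)
            direction = poly[-1] - poly[-1 - k]
            nrm = np.hypot(*direction)
            if nrm == 0:
                continue
            direction = direction / nrm
            tip = poly[-1].astype(float)
            r = int(round(tip[1] / px))
            c = int(round(tip[0] / px))
            cap = 2.0 * dt[min(max(r, 0), ny - 1), min(max(c, 0), nx - 1)] + 2 * px
            step = 0.25 * px
            dist = 0.0
            pt = tip.copy()
            while dist + step <= cap and inside(pt + step * direction):
                pt = pt + step * direction
                dist += step
            if dist > 0:
                if end == 1:
                    b.polyline = np.vstack([b.polyline, pt])
                else:
                    b.polyline = np.vstack([pt, b.polyline[::1]])
                b.length += dist
                node = graph.nodes[nid]
                node.x, node.y = float(pt[0]), float(pt[1])


def skeletonize_network(mask: RasterImage, prune_length: float = 10.0,
                        extend_ends: bool = True) -> SkeletonGraph:
    """One-pixel-wide skeleton graph of a binary vessel mask.

    Junction pixels (≥3 neighbors) are merged into single junction nodes
    by 8-connectivity; endpoint pixels (≤1 neighbor) become endpoint
    nodes; branches are maximal chains between nodes. Terminal branches
    shorter than ``prune_length`` μm are pruned (iteratively), then the
    surviving terminal branches are extended to the mask boundary.
    An empty mask yields an empty graph.
    """
    m = mask.as_bool()
    if not m.any():
        return SkeletonGraph([], [], np.zeros_like(m), mask.pixel_size)
    sk = skeletonize(m)
    sk, graph = _prune_spurs(sk, mask.pixel_size, prune_length)
    if extend_ends:
        _extend_terminals(graph, m)
    return graph


# ---------------------------------------------------------------------------
# metrics

def compute_morphology(mask: RasterImage, graph: SkeletonGraph,
                       roi_area: float | None = None,
                       roi_mask: np.ndarray | None = None) -> MorphologyMetrics:
    """Morphology metrics from a mask and its skeleton graph.

    ``roi_area`` is in mm² and defaults to the full image (or the supplied
    ``roi_mask``). Connectivity is flagged undefined (NaN) when the graph
    has no endpoints.
    """
    m = mask.as_bool()
    px2 = mask.pixel_area
    if roi_mask is not None:
        n_roi_px = int(np.count_nonzero(roi_mask))
        m = m & roi_mask
    else:
        n_roi_px = m.size
    if roi_area is None:
        roi_area = n_roi_px * px2 * 1e-6  # μm² → mm²

    vessel_area = float(np.count_nonzero(m)) * px2
    skel_len = graph.total_length
    n_j, n_e, n_b = graph.n_junctions, graph.n_endpoints, graph.n_branches

    if n_e > 0:
        connectivity, defined = n_j / n_e, True
    else:
        connectivity, defined = float("nan"), False
    eff_d = vessel_area / skel_len if skel_len > 0 else 0.0
    density = n_b / roi_area if roi_area > 0 else 0.0
    coverage = 100.0 * np.count_nonzero(m) / n_roi_px if n_roi_px else 0.0
    mean_len = skel_len / n_b if n_b else 0.0
    return MorphologyMetrics(
        connectivity=connectivity, connectivity_defined=defined,
        branch_density=density, effective_diameter=eff_d,
        area_coverage=coverage, mean_branch_length=mean_len,
        total_vessel_area=vessel_area, total_skeleton_length=skel_len,
        n_junctions=n_j, n_endpoints=n_e, n_branches=n_b)


def compute_perfused_fraction(vessel_mask: RasterImage,
                              dextran_mask: RasterImage) -> float:
    """Percent of vessel area positive for the intravascular tracer."""
    v = vessel_mask.as_bool()
    d = dextran_mask.as_bool()
    if v.shape != d.shape or vessel_mask.pixel_size != dextran_mask.pixel_size:
        raise ValueError("vessel and dextran masks must share grid and pixel size")
    nv = np.count_nonzero(v)
    if nv == 0:
        raise ValueError("empty vessel mask")
    return 100.0 * np.count_nonzero(v & d) / nv


def measure_matrix_intensity(stain_image: RasterImage,
                             vessel_mask: RasterImage,
                             background: float = 0.0) -> float:
    """Integrated background-subtracted stain intensity per vessel area.

    Returns AU·μm²/μm² = AU (integrated field intensity normalized to
    vessel area), the normalization used for matrix-protein stains.
    """
    if stain_image.shape != vessel_mask.shape:
        raise ValueError("stain image and vessel mask must be aligned")
    v = vessel_mask.as_bool()
    area = np.count_nonzero(v) * vessel_mask.pixel_area
    if area == 0:
        raise ValueError("zero vessel area")
    total = float(np.sum(np.asarray(stain_image.pixels, float) - background)) \
        * stain_image.pixel_area
    return total / area
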