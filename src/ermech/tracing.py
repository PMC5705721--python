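"""Tubule centerline extraction with an open active contour.

The tracer enhances curvilinear structure with a Hessian-eigenvalue ridge
filter, initialises a polyline as the minimum-cost path between two seed
endpoints on the inverted ridge response, and refines it by minimising

    E = integral( alpha |c'|^2 + beta |c''|^2 - w I(c) ) ds

with a semi-implicit (pentadiagonal) update and free, unclamped ends.
Vertices are resampled to uniform arc-length spacing every iteration,
which regularises the parametrisation without the end-shrinkage a
stretching term causes on open contours (``alpha_stretch`` therefore
defaults to 0 and remains available).

Coordinates are continuous and in micrometres: the centre of image pixel
``(row=0, col=0)`` sits at the world origin and pixel centres lie at
integer multiples of ``pixel_size``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .chains import FiberChain, FiberNetwork, resample_polyline

__all__ = [
    "TraceConfig",
    "enhance_ridges",
    "initialize_contour",
    "optimize_open_contour",
    "detect_junctions",
    "trace_tube",
    "px_to_um",
    "um_to_px",
]


@dataclass
class TraceConfig:
    """Open-active-contour parameters.

    Weights are non-negative; ``convergence_tol`` and ``segment_length``
    are in micrometres, ``ridge_sigma`` and ``step_size`` in pixel units.
    """

    alpha_stretch: float = 0.0
    beta_bend: float = 20.0
    image_weight: float = 2.0
    step_size: float = 0.5
    max_iterations: int = 400
    convergence_tol: float = 1e-3
    segment_length: float = 0.1
    ridge_sigma: float = 1.5

    def __post_init__(self) -> None:
        if min(self.alpha_stretch, self.beta_bend, self.image_weight) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.step_size <= 0 or self.segment_length <= 0:
            raise ValueError("step_size and segment_length must be positive")


def px_to_um(points_px: np.ndarray, pixel_size: float, origin_um=(0.0, 0.0)) -> np.ndarray:
    """Pixel (x=col, y=row) coordinates to world micrometres."""
    return np.asarray(points_px, dtype=float) * pixel_size + np.asarray(origin_um)


def um_to_px(points_um: np.ndarray, pixel_size: float, origin_um=(0.0, 0.0)) -> np.ndarray:
    """World micrometres to pixel (x=col, y=row) coordinates."""
    return (np.asarray(points_um, dtype=float) - np.asarray(origin_um)) / pixel_size


def enhance_ridges(image: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Hessian-eigenvalue ridge response for bright curvilinear structure.

    Non-negative, maximal along tube axes; invariant to constant offsets.
    """
    from skimage.filters import sato

    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("ridge enhancement expects a 2D image")
    return sato(image, sigmas=[sigma], black_ridges=False, mode="reflect")


def initialize_contour(
    ridge_image: np.ndarray, endpoints: tuple[tuple[float, float], tuple[float, float]]
) -> np.ndarray:
    """Minimum-cost path between two endpoints on the inverted ridge map.

    Endpoints and the returned polyline are in pixel (x, y) coordinates.
    Swapping the endpoints returns the exact reversed path.
    """
    from skimage.graph import route_through_array

    ridge = np.asarray(ridge_image, dtype=float)
    (x0, y0), (x1, y1) = endpoints
    p0 = (int(round(y0)), int(round(x0)))
    p1 = (int(round(y1)), int(round(x1)))
    for r, c in (p0, p1):
        if not (0 <= r < ridge.shape[0] and 0 <= c < ridge.shape[1]):
            raise ValueError(f"endpoint (row={r}, col={c}) outside the image")
    if p0 == p1:
        raise ValueError("endpoints coincide; a path needs two distinct points")

    cost = ridge.max() - ridge + 1e-9 * max(ridge.max(), 1.0)
    swap = p1 < p0  # canonical order makes the path reversal-symmetric
    a, b = (p1, p0) if swap else (p0, p1)
    path, _ = route_through_array(cost, a, b, fully_connected=True, geometric=True)
    path = np.array(path, dtype=float)[:, ::-1]  # (row, col) -> (x, y)
    return path[::-1] if swap else path


def _internal_matrix(n: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """(I + gamma * (alpha K2 + beta K4)) for an open contour with free ends.

    K2/K4 are the Gram matrices of the first/second difference operators,
    giving natural (free) boundary conditions automatically.
    """
    d1 = np.zeros((n - 1, n))
    idx = np.arange(n - 1)
    d1[idx, idx] = -1.0
    d1[idx, idx + 1] = 1.0
    k2 = d1.T @ d1
    if n > 2:
        d2 = np.zeros((n - 2, n))
        idx = np.arange(n - 2)
        d2[idx, idx] = 1.0
        d2[idx, idx + 1] = -2.0
        d2[idx, idx + 2] = 1.0
        k4 = d2.T @ d2
    else:
        k4 = np.zeros((n, n))
    return np.eye(n) + gamma * (alpha * k2 + beta * k4)


def optimize_open_contour(
    image: np.ndarray,
    init_um: np.ndarray,
    config: TraceConfig,
    pixel_size: float,
    origin_um=(0.0, 0.0),
    source_image_id: str = "",
) -> FiberChain:
    """Refine an initial polyline to the tubule centerline.

    ``init_um`` is an (n, 2) polyline in micrometres.  Stops when the mean
    vertex displacement per iteration falls below ``convergence_tol`` or
    after ``max_iterations``; raises if any vertex leaves the image
    (divergence), reporting the iteration index.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    init_um = np.asarray(init_um, dtype=float)
    if init_um.ndim != 2 or init_um.shape[0] < 2:
        raise ValueError("initial polyline needs at least 2 vertices")

    # normalised, lightly smoothed image and its gradient field
    smooth = gaussian_filter(image, 1.0)
    rng_val = smooth.max() - smooth.min()
    norm = (smooth - smooth.min()) / (rng_val if rng_val > 0 else 1.0)
    gy, gx = np.gradient(norm)

    seg_px = config.segment_length / pixel_size
    snake = um_to_px(init_um, pixel_size, origin_um)
    snake = resample_polyline(snake, seg_px)
    gamma = config.step_size
    w = config.image_weight
    solver_n = -1
    inv = None

    for iteration in range(config.max_iterations):
        n = snake.shape[0]
        if n != solver_n:
            inv = np.linalg.inv(
                _internal_matrix(n, config.alpha_stretch, config.beta_bend, gamma)
            )
            solver_n = n
        fx = map_coordinates(gx, [snake[:, 1], snake[:, 0]], order=1, mode="nearest")
        fy = map_coordinates(gy, [snake[:, 1], snake[:, 0]], order=1, mode="nearest")
        force = np.stack([fx, fy], axis=1)
        new = inv @ (snake + gamma * w * force)
        if (
            new[:, 0].min() < -0.5
            or new[:, 1].min() < -0.5
            or new[:, 0].max() > image.shape[1] - 0.5
            or new[:, 1].max() > image.shape[0] - 0.5
        ):
            raise RuntimeError(
                f"contour diverged outside the image at iteration {iteration}"
            )
        moved = float(np.mean(np.linalg.norm(new - snake, axis=1))) * pixel_size
        snake = resample_polyline(new, seg_px)
        if moved < config.convergence_tol:
            break

    out_um = resample_polyline(
        px_to_um(snake, pixel_size, origin_um), config.segment_length
    )
    return FiberChain(
        vertices=out_um,
        segment_length=config.segment_length,
        source_image_id=source_image_id,
        chain_id="trace-0",
    )


def trace_tube(
    image: np.ndarray,
    endpoints_um: tuple[tuple[float, float], tuple[float, float]],
    config: TraceConfig,
    pixel_size: float,
    origin_um=(0.0, 0.0),
    source_image_id: str = "",
) -> FiberChain:
    """Convenience pipeline: ridge filter, shortest-path init, snake."""
    ridge = enhance_ridges(image, config.ridge_sigma)
    eps_px = [tuple(um_to_px(np.array(p), pixel_size, origin_um)) for p in endpoints_um]
    init_px = initialize_contour(ridge, (eps_px[0], eps_px[1]))
    init_um = px_to_um(init_px, pixel_size, origin_um)
    return optimize_open_contour(
        image, init_um, config, pixel_size, origin_um, source_image_id
    )


def detect_junctions(chains: list[FiberChain], radius_tol: float = 0.15) -> FiberNetwork:
    """Find points where three or more chain arms meet.

    Chain endpoints within ``radius_tol`` (um) of each other are clustered
    (single-linkage); a chain passing through a cluster contributes two
    arms, a chain ending there contributes one.  Clusters with total
    degree >= 3 become junctions at the arm centroid.
    """
    if not chains:
        raise ValueError("need at least one chain")
    endpoints = []
    for ci, ch in enumerate(chains):
        endpoints.append((ch.vertices[0, :2], ci))
        endpoints.append((ch.vertices[-1, :2], ci))
    pts = np.array([p for p, _ in endpoints])

    # single-linkage clustering of endpoints within radius_tol
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    for i, j in tree.query_pairs(radius_tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    junctions: list[tuple[float, float, int]] = []
    for members in clusters.values():
        centroid = pts[members].mean(axis=0)
        degree = 0
        for ci, ch in enumerate(chains):
            verts = ch.vertices[:, :2]
            near = np.linalg.norm(verts - centroid, axis=1) <= radius_tol
            if not near.any():
                continue
            runs = np.flatnonzero(np.diff(np.concatenate([[0], near.view(np.int8), [0]])))
            for start, stop in zip(runs[::2], runs[1::2]):
                ends_touch = int(start == 0) + int(stop == len(verts))
                degree += 1 if ends_touch else 2
        if degree >= 3:
            junctions.append((float(centroid[0]), float(centroid[1]), degree))
    return FiberNetwork(chains=list(chains), junctions=junctions)
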