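"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the three input classes the analysis consumes:

* worm-like-chain (WLC) fibre backbones and branched degree-3 networks
  with prescribed persistence length,
* PSF-convolved, noisy renderings of hollow tubes (diffraction-limited or
  STORM-like pixel sizes) and localization tables of points on the tube
  surface,
* transverse-fluctuation tracks of tensioned semi-flexible filaments,
  with an optional actively driven (super-diffusive) component.

All generators are deterministic for a fixed seed and return ground-truth
metadata alongside the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter
from scipy.spatial import cKDTree

from .chains import FiberChain, FiberNetwork, resample_polyline
from .constants import K_B, DEFAULT_TEMPERATURE, DEFAULT_VISCOSITY
from .dynamics import TransverseTrack

__all__ = [
    "WLCParams",
    "RenderParams",
    "FluctuationParams",
    "generate_wlc_chain",
    "generate_wlc_ensemble",
    "generate_branched_network",
    "render_image",
    "generate_localizations",
    "simulate_transverse_fluctuations",
    "generate_track_population",
    "wlc_mean_square_end_to_end",
]


# ---------------------------------------------------------------------------
# Worm-like chains


@dataclass
class WLCParams:
    """Parameters of a discrete worm-like chain.

    Lengths in micrometres. ``dimensionality`` selects how the chain is
    generated and returned:

    * ``"2D"``: planar chain, Gaussian tangent-angle increments of variance
      ``2 * segment_length / persistence_length`` per segment, so the
      in-plane tangent correlation is ``exp(-s / L_p)``.
    * ``"3D"``: tangent rotated on the sphere each step with
      ``<cos(theta)> = exp(-segment_length / L_p)`` (exact exponential
      tangent decorrelation), azimuth uniform.
    * ``"3D-projected"``: a 3D chain orthogonally projected to the x-y
      plane and resampled to uniform spacing.
    """

    persistence_length: float
    contour_length: float
    segment_length: float
    dimensionality: str = "3D"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.contour_length < self.segment_length:
            raise ValueError(
                "contour_length must be at least one segment_length "
                f"(got L_c={self.contour_length}, ds={self.segment_length})"
            )
        if self.dimensionality not in ("2D", "3D", "3D-projected"):
            raise ValueError(f"unknown dimensionality {self.dimensionality!r}")

    @property
    def n_segments(self) -> int:
        return max(1, int(round(self.contour_length / self.segment_length)))


def wlc_mean_square_end_to_end(L_c: float, L_p: float) -> float:
    """Kratky-Porod mean-square end-to-end distance.

    <R^2> = 2 L_p (L_c - L_p [1 - exp(-L_c/L_p)]).  This closed form holds
    for any chain whose tangent correlation is exp(-s/L_p), which is the
    convention of both the 2D and the 3D generator here.
    """
    if L_c <= 0 or L_p <= 0:
        raise ValueError("L_c and L_p must be positive")
    x = L_c / L_p
    if x < 1e-4:
        # series expansion to avoid the L_c - L_p*(1-exp(-x)) cancellation
        return L_c**2 * (1.0 - x / 3.0 + x**2 / 12.0 - x**3 / 60.0)
    return 2.0 * L_p * (L_c - L_p * (1.0 - math.exp(-x)))


def _vmf_concentration(mean_cos: float) -> float:
    """Concentration kappa of the spherical step distribution
    p(cos t) ~ exp(kappa cos t) with the requested <cos t>."""
    if mean_cos >= 1.0 - 1e-15:
        return 1e15

    def langevin(k: float) -> float:
        # coth(k) - 1/k, stable for large k
        if k > 30:
            return 1.0 - 1.0 / k
        return 1.0 / math.tanh(k) - 1.0 / k

    lo, hi = 1e-8, 10.0
    while langevin(hi) < mean_cos:
        hi *= 4.0
        if hi > 1e16:
            return hi
    return brentq(lambda k: langevin(k) - mean_cos, lo, hi, xtol=1e-12, rtol=1e-12)


def _sample_cos_theta(kappa: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sampling of cos(theta) from p ~ exp(kappa cos theta)."""
    if kappa < 1e-8:
        return 2.0 * u - 1.0
    # cos = 1 + log(u + (1-u) e^{-2 kappa}) / kappa, computed stably
    return 1.0 + np.log1p(np.expm1(-2.0 * kappa) * (1.0 - u)) / kappa


def _wlc_vertices_3d(params: WLCParams, n_chains: int, rng: np.random.Generator) -> np.ndarray:
    """(n_chains, n_segments+1, 3) vertex arrays of 3D WLC chains."""
    n = params.n_segments
    ds = params.segment_length
    mean_cos = math.exp(-ds / params.persistence_length)
    kappa = _vmf_concentration(mean_cos)

    cos_t = _sample_cos_theta(kappa, rng.random((n_chains, n)))
    np.clip(cos_t, -1.0, 1.0, out=cos_t)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, (n_chains, n))

    tangents = np.empty((n_chains, n, 3))
    t = np.tile(np.array([1.0, 0.0, 0.0]), (n_chains, 1))
    for i in range(n):
        if i > 0:
            # rotate each current tangent by (theta_i, phi_i) in its own frame
            ref = np.where(
                (np.abs(t[:, 2]) < 0.9)[:, None],
                np.tile(np.array([0.0, 0.0, 1.0]), (n_chains, 1)),
                np.tile(np.array([1.0, 0.0, 0.0]), (n_chains, 1)),
            )
            e1 = np.cross(ref, t)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            ct, st = cos_t[:, i, None], sin_t[:, i, None]
            cp, sp = np.cos(phi[:, i, None]), np.sin(phi[:, i, None])
            t = ct * t + st * (cp * e1 + sp * e2)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
        tangents[:, i] = t

    verts = np.zeros((n_chains, n + 1, 3))
    verts[:, 1:] = np.cumsum(tangents * ds, axis=1)
    return verts


def _wlc_vertices_2d(params: WLCParams, n_chains: int, rng: np.random.Generator) -> np.ndarray:
    n = params.n_segments
    ds = params.segment_length
    sigma = math.sqrt(2.0 * ds / params.persistence_length)
    dphi = rng.normal(0.0, sigma, (n_chains, n))
    dphi[:, 0] = 0.0  # initial tangent along +x
    phi = np.cumsum(dphi, axis=1)
    tangents = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    verts = np.zeros((n_chains, n + 1, 2))
    verts[:, 1:] = np.cumsum(tangents * ds, axis=1)
    return verts


def generate_wlc_ensemble(params: WLCParams, n_chains: int) -> np.ndarray:
    """Vertex arrays for ``n_chains`` independent chains with the same
    parameters (seeded by ``params.seed``).

    Returns shape ``(n_chains, n_vertices, 2 or 3)``.  For
    ``"3D-projected"`` the raw projection is returned without uniform
    resampling (use :func:`generate_wlc_chain` for single resampled chains).
    """
    rng = np.random.default_rng(params.seed)
    if params.dimensionality == "2D":
        return _wlc_vertices_2d(params, n_chains, rng)
    verts = _wlc_vertices_3d(params, n_chains, rng)
    if params.dimensionality == "3D-projected":
        return verts[:, :, :2]
    return verts


def generate_wlc_chain(params: WLCParams) -> FiberChain:
    """A single worm-like chain as a :class:`FiberChain`.

    ``"3D-projected"`` chains are generated at a 4x finer step, projected,
    spline-smoothed (projection creates sub-segment zigzags wherever the
    3D tangent tilts out of plane, which a real traced centerline would
    not resolve) and resampled to the requested segment length.
    """
    if params.dimensionality == "3D-projected":
        from dataclasses import replace as _replace

        from scipy.interpolate import splev, splprep

        from .chains import polyline_arclength

        fine = _replace(params, segment_length=params.segment_length / 4.0)
        verts = generate_wlc_ensemble(fine, 1)[0]
        arc = polyline_arclength(verts)
        tck, _ = splprep(
            [verts[:, 0], verts[:, 1]],
            u=arc,
            s=len(verts) * (0.2 * params.segment_length) ** 2,
        )
        u = np.linspace(0.0, arc[-1], 4 * len(verts))
        verts = np.stack(splev(u, tck), axis=1)
    else:
        verts = generate_wlc_ensemble(params, 1)[0]
    if params.dimensionality == "3D-projected":
        verts = resample_polyline(verts, params.segment_length)
    return FiberChain(
        vertices=verts,
        segment_length=params.segment_length,
        source_image_id=f"wlc(seed={params.seed})",
        chain_id="wlc-0",
    )


# ---------------------------------------------------------------------------
# Branched networks


def generate_branched_network(
    n_cells: int,
    edge_length_range: tuple[float, float] = (1.0, 5.0),
    persistence_length: float = 3.03,
    seed: int = 0,
    segment_length: float = 0.05,
) -> FiberNetwork:
    """Planar degree-3 (honeycomb-topology) network of WLC edges.

    Junction-to-junction contour lengths are uniform within
    ``edge_length_range`` (micrometres); every interior node has degree 3.
    Junction coordinates and per-edge contour lengths are recorded as
    ground truth on the returned network (``junctions`` attribute and the
    chains themselves).
    """
    import networkx as nx

    lo, hi = edge_length_range
    if not (0 < lo < hi):
        raise ValueError("edge_length_range must satisfy 0 < min < max")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if n_cells == 0:
        return FiberNetwork(chains=[], junctions=[])

    rng = np.random.default_rng(seed)
    m = max(1, int(round(math.sqrt(n_cells))))
    n = max(1, int(math.ceil(n_cells / m)))
    g = nx.hexagonal_lattice_graph(m, n)
    pos = nx.get_node_attributes(g, "pos")

    # scale the unit lattice so straight edges sit mid-range, then jitter the
    # nodes with a bounded displacement so edge lengths stay inside the range
    # (max length change per edge is 2*sqrt(2)*jitter, plus ~2% WLC excess)
    target = 0.5 * (lo + hi)
    headroom = min(hi / 1.04 - target, target - lo * 1.02)
    jitter = max(0.0, 0.9 * headroom / (2.0 * math.sqrt(2.0)))
    coords = {
        k: np.asarray(p, dtype=float) * target + rng.uniform(-jitter, jitter, 2)
        for k, p in pos.items()
    }

    chains: list[FiberChain] = []
    for idx, (u, v) in enumerate(sorted(g.edges())):
        a, b = coords[u], coords[v]
        straight = float(np.linalg.norm(b - a))
        # draw a WLC of matching contour length and warp its ends onto (a, b)
        L_e = float(np.clip(straight * (1.0 + abs(rng.normal(0.0, 0.02))), lo, hi))
        wlc = WLCParams(
            persistence_length=persistence_length,
            contour_length=max(L_e, 2 * segment_length),
            segment_length=segment_length,
            dimensionality="2D",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        verts = generate_wlc_ensemble(wlc, 1)[0]
        # rigid rotate/translate so the chord aligns with a -> b
        chord = verts[-1] - verts[0]
        ang = math.atan2(b[1] - a[1], b[0] - a[0]) - math.atan2(chord[1], chord[0])
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        verts = (verts - verts[0]) @ rot.T + a
        # linear end-blend so the last vertex lands exactly on b
        frac = np.linspace(0.0, 1.0, len(verts))[:, None]
        verts = verts + frac * (b - verts[-1])
        verts = resample_polyline(verts, segment_length)
        chains.append(
            FiberChain(
                vertices=verts,
                segment_length=segment_length,
                source_image_id=f"network(seed={seed})",
                chain_id=f"edge-{idx}",
            )
        )

    junctions = [
        (float(coords[k][0]), float(coords[k][1]), g.degree[k])
        for k in sorted(g.nodes())
        if g.degree[k] >= 3
    ]
    return FiberNetwork(chains=chains, junctions=junctions)


# ---------------------------------------------------------------------------
# Image rendering


@dataclass
class RenderParams:
    """Rendering model for a hollow tube imaged by fluorescence.

    ``pixel_size`` and ``psf_sigma`` in micrometres; ``tube_outer_radius``
    and ``wall_thickness`` in nanometres.  Intensity is the line integral
    through the annular membrane shell, convolved with a Gaussian PSF and
    scaled so the peak signal equals ``photon_peak`` above ``background``.
    """

    pixel_size: float = 0.1
    psf_sigma: float = 0.125
    tube_outer_radius: float = 44.1
    wall_thickness: float = 4.0
    photon_peak: float = 200.0
    background: float = 10.0
    noise_model: str = "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.wall_thickness < 0 or (
            self.tube_outer_radius > 0 and self.tube_outer_radius <= self.wall_thickness
        ):
            raise ValueError("need tube_outer_radius > wall_thickness >= 0")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def tube_profile(
    d_um: np.ndarray,
    outer_radius_nm: float,
    wall_thickness_nm: float,
    psf_sigma_um: float,
    n_phi: int = 256,
) -> np.ndarray:
    """Cross-sectional intensity profile of a hollow tube, PSF-convolved.

    ``d_um`` are signed distances from the tube axis in micrometres.  The
    profile is the projection of an annular shell (outer radius R, wall
    thickness t) convolved with a Gaussian of ``psf_sigma_um``; peak is
    normalised to 1.  ``R = 0`` renders a line source.
    """
    d = np.atleast_1d(np.asarray(d_um, dtype=float))
    R = outer_radius_nm * 1e-3  # um
    t = min(wall_thickness_nm * 1e-3, R) if R > 0 else 0.0
    sigma = psf_sigma_um if psf_sigma_um > 0 else 1e-4  # numerical line width

    if R == 0:
        prof = np.exp(-0.5 * (d / sigma) ** 2)
        return prof / prof.max()

    # average over shell radii (thin wall -> few radial samples suffice)
    radii = np.linspace(max(R - t, 1e-6) if t > 0 else R, R, 5 if t > 0 else 1)
    phi = (np.arange(n_phi) + 0.5) * np.pi / n_phi
    prof = np.zeros_like(d)
    for r in radii:
        centers = r * np.cos(phi)  # projected positions of shell elements
        prof += np.exp(-0.5 * ((d[:, None] - centers[None, :]) / sigma) ** 2).sum(axis=1)
    return prof / prof.max()


def render_image(
    network_or_chain: FiberChain | FiberNetwork,
    params: RenderParams,
    fov_um: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render a 16-bit image of a chain or network of hollow tubes.

    Returns ``(image, ground_truth)`` where ``image[row, col]`` follows the
    convention that pixel centre ``(row, col)`` sits at world coordinates
    ``origin + (col, row) * pixel_size`` and ground truth carries the
    centerline(s) in pixel coordinates, the tube radius, pixel size and
    origin.
    """
    chains = (
        network_or_chain.chains
        if isinstance(network_or_chain, FiberNetwork)
        else [network_or_chain]
    )
    if not chains:
        raise ValueError("nothing to render")
    allv = np.vstack([c.vertices[:, :2] for c in chains])
    margin = 4.0 * (params.psf_sigma + params.tube_outer_radius * 1e-3) + 2.0 * params.pixel_size
    if fov_um is None:
        x0, y0 = allv.min(axis=0) - margin
        x1, y1 = allv.max(axis=0) + margin
    else:
        (x0, x1), (y0, y1) = fov_um
    if params.pixel_size >= min(x1 - x0, y1 - y0):
        raise ValueError("pixel_size must be smaller than the field of view")

    n_cols = int(math.ceil((x1 - x0) / params.pixel_size)) + 1
    n_rows = int(math.ceil((y1 - y0) / params.pixel_size)) + 1
    origin = np.array([x0, y0])

    # dense centerline points for distance lookup
    dense = np.vstack(
        [resample_polyline(c.vertices[:, :2], params.pixel_size / 4.0) for c in chains]
    )
    tree = cKDTree(dense)
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    px = np.stack([cols.ravel(), rows.ravel()], axis=1) * params.pixel_size + origin
    dist, _ = tree.query(px, workers=-1)

    # 1D profile lookup table
    reach = 5.0 * (params.psf_sigma + params.tube_outer_radius * 1e-3) + params.pixel_size
    d_grid = np.linspace(0.0, reach, 600)
    p_grid = tube_profile(
        d_grid, params.tube_outer_radius, params.wall_thickness, params.psf_sigma
    )
    signal = np.interp(dist, d_grid, p_grid, right=0.0).reshape(n_rows, n_cols)
    expected = params.photon_peak * signal + params.background

    rng = np.random.default_rng(params.seed)
    if params.noise_model == "poisson":
        image = rng.poisson(expected).astype(np.float64)
    elif params.noise_model == "gaussian":
        image = expected + rng.normal(0.0, math.sqrt(max(params.background, 1.0)), expected.shape)
    else:
        image = expected
    image = np.clip(np.round(image), 0, 65535).astype(np.uint16)

    ground_truth = {
        "pixel_size_um": params.pixel_size,
        "origin_um": origin.tolist(),
        "tube_outer_radius_nm": params.tube_outer_radius,
        "psf_sigma_um": params.psf_sigma,
        "centerlines_px": [
            ((c.vertices[:, :2] - origin) / params.pixel_size).tolist() for c in chains
        ],
        "contour_lengths_um": [c.contour_length() for c in chains],
    }
    return image, ground_truth


def generate_localizations(
    chain: FiberChain,
    tube_outer_radius_nm: float = 44.1,
    loc_precision_nm: float = 10.0,
    density_per_um: float = 500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Localization table of fluorophores on the tube surface, projected
    to 2D, in the CSV dialect of single-molecule reconstruction software
    (columns ``"x [nm]"``, ``"y [nm]"``, ``"uncertainty [nm]"``)."""
    if density_per_um <= 0:
        raise ValueError("density_per_um must be positive")
    if loc_precision_nm < 0 or tube_outer_radius_nm < 0:
        raise ValueError("radius and precision must be non-negative")
    rng = np.random.default_rng(seed)
    L_c = chain.contour_length()
    n = rng.poisson(density_per_um * L_c)

    s = np.sort(rng.uniform(0.0, L_c, n))
    arc = chain.arc_positions()
    verts = chain.vertices[:, :2]
    x = np.interp(s, arc, verts[:, 0])
    y = np.interp(s, arc, verts[:, 1])
    # local tangent -> normal
    seg = np.clip(np.searchsorted(arc, s, side="right") - 1, 0, len(arc) - 2)
    tvec = verts[seg + 1] - verts[seg]
    tvec /= np.linalg.norm(tvec, axis=1, keepdims=True)
    normal = np.stack([-tvec[:, 1], tvec[:, 0]], axis=1)

    # ring position projected: offset = R cos(phi) along the normal
    offset_um = tube_outer_radius_nm * 1e-3 * np.cos(rng.uniform(0.0, 2 * np.pi, n))
    pts_nm = (np.stack([x, y], axis=1) + normal * offset_um[:, None]) * 1e3
    if loc_precision_nm > 0:
        pts_nm += rng.normal(0.0, loc_precision_nm, pts_nm.shape)
    return pd.DataFrame(
        {
            "x [nm]": pts_nm[:, 0],
            "y [nm]": pts_nm[:, 1],
            "uncertainty [nm]": np.full(n, float(loc_precision_nm)),
        }
    )


# ---------------------------------------------------------------------------
# Transverse fluctuations of a tensioned filament


@dataclass
class FluctuationParams:
    """Overdamped normal-mode Langevin model of a filament pinned at both
    ends, with bending rigidity ``kappa_pol = L_p k_B T`` and tension
    ``f = tension_stress * pi * R^2`` (stress times outer cross-section;
    the area convention is declared here and in outputs).

    ``active_drift`` [um/s] adds persistent directed motion of the whole
    filament, emulating the motor-driven super-diffusive population.
    """

    persistence_length: float = 3.03  # um
    filament_length: float = 30.0  # um
    tension_stress: float = 58.3  # Pa
    solvent_viscosity: float = DEFAULT_VISCOSITY  # Pa s
    temperature: float = DEFAULT_TEMPERATURE  # K
    tube_radius_nm: float = 44.1
    n_modes: int = 100
    dt: float = 1e-3  # s
    duration: float = 10.0  # s
    active_drift: float = 0.0  # um/s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "persistence_length",
            "filament_length",
            "solvent_viscosity",
            "temperature",
            "tube_radius_nm",
            "dt",
            "duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tension_stress < 0 or self.active_drift < 0:
            raise ValueError("tension_stress and active_drift must be >= 0")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @property
    def kappa_pol(self) -> float:
        """Bending rigidity [J m]."""
        return self.persistence_length * 1e-6 * K_B * self.temperature

    @property
    def tension_force(self) -> float:
        """Tension f = sigma * pi * R^2 [N]."""
        return self.tension_stress * math.pi * (self.tube_radius_nm * 1e-9) ** 2

    @property
    def drag_per_length(self) -> float:
        """Transverse slender-body drag coefficient per unit length
        [Pa s], 4 pi eta / (ln(L/2R) + 0.84)."""
        logterm = math.log(
            self.filament_length * 1e-6 / (2.0 * self.tube_radius_nm * 1e-9)
        )
        return 4.0 * math.pi * self.solvent_viscosity / (logterm + 0.84)

    def mode_wavenumbers(self) -> np.ndarray:
        L = self.filament_length * 1e-6
        return np.arange(1, self.n_modes + 1) * math.pi / L

    def mode_stiffness(self) -> np.ndarray:
        """kappa q^4 + f q^2 per mode [N/m^2... energy density units]."""
        q = self.mode_wavenumbers()
        return self.kappa_pol * q**4 + self.tension_force * q**2

    def mode_relaxation_times(self) -> np.ndarray:
        """tau_q = zeta / (kappa q^4 + f q^2) [s]."""
        return self.drag_per_length / self.mode_stiffness()

    def mode_equilibrium_variance(self) -> np.ndarray:
        """<a_q^2> = k_B T / [(L/2) (kappa q^4 + f q^2)] [m^2]."""
        L = self.filament_length * 1e-6
        return K_B * self.temperature / (0.5 * L * self.mode_stiffness())


def midpoint_msd_expected(params: FluctuationParams, lags_s: np.ndarray) -> np.ndarray:
    """Exact ensemble-average transverse MSD of the filament midpoint [um^2].

    Mode sum 2 <a_q^2> sin^2(q L/2) (1 - exp(-tau/tau_q)) plus the
    ballistic term from ``active_drift``.
    """
    lags = np.asarray(lags_s, dtype=float)
    var = params.mode_equilibrium_variance()
    tau = params.mode_relaxation_times()
    n = np.arange(1, params.n_modes + 1)
    s_mid = np.sin(n * np.pi / 2.0) ** 2
    msd_m2 = (2.0 * var * s_mid * (1.0 - np.exp(-lags[:, None] / tau))).sum(axis=1)
    return msd_m2 * 1e12 + (params.active_drift * lags) ** 2


def simulate_transverse_fluctuations(
    params: FluctuationParams,
    strict_dt: bool = False,
    return_modes: bool = False,
    track_id: str = "sim-0",
):
    """Simulate the midpoint transverse displacement of the filament.

    Each sine mode evolves as an exact Ornstein-Uhlenbeck update (the
    discrete map is statistically exact at any ``dt``); modes whose
    relaxation time is shorter than ``dt`` are therefore still correctly
    equilibrated, but their sub-step dynamics are unresolved, which
    triggers a warning (or an error with ``strict_dt=True``).

    Returns a :class:`~ermech.dynamics.TransverseTrack` (displacement in
    um), or ``(track, modes)`` with the raw mode trajectories when
    ``return_modes`` is set.
    """
    tau = params.mode_relaxation_times()
    if params.dt > tau[-1]:
        mode = int(np.argmax(params.dt > tau)) + 1
        msg = (
            f"dt={params.dt} s exceeds the relaxation time "
            f"{tau[mode - 1]:.3g} s of mode {mode}; dynamics of modes >= {mode} "
            "are unresolved below one sampling step"
        )
        if strict_dt:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    rng = np.random.default_rng(params.seed)
    n_steps = max(1, int(round(params.duration / params.dt)))
    var = params.mode_equilibrium_variance()
    rho = np.exp(-params.dt / tau)
    drive = np.sqrt(var * (1.0 - rho**2))

    n = np.arange(1, params.n_modes + 1)
    s_mid = np.sin(n * np.pi / 2.0)

    a0 = rng.normal(0.0, np.sqrt(var))
    noise = rng.standard_normal((n_steps, params.n_modes))
    modes = None
    if return_modes:
        modes = np.empty((n_steps + 1, params.n_modes))
        modes[0] = a0
    # a_{k+1} = rho a_k + drive xi_k  (exact OU update), vectorised per mode
    # via an AR(1) filter over the time axis.  Even modes have a node at
    # the midpoint and are only evolved when their trajectory is requested.
    traj = np.zeros(n_steps + 1)
    for j in range(params.n_modes):
        if s_mid[j] == 0.0 and modes is None:
            continue
        x = lfilter([1.0], [1.0, -rho[j]], drive[j] * noise[:, j], zi=[rho[j] * a0[j]])[0]
        aj = np.concatenate([[a0[j]], x])
        if modes is not None:
            modes[:, j] = aj
        if s_mid[j] != 0.0:
            traj += s_mid[j] * aj
    h = traj * 1e6  # m -> um

    times = np.arange(n_steps + 1) * params.dt
    h = h + params.active_drift * times
    track = TransverseTrack(times=times, displacement=h, track_id=track_id)
    if return_modes:
        return track, {
            "amplitudes_m": modes,
            "equilibrium_variance_m2": var,
            "relaxation_times_s": tau,
        }
    return track


def generate_track_population(
    n_passive: int,
    n_active: int,
    params: FluctuationParams | None = None,
    seed: int = 0,
    active_drift: float | None = None,
) -> tuple[list[TransverseTrack], list[str]]:
    """Labelled mixture of passive (tensioned, sub-diffusive) and actively
    driven (super-diffusive) transverse tracks for classifier testing.

    Returns ``(tracks, labels)`` with labels ``"passive"``/``"active"``.
    """
    if n_passive + n_active < 1:
        raise ValueError("need at least one track")
    if params is None:
        params = FluctuationParams()
    drift = active_drift if active_drift is not None else (
        params.active_drift if params.active_drift > 0 else 0.2
    )
    rng = np.random.default_rng(seed)
    tracks: list[TransverseTrack] = []
    labels: list[str] = []
    from dataclasses import replace

    for i in range(n_passive + n_active):
        is_active = i >= n_passive
        p = replace(
            params,
            active_drift=drift if is_active else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        kind = "active" if is_active else "passive"
        tracks.append(
            simulate_transverse_fluctuations(p, track_id=f"{kind}-{i}")
        )
        labels.append(kind)
    return tracks, labels
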