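"""Persistence-length estimation from traced fibre geometry.

For a worm-like chain the mean-square end-to-end distance is

    <R^2> = 2 L_p (L_c - L_p [1 - exp(-L_c / L_p)])

so measuring (L_c, R) per fibre and fitting this relation yields the
persistence length L_p.  The end-to-end route is preferred over direct
tangent-correlation fitting because it is dominated by the longest
bending modes and therefore less sensitive to short-length-scale tracing
noise; a tangent-correlation estimator is provided as a diagnostic only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .chains import FiberChain, FiberNetwork
from .synthetic import wlc_mean_square_end_to_end

__all__ = [
    "ChainGeometry",
    "PersistenceFit",
    "LogNormalSummary",
    "chain_geometry",
    "wlc_msre",
    "fit_persistence_length",
    "invert_single_chain",
    "segment_between_junctions",
    "fit_lognormal",
    "tangent_correlation_lp",
]

# closed form shared with the generator module
wlc_msre = wlc_mean_square_end_to_end


@dataclass
class ChainGeometry:
    """Contour length and end-to-end distance of one fibre [um]."""

    contour_length: float
    end_to_end: float
    chain_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.end_to_end <= self.contour_length * (1 + 1e-9)):
            raise ValueError(
                f"need 0 <= R <= L_c, got R={self.end_to_end}, L_c={self.contour_length}"
            )


@dataclass
class PersistenceFit:
    """Fitted persistence length with its uncertainty."""

    L_p: float  # um
    stderr: float  # um
    n_chains: int
    fit_domain: tuple[float, float]  # (min L_c, max L_c) used
    method: str  # "ensemble_binned", "ensemble_unbinned" or "per_fiber"
    flagged: int = 0  # chains hitting the inversion bracket (per_fiber)


@dataclass
class LogNormalSummary:
    """Maximum-likelihood log-normal fit of a positive-valued sample."""

    mu: float  # mean of log values
    sigma_log: float  # sd of log values
    mean: float  # arithmetic mean of the sample
    n: int
    degenerate: bool = False  # all values (numerically) equal


def chain_geometry(chain: FiberChain) -> ChainGeometry:
    """L_c (sum of segment lengths) and R (first-to-last distance)."""
    return ChainGeometry(
        contour_length=chain.contour_length(),
        end_to_end=chain.end_to_end(),
        chain_id=chain.chain_id,
    )


def invert_single_chain(
    geom: ChainGeometry, bracket_scale: float | None = None
) -> tuple[float, bool]:
    """Per-fibre L_p from inverting the end-to-end relation by bisection.

    Returns ``(L_p, flagged)``; ``flagged`` is True when R >= L_c (or the
    root lies outside the bracket), in which case L_p sits at the upper
    bracket.  ``bracket_scale`` defaults to the chain's own L_c.
    """
    L_c, R = geom.contour_length, geom.end_to_end
    scale = bracket_scale if bracket_scale is not None else L_c
    lo, hi = 1e-4 * scale, 1e4 * scale
    target = R**2
    if target >= wlc_msre(L_c, hi):
        return hi, True
    if target <= wlc_msre(L_c, lo):
        return lo, True
    lp = brentq(lambda p: wlc_msre(L_c, p) - target, lo, hi, xtol=1e-12 * scale)
    return float(lp), False


def fit_persistence_length(
    geoms: list[ChainGeometry],
    method: str = "ensemble_binned",
    n_bins: int = 12,
) -> PersistenceFit:
    """Fit L_p to a set of (L_c, R) measurements.

    ``ensemble_binned`` (default): R^2 is averaged within log-spaced L_c
    bins and the end-to-end relation is fitted by weighted nonlinear least
    squares (weights = per-bin counts).  ``ensemble_unbinned`` fits all
    (L_c, R^2) pairs directly.  ``per_fiber`` inverts the relation per
    fibre and summarises the distribution by its mean, with the standard
    error of the mean as the uncertainty.
    """
    if method not in ("ensemble_binned", "ensemble_unbinned", "per_fiber"):
        raise ValueError(f"unknown method {method!r}")
    if not geoms:
        raise ValueError("no chains given")
    L_c = np.array([g.contour_length for g in geoms])
    R2 = np.array([g.end_to_end**2 for g in geoms])
    if np.all(L_c <= 0):
        raise ValueError("all chains have zero contour length")
    domain = (float(L_c.min()), float(L_c.max()))

    if method == "per_fiber":
        scale = float(np.median(L_c))
        values, flags = [], 0
        for g in geoms:
            lp, flagged = invert_single_chain(g, bracket_scale=scale)
            values.append(lp)
            flags += int(flagged)
        values = np.array(values)
        ok = values[np.isfinite(values)]
        return PersistenceFit(
            L_p=float(np.mean(ok)),
            stderr=float(np.std(ok, ddof=1) / math.sqrt(len(ok))) if len(ok) > 1 else 0.0,
            n_chains=len(geoms),
            fit_domain=domain,
            method=method,
            flagged=flags,
        )

    if len(geoms) < 5:
        raise ValueError("ensemble fit needs at least 5 chains")

    if method == "ensemble_binned":
        edges = np.geomspace(L_c.min() * (1 - 1e-9), L_c.max() * (1 + 1e-9), n_bins + 1)
        idx = np.clip(np.digitize(L_c, edges) - 1, 0, n_bins - 1)
        xs, ys, ws = [], [], []
        for b in range(n_bins):
            sel = idx == b
            if sel.sum() == 0:
                continue
            xs.append(L_c[sel].mean())
            ys.append(R2[sel].mean())
            ws.append(sel.sum())
        x, y, w = np.array(xs), np.array(ys), np.array(ws, dtype=float)
    else:
        x, y, w = L_c, R2, np.ones_like(L_c)

    def model(lc, lp):
        return np.array([wlc_msre(v, lp) for v in np.atleast_1d(lc)])

    # R^2 fluctuations scale with their mean, so the fit needs relative
    # weights; weighting by the *observed* values would correlate the
    # weights with the noise and bias L_p, so iterate with model-based
    # weights instead (IRLS, converges in a couple of rounds).
    lp = max(float(np.median(L_c)), 1e-6)
    popt, pcov = [lp], None
    for _ in range(3):
        sigma = model(x, popt[0]) / np.sqrt(w)
        popt, pcov = curve_fit(
            model, x, y, p0=[popt[0]], sigma=sigma, absolute_sigma=False,
            bounds=(1e-8, np.inf), maxfev=10000,
        )
    return PersistenceFit(
        L_p=float(popt[0]),
        stderr=float(np.sqrt(pcov[0, 0])),
        n_chains=len(geoms),
        fit_domain=domain,
        method=method,
    )


def segment_between_junctions(
    network: FiberNetwork, junction_radius: float = 0.15, min_vertices: int = 3
) -> list[FiberChain]:
    """Cut every chain at its junction-adjacent vertices.

    Vertices within ``junction_radius`` (um) of any junction are treated
    as junction material and excluded; the remaining runs of consecutive
    vertices become independent segments (runs shorter than
    ``min_vertices`` are discarded).  Junction-free chains pass through
    unchanged.
    """
    if not network.junctions:
        return list(network.chains)
    jxy = network.junction_coords()
    out: list[FiberChain] = []
    for chain in network.chains:
        verts = chain.vertices[:, :2]
        d = np.min(np.linalg.norm(verts[:, None, :] - jxy[None, :, :], axis=2), axis=1)
        keep = d > junction_radius
        if keep.all():
            out.append(chain)
            continue
        # contiguous runs of kept vertices
        edges = np.flatnonzero(np.diff(np.concatenate([[0], keep.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start >= min_vertices:
                out.append(
                    FiberChain(
                        vertices=chain.vertices[start:stop],
                        segment_length=chain.segment_length,
                        source_image_id=chain.source_image_id,
                        chain_id=f"{chain.chain_id}[{start}:{stop}]",
                    )
                )
    return out


def fit_lognormal(values) -> LogNormalSummary:
    """MLE log-normal fit (mean and sd of log values)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(v <= 0):
        raise ValueError("log-normal fit requires strictly positive values")
    logs = np.log(v)
    sigma = float(np.std(logs, ddof=0))
    return LogNormalSummary(
        mu=float(np.mean(logs)),
        sigma_log=sigma,
        mean=float(np.mean(v)),
        n=int(v.size),
        degenerate=sigma < 1e-12,
    )


def tangent_correlation_lp(chain: FiberChain, max_separation: float | None = None) -> float:
    """Diagnostic L_p from the tangent autocorrelation decay.

    Fits log <t(0) . t(s)> = -s / L_p over separations up to
    ``max_separation`` (default: half the contour length).
    """
    vec = chain.segment_vectors
    tang = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    ds = float(np.mean(chain.segment_lengths))
    n = tang.shape[0]
    max_k = n - 1 if max_separation is None else min(n - 1, int(max_separation / ds))
    if max_k < 1:
        raise ValueError("chain too short for tangent correlation")
    seps, corr = [], []
    for k in range(1, max_k + 1):
        c = float(np.mean((tang[:-k] * tang[k:]).sum(axis=1)))
        if c <= 0:
            break
        seps.append(k * ds)
        corr.append(c)
    if len(seps) < 2:
        raise ValueError("tangent correlation decays too fast to fit")
    slope = np.polyfit(np.array(seps), np.log(np.array(corr)), 1)[0]
    if slope >= 0:
        raise ValueError("tangent correlation does not decay")
    return float(-1.0 / slope)
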