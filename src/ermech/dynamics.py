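"""Transverse-motion analysis: MSD curves, power-law regimes, population
splitting, and tension-stress estimation.

The measured quantity is the signed displacement of one tubule point along
a fixed line perpendicular to the tubule backbone.  Its time-averaged MSD

    msd(tau) = < (h(t + tau) - h(t))^2 >_t

is fitted with power laws ``A tau^alpha``; sub-diffusive tracks
(alpha < 1 at long lags) are equilibrium fluctuations of a filament under
tension and their ensemble amplitude yields the tension stress, while
super-diffusive tracks (1 < alpha < 2) reflect active, motor-driven
transport.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, DEFAULT_TEMPERATURE

__all__ = [
    "TransverseTrack",
    "MSDCurve",
    "PowerLawFit",
    "PopulationSplit",
    "StressEstimate",
    "track_transverse",
    "compute_msd",
    "fit_power_law",
    "classify_tracks",
    "ensemble_msd",
    "estimate_stress",
    "transverse_msd_model",
]


@dataclass
class TransverseTrack:
    """Signed transverse position of one tubule point over time.

    ``times`` in seconds (uniformly spaced), ``displacement`` in um.
    """

    times: np.ndarray
    displacement: np.ndarray
    track_id: str = ""
    #: ratio of longitudinal to transverse displacement variance, when the
    #: track was built by projecting 2D motion onto the backbone normal
    longitudinal_fraction: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.displacement.size:
            raise ValueError("times and displacement must be 1D and equal length")
        if self.times.size < 2:
            raise ValueError("a track needs at least 2 samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform within 1%")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class MSDCurve:
    """Time-averaged MSD versus lag time."""

    lags: np.ndarray  # s, ascending
    msd: np.ndarray  # um^2
    n_pairs: np.ndarray  # overlapping pairs per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class PowerLawFit:
    """msd = A * tau^alpha over a lag window, from a log-log fit."""

    alpha: float
    prefactor: float  # um^2 s^-alpha
    fit_window: tuple[float, float]
    r_squared: float


@dataclass
class PopulationSplit:
    """Per-track labels and per-population ensemble curves."""

    labels: dict[str, str]  # track_id -> label
    alphas: dict[str, float]  # track_id -> long-lag exponent (labelled tracks)
    ensembles: dict[str, MSDCurve]  # population -> ensemble MSD
    regime_fits: dict[str, PowerLawFit]  # named fits (see classify_tracks)


@dataclass
class StressEstimate:
    """Tension stress from the sub-diffusive fluctuation amplitude."""

    sigma_Pa: float
    tension_force_N: float  # with the declared area convention f = sigma pi R^2
    tension_length_m: float  # l_t = sqrt(kappa_pol / f)
    prefactor_A: float  # um^2 s^-1/2
    alpha_check: float  # exponent measured on the input curve
    L_p_assumed_um: float
    eta_assumed_Pa_s: float
    temperature_K: float
    radius_assumed_nm: float
    area_convention: str = "f = sigma * pi * R_outer^2"
    validity_sigma_min_Pa: float | None = None


# ---------------------------------------------------------------------------


def track_transverse(
    times: np.ndarray,
    positions: np.ndarray,
    reference_chain,
    track_id: str = "",
) -> TransverseTrack:
    """Project 2D point positions onto the perpendicular of the nearest
    backbone segment (at t=0), giving the signed transverse displacement.

    The ratio of longitudinal to transverse displacement variance is
    recorded on the track, quantifying how good the transverse
    approximation is for this motion.
    """
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2 or positions.shape[0] < 2:
        raise ValueError("positions must be (n, 2) with n >= 2")

    verts = reference_chain.vertices[:, :2]
    seg_vec = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    p0 = positions[0]
    # nearest segment to the initial position
    t_par = np.clip(
        ((p0 - verts[:-1]) * seg_vec).sum(axis=1) / seg_len**2, 0.0, 1.0
    )
    feet = verts[:-1] + t_par[:, None] * seg_vec
    i = int(np.argmin(np.linalg.norm(feet - p0, axis=1)))
    tangent = seg_vec[i] / seg_len[i]
    normal = np.array([-tangent[1], tangent[0]])

    rel = positions - feet[i]
    transverse = rel @ normal
    longitudinal = rel @ tangent
    var_l = float(np.var(longitudinal))
    var_t = float(np.var(transverse))
    frac = var_l / var_t if var_t > 0 else math.inf
    return TransverseTrack(
        times=times,
        displacement=transverse,
        track_id=track_id,
        longitudinal_fraction=frac,
    )


def compute_msd(track: TransverseTrack, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD at every integer-multiple lag up to
    ``max_lag_fraction`` of the track duration.

    Equals the naive double-loop average exactly (same pairs, same
    weights).
    """
    h = track.displacement
    n = h.size
    dt = track.dt
    max_lag = max(1, int(math.floor(max_lag_fraction * (n - 1))))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in lags:
        diff = h[k:] - h[:-k]
        msd[k - 1] = np.mean(diff**2)
        n_pairs[k - 1] = diff.size
    return MSDCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def fit_power_law(curve: MSDCurve, window: tuple[float, float]) -> PowerLawFit:
    """Least-squares fit of log(msd) vs log(tau) within ``window``."""
    lo, hi = window
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    sel &= curve.msd > 0
    if sel.sum() < 4:
        raise ValueError(
            f"need >= 4 positive MSD points in window ({lo}, {hi}), got {int(sel.sum())}"
        )
    x = np.log(curve.lags[sel])
    y = np.log(curve.msd[sel])
    alpha, logA = np.polyfit(x, y, 1)
    resid = y - (alpha * x + logA)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        alpha=float(alpha),
        prefactor=float(np.exp(logA)),
        fit_window=(lo, hi),
        r_squared=r2,
    )


def ensemble_msd(
    curves: list[MSDCurve], weight_by_pairs: bool = False
) -> MSDCurve:
    """Average MSD curves across tracks at their common lags.

    By default every track contributes equally at each shared lag;
    ``weight_by_pairs`` switches to weighting by the number of
    overlapping pairs.
    """
    if not curves:
        raise ValueError("no curves to average")
    # common lag grid: lags present in every curve (uniform dt assumed)
    common = curves[0].lags
    for c in curves[1:]:
        common = common[np.isin(np.round(common, 9), np.round(c.lags, 9))]
    if common.size == 0:
        raise ValueError("curves share no common lags")
    msd = np.zeros_like(common)
    wsum = np.zeros_like(common)
    npairs = np.zeros(common.size, dtype=int)
    for c in curves:
        idx = np.searchsorted(np.round(c.lags, 9), np.round(common, 9))
        w = c.n_pairs[idx].astype(float) if weight_by_pairs else np.ones(common.size)
        msd += w * c.msd[idx]
        wsum += w
        npairs += c.n_pairs[idx]
    return MSDCurve(lags=common, msd=msd / wsum, n_pairs=npairs)


def classify_tracks(
    tracks: list[TransverseTrack],
    short_cutoff: float = 5.0,
    regime_break: float = 2.0,
    alpha_split: float = 1.0,
    alpha_ballistic: float = 2.0,
    max_lag_fraction: float = 0.5,
    weight_by_pairs: bool = False,
) -> PopulationSplit:
    """Split tracks into sub- and super-diffusive populations.

    Tracks shorter than ``short_cutoff`` seconds are excluded.  Each
    remaining track gets a long-lag exponent alpha from a log-log fit of
    its MSD at lags above ``regime_break``; ``alpha < alpha_split`` labels
    it sub-diffusive, ``alpha_split <= alpha < alpha_ballistic``
    super-diffusive, and ``alpha >= alpha_ballistic`` is excluded as
    anomalously fast.  Ensemble MSDs are computed per population, and the
    super-diffusive ensemble additionally gets short-lag
    (``tau <= regime_break``) and long-lag regime fits.
    """
    if not tracks:
        raise ValueError("no tracks given")
    labels: dict[str, str] = {}
    alphas: dict[str, float] = {}
    curves: dict[str, MSDCurve] = {}
    for i, tr in enumerate(tracks):
        tid = tr.track_id or f"track-{i}"
        if tr.duration < short_cutoff:
            labels[tid] = "excluded_short"
            continue
        curve = compute_msd(tr, max_lag_fraction=max_lag_fraction)
        try:
            fit = fit_power_law(curve, (regime_break, curve.lags[-1]))
        except ValueError:
            labels[tid] = "excluded_short"
            continue
        curves[tid] = curve
        alphas[tid] = fit.alpha
        if fit.alpha < alpha_split:
            labels[tid] = "subdiffusive"
        elif fit.alpha < alpha_ballistic:
            labels[tid] = "superdiffusive"
        else:
            labels[tid] = "excluded_fast"
    if not any(lbl in ("subdiffusive", "superdiffusive") for lbl in labels.values()):
        raise ValueError("no track survives the duration and exponent filters")

    ensembles: dict[str, MSDCurve] = {}
    regime_fits: dict[str, PowerLawFit] = {}
    for pop in ("subdiffusive", "superdiffusive"):
        members = [curves[t] for t, lbl in labels.items() if lbl == pop]
        if not members:
            continue
        ens = ensemble_msd(members, weight_by_pairs=weight_by_pairs)
        ensembles[pop] = ens
        try:
            if pop == "subdiffusive":
                regime_fits["subdiffusive"] = fit_power_law(
                    ens, (ens.lags[0], ens.lags[-1])
                )
            else:
                regime_fits["superdiffusive_short"] = fit_power_law(
                    ens, (ens.lags[0], regime_break)
                )
                regime_fits["superdiffusive_long"] = fit_power_law(
                    ens, (regime_break, ens.lags[-1])
                )
        except ValueError:
            pass
    return PopulationSplit(
        labels=labels, alphas=alphas, ensembles=ensembles, regime_fits=regime_fits
    )


# ---------------------------------------------------------------------------
# Tension stress from the fluctuation amplitude


def transverse_msd_model(
    tau_s: np.ndarray,
    sigma_Pa: float,
    L_p_um: float,
    eta_Pa_s: float,
    temperature_K: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Tensioned-fibre transverse MSD model, msd = A tau^{1/2} with

        A = (k_B T / sigma)^{3/4} L_p^{1/4} / (2 eta^{1/2})

    evaluated in SI and returned in um^2 (tau in seconds).
    """
    tau = np.asarray(tau_s, dtype=float)
    kT = K_B * temperature_K
    A = (kT / sigma_Pa) ** 0.75 * (L_p_um * 1e-6) ** 0.25 / (2.0 * math.sqrt(eta_Pa_s))
    return A * np.sqrt(tau) * 1e12


def estimate_stress(
    subdiffusive_ensemble: MSDCurve,
    L_p_um: float,
    eta_Pa_s: float,
    temperature_K: float = DEFAULT_TEMPERATURE,
    radius_nm: float = 44.1,
    contour_length_um: float | None = None,
) -> StressEstimate:
    """Invert the tensioned-fibre amplitude for the tension stress.

    Fits ``msd = A tau^{1/2}`` (linear least squares in sqrt(tau)) and
    inverts ``sigma = k_B T (L_p^{1/4} / (2 eta^{1/2} A))^{4/3}``.  Also
    reports the tension force ``f = sigma pi R^2`` (area convention
    declared on the result), the tension length ``l_t = sqrt(kappa_pol/f)``
    and, if a contour length is given, the lower stress bound
    ``k_B T L_p / L^2`` for the validity of the tensioned-fluctuation
    regime.
    """
    curve = subdiffusive_ensemble
    if curve.lags.size < 2:
        raise ValueError("need at least 2 MSD points")
    fit = fit_power_law(curve, (curve.lags[0], curve.lags[-1]))
    if abs(fit.alpha - 0.5) > 0.1:
        warnings.warn(
            f"ensemble MSD exponent {fit.alpha:.3f} deviates from the tau^1/2 "
            "tensioned-fibre regime; stress estimate may not apply",
            stacklevel=2,
        )
    # amplitude with the exponent pinned at 1/2
    root_tau = np.sqrt(curve.lags)
    A_um = float(np.dot(root_tau, curve.msd) / np.dot(root_tau, root_tau))
    if A_um <= 0:
        raise ValueError("non-positive fitted amplitude")
    A_SI = A_um * 1e-12  # m^2 s^-1/2

    kT = K_B * temperature_K
    sigma = kT * ((L_p_um * 1e-6) ** 0.25 / (2.0 * math.sqrt(eta_Pa_s) * A_SI)) ** (4.0 / 3.0)
    kappa_pol = L_p_um * 1e-6 * kT
    force = sigma * math.pi * (radius_nm * 1e-9) ** 2
    l_t = math.sqrt(kappa_pol / force)
    sigma_min = None
    if contour_length_um is not None:
        sigma_min = kT * L_p_um * 1e-6 / (contour_length_um * 1e-6) ** 2
    return StressEstimate(
        sigma_Pa=float(sigma),
        tension_force_N=float(force),
        tension_length_m=float(l_t),
        prefactor_A=A_um,
        alpha_check=fit.alpha,
        L_p_assumed_um=L_p_um,
        eta_assumed_Pa_s=eta_Pa_s,
        temperature_K=temperature_K,
        radius_assumed_nm=radius_nm,
        validity_sigma_min_Pa=sigma_min,
    )
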