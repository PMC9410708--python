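"""Nanorheology from GEM nanoparticle tracks.

40-nm genetically encoded multimeric nanoparticles (GEMs) act as passive
rheological probes of the cytoplasm and nucleoplasm.  Starting from 2D
particle tracks (100 Hz, 10 s by default), this module computes
time-averaged mean-square displacements, the truncated effective
diffusivity (MSD = 4 D_eff tau over the first lags), the anomalous exponent
alpha from the log-log MSD slope, and fits of the Phillies stretched-
exponential model D_eff = D0 exp(-beta C^lambda) relating tracer mobility
to macromolecular crowding.  Inverting the lambda = 1 Phillies law converts
relative D_eff changes into relative concentration (dilution) changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .constants import (
    DEFAULT_TEMPERATURE_K,
    K_BOLTZMANN,
    M2_PER_S_TO_UM2_PER_S,
    WATER_VISCOSITY_30C,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrackSet",
    "MSDCurve",
    "DiffusionFit",
    "PhilliesFit",
    "VolumePhilliesFit",
    "compute_msd",
    "fit_deff",
    "fit_deff_per_track",
    "fit_alpha",
    "stokes_einstein_d0",
    "fit_phillies",
    "phillies_vs_volume",
    "infer_dilution_from_deff",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass
class TrackSet:
    """2D particle trajectories with acquisition metadata.

    ``data`` holds one row per localization with columns ``track_id``,
    ``frame``, ``t_s``, ``x_um``, ``y_um``.  Frames must strictly increase
    within each track; gaps are allowed and break a track into segments
    during MSD computation.
    """

    data: pd.DataFrame
    dt: float = 0.01  # frame interval, s
    compartment: str = ""  # {cytoplasm, nucleoplasm}
    condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if self.data.empty:
            raise ValueError("track table is empty")
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        frame_diff = self.data.groupby("track_id")["frame"].diff().dropna()
        if (frame_diff <= 0).any():
            raise ValueError("frames must strictly increase within each track")

    @property
    def n_tracks(self) -> int:
        return int(self.data["track_id"].nunique())


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble MSD as a function of lag time."""

    tau: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # um^2
    n_displacements: np.ndarray
    mode: str = "ensemble"
    n_tracks: int = 0


@dataclass(frozen=True)
class DiffusionFit:
    """Effective diffusivity and/or anomalous exponent of an MSD curve."""

    D_eff: float = float("nan")  # um^2/s
    alpha: float = float("nan")
    stderr_D: float = float("nan")
    stderr_alpha: float = float("nan")
    n_lags: int = 0
    n_tracks: int = 0


@dataclass(frozen=True)
class PhilliesFit:
    """Phillies stretched-exponential fit D = D0 exp(-beta C^lambda)."""

    D0: float
    beta: float
    lam: float
    stderr_D0: float = float("nan")
    stderr_beta: float = float("nan")
    stderr_lam: float = float("nan")
    covariance: np.ndarray = field(default_factory=lambda: np.full((3, 3), np.nan))
    lambda_fixed: bool = True

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return self.D0 * np.exp(-self.beta * np.asarray(conc, dtype=float) ** self.lam)


@dataclass(frozen=True)
class VolumePhilliesFit:
    """Volume parameterization ln D = ln A - kappa / (V - b) of the lambda=1 law."""

    A: float
    kappa: float
    b: float
    stderr_lnA: float = float("nan")
    stderr_kappa: float = float("nan")

    def predict(self, volume: np.ndarray) -> np.ndarray:
        v = np.asarray(volume, dtype=float)
        return self.A * np.exp(-self.kappa / (v - self.b))


def _segments(track: pd.DataFrame) -> list[np.ndarray]:
    """Split one track at frame gaps into contiguous (x, y) segments."""
    frames = track["frame"].to_numpy()
    xy = track[["x_um", "y_um"]].to_numpy(dtype=float)
    breaks = np.flatnonzero(np.diff(frames) != 1)
    return [seg for seg in np.split(xy, breaks + 1)]


def compute_msd(
    tracks: TrackSet,
    max_lag_frames: int = 100,
    mode: str = "ensemble",
    min_track_length: int = 10,
) -> MSDCurve:
    """Time-averaged MSD per track, pooled across the ensemble.

    For each contiguous track segment of length L and each lag k <= L - 1,
    all L - k overlapping displacements contribute.  In ``ensemble`` mode
    (default) the pooled MSD at each lag is the displacement-count-weighted
    mean; ``mean_of_tracks`` averages per-track MSD curves unweighted.
    Tracks shorter than ``min_track_length`` frames are discarded.
    """
    if mode not in ("ensemble", "mean_of_tracks"):
        raise ValueError(f"unknown averaging mode {mode!r}")
    sums = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=np.int64)
    per_track: list[np.ndarray] = []
    n_used = 0
    for _, track in tracks.data.groupby("track_id", sort=False):
        if len(track) < min_track_length:
            continue
        n_used += 1
        t_sums = np.zeros(max_lag_frames)
        t_counts = np.zeros(max_lag_frames, dtype=np.int64)
        for seg in _segments(track):
            L = len(seg)
            for k in range(1, min(max_lag_frames, L - 1) + 1):
                d = seg[k:] - seg[:-k]
                t_sums[k - 1] += float(np.einsum("ij,ij->", d, d))
                t_counts[k - 1] += L - k
        sums += t_sums
        counts += t_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            per_track.append(np.where(t_counts > 0, t_sums / t_counts, np.nan))
    if n_used == 0:
        raise ValueError(
            f"no track has >= {min_track_length} frames; nothing to average"
        )
    valid = counts > 0
    tau = (np.arange(1, max_lag_frames + 1) * tracks.dt)[valid]
    if mode == "ensemble":
        msd = (sums[valid] / counts[valid])
    else:
        stacked = np.vstack(per_track)[:, valid]
        msd = np.nanmean(stacked, axis=0)
    return MSDCurve(tau=tau, msd=msd, n_displacements=counts[valid], mode=mode, n_tracks=n_used)


def fit_deff(msd: MSDCurve, n_points: int = 10, with_offset: bool = False) -> DiffusionFit:
    """Truncated-MSD effective diffusivity: MSD(tau) = 4 D_eff tau.

    Least squares through the origin on the first ``n_points`` lags (the
    canonical 2D Brownian law has no offset).  ``with_offset`` adds a free
    intercept, useful when quantifying static localization error, which
    inflates the MSD by 4 sigma_loc^2.
    """
    if msd.tau.size < n_points:
        raise ValueError(
            f"requested {n_points} lags but MSD has only {msd.tau.size}: "
            f"available lags up to {msd.tau.max() if msd.tau.size else 0:.4g} s"
        )
    tau = msd.tau[:n_points]
    y = msd.msd[:n_points]
    X = np.column_stack([4.0 * tau, np.ones_like(tau)]) if with_offset else (4.0 * tau)[:, None]
    res = sm.OLS(y, X).fit()
    return DiffusionFit(
        D_eff=float(res.params[0]),
        stderr_D=float(res.bse[0]),
        n_lags=n_points,
        n_tracks=msd.n_tracks,
    )


def fit_deff_per_track(
    tracks: TrackSet, n_points: int = 10, min_track_length: int = 10
) -> pd.DataFrame:
    """Per-track truncated-MSD diffusivities (one D_eff per track)."""
    rows = []
    for tid, track in tracks.data.groupby("track_id", sort=False):
        if len(track) < min_track_length:
            continue
        sub = TrackSet(track, dt=tracks.dt, compartment=tracks.compartment)
        msd = compute_msd(sub, max_lag_frames=n_points, min_track_length=min_track_length)
        if msd.tau.size < n_points:
            continue
        rows.append({"track_id": tid, "d_eff": fit_deff(msd, n_points).D_eff})
    if not rows:
        raise ValueError("no track long enough for a per-track fit")
    return pd.DataFrame(rows)


def fit_alpha(msd: MSDCurve, fit_range: tuple[int, int] = (2, 50)) -> DiffusionFit:
    """Anomalous exponent from the log-log MSD slope, MSD ~ tau^alpha.

    ``fit_range`` selects lag indices (1-based frame lags, default 2-50).
    Non-positive MSD values in range are excluded with a warning.  Values of
    alpha outside (0.3, 1.5) are flagged in the log: they usually indicate a
    fit-range or tracking problem rather than genuine physics.
    """
    lo, hi = fit_range
    lag_index = np.rint(msd.tau / msd.tau[0]).astype(int) if msd.tau.size else np.array([])
    sel = (lag_index >= lo) & (lag_index <= hi)
    tau, y = msd.tau[sel], msd.msd[sel]
    pos = y > 0
    if (~pos).any():
        logger.warning("excluding %d non-positive MSD values from alpha fit", int((~pos).sum()))
        tau, y = tau[pos], y[pos]
    if tau.size < 5:
        raise ValueError(f"need >= 5 usable lags in range {fit_range}, have {tau.size}")
    res = sm.OLS(np.log(y), sm.add_constant(np.log(tau))).fit()
    alpha = float(res.params[1])
    if not (0.3 < alpha < 1.5):
        logger.warning("fitted alpha=%.3g outside the plausible (0.3, 1.5) band", alpha)
    return DiffusionFit(
        alpha=alpha,
        stderr_alpha=float(res.bse[1]),
        n_lags=int(tau.size),
        n_tracks=msd.n_tracks,
    )


def stokes_einstein_d0(
    radius_m: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    viscosity_pa_s: float = WATER_VISCOSITY_30C,
) -> float:
    """Stokes-Einstein diffusivity kB T / (6 pi eta r) in um^2/s."""
    if radius_m <= 0 or temperature <= 0 or viscosity_pa_s <= 0:
        raise ValueError("radius, temperature and viscosity must be positive")
    d_m2_s = K_BOLTZMANN * temperature / (6.0 * np.pi * viscosity_pa_s * radius_m)
    return d_m2_s * M2_PER_S_TO_UM2_PER_S


def _clean_positive(conc: np.ndarray, deff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    conc = np.asarray(conc, dtype=float)
    deff = np.asarray(deff, dtype=float)
    ok = deff > 0
    if (~ok).any():
        logger.warning("excluding %d non-positive D_eff values", int((~ok).sum()))
    return conc[ok], deff[ok]


def fit_phillies(
    table: pd.DataFrame,
    lambda_mode: str | float = "free",
    conc_col: str = "conc",
    deff_col: str = "d_eff",
) -> PhilliesFit:
    """Fit the Phillies law D = D0 exp(-beta C^lambda).

    With lambda fixed (``lambda_mode`` a number) the model is linear in
    ln D vs C^lambda and solved by OLS.  With ``lambda_mode='free'`` a
    nonlinear least-squares fit of (ln D0, beta, lambda) is initialized
    from the lambda = 1 linear fit.
    """
    conc, deff = _clean_positive(table[conc_col], table[deff_col])
    free = lambda_mode == "free"
    if np.unique(conc).size < (4 if free else 3):
        raise ValueError(
            f"need >= {4 if free else 3} distinct concentrations, have {np.unique(conc).size}"
        )
    log_d = np.log(deff)

    def linear_fit(lam: float):
        res = sm.OLS(log_d, sm.add_constant(conc**lam)).fit()
        return res

    if not free:
        lam = float(lambda_mode)
        res = linear_fit(lam)
        ln_d0, slope = float(res.params[0]), float(res.params[1])
        cov = np.full((3, 3), np.nan)
        cov[:2, :2] = np.asarray(res.cov_params())
        return PhilliesFit(
            D0=float(np.exp(ln_d0)),
            beta=-slope,
            lam=lam,
            stderr_D0=float(np.exp(ln_d0) * res.bse[0]),
            stderr_beta=float(res.bse[1]),
            covariance=cov,
            lambda_fixed=True,
        )

    init = linear_fit(1.0)
    p0 = [float(init.params[0]), max(-float(init.params[1]), 1e-8), 1.0]

    def model(c, ln_d0, beta, lam):
        return ln_d0 - beta * c**lam

    try:
        popt, pcov = curve_fit(model, conc, log_d, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"free-lambda Phillies fit did not converge ({exc}); the lambda=1 "
            f"linear fit gives D0={np.exp(p0[0]):.4g}, beta={p0[1]:.4g}"
        ) from exc
    ln_d0, beta, lam = popt
    se = np.sqrt(np.diag(pcov))
    return PhilliesFit(
        D0=float(np.exp(ln_d0)),
        beta=float(beta),
        lam=float(lam),
        stderr_D0=float(np.exp(ln_d0) * se[0]),
        stderr_beta=float(se[1]),
        stderr_lam=float(se[2]),
        covariance=pcov,
        lambda_fixed=False,
    )


def phillies_vs_volume(
    table: pd.DataFrame,
    b: float,
    volume_col: str = "volume_um3",
    deff_col: str = "d_eff",
) -> VolumePhilliesFit:
    """Phillies lambda=1 law parameterized by compartment volume.

    For an ideal osmometer the internal concentration is C = N/(V - b), so
    the lambda = 1 Phillies law becomes ln D = ln A - kappa/(V - b) with
    kappa = beta N.  Linear in 1/(V - b); fitted by OLS.
    """
    vol = np.asarray(table[volume_col], dtype=float)
    if (vol <= b).any():
        bad = vol[vol <= b]
        raise ValueError(f"volumes must exceed the dry volume b={b}; offending: {bad[:5]}")
    _, deff = _clean_positive(vol, np.asarray(table[deff_col], dtype=float))
    vol = vol[np.asarray(table[deff_col], dtype=float) > 0]
    x = 1.0 / (vol - b)
    res = sm.OLS(np.log(deff), sm.add_constant(x)).fit()
    return VolumePhilliesFit(
        A=float(np.exp(res.params[0])),
        kappa=-float(res.params[1]),
        b=b,
        stderr_lnA=float(res.bse[0]),
        stderr_kappa=float(res.bse[1]),
    )


def infer_dilution_from_deff(D_ratio: float, phillies: PhilliesFit, C_ref: float) -> float:
    """Fractional concentration change implied by a relative D_eff change.

    With lambda = 1, D2/D1 = exp(-beta (C2 - C1)) inverts to
    delta C / C_ref = -ln(D_ratio) / (beta C_ref).  Returned with the
    dilution sign convention: positive when the compartment got more dilute
    (D_ratio > 1).
    """
    if D_ratio <= 0:
        raise ValueError("D_ratio must be positive")
    if phillies.beta <= 0 or C_ref <= 0:
        raise ValueError("cannot invert the Phillies law with beta * C_ref <= 0")
    if abs(phillies.lam - 1.0) > 1e-6:
        logger.warning("dilution inversion assumes lambda=1; fit has lambda=%.3g", phillies.lam)
    return float(np.log(D_ratio) / (phillies.beta * C_ref))
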