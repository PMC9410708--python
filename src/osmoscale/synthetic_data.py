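"""Seeded generators for every input the analysis pipeline consumes.

The generators emulate the study's measurement tables — osmotic-shift
volumes, GEM particle tracks, growth-trajectory time lapses, and
crowding-vs-diffusivity tables — with the statistical structure the
analysis assumes: the ideal/tense-osmometer forward model for volumes,
Brownian or exactly-sampled fractional Brownian motion for tracks, the
exponential-growth partitioning model for trajectories, and lognormal
multiplicative measurement noise throughout.  One integer seed fixes every
output bit-for-bit.

Default conditions mirror the experimental regime: isotonic 0.4 M sorbitol
with shifts over 0.2-1.0 M, normalized dry volume 25%, 100 Hz tracking for
10 s, cytoplasmic D_eff 0.40 um^2/s, growth rate 0.006 min^-1, equilibrium
N/C fraction 7.5%, and an asymmetric-division mutant whose daughters are
born with dispersed N/C ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bvh_analysis import single_compartment_volume
from .gem_rheology import TrackSet
from .growth_homeostasis import GrowthTrajectory

__all__ = [
    "GeneratorConfig",
    "gen_shift_dataset",
    "gen_brownian_tracks",
    "gen_fbm_tracks",
    "gen_homeostasis_population",
    "gen_phillies_dataset",
    "fractional_gaussian_noise",
]

M_SORBITOL_TO_MOSM = 1000.0  # 1 M sorbitol contributes ~1 Osm


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings: seed and measurement-noise scales."""

    seed: int = 0
    volume_cv: float = 0.05  # multiplicative lognormal volume noise
    loc_sigma_um: float = 0.03  # static localization error for tracks

    def __post_init__(self) -> None:
        if self.volume_cv < 0 or self.loc_sigma_um < 0:
            raise ValueError("noise scales must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-stream generator fanned out from the seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def gen_shift_dataset(
    config: GeneratorConfig,
    nub: float = 0.25,
    sigma: float = 0.0,
    n_cells: int = 400,
    conc_levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0),
    c_iso: float = 0.4,
    mean_v_iso: float = 100.0,
    size_cv: float = 0.3,
    group: str = "protoplast",
    compartment: str = "cell",
    paired: bool = False,
) -> pd.DataFrame:
    """Osmotic-shift volume table from the osmometer forward model.

    Each cell gets a lognormal isotonic volume (CV ``size_cv``, an
    asynchronous population), a dry volume ``nub * V_iso`` and the osmolyte
    amount consistent with the isotonic state; its post-shift volume comes
    from the tension-``sigma`` forward model, and both measured volumes
    carry independent multiplicative noise.  Concentrations are recorded in
    M-sorbitol equivalents (the solver works in mOsm internally; BVH math
    uses only ratios).  With ``paired`` the isotonic level is skipped so
    every record is a true before/after pair for osmolyte inference.
    """
    if c_iso not in conc_levels and not paired:
        raise ValueError("conc_levels must include the isotonic level c_iso")
    rng = config.rng(0)
    levels = [c for c in conc_levels if not (paired and c == c_iso)]
    v_iso_true = mean_v_iso * _lognormal_factor(rng, size_cv, n_cells)
    assigned = np.array([levels[i % len(levels)] for i in range(n_cells)])
    rows = []
    for i in range(n_cells):
        b = nub * v_iso_true[i]
        n_amount = (c_iso * M_SORBITOL_TO_MOSM) * (v_iso_true[i] - b)
        c_out = assigned[i]
        v_true = single_compartment_volume(n_amount, b, sigma, c_out * M_SORBITOL_TO_MOSM)
        rows.append(
            {
                "cell_id": f"cell{i:04d}",
                "compartment": compartment,
                "group": group,
                "c_iso": c_iso,
                "c_out": c_out,
                "conc_units": "M_sorbitol",
                "v_iso_um3": v_iso_true[i],
                "v_um3": v_true,
            }
        )
    df = pd.DataFrame(rows)
    df["v_iso_um3"] *= _lognormal_factor(rng, config.volume_cv, len(df))
    df["v_um3"] *= _lognormal_factor(rng, config.volume_cv, len(df))
    return df


def _tracks_frame(positions: np.ndarray, dt: float) -> pd.DataFrame:
    """Stack an (n_tracks, n_frames, 2) position array into a track table."""
    n_tracks, n_frames, _ = positions.shape
    frames = np.tile(np.arange(n_frames), n_tracks)
    return pd.DataFrame(
        {
            "track_id": np.repeat([f"track{i:05d}" for i in range(n_tracks)], n_frames),
            "frame": frames,
            "t_s": frames * dt,
            "x_um": positions[:, :, 0].ravel(),
            "y_um": positions[:, :, 1].ravel(),
        }
    )


def gen_brownian_tracks(
    config: GeneratorConfig,
    D: float = 0.40,
    dt: float = 0.01,
    duration: float = 10.0,
    n_tracks: int = 100,
    loc_sigma: float = 0.0,
    compartment: str = "cytoplasm",
    condition: str = "",
) -> TrackSet:
    """2D Brownian tracks: Gaussian steps of variance 2 D dt per axis.

    ``loc_sigma`` (um) adds static localization error per point, which
    inflates the expected MSD by 4 loc_sigma^2 at every lag.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = config.rng(1)
    n_steps = int(round(duration / dt))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_tracks, n_steps, 2))
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if loc_sigma > 0:
        pos = pos + rng.normal(0.0, loc_sigma, size=pos.shape)
    return TrackSet(_tracks_frame(pos, dt), dt=dt, compartment=compartment, condition=condition)


def fractional_gaussian_noise(
    rng: np.random.Generator, hurst: float, n_steps: int, n_series: int
) -> np.ndarray:
    """Exact fractional Gaussian noise via Davies-Harte circulant embedding.

    Returns ``(n_series, n_steps)`` unit-spacing fGn samples whose cumulative
    sums are standard fractional Brownian motion with the requested Hurst
    index (Var B_H(k) = k^(2H)).  The circulant eigenvalues of the fGn
    autocovariance are non-negative for H in (0, 1), making the synthesis
    exact rather than an autoregressive approximation.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"Hurst index must be in (0, 1), got {hurst}")
    k = np.arange(n_steps + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
    )
    circ = np.concatenate([gamma[:-1], gamma[-1:], gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8:
        raise RuntimeError(
            f"circulant embedding not non-negative definite (min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    m = lam.size  # 2 * n_steps
    w = np.zeros((n_series, m), dtype=complex)
    half = n_steps
    w[:, 0] = np.sqrt(lam[0] / m) * rng.standard_normal(n_series)
    w[:, half] = np.sqrt(lam[half] / m) * rng.standard_normal(n_series)
    re = rng.standard_normal((n_series, half - 1))
    im = rng.standard_normal((n_series, half - 1))
    w[:, 1:half] = np.sqrt(lam[1:half] / (2.0 * m)) * (re + 1j * im)
    w[:, half + 1 :] = np.conj(w[:, half - 1 : 0 : -1])
    return np.fft.fft(w, axis=1).real[:, :n_steps]


def gen_fbm_tracks(
    config: GeneratorConfig,
    D_scale: float = 0.40,
    alpha: float = 0.8,
    dt: float = 0.01,
    duration: float = 10.0,
    n_tracks: int = 500,
    loc_sigma: float = 0.0,
    compartment: str = "nucleoplasm",
    condition: str = "",
) -> TrackSet:
    """Subdiffusive 2D tracks from exact fractional Brownian motion.

    Positions are sqrt(2 D_scale) B_H(t) per axis with H = alpha/2, so the
    2D ensemble MSD is exactly 4 D_scale tau^alpha (tau in s, MSD in um^2
    when D_scale is in um^2/s^alpha).  alpha = 1 reduces to Brownian motion.
    """
    if not (0.0 < alpha < 2.0):
        raise ValueError(f"anomalous exponent alpha must be in (0, 2), got {alpha}")
    rng = config.rng(2)
    hurst = alpha / 2.0
    n_steps = int(round(duration / dt))
    fgn = fractional_gaussian_noise(rng, hurst, n_steps, 2 * n_tracks)
    steps = fgn.reshape(n_tracks, 2, n_steps).transpose(0, 2, 1)
    steps = steps * np.sqrt(2.0 * D_scale) * dt**hurst
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if loc_sigma > 0:
        pos = pos + rng.normal(0.0, loc_sigma, size=pos.shape)
    return TrackSet(_tracks_frame(pos, dt), dt=dt, compartment=compartment, condition=condition)


def gen_homeostasis_population(
    config: GeneratorConfig,
    gammaC: float = 0.006,
    f0: float = 0.075,
    n_cells: int = 100,
    t_grid: np.ndarray | None = None,
    division_asymmetry_sd: float = 0.10,
    mean_mother_vc: float = 160.0,
    size_cv: float = 0.15,
    mode: str = "exponential",
) -> list[GrowthTrajectory]:
    """Time-lapse cohort of daughters born with dispersed N/C ratios.

    Mothers sit at the N/C fixed point (nc = f0) and divide with an
    asymmetrically placed septum — the daughter inherits a fraction
    a ~ Normal(0.5, ``division_asymmetry_sd``) of the mother volume — while
    mitosis still yields two equal nuclei, so a daughter is born with
    nc0 = f0 / (2a).  Symmetric division (sd = 0) collapses the nc0
    dispersion to measurement noise, the wild-type-like regime; the default
    sd emulates the asymmetric-division mutant with roughly threefold wider
    nc0 spread.  Growth follows the exponential (or linear) partitioning
    model; both volume series carry multiplicative measurement noise.
    """
    if division_asymmetry_sd < 0:
        raise ValueError("division_asymmetry_sd must be non-negative")
    rng = config.rng(3)
    if t_grid is None:
        t_grid = np.arange(0.0, 44.0, 4.0)
    t_grid = np.asarray(t_grid, dtype=float)
    mothers = mean_mother_vc * _lognormal_factor(rng, size_cv, n_cells)
    asym = np.clip(rng.normal(0.5, division_asymmetry_sd, n_cells), 0.25, 0.75)
    out = []
    for i in range(n_cells):
        vc0 = asym[i] * mothers[i]
        vn0 = f0 * mothers[i] / 2.0  # equal nuclei regardless of septum position
        if mode == "exponential":
            vc = vc0 * np.exp(gammaC * t_grid)
        elif mode == "linear":
            vc = vc0 + gammaC * vc0 * t_grid
        else:
            raise ValueError(f"unknown growth mode {mode!r}")
        vn = vn0 + f0 * (vc - vc0)
        vc_meas = vc * _lognormal_factor(rng, config.volume_cv, t_grid.size)
        vn_meas = vn * _lognormal_factor(rng, config.volume_cv, t_grid.size)
        out.append(
            GrowthTrajectory(cell_id=f"cell{i:04d}", times=t_grid, vc=vc_meas, vn=vn_meas)
        )
    return out


def gen_phillies_dataset(
    config: GeneratorConfig,
    D0: float = 13.9,
    beta: float = 0.0071,
    lam: float = 1.0,
    conc_levels: tuple[float, ...] = (250.0, 375.0, 500.0, 750.0, 1000.0),
    n_per_level: int = 20,
    noise_cv: float = 0.10,
) -> pd.DataFrame:
    """D_eff-vs-concentration table from the Phillies law plus noise.

    Defaults put D_eff at the isotonic 500 mOsm near the cytoplasmic
    0.40 um^2/s given the aqueous Stokes-Einstein D0 of a 40-nm particle.
    Noise is multiplicative lognormal per measurement.
    """
    rng = config.rng(4)
    conc = np.repeat(np.asarray(conc_levels, dtype=float), n_per_level)
    d_true = D0 * np.exp(-beta * conc**lam)
    d_meas = d_true * _lognormal_factor(rng, noise_cv, conc.size)
    return pd.DataFrame({"conc": conc, "d_eff": d_meas})
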