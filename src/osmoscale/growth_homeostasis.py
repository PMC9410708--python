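"""Exponential-growth model of N/C-ratio homeostasis.

Cell volume grows exponentially, dV_C/dt = gamma_C V_C, because biosynthesis
scales with cytoplasmic content.  A fixed fraction f0 of newly made
osmotically active macromolecules partitions into the nucleus, so
dV_N/dt = f0 gamma_C V_C.  Writing rho = V_N/V_C, these combine into the
relaxation law

    d rho / dt = gamma_C (f0 - rho),

whose solution rho(t) = f0 + (rho0 - f0) exp(-gamma_C t) returns any
aberrant N/C ratio to f0 with rate constant gamma_C and no feedback: the
correction rate gamma_NC equals -gamma_C for free.  The regression
estimators here mirror the experimental readout: per-cell volume slopes
over a 40-min window regressed on initial volume give gamma_C, and per-cell
N/C slopes regressed on the initial N/C ratio give gamma_NC and the
equilibrium fraction f0 as the x-intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthTrajectory",
    "GrowthRateFit",
    "HomeostasisFit",
    "simulate_growth",
    "nc_trajectory_analytic",
    "trajectories_to_frame",
    "frame_to_trajectories",
    "fit_growth_rate",
    "fit_correction_rate",
    "generations_to_correct",
]

TRAJECTORY_COLUMNS = ["cell_id", "t_min", "vc_um3", "vn_um3", "mitotic"]

DEFAULT_T_GRID = np.arange(0.0, 44.0, 4.0)  # 0-40 min every 4 min


@dataclass
class GrowthTrajectory:
    """Time-lapse cell and nuclear volumes for one cell."""

    cell_id: str
    times: np.ndarray  # min
    vc: np.ndarray  # um^3
    vn: np.ndarray  # um^3
    mitotic: np.ndarray = field(default=None)  # bool per timepoint

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vc = np.asarray(self.vc, dtype=float)
        self.vn = np.asarray(self.vn, dtype=float)
        if self.mitotic is None:
            self.mitotic = np.zeros(self.times.size, dtype=bool)
        self.mitotic = np.asarray(self.mitotic, dtype=bool)
        if not (self.times.size == self.vc.size == self.vn.size == self.mitotic.size):
            raise ValueError("times, vc, vn and mitotic must have equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must strictly increase")
        if (self.vc <= 0).any() or (self.vn <= 0).any():
            raise ValueError("volumes must be positive")

    @property
    def nc(self) -> np.ndarray:
        """N/C volume-ratio series."""
        return self.vn / self.vc


@dataclass(frozen=True)
class GrowthRateFit:
    """Population exponential growth rate gamma_C (min^-1)."""

    gammaC: float
    stderr: float
    n_cells: int
    per_cell: pd.DataFrame = field(default=None, repr=False)


@dataclass(frozen=True)
class HomeostasisFit:
    """Homeostasis regression: d(N/C)/dt against initial N/C ratio."""

    gammaNC: float  # slope, min^-1; the model predicts -gamma_C
    stderr_gammaNC: float
    f0_hat: float  # x-intercept: equilibrium N/C fraction
    stderr_f0: float
    n_cells: int
    per_cell: pd.DataFrame = field(default=None, repr=False)

    def predicted_line(self, gammaC: float, f0: float, nc_grid: np.ndarray) -> np.ndarray:
        """Parameter-free model line d(nc)/dt = gamma_C (f0 - nc)."""
        return gammaC * (f0 - np.asarray(nc_grid, dtype=float))


def simulate_growth(
    VC0: float,
    VN0: float,
    gammaC: float,
    f0: float,
    t_grid: np.ndarray | None = None,
    mode: str = "exponential",
    cell_id: str = "sim",
) -> GrowthTrajectory:
    """Noise-free growth trajectory under the passive partitioning model.

    ``exponential``: V_C(t) = V_C0 e^(gamma_C t), with the nucleus receiving
    the fraction f0 of all added volume.  ``linear``: constant volume gain
    k = gamma_C V_C0 per unit time (same initial rate, no size feedback),
    again split f0 to the nucleus.
    """
    if gammaC <= 0:
        raise ValueError("gammaC must be positive")
    if not (0.0 < f0 < 1.0):
        raise ValueError("f0 must lie in (0, 1)")
    if not (0.0 < VN0 < VC0):
        raise ValueError("need 0 < VN0 < VC0")
    t = DEFAULT_T_GRID.copy() if t_grid is None else np.asarray(t_grid, dtype=float)
    if mode == "exponential":
        vc = VC0 * np.exp(gammaC * t)
    elif mode == "linear":
        vc = VC0 + gammaC * VC0 * t
    else:
        raise ValueError(f"unknown growth mode {mode!r}")
    vn = VN0 + f0 * (vc - VC0)
    return GrowthTrajectory(cell_id=cell_id, times=t, vc=vc, vn=vn)


def nc_trajectory_analytic(nc0: float, f0: float, gammaC: float, t: float) -> float:
    """Closed-form N/C ratio under exponential growth.

    Solution of d(nc)/dt = gamma_C (f0 - nc):
    nc(t) = f0 + (nc0 - f0) exp(-gamma_C t).
    """
    if gammaC <= 0:
        raise ValueError("gammaC must be positive")
    return f0 + (nc0 - f0) * math.exp(-gammaC * t)


def trajectories_to_frame(trajectories: list[GrowthTrajectory]) -> pd.DataFrame:
    """Stack trajectories into the long-format trajectory table."""
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "t_min": tr.times,
                "vc_um3": tr.vc,
                "vn_um3": tr.vn,
                "mitotic": tr.mitotic.astype(int),
            }
        )
        for tr in trajectories
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[GrowthTrajectory]:
    """Inverse of :func:`trajectories_to_frame`."""
    out = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("t_min")
        mito = sub["mitotic"].to_numpy().astype(bool) if "mitotic" in sub else None
        out.append(
            GrowthTrajectory(
                cell_id=str(cid),
                times=sub["t_min"].to_numpy(),
                vc=sub["vc_um3"].to_numpy(),
                vn=sub["vn_um3"].to_numpy(),
                mitotic=mito,
            )
        )
    return out


def _per_cell_slope(t: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of y on t."""
    res = sm.OLS(y, sm.add_constant(t)).fit()
    return float(res.params[1])


def _usable_cells(
    trajectories: list[GrowthTrajectory], min_timepoints: int
) -> list[tuple[GrowthTrajectory, np.ndarray]]:
    usable = []
    for tr in trajectories:
        keep = ~tr.mitotic
        if keep.sum() < min_timepoints:
            logger.warning(
                "dropping cell %s: only %d non-mitotic timepoints", tr.cell_id, keep.sum()
            )
            continue
        usable.append((tr, keep))
    return usable


def fit_growth_rate(
    trajectories: list[GrowthTrajectory],
    min_timepoints: int = 3,
    min_cells: int = 10,
) -> GrowthRateFit:
    """Estimate gamma_C from per-cell volume slopes vs initial volume.

    Exponential growth implies dV/dt = gamma_C V, so the OLS slope of each
    cell's volume gain rate against its initial volume estimates gamma_C.
    Mitotic timepoints are excluded.  Size-independent (linear) growth
    yields a slope near zero.
    """
    usable = _usable_cells(trajectories, min_timepoints)
    if len(usable) < min_cells:
        raise ValueError(f"need >= {min_cells} usable cells, have {len(usable)}")
    rows = [
        {
            "cell_id": tr.cell_id,
            "v0": float(tr.vc[keep][0]),
            "dv_dt": _per_cell_slope(tr.times[keep], tr.vc[keep]),
        }
        for tr, keep in usable
    ]
    per_cell = pd.DataFrame(rows)
    res = sm.OLS(per_cell["dv_dt"], sm.add_constant(per_cell["v0"])).fit()
    return GrowthRateFit(
        gammaC=float(res.params.iloc[1]),
        stderr=float(res.bse.iloc[1]),
        n_cells=len(per_cell),
        per_cell=per_cell,
    )


def fit_correction_rate(
    trajectories: list[GrowthTrajectory],
    min_timepoints: int = 3,
    min_cells: int = 10,
    min_nc0_sd: float = 0.005,
) -> HomeostasisFit:
    """Homeostasis regression: per-cell d(N/C)/dt against initial N/C.

    The slope is the correction rate gamma_NC (the passive model predicts
    gamma_NC = -gamma_C) and the x-intercept estimates the equilibrium
    fraction f0.  Requires genuine spread in initial N/C ratios
    (SD >= ``min_nc0_sd``): a cohort sitting at the fixed point carries no
    information about the correction rate.
    """
    usable = _usable_cells(trajectories, min_timepoints)
    if len(usable) < min_cells:
        raise ValueError(f"need >= {min_cells} usable cells, have {len(usable)}")
    rows = [
        {
            "cell_id": tr.cell_id,
            "nc0": float(tr.nc[keep][0]),
            "dnc_dt": _per_cell_slope(tr.times[keep], tr.nc[keep]),
        }
        for tr, keep in usable
    ]
    per_cell = pd.DataFrame(rows)
    nc0_sd = float(per_cell["nc0"].std(ddof=1))
    if nc0_sd < min_nc0_sd:
        raise ValueError(
            f"initial N/C spread SD={nc0_sd:.4g} below {min_nc0_sd}; the "
            "correction-rate regression is uninformative at the fixed point"
        )
    res = sm.OLS(per_cell["dnc_dt"], sm.add_constant(per_cell["nc0"])).fit()
    a, b = float(res.params.iloc[0]), float(res.params.iloc[1])
    cov = np.asarray(res.cov_params())
    f0_hat = -a / b
    # delta method on f0 = -a/b
    grad = np.array([-1.0 / b, a / b**2])
    var_f0 = float(grad @ cov @ grad)
    return HomeostasisFit(
        gammaNC=b,
        stderr_gammaNC=float(res.bse.iloc[1]),
        f0_hat=f0_hat,
        stderr_f0=math.sqrt(max(var_f0, 0.0)),
        n_cells=len(per_cell),
        per_cell=per_cell,
    )


def generations_to_correct(
    nc0: float, f0: float, gammaC: float, tolerance: float
) -> tuple[float, float]:
    """Time and generations to shrink an N/C deviation below ``tolerance``.

    The deviation decays as |nc0 - f0| e^(-gamma_C t), so
    t* = ln(|nc0 - f0| / tol) / gamma_C and, since one doubling takes
    ln 2 / gamma_C, the generation count is log2(|nc0 - f0| / tol).
    Returns (0, 0) when the deviation is already within tolerance.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if gammaC <= 0:
        raise ValueError("gammaC must be positive")
    deviation = abs(nc0 - f0)
    if deviation <= tolerance:
        return 0.0, 0.0
    t_star = math.log(deviation / tolerance) / gammaC
    return t_star, math.log2(deviation / tolerance)
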