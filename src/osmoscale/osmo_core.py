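"""Steady-state nested-osmometer model of cell and nuclear size.

The cell and its nucleus are treated as two nested spherical osmometers.
Each compartment holds a fixed amount of osmotically active macromolecules
(colloids that cannot cross the bounding membrane), a non-osmotic (dry)
volume ``b``, and a membrane under tension ``sigma``.  At steady state the
colloid osmotic pressure jump across each membrane balances its Laplace
pressure, giving the coupled system

    (C_cy - C_out) * R T = 2 sigma_C / R_C,
    (C_n  - C_cy ) * R T = 2 sigma_N / R_N,

with C_cy = N_cy / (V_C - V_N - b_cy), C_n = N_n / (V_N - b_n) and
R_X = (3 V_X / 4 pi)^(1/3).  The system has a unique solution with positive
free volumes, found here by nested monotone bracketing (no Jacobian).

In the limit of zero nuclear tension and matched normalized non-osmotic
volumes the nuclear-to-cell volume ratio collapses to the closed form
N_nucleus / N_cell, independent of the external osmolarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE_K, R_GAS, UM_TO_M

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "Medium",
    "CellState",
    "SensitivityGrid",
    "SteadyStateError",
    "laplace_concentration_jump",
    "solve_steady_state",
    "nc_ratio_closed_form",
    "shock_response",
    "nc_sensitivity",
    "phase_diagram",
    "matched_bn",
    "bn_for_nub_ratio",
    "make_cout_sweep",
]

_BRACKET_EPS = 1e-9
_VOL_RTOL = 1e-12


class SteadyStateError(RuntimeError):
    """Raised when the steady-state solver cannot bracket or converge."""


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the two nested osmometers.

    Parameters
    ----------
    NN, NCy:
        Nuclear and cytoplasmic osmolyte amounts (mOsm um^3, i.e.
        concentration x volume units).
    bN, bC:
        Nuclear and whole-cell non-osmotic volumes (um^3); the cytoplasmic
        part is ``bCy = bC - bN``.
    sigmaC, sigmaN:
        Effective cell-surface and nuclear-envelope tensions (N/m).
    temperature:
        Absolute temperature (K).
    """

    NN: float
    NCy: float
    bN: float
    bC: float
    sigmaC: float = 0.0
    sigmaN: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.NN <= 0 or self.NCy <= 0:
            raise ValueError("osmolyte amounts NN and NCy must be positive")
        if not (0.0 <= self.bN <= self.bC):
            raise ValueError(f"need 0 <= bN <= bC, got bN={self.bN}, bC={self.bC}")
        if self.sigmaC < 0 or self.sigmaN < 0:
            raise ValueError("membrane tensions must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def bCy(self) -> float:
        """Cytoplasmic non-osmotic volume (um^3)."""
        return self.bC - self.bN

    @property
    def NCell(self) -> float:
        """Total cellular osmolyte amount (mOsm um^3)."""
        return self.NN + self.NCy


@dataclass(frozen=True)
class Medium:
    """External medium of osmolarity ``Cout`` (mOsm)."""

    Cout: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.Cout <= 0:
            raise ValueError(f"external concentration must be positive, got {self.Cout}")


@dataclass(frozen=True)
class CellState:
    """A steady-state solution of the nested-osmometer system."""

    VC: float
    VN: float
    CCy: float
    CN: float
    residual_norm: float
    nc_ratio: float


@dataclass(frozen=True)
class SensitivityGrid:
    """N/C-ratio osmotic-shock sensitivity over a parameter grid.

    ``values[i, j]`` is the sensitivity score (max - min)/iso of the N/C
    ratio over ``cout_range`` at non-osmotic volume ratio ``axis1[i]``
    (nu_bC / nu_bN) and nuclear tension ``axis2[j]``.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    cout_range: np.ndarray = field(default_factory=lambda: np.array([]))


def laplace_concentration_jump(
    sigma: float, V: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Osmolarity jump (mOsm) balancing the Laplace pressure of a sphere.

    For a spherical compartment of volume ``V`` (um^3) bounded by a membrane
    under tension ``sigma`` (N/m), the Laplace pressure 2 sigma / R maps to a
    concentration difference 2 sigma / (R * R_gas * T) via Van't Hoff's law.
    Zero tension gives a zero jump.
    """
    if V <= 0:
        raise ValueError(f"volume must be positive, got {V}")
    if sigma < 0:
        raise ValueError(f"tension must be non-negative, got {sigma}")
    if sigma == 0.0:
        return 0.0
    radius_m = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0) * UM_TO_M
    return 2.0 * sigma / (radius_m * R_GAS * temperature)


def _inner_residual(VN: float, VC: float, p: ModelParams) -> float:
    """Nuclear balance residual (mOsm) at fixed cell volume."""
    CN = p.NN / (VN - p.bN)
    CCy = p.NCy / (VC - VN - p.bCy)
    return CN - CCy - laplace_concentration_jump(p.sigmaN, VN, p.temperature)


def _solve_nuclear_volume(VC: float, p: ModelParams) -> float:
    lo = p.bN + max(p.bN, 1.0) * _BRACKET_EPS
    hi = VC - p.bCy - max(p.bCy, 1.0) * _BRACKET_EPS
    if hi <= lo:
        raise SteadyStateError(
            f"no admissible nuclear volume inside cell volume VC={VC:.6g} "
            f"(bracket [{lo:.6g}, {hi:.6g}] is empty)"
        )
    # C_N - C_Cy diverges to +inf at lo and -inf at hi, so a root exists.
    return brentq(_inner_residual, lo, hi, args=(VC, p), xtol=1e-15, rtol=_VOL_RTOL)


def solve_steady_state(params: ModelParams, medium: Medium) -> CellState:
    """Solve the coupled pressure-balance equations for (VC, VN).

    Nested bracketing: for each trial cell volume the nuclear balance is
    solved by bisection (its residual changes sign across the admissible
    nuclear-volume interval), then the cytoplasmic balance residual is
    driven to zero in the outer bracket.  Deterministic for fixed inputs.

    Raises
    ------
    SteadyStateError
        If no root lies in the outer bracket, e.g. when ``Cout`` is so
        large that the free volume collapses numerically.
    """
    p, Cout = params, medium.Cout

    def outer_residual(VC: float) -> float:
        VN = _solve_nuclear_volume(VC, p)
        CCy = p.NCy / (VC - VN - p.bCy)
        return CCy - Cout - laplace_concentration_jump(p.sigmaC, VC, p.temperature)

    lo = p.bC + max(p.bC, 1.0) * 1e2 * _BRACKET_EPS
    hi = 10.0 * (p.NCell / Cout + p.bC)
    try:
        f_lo, f_hi = outer_residual(lo), outer_residual(hi)
        if f_lo * f_hi > 0:
            raise SteadyStateError(
                f"no steady state bracketed for Cout={Cout} mOsm in "
                f"VC in [{lo:.6g}, {hi:.6g}] (residuals {f_lo:.3g}, {f_hi:.3g})"
            )
        VC = brentq(outer_residual, lo, hi, xtol=1e-15, rtol=_VOL_RTOL)
    except SteadyStateError:
        raise
    except ValueError as exc:  # pragma: no cover - defensive
        raise SteadyStateError(
            f"steady-state solve failed for Cout={Cout} mOsm: {exc}"
        ) from exc

    VN = _solve_nuclear_volume(VC, p)
    CCy = p.NCy / (VC - VN - p.bCy)
    CN = p.NN / (VN - p.bN)
    res_cell = abs(CCy - Cout - laplace_concentration_jump(p.sigmaC, VC, p.temperature))
    res_nuc = abs(CN - CCy - laplace_concentration_jump(p.sigmaN, VN, p.temperature))
    return CellState(
        VC=VC,
        VN=VN,
        CCy=CCy,
        CN=CN,
        residual_norm=max(res_cell, res_nuc),
        nc_ratio=VN / VC,
    )


def nc_ratio_closed_form(params: ModelParams) -> float:
    """Closed-form N/C ratio N_nucleus / N_cell.

    Exact when the nuclear tension vanishes and the normalized non-osmotic
    volumes of nucleus and cytoplasm are matched; in that limit the ratio
    is set purely by how the osmotically active molecules partition.
    """
    total = params.NN + params.NCy
    if total <= 0:
        raise ValueError("total osmolyte amount must be positive")
    return params.NN / total


def shock_response(params: ModelParams, couts: list[Medium]) -> list[CellState]:
    """Steady states across a series of external osmolarities, order kept."""
    if not couts:
        raise ValueError("couts must be non-empty")
    states = []
    for medium in couts:
        try:
            states.append(solve_steady_state(params, medium))
        except SteadyStateError as exc:
            raise SteadyStateError(f"at Cout={medium.Cout} mOsm: {exc}") from exc
    return states


def nc_sensitivity(
    params: ModelParams, cout_range: np.ndarray, cout_iso: float | None = None
) -> float:
    """Osmotic-shock sensitivity of the N/C ratio over an osmolarity sweep.

    Score = (max - min) of the N/C ratio over the sweep, normalized by the
    isotonic N/C ratio.  Zero for an osmotically invariant N/C ratio.
    """
    cout_range = np.asarray(cout_range, dtype=float)
    if cout_iso is None:
        cout_iso = float(np.median(cout_range))
    ratios = [solve_steady_state(params, Medium(c)).nc_ratio for c in cout_range]
    iso = solve_steady_state(params, Medium(cout_iso)).nc_ratio
    return (max(ratios) - min(ratios)) / iso


def matched_bn(params: ModelParams) -> float:
    """Nuclear non-osmotic volume giving matched normalized dry fractions.

    ``bN = (NN / NCell) * bC`` makes nu_bN = nu_bC exactly in the
    zero-tension state at any external osmolarity.
    """
    return params.NN / params.NCell * params.bC


def bn_for_nub_ratio(params: ModelParams, nub_ratio: float, cout_iso: float) -> float:
    """Nuclear dry volume realizing a target nu_bC / nu_bN at isotonic state.

    Uses the zero-tension isotonic volumes (where VC is independent of bN):
    nu_bC = bC/(bC + NCell/Ciso) and nu_bN(bN) = bN/(bN + NN/Ciso); solves
    the latter for the requested ratio.  Exact at zero tension, a good
    parameterization otherwise.
    """
    if nub_ratio <= 0:
        raise ValueError("nub_ratio must be positive")
    nu_bC = params.bC / (params.bC + params.NCell / cout_iso)
    target = nu_bC / nub_ratio
    if target >= 1.0:
        raise ValueError(f"unreachable nu_bN target {target:.3g} for ratio {nub_ratio}")
    return target * (params.NN / cout_iso) / (1.0 - target)


def make_cout_sweep(cout_iso: float, lo: float = 0.5, hi: float = 2.0, n: int = 41) -> np.ndarray:
    """Log-spaced osmolarity sweep with Ciso/Cout spanning [lo, hi]."""
    ratios = np.logspace(math.log10(lo), math.log10(hi), n)
    return cout_iso / ratios


def phase_diagram(
    nub_ratio_grid: np.ndarray,
    sigmaN_grid: np.ndarray,
    base_params: ModelParams,
    cout_range: np.ndarray | None = None,
    cout_iso: float = 500.0,
) -> SensitivityGrid:
    """N/C-ratio shock sensitivity over (nu_bC/nu_bN, sigma_N) grids.

    Grid points where the solver fails are recorded as NaN with a logged
    warning rather than aborting the sweep.  The cell at (ratio=1,
    sigma_N=0) is exactly zero: matched dry fractions with a tensionless
    nuclear envelope make the N/C ratio osmotically invariant.
    """
    nub_ratio_grid = np.asarray(nub_ratio_grid, dtype=float)
    sigmaN_grid = np.asarray(sigmaN_grid, dtype=float)
    if nub_ratio_grid.size == 0 or sigmaN_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if cout_range is None:
        cout_range = make_cout_sweep(cout_iso)
    values = np.full((nub_ratio_grid.size, sigmaN_grid.size), np.nan)
    for i, ratio in enumerate(nub_ratio_grid):
        try:
            bN = bn_for_nub_ratio(base_params, ratio, cout_iso)
            p_ratio = replace(base_params, bN=bN)
        except ValueError as exc:
            logger.warning("skipping nub_ratio=%g: %s", ratio, exc)
            continue
        for j, sigmaN in enumerate(sigmaN_grid):
            p = replace(p_ratio, sigmaN=sigmaN)
            try:
                values[i, j] = nc_sensitivity(p, cout_range, cout_iso)
            except SteadyStateError as exc:
                logger.warning(
                    "solver failed at nub_ratio=%g sigmaN=%g: %s", ratio, sigmaN, exc
                )
    return SensitivityGrid(
        axis1=nub_ratio_grid, axis2=sigmaN_grid, values=values, cout_range=np.asarray(cout_range)
    )
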