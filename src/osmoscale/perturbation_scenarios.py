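"""Model counterparts of nuclear-export block and translation-block assays.

Blocking nuclear export (leptomycin B) progressively traps macromolecules
in the nucleus: modelled as a scheduled transfer of cytoplasmic osmolyte
amount into the nucleus while growth continues, with the steady state
re-solved at each step.  Inhibiting translation (cycloheximide) removes
osmolytes from both compartments in proportion: modelled as a uniform
scaling of the two amounts, which leaves the closed-form N/C ratio exactly
unchanged — the model's explanation for why slowed growth preserves the
N/C ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .osmo_core import CellState, Medium, ModelParams, SteadyStateError, matched_bn, solve_steady_state

__all__ = [
    "RedistributionSchedule",
    "simulate_redistribution",
    "simulate_uniform_dilution",
]


@dataclass(frozen=True)
class RedistributionSchedule:
    """Time course of solute transfer and synthesis modulation.

    ``transfer_fraction[i]`` is the cumulative fraction of the (current)
    cytoplasmic osmolyte pool moved into the nucleus by ``times[i]`` —
    non-decreasing, in [0, 1).  ``synthesis_modifier[i]`` multiplies the
    biosynthesis rate over the following interval (1 = unperturbed,
    0 = full translation block).
    """

    times: np.ndarray  # min, starting at 0
    transfer_fraction: np.ndarray
    synthesis_modifier: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "transfer_fraction", np.asarray(self.transfer_fraction, dtype=float))
        object.__setattr__(self, "synthesis_modifier", np.asarray(self.synthesis_modifier, dtype=float))
        if not (self.times.size == self.transfer_fraction.size == self.synthesis_modifier.size):
            raise ValueError("schedule arrays must have equal length")
        if self.times.size < 2 or self.times[0] != 0.0 or (np.diff(self.times) <= 0).any():
            raise ValueError("times must start at 0 and strictly increase")
        tf = self.transfer_fraction
        if (tf < 0).any() or (tf >= 1).any() or (np.diff(tf) < 0).any():
            raise ValueError("transfer_fraction must be non-decreasing in [0, 1)")
        if (self.synthesis_modifier < 0).any():
            raise ValueError("synthesis_modifier must be non-negative")

    @classmethod
    def linear_ramp(
        cls,
        total_fraction: float,
        duration: float = 60.0,
        dt: float = 1.0,
        modifier: float = 1.0,
    ) -> "RedistributionSchedule":
        """Linear transfer ramp reaching ``total_fraction`` at ``duration``."""
        times = np.arange(0.0, duration + dt / 2, dt)
        frac = total_fraction * times / duration
        return cls(times, frac, np.full_like(times, modifier))


def simulate_redistribution(
    params: ModelParams,
    schedule: RedistributionSchedule,
    gammaC: float,
    f0: float,
    medium: Medium | None = None,
    move_dry_volume: bool = True,
) -> pd.DataFrame:
    """Solute redistribution into the nucleus under continued growth.

    At each schedule step the osmolyte amounts grow exponentially
    (rate gamma_C x the synthesis modifier, fraction f0 of new material to
    the nucleus), the scheduled increment of the cytoplasmic pool is moved
    into the nucleus (transfer conserves the total exactly), and the
    nested-osmometer steady state is re-solved.  Dry volume follows the
    solutes by default, keeping the normalized non-osmotic volumes matched,
    as observed experimentally; ``move_dry_volume=False`` freezes ``bN``.

    Returns a tidy time series with columns
    ``t_min, vc_um3, vn_um3, nc_ratio, ccy_mosm, cn_mosm, nn, ncy``.
    """
    if medium is None:
        medium = Medium(500.0)
    NN, NCy = params.NN, params.NCy
    bC0, N0 = params.bC, params.NN + params.NCy
    rows = []
    times = schedule.times
    for i, t in enumerate(times):
        if i > 0:
            dt = times[i] - times[i - 1]
            # growth over the preceding interval, exact exponential update
            growth = (NN + NCy) * (np.exp(gammaC * schedule.synthesis_modifier[i - 1] * dt) - 1.0)
            NN += f0 * growth
            NCy += (1.0 - f0) * growth
            moved = (schedule.transfer_fraction[i] - schedule.transfer_fraction[i - 1]) * NCy
            NN += moved
            NCy -= moved
        total = NN + NCy
        bC = bC0 * total / N0  # dry mass tracks total biosynthesis
        bN = (NN / total) * bC if move_dry_volume else min(params.bN, bC)
        p = replace(params, NN=NN, NCy=NCy, bN=bN, bC=bC)
        try:
            state = solve_steady_state(p, medium)
        except SteadyStateError as exc:
            raise SteadyStateError(f"at t={t} min: {exc}") from exc
        rows.append(
            {
                "t_min": t,
                "vc_um3": state.VC,
                "vn_um3": state.VN,
                "nc_ratio": state.nc_ratio,
                "ccy_mosm": state.CCy,
                "cn_mosm": state.CN,
                "nn": NN,
                "ncy": NCy,
            }
        )
    return pd.DataFrame(rows)


def simulate_uniform_dilution(
    params: ModelParams,
    dilution_factor: float,
    medium: Medium | None = None,
) -> tuple[CellState, CellState]:
    """Uniform osmolyte loss on both sides of the nuclear envelope.

    Scales NN and NCy by the same factor and re-solves the steady state;
    with zero nuclear tension and matched dry fractions the N/C ratio is
    exactly invariant (the closed form depends only on the amount ratio).
    """
    if not (0.0 < dilution_factor <= 1.0):
        raise ValueError("dilution_factor must be in (0, 1]")
    if medium is None:
        medium = Medium(500.0)
    before = solve_steady_state(params, medium)
    scaled = replace(
        params, NN=params.NN * dilution_factor, NCy=params.NCy * dilution_factor
    )
    after = solve_steady_state(scaled, medium)
    return before, after
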