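"""Boyle-Van't Hoff (BVH) analysis of osmotic-shift volume data.

An ideal osmometer obeys V = b + N/C: its free-water volume scales inversely
with the external osmolarity while the non-osmotic (dry) volume ``b`` is
fixed.  On a BVH plot of normalized volume V/V_iso against normalized
inverse concentration C_iso/C, ideal behaviour is a straight line through
(1, 1) with intercept nu_b = b/V_iso, the normalized non-osmotic volume.
Significant membrane tension (or a cell wall) bends the plot, which the
lack-of-fit machinery here detects.

The paired-shift algebra inverts the ideal-osmometer law to recover each
cell's osmolyte amount N and its isotonic internal osmolarity from a single
before/after volume pair and the known osmolarity step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq

from .constants import DEFAULT_TEMPERATURE_K, PARTICLES_PER_MOSM_UM3, particles_per_um3_to_mosm
from .osmo_core import laplace_concentration_jump

logger = logging.getLogger(__name__)

__all__ = [
    "BVHFit",
    "OsmolyteEstimate",
    "LackOfFitResult",
    "NoReplicationError",
    "normalize_shift_data",
    "fit_bvh_linear",
    "ideality_test",
    "quadratic_curvature_test",
    "predict_bvh_curve",
    "single_compartment_volume",
    "infer_osmolytes",
    "osmolarity_from_density",
    "sphere_area_ratio",
]

SHIFT_COLUMNS = ["cell_id", "compartment", "group", "c_iso", "c_out", "conc_units", "v_iso_um3", "v_um3"]


class NoReplicationError(ValueError):
    """Raised when the pure-error lack-of-fit test has no replicated x levels.

    The quadratic-curvature t-test (:func:`quadratic_curvature_test`) is the
    fallback for unreplicated designs.
    """


@dataclass(frozen=True)
class LackOfFitResult:
    statistic: float
    p_value: float
    df: tuple[int, int]
    method: str  # "pure_error_F" or "quadratic_t"


@dataclass(frozen=True)
class BVHFit:
    """Fitted BVH line y = slope * x + intercept.

    The intercept is the normalized non-osmotic volume nu_b; for an ideal
    osmometer slope + intercept = 1 (the line passes through (1, 1)).
    """

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r_squared: float
    n_points: int
    compartment: str = ""
    lack_of_fit_p: float = float("nan")

    @property
    def passes_through_iso(self) -> bool:
        """Whether slope + intercept is within 2 SE of 1."""
        se = np.hypot(self.stderr_slope, self.stderr_intercept)
        return bool(abs(self.slope + self.intercept - 1.0) <= 2.0 * se)


@dataclass(frozen=True)
class OsmolyteEstimate:
    """Per-cell osmolyte amount and inferred isotonic internal osmolarity."""

    cell_id: str
    N: float  # mOsm um^3
    C_iso_internal: float  # mOsm
    b_used: float  # um^3
    quality_warning: str = ""

    @property
    def n_particles(self) -> float:
        return self.N * PARTICLES_PER_MOSM_UM3


def normalize_shift_data(records: pd.DataFrame) -> pd.DataFrame:
    """Map shift records to BVH coordinates (x = C_iso/C_out, y = V/V_iso).

    One point per record, grouped by compartment and group label.  Raises if
    a single group mixes concentration conventions (molar sorbitol vs total
    mOsm): BVH arithmetic only uses concentration ratios, so units must be
    consistent within a group.
    """
    if records.empty:
        raise ValueError("no shift records supplied")
    df = records.copy()
    for col in ("c_iso", "c_out", "v_iso_um3", "v_um3"):
        if col not in df.columns:
            raise ValueError(f"shift table missing required column {col!r}")
        if (df[col] <= 0).any():
            raise ValueError(f"column {col!r} must be positive")
    if "group" not in df.columns:
        df["group"] = ""
    if "compartment" not in df.columns:
        df["compartment"] = "cell"
    if "conc_units" in df.columns:
        mixed = df.groupby("group")["conc_units"].nunique()
        bad = mixed[mixed > 1]
        if not bad.empty:
            raise ValueError(
                f"mixed concentration units within group(s) {list(bad.index)}; "
                "declare one convention per group"
            )
    df["x"] = df["c_iso"] / df["c_out"]
    df["y"] = df["v_um3"] / df["v_iso_um3"]
    keep = [c for c in ("cell_id", "compartment", "group") if c in df.columns]
    return df[keep + ["x", "y"]]


def fit_bvh_linear(points: pd.DataFrame, force_through_iso: bool = False) -> BVHFit:
    """Ordinary-least-squares BVH line fit.

    By default both coefficients are free and the through-(1,1) consistency
    is reported via :attr:`BVHFit.passes_through_iso`.  With
    ``force_through_iso`` the line is constrained through (1, 1) and only
    the slope is estimated (intercept = 1 - slope).

    The ideality (lack-of-fit) p-value uses the pure-error F-test when x
    levels are replicated, otherwise the quadratic-curvature t-test.
    """
    x = np.asarray(points["x"], dtype=float)
    y = np.asarray(points["y"], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a BVH fit")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all x values identical")

    if force_through_iso:
        # y - 1 = m (x - 1), one free coefficient
        res = sm.OLS(y - 1.0, (x - 1.0)[:, None]).fit()
        slope = float(res.params[0])
        se = float(res.bse[0])
        fit_args = dict(slope=slope, intercept=1.0 - slope, stderr_slope=se, stderr_intercept=se)
        r2 = float(res.rsquared)
    else:
        res = sm.OLS(y, sm.add_constant(x)).fit()
        fit_args = dict(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            stderr_slope=float(res.bse[1]),
            stderr_intercept=float(res.bse[0]),
        )
        r2 = float(res.rsquared)

    try:
        lof = ideality_test(x, y)
    except NoReplicationError:
        lof = quadratic_curvature_test(x, y)
    fit = BVHFit(
        **fit_args,
        r_squared=r2,
        n_points=int(x.size),
        compartment=str(points["compartment"].iloc[0]) if "compartment" in points else "",
        lack_of_fit_p=lof.p_value,
    )
    if not (0.0 <= fit.intercept < 1.0):
        logger.warning(
            "BVH intercept %.3g outside [0, 1): not interpretable as a dry-volume fraction",
            fit.intercept,
        )
    return fit


def ideality_test(x: np.ndarray, y: np.ndarray) -> LackOfFitResult:
    """Pure-error lack-of-fit F-test of the linear BVH model.

    Decomposes the residual sum of squares around the fitted line into
    pure error (within replicated x levels) and lack of fit (between level
    means and the line).  A small p-value rejects ideal-osmometer
    (linear) behaviour.

    Raises
    ------
    NoReplicationError
        If no x level is replicated; use :func:`quadratic_curvature_test`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    levels, inverse = np.unique(x, return_inverse=True)
    counts = np.bincount(inverse)
    if (counts < 2).all() or levels.size < 2:
        raise NoReplicationError(
            "pure-error lack-of-fit test needs replicated x levels; "
            "fall back to the quadratic-curvature t-test"
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    sse = float(res.ssr)
    group_means = np.bincount(inverse, weights=y) / counts
    sspe = float(np.sum((y - group_means[inverse]) ** 2))
    df_pe = int(x.size - levels.size)
    df_lof = int(levels.size - 2)
    if df_lof == 0:
        # two x levels: the line interpolates the level means, no curvature testable
        return LackOfFitResult(0.0, 1.0, (0, df_pe), "pure_error_F")
    sslof = max(sse - sspe, 0.0)
    f_stat = (sslof / df_lof) / (sspe / df_pe)
    p = float(stats.f.sf(f_stat, df_lof, df_pe))
    return LackOfFitResult(float(f_stat), p, (df_lof, df_pe), "pure_error_F")


def quadratic_curvature_test(x: np.ndarray, y: np.ndarray) -> LackOfFitResult:
    """Curvature t-test: significance of a quadratic term added to the line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("curvature test needs at least 3 distinct x values")
    X = np.column_stack([np.ones_like(x), x, x * x])
    res = sm.OLS(y, X).fit()
    t_stat = float(res.tvalues[2])
    p = float(res.pvalues[2])
    return LackOfFitResult(t_stat, p, (1, int(res.df_resid)), "quadratic_t")


def single_compartment_volume(
    N: float,
    b: float,
    sigma: float,
    Cout: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Steady-state volume of one osmometer with membrane tension.

    Solves N/(V - b) = Cout + 2 sigma/(R R_gas T) for V; reduces to the
    ideal law V = b + N/Cout at zero tension.
    """
    if N <= 0 or Cout <= 0 or b < 0:
        raise ValueError("need N > 0, Cout > 0, b >= 0")
    if sigma == 0.0:
        return b + N / Cout

    def resid(V: float) -> float:
        return N / (V - b) - Cout - laplace_concentration_jump(sigma, V, temperature)

    lo = b + max(b, 1.0) * 1e-12
    hi = 10.0 * (N / Cout + b + 1.0)
    return brentq(resid, lo, hi, xtol=1e-15, rtol=1e-12)


def predict_bvh_curve(
    N: float,
    b: float,
    sigma: float,
    cout_grid: np.ndarray,
    c_iso: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Theoretical BVH curve for a single tense osmometer.

    Returns one row per external osmolarity with columns ``cout``, ``v_um3``,
    ``x`` (= c_iso/cout) and ``y`` (= V/V_iso).  At zero tension the curve is
    exactly the BVH line y = (1 - nu_b) x + nu_b; tension flattens the
    hypotonic branch (swelling resisted by the Laplace pressure).  Points
    where the solver fails are emitted as NaN with a warning.
    """
    cout_grid = np.asarray(cout_grid, dtype=float)
    v_iso = single_compartment_volume(N, b, sigma, c_iso, temperature)
    vols = np.full(cout_grid.shape, np.nan)
    for i, cout in enumerate(cout_grid):
        try:
            vols[i] = single_compartment_volume(N, b, sigma, cout, temperature)
        except (ValueError, RuntimeError) as exc:
            logger.warning("BVH curve point Cout=%g failed: %s", cout, exc)
    return pd.DataFrame(
        {"cout": cout_grid, "v_um3": vols, "x": c_iso / cout_grid, "y": vols / v_iso}
    )


def infer_osmolytes(
    V_before: float,
    V_after: float,
    deltaC: float,
    b: float,
    cell_id: str = "",
) -> OsmolyteEstimate:
    """Recover osmolyte amount N and internal osmolarity from one shift.

    For an ideal osmometer the amount N = C (V - b) is conserved across the
    shift, so with a known external osmolarity step deltaC = C2 - C1 the
    pre-shift internal osmolarity follows from

        C1 = deltaC * (V2 - b) / ((V1 - b) - (V2 - b)),    N = C1 * (V1 - b).

    Exact round-trip on noiseless forward-generated data.  A volume change
    whose sign contradicts the shift direction (e.g. growth under a
    hypertonic step) yields a flagged estimate rather than an error.
    """
    free1, free2 = V_before - b, V_after - b
    if free1 <= 0 or free2 <= 0:
        raise ValueError(
            f"free volumes must be positive, got {free1:.4g} and {free2:.4g} um^3"
        )
    if V_before == V_after:
        raise ValueError("volumes before and after the shift are identical")
    if deltaC == 0:
        raise ValueError("concentration step deltaC must be non-zero")
    warning = ""
    if deltaC * (free1 - free2) < 0:
        warning = (
            f"volume change (dV={V_after - V_before:+.4g} um^3) inconsistent "
            f"with shift sign (dC={deltaC:+.4g} mOsm)"
        )
        warnings.warn(warning, stacklevel=2)
    C1 = deltaC * free2 / (free1 - free2)
    N = C1 * free1
    return OsmolyteEstimate(
        cell_id=cell_id, N=N, C_iso_internal=C1, b_used=b, quality_warning=warning
    )


def osmolarity_from_density(n_per_um3: float) -> float:
    """Osmolarity (mOsm) of a solution with ``n_per_um3`` particles per um^3."""
    return particles_per_um3_to_mosm(n_per_um3)


def sphere_area_ratio(volume_ratio: float) -> float:
    """Surface-area ratio of a sphere given its volume ratio (v^(2/3))."""
    if volume_ratio <= 0:
        raise ValueError("volume ratio must be positive")
    return volume_ratio ** (2.0 / 3.0)
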