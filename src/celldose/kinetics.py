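"""Time-activity curves, cumulated activity, and spatial activity assignment.

Cumulated activity (A-tilde, Bq s) is the time integral of the activity in a
source region; multiplied by the matching cellular S value it gives absorbed
dose.  Measured uptake data are sparse (typically 1 h and 24 h points), so the
integral uses trapezoidal integration of the piecewise-linear curve anchored
at zero activity at exposure start.  Beyond the last measurement the activity
can be extrapolated assuming physical decay only (no further uptake).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "TimeActivityCurve",
    "CumulatedActivityMap",
    "cumulated_activity",
    "decay_extrapolation",
    "assign_activity",
    "split_nonnuclear",
    "two_point_activities",
]

COMPARTMENTS = ("cell", "N", "Cy", "Cs")
SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-cell activity samples in one compartment.

    ``times_h`` strictly increasing (hours, not including t=0);
    ``activities_Bq`` the matching activities per cell.  Zero activity at
    t=0 is implied: uptake starts when exposure starts.
    """

    compartment: str
    times_h: np.ndarray
    activities_Bq: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_Bq, dtype=float)
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if t.ndim != 1 or t.shape != a.shape or t.size == 0:
            raise ValueError("times and activities must be equal-length 1D arrays")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(a < 0):
            raise ValueError("activities must be non-negative")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_Bq", a)

    def with_origin(self) -> tuple[np.ndarray, np.ndarray]:
        """Times/activities with the implied (0, 0) sample prepended."""
        return (np.concatenate([[0.0], self.times_h]),
                np.concatenate([[0.0], self.activities_Bq]))


def cumulated_activity(curve: TimeActivityCurve, t_end_h: float) -> float:
    """Trapezoidal cumulated activity (Bq s) from exposure start to ``t_end_h``.

    The curve is treated as piecewise linear through (0, 0) and the samples;
    ``t_end_h`` beyond the last sample is an error (use
    :func:`decay_extrapolation` for the post-measurement tail).
    """
    t, a = curve.with_origin()
    if t_end_h < 0:
        raise ValueError("t_end must be non-negative")
    if t_end_h > t[-1] + 1e-12:
        raise ValueError(
            f"t_end {t_end_h} h beyond last sample {t[-1]} h; "
            "use decay_extrapolation for the post-measurement tail")
    a_end = np.interp(t_end_h, t, a)
    keep = t < t_end_h
    tt = np.concatenate([t[keep], [t_end_h]])
    aa = np.concatenate([a[keep], [a_end]])
    return float(np.trapezoid(aa, tt) * SECONDS_PER_HOUR)


def decay_extrapolation(A_end_Bq: float, half_life_days: float,
                        horizon_days: float) -> float:
    """Cumulated activity (Bq s) of ``A_end * exp(-lambda t)`` over
    ``horizon_days``; ``horizon=inf`` gives ``A_end / lambda``."""
    if A_end_Bq < 0:
        raise ValueError("activity must be non-negative")
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    lam = np.log(2.0) / (half_life_days * SECONDS_PER_DAY)  # 1/s
    if np.isinf(horizon_days):
        return float(A_end_Bq / lam)
    if horizon_days < 0:
        raise ValueError("horizon must be non-negative")
    return float(A_end_Bq * (1.0 - np.exp(-lam * horizon_days * SECONDS_PER_DAY)) / lam)


def split_nonnuclear(acum_cell: float, acum_nucleus: float,
                     cy_fraction: float = 0.5) -> dict[str, float]:
    """Split whole-cell cumulated activity into the MIRD source triple.

    The non-nuclear share ``acum_cell - acum_nucleus`` is divided between
    cytoplasm and cell surface; measurements rarely resolve the two, so the
    default split is 50/50 and ``cy_fraction`` exposes the assumption.
    """
    if acum_nucleus > acum_cell:
        raise ValueError("nuclear cumulated activity exceeds whole-cell value")
    if not 0.0 <= cy_fraction <= 1.0:
        raise ValueError("cy_fraction must be in [0, 1]")
    rest = acum_cell - acum_nucleus
    return {"N": acum_nucleus, "Cy": cy_fraction * rest,
            "Cs": (1.0 - cy_fraction) * rest}


def two_point_activities(acum_1h: float, acum_24h: float) -> tuple[float, float]:
    """Invert two-point trapezoidal cumulated activities back to the
    activities at 1 h and 24 h (Bq), assuming A(0) = 0 and piecewise-linear
    uptake.  Used to continue a measured time course into the decay-only
    regime."""
    A1 = 2.0 * acum_1h / SECONDS_PER_HOUR
    A24 = 2.0 * (acum_24h - acum_1h) / (23.0 * SECONDS_PER_HOUR) - A1
    return A1, max(A24, 0.0)


@dataclass
class CumulatedActivityMap:
    """Per-cell cumulated activity (Bq s) in each MIRD source region.

    ``scenario`` is ``"uniform"`` or ``"peripheral"``; under the peripheral
    scenario only cells in the outer shell carry activity.
    """

    A_N: np.ndarray
    A_Cy: np.ndarray
    A_Cs: np.ndarray
    scenario: str
    shell_depth_um: float | None = None
    exposure_h: float | None = None

    @property
    def n_cells(self) -> int:
        return self.A_N.size

    @property
    def total(self) -> dict[str, float]:
        return {"N": float(self.A_N.sum()), "Cy": float(self.A_Cy.sum()),
                "Cs": float(self.A_Cs.sum())}

    def scaled(self, factor: float) -> "CumulatedActivityMap":
        return CumulatedActivityMap(self.A_N * factor, self.A_Cy * factor,
                                    self.A_Cs * factor, self.scenario,
                                    self.shell_depth_um, self.exposure_h)


def assign_activity(model, per_cell_triple: dict[str, float], scenario: str,
                    *, shell_depth_um: float | None = None,
                    exposure_h: float | None = None) -> CumulatedActivityMap:
    """Distribute per-cell cumulated activity over a packed assembly.

    ``per_cell_triple`` maps ``{"N", "Cy", "Cs"}`` to Bq s per labeled cell.
    Under ``"uniform"`` every cell carries the triple; under ``"peripheral"``
    only cells within ``shell_depth_um`` of the spheroid surface do, and
    interior cells carry zero (they are irradiated by cross-fire only).
    """
    from .packing import peripheral_mask

    for key in ("N", "Cy", "Cs"):
        if per_cell_triple.get(key, 0.0) < 0:
            raise ValueError(f"negative cumulated activity for {key}")
    n = model.n_cells
    if scenario == "uniform":
        w = np.ones(n)
    elif scenario == "peripheral":
        if shell_depth_um is None:
            shell_depth_um = 4.0 * float(np.mean(model.R_c))  # two mean diameters
        w = peripheral_mask(model, shell_depth_um).astype(float)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return CumulatedActivityMap(
        A_N=w * per_cell_triple.get("N", 0.0),
        A_Cy=w * per_cell_triple.get("Cy", 0.0),
        A_Cs=w * per_cell_triple.get("Cs", 0.0),
        scenario=scenario, shell_depth_um=shell_depth_um, exposure_h=exposure_h)
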