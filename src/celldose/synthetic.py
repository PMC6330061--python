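"""Synthetic inputs and bundled benchmark scenarios.

Everything the pipeline consumes can be generated here without external
data: subcellular internalization time courses with compartment structure
and measurement noise, correlated cell/nucleus radius distributions, and
spatial uptake patterns.

The module also bundles a registry of benchmark scenarios for three
carcinoma cell lines (MDA-MB-468 breast, SQ20B head-and-neck squamous,
231-H2N HER2-transfected breast) exposed to an In-111-labeled EGFR-targeted
peptide ("EGF", 8 MBq/ug at 40 nM) or an In-111-labeled anti-HER2 antibody
("Tz", trastuzumab, 6 MBq/ug at 10 nM) for 1 h or 24 h: measured cell and
nucleus radii, LQ radiosensitivity from acute cesium irradiation, whole-cell
and nuclear cumulated activities from two-point trapezoidal integration of
internalization assays, and the spatial uptake pattern (uniform vs
peripheral rim) observed by microautoradiography of treated spheroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import TimeActivityCurve, split_nonnuclear
from .packing import RadiiDistribution
from .radiobiology import RadiosensitivityParams

__all__ = [
    "SyntheticUptakeSpec",
    "generate_timecourse",
    "CELL_LINES",
    "CellLineInfo",
    "Scenario",
    "load_scenario",
    "available_scenarios",
]


@dataclass(frozen=True)
class SyntheticUptakeSpec:
    """Specification for a synthetic internalization time course.

    ``plateaus_Bq`` maps compartments N/Cy/Cs to the activity per cell
    reached at ``t_plateau_h``; ``shape`` is "linear" (ramp to plateau) or
    "saturating" (exponential approach with rate ``rate_per_h``);
    ``noise_cv`` applies multiplicative lognormal measurement noise.
    """

    plateaus_Bq: dict
    sampling_times_h: tuple = (1.0, 24.0)
    shape: str = "linear"
    t_plateau_h: float = 24.0
    rate_per_h: float = 0.2
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.plateaus_Bq.values()):
            raise ValueError("plateau activities must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.shape not in ("linear", "saturating"):
            raise ValueError(f"unknown uptake shape {self.shape!r}")


def generate_timecourse(spec: SyntheticUptakeSpec) -> dict[str, TimeActivityCurve]:
    """Generate per-compartment time-activity curves (plus their whole-cell
    sum), deterministic for a given seed.

    Noiseless curves follow the requested shape exactly; with noise, each
    sample is multiplied by an independent lognormal factor of unit mean and
    coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times_h, dtype=float)
    curves: dict[str, TimeActivityCurve] = {}
    total = np.zeros_like(t)
    for comp in ("N", "Cy", "Cs"):
        plateau = float(spec.plateaus_Bq.get(comp, 0.0))
        if spec.shape == "linear":
            a = plateau * np.clip(t / spec.t_plateau_h, 0.0, 1.0)
        else:
            a = plateau * (1.0 - np.exp(-spec.rate_per_h * t))
        if spec.noise_cv > 0:
            sigma = np.sqrt(np.log1p(spec.noise_cv**2))
            a = a * rng.lognormal(-sigma**2 / 2.0, sigma, size=t.shape)
        curves[comp] = TimeActivityCurve(comp, t, a)
        total = total + a
    curves["cell"] = TimeActivityCurve("cell", t, total)
    return curves


@dataclass(frozen=True)
class CellLineInfo:
    """Measured geometry and radiosensitivity of one cell line."""

    name: str
    radii: RadiiDistribution
    alpha: float
    beta: float

    def params(self, *, repair_half_time_h=1.5, rbe_nucleus=4.0) -> RadiosensitivityParams:
        return RadiosensitivityParams(self.alpha, self.beta,
                                      repair_half_time_h, rbe_nucleus)


CELL_LINES = {
    "MDA-468": CellLineInfo("MDA-468", RadiiDistribution(9.45, 1.71, 6.65, 1.30),
                            alpha=0.46, beta=0.003),
    "SQ20B": CellLineInfo("SQ20B", RadiiDistribution(10.61, 1.24, 8.10, 1.39),
                          alpha=0.20, beta=0.001),
    "231-H2N": CellLineInfo("231-H2N", RadiiDistribution(11.21, 2.59, 7.09, 1.44),
                            alpha=0.12, beta=0.06),
}

AGENTS = {
    "EGF": "In-111-EGF (EGFR-targeted peptide, 8 MBq/ug, 40 nM)",
    "Tz": "In-111-trastuzumab (anti-HER2 antibody, 6 MBq/ug, 10 nM)",
}

# (cell line, agent, hours) -> (whole-cell Atilde, nuclear Atilde) in Bq s,
# from two-point trapezoidal integration of the internalization assays
_CUMULATED = {
    ("MDA-468", "EGF", 1): (331.0, 72.0),
    ("MDA-468", "EGF", 24): (19558.0, 3688.0),
    ("SQ20B", "EGF", 1): (242.0, 42.0),
    ("SQ20B", "EGF", 24): (15594.0, 1597.0),
    ("231-H2N", "EGF", 1): (13.0, 2.0),
    ("231-H2N", "EGF", 24): (1533.0, 108.0),
    ("MDA-468", "Tz", 1): (10.0, 1.0),
    ("MDA-468", "Tz", 24): (1026.0, 67.0),
    ("SQ20B", "Tz", 1): (14.0, 2.0),
    ("SQ20B", "Tz", 24): (1274.0, 170.0),
    ("231-H2N", "Tz", 1): (96.0, 46.0),
    ("231-H2N", "Tz", 24): (5947.0, 1884.0),
}

# Microautoradiography of treated spheroids: which exposures leave activity
# confined to the peripheral rim.  EGF penetrates loosely packed MDA-MB-468
# spheroids by 24 h but stays peripheral in densely rimmed SQ20B spheroids;
# the antibody reaches the 231-H2N core only by 24 h.  Exposures with
# negligible uptake are treated as uniform.
_PERIPHERAL = {
    ("MDA-468", "EGF", 1), ("SQ20B", "EGF", 1), ("SQ20B", "EGF", 24),
    ("231-H2N", "Tz", 1),
}

# Experimental clonogenic surviving fractions (mean, SD%), for comparison
# only -- never an input to the dose pipeline.
EXPERIMENTAL_SF = {
    ("MDA-468", "EGF", 1): (0.71, 0.10), ("MDA-468", "EGF", 24): (0.01, 0.01),
    ("SQ20B", "EGF", 1): (0.95, 0.15), ("SQ20B", "EGF", 24): (0.35, 0.12),
    ("231-H2N", "EGF", 1): (0.92, 0.09), ("231-H2N", "EGF", 24): (0.99, 0.05),
    ("MDA-468", "Tz", 1): (0.97, 0.05), ("MDA-468", "Tz", 24): (0.75, 0.04),
    ("SQ20B", "Tz", 1): (1.10, 0.06), ("SQ20B", "Tz", 24): (1.08, 0.16),
    ("231-H2N", "Tz", 1): (0.87, 0.17), ("231-H2N", "Tz", 24): (0.46, 0.09),
}


@dataclass(frozen=True)
class Scenario:
    """A fully specified exposure: geometry, kinetics, radiosensitivity and
    spatial pattern for one (cell line, agent, duration) combination."""

    name: str
    cell_line: CellLineInfo
    agent: str
    exposure_h: float
    acum_cell: float
    acum_nucleus: float
    spatial: str  # "uniform" | "peripheral"
    cy_fraction: float = 0.5

    @property
    def triple(self) -> dict[str, float]:
        """Per-cell cumulated activity split into the MIRD source regions."""
        return split_nonnuclear(self.acum_cell, self.acum_nucleus,
                                self.cy_fraction)


def available_scenarios() -> list[str]:
    return [f"{line}/{agent}/{h}h" for (line, agent, h) in sorted(_CUMULATED)]


def load_scenario(name: str, *, cy_fraction: float = 0.5) -> Scenario:
    """Load a benchmark scenario by name, e.g. ``"MDA-468/EGF/24h"``."""
    try:
        line, agent, dur = name.split("/")
        hours = int(dur.rstrip("h"))
        acum_cell, acum_nucleus = _CUMULATED[(line, agent, hours)]
    except (ValueError, KeyError):
        raise KeyError(
            f"unknown scenario {name!r}; available: {available_scenarios()}"
        ) from None
    spatial = "peripheral" if (line, agent, hours) in _PERIPHERAL else "uniform"
    return Scenario(name=name, cell_line=CELL_LINES[line], agent=agent,
                    exposure_h=float(hours), acum_cell=acum_cell,
                    acum_nucleus=acum_nucleus, spatial=spatial,
                    cy_fraction=cy_fraction)
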