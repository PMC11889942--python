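"""Linear calibration between relaxation rate and nanoparticle concentration.

For SPIO-type agents the transverse relaxation rate rises linearly with the
local Fe concentration, ``rate = slope * C + intercept``, where the slope is
the relaxivity-like transformation coefficient (s⁻¹ per μg/mL) and the
intercept is the agent-free baseline rate of the suspending medium.  The
coefficient is estimated by ordinary least squares over tube phantoms of
known concentration, then inverted to turn rate maps (or ΔR2* maps, whose
baseline cancels in the pre/post subtraction) into concentration maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .quantification import DeltaMap
from .relaxometry import RelaxationMap

__all__ = ["CalibrationModel", "ConcentrationMap", "calibrate", "invert"]

DOMAINS = ("R2", "R2*", "dR2*")


@dataclass
class CalibrationModel:
    """Fitted line rate = slope * conc + intercept.

    slope : s⁻¹ per (μg/mL); positive for a valid SPIO calibration.
    intercept : s⁻¹, the agent-free baseline rate.
    domain : which rate quantity the line was fitted on ("R2", "R2*", "dR2*").
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    domain: str = "R2"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown calibration domain {self.domain!r}")
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")

    def forward(self, conc):
        """Predicted rate at concentration ``conc``."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


@dataclass
class ConcentrationMap:
    """Per-voxel agent concentration (μg/mL), non-negative on valid voxels."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    valid: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")


def calibrate(points: Iterable[tuple[float, float]], domain: str = "R2") -> CalibrationModel:
    """Ordinary least squares of rate on concentration.

    Parameters
    ----------
    points : iterable of (concentration in μg/mL, rate in s⁻¹).
    domain : the rate quantity the points come from.

    With exactly two points the fitted line passes through both.  Raises if
    fewer than two points are given or all concentrations coincide (singular
    design).  ``r_squared`` is reported as exactly 1.0 when the points are
    collinear to machine precision.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (conc, rate) points")
    conc, rate = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations are equal: singular design")

    # 2-parameter normal equations in centred form (numerically stable)
    cbar, rbar = conc.mean(), rate.mean()
    scc = ((conc - cbar) ** 2).sum()
    scr = ((conc - cbar) * (rate - rbar)).sum()
    slope = scr / scc
    intercept = rbar - slope * cbar

    resid = rate - (intercept + slope * conc)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((rate - rbar) ** 2).sum())
    if ss_tot == 0 or ss_res <= 1e-12 * max(ss_tot, 1.0):
        r2 = 1.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))

    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            r_squared=r2, n_points=int(pts.shape[0]),
                            domain=domain)


def invert(model: CalibrationModel,
           rate_map: Union[RelaxationMap, DeltaMap],
           use_intercept: bool | None = None) -> ConcentrationMap:
    """Convert a rate map into a concentration map via the fitted line.

    For R2/R2* maps the fitted intercept (agent-free baseline) is subtracted:
    ``C = (rate - intercept) / slope``.  For ΔR2* maps the baseline has
    already cancelled in the pre/post subtraction, so a zero intercept is
    forced by default: ``C = Δrate / slope``; pass ``use_intercept=True`` to
    override.  Negative concentrations are clipped to zero and counted in
    ``n_clipped`` as a quality-control signal.
    """
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive to invert")
    if isinstance(rate_map, DeltaMap):
        if model.domain not in ("dR2*", "R2", "R2*"):
            raise ValueError(f"domain {model.domain!r} cannot map a ΔR2* map")
        intercept = model.intercept if use_intercept else 0.0
        values, valid, spacing = rate_map.values, rate_map.valid, rate_map.spacing
    else:
        if not rate_map.is_rate:
            raise ValueError("invert expects a rate-kind map; call to_rate first")
        if model.domain == "dR2*":
            raise ValueError("a ΔR2*-domain model cannot map an absolute rate map")
        intercept = 0.0 if use_intercept is False else model.intercept
        values, valid, spacing = rate_map.values, rate_map.valid, rate_map.spacing

    with np.errstate(invalid="ignore"):
        conc = (values - intercept) / model.slope
    negative = valid & (conc < 0)
    n_clipped = int(negative.sum())
    conc = np.where(valid, np.clip(conc, 0.0, None), np.nan)
    return ConcentrationMap(values=conc, spacing=spacing, valid=valid,
                            n_clipped=n_clipped)
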