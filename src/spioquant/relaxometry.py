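"""Mono-exponential transverse relaxometry.

Estimates per-voxel (or per-tube) S0 and T2/T2* from multi-echo magnitude
data under the signal model ``S(TE) = S0 * exp(-TE / T2)``, and converts
relaxation-time maps to rate maps (``R2* = 1000 / T2*`` with T2* in ms and
R2* in s⁻¹).

Two fit methods are provided:

``loglinear``
    Weighted least squares on ``ln S`` versus TE with weights ``S²`` — the
    standard variance-stabilising choice, since for additive noise of
    constant variance the variance of ``ln S`` is approximately ``σ²/S²``.
    Closed form, deterministic, and exact on noiseless data.
``nls``
    Nonlinear least squares on the exponential model itself
    (scipy ``curve_fit``), initialised from the log-linear solution.

Echoes at or below a noise floor (default twice the known channel sigma) are
excluded per voxel before fitting, because the Rician noise floor biases
log-domain fits at low SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import EchoSeries, MultiEchoVolume

__all__ = [
    "DecayFit",
    "RelaxationMap",
    "FitConfig",
    "fit_monoexponential",
    "fit_volume",
    "to_rate",
    "to_time",
]

TIME_KINDS = ("T2", "T2*")
RATE_KINDS = ("R2", "R2*")
_RATE_OF_TIME = {"T2": "R2", "T2*": "R2*"}
_TIME_OF_RATE = {v: k for k, v in _RATE_OF_TIME.items()}

DEFAULT_T2_BOUNDS = (1.0, 2000.0)  # ms; scanner-plausible range


@dataclass
class DecayFit:
    """Result of a mono-exponential fit for one series."""

    s0_hat: float
    t2_hat: float        # ms
    r_squared: float
    valid: bool
    n_used: int = 0      # echoes above the noise floor actually fitted


@dataclass
class FitConfig:
    """Settings for voxel-wise fitting."""

    method: str = "loglinear"                 # "loglinear" | "nls"
    t2_bounds: tuple[float, float] = DEFAULT_T2_BOUNDS
    noise_floor: Optional[float] = None       # signal units; None -> 2*sigma
    snr_k: float = 5.0                        # first-echo mask: S(TE1) >= k*sigma
    noise_sigma: Optional[float] = None       # overrides volume metadata


@dataclass
class RelaxationMap:
    """Per-voxel relaxation time (ms) or rate (s⁻¹) with a validity mask."""

    values: np.ndarray
    kind: str                                # "T2" | "T2*" | "R2" | "R2*"
    spacing: tuple[float, float, float]
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.kind not in TIME_KINDS + RATE_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask shapes differ")

    @property
    def is_rate(self) -> bool:
        return self.kind in RATE_KINDS


def _resolve_floor(noise_floor: Optional[float],
                   noise_sigma: Optional[float]) -> float:
    if noise_floor is not None:
        return float(noise_floor)
    if noise_sigma is not None:
        return 2.0 * float(noise_sigma)
    return 0.0


def _loglinear(tes: np.ndarray, sig: np.ndarray) -> tuple[float, float, float]:
    """Weighted LS of ln(S) on TE, weights S².  Returns (s0, t2, r²)."""
    y = np.log(sig)
    w = sig ** 2
    sw = w.sum()
    tbar = (w * tes).sum() / sw
    ybar = (w * y).sum() / sw
    stt = (w * (tes - tbar) ** 2).sum()
    sty = (w * (tes - tbar) * (y - ybar)).sum()
    slope = sty / stt
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * tes)
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if ss_tot > 0 and ss_res < 1e-12 * ss_tot:
        r2 = 1.0
    t2 = -1.0 / slope if slope < 0 else np.inf
    return float(np.exp(intercept)), float(t2), float(min(r2, 1.0))


def fit_monoexponential(series: EchoSeries, method: str = "loglinear",
                        bounds: tuple[float, float] = DEFAULT_T2_BOUNDS,
                        noise_floor: Optional[float] = None) -> DecayFit:
    """Fit ``S0 * exp(-TE/T2)`` to one echo series.

    Echoes with signal at or below the noise floor are dropped.  A fit whose
    decay rate is non-positive, or whose T2 falls outside ``bounds``, is
    returned with ``valid=False`` rather than raising.

    Parameters
    ----------
    series : the echo series to fit.
    method : "loglinear" (closed-form weighted log fit, default) or "nls"
        (exponential-domain least squares initialised from the log fit).
    bounds : plausible T2 range in ms; fits outside are marked invalid.
    noise_floor : signal threshold; defaults to ``2 * series.noise_sigma``.
    """
    if method not in ("loglinear", "nls"):
        raise ValueError(f"unknown fit method {method!r}")
    floor = _resolve_floor(noise_floor, series.noise_sigma or None)
    keep = series.signals > max(floor, 0.0)
    tes = series.echo_times[keep]
    sig = series.signals[keep]
    if tes.size < 2:
        return DecayFit(np.nan, np.nan, 0.0, False, n_used=int(tes.size))

    s0, t2, r2 = _loglinear(tes, sig)
    if method == "nls" and np.isfinite(t2):
        try:
            popt, _ = curve_fit(
                lambda te, a, tt: a * np.exp(-te / tt), tes, sig,
                p0=[s0, t2], maxfev=2000,
            )
            s0, t2 = float(popt[0]), float(popt[1])
            pred = s0 * np.exp(-tes / t2)
            ss_res = float(((sig - pred) ** 2).sum())
            ss_tot = float(((sig - sig.mean()) ** 2).sum())
            r2 = 1.0 if ss_tot == 0 or ss_res < 1e-12 * ss_tot \
                else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
        except RuntimeError:
            return DecayFit(s0, t2, r2, False, n_used=int(tes.size))

    valid = bool(np.isfinite(t2) and t2 > 0 and bounds[0] <= t2 <= bounds[1])
    return DecayFit(s0, t2, r2, valid, n_used=int(tes.size))


def fit_volume(vol: MultiEchoVolume, config: Optional[FitConfig] = None) -> RelaxationMap:
    """Voxel-wise mono-exponential fit of a 4-D multi-echo volume.

    Voxels failing the first-echo SNR mask (``S(TE₁) >= snr_k * sigma`` when
    the noise level is known), or with fewer than two echoes above the noise
    floor, or with out-of-bounds fits, are flagged invalid.  Returns a
    relaxation-time map whose kind is "T2*" for gradient-echo acquisitions
    and "T2" for spin-echo.

    The log-linear path is fully vectorised; ``method="nls"`` refines each
    valid voxel with :func:`fit_monoexponential` (slower, per-voxel loop).
    """
    config = config or FitConfig()
    if vol.n_echoes < 2:
        raise ValueError("at least two echoes are required")
    sigma = config.noise_sigma if config.noise_sigma is not None else vol.noise_sigma
    floor = _resolve_floor(config.noise_floor, sigma)
    kind = "T2" if "SE" in vol.acquisition.upper() and "GRE" not in vol.acquisition.upper() else "T2*"

    shape3 = vol.data.shape[:3]
    sig = vol.data.reshape(-1, vol.n_echoes)
    tes = vol.echo_times

    keep = sig > max(floor, 0.0)
    w = np.where(keep, sig ** 2, 0.0)
    # log only where kept; placeholder 1.0 elsewhere gets zero weight
    y = np.log(np.where(keep, sig, 1.0))

    n_used = keep.sum(axis=1)
    enough = n_used >= 2
    sw = w.sum(axis=1)
    sw_safe = np.where(sw > 0, sw, 1.0)
    tbar = (w * tes).sum(axis=1) / sw_safe
    ybar = (w * y).sum(axis=1) / sw_safe
    dt = tes[None, :] - tbar[:, None]
    dy = y - ybar[:, None]
    stt = (w * dt ** 2).sum(axis=1)
    sty = (w * dt * dy).sum(axis=1)
    stt_safe = np.where(stt > 0, stt, 1.0)
    slope = sty / stt_safe

    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(slope < 0, -1.0 / slope, np.nan)

    lo, hi = config.t2_bounds
    valid = enough & (stt > 0) & np.isfinite(t2) & (t2 >= lo) & (t2 <= hi)
    if sigma is not None and sigma > 0:
        valid &= sig[:, 0] >= config.snr_k * sigma

    values = np.where(valid, t2, np.nan).reshape(shape3)
    valid3 = valid.reshape(shape3)

    if config.method == "nls":
        flat_vals = values.reshape(-1)
        for i in np.flatnonzero(valid):
            series = EchoSeries(tes, sig[i], noise_sigma=sigma or 0.0)
            fit = fit_monoexponential(series, method="nls",
                                      bounds=config.t2_bounds,
                                      noise_floor=config.noise_floor)
            flat_vals[i] = fit.t2_hat if fit.valid else np.nan
            if not fit.valid:
                valid.reshape(-1)[i] = False
        values = flat_vals.reshape(shape3)
        valid3 = valid.reshape(shape3)

    return RelaxationMap(values=values, kind=kind, spacing=vol.spacing,
                         valid=valid3)


def to_rate(m: RelaxationMap) -> RelaxationMap:
    """Convert a relaxation-time map (ms) to a rate map (s⁻¹): R = 1000 / T.

    Voxels with non-positive times are marked invalid rather than mapped to
    infinity; invalid voxels stay invalid.
    """
    if m.kind not in TIME_KINDS:
        raise ValueError(f"to_rate expects a time-kind map, got {m.kind!r}")
    ok = m.valid & np.isfinite(m.values) & (m.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ok, 1000.0 / m.values, np.nan)
    return RelaxationMap(values=values, kind=_RATE_OF_TIME[m.kind],
                         spacing=m.spacing, valid=ok)


def to_time(m: RelaxationMap) -> RelaxationMap:
    """Inverse of :func:`to_rate`: T (ms) = 1000 / R (s⁻¹)."""
    if m.kind not in RATE_KINDS:
        raise ValueError(f"to_time expects a rate-kind map, got {m.kind!r}")
    ok = m.valid & np.isfinite(m.values) & (m.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(ok, 1000.0 / m.values, np.nan)
    return RelaxationMap(values=values, kind=_TIME_OF_RATE[m.kind],
                         spacing=m.spacing, valid=ok)
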