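"""Digital phantoms and brain scenes with known ground truth.

This module stands in for the scanner.  It produces two kinds of object:

* **Tube phantoms** — agarose tubes doped with iron-oxide (SPIO) nanoparticles
  at known Fe concentrations.  Each tube decays mono-exponentially,
  ``S(TE) = S0 * exp(-TE / T2)``, with T2 set by a linear rate–concentration
  law ``R2 = intercept + relaxivity * C`` (R2 in s⁻¹, C in μg Fe/mL).
* **Pre/post-injection brain scenes** — a 3-D grid with a uniform background
  R2*, an ellipsoidal tumor, and an uptake sub-region where nanoparticle
  accumulation raises R2* by ``relaxivity * C``.  The scene returns both the
  noisy multi-echo magnitude volumes and the exact ground-truth maps, so every
  downstream stage can be checked against truth.

Magnitude-MRI noise is Rician: the magnitude of a complex signal whose real
and imaginary channels carry independent Gaussian noise of standard deviation
``sigma``.  At zero underlying amplitude this reduces to a Rayleigh
distribution with mean ``sigma * sqrt(pi/2)``; at high SNR it approaches
additive Gaussian noise.  All randomness flows through one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "TubeSpec",
    "PhantomSpec",
    "Ellipsoid",
    "SceneSpec",
    "EchoSeries",
    "MultiEchoVolume",
    "SceneTruth",
    "ANCHOR_POINTS",
    "anchored_rate_law",
    "t2_from_concentration",
    "reference_phantom_spec",
    "reference_scene_spec",
    "default_phantom_echo_times",
    "add_rician_noise",
    "simulate_decay",
    "simulate_phantom",
    "simulate_scene",
]

# Printed calibration anchors for the SPIO-antibody agent in 1% agarose:
# (Fe concentration in μg/mL, measured T2 in ms).
ANCHOR_POINTS: tuple[tuple[float, float], ...] = ((0.98, 71.1), (15.7, 13.1))


def anchored_rate_law() -> tuple[float, float]:
    """Linear R2-vs-concentration law through the two anchor tubes.

    Returns
    -------
    (slope, intercept)
        Relaxivity-like slope in s⁻¹ per (μg/mL) and agent-free intercept in
        s⁻¹, from the exact two-point line through the anchors.
    """
    (c1, t2_1), (c2, t2_2) = ANCHOR_POINTS
    r1, r2 = 1000.0 / t2_1, 1000.0 / t2_2
    slope = (r2 - r1) / (c2 - c1)
    intercept = r1 - slope * c1
    return slope, intercept


def t2_from_concentration(conc: float, slope: float | None = None,
                          intercept: float | None = None) -> float:
    """T2 (ms) implied by the linear rate law at Fe concentration ``conc``."""
    if slope is None or intercept is None:
        slope, intercept = anchored_rate_law()
    return 1000.0 / (intercept + slope * float(conc))


def default_phantom_echo_times() -> np.ndarray:
    """Echo times (ms) of the phantom fitting protocol: 16–376 ms, 8 ms steps."""
    return np.arange(16.0, 376.0 + 1e-9, 8.0)


class TubeSpec(BaseModel):
    """One agarose tube: identity, Fe load, true relaxation time, amplitude."""

    tube_id: str
    fe_conc: float = Field(ge=0.0, description="μg Fe per mL")
    true_t2: float = Field(gt=0.0, description="ms")
    s0: float = Field(gt=0.0, description="signal units")


class PhantomSpec(BaseModel):
    """A set of tubes scanned with a shared multi-echo protocol."""

    tubes: list[TubeSpec]
    echo_times: list[float] = Field(min_length=2)
    noise_sigma: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @field_validator("echo_times")
    @classmethod
    def _echoes_increasing_positive(cls, v: list[float]) -> list[float]:
        arr = np.asarray(v, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("echo times must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _unique_tube_ids(self) -> "PhantomSpec":
        ids = [t.tube_id for t in self.tubes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tube_id in phantom spec")
        return self


class Ellipsoid(BaseModel):
    """Axis-aligned ellipsoid in 0-based voxel coordinates (voxel centers)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    @field_validator("semi_axes")
    @classmethod
    def _positive(cls, v):
        if any(a <= 0 for a in v):
            raise ValueError("semi-axes must be positive")
        return v

    def mask(self, shape: Sequence[int]) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        q = sum(((idx[i] - self.center[i]) / self.semi_axes[i]) ** 2
                for i in range(3))
        return q <= 1.0


class SceneSpec(BaseModel):
    """Pre/post-injection brain scene with an ellipsoidal tumor and uptake."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = Field(description="mm per axis")
    background_r2star: float = Field(gt=0.0, description="s⁻¹")
    tumor: Ellipsoid
    uptake: Ellipsoid
    conc: float = Field(ge=0.0, description="μg/mL in the uptake region")
    relaxivity: float = Field(gt=0.0, description="s⁻¹ per (μg/mL)")
    s0: float = Field(gt=0.0)
    echo_times: list[float] = Field(min_length=2)
    noise_sigma: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @field_validator("shape")
    @classmethod
    def _shape_positive(cls, v):
        if any(n < 1 for n in v):
            raise ValueError("grid shape must be positive")
        return v

    @field_validator("spacing")
    @classmethod
    def _spacing_positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("voxel spacing must be positive")
        return v

    @model_validator(mode="after")
    def _uptake_in_grid(self) -> "SceneSpec":
        for i in range(3):
            lo = self.uptake.center[i] - self.uptake.semi_axes[i]
            hi = self.uptake.center[i] + self.uptake.semi_axes[i]
            if lo < -0.5 or hi > self.shape[i] - 0.5:
                raise ValueError(
                    f"uptake region extends outside the grid on axis {i}: "
                    f"[{lo:.1f}, {hi:.1f}] vs shape {self.shape[i]}"
                )
        return self


@dataclass
class EchoSeries:
    """Signal intensity at each echo time for one voxel or tube."""

    echo_times: np.ndarray  # ms
    signals: np.ndarray     # arbitrary units, >= 0 (magnitude)
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.echo_times.shape != self.signals.shape:
            raise ValueError("echo_times and signals must have the same length")
        if np.any(self.signals < 0):
            raise ValueError("magnitude signals must be non-negative")


@dataclass
class MultiEchoVolume:
    """4-D magnitude image (x, y, z, echo) with grid and echo metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # mm
    echo_times: np.ndarray               # ms
    acquisition: str = "T2*GRE"
    noise_sigma: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, echo)")
        if self.data.shape[3] != self.echo_times.size:
            raise ValueError(
                f"echo dimension ({self.data.shape[3]}) does not match "
                f"echo_times length ({self.echo_times.size})"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[3]


@dataclass
class SceneTruth:
    """Exact ground-truth maps of a simulated scene."""

    r2star_pre: np.ndarray   # s⁻¹
    r2star_post: np.ndarray  # s⁻¹
    conc: np.ndarray         # μg/mL
    tumor_mask: np.ndarray   # bool
    uptake_mask: np.ndarray  # bool


def add_rician_noise(signal, sigma: float, seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None):
    """Corrupt a non-negative amplitude with Rician magnitude noise.

    The output is ``sqrt((S + g1)^2 + g2^2)`` with ``g1, g2 ~ N(0, sigma)``
    independent per element.  ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    arr = np.asarray(signal, dtype=float)
    if sigma == 0:
        return arr.copy() if arr.ndim else float(arr)
    if rng is None:
        rng = np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, size=arr.shape)
    g2 = rng.normal(0.0, sigma, size=arr.shape)
    out = np.hypot(arr + g1, g2)
    return out if arr.ndim else float(out)


def simulate_decay(s0: float, t2: float, echo_times, noise_sigma: float = 0.0,
                   seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None) -> EchoSeries:
    """Mono-exponential decay ``S(TE) = S0 exp(-TE/T2)`` with Rician noise.

    Parameters
    ----------
    s0 : signal amplitude at TE = 0.
    t2 : transverse relaxation time in ms; must be positive.
    echo_times : echo times in ms; must be non-empty.
    noise_sigma : per-channel Gaussian SD of the complex noise.
    seed : integer seed; the same seed reproduces the series bit-identically.
    """
    if t2 <= 0:
        raise ValueError("t2 must be positive")
    tes = np.asarray(echo_times, dtype=float)
    if tes.size == 0:
        raise ValueError("echo_times must be non-empty")
    clean = s0 * np.exp(-tes / t2)
    signals = add_rician_noise(clean, noise_sigma, seed=seed, rng=rng)
    return EchoSeries(echo_times=tes, signals=np.asarray(signals),
                      noise_sigma=noise_sigma)


def simulate_phantom(spec: PhantomSpec) -> pd.DataFrame:
    """Simulate every tube of a phantom spec.

    Returns a DataFrame with columns ``tube_id``, ``fe_conc``, ``series``
    (an :class:`EchoSeries` per row), preserving tube order.  Each tube draws
    its noise from an independent stream spawned from the spec seed, so the
    result for tube *k* does not depend on how many tubes precede it.
    """
    rng = np.random.default_rng(spec.seed)
    streams = rng.spawn(len(spec.tubes)) if spec.tubes else []
    rows = []
    for tube, sub in zip(spec.tubes, streams):
        series = simulate_decay(tube.s0, tube.true_t2, spec.echo_times,
                                noise_sigma=spec.noise_sigma, rng=sub)
        rows.append({"tube_id": tube.tube_id, "fe_conc": tube.fe_conc,
                     "series": series})
    return pd.DataFrame(rows, columns=["tube_id", "fe_conc", "series"])


# Serial two-fold dilution from the top anchor concentration down to the
# bottom anchor, plus an agent-free tube: the standard way a phantom set
# spanning 0–15.7 μg/mL is prepared.
_REFERENCE_CONCS = (0.0, 0.98, 1.96, 3.93, 7.85, 15.7)


def reference_phantom_spec(noise_sigma: float = 0.0, seed: int = 0,
                           echo_times: Optional[Sequence[float]] = None,
                           s0: float = 1000.0) -> PhantomSpec:
    """The packaged tube-phantom fixture.

    Six tubes spanning 0–15.7 μg Fe/mL.  T2 values are placed on the linear
    rate–concentration law through the two anchor tubes, so the 0.98 and
    15.7 μg/mL tubes have T2 of exactly 71.1 and 13.1 ms.  Default protocol:
    echo times 16–376 ms in 8 ms steps; pass ``echo_times`` explicitly for
    the 8 ms / 50-echo acquisition dialect.
    """
    slope, intercept = anchored_rate_law()
    if echo_times is None:
        echo_times = default_phantom_echo_times()
    tubes = [
        TubeSpec(tube_id=f"tube{i:02d}", fe_conc=c,
                 true_t2=t2_from_concentration(c, slope, intercept), s0=s0)
        for i, c in enumerate(_REFERENCE_CONCS)
    ]
    return PhantomSpec(tubes=tubes, echo_times=list(np.asarray(echo_times, float)),
                       noise_sigma=noise_sigma, seed=seed)


def reference_scene_spec(noise_sigma: float = 0.0, seed: int = 0,
                         shape: tuple[int, int, int] = (64, 64, 64),
                         conc: float = 7.0) -> SceneSpec:
    """A default brain scene: 64³ grid, ellipsoidal tumor with a central
    uptake core at 7 μg/mL, background R2* 20 s⁻¹ (T2* = 50 ms, typical
    cortical tissue at 7 T), relaxivity from the anchored phantom law, and
    the in vivo 16-echo protocol (TE = 3.3 + 3k ms)."""
    slope, _ = anchored_rate_law()
    cx, cy, cz = (s / 2.0 for s in shape)
    scale = min(shape) / 64.0
    return SceneSpec(
        shape=shape,
        spacing=(0.0625, 0.0625, 0.5),
        background_r2star=20.0,
        tumor=Ellipsoid(center=(cx, cy, cz),
                        semi_axes=(16 * scale, 14 * scale, 12 * scale)),
        uptake=Ellipsoid(center=(cx, cy, cz),
                         semi_axes=(10 * scale, 9 * scale, 8 * scale)),
        conc=conc,
        relaxivity=slope,
        s0=1000.0,
        echo_times=list(3.3 + 3.0 * np.arange(16)),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def simulate_scene(spec: SceneSpec) -> tuple[MultiEchoVolume, MultiEchoVolume, SceneTruth]:
    """Simulate pre- and post-injection multi-echo volumes of a scene.

    Pre-injection R2* is the uniform background; post-injection R2* adds
    ``relaxivity * conc`` inside the uptake region.  Both volumes share the
    grid and echo metadata.  Returns ``(pre, post, truth)`` where ``truth``
    carries the exact R2* maps, concentration map and masks.
    """
    tumor_mask = spec.tumor.mask(spec.shape)
    uptake_mask = spec.uptake.mask(spec.shape)
    if not np.all(tumor_mask[uptake_mask]):
        raise ValueError("uptake region must be contained in the tumor")

    r2_pre = np.full(spec.shape, spec.background_r2star, dtype=float)
    conc_map = np.where(uptake_mask, spec.conc, 0.0)
    r2_post = r2_pre + spec.relaxivity * conc_map

    tes = np.asarray(spec.echo_times, dtype=float)
    # rates are s⁻¹, TE in ms: decay exponent is -TE * R2 / 1000
    clean_pre = spec.s0 * np.exp(-tes[None, None, None, :] * r2_pre[..., None] / 1000.0)
    clean_post = spec.s0 * np.exp(-tes[None, None, None, :] * r2_post[..., None] / 1000.0)

    rng = np.random.default_rng(spec.seed)
    data_pre = add_rician_noise(clean_pre, spec.noise_sigma, rng=rng)
    data_post = add_rician_noise(clean_post, spec.noise_sigma, rng=rng)

    meta = dict(spacing=spec.spacing, echo_times=tes, acquisition="T2*GRE",
                noise_sigma=spec.noise_sigma, seed=spec.seed)
    pre = MultiEchoVolume(data=data_pre, **meta)
    post = MultiEchoVolume(data=data_post, **meta)
    truth = SceneTruth(r2star_pre=r2_pre, r2star_post=r2_post, conc=conc_map,
                       tumor_mask=tumor_mask, uptake_mask=uptake_mask)
    return pre, post, truth
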