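"""Sinusoidal limb-force model of symmetrical quadrupedal walking.

A walking quadruped is reduced to four limbs that each press on the
center of mass (CoM) with prescribed, mass-specific force waveforms while
in stance:

* vertical: a half-sine of amplitude ``Az`` spanning the stance period,
  with ``Az = pi * g / (8 * DF)`` so that the four limbs together support
  body weight exactly at any duty factor ``DF``;
* fore-aft: a full sine of amplitude ``Ax = fore_aft_ratio * Az``
  (decelerate-then-accelerate for upright walking; sign-reversed for
  suspended, sloth-like progression), optionally supplemented by a
  half-sine bias of amplitude ``bias_ratio * Az`` — net forward impulse
  from the hindlimbs balanced by a net backward impulse from the
  forelimbs;
* lateral: an optional half-sine of amplitude ``medial_ratio * Az``
  directed toward the body midline by every limb.

CoM velocities follow by integrating the summed limb forces (minus
gravity, vertically) over the periodic stride, subtracting means so that
vertical and lateral velocities fluctuate about zero, and adding a mean
forward speed. The mechanical "limb work" cost of a stride is the sum
over limbs of the time-integral of the *positive* part of each limb's
instantaneous power ``P = F . V``: negative work by one limb cannot power
positive work performed simultaneously by another, and no elastic
recovery is allowed.

Units are dimensionless model units throughout: body mass 1, gravity
``g = 1`` and stride period ``Tstride = 1`` by default, so forces are in
units of body weight and velocities in units of ``g * Tstride``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "ConfigError",
    "LimbId",
    "LH",
    "LF",
    "RH",
    "RF",
    "LIMBS",
    "GaitConfig",
    "ForceSeries",
    "ComState",
    "vertical_amplitude",
    "footfall_schedule",
    "limb_force_series",
    "all_limb_forces",
    "com_velocities",
    "limb_power_series",
    "stride_work_cost",
    "stance_angle",
    "gait_time_series",
]


class ConfigError(ValueError):
    """Invalid gait configuration (out-of-range parameter or an

    insufficient mean forward speed)."""


@dataclass(frozen=True, order=True)
class LimbId:
    """One of the four limbs, identified by girdle and side."""

    girdle: Literal["hind", "fore"]
    side: Literal["left", "right"]

    @property
    def label(self) -> str:
        """Two-letter Hildebrand label: LH, LF, RH or RF."""
        return self.side[0].upper() + self.girdle[0].upper()

    @property
    def is_hind(self) -> bool:
        return self.girdle == "hind"

    @property
    def is_left(self) -> bool:
        return self.side == "left"

    @classmethod
    def from_label(cls, label: str) -> "LimbId":
        try:
            side = {"L": "left", "R": "right"}[label[0].upper()]
            girdle = {"H": "hind", "F": "fore"}[label[1].upper()]
        except (KeyError, IndexError):
            raise ValueError(f"unknown limb label {label!r}; expected one of LH, LF, RH, RF")
        return cls(girdle, side)  # type: ignore[arg-type]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


LH = LimbId("hind", "left")
LF = LimbId("fore", "left")
RH = LimbId("hind", "right")
RF = LimbId("fore", "right")

#: The four limbs in footfall-schedule order (left hind first).
LIMBS: tuple[LimbId, ...] = (LH, LF, RH, RF)


@dataclass(frozen=True)
class GaitConfig:
    """Full parameterization of one model variant at one (DF, phase) point.

    Parameters
    ----------
    duty_factor
        Fraction of the stride period each limb spends in ground contact,
        identical for all four limbs. Walking requires ``0.5 < DF < 1``.
    phase_pct
        Hildebrand limb phase: percent of the stride by which the
        ipsilateral forefoot contact follows the hindfoot contact,
        in ``[0, 100)``. 25 gives evenly spaced footfalls, 50 trot
        timing, 0 pace timing.
    fore_aft_ratio
        Amplitude of the fore-aft full sine relative to the vertical
        amplitude. The default 0.2 corresponds to a stance sweep angle of
        roughly 30 degrees (see :func:`stance_angle`).
    bias_ratio
        Amplitude of the fore-aft half-sine bias relative to the vertical
        amplitude (hindlimbs net-forward, forelimbs net-backward).
        0 for the base model, 0.1 for the biased and full variants.
    medial_ratio
        Amplitude of the medially directed half-sine relative to the
        vertical amplitude. 0 for planar variants, 0.05 for the full
        variant.
    orientation
        ``"upright"`` or ``"suspended"``. Suspended (below-branch,
        sloth-like) progression reverses the sign of the fore-aft full
        sine only.
    gravity, stride_period
        Mass-specific weight and stride duration; both default to 1
        (dimensionless model units).
    mean_forward_speed
        Mean fore-aft CoM velocity added to the integrated fluctuation.
        ``None`` (default) resolves to ``max(g * Tstride, 1.5 * p2p)``
        where ``p2p`` is the peak-to-peak fore-aft velocity fluctuation:
        a value constant across any standard (DF, phase) sweep yet always
        sufficient to keep the instantaneous fore-aft velocity forward.
        The cost ordering over phases is insensitive to this choice as
        long as the fore-aft velocity stays positive and the value does
        not vary within a sweep.
    samples_per_stride
        Size of the uniform circular time grid (>= 256; default 2048).
    """

    duty_factor: float
    phase_pct: float
    fore_aft_ratio: float = 0.2
    bias_ratio: float = 0.0
    medial_ratio: float = 0.0
    orientation: Literal["upright", "suspended"] = "upright"
    gravity: float = 1.0
    stride_period: float = 1.0
    mean_forward_speed: float | None = None
    samples_per_stride: int = 2048

    def __post_init__(self) -> None:
        if not 0.5 < self.duty_factor < 1.0:
            raise ConfigError(
                f"duty_factor must lie in (0.5, 1) for walking, got {self.duty_factor}"
            )
        if not 0.0 <= self.phase_pct < 100.0:
            raise ConfigError(f"phase_pct must lie in [0, 100), got {self.phase_pct}")
        for name in ("fore_aft_ratio", "bias_ratio", "medial_ratio"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gravity <= 0:
            raise ConfigError(f"gravity must be > 0, got {self.gravity}")
        if self.stride_period <= 0:
            raise ConfigError(f"stride_period must be > 0, got {self.stride_period}")
        if self.orientation not in ("upright", "suspended"):
            raise ConfigError(f"orientation must be 'upright' or 'suspended', got {self.orientation!r}")
        if self.mean_forward_speed is not None and self.mean_forward_speed <= 0:
            raise ConfigError("mean_forward_speed must be positive when given")
        if self.samples_per_stride < 256:
            raise ConfigError(f"samples_per_stride must be >= 256, got {self.samples_per_stride}")

    @property
    def stance_period(self) -> float:
        """Stance duration ``Tstance = DF * Tstride``."""
        return self.duty_factor * self.stride_period

    def at(self, duty_factor: float | None = None, phase_pct: float | None = None) -> "GaitConfig":
        """Copy of this configuration at another (DF, phase) grid point."""
        kwargs = {}
        if duty_factor is not None:
            kwargs["duty_factor"] = duty_factor
        if phase_pct is not None:
            kwargs["phase_pct"] = phase_pct
        return replace(self, **kwargs)

    def time_grid(self) -> np.ndarray:
        """Uniform circular time grid over one stride (endpoint excluded)."""
        n = self.samples_per_stride
        return np.arange(n) * (self.stride_period / n)


@dataclass(frozen=True)
class ForceSeries:
    """Mass-specific 3-component force of one limb over the circular grid.

    ``forces`` has shape ``(N, 3)`` with columns (fore-aft ``Fx``,
    lateral ``Fy``, vertical ``Fz``); nonzero only inside the stance
    window ``[onset, onset + DF)`` (stride fractions, mod 1).
    """

    limb: LimbId
    onset: float
    times: np.ndarray = field(repr=False)
    forces: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must have shape (N, 3)")
        if len(self.times) != len(self.forces):
            raise ValueError("times and forces must have equal length")


@dataclass(frozen=True)
class ComState:
    """CoM velocity components over the stride, consistent with the forces.

    ``velocities`` has shape ``(N, 3)`` with columns (``Vx``, ``Vy``,
    ``Vz``); vertical and lateral components average to zero over the
    stride and the fore-aft component averages to ``mean_forward_speed``
    and is strictly positive at every sample.
    """

    times: np.ndarray = field(repr=False)
    velocities: np.ndarray = field(repr=False)
    mean_forward_speed: float


def vertical_amplitude(duty_factor: float, gravity: float = 1.0) -> float:
    """Half-sine vertical force amplitude giving exact weight support.

    Each limb's half-sine averages ``2/pi`` of its amplitude over stance
    and is active for a fraction ``DF`` of the stride, so four limbs
    supply a stride-averaged vertical force ``Az * 8 * DF / pi``.
    Setting this equal to ``g`` gives ``Az = pi * g / (8 * DF)``.

    Raises
    ------
    ConfigError
        If ``duty_factor`` or ``gravity`` is not positive (or DF > 1).
    """
    if not 0.0 < duty_factor <= 1.0:
        raise ConfigError(f"duty_factor must lie in (0, 1], got {duty_factor}")
    if gravity <= 0:
        raise ConfigError(f"gravity must be > 0, got {gravity}")
    return math.pi * gravity / (8.0 * duty_factor)


def footfall_schedule(phase_pct: float) -> dict[LimbId, float]:
    """Contact onsets (stride fractions) for LH, LF, RH, RF.

    The left hind defines the stride start; the ipsilateral fore follows
    by ``phase_pct / 100``; the right side repeats the left half a stride
    later (symmetrical gait).
    """
    if not 0.0 <= phase_pct < 100.0:
        raise ConfigError(f"phase_pct must lie in [0, 100), got {phase_pct}")
    p = phase_pct / 100.0
    return {LH: 0.0, LF: p % 1.0, RH: 0.5, RF: (0.5 + p) % 1.0}


def _stance_window(config: GaitConfig, onset: float) -> tuple[np.ndarray, np.ndarray]:
    """Stance mask and local stance time for a limb with the given onset."""
    t = config.time_grid()
    tau = (t - onset * config.stride_period) % config.stride_period
    mask = tau < config.stance_period
    return mask, np.where(mask, tau, 0.0)


def limb_force_series(config: GaitConfig, limb: LimbId) -> ForceSeries:
    """Force profile of one limb over the circular stride grid.

    Within stance (local time ``tau`` in ``[0, Tstance)``):

    * ``Fz = Az * sin(pi * tau / Tstance)``
    * ``Fx = s * Ax * sin(2*pi * tau / Tstance) + b * Ab * sin(pi * tau / Tstance)``
      with ``s = -1`` upright (decelerate then accelerate), ``+1``
      suspended, and ``b = +1`` for hind limbs, ``-1`` for fore limbs;
    * ``Fy = m * Ay * sin(pi * tau / Tstance)`` with ``m`` directed toward
      the midline: with +y to the animal's left, left limbs push the CoM
      rightward (``m = -1``) and right limbs leftward (``m = +1``). Costs
      are invariant under the mirror convention.

    All components are zero outside stance.
    """
    az = vertical_amplitude(config.duty_factor, config.gravity)
    ax = config.fore_aft_ratio * az
    ab = config.bias_ratio * az
    ay = config.medial_ratio * az

    onset = footfall_schedule(config.phase_pct)[limb]
    mask, tau = _stance_window(config, onset)
    half = np.where(mask, np.sin(np.pi * tau / config.stance_period), 0.0)
    full = np.where(mask, np.sin(2.0 * np.pi * tau / config.stance_period), 0.0)

    s = 1.0 if config.orientation == "suspended" else -1.0
    b = 1.0 if limb.is_hind else -1.0
    m = -1.0 if limb.is_left else 1.0

    fz = az * half
    fx = s * ax * full + b * ab * half
    fy = m * ay * half
    return ForceSeries(limb=limb, onset=onset, times=config.time_grid(),
                       forces=np.column_stack([fx, fy, fz]))


def all_limb_forces(config: GaitConfig) -> dict[LimbId, ForceSeries]:
    """Force series for all four limbs, keyed by :class:`LimbId`."""
    return {limb: limb_force_series(config, limb) for limb in LIMBS}


def _circular_cumtrapz(y: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative trapezoidal integral on a uniform circular grid."""
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * dt, axis=0)
    return out


def stride_integral(values: np.ndarray, stride_period: float) -> np.ndarray:
    """Integral of a periodic sample sequence over one stride.

    On a uniform circular grid the trapezoidal rule with wrap-around
    reduces to the sample mean times the period.
    """
    return np.mean(values, axis=0) * stride_period


def com_velocities(
    forces: Mapping[LimbId, ForceSeries] | Iterable[ForceSeries],
    config: GaitConfig,
) -> ComState:
    """CoM velocities from the summed limb forces.

    The net mass-specific force (total limb force, minus gravity on the
    vertical component) is integrated cumulatively over the periodic
    stride; each component's stride mean is subtracted so vertical and
    lateral velocities fluctuate about zero, and the mean forward speed
    is added to the fore-aft component.

    Raises
    ------
    ConfigError
        If the resolved fore-aft velocity is not strictly positive at
        every sample; pass a larger ``mean_forward_speed``.
    ValueError
        If the four series are not on a common grid or the vertical
        impulse does not balance gravity.
    """
    series = list(forces.values()) if isinstance(forces, Mapping) else list(forces)
    if len({fs.limb for fs in series}) != 4 or len(series) != 4:
        raise ValueError("com_velocities requires exactly the four distinct limbs")
    n = config.samples_per_stride
    if any(len(fs.forces) != n for fs in series):
        raise ValueError("force series are not on the configured time grid")

    total = np.sum([fs.forces for fs in series], axis=0)
    net = total.copy()
    net[:, 2] -= config.gravity
    mean_net = net.mean(axis=0)
    if abs(mean_net[2]) > 1e-4 * config.gravity:
        raise ValueError(
            "total vertical impulse does not balance gravity; "
            "force series are inconsistent with the configuration"
        )
    # Subtract the (numerically tiny) discrete mean so that the
    # integrated velocity is exactly periodic on the grid.
    net -= mean_net

    dt = config.stride_period / n
    vel = _circular_cumtrapz(net, dt)
    vel -= vel.mean(axis=0)

    v0 = config.mean_forward_speed
    if v0 is None:
        p2p = float(vel[:, 0].max() - vel[:, 0].min())
        v0 = max(config.gravity * config.stride_period, 1.5 * p2p)
    vel[:, 0] += v0
    if vel[:, 0].min() <= 0.0:
        raise ConfigError(
            "instantaneous fore-aft velocity is not strictly positive; "
            "increase mean_forward_speed"
        )
    return ComState(times=config.time_grid(), velocities=vel, mean_forward_speed=float(v0))


def limb_power_series(force_series: ForceSeries, com: ComState) -> np.ndarray:
    """Instantaneous limb power ``P = F . V`` over the stride.

    Components cancel *within* the limb before any rectification: a
    positive vertical-force power concurrent with an equal negative
    fore-aft power yields zero limb power.
    """
    if len(force_series.forces) != len(com.velocities):
        raise ValueError("force series and CoM state are on different grids")
    return np.einsum("ij,ij->i", force_series.forces, com.velocities)


def stride_work_cost(config: GaitConfig) -> float:
    """Positive limb work summed over the four limbs for one stride.

    The cost is ``sum_limbs integral max(P_limb, 0) dt``; it is
    deterministic for a fixed configuration and grid.
    """
    forces = all_limb_forces(config)
    com = com_velocities(forces, config)
    cost = 0.0
    for fs in forces.values():
        p = limb_power_series(fs, com)
        cost += float(stride_integral(np.maximum(p, 0.0), config.stride_period))
    return cost


def stance_angle(fore_aft_ratio: float) -> float:
    """Stance sweep angle (degrees) implied by a fore-aft amplitude ratio.

    At a quarter of the way through stance the half-sine vertical force
    is ``Az * sin(pi/4)`` and the full-sine fore-aft force is at its
    extreme ``Ax``; treating their resultant as pure compression along
    the leg, the leg leans ``atan(|Fx| / Fz)`` from vertical, and by
    symmetry the total sweep is twice that:
    ``Phi = 2 * atan(sqrt(2) * Ax / Az)``.

    A ratio of 0.2 gives approximately 30 degrees.
    """
    if fore_aft_ratio < 0:
        raise ConfigError(f"fore_aft_ratio must be >= 0, got {fore_aft_ratio}")
    return math.degrees(2.0 * math.atan(math.sqrt(2.0) * fore_aft_ratio))


def gait_time_series(config: GaitConfig):
    """Tidy per-limb time series of forces, CoM velocities and limb power.

    Returns a :class:`pandas.DataFrame` with columns ``time_fraction,
    limb, fx, fy, fz, vx, vy, vz, power`` (one block of N rows per limb).
    """
    import pandas as pd

    forces = all_limb_forces(config)
    com = com_velocities(forces, config)
    frac = config.time_grid() / config.stride_period
    blocks = []
    for limb in LIMBS:
        fs = forces[limb]
        power = limb_power_series(fs, com)
        blocks.append(
            pd.DataFrame(
                {
                    "time_fraction": frac,
                    "limb": limb.label,
                    "fx": fs.forces[:, 0],
                    "fy": fs.forces[:, 1],
                    "fz": fs.forces[:, 2],
                    "vx": com.velocities[:, 0],
                    "vy": com.velocities[:, 1],
                    "vz": com.velocities[:, 2],
                    "power": power,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)
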