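"""Collision-mechanics diagnostics for the limb-force model.

Locomotor losses can be framed by the angle between a limb's force (or
net impulse) vector and the CoM velocity: losses shrink as the angle
approaches perpendicular. This module computes net limb impulses,
per-sample force-velocity angles, and the sign of the early-stance
vertical CoM velocity whose reversal with duty factor underlies the
switch of work-minimizing phase families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .force_model import (
    LH,
    ComState,
    ForceSeries,
    GaitConfig,
    LimbId,
    all_limb_forces,
    com_velocities,
    limb_power_series,
    stride_integral,
)

__all__ = [
    "ImpulseVector",
    "net_limb_impulse",
    "force_velocity_angle_series",
    "early_stance_vertical_velocity_sign",
    "diagnostics_frame",
]

#: Samples with force or velocity magnitude below this are excluded from angles.
MIN_MAGNITUDE = 1e-12


@dataclass(frozen=True)
class ImpulseVector:
    """Stride-integrated mass-specific force of one limb (fore-aft, lateral, vertical)."""

    limb: LimbId
    components: np.ndarray

    @property
    def fore_aft(self) -> float:
        return float(self.components[0])

    @property
    def lateral(self) -> float:
        return float(self.components[1])

    @property
    def vertical(self) -> float:
        return float(self.components[2])


def net_limb_impulse(force_series: ForceSeries, stride_period: float = 1.0) -> ImpulseVector:
    """Componentwise stride integral of one limb's force.

    For the base model the fore-aft component vanishes (full sine); with
    a fore-aft bias the hindlimb impulse tilts forward and the forelimb
    impulse backward by ``bias_ratio * Az * (2/pi) * Tstance`` each.
    """
    comps = stride_integral(force_series.forces, stride_period)
    return ImpulseVector(limb=force_series.limb, components=comps)


def force_velocity_angle_series(
    force_series: ForceSeries, com: ComState
) -> tuple[np.ndarray, np.ndarray]:
    """Angle (degrees) between limb force and CoM velocity at stance samples.

    Returns ``(time_fractions, angles_deg)`` restricted to samples where
    both vectors have magnitude above :data:`MIN_MAGNITUDE`. An angle
    above 90 degrees is equivalent to instantaneous negative limb power.
    """
    f = force_series.forces
    v = com.velocities
    if len(f) != len(v):
        raise ValueError("force series and CoM state are on different grids")
    fmag = np.linalg.norm(f, axis=1)
    vmag = np.linalg.norm(v, axis=1)
    keep = (fmag > MIN_MAGNITUDE) & (vmag > MIN_MAGNITUDE)
    cosang = np.einsum("ij,ij->i", f[keep], v[keep]) / (fmag[keep] * vmag[keep])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return force_series.times[keep], angles


def early_stance_vertical_velocity_sign(config: GaitConfig) -> int:
    """Sign of the mean CoM vertical velocity over the first half of hind stance.

    Evaluated over the first half of the left-hind stance window (the LH
    onset defines the stride start). At trot timing (phase 50) the base
    model yields -1 (downward) at low duty factors such as 0.65 and +1
    (upward) at high duty factors such as 0.80.
    """
    com = com_velocities(all_limb_forces(config), config)
    t = config.time_grid()
    mask = t < 0.5 * config.stance_period
    mean_vz = float(com.velocities[mask, 2].mean())
    return 1 if mean_vz > 0 else -1


def diagnostics_frame(config: GaitConfig):
    """Per-limb power and force-velocity angle over the stride.

    DataFrame columns: ``time_fraction, limb, power, angle_deg`` (angle
    is NaN outside stance or at negligible-magnitude samples).
    """
    import pandas as pd

    forces = all_limb_forces(config)
    com = com_velocities(forces, config)
    frac = config.time_grid() / config.stride_period
    blocks = []
    for limb, fs in forces.items():
        power = limb_power_series(fs, com)
        angle = np.full(len(frac), np.nan)
        times, ang = force_velocity_angle_series(fs, com)
        idx = np.searchsorted(config.time_grid(), times)
        angle[idx] = ang
        blocks.append(
            pd.DataFrame(
                {
                    "time_fraction": frac,
                    "limb": limb.label,
                    "power": power,
                    "angle_deg": angle,
                }
            )
        )
    return pd.concat(blocks, ignore_index=True)
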