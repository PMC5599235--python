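"""Synthetic footfall events and species ensembles.

Emulates the statistical structure of video-derived gait observations:
footfall event logs generated from a target duty factor, phase and
stride period with Gaussian timing jitter (frame-timing measurement
error), and species ensembles with the two-cluster gait-space structure
(a high duty factor / phase 40-50 % group and a lower duty factor /
phase near 25 % group), so measurement, clustering and regression can be
exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .force_model import LIMBS, footfall_schedule
from .kinematics import FootfallEvents

__all__ = [
    "EventGeneratorSpec",
    "GroupSpec",
    "EnsembleSpec",
    "generate_events",
    "generate_species_ensemble",
]

# Jitter draws are truncated at +/- 3 SD before being applied.
JITTER_CAP_SD = 3.0


@dataclass(frozen=True)
class EventGeneratorSpec:
    """Parameters for one synthetic footfall-event sequence."""

    duty_factor: float
    phase_pct: float
    stride_period: float = 1.0
    n_strides: int = 20
    timing_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.duty_factor < 1.0:
            raise ValueError(f"duty_factor must lie in (0.5, 1), got {self.duty_factor}")
        if not 0.0 <= self.phase_pct < 100.0:
            raise ValueError(f"phase_pct must lie in [0, 100), got {self.phase_pct}")
        if self.stride_period <= 0:
            raise ValueError("stride_period must be > 0")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.timing_jitter_sd < 0:
            raise ValueError("timing_jitter_sd must be >= 0")


def generate_events(spec: EventGeneratorSpec) -> FootfallEvents:
    """Timed contact/lift events for all four limbs over ``n_strides`` strides.

    Contacts follow the symmetrical-gait footfall schedule scaled by the
    stride period; each lift trails its contact by ``DF * Tstride``.
    Independent Gaussian jitter (truncated at 3 SD) is added to every
    event time. Deterministic for a fixed spec.

    Raises
    ------
    ValueError
        If the jitter is large enough to invert an event ordering even
        after truncation.
    """
    rng = np.random.default_rng(spec.seed)
    onsets = footfall_schedule(spec.phase_pct)
    rows = []
    for limb in LIMBS:
        for i in range(spec.n_strides):
            contact = (i + onsets[limb]) * spec.stride_period
            lift = contact + spec.duty_factor * spec.stride_period
            rows.append((limb.label, "contact", contact))
            rows.append((limb.label, "lift", lift))
    table = pd.DataFrame(rows, columns=["limb", "event", "time_s"])
    if spec.timing_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.timing_jitter_sd, size=len(table))
        cap = JITTER_CAP_SD * spec.timing_jitter_sd
        table["time_s"] += np.clip(jitter, -cap, cap)
    try:
        return FootfallEvents(table)
    except ValueError as exc:
        raise ValueError(
            f"timing jitter sd={spec.timing_jitter_sd} inverted an event ordering "
            f"(stride period {spec.stride_period}); reduce the jitter"
        ) from exc


@dataclass(frozen=True)
class GroupSpec:
    """Gaussian gait-parameter distribution of one species group."""

    mean_duty_factor: float
    mean_phase_pct: float
    sd_duty_factor: float = 0.0
    sd_phase_pct: float = 0.0
    n_species: int = 20

    def __post_init__(self) -> None:
        if not 0.5 < self.mean_duty_factor < 1.0:
            raise ValueError("mean_duty_factor must lie in (0.5, 1)")
        if not 0.0 <= self.mean_phase_pct < 100.0:
            raise ValueError("mean_phase_pct must lie in [0, 100)")
        if self.sd_duty_factor < 0 or self.sd_phase_pct < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass(frozen=True)
class EnsembleSpec:
    """Two-or-more-group species ensemble specification."""

    groups: tuple[GroupSpec, ...] = field(
        default=(
            GroupSpec(0.80, 44.0, 0.04, 3.0, 17),  # slow/high-DF grouping
            GroupSpec(0.68, 21.0, 0.04, 6.0, 35),  # 'normal mammalian' grouping
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1:
            raise ValueError("at least one group is required")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Gaussian draws restricted to (lo, hi) by resampling, not clipping."""
    if sd == 0.0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = (out <= lo) | (out >= hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValueError("could not draw values inside the valid range; SD too large")


def generate_species_ensemble(spec: EnsembleSpec) -> pd.DataFrame:
    """Synthetic species-median table with known group labels.

    Returns a DataFrame shaped like the packaged species table
    (``species, group, median_duty_factor, median_phase_pct, n,
    sd_duty_factor, sd_phase_pct``); ``group`` carries the generating
    group (1-based) as ground truth. Duty factors are resampled into
    (0.5, 0.999) and phases into [0, 100) to avoid boundary atoms.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g, grp in enumerate(spec.groups, start=1):
        dfs = _truncated_normal(
            rng, grp.mean_duty_factor, grp.sd_duty_factor, 0.5, 0.999, grp.n_species
        )
        phases = _truncated_normal(
            rng, grp.mean_phase_pct, grp.sd_phase_pct, -1e-12, 100.0, grp.n_species
        )
        phases = np.maximum(phases, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "species": [f"synthetic_g{g}_s{i:02d}" for i in range(grp.n_species)],
                    "group": g,
                    "median_duty_factor": dfs,
                    "median_phase_pct": phases,
                    "n": 1,
                    "sd_duty_factor": np.nan,
                    "sd_phase_pct": np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
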