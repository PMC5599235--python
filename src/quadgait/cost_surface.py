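"""Limb-work cost surfaces over the (duty factor x limb phase) plane.

Sweeps :func:`quadgait.force_model.stride_work_cost` over a grid,
normalizes within each duty-factor row for presentation, locates the
(circular) row minima and the global-minimum line, and bisects for the
critical duty factor at which the work-minimizing phase family switches
between synchronous timing {0, 50} and evenly spaced timing {25, 75}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .force_model import ConfigError, GaitConfig, stride_work_cost

__all__ = [
    "VARIANTS",
    "variant_config",
    "CostSurface",
    "MinimaLine",
    "compute_cost_surface",
    "find_row_minima",
    "global_minimum_line",
    "critical_duty_factor",
    "default_df_grid",
    "default_phase_grid",
]

#: Named model variants: configuration overrides relative to the base model.
VARIANTS: dict[str, dict] = {
    # net-vertical limb impulses, decelerate-accelerate fore-aft force
    "base": {},
    # suspended, sloth-like progression: fore-aft full sine reversed
    "sloth": {"orientation": "suspended"},
    # inclined limb impulses: hindlimbs net-forward, forelimbs net-backward
    "bias": {"bias_ratio": 0.1},
    # bias plus a small medial impulse from each limb
    "full": {"bias_ratio": 0.1, "medial_ratio": 0.05},
}

#: Relative tolerance for treating two row costs as tied.
TIE_RTOL = 1e-9


def variant_config(
    variant: str | GaitConfig,
    duty_factor: float = 0.75,
    phase_pct: float = 25.0,
    **overrides,
) -> GaitConfig:
    """A :class:`GaitConfig` for a named variant (or pass one through).

    ``variant`` may be one of ``"base"``, ``"sloth"``, ``"bias"``,
    ``"full"`` or an existing configuration used as a template.
    """
    if isinstance(variant, GaitConfig):
        kwargs = {"duty_factor": duty_factor, "phase_pct": phase_pct, **overrides}
        return replace(variant, **kwargs)
    try:
        base = VARIANTS[variant]
    except KeyError:
        raise ConfigError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        ) from None
    return GaitConfig(duty_factor=duty_factor, phase_pct=phase_pct, **{**base, **overrides})


def default_df_grid() -> np.ndarray:
    """Duty factors 0.55 to 0.95 in steps of 0.005."""
    return np.arange(110, 191) * 0.005


def default_phase_grid() -> np.ndarray:
    """Phases 0 to 99.5 % in steps of 0.5 % (symmetry phases on-grid)."""
    return np.arange(200) * 0.5


@dataclass(frozen=True)
class CostSurface:
    """Raw and per-row-normalized stride work cost on a (DF x phase) grid."""

    df_grid: np.ndarray = field(repr=False)
    phase_grid: np.ndarray = field(repr=False)
    raw: np.ndarray = field(repr=False)
    normalized: np.ndarray = field(repr=False)
    variant: GaitConfig

    def row(self, duty_factor: float) -> np.ndarray:
        """Raw cost row for a duty factor that lies on the grid."""
        idx = np.flatnonzero(np.isclose(self.df_grid, duty_factor, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise ValueError(f"duty factor {duty_factor} is not on the surface grid")
        return self.raw[idx[0]]

    def to_frame(self):
        """Long-form DataFrame: duty_factor, phase_pct, cost, cost_normalized."""
        import pandas as pd

        dd, pp = np.meshgrid(self.df_grid, self.phase_grid, indexing="ij")
        return pd.DataFrame(
            {
                "duty_factor": dd.ravel(),
                "phase_pct": pp.ravel(),
                "cost": self.raw.ravel(),
                "cost_normalized": self.normalized.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame, variant: GaitConfig | None = None) -> "CostSurface":
        """Rebuild a surface from the long-form CSV layout."""
        pivot = frame.pivot(index="duty_factor", columns="phase_pct", values="cost")
        norm = frame.pivot(index="duty_factor", columns="phase_pct", values="cost_normalized")
        template = variant if variant is not None else variant_config("base")
        return cls(
            df_grid=pivot.index.to_numpy(float),
            phase_grid=pivot.columns.to_numpy(float),
            raw=pivot.to_numpy(float),
            normalized=norm.to_numpy(float),
            variant=template,
        )


@dataclass(frozen=True)
class MinimaLine:
    """Per-duty-factor minima annotations for a cost surface.

    ``global_phases[i]`` is the tie set of phases attaining the row
    minimum (two members for planar variants, where phases P and P+50
    are equivalent); ``local_minima[i]`` lists all circular local-minimum
    phases; ``tie[i]`` flags rows whose global minimum is a tie.
    """

    duty_factors: np.ndarray = field(repr=False)
    local_minima: list[list[float]]
    global_phases: list[list[float]]
    global_normalized_cost: list[float]
    tie: list[bool]


def _row_costs(template: GaitConfig, duty_factor: float, phases: np.ndarray) -> np.ndarray:
    return np.array(
        [stride_work_cost(template.at(duty_factor, float(p))) for p in phases]
    )


def compute_cost_surface(
    variant: str | GaitConfig = "base",
    df_grid: Sequence[float] | None = None,
    phase_grid: Sequence[float] | None = None,
    **overrides,
) -> CostSurface:
    """Stride work cost at every (duty factor, phase) grid node.

    Rows are additionally min-max rescaled to [0, 1] within each duty
    factor for presentation; minima detection always uses the raw rows
    (the argmin is invariant either way).
    """
    template = variant_config(variant, **overrides)
    df_grid = default_df_grid() if df_grid is None else np.asarray(df_grid, float)
    phase_grid = default_phase_grid() if phase_grid is None else np.asarray(phase_grid, float)
    if df_grid.size == 0 or np.any(df_grid <= 0.5) or np.any(df_grid >= 1.0):
        raise ConfigError("df_grid values must lie in (0.5, 1)")
    if phase_grid.size == 0 or np.any(phase_grid < 0.0) or np.any(phase_grid >= 100.0):
        raise ConfigError("phase_grid values must lie in [0, 100)")

    raw = np.empty((df_grid.size, phase_grid.size))
    for i, df in enumerate(df_grid):
        raw[i] = _row_costs(template, float(df), phase_grid)

    normalized = np.empty_like(raw)
    for i, row in enumerate(raw):
        span = row.max() - row.min()
        if span <= TIE_RTOL * max(abs(row.max()), 1.0):
            warnings.warn(
                f"constant cost row at duty factor {df_grid[i]:g}; normalized row set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            normalized[i] = 0.0
        else:
            normalized[i] = (row - row.min()) / span
    return CostSurface(df_grid=df_grid, phase_grid=phase_grid, raw=raw,
                       normalized=normalized, variant=template)


def _local_min_groups(row: np.ndarray, phases: np.ndarray) -> list[tuple[float, float]]:
    """Circular local-minimum (phase, value) pairs with plateau grouping.

    Values within ``TIE_RTOL`` (relative to the row scale) of each other
    are treated as equal; a plateau reports its central phase.
    """
    n = row.size
    tol = TIE_RTOL * max(float(np.abs(row).max()), 1e-300)
    if row.max() - row.min() <= tol:
        warnings.warn("constant cost row: no local minima", RuntimeWarning, stacklevel=3)
        return []
    # group circularly adjacent samples whose values are equal within tol
    flat = np.abs(np.diff(row, append=row[:1])) <= tol  # flat[i]: i ~ i+1
    groups: list[list[int]] = []
    i = 0
    visited = np.zeros(n, bool)
    # start each run at an index whose predecessor is not flat-linked
    starts = [i for i in range(n) if not flat[(i - 1) % n]]
    if not starts:  # fully flat ring already handled above
        return []
    for s in starts:
        run = [s]
        j = s
        while flat[j]:
            j = (j + 1) % n
            run.append(j)
        groups.append(run)
    out = []
    for run in groups:
        lo, hi = run[0], run[-1]
        left, right = row[(lo - 1) % n], row[(hi + 1) % n]
        val = float(row[lo])
        if left > val + tol and right > val + tol:
            center = run[len(run) // 2]
            out.append((float(phases[center]), val))
    return sorted(out)


def find_row_minima(surface: CostSurface, duty_factor: float) -> list[float]:
    """Circular local-minimum phases of one duty-factor row (sorted).

    Plateaus report their central phase; a constant row yields an empty
    list with a warning. The duty factor must lie on the grid exactly
    (no interpolation).
    """
    row = surface.row(duty_factor)
    return [p for p, _ in _local_min_groups(row, surface.phase_grid)]


def global_minimum_line(surface: CostSurface) -> MinimaLine:
    """Argmin phase(s) per duty-factor row; ties reported as tie sets."""
    local_all, global_all, costs, ties = [], [], [], []
    for i in range(surface.df_grid.size):
        row = surface.raw[i]
        groups = _local_min_groups(row, surface.phase_grid)
        local_all.append([p for p, _ in groups])
        if not groups:
            global_all.append([])
            costs.append(float("nan"))
            ties.append(False)
            continue
        best = min(v for _, v in groups)
        tol = TIE_RTOL * max(float(np.abs(row).max()), 1e-300)
        winners = [p for p, v in groups if v <= best + tol]
        global_all.append(winners)
        costs.append(float(surface.normalized[i][np.argmin(row)]))
        ties.append(len(winners) > 1)
    return MinimaLine(
        duty_factors=surface.df_grid,
        local_minima=local_all,
        global_phases=global_all,
        global_normalized_cost=costs,
        tie=ties,
    )


_SYNC_FAMILY = (0.0, 50.0)
_EVEN_FAMILY = (25.0, 75.0)


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 100.0
    return min(d, 100.0 - d)


def _minima_family(template: GaitConfig, duty_factor: float, phases: np.ndarray) -> str:
    """Which phase family the global row minimum is (circularly) closer to."""
    row = _row_costs(template, duty_factor, phases)
    gp = float(phases[int(np.argmin(row))])
    d_sync = min(_circ_dist(gp, f) for f in _SYNC_FAMILY)
    d_even = min(_circ_dist(gp, f) for f in _EVEN_FAMILY)
    return "sync" if d_sync < d_even else "even"


def critical_duty_factor(
    variant: str | GaitConfig = "base",
    tolerance: float = 0.002,
    df_bounds: tuple[float, float] = (0.55, 0.95),
    phase_step: float = 0.5,
    **overrides,
) -> float:
    """Duty factor at which the work-minimizing phase family switches.

    Bisects on the indicator "global row minimum nearer {0, 50} than
    {25, 75}" between the bounds. For the base (upright) model with
    fore-aft ratio 0.2 the switch lies near DF = 0.75; it moves higher
    with larger fore-aft amplitude, and the suspended variant switches
    in the opposite direction.

    Raises
    ------
    ConfigError
        If the variant has medial forces (minima families are then not
        symmetric) or no family switch occurs between the bounds.
    """
    template = variant_config(variant, **overrides)
    if template.medial_ratio != 0:
        raise ConfigError("critical_duty_factor requires medial_ratio == 0")
    if tolerance <= 0:
        raise ConfigError("tolerance must be > 0")
    phases = np.arange(0.0, 100.0, phase_step)
    lo, hi = df_bounds
    f_lo = _minima_family(template, lo, phases)
    f_hi = _minima_family(template, hi, phases)
    if f_lo == f_hi:
        raise ConfigError(
            f"no minima-family switch between duty factors {lo} and {hi}"
        )
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if _minima_family(template, mid, phases) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def plot_surface(surface: CostSurface, path: str, dpi: int = 150) -> None:
    """Export a heat map PNG (phase on x, duty factor descending on y)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    extent = (
        float(surface.phase_grid[0]),
        float(surface.phase_grid[-1]),
        float(surface.df_grid[0]),
        float(surface.df_grid[-1]),
    )
    im = ax.imshow(
        surface.normalized,
        origin="lower",
        aspect="auto",
        extent=extent,
        cmap="RdYlBu_r",
    )
    ax.invert_yaxis()
    ax.set_xlabel("limb phase (%)")
    ax.set_ylabel("duty factor")
    fig.colorbar(im, ax=ax, label="normalized limb work cost")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
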