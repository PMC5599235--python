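"""Observational gait-space analysis: Hildebrand metrics and species table.

Duty factor and limb phase are estimated from timed footfall events
(per-limb contact/lift logs); a packaged table of median gait parameters
for 52 quadrupedal species supports the two-group K-means classification
and the phase-versus-duty-factor regression of the observational gait
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .force_model import LH, LimbId

__all__ = [
    "FootfallEvents",
    "SpeciesRecord",
    "duty_factor_from_events",
    "limb_phase_from_events",
    "load_species_table",
    "species_records",
    "kmeans_two_groups",
    "fit_phase_df_regression",
    "RegressionFit",
]

EVENT_COLUMNS = ("limb", "event", "time_s")
_VALID_EVENTS = {"contact", "lift"}
_VALID_LIMBS = {"LH", "LF", "RH", "RF"}


@dataclass(frozen=True)
class FootfallEvents:
    """Ordered per-limb contact/lift events spanning at least one stride.

    Wraps a DataFrame with columns ``limb`` (LH|LF|RH|RF), ``event``
    (contact|lift) and ``time_s``. Events are sorted by time on
    construction; per limb they must alternate contact/lift and be
    strictly increasing.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.events
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"events table is missing columns: {sorted(missing)}")
        bad = set(df["limb"]) - _VALID_LIMBS
        if bad:
            raise ValueError(f"unknown limb labels: {sorted(bad)}")
        bad = set(df["event"]) - _VALID_EVENTS
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        object.__setattr__(self, "events", df)
        for limb, sub in df.groupby("limb"):
            times = sub["time_s"].to_numpy(float)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"event times for limb {limb} are not strictly increasing")
            kinds = sub["event"].to_list()
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise ValueError(f"events for limb {limb} do not alternate contact/lift")

    @classmethod
    def from_csv(cls, path) -> "FootfallEvents":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    def times_of(self, limb: LimbId | str, event: str) -> np.ndarray:
        label = limb if isinstance(limb, str) else limb.label
        sub = self.events[(self.events["limb"] == label) & (self.events["event"] == event)]
        return sub["time_s"].to_numpy(float)


class SpeciesRecord(NamedTuple):
    """One species-median row of the packaged gait table."""

    species: str
    group: int
    median_duty_factor: float
    median_phase_pct: float
    n: int
    sd_duty_factor: float | None
    sd_phase_pct: float | None


class RegressionFit(NamedTuple):
    """OLS fit of median phase (%) on median duty factor."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float


def duty_factor_from_events(events: FootfallEvents, limb: LimbId | str = LH) -> float:
    """Duty factor of one limb: contact duration over stride period.

    Averaged arithmetically over all complete strides (consecutive
    contact pairs). The reference limb defaults to the left hind, per
    the convention that duty factor is defined on a hind limb.
    """
    label = limb if isinstance(limb, str) else limb.label
    contacts = events.times_of(label, "contact")
    lifts = events.times_of(label, "lift")
    if contacts.size < 2:
        raise ValueError(
            f"need at least two contacts of limb {label} to measure a stride period"
        )
    values = []
    for c0, c1 in zip(contacts, contacts[1:]):
        lift = lifts[(lifts > c0) & (lifts < c1)]
        if lift.size != 1:
            raise ValueError(f"no single lift of limb {label} between contacts at {c0} and {c1}")
        values.append((lift[0] - c0) / (c1 - c0))
    return float(np.mean(values))


def _circular_mean_phase(phases_pct: np.ndarray) -> float:
    """Mean of phases on the 0-100 circle (plain mean when no wrap risk)."""
    if phases_pct.max() - phases_pct.min() < 50.0:
        return float(np.mean(phases_pct))
    ang = phases_pct * (2.0 * np.pi / 100.0)
    mean = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float((mean * 100.0 / (2.0 * np.pi)) % 100.0)


def limb_phase_from_events(events: FootfallEvents, side: str = "left") -> float:
    """Hildebrand limb phase (%): fore contact lag after ipsilateral hind.

    For each complete hind-limb stride, the first ipsilateral fore
    contact within the stride defines ``100 * (t_fore - t_hind) /
    stride_period``; per-stride values are averaged (circularly when
    they straddle the 0/100 wrap).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    prefix = side[0].upper()
    hind = events.times_of(prefix + "H", "contact")
    fore = events.times_of(prefix + "F", "contact")
    if hind.size < 2:
        raise ValueError(f"need at least two {prefix}H contacts to measure a stride period")
    stride = float(np.mean(np.diff(hind)))
    values = []
    for f in fore:
        preceding = hind[hind <= f]
        if preceding.size == 0:
            continue  # fore contact before the first recorded hind contact
        lag = f - preceding[-1]
        if lag > 1.5 * stride:
            continue  # stray contact with no matching stride
        values.append(100.0 * ((lag % stride) / stride))
    if len(values) < hind.size - 1:
        raise ValueError(
            f"missing {prefix}F contact within one stride of a {prefix}H contact"
        )
    return _circular_mean_phase(np.asarray(values)) % 100.0


def load_species_table() -> pd.DataFrame:
    """The packaged species gait table (52 species medians).

    Columns: ``species, group, median_duty_factor, median_phase_pct, n,
    sd_duty_factor, sd_phase_pct`` (SDs empty where only one observation
    exists). Group 1 is the high duty factor, phase 40-50 % grouping
    (reptiles, amphibians, mouse, hippo); Group 2 the 'normal mammalian'
    grouping with lower duty factors and phases around or below 25 %.
    """
    ref = resources.files("quadgait.data").joinpath("species_gaits.csv")
    try:
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise RuntimeError("packaged species gait table is missing") from exc
    _validate_species_table(table)
    return table


def _validate_species_table(table: pd.DataFrame) -> None:
    required = {"species", "median_duty_factor", "median_phase_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"species table is missing columns: {sorted(missing)}")
    df = table["median_duty_factor"]
    ph = table["median_phase_pct"]
    if not ((df > 0.5) & (df < 1.0)).all():
        raise ValueError("median duty factors must lie in (0.5, 1)")
    if not ((ph >= 0.0) & (ph < 100.0)).all():
        raise ValueError("median phases must lie in [0, 100)")
    if "n" in table.columns and not (table["n"] >= 1).all():
        raise ValueError("observation counts must be >= 1")


def species_records(table: pd.DataFrame) -> list[SpeciesRecord]:
    """Rows of a species table as typed records (NaN SDs become None)."""
    out = []
    for row in table.itertuples(index=False):
        sd_df = getattr(row, "sd_duty_factor", float("nan"))
        sd_ph = getattr(row, "sd_phase_pct", float("nan"))
        out.append(
            SpeciesRecord(
                species=row.species,
                group=int(getattr(row, "group", 0)),
                median_duty_factor=float(row.median_duty_factor),
                median_phase_pct=float(row.median_phase_pct),
                n=int(getattr(row, "n", 1)),
                sd_duty_factor=None if pd.isna(sd_df) else float(sd_df),
                sd_phase_pct=None if pd.isna(sd_ph) else float(sd_ph),
            )
        )
    return out


def kmeans_two_groups(table: pd.DataFrame, seed: int = 0, n_init: int = 50) -> np.ndarray:
    """Two-group K-means labels on (duty factor, phase), z-scored.

    Features are standardized before clustering so that phase (measured
    in percent) does not dominate the Euclidean metric. The cluster with
    the higher mean duty factor is labeled 1, the other 2; labels are
    returned in table row order and are deterministic given the seed.
    """
    _validate_species_table(table)
    X = table[["median_duty_factor", "median_phase_pct"]].to_numpy(float)
    if len(X) < 2:
        raise ValueError("need at least two records to cluster")
    if np.allclose(X, X[0]):
        raise ValueError("cannot cluster identical points into two groups")
    from sklearn.cluster import KMeans

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Z = (X - mean) / std
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(Z)
    labels = km.labels_
    high = 1 if X[labels == 1, 0].mean() > X[labels == 0, 0].mean() else 0
    return np.where(labels == high, 1, 2)


def fit_phase_df_regression(table: pd.DataFrame) -> RegressionFit:
    """Unweighted OLS of median phase (%) on median duty factor.

    Fitted across species-median rows; for the packaged table this
    reproduces the observational gait-space trend of roughly
    ``phase (%) = 130 DF - 66``.
    """
    _validate_species_table(table)
    if len(table) < 3:
        raise ValueError("need at least three records to fit a regression")
    import statsmodels.api as sm

    x = table["median_duty_factor"].to_numpy(float)
    y = table["median_phase_pct"].to_numpy(float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
    )
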