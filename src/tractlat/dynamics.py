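"""Lifespan analytics derived from fitted asymmetry charts.

Four summaries of the population-median LI trajectory:

- its first derivative across age (finite differences);
- lateralization reversals — ages where the median crosses zero, i.e. the
  typical direction of asymmetry flips hemisphere;
- epoch slopes — the mean per-year rate of change of |median LI| within six
  predefined life stages (positive = strengthening asymmetry, negative =
  attenuation);
- snapshot tables of median LI and rightward prevalence at six
  representative ages (the median age of each epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CentileChart, NormativeModel, prevalence_right

__all__ = [
    "Epoch",
    "DEFAULT_EPOCHS",
    "SNAPSHOT_AGES",
    "ReversalEvent",
    "EpochSlope",
    "median_derivative",
    "detect_reversals",
    "epoch_slopes",
    "snapshot_summary",
    "snapshot_heatmaps",
]


@dataclass(frozen=True)
class Epoch:
    """A life stage [lo, hi) in years; the final epoch closes its upper bound."""

    name: str
    lo: float
    hi: float
    closed_upper: bool = False

    def contains(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        upper = ages <= self.hi if self.closed_upper else ages < self.hi
        return (ages >= self.lo) & upper


DEFAULT_EPOCHS: tuple[Epoch, ...] = (
    Epoch("early childhood", 2, 5),
    Epoch("childhood", 5, 12),
    Epoch("adolescence", 12, 20),
    Epoch("early adulthood", 20, 40),
    Epoch("midlife", 40, 60),
    Epoch("older adulthood", 60, 100, closed_upper=True),
)

#: Median age of each epoch, used for discrete snapshot summaries.
SNAPSHOT_AGES: tuple[float, ...] = (3.0, 9.0, 17.0, 30.0, 50.0, 80.0)


@dataclass(frozen=True)
class ReversalEvent:
    tract: str
    feature: str
    context: str
    age_years: float
    direction: str  # "left_to_right" (− to +) or "right_to_left" (+ to −)


@dataclass(frozen=True)
class EpochSlope:
    tract: str
    feature: str
    epoch: str
    slope: float  # d|median LI|/dt, per year


def median_derivative(chart: CentileChart) -> np.ndarray:
    """First derivative of the median LI trajectory across age.

    Central finite differences on interior grid points, one-sided at the two
    ends; same length as the grid.  Requires at least 3 grid points.
    """
    if chart.age_grid.size < 3:
        raise ValueError("grid too short for derivatives (need >= 3 points)")
    return np.gradient(chart.median(), chart.age_grid)


def detect_reversals(chart: CentileChart, min_excursion: float = 0.0) -> list[ReversalEvent]:
    """Zero-crossings of the median LI curve.

    One event per sign change between adjacent grid points, with the
    crossing age linearly interpolated.  A crossing is suppressed when the
    largest |median| excursions on both flanking segments stay below
    ``min_excursion`` (default 0: report every sign change).
    """
    m = chart.median()
    ages = chart.age_grid
    idx = np.nonzero(m[:-1] * m[1:] < 0)[0]
    # segment extrema between consecutive crossings (and the curve ends)
    bounds = [0, *(i + 1 for i in idx), m.size]
    excursions = [
        float(np.max(np.abs(m[bounds[s]:bounds[s + 1]]))) for s in range(len(bounds) - 1)
    ]
    events = []
    for s, i in enumerate(idx):
        if excursions[s] < min_excursion and excursions[s + 1] < min_excursion:
            continue
        frac = m[i] / (m[i] - m[i + 1])
        age = ages[i] + frac * (ages[i + 1] - ages[i])
        direction = "left_to_right" if m[i] < 0 else "right_to_left"
        events.append(
            ReversalEvent(chart.tract, chart.feature, chart.context, float(age), direction)
        )
    return events


def epoch_slopes(
    chart: CentileChart, epochs: tuple[Epoch, ...] = DEFAULT_EPOCHS
) -> list[EpochSlope]:
    """Mean slope of |median LI| within each epoch.

    Computed as the mean of first-difference derivatives of |median| over
    adjacent grid-point pairs inside the epoch; on a uniform grid this equals
    (|median|(last) − |median|(first)) / (age span).  An epoch containing a
    zero crossing mixes signs — the absolute value is taken before
    differencing, matching the finite-difference definition verbatim.
    Requires at least 2 grid points per epoch.
    """
    ages = chart.age_grid
    absm = np.abs(chart.median())
    out = []
    for epoch in epochs:
        mask = epoch.contains(ages)
        if mask.sum() < 2:
            raise ValueError(
                f"epoch {epoch.name!r} [{epoch.lo}, {epoch.hi}) intersects the grid "
                f"in {int(mask.sum())} point(s); need >= 2"
            )
        a = ages[mask]
        v = absm[mask]
        slope = float(np.mean(np.diff(v) / np.diff(a)))
        out.append(EpochSlope(chart.tract, chart.feature, epoch.name, slope))
    return out


def snapshot_summary(
    models: dict[tuple[str, str], NormativeModel],
    ages=SNAPSHOT_AGES,
    context: str = "average",
) -> pd.DataFrame:
    """Median LI and rightward prevalence per tract–feature at snapshot ages.

    Returns a long table (tract, feature, age_years, median_li, pct_right);
    use :func:`snapshot_heatmaps` for the two wide layouts.  Raises if a
    snapshot age lies outside a model's fitted support.
    """
    ages = np.asarray(ages, dtype=float)
    rows = []
    for (tract, feature), model in models.items():
        lo, hi = model.age_range
        if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
            raise ValueError(
                f"snapshot ages outside fitted support [{lo:.1f}, {hi:.1f}] "
                f"for {tract}/{feature}"
            )
        mu, _ = model.predict(ages, context)
        pct = prevalence_right(model, ages, context)
        for a, m, p in zip(ages, mu, pct):
            rows.append(
                {"tract": tract, "feature": feature, "age_years": float(a),
                 "median_li": float(m), "pct_right": float(p)}
            )
    return pd.DataFrame(rows)


def snapshot_heatmaps(summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the snapshot table into (median LI, prevalence) heatmap layouts:
    tract–feature rows x age columns."""
    median = summary.pivot_table(
        index=["tract", "feature"], columns="age_years", values="median_li", sort=False
    )
    prevalence = summary.pivot_table(
        index=["tract", "feature"], columns="age_years", values="pct_right", sort=False
    )
    return median, prevalence
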