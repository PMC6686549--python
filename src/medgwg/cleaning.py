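"""Monotonic cleaning of longitudinal child height series.

Child height should never decrease; EMR-style growth tables contain
entry errors that break that pattern.  A value departs from the
monotonic pattern when it falls below the running maximum of all earlier
values by more than a tolerance.  Flagged (or missing) values are
re-imputed by two methods and fused:

* Last & Next — the mean of the nearest usable neighbours on each side;
* fractional linear regression — the OLS line through the child's
  usable (age, height) points, evaluated at the flagged age;

with default fusion weights 0.3 (Last & Next) and 0.7 (regression).
Only height is cleaned; weight may legitimately decrease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ImputationError

logger = logging.getLogger(__name__)

_MAX_PASSES = 10


@dataclass
class CleaningConfig:
    """Weights for the two imputation methods and the departure tolerance."""

    w_lastnext: float = 0.3
    w_fracreg: float = 0.7
    tolerance: float = 0.0

    def __post_init__(self):
        if self.w_lastnext < 0 or self.w_fracreg < 0:
            raise ConfigError("cleaning weights must be non-negative")
        if abs(self.w_lastnext + self.w_fracreg - 1.0) > 1e-9:
            raise ConfigError("w_lastnext + w_fracreg must equal 1")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")


@dataclass
class GrowthSeries:
    """One child's height series: ages (months, ascending) and values (cm)."""

    child_id: object
    ages: np.ndarray
    values: np.ndarray
    flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ConfigError("ages and values must have equal length")
        if self.ages.size > 1 and not np.all(np.diff(self.ages) > 0):
            raise ConfigError(f"ages must be strictly ascending (child {self.child_id})")
        if self.flags is None:
            self.flags = np.zeros(self.ages.size, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.ages.shape:
                raise ConfigError("flags must match series length")

    def usable(self) -> np.ndarray:
        """Mask of indices that are neither flagged nor missing."""
        return ~self.flags & np.isfinite(self.values)


def flag_nonmonotone(series: GrowthSeries,
                     config: CleaningConfig | None = None) -> GrowthSeries:
    """Flag values that depart from the monotonic pattern.

    Index i > 0 is flagged iff value[i] < max(value[0..i-1]) - tolerance
    (missing earlier values are ignored in the running maximum); missing
    values are flagged for imputation as well.
    """
    config = config or CleaningConfig()
    v = series.values
    flags = np.zeros(v.size, dtype=bool)
    running = -np.inf
    for i in range(v.size):
        if not np.isfinite(v[i]):
            flags[i] = True
            continue
        if v[i] < running - config.tolerance:
            flags[i] = True
        else:
            running = max(running, v[i])
    return replace(series, flags=flags)


def _nearest_usable(series: GrowthSeries, index: int, step: int) -> float | None:
    i = index + step
    usable = series.usable()
    while 0 <= i < series.values.size:
        if usable[i]:
            return float(series.values[i])
        i += step
    return None


def impute_last_next(series: GrowthSeries, index: int) -> float:
    """Mean of the nearest usable neighbours before and after ``index``."""
    prev = _nearest_usable(series, index, -1)
    nxt = _nearest_usable(series, index, +1)
    if prev is None and nxt is None:
        raise ImputationError(
            f"child {series.child_id}: no usable neighbour at index {index}")
    if prev is None:
        return nxt
    if nxt is None:
        return prev
    return 0.5 * (prev + nxt)


def impute_fractional_regression(series: GrowthSeries, index: int) -> float:
    """OLS line through the usable (age, value) points, at ages[index].

    Falls back to the mean of usable values when all usable ages
    coincide (zero age variance).
    """
    usable = series.usable()
    if usable.sum() < 2:
        raise ImputationError(
            f"child {series.child_id}: need >= 2 usable points for regression")
    x = series.ages[usable]
    y = series.values[usable]
    if np.ptp(x) == 0:
        return float(np.mean(y))
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept + slope * series.ages[index])


def clean_series(series: GrowthSeries,
                 config: CleaningConfig | None = None) -> GrowthSeries:
    """Replace flagged/missing heights by the fused imputation.

    Each flagged value becomes ``w_lastnext * LastNext + w_fracreg *
    regression``.  Replacement is iterated (bounded passes) until
    re-flagging finds no departures; a still-departing value after the
    final pass is clamped to the running maximum so the output always
    satisfies the monotonicity rule.  Usable values are bit-identical in
    the output.
    """
    config = config or CleaningConfig()
    current = flag_nonmonotone(series, config)
    if not current.flags.any():
        return replace(current, flags=np.zeros(current.values.size, dtype=bool))
    for _ in range(_MAX_PASSES):
        if not current.flags.any():
            break
        values = current.values.copy()
        for i in np.flatnonzero(current.flags):
            try:
                ln = impute_last_next(current, i)
            except ImputationError:
                ln = None
            try:
                fr = impute_fractional_regression(current, i)
            except ImputationError:
                fr = None
            if ln is None and fr is None:
                raise ImputationError(
                    f"child {current.child_id}: index {i} has no usable "
                    "neighbours and too few points for regression")
            if ln is None:
                new = fr
            elif fr is None:
                new = ln
            else:
                new = config.w_lastnext * ln + config.w_fracreg * fr
            logger.debug("child %s age %.1f: %.2f -> %.2f",
                         current.child_id, current.ages[i], values[i], new)
            values[i] = new
        current = flag_nonmonotone(
            GrowthSeries(current.child_id, current.ages, values), config)
    if current.flags.any():
        # pathological series: enforce the running-max rule directly
        values = current.values.copy()
        running = -np.inf
        for i in range(values.size):
            if current.flags[i] and values[i] < running - config.tolerance:
                values[i] = running
            running = max(running, values[i])
        current = flag_nonmonotone(
            GrowthSeries(current.child_id, current.ages, values), config)
    return current


def clean_growth_table(growth: pd.DataFrame,
                       config: CleaningConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean every child's height series in a long-format growth table.

    Returns the cleaned table (same shape and order) and a change log
    with one row per imputed value (child id, age, old, new).
    """
    config = config or CleaningConfig()
    growth = growth.copy()
    growth["height_cm"] = growth["height_cm"].astype(float)
    changes = []
    for child_id, grp in growth.groupby("child_id", sort=False):
        grp = grp.sort_values("age_months")
        series = GrowthSeries(child_id, grp["age_months"].to_numpy(),
                              grp["height_cm"].to_numpy())
        cleaned = clean_series(series, config)
        delta = ~np.isclose(series.values, cleaned.values, equal_nan=True)
        for pos in np.flatnonzero(delta):
            changes.append({"child_id": child_id,
                            "age_months": series.ages[pos],
                            "old_height_cm": series.values[pos],
                            "new_height_cm": cleaned.values[pos]})
        growth.loc[grp.index, "height_cm"] = cleaned.values
    log = pd.DataFrame(changes, columns=["child_id", "age_months",
                                         "old_height_cm", "new_height_cm"])
    return growth, log
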