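"""Uniformly sampled time series, CSV I/O and capacitation indicators.

The analyses in this package act on short, strictly uniform series: hourly
indicator measurements along a capacitating incubation (time in hours, t = 0
at the start of incubation) and monthly measurements over consecutive years
(fractional month index, 1 = first January, samples taken mid-month).
Irregular sampling and missing values are hard errors by design — the rhythm
detectors downstream assume a constant sampling interval.

Besides the data model this module provides the bespoke indicator arithmetic
used throughout: net percentages (induced minus spontaneous acrosome
reaction; chemotaxis with minus without attractant), third-quartile
fluorescence exceedance, and threshold binning of sample collections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DataError,
    DomainError,
    FormatError,
    InsufficientDataError,
    SpacingError,
)

__all__ = [
    "TimeSeries",
    "ReplicatePanel",
    "NetPercentage",
    "read_series_csv",
    "write_series_csv",
    "detrend_linear",
    "net_percentage",
    "q3_exceedance",
    "threshold_fractions",
]

#: relative tolerance on deviations from the nominal sampling interval
_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled numeric series.

    Parameters
    ----------
    times
        Strictly increasing, uniformly spaced timestamps in ``time_unit``.
    values
        Finite observations, same length as ``times`` (length >= 2).
    sampling_interval
        Nominal spacing; inferred from ``times`` when omitted.
    time_unit
        Free-text unit label ("hour", "month", ...), carried through results.
    label
        Free-text series name.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_interval: float = None  # type: ignore[assignment]
    time_unit: str = "sample"
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise DataError("times and values must be 1-d and equally long")
        if len(times) < 2:
            raise InsufficientDataError("a series needs at least 2 points")
        if not np.all(np.isfinite(times)):
            raise DataError("non-finite timestamp")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise DataError(f"non-finite value at position {bad}")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise SpacingError("times must be strictly increasing")
        interval = self.sampling_interval
        if interval is None:
            interval = float(np.median(diffs))
            object.__setattr__(self, "sampling_interval", interval)
        if interval <= 0:
            raise SpacingError("sampling_interval must be positive")
        tol = _SPACING_RTOL * max(1.0, abs(interval))
        if np.max(np.abs(diffs - interval)) >= tol:
            raise SpacingError(
                f"non-uniform sampling: max deviation "
                f"{np.max(np.abs(diffs - interval)):.3g} from interval {interval:g}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        """New series on the same time axis with different values."""
        return replace(
            self, values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class ReplicatePanel:
    """Several replicate series sharing one time axis, plus mean ± SEM.

    ``sem`` uses the sample standard deviation (ddof=1) divided by sqrt(n),
    matching the "mean ± SEM of N independent samples" convention.
    """

    replicates: tuple[TimeSeries, ...]
    mean_series: TimeSeries = field(init=False)
    sem_series: TimeSeries = field(init=False)

    def __post_init__(self) -> None:
        if len(self.replicates) < 2:
            raise InsufficientDataError("a panel needs at least 2 replicates")
        t0 = self.replicates[0].times
        for rep in self.replicates[1:]:
            if len(rep.times) != len(t0) or np.max(np.abs(rep.times - t0)) > 0:
                raise AlignmentError("replicates must share identical times")
        mat = np.vstack([rep.values for rep in self.replicates])
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
        base = self.replicates[0]
        object.__setattr__(
            self, "mean_series", base.with_values(mean, label=f"{base.label} mean")
        )
        object.__setattr__(
            self, "sem_series", base.with_values(sem, label=f"{base.label} sem")
        )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def read_series_csv(
    path,
    time_column: str = "time",
    value_column: str = "value",
    replicate_column: str | None = None,
    time_unit: str = "sample",
    label: str = "",
):
    """Read a TimeSeries (or, with ``replicate_column``, a ReplicatePanel).

    The dialect is plain comma-separated UTF-8 with a header row. Rows are
    sorted by time; blank or non-numeric cells raise :class:`DataError`
    naming the offending row (1-based, excluding the header).
    """
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
    for col in filter(None, (time_column, value_column, replicate_column)):
        if col not in frame.columns:
            raise FormatError(f"missing column {col!r} in {path}")

    def _numeric(col: str) -> np.ndarray:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise DataError(
                f"missing or non-numeric {col!r} in row {int(bad[0]) + 1} of {path}"
            )
        return parsed.to_numpy(dtype=float)

    times = _numeric(time_column)
    values = _numeric(value_column)
    if replicate_column is None:
        order = np.argsort(times, kind="stable")
        return TimeSeries(times[order], values[order], time_unit=time_unit,
                          label=label or value_column)
    reps = []
    for rep_id, grp in frame.assign(_t=times, _v=values).groupby(
        replicate_column, sort=True
    ):
        grp = grp.sort_values("_t", kind="stable")
        reps.append(
            TimeSeries(
                grp["_t"].to_numpy(), grp["_v"].to_numpy(),
                time_unit=time_unit, label=f"{label or value_column}:{rep_id}",
            )
        )
    return ReplicatePanel(tuple(reps))


def write_series_csv(
    series,
    path,
    time_column: str = "time",
    value_column: str = "value",
    replicate_column: str = "replicate",
    float_format: str = "%.9g",
) -> None:
    """Write a TimeSeries or ReplicatePanel as CSV.

    The default format keeps 9 significant digits; pass ``"%.17g"`` for an
    exact binary round-trip.
    """
    if isinstance(series, ReplicatePanel):
        frames = []
        for i, rep in enumerate(series.replicates, start=1):
            frames.append(
                pd.DataFrame(
                    {time_column: rep.times, value_column: rep.values,
                     replicate_column: i}
                )
            )
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = pd.DataFrame(
            {time_column: series.times, value_column: series.values}
        )
    frame.to_csv(path, index=False, float_format=float_format)


def detrend_linear(series: TimeSeries) -> TimeSeries:
    """Residuals after an ordinary least-squares straight-line fit.

    Removes the slow drift (e.g. the saturating rise of %ARi / %Chex along
    incubation) so that periodicity detectors see the fluctuations only.
    Residual mean is zero to numerical precision; applying the operation
    twice is the same as applying it once.
    """
    if len(series) < 3:
        raise InsufficientDataError("detrend_linear needs at least 3 points")
    t = series.times - series.times.mean()  # centring keeps the fit well-posed
    slope, intercept = np.polyfit(t, series.values, 1)
    residuals = series.values - (slope * t + intercept)
    return series.with_values(residuals, label=f"{series.label} (detrended)")


class NetPercentage(NamedTuple):
    """Treated-minus-control percentage with a negative-net flag."""

    value: float
    is_negative: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def net_percentage(treated_pct: float, control_pct: float) -> NetPercentage:
    """Net indicator: treated minus control, in percentage points.

    This is the arithmetic behind both capacitation proxies: %ARi is the
    induced minus the spontaneous acrosome-reacted percentage, and %Chex is
    the recovery with minus without the progesterone attractant. Negative
    nets are preserved (clamping would bias time-course means) and flagged.
    """
    for name, v in (("treated_pct", treated_pct), ("control_pct", control_pct)):
        if not (0.0 <= v <= 100.0):
            raise DomainError(f"{name}={v} outside [0, 100]")
    diff = float(treated_pct) - float(control_pct)
    return NetPercentage(diff, diff < 0)


def q3_exceedance(reference_values: Sequence[float], test_values: Sequence[float]) -> float:
    """Percentage of ``test_values`` strictly above Q3 of ``reference_values``.

    Q3 is the linear-interpolation (type-7) third quartile, the default of
    mainstream numeric stacks; "exceeding" is read strictly, so ties at the
    quartile do not count. This is the flow-cytometry gating statistic:
    reference = non-capacitated fluorescence intensities, test = treated.
    """
    ref = np.asarray(reference_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.size == 0 or test.size == 0:
        raise DomainError("samples must be non-empty")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(test))):
        raise DataError("non-finite sample value")
    q3 = float(np.quantile(ref, 0.75))
    return 100.0 * float(np.mean(test > q3))


def threshold_fractions(
    samples: Sequence[float], cut_low: float, cut_high: float
) -> tuple[float, float, float]:
    """Percent of samples below, within and above a [cut_low, cut_high] band.

    Bins are [0, cut_low), [cut_low, cut_high], (cut_high, 100]; the three
    percentages sum to exactly 100 (the last is computed as the complement).
    Used to summarise how many semen samples fall in a given indicator range
    (e.g. <3 %, 3-10 %, >10 % ARi) at each incubation time.
    """
    vals = np.asarray(samples, dtype=float)
    if vals.size == 0:
        raise DomainError("samples must be non-empty")
    if not cut_low < cut_high:
        raise DomainError(f"cut_low={cut_low} must be < cut_high={cut_high}")
    n = vals.size
    below = 100.0 * np.count_nonzero(vals < cut_low) / n
    within = 100.0 * np.count_nonzero((vals >= cut_low) & (vals <= cut_high)) / n
    above = 100.0 - below - within
    return (below, within, above)
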