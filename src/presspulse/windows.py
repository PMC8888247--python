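"""Segmentation of perturbation cycles and response-window detection.

Each replicate's chlorophyll-a timeseries is divided into perturbation
cycles running from one pulse day to the next (the last cycle runs to the
series end).  Within a cycle three levels are extracted:

* the *pre-response condition* C0 — the mean of the least-variance moving
  window (at least 2 sampling points spanning at least 3 calendar days,
  inclusive) found before the response peak.  Because responses lag the
  pulse, the search may reach back into the tail of the previous cycle
  (by default from the midpoint between the previous peak and the pulse);
* the *peak* — the maximum observed value after the pulse day;
* the *post-event condition* — for interior cycles, identically the next
  cycle's pre-response condition (chaining); for the final cycle, the
  least-variance window in the last quarter of the cycle, flagged
  unrecovered when its variance exceeds a configurable multiple of the
  pre-response variance.

Windows are built on the available samples only; no smoothing or
imputation is applied before the variance scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore
        pass


@dataclass(frozen=True)
class PreResponseWindow:
    start_day: int
    end_day: int
    mean: float
    variance: float


@dataclass(frozen=True)
class ResponseWindow:
    """One cycle's pre-response, peak and post-event levels for one replicate."""

    cycle_id: int
    replicate_id: str
    treatment_label: str
    c0: float
    c0_window_start: int
    c0_window_end: int
    c0_variance: float
    peak_value: float
    peak_day: int
    dx_level: float
    dx_window_start: int
    dx_window_end: int
    recovered_flag: bool


def detect_pre_response(
    days: Sequence[int],
    values: Sequence[float],
    start: float | None = None,
    end: float | None = None,
    min_points: int = 2,
    min_span_days: int = 3,
) -> PreResponseWindow:
    """Least-variance moving window of samples within [start, end).

    Candidate windows are all contiguous runs of samples with at least
    ``min_points`` points whose inclusive calendar span
    (last day - first day + 1) is at least ``min_span_days``.  The window
    with the smallest unbiased sample variance wins; ties break to the
    earliest start day, then to the shortest window.
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    if days.shape != values.shape:
        raise ValueError("days and values must have equal length")
    order = np.argsort(days, kind="stable")
    days, values = days[order], values[order]
    mask = np.ones(len(days), dtype=bool)
    if start is not None:
        mask &= days >= start
    if end is not None:
        mask &= days < end
    d, v = days[mask], values[mask]
    if len(d) < min_points:
        raise ValueError(
            f"need at least {min_points} samples in the search interval, got {len(d)}"
        )

    best: tuple[float, int, int] | None = None  # (variance, start_day, n)
    best_window: PreResponseWindow | None = None
    n = len(d)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    csq = np.concatenate(([0.0], np.cumsum(v * v)))
    for i in range(n):
        for j in range(i + min_points - 1, n):
            if d[j] - d[i] + 1 < min_span_days:
                continue
            m = j - i + 1
            s, sq = csum[j + 1] - csum[i], csq[j + 1] - csq[i]
            var = max(0.0, (sq - s * s / m) / (m - 1))
            key = (var, int(d[i]), m)
            if best is None or key < best:
                best = key
                best_window = PreResponseWindow(
                    start_day=int(d[i]), end_day=int(d[j]),
                    mean=s / m, variance=var,
                )
    assert best_window is not None
    return best_window


def segment_cycles(
    days: Sequence[int],
    values: Sequence[float],
    pulse_days: Sequence[int],
    replicate_id: str = "",
    treatment_label: str = "",
    min_points: int = 2,
    min_span_days: int = 3,
    lookback_fraction: float = 0.5,
    final_quarter_fraction: float = 0.75,
    unrecovered_var_multiple: float = 5.0,
    stable_cv_floor: float = 0.02,
) -> list[ResponseWindow]:
    """Extract one :class:`ResponseWindow` per perturbation cycle.

    ``lookback_fraction`` places the start of cycle p's pre-response search
    between the previous cycle's peak and the pulse day (0 = at the
    previous peak, 1 = at the pulse).  The final cycle's post-event window
    is the least-variance window in the last ``1 - final_quarter_fraction``
    of the cycle; it is flagged unrecovered when its variance exceeds
    ``unrecovered_var_multiple`` times the pre-response variance and its
    coefficient of variation exceeds ``stable_cv_floor`` (the floor keeps
    near-noiseless plateaus from being flagged on vanishing variances).
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    order = np.argsort(days, kind="stable")
    days, values = days[order], values[order]
    pulse_days = sorted(pulse_days)
    if not pulse_days:
        raise ValueError("at least one pulse day is required")
    if pulse_days[0] < days[0] or pulse_days[-1] > days[-1]:
        raise ValueError("pulse_days must lie within the sampled span")

    edges = list(pulse_days) + [int(days[-1]) + 1]
    n_cycles = len(pulse_days)

    # peaks first: the pre-response search interval ends at the peak
    peaks: list[tuple[float, int]] = []
    for p in range(n_cycles):
        sel = (days > edges[p]) & (days < edges[p + 1] + (1 if p == n_cycles - 1 else 0))
        if not sel.any():
            raise ValueError(f"no samples after pulse day {edges[p]}")
        vals, dd = values[sel], days[sel]
        k = int(np.argmax(vals))
        peaks.append((float(vals[k]), int(dd[k])))

    # pre-response window per cycle, searched before that cycle's peak
    pre: list[PreResponseWindow] = []
    for p in range(n_cycles):
        peak_day = peaks[p][1]
        if p == 0:
            lo = days[0]
        else:
            prev_peak = peaks[p - 1][1]
            lo = prev_peak + lookback_fraction * (edges[p] - prev_peak)
        try:
            w = detect_pre_response(
                days, values, start=lo, end=peak_day,
                min_points=min_points, min_span_days=min_span_days,
            )
        except ValueError:
            # too few samples between lookback start and peak: widen to the
            # previous peak (or series start)
            lo = days[0] if p == 0 else peaks[p - 1][1]
            w = detect_pre_response(
                days, values, start=lo, end=peak_day,
                min_points=min_points, min_span_days=min_span_days,
            )
        pre.append(w)

    out: list[ResponseWindow] = []
    for p in range(n_cycles):
        c0w = pre[p]
        peak_value, peak_day = peaks[p]
        if p < n_cycles - 1:
            nxt = pre[p + 1]
            dx_level, dx_start, dx_end = nxt.mean, nxt.start_day, nxt.end_day
            recovered = nxt.start_day <= edges[p + 1]
        else:
            lo = edges[p] + final_quarter_fraction * (days[-1] - edges[p])
            try:
                fin = detect_pre_response(
                    days, values, start=lo, end=days[-1] + 1,
                    min_points=min_points, min_span_days=min_span_days,
                )
            except ValueError:
                lo = edges[p] + 0.5 * (days[-1] - edges[p])
                fin = detect_pre_response(
                    days, values, start=lo, end=days[-1] + 1,
                    min_points=min_points, min_span_days=min_span_days,
                )
            dx_level, dx_start, dx_end = fin.mean, fin.start_day, fin.end_day
            cv = np.sqrt(fin.variance) / fin.mean if fin.mean > 0 else np.inf
            recovered = (
                fin.variance <= unrecovered_var_multiple * c0w.variance
                or cv <= stable_cv_floor
            )
        out.append(
            ResponseWindow(
                cycle_id=p + 1,
                replicate_id=replicate_id,
                treatment_label=treatment_label,
                c0=c0w.mean,
                c0_window_start=c0w.start_day,
                c0_window_end=c0w.end_day,
                c0_variance=c0w.variance,
                peak_value=peak_value,
                peak_day=peak_day,
                dx_level=dx_level,
                dx_window_start=dx_start,
                dx_window_end=dx_end,
                recovered_flag=bool(recovered),
            )
        )
    return out


def windows_to_frame(windows: Iterable[ResponseWindow]) -> pd.DataFrame:
    return pd.DataFrame([w.__dict__ for w in windows])


def frame_to_windows(df: pd.DataFrame) -> list[ResponseWindow]:
    defaults = {
        "treatment_label": "", "c0_window_start": 0, "c0_window_end": 0,
        "c0_variance": 0.0, "peak_day": 0, "dx_window_start": 0,
        "dx_window_end": 0, "recovered_flag": True,
    }
    out = []
    for row in df.to_dict("records"):
        rec = {**defaults, **{k: v for k, v in row.items() if k in ResponseWindow.__dataclass_fields__}}
        out.append(ResponseWindow(**rec))
    return out


class CycleSegmenter(TransformerMixin, BaseEstimator):
    """Transformer from a tidy timeseries table to a response-windows table.

    Expects columns ``day``, ``replicate``, ``treatment`` and a response
    column (default ``chl_total``); emits one row per replicate x cycle.
    Stateless: ``fit`` validates, ``transform`` segments.
    """

    def __init__(
        self,
        pulse_days: Sequence[int] = (4, 40, 68),
        response_column: str = "chl_total",
        min_points: int = 2,
        min_span_days: int = 3,
        lookback_fraction: float = 0.5,
        final_quarter_fraction: float = 0.75,
        unrecovered_var_multiple: float = 5.0,
        stable_cv_floor: float = 0.02,
    ):
        self.pulse_days = pulse_days
        self.response_column = response_column
        self.min_points = min_points
        self.min_span_days = min_span_days
        self.lookback_fraction = lookback_fraction
        self.final_quarter_fraction = final_quarter_fraction
        self.unrecovered_var_multiple = unrecovered_var_multiple
        self.stable_cv_floor = stable_cv_floor

    def fit(self, X: pd.DataFrame, y=None) -> "CycleSegmenter":
        self._check(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        windows: list[ResponseWindow] = []
        for (trt, rep), grp in X.groupby(["treatment", "replicate"], sort=True):
            windows.extend(
                segment_cycles(
                    grp["day"].to_numpy(),
                    grp[self.response_column].to_numpy(),
                    self.pulse_days,
                    replicate_id=str(rep),
                    treatment_label=str(trt),
                    min_points=self.min_points,
                    min_span_days=self.min_span_days,
                    lookback_fraction=self.lookback_fraction,
                    final_quarter_fraction=self.final_quarter_fraction,
                    unrecovered_var_multiple=self.unrecovered_var_multiple,
                    stable_cv_floor=self.stable_cv_floor,
                )
            )
        return windows_to_frame(windows)

    def _check(self, X: pd.DataFrame) -> None:
        required = {"day", "replicate", "treatment", self.response_column}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"timeseries table missing columns: {sorted(missing)}")
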