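"""Displacement, resistance and recovery indices for pulse perturbations.

Following Orwin & Wardle-style proportional indices, one perturbation
cycle is summarised by three levels of the response variable (here total
chlorophyll-a): the pre-response condition C0, the response peak, and the
post-event condition.  From these,

    D0 = |peak - C0|              (maximum displacement, ug/L)
    Dx = |post-event - C0|        (residual displacement, ug/L)
    RS = 1 - 2*D0 / (C0 + D0)     (resistance, in (-1, 1])
    RC = 2*D0 / (D0 + Dx) - 1     (recovery,   in (-1, 1])

RS = 1 means the pulse left no mark; RS = 0 a 100% change relative to C0;
negative RS a more-than-100% change.  RC = 1 is full return to C0, RC = 0
no recovery (the system stays at the peak's displacement), negative RC a
drift beyond the displacement.  Both indices are dimensionless and
scale-invariant, so systems of different trophic state compare directly.

For reporting, both indices are mapped onto a 0-10 scale by strictly
increasing piecewise-linear maps anchored at RS: 1->10, 0->9, -1->0 and
RC: 1->10, 0->1, -1->0 (the low-resistance / high-recovery half of each
range is expanded).  The maps are injectable wherever they are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd

try:  # sklearn is used only for the estimator facade
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    BaseEstimator = object

    class TransformerMixin:  # type: ignore
        pass

from .design import ExperimentDesign
from .windows import ResponseWindow


@dataclass(frozen=True)
class PerturbationMetrics:
    """All indices for one replicate x cycle."""

    cycle_id: int
    replicate_id: str
    treatment_label: str
    pulse_intensity: float
    c0: float
    peak: float
    d0: float
    dx: float
    rs_raw: float
    rc_raw: float
    rs_scaled: float
    rc_scaled: float
    degenerate: bool = False  # undisplaced cycle (d0 = dx = 0)


def max_displacement(c0: float, peak: float) -> float:
    """Magnitude of the peak's departure from the pre-response condition."""
    if c0 < 0 or peak < 0:
        raise ValueError("c0 and peak must be non-negative")
    return abs(peak - c0)


def resistance(c0: float, d0: float) -> float:
    """RS = 1 - 2*D0/(C0 + D0); 1 iff D0 = 0, approaching -1 as D0 grows."""
    if c0 < 0 or d0 < 0:
        raise ValueError("c0 and d0 must be non-negative")
    if c0 + d0 == 0:
        raise ValueError("resistance undefined for c0 + d0 = 0")
    return 1.0 - 2.0 * d0 / (c0 + d0)


def recovery(d0: float, dx: float) -> float:
    """RC = 2*D0/(D0 + Dx) - 1; 1 iff Dx = 0, 0 iff Dx = D0, negative on drift.

    An undisplaced cycle (d0 = dx = 0) is defined as full recovery; callers
    needing to distinguish it should test the inputs (see compute_metrics,
    which flags it).
    """
    if d0 < 0 or dx < 0:
        raise ValueError("d0 and dx must be non-negative")
    if d0 + dx == 0:
        return 1.0
    return 2.0 * d0 / (d0 + dx) - 1.0


def rescale_resistance(rs_raw: float) -> float:
    """Map RS from [-1, 1] onto [0, 10]: 1->10, 0->9, -1->0, strictly increasing."""
    if not -1.0 <= rs_raw <= 1.0:
        raise ValueError(f"rs_raw outside [-1, 1]: {rs_raw!r}")
    if rs_raw >= 0:
        return 9.0 + rs_raw
    return 9.0 * (1.0 + rs_raw)


def rescale_recovery(rc_raw: float) -> float:
    """Map RC from [-1, 1] onto [0, 10]: 1->10, 0->1, -1->0, strictly increasing."""
    if not -1.0 <= rc_raw <= 1.0:
        raise ValueError(f"rc_raw outside [-1, 1]: {rc_raw!r}")
    if rc_raw >= 0:
        return 1.0 + 9.0 * rc_raw
    return 1.0 + rc_raw


def compute_metrics(
    windows: Iterable[ResponseWindow],
    design: ExperimentDesign,
    rescale_rs: Callable[[float], float] = rescale_resistance,
    rescale_rc: Callable[[float], float] = rescale_recovery,
) -> list[PerturbationMetrics]:
    """Evaluate all indices for each detected response window.

    ``pulse_intensity`` is attached from the design's pulse fractions;
    windows referring to a cycle the design does not define raise KeyError.
    """
    out: list[PerturbationMetrics] = []
    n_cycles = len(design.pulse_days)
    for w in windows:
        if not 1 <= w.cycle_id <= n_cycles:
            raise KeyError(
                f"window cycle {w.cycle_id} not in design (1..{n_cycles})"
            )
        intensity = design.pulse_fractions[w.cycle_id - 1]
        d0 = max_displacement(w.c0, w.peak_value)
        dx = abs(w.dx_level - w.c0)
        degenerate = d0 == 0 and dx == 0
        rs = resistance(w.c0, d0)
        rc = recovery(d0, dx)
        out.append(
            PerturbationMetrics(
                cycle_id=w.cycle_id,
                replicate_id=w.replicate_id,
                treatment_label=w.treatment_label,
                pulse_intensity=intensity,
                c0=w.c0,
                peak=w.peak_value,
                d0=d0,
                dx=dx,
                rs_raw=rs,
                rc_raw=rc,
                rs_scaled=rescale_rs(max(-1.0, min(1.0, rs))),
                rc_scaled=rescale_rc(max(-1.0, min(1.0, rc))),
                degenerate=degenerate,
            )
        )
    return out


def metrics_to_frame(metrics: Sequence[PerturbationMetrics]) -> pd.DataFrame:
    """Tidy table, one row per replicate x cycle."""
    return pd.DataFrame([m.__dict__ for m in metrics])


class PerturbationIndices(TransformerMixin, BaseEstimator):
    """Transformer from a windows table to a perturbation-metrics table.

    Operates on the tidy windows DataFrame produced by
    :class:`presspulse.windows.CycleSegmenter`.  Stateless: ``fit`` only
    validates; ``transform`` returns the metrics DataFrame.
    """

    def __init__(
        self,
        design: ExperimentDesign | None = None,
        rescale_rs: Callable[[float], float] = rescale_resistance,
        rescale_rc: Callable[[float], float] = rescale_recovery,
    ):
        self.design = design
        self.rescale_rs = rescale_rs
        self.rescale_rc = rescale_rc

    def fit(self, X: pd.DataFrame, y=None) -> "PerturbationIndices":
        self._check(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check(X)
        from .windows import frame_to_windows

        design = self.design or ExperimentDesign.default()
        metrics = compute_metrics(
            frame_to_windows(X), design, self.rescale_rs, self.rescale_rc
        )
        return metrics_to_frame(metrics)

    @staticmethod
    def _check(X: pd.DataFrame) -> None:
        required = {"cycle_id", "replicate_id", "c0", "peak_value", "dx_level"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"windows table missing columns: {sorted(missing)}")
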