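"""Dilution mass balance for nutrient dosing and N:P limitation bands.

A mesocosm of total volume V is rebuilt at each perturbation from three
water masses: what is left after sampling (volume ``vc`` at concentration
``cc_prev``), refill water (``vr``, ``cr``) and dosing stock (``vs``,
``cs``).  The post-dose total phosphorus is the volume-weighted mean

    TP = (cc_prev*vc + cr*vr + cs*vs) / (vc + vr + vs),

and the stock volume needed to reach a target TP follows by inverting the
same balance with the refill volume absorbing the slack so that
vc + vr + vs equals the mesocosm volume.

Dissolved-nutrient stoichiometry is classified against molar N:P bands:
above 25:1 phosphorus-limited, 16:1-25:1 co-limited (Redfield ratio at the
lower bound), below 16:1 nitrogen-limited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

N_ATOMIC_MASS = 14.007
P_ATOMIC_MASS = 30.974

P_LIMITED = "P-limited"
CO_LIMITED = "co-limited"
N_LIMITED = "N-limited"


class InfeasibleDoseError(ValueError):
    """Raised when no non-negative stock volume can reach the target TP."""


@dataclass(frozen=True)
class DosingStep:
    """One dilution step.  Volumes in L, concentrations in mg P/L."""

    cc_prev: float
    vc: float
    cr: float
    vr: float
    cs: float
    vs: float
    total_volume: float = 10.0

    def __post_init__(self) -> None:
        for name in ("cc_prev", "vc", "cr", "vr", "cs", "vs", "total_volume"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isclose(
            self.vc + self.vr + self.vs, self.total_volume, rel_tol=1e-9, abs_tol=1e-9
        ):
            raise ValueError(
                f"volumes must close: vc+vr+vs = {self.vc + self.vr + self.vs} "
                f"!= total_volume = {self.total_volume}"
            )


def predict_tp(step: DosingStep) -> float:
    """Post-dose TP (mg/L): total P mass divided by total volume."""
    total = step.vc + step.vr + step.vs
    if total <= 0:
        raise ValueError("total volume must be positive")
    return (step.cc_prev * step.vc + step.cr * step.vr + step.cs * step.vs) / total


def solve_dose_volume(
    target_tp: float,
    cc_prev: float,
    vc: float,
    cr: float,
    cs: float,
    total_volume: float = 10.0,
    vr: float | None = None,
) -> float:
    """Stock volume ``vs`` (L) that reaches ``target_tp`` after mixing.

    The refill volume absorbs the slack: vr = total_volume - vc - vs, so the
    planned ``vr`` (if given) only serves as a consistency hint and is not
    constrained.  Raises :class:`InfeasibleDoseError` when the target lies
    outside the reachable range [no-dose mixture, full-stock top-up].
    """
    for name, v in (("target_tp", target_tp), ("cc_prev", cc_prev), ("vc", vc),
                    ("cr", cr), ("cs", cs), ("total_volume", total_volume)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
    if vc > total_volume:
        raise ValueError("vc exceeds total_volume")

    slack = total_volume - vc
    lo = (cc_prev * vc + cr * slack) / total_volume      # vs = 0
    hi = (cc_prev * vc + cs * slack) / total_volume      # vs = slack
    lo, hi = min(lo, hi), max(lo, hi)
    if not lo - 1e-12 <= target_tp <= hi + 1e-12:
        raise InfeasibleDoseError(
            f"target {target_tp} mg/L outside reachable range "
            f"[{lo:.6g}, {hi:.6g}] for stock {cs} mg/L"
        )
    if math.isclose(cs, cr, rel_tol=0, abs_tol=0.0) or cs == cr:
        # any vs gives the same mixture; smallest dose wins
        return 0.0
    vs = (target_tp * total_volume - cc_prev * vc - cr * slack) / (cs - cr)
    return float(min(max(vs, 0.0), slack))


def completed_step(
    target_tp: float,
    cc_prev: float,
    vc: float,
    cr: float,
    cs: float,
    total_volume: float = 10.0,
) -> DosingStep:
    """Solve for vs and return the closed DosingStep (vr absorbs the slack)."""
    vs = solve_dose_volume(target_tp, cc_prev, vc, cr, cs, total_volume)
    return DosingStep(
        cc_prev=cc_prev, vc=vc, cr=cr, vr=total_volume - vc - vs,
        cs=cs, vs=vs, total_volume=total_volume,
    )


@dataclass(frozen=True)
class LimitationThresholds:
    """Molar N:P band edges; the closed band [lower, upper] is co-limitation."""

    lower: float = 16.0
    upper: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("thresholds must satisfy 0 < lower < upper")


def molar_np_ratio(din, dip):
    """Molar N:P from mass concentrations (ug N/L, ug P/L)."""
    din = np.asarray(din, dtype=float)
    dip = np.asarray(dip, dtype=float)
    if np.any(din <= 0) or np.any(dip <= 0):
        raise ValueError("din and dip must be positive")
    return (din / N_ATOMIC_MASS) / (dip / P_ATOMIC_MASS)


def classify_limitation(
    din: float, dip: float, thresholds: LimitationThresholds | None = None
) -> str:
    """Classify one sample's nutrient limitation from dissolved N and P."""
    thresholds = thresholds or LimitationThresholds()
    ratio = float(molar_np_ratio(din, dip))
    if ratio > thresholds.upper:
        return P_LIMITED
    if ratio < thresholds.lower:
        return N_LIMITED
    return CO_LIMITED


def classify_limitation_series(
    din, dip, thresholds: LimitationThresholds | None = None
) -> np.ndarray:
    """Vectorized limitation classes for paired DIN/DIP arrays."""
    thresholds = thresholds or LimitationThresholds()
    ratio = molar_np_ratio(din, dip)
    out = np.full(ratio.shape, CO_LIMITED, dtype=object)
    out[ratio > thresholds.upper] = P_LIMITED
    out[ratio < thresholds.lower] = N_LIMITED
    return out
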