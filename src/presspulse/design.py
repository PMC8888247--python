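"""Experiment design and simulation parameter containers.

The default design mirrors a 105-day press-pulse mesocosm experiment:
three treatments (a control and two phosphorus-enrichment levels) with six
replicate 10-L mesocosms each, sampled every other day, and three
H2O2-mortality pulse perturbations at days 4, 40 and 68 removing 50%, 15%
and 30% of the community respectively.  Enrichment treatments receive
stepwise K2HPO4 doses immediately after each pulse, ramping total
phosphorus toward a mid-strong (0.41 mg/L) or strong (0.82 mg/L) endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Treatment:
    """One press-perturbation arm.

    ``tp_targets`` lists the total-phosphorus concentration (mg P/L) the
    mesocosm is dosed toward at each pulse day; an empty tuple means the
    arm is never dosed (control).
    """

    label: str
    tp_targets: tuple[float, ...] = ()

    @property
    def enriched(self) -> bool:
        return len(self.tp_targets) > 0


@dataclass(frozen=True)
class ExperimentDesign:
    """Schedule and physical configuration of a press-pulse experiment."""

    treatments: tuple[Treatment, ...]
    n_replicates: int = 6
    duration_days: int = 105
    sampling_interval_days: int = 2
    pulse_days: tuple[int, ...] = (4, 40, 68)
    pulse_fractions: tuple[float, ...] = (0.50, 0.15, 0.30)
    mesocosm_volume: float = 10.0          # L
    refill_tp: float = 0.012               # mg P/L, control-like refill water
    stock_tp: float = 40.0                 # mg P/L, dosing stock (stand-in)
    sample_loss_volume: float = 0.07       # L withdrawn per sampling

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.sampling_interval_days < 1:
            raise ValueError("sampling_interval_days must be >= 1")
        if len(self.pulse_fractions) != len(self.pulse_days):
            raise ValueError(
                "pulse_fractions and pulse_days must have equal length"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.pulse_fractions):
            raise ValueError("pulse_fractions must lie in [0, 1]")
        if list(self.pulse_days) != sorted(set(self.pulse_days)):
            raise ValueError("pulse_days must be strictly increasing")
        if self.pulse_days and not (
            0 <= self.pulse_days[0] and self.pulse_days[-1] < self.duration_days
        ):
            raise ValueError("pulse_days must lie within the experiment span")
        if self.mesocosm_volume <= 0:
            raise ValueError("mesocosm_volume must be positive")
        for trt in self.treatments:
            if trt.tp_targets and len(trt.tp_targets) != len(self.pulse_days):
                raise ValueError(
                    f"treatment {trt.label!r}: tp_targets must match pulse count"
                )

    @property
    def sampling_days(self) -> tuple[int, ...]:
        return tuple(range(0, self.duration_days, self.sampling_interval_days))

    @property
    def n_mesocosms(self) -> int:
        return self.n_replicates * len(self.treatments)

    def cycle_bounds(self) -> list[tuple[int, int]]:
        """[pulse_day, next_pulse_day) intervals; last cycle runs to the end."""
        edges = list(self.pulse_days) + [self.duration_days]
        return [(edges[i], edges[i + 1]) for i in range(len(self.pulse_days))]

    def replicate_ids(self) -> list[tuple[str, str]]:
        """(treatment_label, replicate_id) pairs, replicate ids unique overall."""
        out = []
        for trt in self.treatments:
            for r in range(1, self.n_replicates + 1):
                out.append((trt.label, f"{trt.label}_{r}"))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = [asdict(t) for t in self.treatments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        d = dict(d)
        d["treatments"] = tuple(
            Treatment(label=t["label"], tp_targets=tuple(t.get("tp_targets", ())))
            for t in d["treatments"]
        )
        for key in ("pulse_days", "pulse_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def default(cls) -> "ExperimentDesign":
        """The 3 x 6 design: control, mid-strong (0.41) and strong (0.82 mg/L)."""
        return cls(
            treatments=(
                Treatment("control"),
                Treatment("mid", tp_targets=(0.137, 0.273, 0.41)),
                Treatment("strong", tp_targets=(0.273, 0.547, 0.82)),
            )
        )


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic mesocosm generator.

    Rates are per day; concentrations are per litre. ``chl_yield`` links the
    chlorophyll-a and phosphorus ledgers (ug Chl-a fixable per ug dissolved
    P), ``base_K`` is the pre-enrichment carrying capacity in Chl-a units.
    ``hardening_per_cycle`` (< 1) damps the bloom response after each
    completed pulse; ``recovery_loss_per_cycle`` raises, cycle by cycle, the
    fraction of each displacement that is retained as a new, higher
    baseline; ``eutro_displacement_multiplier`` is the saturated carrying-
    capacity multiplier that enrichment confers, scaling both baselines and
    bloom amplitudes of enriched treatments.
    """

    growth_rate: float = 1.0
    chl_yield: float = 3.0
    base_K: float = 2.0
    remineralization_rate: float = 0.1
    noise_cv: float = 0.1
    hardening_per_cycle: float = 0.3
    recovery_loss_per_cycle: float = 0.15
    eutro_displacement_multiplier: float = 2.0
    seed: int = 0
    # response shaping
    response_gain: float = 35.0           # bloom amplitude per unit pre-pulse capacity
    response_decay_rate: float = 0.18     # per-day decay of the bloom boost
    intensity_exponent: float = 0.25      # bloom ~ pulse_fraction ** exponent
    capacity_lag_days: float = 12.0       # delay before enrichment raises capacity
    capacity_ramp_width: float = 2.5      # days; steepness of the capacity sigmoid
    capacity_tp_sat: float = 0.1          # mg/L TP at which capacity gain saturates
    # nutrient observation layer
    initial_po4: float = 70.0             # ug P/L dissolved at start
    initial_din: float = 800.0            # ug N/L dissolved at start
    n_quota: float = 2.4                  # ug N per ug Chl-a in biomass
    luxury_uptake_rate: float = 0.25      # per-day sequestration of surplus PO4
    # observation constants
    biovolume_per_chl: float = 2.0e5      # um^3/ml per ug Chl-a/L
    replicate_cv: float = 0.03            # lognormal spread of replicate baselines
    dt: float = 0.5                       # integrator substep, days

    def __post_init__(self) -> None:
        nonneg = (
            "growth_rate", "base_K", "remineralization_rate", "noise_cv",
            "hardening_per_cycle", "recovery_loss_per_cycle",
            "response_gain", "response_decay_rate", "capacity_lag_days",
            "initial_po4", "initial_din", "n_quota", "luxury_uptake_rate",
            "biovolume_per_chl", "replicate_cv",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.chl_yield) or self.chl_yield <= 0:
            raise ValueError("chl_yield must be finite and > 0")
        if self.eutro_displacement_multiplier < 0 or not math.isfinite(
            self.eutro_displacement_multiplier
        ):
            raise ValueError("eutro_displacement_multiplier must be finite and >= 0")
        if not 0 < self.dt <= 1:
            raise ValueError("dt must lie in (0, 1]")
        if self.capacity_ramp_width <= 0:
            raise ValueError("capacity_ramp_width must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)
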