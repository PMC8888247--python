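"""Synthetic mesocosm generator for press-pulse perturbation experiments.

The generator reproduces the statistical structure the downstream analysis
assumes: stepwise phosphorus enrichment (press), instantaneous fractional
mortality events with nutrient turnover (pulses), transient chlorophyll-a
blooms after each pulse, baselines that ratchet upward across cycles
(incomplete recovery), bloom responses that damp with each completed pulse
(hardening), and enriched treatments whose baselines *and* bloom
amplitudes are scaled by a common carrying-capacity multiplier — so that
absolute displacement grows with enrichment while the proportional
resistance index does not.

Mechanics, per mesocosm
-----------------------
State tracks chlorophyll-a biomass ``chl`` and a phosphorus ledger in
ug P/L — dissolved ``po4``, dead-organic ``dead_p`` (remineralizing),
sequestered ``seq_p`` (refractory) — plus dissolved inorganic nitrogen.
Biomass growth follows the exact discrete logistic map toward a
time-varying target capacity

    K(t) = min( kappa(t) * G + boost(t),  chl + chl_yield * po4 ),

where ``G`` is the ratcheting baseline capacity, ``kappa`` rises from 1
toward ``eutro_displacement_multiplier`` along a lagged sigmoid once
dosing raises total P past a small saturation level (capacity saturates
quickly in TP — nitrogen and light, not phosphorus, cap the bloom ceiling
in enriched systems — and the community restructuring that realises the
higher capacity takes about two weeks), and
``boost`` is the decaying bloom drive injected by each pulse.  All biomass
increments draw phosphorus from the dissolved pool and all decrements
return it to the dead pool, so in a closed configuration (no dosing, no
refill) total phosphorus is conserved exactly.

A pulse with volume fraction f kills f of the biomass (moved to the dead
pool), then triggers a bloom boost

    D_p = response_gain * hardening^(completed pulses) * f^(1/4) * kappa * G,

and ratchets the baseline G upward by ``min(1, recovery_loss_per_cycle * p)``
of D_p — the imposed loss of recovery.  Enrichment doses are applied just
after the pulse through the dilution mass balance of
:mod:`presspulse.dosing`, with refill water compensating sampling losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ExperimentDesign, SimulationParams, Treatment
from .dosing import solve_dose_volume

OBS_COLUMNS = [
    "treatment", "replicate", "day", "chl_total",
    "chl_cyano", "chl_green", "chl_diatom",
    "po4", "din", "biovolume",
]


@dataclass
class MesocosmState:
    """Internal compartments of one mesocosm (per-litre units)."""

    chl: float                  # ug Chl-a/L
    po4: float                  # ug P/L dissolved
    dead_p: float               # ug P/L dead organic, remineralizing
    seq_p: float = 0.0          # ug P/L sequestered (refractory)
    din: float = 400.0          # ug N/L dissolved
    dead_n: float = 0.0         # ug N/L dead organic
    chl_yield: float = 1.0      # ug Chl-a per ug P
    n_quota: float = 7.2        # ug N per ug Chl-a
    baseline: float = 2.0       # G: ratcheting equilibrium capacity, chl units
    capacity_mult: float = 1.0  # kappa: current press capacity multiplier
    capacity_target: float = 1.0
    first_dose_time: float | None = None
    time: float = 0.0           # days since experiment start
    boost: float = 0.0          # decaying bloom drive, chl units
    pulses_done: int = 0

    def total_p(self) -> float:
        """Total phosphorus across all compartments (ug P/L)."""
        return self.po4 + self.chl / self.chl_yield + self.dead_p + self.seq_p


def apply_pulse(state: MesocosmState, fraction: float) -> MesocosmState:
    """Instantaneous fractional mortality of the whole community.

    Biomass is reduced by exactly ``fraction``; the killed biomass'
    phosphorus and nitrogen move to the dead-organic pools; dissolved
    nutrients are unchanged at the pulse instant.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction!r}")
    killed = fraction * state.chl
    return replace(
        state,
        chl=state.chl - killed,
        dead_p=state.dead_p + killed / state.chl_yield,
        dead_n=state.dead_n + killed * state.n_quota,
    )


def _advance(state: MesocosmState, params: SimulationParams, days: float,
             po4_ref: float) -> None:
    """Integrate the compartment dynamics forward by ``days`` (in place)."""
    dt = params.dt
    n_steps = max(1, round(days / dt))
    dt = days / n_steps
    y = state.chl_yield
    for _ in range(n_steps):
        # remineralization of dead organic matter
        frac = 1.0 - math.exp(-params.remineralization_rate * dt)
        rel_p, rel_n = state.dead_p * frac, state.dead_n * frac
        state.dead_p -= rel_p
        state.po4 += rel_p
        state.dead_n -= rel_n
        state.din += rel_n
        # sequestration of dosed-surplus phosphate toward the ambient level
        surplus = state.po4 - po4_ref
        if surplus > 0 and params.luxury_uptake_rate > 0:
            lux = surplus * (1.0 - math.exp(-params.luxury_uptake_rate * dt))
            state.po4 -= lux
            state.seq_p += lux
        # logistic growth toward the current target capacity
        k_press = state.capacity_mult * state.baseline + state.boost
        k_quota = state.chl + y * state.po4
        k = max(min(k_press, k_quota), 1e-12)
        b = state.chl
        if b > 0 and params.growth_rate > 0:
            g = math.exp(params.growth_rate * dt)
            b_new = k * b * g / (k + b * (g - 1.0))
            delta = b_new - b
            if delta > 0:
                delta = min(delta, y * state.po4, state.din / state.n_quota)
                state.po4 -= delta / y
                state.din -= delta * state.n_quota
            else:
                state.dead_p += -delta / y
                state.dead_n += -delta * state.n_quota
            state.chl = b + delta
        # bloom drive decay and lagged press-capacity ramp
        state.boost *= math.exp(-params.response_decay_rate * dt)
        state.time += dt
        if state.first_dose_time is not None:
            z = (state.time - state.first_dose_time - params.capacity_lag_days)
            sig = 1.0 / (1.0 + math.exp(-z / params.capacity_ramp_width))
            state.capacity_mult = 1.0 + (state.capacity_target - 1.0) * sig


def _dose_and_refill(
    state: MesocosmState,
    treatment: Treatment,
    design: ExperimentDesign,
    pulse_index: int,
    refill_volume: float,
    refill_din: float,
) -> None:
    """Apply the refill/dosing dilution step of one perturbation (in place)."""
    total = design.mesocosm_volume
    vr_loss = min(refill_volume, total)
    vc = total - vr_loss
    if treatment.enriched:
        target = treatment.tp_targets[pulse_index]
        tp_cur = state.total_p() / 1000.0  # ug/L -> mg/L
        vs = solve_dose_volume(
            target, cc_prev=tp_cur, vc=vc, cr=design.refill_tp,
            cs=design.stock_tp, total_volume=total,
        )
    else:
        vs = 0.0
    vr = total - vc - vs
    if vr_loss <= 0 and vs <= 0:
        return  # closed configuration: nothing exchanged
    d = vc / total
    for attr in ("chl", "po4", "dead_p", "seq_p", "din", "dead_n"):
        setattr(state, attr, getattr(state, attr) * d)
    state.po4 += design.refill_tp * 1000.0 * vr / total
    state.din += refill_din * vr / total
    state.po4 += design.stock_tp * 1000.0 * vs / total


def _capacity_saturation(tp_now: float, tp0: float, tp_sat: float) -> float:
    """Fraction of the enrichment capacity gain realised at total P ``tp_now``."""
    if tp_sat <= tp0:
        return 1.0 if tp_now > tp0 else 0.0
    return min(1.0, max(0.0, (tp_now - tp0) / (tp_sat - tp0)))


def _shares(sat: float) -> tuple[float, float, float]:
    """Cyano/green/diatom chlorophyll shares; cyanobacteria gain with enrichment."""
    w = np.array([0.4 + 2.2 * sat, 1.0, 0.8])
    w /= w.sum()
    return float(w[0]), float(w[1]), float(w[2])


def simulate_experiment(
    design: ExperimentDesign,
    params: SimulationParams,
    initial_chl: float | None = None,
) -> pd.DataFrame:
    """Simulate all mesocosms of a design; tidy frame, one row per replicate x day.

    Identical (design, params) are bit-reproducible.  ``initial_chl``
    overrides the starting biomass (defaults to the baseline capacity, i.e.
    equilibrium start).
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(design.n_mesocosms)
    sigma = math.sqrt(math.log(1.0 + params.noise_cv ** 2))
    rep_sigma = math.sqrt(math.log(1.0 + params.replicate_cv ** 2))
    sampling_days = set(design.sampling_days)
    pulse_lookup = {d: i for i, d in enumerate(design.pulse_days)}

    rows: list[tuple] = []
    idx = 0
    for trt in design.treatments:
        for r in range(1, design.n_replicates + 1):
            rng = np.random.default_rng(children[idx])
            idx += 1
            rep_id = f"{trt.label}_{r}"
            scale = rng.lognormal(mean=-rep_sigma ** 2 / 2, sigma=rep_sigma)
            g0 = params.base_K * scale
            state = MesocosmState(
                chl=(initial_chl if initial_chl is not None else g0),
                po4=params.initial_po4 * scale,
                dead_p=0.0,
                din=params.initial_din * scale,
                chl_yield=params.chl_yield,
                n_quota=params.n_quota,
                baseline=g0,
            )
            tp0 = state.total_p() / 1000.0
            po4_ref = state.po4
            samples_since_pulse = 0

            def lognoise() -> float:
                return float(rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma))

            for day in range(design.duration_days):
                if day in sampling_days:
                    samples_since_pulse += 1
                    chl_obs = state.chl * lognoise()
                    po4_obs = state.po4 * lognoise()
                    din_obs = state.din * lognoise()
                    bv_obs = params.biovolume_per_chl * state.chl * lognoise()
                    sat = _capacity_saturation(
                        state.total_p() / 1000.0, tp0, params.capacity_tp_sat
                    )
                    s_cy, s_gr, _ = _shares(sat)
                    chl_cy = s_cy * chl_obs
                    chl_gr = s_gr * chl_obs
                    rows.append((
                        trt.label, rep_id, day, chl_obs,
                        chl_cy, chl_gr, chl_obs - chl_cy - chl_gr,
                        po4_obs, din_obs, bv_obs,
                    ))
                if day in pulse_lookup:
                    p = pulse_lookup[day]
                    f = design.pulse_fractions[p]
                    if f > 0:
                        state = apply_pulse(state, f)
                    _dose_and_refill(
                        state, trt, design, p,
                        refill_volume=design.sample_loss_volume * samples_since_pulse,
                        refill_din=params.initial_din,
                    )
                    samples_since_pulse = 0
                    if trt.enriched:
                        sat = _capacity_saturation(
                            state.total_p() / 1000.0, tp0, params.capacity_tp_sat
                        )
                        state.capacity_target = 1.0 + (
                            params.eutro_displacement_multiplier - 1.0
                        ) * sat
                        if state.first_dose_time is None and sat > 0:
                            state.first_dose_time = float(day)
                    if f > 0:
                        amplitude = (
                            params.response_gain
                            * params.hardening_per_cycle ** state.pulses_done
                            * f ** params.intensity_exponent
                            * state.capacity_mult * state.baseline
                        )
                        state.boost += amplitude
                        retained = min(
                            1.0,
                            params.recovery_loss_per_cycle * (state.pulses_done + 1),
                        )
                        state.baseline += retained * amplitude / state.capacity_mult
                    state.pulses_done += 1
                _advance(state, params, 1.0, po4_ref)

    df = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return df
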