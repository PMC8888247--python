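"""Synthetic mesocosm generator: dynamics, pulses, conservation, determinism."""

import math

import numpy as np
import pytest

from presspulse.design import ExperimentDesign, SimulationParams, Treatment
from presspulse.metrics import PerturbationIndices
from presspulse.simulate import (
    MesocosmState, apply_pulse, simulate_experiment, _advance,
)
from presspulse.windows import CycleSegmenter


def _noiseless(**kw):
    kw.setdefault("noise_cv", 0.0)
    kw.setdefault("replicate_cv", 0.0)
    return SimulationParams(seed=0, **kw)


class TestApplyPulse:
    def test_zero_fraction_is_identity(self):
        st = MesocosmState(chl=10.0, po4=5.0, dead_p=1.0)
        assert apply_pulse(st, 0.0) == st

    def test_full_mortality_moves_all_biomass_phosphorus(self):
        st = MesocosmState(chl=10.0, po4=5.0, dead_p=0.0, chl_yield=2.0)
        out = apply_pulse(st, 1.0)
        assert out.chl == 0.0
        assert out.dead_p == pytest.approx(5.0)  # 10 ug chl / 2 ug-chl-per-ug-P
        assert out.po4 == st.po4  # dissolved untouched at the pulse instant

    def test_partial_mortality_arithmetic(self):
        st = MesocosmState(chl=10.0, po4=5.0, dead_p=2.0, chl_yield=1.0)
        out = apply_pulse(st, 0.3)
        assert out.chl == pytest.approx(7.0)
        assert out.dead_p == pytest.approx(2.0 + 3.0)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, math.nan])
    def test_fraction_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_pulse(MesocosmState(chl=1.0, po4=1.0, dead_p=0.0), bad)


class TestDynamicsLimits:
    def test_pulse_free_noise_free_run_follows_logistic_closed_form(self):
        design = ExperimentDesign(
            treatments=(Treatment("control"),), n_replicates=1,
            pulse_days=(), pulse_fractions=(), sample_loss_volume=0.0,
        )
        params = _noiseless(base_K=10.0, initial_po4=100.0, luxury_uptake_rate=0.0)
        ts = simulate_experiment(design, params, initial_chl=1.0)
        t = ts["day"].to_numpy(float)
        K, r, b0 = 10.0, params.growth_rate, 1.0
        expected = K * b0 * np.exp(r * t) / (K + b0 * (np.exp(r * t) - 1.0))
        np.testing.assert_allclose(ts["chl_total"].to_numpy(), expected, rtol=1e-9)

    def test_pure_mortality_halves_biomass_at_the_pulse(self):
        design = ExperimentDesign(
            treatments=(Treatment("control"),), n_replicates=1,
            pulse_days=(4,), pulse_fractions=(0.5,), sample_loss_volume=0.0,
        )
        params = _noiseless(growth_rate=0.0, remineralization_rate=0.0)
        ts = simulate_experiment(design, params).set_index("day")
        assert ts.loc[6, "chl_total"] == pytest.approx(0.5 * ts.loc[4, "chl_total"])

    def test_closed_system_conserves_total_phosphorus(self, closed_design):
        """Oracle: sum the dissolved/biomass/dead/sequestered P compartments
        at every step of a pulsed but undosed, unrefilled run."""
        params = _noiseless()
        st = MesocosmState(
            chl=params.base_K, po4=params.initial_po4, dead_p=0.0,
            din=params.initial_din, chl_yield=params.chl_yield,
            n_quota=params.n_quota, baseline=params.base_K,
        )
        total0 = st.total_p()
        fractions = dict(zip(closed_design.pulse_days, closed_design.pulse_fractions))
        for day in range(closed_design.duration_days):
            if day in fractions:
                st = apply_pulse(st, fractions[day])
            _advance(st, params, 1.0, po4_ref=params.initial_po4)
            assert st.total_p() == pytest.approx(total0, rel=1e-9)


class TestExperimentStructure:
    def test_one_timeseries_per_replicate_at_sampling_cadence(
        self, ref_design, sim_timeseries
    ):
        assert len(sim_timeseries) == 18 * 53
        counts = sim_timeseries.groupby(["treatment", "replicate"])["day"].count()
        assert (counts == 53).all()
        days = sim_timeseries["day"].unique()
        assert days.min() == 0 and days.max() == 104 and len(days) == 53

    def test_all_concentrations_non_negative(self, sim_timeseries):
        cols = ["chl_total", "chl_cyano", "chl_green", "chl_diatom",
                "po4", "din", "biovolume"]
        assert (sim_timeseries[cols] >= 0).all().all()

    def test_group_fractions_sum_to_total(self, sim_timeseries):
        total = (sim_timeseries["chl_cyano"] + sim_timeseries["chl_green"]
                 + sim_timeseries["chl_diatom"])
        np.testing.assert_allclose(total, sim_timeseries["chl_total"], rtol=1e-12)

    def test_identical_seed_bit_reproducible(self, ref_design):
        a = simulate_experiment(ref_design, SimulationParams(seed=11))
        b = simulate_experiment(ref_design, SimulationParams(seed=11))
        assert a.equals(b)

    def test_different_seeds_differ(self, ref_design):
        a = simulate_experiment(ref_design, SimulationParams(seed=11))
        b = simulate_experiment(ref_design, SimulationParams(seed=12))
        assert not a.equals(b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(growth_rate=-1.0)
        with pytest.raises(ValueError):
            SimulationParams(chl_yield=0.0)
        with pytest.raises(ValueError):
            SimulationParams(noise_cv=math.inf)


class TestScenarioStructure:
    def test_raising_displacement_multiplier_raises_enriched_peaks_only(
        self, ref_design
    ):
        def windows(mult):
            ts = simulate_experiment(
                ref_design, _noiseless(eutro_displacement_multiplier=mult)
            )
            seg = CycleSegmenter(pulse_days=ref_design.pulse_days)
            return seg.fit(ts).transform(ts)

        lo, hi = windows(2.0), windows(2.5)
        merged = lo.merge(hi, on=["replicate_id", "cycle_id"], suffixes=("_lo", "_hi"))
        enriched = merged[merged["treatment_label_lo"] != "control"]
        control = merged[merged["treatment_label_lo"] == "control"]
        assert (enriched["peak_value_hi"] >= enriched["peak_value_lo"] - 1e-9).all()
        np.testing.assert_allclose(
            control["peak_value_lo"], control["peak_value_hi"], rtol=1e-12
        )

    def test_emulated_study_conditions(self, ref_design):
        """Rising baselines, increasing resistance, and recovery loss within
        each arm across the three cycles (noise off)."""
        small = ExperimentDesign(treatments=ref_design.treatments, n_replicates=1)
        ts = simulate_experiment(small, _noiseless())
        seg = CycleSegmenter(pulse_days=small.pulse_days)
        win = seg.fit(ts).transform(ts)
        met = PerturbationIndices(design=small).fit(win).transform(win)
        for _, grp in met.groupby("treatment_label"):
            grp = grp.sort_values("cycle_id")
            assert grp["c0"].is_monotonic_increasing        # baselines ratchet up
            assert grp["rs_scaled"].is_monotonic_increasing  # hardening
        control = met[met["treatment_label"] == "control"].sort_values("cycle_id")
        assert control["rc_scaled"].is_monotonic_decreasing  # recovery loss
        # enriched absolute displacement ~2x control once the press is realised
        wide = met.pivot_table(index="cycle_id", columns="treatment_label",
                               values="d0")
        late = wide.loc[[2, 3]]
        ratio = (late[["mid", "strong"]].mean(axis=1) / late["control"])
        assert ((ratio > 1.6) & (ratio < 2.4)).all()
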