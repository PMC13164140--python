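"""Batch-reactor integration: ideal-gas initial state, mass-action rates,
stiff trajectories and their conservation/monotonicity structure."""

import numpy as np
import pytest

from lipoxkin import (
    IntegrationError,
    ReactorConditions,
    conservation_laws,
    initial_state,
    rate_of_progress_ranking,
    simulate,
    species_rates,
)
from lipoxkin.reactor import R_GAS_CM3_ATM

T12 = 43_200.0


class TestInitialState:
    def test_total_concentration_ideal_gas(self, mech):
        cond = ReactorConditions(T=363.15)
        c0 = initial_state(mech, cond)
        # oracle: direct ideal-gas evaluation
        assert c0.sum() == pytest.approx(1.0 / (R_GAS_CM3_ATM * 363.15), rel=1e-12)
        assert c0.sum() == pytest.approx(3.356e-5, rel=1e-3)

    def test_fractions_preserved(self, mech):
        c0 = initial_state(mech, ReactorConditions(T=363.15))
        assert c0[mech.species_index("LINOLEIC")] / c0.sum() == pytest.approx(0.010)

    def test_ideal_gas_scaling_with_temperature(self, mech):
        c1 = initial_state(mech, ReactorConditions(T=300.0))
        c2 = initial_state(mech, ReactorConditions(T=600.0))
        assert np.allclose(c2, c1 / 2.0)

    def test_unnormalized_composition_rejected(self, mech):
        from lipoxkin import Mechanism, MechanismError, SpeciesDef

        bad = Mechanism(
            species=[SpeciesDef("A", "inert", 0.5), SpeciesDef("B", "inert", 0.4)],
            reactions=[],
        )
        with pytest.raises(MechanismError):
            initial_state(bad, ReactorConditions(T=300.0))


class TestSpeciesRates:
    def test_only_initiation_active_at_start(self, mech):
        c0 = initial_state(mech, ReactorConditions(T=323.15))
        k = mech.rate_constants(323.15)
        dc = species_rates(mech, c0, 323.15)
        i_lin, i_o2 = mech.species_index("LINOLEIC"), mech.species_index("O2")
        q1 = k[0] * c0[i_lin] * c0[i_o2]
        # with all radicals zero, dc/dt is the initiation column times q1
        assert np.allclose(dc, mech.stoich_matrix[:, 0] * q1)

    def test_initial_initiation_rate_magnitude(self, mech):
        # hand evaluation of k1*c_LIN*c_O2 at 323.15 K
        c0 = initial_state(mech, ReactorConditions(T=323.15))
        k1 = mech.rate_constants(323.15)[0]
        q1 = k1 * c0[mech.species_index("LINOLEIC")] * c0[mech.species_index("O2")]
        assert q1 == pytest.approx(8.0e-16, rel=0.05)

    def test_conservation_vectors_annihilate_rates(self, mech, rng):
        c = np.abs(rng.normal(1e-6, 1e-6, size=len(mech.species)))
        dc = species_rates(mech, c, 350.0)
        for w in conservation_laws(mech):
            assert abs(float(w @ dc)) <= 1e-12 * np.abs(dc).max()


class TestSimulate:
    @pytest.mark.parametrize(
        "celsius,species,expected",
        [
            (50.0, "ROOH", 1.84e-5),
            (50.0, "HEXANAL", 8.21e-11),
            (90.0, "LINOLEIC", 0.008183),
        ],
    )
    def test_published_endpoint_fractions(self, all_trajs, celsius, species, expected):
        traj = all_trajs[celsius]
        assert traj.species_fraction(species, T12) == pytest.approx(expected, rel=0.02)

    def test_zero_duration_returns_initial_composition(self, mech):
        traj = simulate(mech, ReactorConditions(T=363.15, t_end=0.0))
        assert traj.times.tolist() == [0.0]
        assert np.allclose(traj.mole_fractions[0], mech.initial_mole_fractions)

    def test_mole_fractions_sum_to_one(self, all_trajs):
        for traj in all_trajs.values():
            sums = traj.mole_fractions.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_conservation_laws_hold_along_trajectory(self, mech, all_trajs):
        laws = conservation_laws(mech)
        for traj in all_trajs.values():
            for w in laws:
                series = traj.concentrations @ w
                scale = np.abs(traj.concentrations).max()
                assert np.abs(series - series[0]).max() <= 1e-8 * scale

    def test_monotone_species(self, all_trajs):
        for traj in all_trajs.values():
            x = traj.mole_fractions
            idx = traj.mechanism.species_index
            eps = 1e-15
            assert (np.diff(x[:, idx("O2")]) <= eps).all()
            assert (np.diff(x[:, idx("LYCOPENE")]) <= eps).all()
            for name in ("HEXANAL", "FRAG12", "HO2", "LYCORAD"):
                assert (np.diff(x[:, idx(name)]) >= -eps).all()

    def test_hexanal_equals_frag12(self, all_trajs):
        for traj in all_trajs.values():
            hexanal = traj.species_fraction("HEXANAL")
            frag = traj.species_fraction("FRAG12")
            assert np.allclose(hexanal, frag, rtol=1e-9, atol=1e-30)

    def test_peroxyl_quasi_steady_state_at_90C(self, traj90):
        """ROO plateaus within the first hour; LYCORAD keeps growing."""
        roo = traj90.species_fraction("ROO")
        times = traj90.times
        hours = np.arange(1, 12) * 3600.0
        values = np.interp(hours, times, roo)
        rel_change_per_h = np.abs(np.diff(values)) / values[:-1]
        assert (rel_change_per_h < 0.05).all()
        lycorad = traj90.species_fraction("LYCORAD")
        assert (np.diff(np.interp(hours, times, lycorad)) > 0).all()

    def test_tolerance_robustness(self, mech, traj90):
        tight = simulate(
            mech, ReactorConditions.from_celsius(90.0, t_end=T12), rtol=1e-11
        )
        for sp in ("LINOLEIC", "HEXANAL", "LYCOPENE", "ROOH"):
            a = traj90.species_fraction(sp, T12)
            b = tight.species_fraction(sp, T12)
            assert abs(a - b) / abs(b) < 1e-3

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_integration_error_carries_failing_time(self, mech):
        with pytest.raises(IntegrationError):
            # absurdly large magnitude forces solver failure via overflow
            bad = mech.replace_kinetics(
                0, type(mech.reactions[0].kinetics)(1e200, 0.0, 0.0)
            )
            simulate(bad, ReactorConditions(T=363.15, t_end=T12))


class TestRateOfProgress:
    def test_oxygen_addition_is_fastest(self, all_trajs):
        for traj in all_trajs.values():
            j, label, _ = rate_of_progress_ranking(traj)[0]
            assert set(traj.mechanism.reactions[j].reactants) == {"LINRAD", "O2"}

    def test_zero_radical_steps_silent_at_t0(self, traj90):
        q0 = traj90.rates_of_progress[0]
        assert q0[0] > 0  # initiation runs off the initial composition
        assert np.allclose(q0[1:], 0.0)

    def test_oxygen_addition_speedup_about_two_orders(self, traj50, traj90):
        j = 1  # LINRAD + O2 -> ROO
        q50 = traj50.rates_of_progress[-1, j]
        q90 = traj90.rates_of_progress[-1, j]
        assert 30.0 <= q90 / q50 <= 300.0


class TestTrajectoryIO:
    def test_write_tsv_and_sidecar(self, traj50, tmp_path):
        out = tmp_path / "traj.tsv"
        side = tmp_path / "traj.meta.yaml"
        traj50.write(out, sidecar_path=side)
        import pandas as pd
        import yaml

        df = pd.read_csv(out, sep="\t")
        assert {"time_s", "x_LINOLEIC", "c_LINOLEIC", "q_1"} <= set(df.columns)
        assert len(df) == traj50.times.size
        meta = yaml.safe_load(side.read_text())
        assert meta["mechanism_hash"] == traj50.mechanism.content_hash()

    def test_sample_time_validation(self):
        with pytest.raises(ValueError):
            ReactorConditions(T=300.0, t_end=100.0, sample_times=(0.0, 50.0, 40.0))
        with pytest.raises(ValueError):
            ReactorConditions(T=300.0, t_end=100.0, sample_times=(0.0, 200.0))
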