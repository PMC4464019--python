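"""Gillespie simulator: exactness properties and analytic-law recovery."""

import math

import numpy as np
import pytest
from scipy import stats as ss

from trajstat import (
    Reaction,
    ReactionModel,
    generate_ensemble,
    immigration_death,
    load_dataset,
    lotka_volterra,
    mass_action,
    model_from_config,
    pure_death,
    ssa_simulate,
)
from trajstat.errors import ModelError, ParameterError
from trajstat.io import LoadSpec


class TestSsaSimulate:
    def test_absorbing_start_yields_single_row(self):
        model = ReactionModel(
            species=["X"],
            reactions=[Reaction([1], lambda x: 0.0)],
            x0=[3],
        )
        traj = ssa_simulate(model, 10.0, seed=0)
        assert len(traj) == 1
        assert traj.values[0, 0] == 3.0

    def test_pure_death_from_one_has_exactly_one_event(self):
        traj = ssa_simulate(pure_death(mu=2.0, n0=1), 1e6, seed=3)
        # rows: initial state, the single death event
        assert np.array_equal(traj.values[:, 0], [1.0, 0.0])

    def test_seed_determinism(self):
        a = ssa_simulate(lotka_volterra(), 20.0, seed=11)
        b = ssa_simulate(lotka_volterra(), 20.0, seed=11)
        assert a.equals(b)
        c = ssa_simulate(lotka_volterra(), 20.0, seed=12)
        assert not a.equals(c)

    def test_counts_never_negative(self):
        traj = ssa_simulate(lotka_volterra(), 30.0, seed=5)
        assert np.all(traj.values >= 0)

    def test_negative_propensity_is_a_model_error(self):
        model = ReactionModel(
            species=["X"],
            reactions=[Reaction([1], lambda x: -1.0)],
            x0=[0],
        )
        with pytest.raises(ModelError):
            ssa_simulate(model, 1.0, seed=0)

    def test_max_events_guard(self):
        traj = ssa_simulate(immigration_death(k=100.0, mu=0.0), 1e9, seed=1,
                            max_events=25)
        assert len(traj) == 26  # initial row + 25 events

    def test_final_row_holds_state_at_t_max(self):
        traj = ssa_simulate(immigration_death(k=5.0, mu=1.0), 3.0, seed=4)
        assert traj.t_last == 3.0
        assert traj.values[-1, 0] == traj.values[-2, 0]

    def test_waiting_times_are_exponential(self):
        """KS test of inter-event times in a constant-propensity model."""
        k = 2.0
        traj = ssa_simulate(immigration_death(k=k, mu=0.0), 1e9, seed=123,
                            max_events=5000)
        waits = np.diff(traj.times)
        stat = ss.kstest(waits, "expon", args=(0.0, 1.0 / k)).statistic
        critical_1pct = 1.63 / math.sqrt(len(waits))
        assert stat < critical_1pct


class TestBuiltinModels:
    def test_lv_no_spontaneous_prey(self):
        traj = ssa_simulate(lotka_volterra(prey0=0, pred0=10), 50.0, seed=0)
        assert np.all(traj.column("Preys") == 0.0)

    def test_lv_prey_grow_without_predators(self):
        traj = ssa_simulate(lotka_volterra(prey0=10, pred0=0), 5.0, seed=0)
        prey = traj.column("Preys")
        assert np.all(np.diff(prey[:-1]) >= 0)  # birth-only dynamics
        assert np.all(traj.column("Predators") == 0.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ParameterError):
            lotka_volterra(k1=-0.1)
        with pytest.raises(ParameterError):
            immigration_death(k=-1.0, mu=1.0)
        with pytest.raises(ParameterError):
            pure_death(mu=1.0, n0=-1)

    def test_immigration_death_transient_mean(self):
        """Empirical mean within 3 SE of (k/mu)(1 - e^(-mu t))."""
        k, mu, t = 10.0, 1.0, 2.0
        ens = generate_ensemble(immigration_death(k, mu), 500, t, seed=9)
        samples = ens.samples_at(t, "X")
        lam = (k / mu) * (1.0 - math.exp(-mu * t))
        se = math.sqrt(lam / len(samples))  # Poisson variance = mean
        assert abs(samples.mean() - lam) < 3 * se

    def test_pure_death_half_life_mean(self):
        """At t = ln2/mu the mean count is n0/2 (Binomial(n0, 1/2))."""
        mu, n0 = 0.5, 20
        t_half = math.log(2.0) / mu
        ens = generate_ensemble(pure_death(mu, n0), 500, t_half + 0.1, seed=10)
        samples = ens.samples_at(t_half, "X")
        se = math.sqrt(n0 * 0.25 / len(samples))
        assert abs(samples.mean() - n0 / 2) < 3 * se

    def test_mass_action_combinatorics(self):
        prop = mass_action(2.0, [2])  # A + A -> ...
        assert prop([5]) == 2.0 * 5 * 4 / 2
        assert prop([1]) == 0.0
        prop2 = mass_action(3.0, [1, 1])
        assert prop2([4, 6]) == 3.0 * 24


class TestGenerateEnsemble:
    def test_run_count(self):
        ens = generate_ensemble(pure_death(1.0, 5), 100, 2.0, seed=0)
        assert ens.n_runs == 100

    def test_master_seed_reproducibility(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_ensemble(pure_death(1.0, 5), 4, 2.0, seed=7, out_dir=d1)
        generate_ensemble(pure_death(1.0, 5), 4, 2.0, seed=7, out_dir=d2)
        for f1, f2 in zip(sorted(d1.iterdir()), sorted(d2.iterdir())):
            assert f1.read_bytes() == f2.read_bytes()

    def test_written_folder_reloads_identically(self, tmp_path):
        ens = generate_ensemble(
            immigration_death(5.0, 1.0), 6, 3.0, seed=2, out_dir=tmp_path / "runs"
        )
        back = load_dataset(LoadSpec(path=tmp_path / "runs", n_workers=1))
        assert back.equals(ens)

    def test_runs_are_independent_streams(self):
        ens = generate_ensemble(immigration_death(5.0, 1.0), 3, 3.0, seed=2)
        assert not ens[0].equals(ens[1])


class TestModelConfig:
    def test_yaml_model_matches_builtin(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            """
label: decay
species: [X]
x0: [20]
reactions:
  - rate: 0.3
    reactants: {X: 1}
    products: {}
    name: death
"""
        )
        model = model_from_config(cfg)
        builtin = pure_death(0.3, 20)
        assert model.species == builtin.species
        assert np.array_equal(model.x0, builtin.x0)
        for state in ([0], [1], [7]):
            assert model.reactions[0].propensity(state) == pytest.approx(
                builtin.reactions[0].propensity(state)
            )
        a = ssa_simulate(model, 5.0, seed=42)
        b = ssa_simulate(builtin, 5.0, seed=42)
        assert a.equals(b)

    def test_unknown_species_rejected(self, tmp_path):
        cfg = tmp_path / "model.yaml"
        cfg.write_text(
            "species: [X]\nx0: [1]\nreactions:\n  - rate: 1.0\n    reactants: {Y: 1}\n"
        )
        with pytest.raises(ParameterError):
            model_from_config(cfg)
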