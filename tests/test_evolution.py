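"""Stochastic event layer: rates, Gillespie sampling, event application."""

import math

import numpy as np
import pytest
from scipy import stats

from crisprcoevo.community import CommunityState
from crisprcoevo.ecology import EcoParams
from crisprcoevo.evolution import (
    VIRAL_MUTATION,
    EvoParams,
    apply_spacer_acquisition,
    apply_viral_mutation,
    host_acquisition_rates,
    sample_next_event,
    viral_mutation_rate,
    viral_production_rates,
)
from crisprcoevo.strain_space import AlleleRegistry, HostStrain, MolecularParams, ViralStrain


def make_state(host_specs, virus_specs, mol=None, t=0.0):
    """host_specs/virus_specs: list of (spacers/protospacers, density)."""
    hosts = [HostStrain(strain_id=i + 1, spacers=s) for i, (s, _) in enumerate(host_specs)]
    viruses = [
        ViralStrain(strain_id=100 + j, protospacers=g)
        for j, (g, _) in enumerate(virus_specs)
    ]
    N = np.array([d for _, d in host_specs], dtype=float)
    V = np.array([d for _, d in virus_specs], dtype=float)
    return CommunityState(hosts, viruses, N, V, mol or MolecularParams(), t=t)


GENOME = tuple(range(1, 11))


class TestRates:
    def test_no_viruses_no_production(self):
        state = make_state([((), 1e4)], [], MolecularParams())
        _, b = viral_production_rates(state, EcoParams())
        assert b == 0.0

    def test_susceptible_pair_production_rate(self):
        state = make_state([((), 1e4)], [(GENOME, 1e3)], MolecularParams())
        _, b = viral_production_rates(state, EcoParams())
        # beta phi V l N = 50 * 1e-7 * 1e3 * 0.99999 * 1e4
        assert b == pytest.approx(50.0, rel=1e-4)

    def test_fully_immune_community_produces_nothing(self):
        mol = MolecularParams(p=0.0, q=1e-5)
        state = make_state([((1,), 1e4)], [(GENOME, 1e3)], mol)
        _, b = viral_production_rates(state, EcoParams())
        assert b == 0.0

    def test_mutation_rate_is_linear_in_b_and_v(self):
        evo = EvoParams(mu=5e-7)
        assert viral_mutation_rate(1e4, evo, 10) == pytest.approx(0.05)
        assert viral_mutation_rate(0.0, evo, 10) == 0.0
        assert viral_mutation_rate(1e4, evo, 20) == pytest.approx(0.1)

    def test_acquisition_rate_zero_without_q(self):
        mol = MolecularParams(p=1e-5, q=0.0)
        state = make_state([((), 1e4)], [(GENOME, 1e6)], mol)
        a_i, a = host_acquisition_rates(state, EcoParams(), mol)
        assert a == 0.0

    def test_immune_host_acquisition_rate(self):
        mol = MolecularParams(p=0.0, q=1e-5)
        state = make_state([((1,), 1e4)], [(GENOME, 1e6)], mol)
        _, a = host_acquisition_rates(state, EcoParams(), mol)
        # q phi N V (1-p) = 1e-5 * 1e-7 * 1e4 * 1e6
        assert a == pytest.approx(0.01, rel=1e-9)

    def test_identical_hosts_have_identical_rates(self):
        mol = MolecularParams()
        state = make_state([((1,), 5e3), ((2,), 5e3)], [(GENOME, 1e6)], mol)
        a_i, _ = host_acquisition_rates(state, EcoParams(), mol)
        assert a_i[0] == pytest.approx(a_i[1])


class TestSampling:
    def test_zero_total_rate_schedules_nothing(self):
        rng = np.random.default_rng(0)
        sched = sample_next_event(5.0, np.empty(0), 0.0, np.empty(0), 0.0, rng)
        assert math.isinf(sched.next_event_time)
        assert sched.event_kind is None

    def test_waiting_time_mean_matches_exponential(self):
        rng = np.random.default_rng(1)
        R = 0.05
        waits = [
            sample_next_event(0.0, np.array([R]), R, np.empty(0), 0.0, rng).next_event_time
            for _ in range(10**5)
        ]
        assert np.mean(waits) == pytest.approx(20.0, abs=0.2)

    def test_event_kind_split_matches_rate_ratio(self):
        rng = np.random.default_rng(2)
        kinds = [
            sample_next_event(0.0, np.array([3.0]), 3.0, np.array([1.0]), 1.0, rng).event_kind
            for _ in range(10**5)
        ]
        frac_viral = sum(k == VIRAL_MUTATION for k in kinds) / len(kinds)
        assert frac_viral == pytest.approx(0.75, abs=0.01)


class TestApplyViralMutation:
    def test_single_strain_is_always_parent_and_seeded_above_cutoff(self):
        rng = np.random.default_rng(3)
        reg = AlleleRegistry(last_issued=10)
        evo = EvoParams()
        state = make_state([((), 1e4)], [(GENOME, 1e3)])
        sched = sample_next_event(0.0, np.array([1.0]), 1.0, np.empty(0), 0.0, rng)
        child = apply_viral_mutation(state, sched, rng, reg, evo, strain_id=500)
        assert child.parent_id == 100
        assert state.V[-1] == pytest.approx(0.11)
        assert sum(a != b for a, b in zip(GENOME, child.protospacers)) == 1
        assert state.V[0] == 1e3  # parent density untouched

    def test_parent_choice_follows_production_rates(self):
        rng = np.random.default_rng(4)
        reg = AlleleRegistry(last_issued=100)
        evo = EvoParams()
        counts = {100: 0, 101: 0}
        n = 10**4
        for _ in range(n):
            state = make_state([((), 1e4)], [(GENOME, 9e2), (tuple(range(11, 21)), 1e2)])
            sched = sample_next_event(
                0.0, np.array([9.0, 1.0]), 10.0, np.empty(0), 0.0, rng
            )
            child = apply_viral_mutation(state, sched, rng, reg, evo, strain_id=500)
            counts[child.parent_id] += 1
        observed = [counts[100], counts[101]]
        pvalue = stats.chisquare(observed, [0.9 * n, 0.1 * n]).pvalue
        assert pvalue > 0.01

    def test_error_when_no_production(self):
        rng = np.random.default_rng(5)
        state = make_state([((), 1e4)], [(GENOME, 1e3)])
        sched = sample_next_event(0.0, np.zeros(1), 0.0, np.empty(0), 0.0, rng)
        with pytest.raises(ValueError):
            apply_viral_mutation(state, sched, rng, AlleleRegistry(), EvoParams(), 500)


class TestApplySpacerAcquisition:
    def _event(self, state, rng, mol, strain_id=600):
        a_i, a = host_acquisition_rates(state, EcoParams(), mol)
        sched = sample_next_event(0.0, np.empty(0), 0.0, a_i, a, rng)
        return apply_spacer_acquisition(
            state, sched, rng, mol, EvoParams(), strain_id, u_max=8
        )

    def test_acquired_allele_uniform_over_donor_protospacers(self):
        rng = np.random.default_rng(6)
        mol = MolecularParams()
        counts = {g: 0 for g in GENOME}
        n = 10**4
        for _ in range(n):
            state = make_state([((), 1e4)], [(GENOME, 1e6)], mol)
            _, _, _, _, allele = self._event(state, rng, mol)
            counts[allele] += 1
        pvalue = stats.chisquare(list(counts.values())).pvalue
        assert pvalue > 0.01

    def test_acquisition_confers_immunity_to_donor(self):
        rng = np.random.default_rng(7)
        mol = MolecularParams()
        state = make_state([((), 1e4)], [(GENOME, 1e6)], mol)
        child, created, _, donor, _ = self._event(state, rng, mol)
        assert created
        assert set(child.spacers) & set(donor.protospacers)
        assert state.M[-1, 0] == 1.0

    def test_full_locus_stays_at_capacity(self):
        rng = np.random.default_rng(8)
        mol = MolecularParams()
        full = tuple(range(101, 109))
        state = make_state([(full, 1e4)], [(GENOME, 1e6)], mol)
        child, created, parent, _, allele = self._event(state, rng, mol)
        assert created
        assert len(child.spacers) == 8
        assert child.spacers == (allele,) + full[:7]

    def test_duplicate_locus_merges_density(self):
        rng = np.random.default_rng(9)
        mol = MolecularParams()
        # the only possible acquisition outcome (1,) already exists as strain 2
        state = make_state([((), 1e4), ((1,), 50.0)], [((1,) * 10, 1e6)], mol)
        # force the spacer-free host to acquire: zero out the immune host's rate
        a_i = np.array([1.0, 0.0])
        sched = sample_next_event(0.0, np.empty(0), 0.0, a_i, 1.0, rng)
        strain, created, parent, _, _ = apply_spacer_acquisition(
            state, sched, rng, mol, EvoParams(), 600, u_max=8
        )
        assert not created
        assert strain.strain_id == 2
        assert state.n_hosts == 2
        assert state.N[1] == pytest.approx(50.0 + 0.11)

    def test_error_when_no_acquisition_possible(self):
        rng = np.random.default_rng(10)
        mol = MolecularParams(q=0.0)
        state = make_state([((), 1e4)], [(GENOME, 1e6)], mol)
        with pytest.raises(ValueError):
            self._event(state, rng, mol)


def test_no_events_without_mutation_channels():
    """mu = 0 and q = 0 degenerate to pure ODE dynamics."""
    mol = MolecularParams(p=1e-5, q=0.0)
    evo = EvoParams(mu=0.0)
    state = make_state([((), 1e4)], [(GENOME, 1e6)], mol)
    b_j, b = viral_production_rates(state, EcoParams())
    a_i, a = host_acquisition_rates(state, EcoParams(), mol)
    rate = viral_mutation_rate(b, evo, 10)
    assert rate == 0.0 and a == 0.0
    sched = sample_next_event(
        0.0, b_j * evo.mu * 10, rate, a_i, a, np.random.default_rng(0)
    )
    assert math.isinf(sched.next_event_time)
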