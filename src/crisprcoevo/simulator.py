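"""Hybrid ODE-Gillespie driver for the coevolution model.

The community evolves deterministically between discrete events.  Each
integration segment runs from the current clock to the earliest of (a) the
scheduled stochastic event, (b) the next data-output time, and (c) the run
horizon, with a terminal root-finding event on ``min(density) - rho_c`` so
that extinction crossings pause the segment exactly at the threshold.

At every pause the driver:

* removes strains at or below the extinction cutoff (absorbing state),
* applies the scheduled mutation/acquisition event if that is what ended the
  segment,
* records a snapshot if an output time was reached,

and then recomputes all event rates from the current densities and redraws
the exponential waiting time.  Ties are resolved extinction -> stochastic
event -> output.  A run terminates at the horizon or when either the host or
the viral community is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import evolution
from .community import CommunityState
from .ecology import EcoParams
from .evolution import (
    EvoParams,
    host_acquisition_rates,
    sample_next_event,
    viral_mutation_rate,
    viral_production_rates,
)
from .strain_space import (
    DEFAULT_U_MAX,
    DEFAULT_V,
    AlleleRegistry,
    HostStrain,
    MolecularParams,
    ViralStrain,
)

__all__ = ["SimConfig", "Snapshot", "SimulationRecord", "run", "replicate_ensemble"]


@dataclass(frozen=True)
class InitialStrain:
    """One founding strain: its allele tuple and starting density."""

    alleles: tuple[int, ...]
    density: float


@dataclass
class SimConfig:
    """Complete, seedable description of one simulation run.

    Defaults follow the baseline parameterization: molecular error rates
    p = q = 1e-5, logistic hosts (r = 1/h, K = 10^5.5 /mL), burst size 50,
    adsorption 1e-7 mL/h, viral decay 0.1/h, viral mutation rate 5e-7 per
    allele per virion, extinction cutoff 0.1/mL, horizon 2500 h with output
    every 2 h.  The default founder community is one spacer-free host at
    1e4 cells/mL and one virus with ten fresh protospacer alleles at
    1e5 virions/mL (the founder host is susceptible to the founder virus).
    """

    eco: EcoParams = field(default_factory=EcoParams)
    mol: MolecularParams = field(default_factory=MolecularParams)
    evo: EvoParams = field(default_factory=EvoParams)
    u_max: int = DEFAULT_U_MAX
    v: int = DEFAULT_V
    t_max: float = 2500.0
    output_interval: float = 2.0
    init_hosts: Optional[list[InitialStrain]] = None  # None -> default founder
    init_viruses: Optional[list[InitialStrain]] = None
    init_host_density: float = 1e4
    init_virus_density: float = 1e5
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "DOP853"
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.t_max <= 0:
            errors.append("t_max must be positive")
        if self.output_interval <= 0:
            errors.append("output_interval must be positive")
        if self.u_max < 1 or self.v < 1:
            errors.append("u_max and v must be at least 1")
        if self.init_host_density <= self.evo.rho_c:
            errors.append("init_host_density must exceed rho_c")
        if self.init_virus_density <= self.evo.rho_c:
            errors.append("init_virus_density must exceed rho_c")
        for group in (self.init_hosts, self.init_viruses):
            if group:
                for s in group:
                    if s.density <= self.evo.rho_c:
                        errors.append(
                            f"initial strain density {s.density} must exceed rho_c"
                        )
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))


@dataclass
class Snapshot:
    """Densities of all live strains at one output time."""

    t: float
    host_ids: tuple[int, ...]
    host_densities: np.ndarray
    virus_ids: tuple[int, ...]
    virus_densities: np.ndarray


@dataclass
class SimulationRecord:
    """Full output of one run: snapshots, genealogy, event log, termination.

    ``genealogy`` maps strain_id to a dict with keys kind, alleles,
    parent_id, birth_time, death_time (None while alive / censored at the
    final time).  ``events`` is a chronological list of dicts.
    """

    snapshots: list[Snapshot]
    genealogy: dict[int, dict[str, Any]]
    events: list[dict[str, Any]]
    termination: str
    t_end: float
    config: Optional[SimConfig] = None

    def snapshot_times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])


def _genealogy_entry(kind: str, strain) -> dict[str, Any]:
    alleles = strain.spacers if kind == "host" else strain.protospacers
    return {
        "kind": kind,
        "alleles": list(alleles),
        "parent_id": strain.parent_id,
        "birth_time": strain.birth_time,
        "death_time": strain.death_time,
    }


def _default_community(config: SimConfig, registry: AlleleRegistry):
    hosts = [HostStrain(strain_id=1, spacers=(), birth_time=0.0)]
    genome = tuple(registry.new_allele() for _ in range(config.v))
    viruses = [ViralStrain(strain_id=2, protospacers=genome, birth_time=0.0)]
    N = np.array([config.init_host_density])
    V = np.array([config.init_virus_density])
    return hosts, viruses, N, V


def _explicit_community(config: SimConfig, registry: AlleleRegistry):
    hosts, viruses, N, V = [], [], [], []
    sid = 0
    max_allele = 0
    for entry in config.init_hosts or []:
        sid += 1
        hosts.append(HostStrain(strain_id=sid, spacers=tuple(entry.alleles)))
        N.append(entry.density)
        max_allele = max(max_allele, *entry.alleles) if entry.alleles else max_allele
    for entry in config.init_viruses or []:
        sid += 1
        viruses.append(ViralStrain(strain_id=sid, protospacers=tuple(entry.alleles)))
        V.append(entry.density)
        max_allele = max(max_allele, *entry.alleles) if entry.alleles else max_allele
    while registry.last_issued < max_allele:
        registry.new_allele()
    return hosts, viruses, np.array(N, dtype=float), np.array(V, dtype=float)


def _recalc_schedule(state, config, rng):
    b_j, b = viral_production_rates(state, config.eco)
    vrate = viral_mutation_rate(b, config.evo, config.v)
    a_i, a = host_acquisition_rates(state, config.eco, config.mol)
    # scale the per-strain viral rates so their sum equals the channel rate
    vr = b_j * (config.evo.mu * config.v)
    return sample_next_event(state.t, vr, vrate, a_i, a, rng)


def run(config: SimConfig) -> SimulationRecord:
    """Run one replicate of the hybrid simulation.

    Identical config and seed reproduce the record exactly.  Raises
    ``RuntimeError`` if the ODE solver fails on a segment.
    """
    rng = np.random.default_rng(config.seed)
    registry = AlleleRegistry()
    if config.init_hosts is not None or config.init_viruses is not None:
        hosts, viruses, N, V = _explicit_community(config, registry)
    else:
        hosts, viruses, N, V = _default_community(config, registry)
    state = CommunityState(hosts, viruses, N, V, config.mol, t=0.0)
    next_strain_id = max(
        [h.strain_id for h in hosts] + [v.strain_id for v in viruses], default=0
    ) + 1

    genealogy: dict[int, dict[str, Any]] = {}
    for h in hosts:
        genealogy[h.strain_id] = _genealogy_entry("host", h)
    for v in viruses:
        genealogy[v.strain_id] = _genealogy_entry("virus", v)
    events: list[dict[str, Any]] = []
    snapshots: list[Snapshot] = [_snapshot(state)]

    rho_c = config.evo.rho_c
    eco = config.eco
    next_output = config.output_interval
    schedule = _recalc_schedule(state, config, rng)
    termination = "t_max"

    def extinction_event(t, y):
        return y.min() - rho_c

    extinction_event.terminal = True
    extinction_event.direction = -1.0

    while state.t < config.t_max:
        if state.n_hosts == 0:
            termination = "hosts_extinct"
            break
        if state.n_viruses == 0:
            termination = "viruses_extinct"
            break
        t_stop = min(schedule.next_event_time, next_output, config.t_max)

        if t_stop > state.t:
            nh = state.n_hosts
            L = state.L
            r, K, beta, phi, m = eco.r, eco.K, eco.beta, eco.phi, eco.m

            def rhs(t, y):
                N = y[:nh]
                V = y[nh:]
                Ntot = N.sum()
                dN = r * N * (1.0 - Ntot / K) - phi * N * (L @ V)
                dV = beta * phi * V * (L.T @ N) - phi * V * Ntot - m * V
                return np.concatenate([dN, dV])

            try:
                sol = solve_ivp(
                    rhs,
                    (state.t, t_stop),
                    state.densities(),
                    method=config.method,
                    rtol=config.rtol,
                    atol=config.atol,
                    events=extinction_event,
                )
            except ValueError:
                # min(y) is non-smooth; when a strain hovers numerically at
                # the threshold its root bracketing can fail.  Retry with one
                # smooth event per strain.
                per_strain = _per_strain_events(nh + state.n_viruses, rho_c)
                sol = solve_ivp(
                    rhs,
                    (state.t, t_stop),
                    state.densities(),
                    method=config.method,
                    rtol=config.rtol,
                    atol=config.atol,
                    events=per_strain,
                )
                if sol.status == 1:
                    te = min(
                        (ts[0] for ts in sol.t_events if ts.size), default=None
                    )
                    if te is not None:
                        state.t = float(te)
                        k = min(
                            range(len(sol.t_events)),
                            key=lambda i: sol.t_events[i][0]
                            if sol.t_events[i].size
                            else math.inf,
                        )
                        state.set_densities(np.maximum(sol.y_events[k][0], 0.0))
                        _remove_extinct(state, genealogy, events, rho_c)
                        schedule = _recalc_schedule(state, config, rng)
                        continue
            if sol.status == -1:
                raise RuntimeError(
                    f"ODE solver failed at t={state.t:.3f} with {nh} hosts, "
                    f"{state.n_viruses} viruses: {sol.message}"
                )
            if sol.status == 1:  # extinction crossing located; handle it first
                state.t = float(sol.t_events[0][0])
                state.set_densities(np.maximum(sol.y_events[0][0], 0.0))
                _remove_extinct(state, genealogy, events, rho_c)
                schedule = _recalc_schedule(state, config, rng)
                continue
            state.t = float(sol.t[-1])
            state.set_densities(sol.y[:, -1])

        # tie-break at a shared stop time: stochastic event before output
        if schedule.next_event_time <= t_stop and schedule.event_kind is not None:
            next_strain_id = _apply_event(
                state, schedule, rng, registry, config, genealogy, events, next_strain_id
            )
            schedule = _recalc_schedule(state, config, rng)
            continue

        if next_output <= t_stop:
            snapshots.append(_snapshot(state))
            next_output += config.output_interval
            schedule = _recalc_schedule(state, config, rng)
            continue

    if not math.isclose(snapshots[-1].t, state.t, abs_tol=1e-12):
        snapshots.append(_snapshot(state))
    return SimulationRecord(
        snapshots=snapshots,
        genealogy=genealogy,
        events=events,
        termination=termination,
        t_end=state.t,
        config=config,
    )


def _snapshot(state: CommunityState) -> Snapshot:
    return Snapshot(
        t=state.t,
        host_ids=tuple(h.strain_id for h in state.hosts),
        host_densities=state.N.copy(),
        virus_ids=tuple(v.strain_id for v in state.viruses),
        virus_densities=state.V.copy(),
    )


def _per_strain_events(n: int, rho_c: float):
    """One smooth terminal crossing event per strain (fallback path)."""
    def make(i):
        def ev(t, y):
            return y[i] - rho_c
        ev.terminal = True
        ev.direction = -1.0
        return ev
    return [make(i) for i in range(n)]


def _remove_extinct(state, genealogy, events, rho_c):
    """Remove every strain at or below the cutoff (closed threshold).

    A relative hysteresis of 1e-9 absorbs interpolation noise so a strain
    located at the threshold by the root finder is always removed.
    """
    rho_c = rho_c * (1.0 + 1e-9)
    # hosts, highest index first so earlier indices stay valid
    for i in reversed(range(state.n_hosts)):
        if state.N[i] <= rho_c:
            strain = state.remove_host(i, state.t)
            genealogy[strain.strain_id]["death_time"] = state.t
            events.append(
                {"t": state.t, "kind": "extinction", "strain": strain.strain_id,
                 "strain_kind": "host"}
            )
    for j in reversed(range(state.n_viruses)):
        if state.V[j] <= rho_c:
            strain = state.remove_virus(j, state.t)
            genealogy[strain.strain_id]["death_time"] = state.t
            events.append(
                {"t": state.t, "kind": "extinction", "strain": strain.strain_id,
                 "strain_kind": "virus"}
            )


def _apply_event(state, schedule, rng, registry, config, genealogy, events, next_id):
    if schedule.event_kind == evolution.VIRAL_MUTATION:
        child = evolution.apply_viral_mutation(
            state, schedule, rng, registry, config.evo, next_id
        )
        genealogy[child.strain_id] = _genealogy_entry("virus", child)
        parent_alleles = genealogy[child.parent_id]["alleles"]
        pos, allele = next(
            (k, b)
            for k, (a, b) in enumerate(zip(parent_alleles, child.protospacers))
            if a != b
        )
        events.append(
            {
                "t": state.t,
                "kind": evolution.VIRAL_MUTATION,
                "parent_strain": child.parent_id,
                "child_strain": child.strain_id,
                "position": pos,
                "allele": allele,
            }
        )
        return next_id + 1
    strain, created, parent, donor, allele = evolution.apply_spacer_acquisition(
        state, schedule, rng, config.mol, config.evo, next_id, config.u_max
    )
    if created:
        genealogy[strain.strain_id] = _genealogy_entry("host", strain)
    events.append(
        {
            "t": state.t,
            "kind": evolution.HOST_ACQUISITION,
            "parent_strain": parent.strain_id,
            "child_strain": strain.strain_id,
            "donor_virus": donor.strain_id,
            "allele": allele,
            "merged": not created,
        }
    )
    return next_id + 1 if created else next_id


def replicate_ensemble(
    config: SimConfig, n_replicates: int, seeds: Optional[list[int]] = None
) -> list[SimulationRecord]:
    """Run independent replicates differing only in their RNG seed.

    ``seeds`` defaults to ``config.seed + 0 .. n_replicates - 1``; seeds must
    be distinct for the replicates to be independent.
    """
    from dataclasses import replace

    if seeds is None:
        seeds = [config.seed + k for k in range(n_replicates)]
    if len(seeds) != n_replicates:
        raise ValueError("need exactly one seed per replicate")
    return [run(replace(config, seed=s)) for s in seeds]
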