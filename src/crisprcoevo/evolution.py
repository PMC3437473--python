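"""Stochastic genomic-event layer: rates, Gillespie timing, event application.

Two event channels change the strain composition of the community:

* undirected viral mutation — replication errors replace one protospacer
  with a fresh allele.  Virions are produced at total rate ``b``; with a
  per-allele mutation probability ``mu`` over ``v`` protospacers the event
  rate is ``b mu v``, and the mutating parent is chosen proportionally to its
  strain-level production rate ``b_j``;
* directed spacer acquisition — a non-lysed host copies one protospacer of
  the attacking virus into the leading end of its locus.  The per-strain rate
  is the defense-weighted adsorption flux times the acquisition probability
  ``q``; for non-immune pairs survival and acquisition are the same q-event,
  so ``q`` enters once.

Rates use per-mL densities in a nominal 1 mL system, so density products are
event rates directly.  Within an integration segment the rates are frozen;
the simulator recomputes them (and redraws the exponential waiting time) at
every applied event, extinction, and scheduled output time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .community import CommunityState
from .ecology import EcoParams
from .strain_space import (
    AlleleRegistry,
    HostStrain,
    MolecularParams,
    ViralStrain,
    acquire_spacer,
    mutate_protospacer,
)

__all__ = [
    "EvoParams",
    "EventSchedule",
    "viral_production_rates",
    "viral_mutation_rate",
    "host_acquisition_rates",
    "sample_next_event",
    "apply_viral_mutation",
    "apply_spacer_acquisition",
]

VIRAL_MUTATION = "viral_mutation"
HOST_ACQUISITION = "host_acquisition"


@dataclass(frozen=True)
class EvoParams:
    """Evolutionary-layer parameters.

    Parameters
    ----------
    mu
        Per-allele protospacer mutation probability per virion produced.
    rho_c
        Extinction cutoff density, 1/mL; strains at or below it are removed
        (absorbing state).
    seed_factor
        Mutant strains are seeded at ``seed_factor * rho_c`` (10% above the
        cutoff by default).
    """

    mu: float = 5e-7
    rho_c: float = 0.1
    seed_factor: float = 1.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be in [0, 1]")
        if self.rho_c <= 0:
            raise ValueError("rho_c must be positive")
        if self.seed_factor <= 1.0:
            raise ValueError("seed_factor must exceed 1 (seed above the cutoff)")

    @property
    def seed_density(self) -> float:
        return self.seed_factor * self.rho_c


@dataclass
class EventSchedule:
    """Next stochastic event, with the rate table frozen at segment start."""

    next_event_time: float  # absolute time, h; inf if no event is scheduled
    event_kind: str | None
    viral_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    host_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_rate: float = 0.0


def viral_production_rates(
    state: CommunityState, eco: EcoParams
) -> tuple[np.ndarray, float]:
    """Per-strain virion production rates b_j = beta phi V_j sum_i l_ij N_i."""
    if state.n_viruses == 0:
        return np.empty(0), 0.0
    b_j = eco.beta * eco.phi * state.V * (state.L.T @ state.N)
    return b_j, float(b_j.sum())


def viral_mutation_rate(b: float, evo: EvoParams, v: int) -> float:
    """Total undirected-mutation rate b mu v (events/h)."""
    return b * evo.mu * v


def host_acquisition_rates(
    state: CommunityState, eco: EcoParams, mol: MolecularParams
) -> tuple[np.ndarray, float]:
    """Per-strain spacer-acquisition rates.

    a_i = q phi N_i sum_j V_j w_ij with defense weight
    w_ij = (1 - p) M_ij + (1 - M_ij): immune hosts survive adsorptions with
    probability 1 - p and may then acquire; non-immune hosts survive (and
    thereby acquire) with probability q, counted once.
    """
    if state.n_hosts == 0 or state.n_viruses == 0:
        return np.zeros(state.n_hosts), 0.0
    w = (1.0 - mol.p) * state.M + (1.0 - state.M)
    a_i = mol.q * eco.phi * state.N * (w @ state.V)
    return a_i, float(a_i.sum())


def sample_next_event(
    t: float,
    viral_rates: np.ndarray,
    viral_total: float,
    host_rates: np.ndarray,
    host_total: float,
    rng: np.random.Generator,
) -> EventSchedule:
    """Draw the waiting time and kind of the next event (Gillespie).

    The waiting time is exponential with rate R = total viral-mutation rate
    plus total acquisition rate; the kind is chosen with probability
    proportional to its channel rate.  R = 0 schedules no event.
    RNG draw order: (1) waiting time, (2) event kind.
    """
    R = viral_total + host_total
    if R <= 0.0:
        return EventSchedule(math.inf, None, viral_rates, host_rates, 0.0)
    wait = rng.exponential(1.0 / R)
    kind = VIRAL_MUTATION if rng.random() < viral_total / R else HOST_ACQUISITION
    return EventSchedule(t + wait, kind, viral_rates, host_rates, R)


def _choose(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Index drawn proportionally to non-negative weights."""
    total = weights.sum()
    if total <= 0:
        raise ValueError("all channel rates are zero; event should not have fired")
    return int(np.searchsorted(np.cumsum(weights), rng.random() * total, side="right"))


def apply_viral_mutation(
    state: CommunityState,
    schedule: EventSchedule,
    rng: np.random.Generator,
    registry: AlleleRegistry,
    evo: EvoParams,
    strain_id: int,
) -> ViralStrain:
    """Create one mutant viral strain and add it to the community.

    The parent is chosen proportionally to its frozen production rate b_j,
    the mutated position uniformly among the v protospacers, and the new
    allele is fresh.  The mutant is seeded at ``seed_factor * rho_c``; the
    parent's density is unchanged.  RNG draw order: parent, position.
    """
    j = _choose(schedule.viral_rates, rng)
    parent = state.viruses[j]
    pos = int(rng.integers(len(parent.protospacers)))
    genome = mutate_protospacer(parent.protospacers, pos, registry.new_allele())
    child = ViralStrain(
        strain_id=strain_id,
        protospacers=genome,
        parent_id=parent.strain_id,
        birth_time=state.t,
    )
    state.add_virus(child, evo.seed_density)
    return child


def apply_spacer_acquisition(
    state: CommunityState,
    schedule: EventSchedule,
    rng: np.random.Generator,
    mol: MolecularParams,
    evo: EvoParams,
    strain_id: int,
    u_max: int,
) -> tuple[HostStrain | None, HostStrain, ViralStrain, int]:
    """Create (or merge) one spacer-acquisition host strain.

    The acquiring host is chosen proportionally to its frozen acquisition
    rate a_i; the donor virus proportionally to V_j w_ij for that host; the
    acquired protospacer uniformly among the donor's alleles (re-acquiring an
    allele already in the locus is allowed).  The child locus is the parent
    locus with the allele pushed onto the leading end (FIFO at capacity
    ``u_max``).  If the resulting ordered locus equals a live strain's locus,
    the seed density is merged into that strain instead of creating a
    duplicate.  RNG draw order: host, donor virus, protospacer index.

    Returns ``(strain, created, parent, donor, acquired_allele)``; ``strain``
    is the new child, or the existing live strain (``created=False``) when
    the event merged.
    """
    i = _choose(schedule.host_rates, rng)
    parent = state.hosts[i]
    w_row = (1.0 - mol.p) * state.M[i, :] + (1.0 - state.M[i, :])
    j = _choose(state.V * w_row, rng)
    donor = state.viruses[j]
    allele = int(donor.protospacers[int(rng.integers(len(donor.protospacers)))])
    locus = acquire_spacer(parent.spacers, allele, u_max)
    existing = state.find_host(locus)
    if existing is not None:
        state.N[existing] += evo.seed_density
        return state.hosts[existing], False, parent, donor, allele
    child = HostStrain(
        strain_id=strain_id,
        spacers=locus,
        parent_id=parent.strain_id,
        birth_time=state.t,
    )
    state.add_host(child, evo.seed_density)
    return child, True, parent, donor, allele
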