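"""Named deterministic test scenarios with closed-form expectations.

Each fixture is fully determined by its name and seed, so regeneration is
reproducible.  Fixtures return a runnable :class:`SimConfig` plus a dict of
independent expectations (closed-form equilibria, qualitative outcomes)
against which the simulator can be checked.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from .ecology import EcoParams, check_viability_conditions, equilibrium_single_pair
from .evolution import EvoParams
from .simulator import InitialStrain, SimConfig
from .strain_space import MolecularParams

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("lv-pair", "immune-pair", "tiny-diverse")


def make_fixture(name: str, seed: int = 0) -> tuple[SimConfig, dict[str, Any]]:
    """Return (config, expectations) for a named scenario.

    * ``lv-pair`` — one susceptible host, one virus, mutation disabled
      (mu = 0, q = 0); expectations carry the closed-form coexistence
      equilibrium the trajectory must converge to.
    * ``immune-pair`` — one fully immune host (its locus holds a protospacer
      of the only virus), mutation disabled; under the default parameters
      the virus cannot replace its losses, so viral extinction before the
      horizon is expected.
    * ``tiny-diverse`` — 3 hosts x 4 viruses with seed-determined genotypes
      over a small alphabet, for interaction-matrix tests.
    """
    if name == "lv-pair":
        eco = EcoParams()
        config = SimConfig(
            eco=eco,
            mol=MolecularParams(p=1e-5, q=0.0),
            evo=EvoParams(mu=0.0),
            t_max=5000.0,
            output_interval=50.0,
            seed=seed,
        )
        N_star, V_star = equilibrium_single_pair(eco, lysis=1.0)
        return config, {"equilibrium": (N_star, V_star)}

    if name == "immune-pair":
        eco = EcoParams()
        mol = MolecularParams(p=1e-5, q=0.0)
        genome = tuple(range(1, 11))
        config = SimConfig(
            eco=eco,
            mol=mol,
            evo=EvoParams(mu=0.0),
            t_max=2000.0,
            output_interval=10.0,
            init_hosts=[InitialStrain(alleles=(1,), density=1e4)],
            init_viruses=[InitialStrain(alleles=genome, density=1e5)],
            seed=seed,
        )
        dies, _ = check_viability_conditions(eco, mol)
        return config, {"viral_extinction": dies}

    if name == "tiny-diverse":
        rng = np.random.default_rng(seed)
        alphabet = np.arange(1, 21)
        hosts = [
            InitialStrain(
                alleles=tuple(int(a) for a in rng.choice(alphabet, size=3, replace=False)),
                density=float(rng.uniform(1e3, 1e4)),
            )
            for _ in range(3)
        ]
        viruses = [
            InitialStrain(
                alleles=tuple(int(a) for a in rng.choice(alphabet, size=10, replace=False)),
                density=float(rng.uniform(1e4, 1e5)),
            )
            for _ in range(4)
        ]
        config = SimConfig(
            t_max=100.0,
            init_hosts=hosts,
            init_viruses=viruses,
            seed=seed,
        )
        return config, {}

    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
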