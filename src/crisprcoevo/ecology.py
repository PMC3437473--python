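"""Deterministic density dynamics of the host-virus community.

Between stochastic genomic events, strain densities follow a generalized
Lotka-Volterra system with a shared host carrying capacity.  Writing ``N_i``
for host-strain densities (cells/mL), ``V_j`` for viral-strain densities
(virions/mL), and ``l_ij`` for the probability that an adsorption of virus j
on host i ends in lysis,

    dN_i/dt = r N_i (1 - sum_k N_k / K) - phi N_i sum_j l_ij V_j
    dV_j/dt = beta phi V_j sum_i l_ij N_i - phi V_j sum_i N_i - m V_j

Hosts grow logistically toward the shared carrying capacity ``K`` and are
lost to lysis.  Viruses are produced in bursts of ``beta`` per lysis, are
lost by adsorption to any host cell (successful or not), and decay freely at
rate ``m``.  The lysis matrix couples ecology to the genotype layer:
``l_ij = p`` for immune pairs and ``1 - q`` otherwise.

The module also provides the closed-form single-pair equilibrium and the
parameter viability conditions used to select biologically sensible regimes;
both serve as independent oracles for the full simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .strain_space import MolecularParams, immune

__all__ = [
    "EcoParams",
    "InteractionMatrices",
    "build_interaction_matrices",
    "lysis_matrix",
    "rhs",
    "equilibrium_single_pair",
    "check_viability_conditions",
]


@dataclass(frozen=True)
class EcoParams:
    """Ecological life-history parameters (E. coli / phage scale defaults).

    Parameters
    ----------
    r
        Maximum host per-capita growth rate, 1/h.
    K
        Shared host carrying capacity, cells/mL.
    beta
        Burst size, virions released per lysed cell.
    phi
        Adsorption rate constant, mL/h.
    m
        Free-virion decay rate, 1/h.
    """

    r: float = 1.0
    K: float = 10**5.5
    beta: float = 50.0
    phi: float = 1e-7
    m: float = 0.1

    def __post_init__(self) -> None:
        for name in ("r", "K", "beta", "phi", "m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"EcoParams.{name} must be strictly positive")


@dataclass
class InteractionMatrices:
    """Cached host x virus immunity (M) and lysis-probability (L) matrices."""

    M: np.ndarray  # float {0,1}, shape (n_hosts, n_viruses)
    L: np.ndarray  # float {p, 1-q}, same shape


def lysis_matrix(M: np.ndarray, mol: MolecularParams) -> np.ndarray:
    """L_ij = p M_ij + (1 - q)(1 - M_ij)."""
    return mol.p * M + (1.0 - mol.q) * (1.0 - M)


def build_interaction_matrices(hosts, viruses, mol: MolecularParams) -> InteractionMatrices:
    """Compute immunity and lysis matrices for the current strain sets.

    ``hosts`` and ``viruses`` are sequences of strains (or bare genotype
    tuples); empty strain sets yield empty matrices.
    """
    host_sets = [
        h.spacer_set if hasattr(h, "spacer_set") else frozenset(h) for h in hosts
    ]
    viral_sets = [
        v.protospacer_set if hasattr(v, "protospacer_set") else frozenset(v)
        for v in viruses
    ]
    M = np.empty((len(host_sets), len(viral_sets)), dtype=float)
    for i, s in enumerate(host_sets):
        for j, g in enumerate(viral_sets):
            M[i, j] = immune(s, g)
    return InteractionMatrices(M=M, L=lysis_matrix(M, mol))


def rhs(t: float, y: np.ndarray, eco: EcoParams, mats: InteractionMatrices) -> np.ndarray:
    """Time derivative of the concatenated density vector [N_1..N_h, V_1..V_v].

    The logistic term uses the *total* host density (shared carrying
    capacity); virion loss includes adsorptions to immune hosts.
    """
    nh, nv = mats.L.shape
    if y.shape[0] != nh + nv:
        raise ValueError(
            f"density vector of length {y.shape[0]} does not match "
            f"{nh} hosts + {nv} viruses"
        )
    N = y[:nh]
    V = y[nh:]
    Ntot = N.sum()
    dN = eco.r * N * (1.0 - Ntot / eco.K) - eco.phi * N * (mats.L @ V)
    dV = eco.beta * eco.phi * V * (mats.L.T @ N) - eco.phi * V * Ntot - eco.m * V
    return np.concatenate([dN, dV])


def coexistence_threshold(eco: EcoParams) -> float:
    """The quantity 1 + m/(phi K) that effective burst size must exceed."""
    return 1.0 + eco.m / (eco.phi * eco.K)


def equilibrium_single_pair(eco: EcoParams, lysis: float) -> tuple[float, float]:
    """Interior fixed point of the one-host-one-virus system.

    With a single host and virus interacting at lysis probability ``lysis``,
    setting the dynamics to zero gives

        N* = m / (phi (beta lysis - 1)),   V* = (r / phi)(1 - N*/K).

    Requires the coexistence condition ``beta * lysis > 1 + m/(phi K)``
    (equivalently N* < K); otherwise the virus cannot persist and no interior
    equilibrium exists.
    """
    if eco.beta * lysis <= coexistence_threshold(eco):
        raise ValueError(
            "no interior equilibrium: effective burst size beta*lysis = "
            f"{eco.beta * lysis:.4g} does not exceed 1 + m/(phi K) = "
            f"{coexistence_threshold(eco):.4g}"
        )
    N_star = eco.m / (eco.phi * (eco.beta * lysis - 1.0))
    V_star = (eco.r / eco.phi) * (1.0 - N_star / eco.K)
    return N_star, V_star


def check_viability_conditions(
    eco: EcoParams, mol: MolecularParams
) -> tuple[bool, bool]:
    """Check the two parameter-regime conditions the model assumes.

    Returns ``(dies_on_immune, persists_on_susceptible)``:

    * viruses die out on a fully immune host population when their effective
      burst size there stays below replacement: ``beta p < 1 + m/(phi K)``;
    * viruses coexist with non-immune hosts when
      ``beta (1 - q) > 1 + m/(phi K)``.
    """
    thr = coexistence_threshold(eco)
    return (eco.beta * mol.p < thr, eco.beta * (1.0 - mol.q) > thr)
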