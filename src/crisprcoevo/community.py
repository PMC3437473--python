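"""Live community state: strains, densities, and cached interaction matrices.

The state owns the list of live host and viral strains, their density
vectors, and the immunity matrix M (hosts x viruses).  M is updated
incrementally: adding a strain appends one row/column of pairwise matches,
removing a strain deletes its row/column; it is never rebuilt wholesale
during a run.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .ecology import lysis_matrix
from .strain_space import HostStrain, MolecularParams, ViralStrain, immune

__all__ = ["CommunityState"]


class CommunityState:
    """All live strains of one community plus the simulation clock."""

    def __init__(
        self,
        hosts: list[HostStrain],
        viruses: list[ViralStrain],
        N: np.ndarray,
        V: np.ndarray,
        mol: MolecularParams,
        t: float = 0.0,
    ) -> None:
        self.hosts = list(hosts)
        self.viruses = list(viruses)
        self.N = np.asarray(N, dtype=float).copy()
        self.V = np.asarray(V, dtype=float).copy()
        self.mol = mol
        self.t = float(t)
        self._host_index: dict[tuple[int, ...], int] = {
            h.spacers: i for i, h in enumerate(self.hosts)
        }
        self.M = np.empty((len(self.hosts), len(self.viruses)), dtype=float)
        for i, h in enumerate(self.hosts):
            for j, v in enumerate(self.viruses):
                self.M[i, j] = immune(h.spacer_set, v.protospacer_set)
        self._L: Optional[np.ndarray] = None

    # -- cached lysis matrix -------------------------------------------------

    @property
    def L(self) -> np.ndarray:
        if self._L is None:
            self._L = lysis_matrix(self.M, self.mol)
        return self._L

    def _invalidate(self) -> None:
        self._L = None

    # -- queries -------------------------------------------------------------

    @property
    def n_hosts(self) -> int:
        return len(self.hosts)

    @property
    def n_viruses(self) -> int:
        return len(self.viruses)

    def find_host(self, spacers: tuple[int, ...]) -> Optional[int]:
        """Index of the live host strain with this exact ordered locus, if any."""
        return self._host_index.get(tuple(spacers))

    def densities(self) -> np.ndarray:
        """Concatenated [N, V] vector (copy)."""
        return np.concatenate([self.N, self.V])

    def set_densities(self, y: np.ndarray) -> None:
        nh = self.n_hosts
        self.N = np.asarray(y[:nh], dtype=float).copy()
        self.V = np.asarray(y[nh:], dtype=float).copy()

    # -- strain edits --------------------------------------------------------

    def add_host(self, strain: HostStrain, density: float) -> None:
        row = np.fromiter(
            (immune(strain.spacer_set, v.protospacer_set) for v in self.viruses),
            dtype=float,
            count=self.n_viruses,
        )
        self._host_index[strain.spacers] = len(self.hosts)
        self.hosts.append(strain)
        self.N = np.append(self.N, density)
        self.M = np.vstack([self.M, row[None, :]])
        self._invalidate()

    def add_virus(self, strain: ViralStrain, density: float) -> None:
        col = np.fromiter(
            (immune(h.spacer_set, strain.protospacer_set) for h in self.hosts),
            dtype=float,
            count=self.n_hosts,
        )
        self.viruses.append(strain)
        self.V = np.append(self.V, density)
        self.M = np.hstack([self.M, col[:, None]])
        self._invalidate()

    def remove_host(self, i: int, time: float) -> HostStrain:
        strain = self.hosts.pop(i)
        strain.death_time = time
        del self._host_index[strain.spacers]
        for k in range(i, len(self.hosts)):
            self._host_index[self.hosts[k].spacers] = k
        self.N = np.delete(self.N, i)
        self.M = np.delete(self.M, i, axis=0)
        self._invalidate()
        return strain

    def remove_virus(self, j: int, time: float) -> ViralStrain:
        strain = self.viruses.pop(j)
        strain.death_time = time
        self.V = np.delete(self.V, j)
        self.M = np.delete(self.M, j, axis=1)
        self._invalidate()
        return strain
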