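"""Genotype spaces for CRISPR hosts and viruses, and the matching rule.

A host carries an ordered CRISPR locus of up to ``u_max`` spacers, newest
first.  A virus carries a fixed-length tuple of ``v`` protospacers.  Alleles
are abstract integers drawn under an infinite-alleles model: every undirected
mutation introduces an identifier never seen before in the simulation.
Because a single base-pair mismatch is assumed to abolish CRISPR
interference, exact equality of integer identifiers is equivalent to exact
sequence match, and partial matches confer nothing.

The two genomic edit operations are:

* spacer acquisition — a protospacer copied from an attacking virus is
  inserted at the leading end of the host locus; when the locus is full the
  trailing (oldest) spacer is dropped, so the locus is a FIFO of capacity
  ``u_max``;
* protospacer mutation — one position of the viral protospacer tuple is
  replaced by a fresh allele; the tuple length never changes.

All genotype values here are plain tuples of ints, treated immutably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AlleleRegistry",
    "MolecularParams",
    "HostStrain",
    "ViralStrain",
    "new_allele",
    "immune",
    "lysis_probability",
    "acquire_spacer",
    "mutate_protospacer",
]

#: Default CRISPR locus capacity (spacers per host).
DEFAULT_U_MAX = 8
#: Default protospacer count per viral genome.
DEFAULT_V = 10


class AlleleRegistry:
    """Monotone source of fresh allele identifiers.

    Identifiers are strictly increasing positive integers and are never
    reused, which realizes the infinite-alleles assumption: any allele the
    registry issues is guaranteed to differ from every allele already present
    in any genome of the simulation.
    """

    __slots__ = ("_last",)

    def __init__(self, last_issued: int = 0) -> None:
        self._last = int(last_issued)

    def new_allele(self) -> int:
        """Issue the next allele identifier (strictly greater than all prior)."""
        self._last += 1
        return self._last

    @property
    def last_issued(self) -> int:
        return self._last

    def __repr__(self) -> str:  # pragma: no cover
        return f"AlleleRegistry(last_issued={self._last})"


def new_allele(registry: AlleleRegistry) -> int:
    """Functional alias for :meth:`AlleleRegistry.new_allele`."""
    return registry.new_allele()


@dataclass(frozen=True)
class MolecularParams:
    """Error probabilities of the CRISPR interference/acquisition machinery.

    Parameters
    ----------
    p
        Probability that interference fails against a matched virus
        (the host is lysed despite carrying a matching spacer).
    q
        Probability that a non-immune host survives an infection by
        acquiring a new spacer from the attacking virus.
    """

    p: float = 1e-5
    q: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p", "q"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {val}")


@dataclass
class HostStrain:
    """A host strain: ordered spacer locus plus bookkeeping metadata.

    Strain identity is the ordered spacer tuple (leading end first); two live
    host strains never share a locus.
    """

    strain_id: int
    spacers: tuple[int, ...]
    parent_id: Optional[int] = None
    birth_time: float = 0.0
    death_time: Optional[float] = None
    #: cached set view of the locus, for O(min(u, v)) immunity checks
    spacer_set: frozenset[int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.spacers = tuple(self.spacers)
        self.spacer_set = frozenset(self.spacers)


@dataclass
class ViralStrain:
    """A viral strain: fixed-length protospacer tuple plus metadata."""

    strain_id: int
    protospacers: tuple[int, ...]
    parent_id: Optional[int] = None
    birth_time: float = 0.0
    death_time: Optional[float] = None
    protospacer_set: frozenset[int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.protospacers = tuple(self.protospacers)
        self.protospacer_set = frozenset(self.protospacers)


def immune(spacers, protospacers) -> int:
    """CRISPR match indicator M(S, G).

    Returns 1 if at least one spacer of the host exactly matches a
    protospacer of the virus (position-independent), else 0.  An empty locus
    is never immune.
    """
    s = spacers if isinstance(spacers, frozenset) else frozenset(spacers)
    g = protospacers if isinstance(protospacers, frozenset) else frozenset(protospacers)
    return 1 if s & g else 0


def lysis_probability(spacers, protospacers, params: MolecularParams) -> float:
    """Probability that an adsorption of this virus on this host ends in lysis.

    Immune pairs are lysed only through stochastic interference failure
    (probability ``p``); non-immune pairs are lysed unless the host survives
    by acquiring a spacer (probability ``1 - q``).  The complementary
    probability is the host's defense probability.
    """
    return params.p if immune(spacers, protospacers) else 1.0 - params.q


def acquire_spacer(
    spacers: tuple[int, ...], allele: int, u_max: int = DEFAULT_U_MAX
) -> tuple[int, ...]:
    """Insert ``allele`` at the leading end of a spacer locus.

    If the locus already holds ``u_max`` spacers, the trailing (oldest)
    spacer is dropped so the length stays at ``u_max``.  The input tuple is
    not modified.
    """
    new = (allele,) + tuple(spacers)
    return new[:u_max]


def mutate_protospacer(
    genome: tuple[int, ...], position: int, allele: int
) -> tuple[int, ...]:
    """Replace the protospacer at 0-based ``position`` with ``allele``.

    The genome length never changes.  When ``allele`` is freshly issued by
    the registry the result is guaranteed to differ from every existing
    viral genotype.
    """
    if not 0 <= position < len(genome):
        raise IndexError(
            f"protospacer position {position} out of range for genome of length {len(genome)}"
        )
    g = list(genome)
    g[position] = allele
    return tuple(g)
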