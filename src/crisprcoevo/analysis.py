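"""Post-hoc community analyses of simulation records.

* Morisita-Horn similarity between community snapshots, and the full
  time-by-time similarity matrix used to visualize strain turnover;
* positional relative immunity: how much of the viral population the newest
  ``n`` spacers of the host community recognize, relative to full loci;
* strain summaries: counts, total densities, lifetimes, and Muller-style
  proportion tables;
* sensitivity summaries over a grid of the molecular error rates (p, q).

All functions consume :class:`~crisprcoevo.simulator.SimulationRecord`
objects (in memory or re-read from disk) and return pandas/numpy containers.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .simulator import SimulationRecord, Snapshot

__all__ = [
    "morisita_horn",
    "similarity_matrix",
    "relative_immunity",
    "relative_immunity_profile",
    "ensemble_immunity_profile",
    "saturation_time",
    "fraction_virus_recognized",
    "strain_summaries",
    "proportion_table",
    "pq_sweep_summary",
]


# ---------------------------------------------------------------------------
# Morisita-Horn similarity
# ---------------------------------------------------------------------------

def morisita_horn(c1: Mapping[int, float], c2: Mapping[int, float]) -> float:
    """Morisita-Horn similarity of two abundance distributions.

    With n_ij the abundance of strain j in community i and N_i the community
    total,

        psi_i = sum_j n_ij^2 / N_i^2
        Psi   = 2 sum_j n_1j n_2j / ((psi_1 + psi_2) N_1 N_2)

    psi_i is the probability that two randomly chosen individuals of
    community i belong to the same strain.  Psi is symmetric, equals 1 iff
    the two communities have identical composition and relative abundances,
    0 iff their strain sets are disjoint, and is invariant under rescaling
    either community by a positive constant — so per-mL densities can be
    used directly as abundances.
    """
    if not c1 or not c2:
        raise ValueError("Morisita-Horn similarity is undefined for an empty community")
    N1 = sum(c1.values())
    N2 = sum(c2.values())
    if N1 <= 0 or N2 <= 0:
        raise ValueError("community abundances must sum to a positive total")
    psi1 = sum(x * x for x in c1.values()) / (N1 * N1)
    psi2 = sum(x * x for x in c2.values()) / (N2 * N2)
    cross = sum(x * c2[j] for j, x in c1.items() if j in c2)
    return 2.0 * cross / ((psi1 + psi2) * N1 * N2)


def _snapshot_abundances(snap: Snapshot, kind: str) -> Mapping[int, float]:
    if kind == "host":
        return dict(zip(snap.host_ids, snap.host_densities))
    if kind == "virus":
        return dict(zip(snap.virus_ids, snap.virus_densities))
    raise ValueError(f"kind must be 'host' or 'virus', got {kind!r}")


def similarity_matrix(
    record: SimulationRecord,
    kind: str = "host",
    interval: float | None = None,
) -> pd.DataFrame:
    """Pairwise Morisita-Horn matrix over the record's snapshot grid.

    ``interval`` subsamples the grid to (approximately) that spacing in
    hours; None keeps every snapshot.  Snapshots where the community is
    empty are dropped.  The result has unit diagonal and is symmetric, with
    snapshot times as index and columns.
    """
    snaps = [s for s in record.snapshots if _snapshot_abundances(s, kind)]
    if interval is not None:
        kept, next_t = [], -math.inf
        for s in snaps:
            if s.t >= next_t:
                kept.append(s)
                next_t = s.t + interval * (1 - 1e-9)
        snaps = kept
    if len(snaps) < 2:
        raise ValueError("need at least two non-empty snapshots")
    ids: dict[int, int] = {}
    rows, cols, vals = [], [], []
    for i, s in enumerate(snaps):
        for sid, dens in _snapshot_abundances(s, kind).items():
            col = ids.setdefault(sid, len(ids))
            rows.append(i)
            cols.append(col)
            vals.append(dens)
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(snaps), len(ids)))
    totals = np.asarray(A.sum(axis=1)).ravel()
    cross = (A @ A.T).toarray()
    psi = cross.diagonal() / totals**2
    denom = np.add.outer(psi, psi) * np.outer(totals, totals)
    psi_mat = 2.0 * cross / denom
    np.fill_diagonal(psi_mat, 1.0)
    times = [s.t for s in snaps]
    return pd.DataFrame(psi_mat, index=times, columns=times)


# ---------------------------------------------------------------------------
# Positional relative immunity
# ---------------------------------------------------------------------------

def _live_genotypes(record: SimulationRecord, snap: Snapshot):
    gen = record.genealogy
    host_loci = [tuple(gen[i]["alleles"]) for i in snap.host_ids]
    viral_genomes = [frozenset(gen[j]["alleles"]) for j in snap.virus_ids]
    return host_loci, viral_genomes


def saturation_time(record: SimulationRecord, u_max: int | None = None) -> float:
    """First snapshot time at which every live host locus holds u_max spacers.

    Raises ``ValueError`` when saturation is never reached in the record.
    """
    if u_max is None:
        u_max = record.config.u_max if record.config is not None else 8
    for snap in record.snapshots:
        if not snap.host_ids:
            continue
        loci, _ = _live_genotypes(record, snap)
        if all(len(s) == u_max for s in loci):
            return snap.t
    raise ValueError("no snapshot with all host loci at full capacity")


def _match_levels(
    host_loci: Sequence[tuple[int, ...]], viral_genomes: Sequence[frozenset[int]]
) -> np.ndarray:
    """For each virus, the smallest n such that the union of the leading n
    spacers over all hosts contains one of its protospacers (inf if none)."""
    min_pos: dict[int, int] = {}
    for locus in host_loci:
        for k, allele in enumerate(locus, start=1):
            if min_pos.get(allele, k + 1) > k:
                min_pos[allele] = k
    out = np.empty(len(viral_genomes))
    for j, genome in enumerate(viral_genomes):
        out[j] = min((min_pos.get(g, math.inf) for g in genome), default=math.inf)
    return out


def _snapshot_immunity(
    record: SimulationRecord, snap: Snapshot, u_max: int, weighting: str
) -> np.ndarray | None:
    """Density-weighted immunity of the community at spacer depths 1..u_max.

    Returns None for snapshots where either community is empty.
    """
    if not snap.host_ids or not snap.virus_ids:
        return None
    host_loci, viral_genomes = _live_genotypes(record, snap)
    V = snap.virus_densities
    Vtot = V.sum()
    if weighting == "union":
        levels = _match_levels(host_loci, viral_genomes)
        imm = np.zeros(u_max)
        for n in range(1, u_max + 1):
            imm[n - 1] = V[levels <= n].sum() / Vtot
        return imm
    if weighting == "host":
        # host-density-weighted per-strain immunity, for comparison
        N = snap.host_densities
        Ntot = N.sum()
        imm = np.zeros(u_max)
        for i, locus in enumerate(host_loci):
            levels = _match_levels([locus], viral_genomes)
            for n in range(1, u_max + 1):
                imm[n - 1] += (N[i] / Ntot) * V[levels <= n].sum() / Vtot
        return imm
    raise ValueError(f"weighting must be 'union' or 'host', got {weighting!r}")


def relative_immunity_profile(
    record: SimulationRecord,
    u_max: int | None = None,
    weighting: str = "union",
) -> pd.Series:
    """Mean relative immunity by leading-spacer count n = 1..u_max.

    For each post-saturation snapshot, immunity(n) is the fraction of the
    viral population (density-weighted) recognized by the union of the
    leading n spacers over all live hosts; the relative value normalizes by
    immunity(u_max).  Snapshots where the full locus recognizes nothing are
    skipped.  The profile is averaged over all post-saturation snapshots and
    is non-decreasing in n with value 1 at n = u_max by construction.
    """
    if u_max is None:
        u_max = record.config.u_max if record.config is not None else 8
    t_sat = saturation_time(record, u_max)
    profiles = []
    for snap in record.snapshots:
        if snap.t < t_sat:
            continue
        imm = _snapshot_immunity(record, snap, u_max, weighting)
        if imm is None or imm[-1] <= 0:
            continue
        profiles.append(imm / imm[-1])
    if not profiles:
        raise ValueError("no usable post-saturation snapshot in record")
    mean = np.mean(profiles, axis=0)
    return pd.Series(mean, index=pd.RangeIndex(1, u_max + 1, name="n"), name="relative_immunity")


def relative_immunity(
    record: SimulationRecord,
    n: int,
    u_max: int | None = None,
    weighting: str = "union",
) -> float:
    """Mean relative immunity of the newest ``n`` spacers (scalar entry)."""
    profile = relative_immunity_profile(record, u_max=u_max, weighting=weighting)
    return float(profile.loc[n])


def ensemble_immunity_profile(
    records: Sequence[SimulationRecord],
    u_max: int | None = None,
    weighting: str = "union",
) -> pd.DataFrame:
    """Across-replicate mean and standard deviation of the immunity profile.

    Replicates that never reach locus saturation are skipped; at least one
    must remain.
    """
    profiles = []
    for rec in records:
        try:
            profiles.append(relative_immunity_profile(rec, u_max, weighting))
        except ValueError:
            continue
    if not profiles:
        raise ValueError("no replicate reached locus saturation")
    mat = pd.concat(profiles, axis=1)
    return pd.DataFrame(
        {
            "mean": mat.mean(axis=1),
            "sd": mat.std(axis=1, ddof=1) if mat.shape[1] > 1 else 0.0,
            "n_replicates": mat.shape[1],
        }
    )


def fraction_virus_recognized(record: SimulationRecord, snap: Snapshot) -> float:
    """Density-weighted fraction of the viral population matched by any
    spacer of any live host at this snapshot."""
    if not snap.host_ids or not snap.virus_ids:
        return 0.0
    host_loci, viral_genomes = _live_genotypes(record, snap)
    spacer_union = set().union(*map(set, host_loci)) if host_loci else set()
    V = snap.virus_densities
    matched = np.fromiter(
        (bool(g & spacer_union) for g in viral_genomes), dtype=bool, count=len(viral_genomes)
    )
    return float(V[matched].sum() / V.sum())


# ---------------------------------------------------------------------------
# Strain summaries
# ---------------------------------------------------------------------------

def strain_summaries(record: SimulationRecord) -> dict[str, pd.DataFrame]:
    """Strain counts, total densities, lifetimes, and proportion tables.

    Returns a dict with keys:

    * ``counts`` — per snapshot: time, live strain counts and total
      densities of hosts and viruses;
    * ``lifetimes`` — per strain: kind, birth/death times, lifetime
      (censored at the final record time when still alive);
    * ``host_proportions`` / ``virus_proportions`` — long tables of the
      strains comprising at least 1% of their population per snapshot.
    """
    counts = pd.DataFrame(
        {
            "time": [s.t for s in record.snapshots],
            "n_host_strains": [len(s.host_ids) for s in record.snapshots],
            "n_virus_strains": [len(s.virus_ids) for s in record.snapshots],
            "host_density": [s.host_densities.sum() for s in record.snapshots],
            "virus_density": [s.virus_densities.sum() for s in record.snapshots],
        }
    )
    rows = []
    for sid, entry in record.genealogy.items():
        death = entry["death_time"]
        censored = death is None
        end = record.t_end if censored else death
        rows.append(
            {
                "strain_id": sid,
                "kind": entry["kind"],
                "birth_time": entry["birth_time"],
                "death_time": death,
                "lifetime": end - entry["birth_time"],
                "censored": censored,
            }
        )
    lifetimes = pd.DataFrame(rows)
    return {
        "counts": counts,
        "lifetimes": lifetimes,
        "host_proportions": proportion_table(record, "host"),
        "virus_proportions": proportion_table(record, "virus"),
    }


def proportion_table(
    record: SimulationRecord, kind: str = "host", min_fraction: float = 0.01
) -> pd.DataFrame:
    """Muller-plot-ready long table: time, strain_id, proportion.

    Only strains comprising at least ``min_fraction`` of their population at
    a snapshot are included for that snapshot.
    """
    rows = []
    for snap in record.snapshots:
        ab = _snapshot_abundances(snap, kind)
        total = sum(ab.values())
        if total <= 0:
            continue
        for sid, dens in ab.items():
            frac = dens / total
            if frac >= min_fraction:
                rows.append({"time": snap.t, "strain_id": sid, "proportion": frac})
    return pd.DataFrame(rows, columns=["time", "strain_id", "proportion"])


# ---------------------------------------------------------------------------
# p-q sensitivity sweep
# ---------------------------------------------------------------------------

def _record_summary(record: SimulationRecord, window: float = 0.5) -> dict[str, float]:
    """Time-averaged summary over the trailing ``window`` fraction of the
    configured horizon.

    A run that terminated early (a guild went extinct) is extended over the
    remaining window at its absorbing state: the extinct guild contributes
    zero density and zero strains, the surviving guild its final snapshot.
    ``fraction_recognized`` averages over realized snapshots only (it is
    undefined without viruses).
    """
    snaps = record.snapshots
    horizon = record.config.t_max if record.config is not None else record.t_end
    dt = record.config.output_interval if record.config is not None else 1.0
    t0 = horizon * (1.0 - window)
    tail = [s for s in snaps if s.t >= t0] or snaps[-1:]
    host_d = [s.host_densities.sum() for s in tail]
    virus_d = [s.virus_densities.sum() for s in tail]
    n_host = [len(s.host_ids) for s in tail]
    n_virus = [len(s.virus_ids) for s in tail]
    n_pad = max(0, int(round((horizon - record.t_end) / dt)))
    if n_pad:
        last = snaps[-1]
        hosts_gone = record.termination == "hosts_extinct"
        viruses_gone = record.termination != "t_max"  # either guild extinct ends the run
        host_d += [0.0 if hosts_gone else last.host_densities.sum()] * n_pad
        n_host += [0 if hosts_gone else len(last.host_ids)] * n_pad
        virus_d += [0.0 if viruses_gone else last.virus_densities.sum()] * n_pad
        n_virus += [0 if viruses_gone else len(last.virus_ids)] * n_pad
    return {
        "host_density": float(np.mean(host_d)),
        "virus_density": float(np.mean(virus_d)),
        "n_host_strains": float(np.mean(n_host)),
        "n_virus_strains": float(np.mean(n_virus)),
        "fraction_recognized": float(
            np.mean([fraction_virus_recognized(record, s) for s in tail])
        ),
    }


def pq_sweep_summary(
    ensembles: Mapping[tuple[float, float], Sequence[SimulationRecord]],
    window: float = 0.5,
) -> pd.DataFrame:
    """Median (and standard error) summaries per (p, q) parameter cell.

    ``ensembles`` maps (p, q) to its replicate records.  Each replicate is
    summarized by time averages over the trailing ``window`` fraction of the
    run; medians and standard errors are taken across replicates.
    """
    rows = []
    for (p, q), records in sorted(ensembles.items()):
        if len(records) < 2:
            raise ValueError(f"cell (p={p}, q={q}) needs at least 2 replicates")
        per_rep = pd.DataFrame([_record_summary(r, window) for r in records])
        row: dict[str, float] = {"p": p, "q": q, "n_replicates": len(records)}
        for col in per_rep.columns:
            row[f"{col}_median"] = float(per_rep[col].median())
            row[f"{col}_se"] = float(per_rep[col].std(ddof=1) / math.sqrt(len(records)))
        rows.append(row)
    return pd.DataFrame(rows).set_index(["p", "q"])
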