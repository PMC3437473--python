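"""On-disk record format: TSV densities, JSONL genealogy/events, JSON meta.

A record directory contains:

* ``hosts.tsv`` / ``viruses.tsv`` — long format, columns exactly
  (time, strain_id, density), floats at 12 significant digits;
* ``genealogy.jsonl`` — one strain per line:
  {"strain_id", "kind", "parent_id", "birth_time", "death_time",
  "alleles": [ints, leading end first]};
* ``events.jsonl`` — chronological event log;
* ``meta.json`` — config echo, termination reason, end time, version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import config_from_dict, config_to_dict
from .simulator import SimulationRecord, Snapshot

__all__ = ["write_record", "read_record"]

_FLOAT_FMT = "%.12g"


def _densities_frame(record: SimulationRecord, kind: str) -> pd.DataFrame:
    rows = []
    for snap in record.snapshots:
        ids = snap.host_ids if kind == "host" else snap.virus_ids
        dens = snap.host_densities if kind == "host" else snap.virus_densities
        for sid, d in zip(ids, dens):
            rows.append((snap.t, sid, d))
    return pd.DataFrame(rows, columns=["time", "strain_id", "density"])


def write_record(record: SimulationRecord, outdir: str | Path) -> Path:
    """Write a record directory (created if needed); returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, fname in (("host", "hosts.tsv"), ("virus", "viruses.tsv")):
        _densities_frame(record, kind).to_csv(
            outdir / fname, sep="\t", index=False, float_format=_FLOAT_FMT
        )
    with open(outdir / "genealogy.jsonl", "w") as fh:
        for sid in sorted(record.genealogy):
            entry = record.genealogy[sid]
            fh.write(json.dumps({"strain_id": sid, **entry}) + "\n")
    with open(outdir / "events.jsonl", "w") as fh:
        for ev in record.events:
            fh.write(json.dumps(ev) + "\n")
    meta = {
        "version": __version__,
        "termination": record.termination,
        "t_end": record.t_end,
        "config": config_to_dict(record.config) if record.config else None,
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return outdir


def _snapshots_from_frames(hosts: pd.DataFrame, viruses: pd.DataFrame) -> list[Snapshot]:
    times = sorted(set(hosts["time"]).union(viruses["time"]))
    hg = {t: g for t, g in hosts.groupby("time", sort=False)}
    vg = {t: g for t, g in viruses.groupby("time", sort=False)}
    snaps = []
    empty = pd.DataFrame(columns=["strain_id", "density"])
    for t in times:
        h = hg.get(t, empty)
        v = vg.get(t, empty)
        snaps.append(
            Snapshot(
                t=float(t),
                host_ids=tuple(int(x) for x in h["strain_id"]),
                host_densities=np.asarray(h["density"], dtype=float),
                virus_ids=tuple(int(x) for x in v["strain_id"]),
                virus_densities=np.asarray(v["density"], dtype=float),
            )
        )
    return snaps


def read_record(indir: str | Path) -> SimulationRecord:
    """Read a record directory written by :func:`write_record`.

    Densities round-trip to the written 12-significant-digit precision.
    """
    indir = Path(indir)
    for fname in ("hosts.tsv", "viruses.tsv", "genealogy.jsonl", "meta.json"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"record directory {indir} is missing {fname}")
    hosts = pd.read_csv(indir / "hosts.tsv", sep="\t")
    viruses = pd.read_csv(indir / "viruses.tsv", sep="\t")
    genealogy = {}
    with open(indir / "genealogy.jsonl") as fh:
        for line in fh:
            entry = json.loads(line)
            sid = entry.pop("strain_id")
            entry["alleles"] = [int(a) for a in entry["alleles"]]
            genealogy[sid] = entry
    events = []
    events_path = indir / "events.jsonl"
    if events_path.exists():
        with open(events_path) as fh:
            events = [json.loads(line) for line in fh]
    with open(indir / "meta.json") as fh:
        meta = json.load(fh)
    config = config_from_dict(meta["config"]) if meta.get("config") else None
    return SimulationRecord(
        snapshots=_snapshots_from_frames(hosts, viruses),
        genealogy=genealogy,
        events=events,
        termination=meta["termination"],
        t_end=float(meta["t_end"]),
        config=config,
    )
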