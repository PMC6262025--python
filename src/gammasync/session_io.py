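"""Session file I/O: HDF5 LFP stores, TSV spike tables, CSV event tables,
YAML scenario sidecars, and the run manifest.

Directory layout written by :func:`write_session` and expected by
:func:`read_session`::

    session_dir/
      lfp.h5          datasets /V1 and /dLGN with attrs fs, t0, region
      spikes.tsv      columns region, unit_id, time_s
      events.csv      columns onset_s, condition, duration_s
      scenario.yaml   ground-truth CouplingScenario (optional)

A CSV fallback (``lfp_<region>.csv`` with an fs/t0 header comment) is
written when ``lfp_format='csv'``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (EventTable, LfpSignal, ParameterError,
                   SpikeTrain)
from .synthio import CouplingScenario, SyntheticSession

LFP_H5 = "lfp.h5"
SPIKES_TSV = "spikes.tsv"
EVENTS_CSV = "events.csv"
SCENARIO_YAML = "scenario.yaml"


def write_session(session: SyntheticSession, out_dir: str | Path,
                  lfp_format: str = "hdf5") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if lfp_format == "hdf5":
        import h5py

        with h5py.File(out / LFP_H5, "w") as f:
            for lfp in (session.lfp_v1, session.lfp_lgn):
                d = f.create_dataset(lfp.region, data=lfp.samples)
                d.attrs["fs"] = lfp.fs
                d.attrs["t0"] = lfp.t0
                d.attrs["region"] = lfp.region
    elif lfp_format == "csv":
        for lfp in (session.lfp_v1, session.lfp_lgn):
            path = out / f"lfp_{lfp.region}.csv"
            with open(path, "w") as fh:
                fh.write(f"# fs={lfp.fs} t0={lfp.t0} region={lfp.region}\n")
                fh.write("voltage\n")
                np.savetxt(fh, lfp.samples, fmt="%.9g")
    else:
        raise ParameterError(f"unknown lfp_format {lfp_format!r}")

    rows = []
    for train in session.spikes_v1 + session.spikes_lgn:
        for t in train.times:
            rows.append((train.region, train.unit_id, t))
    pd.DataFrame(rows, columns=["region", "unit_id", "time_s"]).to_csv(
        out / SPIKES_TSV, sep="\t", index=False, float_format="%.6f")

    session.events.to_csv(out / EVENTS_CSV)
    with open(out / SCENARIO_YAML, "w") as fh:
        yaml.safe_dump(session.truth.to_dict(), fh, sort_keys=True)
    return out


def _read_lfp_h5(path: Path) -> dict[str, LfpSignal]:
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            d = f[name]
            if "fs" not in d.attrs:
                raise ParameterError(
                    f"LFP dataset {name!r} is missing the fs attribute")
            out[name] = LfpSignal(d[:], fs=float(d.attrs["fs"]),
                                  t0=float(d.attrs.get("t0", 0.0)),
                                  region=str(d.attrs.get("region", name)))
    return out


def _read_lfp_csv(path: Path) -> LfpSignal:
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ParameterError(f"{path.name} lacks the '# fs=... t0=...' header")
    meta = dict(tok.split("=") for tok in header[1:].split())
    samples = np.loadtxt(path, skiprows=2)
    return LfpSignal(samples, fs=float(meta["fs"]), t0=float(meta["t0"]),
                     region=meta.get("region", "V1"))


def read_spike_tsv(path: str | Path) -> dict[str, list[SpikeTrain]]:
    """Read a spike table, validating per-unit ordering and sign.

    Returns trains grouped by region.  Malformed rows are reported with
    their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("region", "unit_id", "time_s"):
        if col not in df.columns:
            raise ParameterError(f"spike table missing column {col!r}")
    neg = df.index[df["time_s"] < 0]
    if len(neg):
        raise ParameterError(
            f"negative spike time at line {int(neg[0]) + 2} of "
            f"{Path(path).name}")
    out: dict[str, list[SpikeTrain]] = {}
    for (region, unit), g in df.groupby(["region", "unit_id"], sort=True):
        t = g["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad_pos = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            line = int(g.index[bad_pos]) + 2
            raise ParameterError(
                f"spike times of unit {unit!r} not strictly ascending "
                f"(line {line})")
        out.setdefault(str(region), []).append(
            SpikeTrain(t, region=str(region), unit_id=str(unit)))
    return out


@dataclass
class SessionBundle:
    """A validated, fully loaded session ready for the pipeline."""

    lfp_v1: LfpSignal
    lfp_lgn: LfpSignal
    spikes_v1: list[SpikeTrain]
    spikes_lgn: list[SpikeTrain]
    events: EventTable
    truth: CouplingScenario | None = None
    source_dir: Path | None = None

    @property
    def span(self) -> tuple[float, float]:
        return (self.lfp_v1.t0, self.lfp_v1.t0 + self.lfp_v1.duration)


def read_session(session_dir: str | Path) -> SessionBundle:
    """Load and validate a session directory written by
    :func:`write_session` (or user files matching the same schema)."""
    d = Path(session_dir)
    if (d / LFP_H5).exists():
        lfps = _read_lfp_h5(d / LFP_H5)
    else:
        lfps = {}
        for region in ("V1", "dLGN"):
            p = d / f"lfp_{region}.csv"
            if not p.exists():
                raise ParameterError(
                    f"no LFP store found in {d} (neither {LFP_H5} nor "
                    f"lfp_<region>.csv)")
            lfps[region] = _read_lfp_csv(p)
    for region in ("V1", "dLGN"):
        if region not in lfps:
            raise ParameterError(f"LFP store lacks region {region!r}")

    spikes = read_spike_tsv(d / SPIKES_TSV)
    events = EventTable.from_csv(d / EVENTS_CSV)

    truth = None
    if (d / SCENARIO_YAML).exists():
        with open(d / SCENARIO_YAML) as fh:
            truth = CouplingScenario.from_dict(yaml.safe_load(fh))

    span = (lfps["V1"].t0, lfps["V1"].t0 + lfps["V1"].duration)
    fixed = {
        r: [SpikeTrain(t.times, t.region, t.unit_id, span)
            for t in spikes.get(r, [])]
        for r in ("V1", "dLGN")
    }
    if not fixed["V1"] or not fixed["dLGN"]:
        raise ParameterError("spike table must contain V1 and dLGN units")
    return SessionBundle(lfp_v1=lfps["V1"], lfp_lgn=lfps["dLGN"],
                         spikes_v1=fixed["V1"], spikes_lgn=fixed["dLGN"],
                         events=events, truth=truth, source_dir=d)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration tree."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of a pipeline run.

    Timestamps are deliberately kept out of this record (they live in the
    run log) so that identical inputs and seed give byte-identical output
    files.
    """

    tool_version: str
    config_hash: str
    seed: int
    input_checksums: dict = field(default_factory=dict)
    stage_seeds: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    stale: bool = True

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
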