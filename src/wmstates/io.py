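"""Session bundles on disk.

A session is a directory with three columnar tables —
``spikes.(csv|parquet)``, ``trials.(csv|parquet)``, ``units.(csv|parquet)``
— plus ``session.json`` carrying the epoch specification and generator
provenance (including synthetic ground truth when present).  Format is
auto-detected from the file extension.  Cue locations from the
120-location task variant are grouped to the 8 canonical angles on read.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSpec, SpikeDataset, group_to_canonical


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG substream of a global seed.

    Adding a stage never perturbs another stage's randomness because each
    stage draws from its own stream keyed by (seed, stage name).
    """
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_session(ds: SpikeDataset, path: str | Path, fmt: str = "csv") -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in (("spikes", ds.spikes), ("trials", ds.trials), ("units", ds.units)):
        if fmt == "csv":
            df.to_csv(path / f"{name}.csv", index=False)
        elif fmt == "parquet":
            df.to_parquet(path / f"{name}.parquet", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    meta = {"epochs": ds.epochs.as_dict(), "meta": ds.meta}
    (path / "session.json").write_text(json.dumps(meta, default=_json_default, indent=1))
    return path


def _read_table(path: Path, name: str) -> pd.DataFrame:
    for ext, reader in ((".csv", pd.read_csv), (".parquet", pd.read_parquet)):
        f = path / f"{name}{ext}"
        if f.exists():
            return reader(f)
    raise FileNotFoundError(f"{name}.csv or {name}.parquet not found in {path}")


def read_session(path: str | Path) -> SpikeDataset:
    path = Path(path)
    spikes = _read_table(path, "spikes")
    trials = _read_table(path, "trials")
    units = _read_table(path, "units")
    meta_file = path / "session.json"
    epochs = EpochSpec()
    meta: dict = {}
    if meta_file.exists():
        raw = json.loads(meta_file.read_text())
        ep = raw.get("epochs", {})
        if ep:
            epochs = EpochSpec(**{k: tuple(v) for k, v in ep.items()})
        meta = raw.get("meta", {})
    trials = trials.copy()
    trials["cue_location_deg"] = group_to_canonical(trials["cue_location_deg"].to_numpy())
    return SpikeDataset(spikes, trials, units, epochs=epochs, meta=meta).validate()
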