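"""File-format contracts: per-batch CSV/JSON layout and run manifests.

Each batch lives in its own directory:

* ``online.csv`` — raw telemetry: time_day, ph, do_pct, temp_c, base_ml,
  o2_flow, co2_flow (15-minute cadence for simulated data);
* ``offline.csv`` — sampling log: day_dpi, vcd, lactate_mM, ammonia_mM,
  glucose_residual_mM, glucose_postfeed_mM, titer_mgL;
* ``meta.json`` — identifiers, day grid and (simulated batches) the
  noise-free truth.

Reading a batch directory routes through
:func:`fedsense.preprocess.assemble_batch`, so files and in-memory records
are interchangeable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batch import BatchRecord
from .preprocess import RAW_CHANNELS, OnlineChannelSeries, assemble_batch

logger = logging.getLogger(__name__)


def write_batch(record: BatchRecord, outdir: str | Path) -> Path:
    """Write one batch directory (online.csv, offline.csv, meta.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if record.raw_online is None:
        raise ValueError(
            f"batch {record.batch_id} has no raw telemetry to write"
        )
    t = record.raw_online["ph"].times
    online = pd.DataFrame({"time_day": t})
    for ch in RAW_CHANNELS:
        series = record.raw_online[ch]
        if not np.array_equal(series.times, t):
            raise ValueError(f"channel {ch} not on the common telemetry grid")
        online[ch] = series.values
    online.to_csv(outdir / "online.csv", index=False)

    from .batch import OFFLINE_VARS

    cols = {"day_dpi": record.sampling_days}
    get = {v: record.offline[np.isin(record.day_grid, record.sampling_days),
                             OFFLINE_VARS.index(v)]
           for v in OFFLINE_VARS}
    cols["vcd"] = get["vcd"]
    cols["lactate_mM"] = get["lactate"]
    cols["ammonia_mM"] = get["ammonia"]
    cols["glucose_residual_mM"] = record.glucose_residual
    cols["glucose_postfeed_mM"] = record.glucose_postfeed
    cols["titer_mgL"] = get["titer"]
    pd.DataFrame(cols).to_csv(outdir / "offline.csv", index=False)

    meta = {
        "batch_id": record.batch_id,
        "pool_id": record.pool_id,
        "passage": record.passage,
        "msx": record.msx,
        "day_grid": record.day_grid.tolist(),
    }
    if record.truth is not None:
        meta["truth"] = {k: np.asarray(v).tolist()
                         for k, v in record.truth.items()}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    logger.info("wrote batch %s to %s (%d telemetry rows, %d samples)",
                record.batch_id, outdir, len(online), len(record.sampling_days))
    return outdir


def read_batch(batch_dir: str | Path) -> BatchRecord:
    """Read a batch directory back through the preprocessing pipeline."""
    batch_dir = Path(batch_dir)
    online = pd.read_csv(batch_dir / "online.csv")
    offline = pd.read_csv(batch_dir / "offline.csv")
    meta = json.loads((batch_dir / "meta.json").read_text())
    t = online["time_day"].to_numpy()
    channels = {
        ch: OnlineChannelSeries(ch, t, online[ch].to_numpy())
        for ch in RAW_CHANNELS
    }
    truth = meta.get("truth")
    if truth is not None:
        truth = {k: np.asarray(v) for k, v in truth.items()}
    logger.info("read batch %s: %d telemetry rows, %d samples",
                meta["batch_id"], len(online), len(offline))
    return assemble_batch(
        channels, offline, np.asarray(meta["day_grid"], dtype=int),
        batch_id=meta["batch_id"], pool_id=meta["pool_id"],
        passage=int(meta.get("passage", 0)), msx=float(meta.get("msx", 50.0)),
        truth=truth,
    )


def write_campaign(batches, split, outdir: str | Path) -> Path:
    """Write a directory of batch subdirectories plus the split file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b in batches:
        write_batch(b, outdir / b.batch_id)
    (outdir / "split.json").write_text(json.dumps(split, indent=1))
    return outdir


def read_campaign(outdir: str | Path):
    outdir = Path(outdir)
    split = json.loads((outdir / "split.json").read_text())
    batches = [read_batch(outdir / bid)
               for bid in sorted(split["train"] + split["test"])]
    return batches, split


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    inputs: list[str | Path],
    seeds: dict,
    outputs: list[str | Path],
) -> Path:
    """Write the run manifest that makes a CLI run reproducible."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "config": config,
        "input_digests": {str(p): file_digest(p) for p in inputs},
        "seeds": seeds,
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def config_to_dict(cfg) -> dict:
    """JSON-serializable snapshot of a dataclass config."""
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
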