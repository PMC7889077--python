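"""Reading and writing spike tables.

A spike table is delimited text (comma by default) with a header row and
columns ``preparation_id, neuron, temperature_C, spike_time_s`` plus an
optional ``epoch_id`` (default ``"e0"``). One row per spike.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import SpikeTrain

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("preparation_id", "neuron", "temperature_C", "spike_time_s")


class SchemaError(ValueError):
    """Input table does not have the expected columns."""


def read_spike_table(path: str | Path, delimiter: str = ",") -> list[SpikeTrain]:
    """Read a spike table into one SpikeTrain per (preparation, neuron, epoch).

    Rows may be in any order; times are sorted per train. Duplicate spike
    times within one train are collapsed with a logged warning (physically
    impossible duplicates are treated as sorting artifacts).

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValueError
        If a time or temperature cannot be parsed (names the row).
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"spike table {path} is missing column {col!r}")
    if "epoch_id" not in df.columns:
        df["epoch_id"] = "e0"
    df["epoch_id"] = df["epoch_id"].fillna("e0")

    for col in ("temperature_C", "spike_time_s"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col} "
                f"at data row {row}")
        # exact strtod conversion: to_numeric's fast path can lose the last ulp
        df[col] = df[col].to_numpy(dtype=float)

    trains: list[SpikeTrain] = []
    grouped = df.groupby(["preparation_id", "neuron", "epoch_id"], sort=True)
    for (prep, neuron, epoch), grp in grouped:
        temps = grp["temperature_C"].unique()
        if len(temps) > 1:
            raise ValueError(
                f"epoch {prep}/{neuron}/{epoch} has multiple temperatures {temps}")
        times = np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        uniq = np.unique(times)
        if uniq.size < times.size:
            log.warning("collapsed %d duplicate spike times in %s/%s/%s",
                        times.size - uniq.size, prep, neuron, epoch)
        trains.append(SpikeTrain(preparation_id=str(prep), neuron=str(neuron),
                                 temperature=float(temps[0]), spike_times=uniq,
                                 epoch_id=str(epoch)))
    return trains


def write_spike_table(trains: Iterable[SpikeTrain], path: str | Path,
                      delimiter: str = ",") -> None:
    """Write trains to a delimited spike table (round-trips with the reader)."""
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append((tr.preparation_id, tr.neuron, tr.temperature,
                         repr(float(t)), tr.epoch_id))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["epoch_id"])
    df.to_csv(path, sep=delimiter, index=False)


def trains_by_key(trains: Iterable[SpikeTrain]) -> dict:
    """Index trains by (preparation_id, neuron, temperature, epoch_id)."""
    out = {}
    for tr in trains:
        k = tr.key()
        if k in out:
            raise ValueError(f"duplicate train key {k}")
        out[k] = tr
    return out
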