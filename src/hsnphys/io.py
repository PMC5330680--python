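"""CSV readers/writers for the assay formats.

All files are RFC 4180 CSV, UTF-8, dot decimal. Units are fixed per format
and carried in the column names:

* events:  ``animal_id,t`` — event times in minutes, strictly increasing
  per animal;
* sweeps:  ``t_ms,V_<mV>,...`` — one current column (µA) per step voltage,
  e.g. ``V_-60``;
* traces:  ``t_s,roi,background`` — fluorescence in AU at a fixed rate;
* stages:  ``genotype,cat1,...,cat7`` — embryo counts over the seven
  ordinal stage categories.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .channel import StepProtocol, SweepSet
from .egglaying import EggTimeline
from .errors import InputError, SchemaError
from .stats import STAGE_CATEGORIES, StageDistribution
from .traces import FluorescenceTrace

__all__ = [
    "read_events",
    "write_events",
    "read_sweeps",
    "write_sweeps",
    "read_traces",
    "write_traces",
    "read_stages",
    "write_stages",
]

logger = logging.getLogger(__name__)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _reject_nan(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if df[c].isna().any():
            row = int(df.index[df[c].isna()][0])
            raise InputError(f"{path}: NaN in column {c!r} at row {row}")


# --- events ------------------------------------------------------------------


def read_events(path) -> list[EggTimeline]:
    """Read per-animal egg-laying event times (minutes)."""
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty events file", path)
        return []
    _require_columns(df, ("animal_id", "t"), path)
    _reject_nan(df, ("t",), path)
    timelines = []
    for animal, grp in df.groupby("animal_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(grp.index[bad[0] + 1])
            raise InputError(
                f"{path}: non-increasing event time for animal {animal!r} at row {row}"
            )
        duration = float(t[-1]) if t.size else 0.0
        timelines.append(EggTimeline(t, duration=max(duration, np.finfo(float).tiny),
                                     animal_id=str(animal)))
    return timelines


def write_events(timelines: list[EggTimeline], path) -> None:
    rows = [
        {"animal_id": tl.animal_id, "t": t}
        for tl in timelines
        for t in tl.event_times
    ]
    pd.DataFrame(rows, columns=["animal_id", "t"]).to_csv(path, index=False)


# --- sweeps ------------------------------------------------------------------


def _voltage_from_label(label: str, path) -> float:
    if not label.startswith("V_"):
        raise SchemaError(f"{path}: sweep column {label!r} must look like 'V_-60'")
    try:
        return float(label[2:])
    except ValueError as exc:
        raise SchemaError(f"{path}: cannot parse voltage from column {label!r}") from exc


def read_sweeps(path, kind: str = "activation", holding: float = -90.0,
                prepulse_duration: float | None = None,
                test_voltage: float | None = None) -> SweepSet:
    """Read a sweep table (t_ms plus one V_<mV> column per step).

    Protocol metadata not stored in the file (kind, holding, prepulse) is
    supplied by the caller; steps and sampling come from the table itself.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("t_ms",), path)
    vcols = [c for c in df.columns if c != "t_ms"]
    if not vcols:
        raise SchemaError(f"{path}: no sweep columns (expected V_<mV>)")
    _reject_nan(df, df.columns, path)
    steps = tuple(_voltage_from_label(c, path) for c in vcols)
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError(f"{path}: need at least 2 samples")
    dt = float(np.median(np.diff(t)))
    protocol = StepProtocol(
        kind=kind,
        holding=holding,
        steps=steps,
        step_duration=float(t[-1]) + dt,
        sample_interval=dt,
        prepulse_duration=prepulse_duration,
        test_voltage=test_voltage,
    )
    currents = df[vcols].to_numpy(dtype=float).T
    return SweepSet(protocol=protocol, time=t, currents=currents)


def write_sweeps(sweeps: SweepSet, path) -> None:
    data = {"t_ms": sweeps.time}
    for v, row in zip(sweeps.protocol.steps, sweeps.currents):
        data[f"V_{v:g}"] = row
    pd.DataFrame(data).to_csv(path, index=False)


# --- traces ------------------------------------------------------------------


def read_traces(path) -> FluorescenceTrace:
    """Read a fluorescence trace (t_s, roi, background)."""
    df = pd.read_csv(path)
    _require_columns(df, ("t_s", "roi", "background"), path)
    _reject_nan(df, ("t_s", "roi", "background"), path)
    t = df["t_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InputError(f"{path}: need at least 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise InputError(f"{path}: time column must be increasing")
    return FluorescenceTrace(
        sample_rate=1.0 / dt,
        roi=df["roi"].to_numpy(dtype=float),
        background=df["background"].to_numpy(dtype=float),
    )


def write_traces(trace: FluorescenceTrace, path) -> None:
    pd.DataFrame(
        {"t_s": trace.times(), "roi": trace.roi, "background": trace.background}
    ).to_csv(path, index=False)


# --- stages ------------------------------------------------------------------

_STAGE_COLS = tuple(f"cat{i}" for i in range(1, len(STAGE_CATEGORIES) + 1))


def read_stages(path) -> dict[str, StageDistribution]:
    """Read per-genotype embryo stage counts."""
    df = pd.read_csv(path)
    _require_columns(df, ("genotype",) + _STAGE_COLS, path)
    _reject_nan(df, _STAGE_COLS, path)
    out: dict[str, StageDistribution] = {}
    for _, row in df.iterrows():
        out[str(row["genotype"])] = StageDistribution(
            np.array([int(row[c]) for c in _STAGE_COLS])
        )
    return out


def write_stages(stages: dict[str, StageDistribution], path) -> None:
    rows = []
    for genotype, dist in stages.items():
        row = {"genotype": genotype}
        row.update({c: int(v) for c, v in zip(_STAGE_COLS, dist.counts)})
        rows.append(row)
    pd.DataFrame(rows, columns=("genotype",) + _STAGE_COLS).to_csv(path, index=False)
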