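"""Readers and writers for the pipeline's delimited-text interfaces.

All tabular files are TSV with a header row, UTF-8, "." decimal
separator and empty fields for missing values; nested results are JSON.
Every writer's output is re-parseable by the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import ActivityTrace, Schedule
from .sihumix import PathwayMap, validate_protein_table


def read_activity_long(path, bin_width: int = 1, total_length: int | None = None) -> list[ActivityTrace]:
    """Read a long-format activity table (well_id, time_s, activity).

    ``bin_width`` declares the tracking software's integration period in
    seconds; cumulative per-period activity is spread evenly over 1-s
    bins.  Bins must be contiguous from 0 per well; silent gaps are an
    error (masked bins are declared with empty activity fields and
    become NaN).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"well_id", "time_s", "activity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    traces = []
    for well_id, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("time_s")
        times = sub["time_s"].to_numpy()
        expected = np.arange(len(times)) * bin_width
        if not np.array_equal(times, expected):
            first_bad = int(np.argmax(times != expected[: len(times)]))
            raise ValueError(
                f"{path}: well {well_id} has a silent gap or irregular bins "
                f"near row {sub.index[first_bad]} (time_s={times[first_bad]})"
            )
        values = sub["activity"].to_numpy(dtype=float)
        if bin_width > 1:
            values = np.repeat(values / bin_width, bin_width)
        if total_length is not None and len(values) < total_length:
            raise ValueError(
                f"{path}: well {well_id} covers {len(values)} s, protocol needs {total_length} s"
            )
        traces.append(ActivityTrace(well_id=str(well_id), values=values))
    if not traces:
        raise ValueError(f"{path}: no activity rows")
    return traces


def write_activity_long(traces: list[ActivityTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {"well_id": t.well_id, "time_s": np.arange(len(t.values)), "activity": t.values}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_plate_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "well_id" not in df.columns:
        raise ValueError(f"{path}: plate metadata must be keyed by well_id")
    return df


def write_schedule(schedule: Schedule, path) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def write_endpoint_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True)


def read_endpoint_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="well_id")


def read_protein_table(path) -> pd.DataFrame:
    """Read the long-format protein-intensity TSV (optional ko/pathways)."""
    df = pd.read_csv(path, sep="\t", dtype={"ko": str, "pathways": str})
    for col in ("ko", "pathways"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return validate_protein_table(df)


def write_protein_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pathway_map(path) -> PathwayMap:
    """Two-column TSV (pathway_id, ko_id) of full pathway membership."""
    df = pd.read_csv(path, sep="\t")
    if not {"pathway_id", "ko_id"}.issubset(df.columns):
        raise ValueError(f"{path}: pathway map needs columns pathway_id, ko_id")
    mapping = {
        pw: frozenset(sub["ko_id"]) for pw, sub in df.groupby("pathway_id", observed=True)
    }
    return PathwayMap(pathway_to_kos=mapping)


def write_pathway_map(pmap: PathwayMap, path) -> None:
    rows = [
        {"pathway_id": pw, "ko_id": ko}
        for pw, kos in sorted(pmap.pathway_to_kos.items())
        for ko in sorted(kos)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_run_manifest(path, config: dict, seed: int) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=_json_default)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "vamrstat_version": __version__,
    }
    write_json(manifest, path)
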