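"""Derivation of the 25 per-well behavioral endpoints.

From the raw window summaries produced by :mod:`vamrstat.protocol` this
module derives the endpoint table used for statistical testing: four
baseline intervals (BSL1-4), two visual startles (VSR1/2), five visual
motor response intervals (VMR1-5), three acoustic startle responses
(ASR1-3, each the mean over five stimulus seconds), the inter-stimulus
and inter-endpoint intervals (ISI1-3, IEI1-3), the habituation metrics
(ASH1, ASH1/5, ASHsum), the inter-bout interval (IBI), and the memory
retention ratio (ASR2/3).

Ratio conventions: the three ratio metrics share the "late over
(early + late)" form, so exact symmetry of their two inputs gives 0.5,
complete habituation gives 0, and values live in [0, 1].  An undefined
0/0 ratio is reported as missing (NaN), never coerced to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .protocol import ActivityTrace, Schedule, segment_matrix

#: the 25 statistical endpoints, in stable output order
ENDPOINT_NAMES: tuple[str, ...] = (
    "BSL1", "BSL2", "BSL3", "BSL4",
    "VSR1", "VSR2",
    "VMR1", "VMR2", "VMR3", "VMR4", "VMR5",
    "ASR1", "ASR2", "ASR3",
    "ISI1", "ISI2", "ISI3",
    "IEI1", "IEI2", "IEI3",
    "ASH1", "ASH1/5", "ASHsum", "IBI", "ASR2/3",
)

#: metadata columns appended after the endpoint columns
GROUP_COLUMNS: tuple[str, ...] = ("colonization", "treatment", "concentration", "flask", "group")


def asr_metric(per_stimulus_vector) -> float:
    """Mean startle response over the stimulus seconds of one ASR block."""
    v = np.asarray(per_stimulus_vector, dtype=float)
    if v.size == 0 or np.isnan(v).all():
        return float("nan")
    return float(np.nanmean(v))


def bout_habituation_score(
    bout_vector, expected_length: int = 30, n_edge: int = 10, convention: str = "fraction"
) -> float:
    """Within-bout habituation score from 30 ordered stimulus responses.

    The response total over the final ``n_edge`` stimuli is compared with
    the combined total over the initial and final ``n_edge`` stimuli,
    which normalizes away individual differences in baseline startle
    amplitude.  ``convention="fraction"`` (default) returns
    ``last / (first + last)`` in [0, 1]; ``"ratio_to_combined_mean"``
    returns the mean of the last responses over the mean of the combined
    initial-and-final set, which is exactly twice the fraction.
    """
    v = np.asarray(bout_vector, dtype=float)
    if v.shape != (expected_length,):
        raise ValueError(f"expected {expected_length} stimulus responses, got shape {v.shape}")
    first = np.nansum(v[:n_edge])
    last = np.nansum(v[-n_edge:])
    if first + last == 0:
        return float("nan")
    score = last / (first + last)
    if convention == "ratio_to_combined_mean":
        return float(2.0 * score)
    if convention != "fraction":
        raise ValueError(f"unknown habituation convention {convention!r}")
    return float(score)


def potentiation_ratio(ash1_total: float, ash5_total: float) -> float:
    """Potentiation of habituation: final-bout activity over the summed
    initial- and final-bout activity (ASH1/5)."""
    if ash1_total < 0 or ash5_total < 0:
        raise ValueError("bout activity totals must be non-negative")
    if np.isnan(ash1_total) or np.isnan(ash5_total):
        return float("nan")
    denom = ash1_total + ash5_total
    if denom == 0:
        return float("nan")
    return float(ash5_total / denom)


def ash_sum(bout_totals) -> float:
    """Total motor activity across all habituation bout windows (ASHsum)."""
    v = np.asarray(bout_totals, dtype=float)
    if v.size == 0 or np.isnan(v).any():
        return float("nan")
    return float(v.sum())


def retention_ratio(asr2_mean: float, asr3_mean: float) -> float:
    """Memory retention (ASR2/3): post-habituation startle scaled to the
    combined pre- and post-habituation startle means."""
    if asr2_mean < 0 or asr3_mean < 0:
        raise ValueError("ASR means must be non-negative")
    if np.isnan(asr2_mean) or np.isnan(asr3_mean):
        return float("nan")
    denom = asr2_mean + asr3_mean
    if denom == 0:
        return float("nan")
    return float(asr3_mean / denom)


def _derive_matrix(raw: dict, convention: str) -> dict[str, np.ndarray]:
    """Vectorized endpoint derivation from raw segment summaries."""
    cols: dict[str, np.ndarray] = {}
    for name, means in raw["interval_means"].items():
        cols[name] = means
    for name, vec in raw["stimulus_vectors"].items():
        cols[name] = np.nanmean(vec, axis=1)

    bout = raw["bout_matrix"]  # (wells, bouts, stimuli)
    n_edge = 10
    first = np.nansum(bout[:, 0, :n_edge], axis=1)
    last = np.nansum(bout[:, 0, -n_edge:], axis=1)
    denom = first + last
    with np.errstate(invalid="ignore", divide="ignore"):
        ash1 = np.where(denom > 0, last / denom, np.nan)
    if convention == "ratio_to_combined_mean":
        ash1 = 2.0 * ash1
    cols["ASH1"] = ash1

    totals = raw["bout_totals"]  # (wells, bouts)
    d15 = totals[:, 0] + totals[:, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        cols["ASH1/5"] = np.where(d15 > 0, totals[:, -1] / d15, np.nan)
    cols["ASHsum"] = totals.sum(axis=1)  # NaN bout -> NaN sum (missing propagates)

    with np.errstate(invalid="ignore", divide="ignore"):
        d23 = cols["ASR2"] + cols["ASR3"]
        cols["ASR2/3"] = np.where(d23 > 0, cols["ASR3"] / d23, np.nan)
    return cols


def build_endpoint_table(
    traces: list[ActivityTrace],
    schedule: Schedule,
    metadata: pd.DataFrame | None = None,
    convention: str = "fraction",
) -> pd.DataFrame:
    """Derive the wells x 25 endpoint table with group labels.

    ``metadata``, if given, must be indexed by (or contain) ``well_id``
    and provide the plate annotation columns (colonization, treatment,
    concentration, flask, optionally a precombined ``group`` label);
    otherwise the annotations carried on the traces are used.  Wells
    present in the activity data but absent from the metadata raise a
    join error listing the offending wells.
    """
    if not traces:
        raise ValueError("no traces supplied")
    lengths = {len(t) for t in traces}
    if len(lengths) > 1:
        raise ValueError(f"traces have inconsistent lengths: {sorted(lengths)}")
    well_ids = [t.well_id for t in traces]
    if len(set(well_ids)) != len(well_ids):
        raise ValueError("duplicate well ids in activity data")

    activity = np.stack([t.values for t in traces])
    raw = segment_matrix(activity, schedule)
    cols = _derive_matrix(raw, convention)
    table = pd.DataFrame({name: cols[name] for name in ENDPOINT_NAMES}, index=pd.Index(well_ids, name="well_id"))

    if metadata is not None:
        meta = metadata.set_index("well_id") if "well_id" in metadata.columns else metadata
        missing = [w for w in well_ids if w not in meta.index]
        if missing:
            raise ValueError(f"wells missing from plate metadata: {missing}")
        meta = meta.loc[well_ids]
        for col in ("colonization", "treatment", "concentration", "flask"):
            table[col] = meta[col].to_numpy() if col in meta.columns else ""
        if "group" in meta.columns:
            table["group"] = meta["group"].to_numpy()
    else:
        table["colonization"] = [t.colonization for t in traces]
        table["treatment"] = [t.treatment for t in traces]
        table["concentration"] = [t.concentration for t in traces]
        table["flask"] = [t.flask for t in traces]
    if "group" not in table.columns:
        table["group"] = table["colonization"].astype(str) + ":" + table["treatment"].astype(str)
    return table


def missing_value_audit(table: pd.DataFrame) -> dict:
    """Per-endpoint and per-well counts of missing endpoint values."""
    endpoints = table[list(ENDPOINT_NAMES)]
    per_well = endpoints.isna().sum(axis=1)
    return {
        "per_endpoint": {k: int(v) for k, v in endpoints.isna().sum().items()},
        "wells_with_missing": {str(w): int(n) for w, n in per_well[per_well > 0].items()},
        "n_wells": int(len(table)),
    }
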