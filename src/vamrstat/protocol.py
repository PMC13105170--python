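"""Assay timeline for the Visual and Acoustic Motor Response (VAMR) assay.

The assay is a fixed sequence of light/dark and acoustic-stimulus phases
delivered to larval zebrafish in multiwell plates while per-second motor
activity (pixel-intensity change per second) is recorded.  This module
models that timeline as explicit, validated half-open windows in whole
seconds and maps each 1-s activity bin of a trace to at most one window.

Timeline (defaults):

* 21 min dark acclimation, of which the first four 5-min intervals are the
  baseline endpoints BSL1-BSL4; the trailing minute is a declared
  unassigned buffer so that BSL1 stays anchored at assay start.
* 10 min light: a 1-s visual startle (VSR1) followed by 9 min 59 s of
  basal activity (VMR1).
* 20 min dark: a 1-s visual startle (VSR2), a 4 min 59 s dark-phase surge
  window (VMR2) and three 5-min return-to-baseline intervals (VMR3-VMR5).
* Acoustic phase: 5 low-volume stimuli a minute apart (ASR1, gaps ISI1),
  a 1-min inter-endpoint interval (IEI1), 5 high-volume stimuli (ASR2,
  ISI2), IEI2, five 60-s habituation bouts of 30 high-volume stimuli at a
  2-s period separated by 60-s inter-bout intervals (IBI), a 3-min IEI3,
  and a final block of 5 high-volume stimuli (ASR3).

Conventions: 0-based time, half-open ``[start, end)`` windows; a stimulus
"response" is the activity in the single second beginning at stimulus
onset.  Masked bins are represented as NaN and must be explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: length of one baseline interval (5 min) in seconds
BASELINE_INTERVAL = 300


class ScheduleError(ValueError):
    """The protocol's phases cannot be tiled into non-overlapping windows."""


@dataclass(frozen=True)
class AssayProtocol:
    """Stimulus timeline parameters, all in whole seconds (or counts).

    ``inter_stimulus_gap`` is the onset-to-onset period of the 1-min
    spaced acoustic stimuli; ``intra_bout_stimulus_period`` the
    onset-to-onset period inside a habituation bout (1-s stimulus plus
    1-s gap by default).
    """

    acclimation_duration: int = 1260
    light_phase_duration: int = 600
    post_light_dark_duration: int = 1200
    startle_window: int = 1
    n_stimuli_per_asr: int = 5
    inter_stimulus_gap: int = 60
    n_habituation_bouts: int = 5
    stimuli_per_bout: int = 30
    intra_bout_stimulus_period: int = 2
    inter_bout_gap: int = 60
    iei1_duration: int = 60
    iei2_duration: int = 60
    iei3_duration: int = 180

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ScheduleError(f"{name} must be an integer number of seconds, got {value!r}")
            if value <= 0:
                raise ScheduleError(f"{name} must be strictly positive, got {value}")
        if self.acclimation_duration < 4 * BASELINE_INTERVAL:
            raise ScheduleError(
                "acclimation_duration must accommodate four 5-min baseline intervals "
                f"(>= {4 * BASELINE_INTERVAL} s), got {self.acclimation_duration}"
            )
        if self.startle_window >= BASELINE_INTERVAL:
            raise ScheduleError("startle_window must be shorter than a 5-min interval")
        if self.light_phase_duration <= self.startle_window:
            raise ScheduleError("light phase must be longer than the startle window")
        vmr_tail = self.post_light_dark_duration - BASELINE_INTERVAL
        if vmr_tail <= 0 or vmr_tail % 3:
            raise ScheduleError(
                "post_light_dark_duration must be one 5-min surge segment plus "
                "three equal return-to-baseline intervals; "
                f"{self.post_light_dark_duration} s cannot be tiled (first conflicting window: VMR3)"
            )
        if self.inter_stimulus_gap < self.startle_window:
            raise ScheduleError("inter_stimulus_gap shorter than the startle window (ASR stimuli overlap)")
        if self.intra_bout_stimulus_period < 1:
            raise ScheduleError("intra_bout_stimulus_period must be at least 1 s")

    # -- derived geometry ------------------------------------------------
    @property
    def asr_block_length(self) -> int:
        """Span of one block of 1-min spaced acoustic stimuli (241 s by default)."""
        return (self.n_stimuli_per_asr - 1) * self.inter_stimulus_gap + self.startle_window

    @property
    def bout_length(self) -> int:
        return self.stimuli_per_bout * self.intra_bout_stimulus_period

    @property
    def habituation_length(self) -> int:
        return (
            self.n_habituation_bouts * self.bout_length
            + (self.n_habituation_bouts - 1) * self.inter_bout_gap
        )

    @property
    def total_length(self) -> int:
        """Total assay length in seconds (4623 for the defaults)."""
        return (
            self.acclimation_duration
            + self.light_phase_duration
            + self.post_light_dark_duration
            + 3 * self.asr_block_length
            + self.iei1_duration
            + self.iei2_duration
            + self.habituation_length
            + self.iei3_duration
        )


@dataclass(frozen=True)
class EndpointWindow:
    """One half-open window ``[start, end)`` carrying an endpoint label."""

    name: str
    start: int
    end: int
    kind: str = "interval"  # interval | stimulus | bout | buffer

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ScheduleError(f"window {self.name}: start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Schedule:
    """All windows of one assay run plus fast index arrays for segmentation."""

    protocol: AssayProtocol
    windows: list[EndpointWindow]
    interval_seconds: dict[str, np.ndarray]
    stimulus_onsets: dict[str, np.ndarray]
    bout_windows: list[tuple[int, int]]
    bout_stimulus_onsets: list[np.ndarray]
    buffers: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return self.protocol.total_length

    def windows_for(self, name: str) -> list[EndpointWindow]:
        return [w for w in self.windows if w.name == name]

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a tidy table (endpoint_name, start, end, kind)."""
        return pd.DataFrame(
            [(w.name, w.start, w.end, w.kind) for w in self.windows],
            columns=["endpoint_name", "start", "end", "kind"],
        )


def _asr_block(windows, label, isi_label, t, p):
    onsets = []
    for k in range(p.n_stimuli_per_asr):
        onset = t + k * p.inter_stimulus_gap
        onsets.append(onset)
        windows.append(EndpointWindow(f"{label}_s{k + 1}", onset, onset + p.startle_window, "stimulus"))
        if k < p.n_stimuli_per_asr - 1:
            windows.append(EndpointWindow(isi_label, onset + p.startle_window, onset + p.inter_stimulus_gap, "interval"))
    return np.asarray(onsets), t + p.asr_block_length


def build_schedule(protocol: AssayProtocol | None = None) -> Schedule:
    """Construct the full window schedule for a protocol.

    Windows are laid out cursor-wise so they cannot overlap by
    construction; the tiling identity (assigned seconds + declared
    buffers == total assay length, each second covered exactly once) is
    verified before returning and a :class:`ScheduleError` names the
    first conflicting window otherwise.
    """
    p = protocol if protocol is not None else AssayProtocol()
    windows: list[EndpointWindow] = []
    buffers: list[tuple[int, int]] = []
    t = 0

    # dark acclimation: BSL1-4 then an unassigned buffer for any remainder
    for i in range(4):
        windows.append(EndpointWindow(f"BSL{i + 1}", t, t + BASELINE_INTERVAL))
        t += BASELINE_INTERVAL
    if t < p.acclimation_duration:
        windows.append(EndpointWindow("unassigned_acclimation", t, p.acclimation_duration, "buffer"))
        buffers.append((t, p.acclimation_duration))
        t = p.acclimation_duration

    # light phase: VSR1 + VMR1
    windows.append(EndpointWindow("VSR1", t, t + p.startle_window))
    windows.append(EndpointWindow("VMR1", t + p.startle_window, t + p.light_phase_duration))
    t += p.light_phase_duration

    # dark phase: VSR2, VMR2 surge, VMR3-5
    windows.append(EndpointWindow("VSR2", t, t + p.startle_window))
    windows.append(EndpointWindow("VMR2", t + p.startle_window, t + BASELINE_INTERVAL))
    vmr_tail = (p.post_light_dark_duration - BASELINE_INTERVAL) // 3
    for i in range(3):
        start = t + BASELINE_INTERVAL + i * vmr_tail
        windows.append(EndpointWindow(f"VMR{i + 3}", start, start + vmr_tail))
    t += p.post_light_dark_duration

    # acoustic startle blocks
    stimulus_onsets: dict[str, np.ndarray] = {}
    stimulus_onsets["ASR1"], t = _asr_block(windows, "ASR1", "ISI1", t, p)
    windows.append(EndpointWindow("IEI1", t, t + p.iei1_duration))
    t += p.iei1_duration
    stimulus_onsets["ASR2"], t = _asr_block(windows, "ASR2", "ISI2", t, p)
    windows.append(EndpointWindow("IEI2", t, t + p.iei2_duration))
    t += p.iei2_duration

    # habituation bouts with inter-bout intervals
    bout_windows: list[tuple[int, int]] = []
    bout_stimulus_onsets: list[np.ndarray] = []
    for b in range(p.n_habituation_bouts):
        bout_windows.append((t, t + p.bout_length))
        windows.append(EndpointWindow(f"ASH_bout{b + 1}", t, t + p.bout_length, "bout"))
        bout_stimulus_onsets.append(t + p.intra_bout_stimulus_period * np.arange(p.stimuli_per_bout))
        t += p.bout_length
        if b < p.n_habituation_bouts - 1:
            windows.append(EndpointWindow("IBI", t, t + p.inter_bout_gap))
            t += p.inter_bout_gap

    windows.append(EndpointWindow("IEI3", t, t + p.iei3_duration))
    t += p.iei3_duration
    stimulus_onsets["ASR3"], t = _asr_block(windows, "ASR3", "ISI3", t, p)

    if t != p.total_length:  # pragma: no cover - guarded by protocol validation
        raise ScheduleError(f"schedule ends at {t} s but protocol total is {p.total_length} s")

    occupancy = np.zeros(p.total_length, dtype=np.int64)
    for w in windows:
        occupancy[w.start:w.end] += 1
    if (occupancy != 1).any():
        bad = int(np.argmax(occupancy != 1))
        offender = next(w for w in windows if w.start <= bad < w.end) if occupancy[bad] > 1 else None
        raise ScheduleError(
            f"second {bad} covered {occupancy[bad]} times"
            + (f" (first conflicting window: {offender.name})" if offender else "")
        )

    interval_seconds: dict[str, np.ndarray] = {}
    for w in windows:
        if w.kind == "interval":
            interval_seconds.setdefault(w.name, [])
            interval_seconds[w.name].append(np.arange(w.start, w.end))
    interval_seconds = {k: np.concatenate(v) for k, v in interval_seconds.items()}

    return Schedule(
        protocol=p,
        windows=windows,
        interval_seconds=interval_seconds,
        stimulus_onsets=stimulus_onsets,
        bout_windows=bout_windows,
        bout_stimulus_onsets=bout_stimulus_onsets,
        buffers=buffers,
    )


@dataclass
class ActivityTrace:
    """Per-well 1-s motor-activity series with plate metadata.

    ``values[t]`` is the activity in second ``[t, t+1)`` from assay
    start.  Masked bins are NaN; negative or silent gaps are rejected.
    """

    well_id: str
    values: np.ndarray
    colonization: str = ""
    treatment: str = ""
    concentration: float = float("nan")
    flask: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError(f"trace {self.well_id}: values must be 1-D")
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError(f"trace {self.well_id}: negative activity values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SegmentSummary:
    """Raw per-endpoint summaries of one trace (pre metric derivation)."""

    interval_means: dict[str, float]
    stimulus_vectors: dict[str, np.ndarray]
    bout_matrix: np.ndarray  # (n_bouts, stimuli_per_bout) per-stimulus responses
    bout_totals: np.ndarray  # (n_bouts,) activity summed over whole bout windows
    masked_counts: dict[str, int]


def segment_matrix(activity: np.ndarray, schedule: Schedule) -> dict:
    """Vectorized segmentation of an (n_wells, n_seconds) activity matrix.

    Returns raw summaries as arrays over wells: interval means
    (NaN-aware; an all-masked window yields NaN), per-stimulus response
    vectors for the ASR blocks and habituation bouts, and whole-window
    bout totals.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2:
        raise ValueError("activity must be a 2-D (wells x seconds) array")
    if activity.shape[1] < schedule.total_length:
        raise ValueError(
            f"traces of length {activity.shape[1]} are shorter than the "
            f"protocol total of {schedule.total_length} s"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN window -> NaN
        interval_means = {
            name: np.nanmean(activity[:, idx], axis=1)
            for name, idx in schedule.interval_seconds.items()
        }
    masked_counts = {
        name: np.isnan(activity[:, idx]).sum(axis=1)
        for name, idx in schedule.interval_seconds.items()
    }
    stimulus_vectors = {
        name: activity[:, onsets] for name, onsets in schedule.stimulus_onsets.items()
    }
    bout_matrix = np.stack(
        [activity[:, onsets] for onsets in schedule.bout_stimulus_onsets], axis=1
    )
    bout_totals = np.stack(
        [np.nansum(activity[:, a:b], axis=1) for a, b in schedule.bout_windows], axis=1
    )
    # a fully masked bout window is missing, not zero
    for j, (a, b) in enumerate(schedule.bout_windows):
        all_masked = np.isnan(activity[:, a:b]).all(axis=1)
        bout_totals[all_masked, j] = np.nan
    return {
        "interval_means": interval_means,
        "stimulus_vectors": stimulus_vectors,
        "bout_matrix": bout_matrix,
        "bout_totals": bout_totals,
        "masked_counts": masked_counts,
    }


def segment_trace(trace: ActivityTrace, schedule: Schedule) -> SegmentSummary:
    """Map one trace onto the schedule and summarize each raw window.

    Interval endpoints report mean activity per second over their
    windows; startle endpoints the activity in each stimulus second;
    bout endpoints the ordered per-stimulus response vector plus the
    whole-window activity total.
    """
    raw = segment_matrix(trace.values[None, :], schedule)
    return SegmentSummary(
        interval_means={k: float(v[0]) for k, v in raw["interval_means"].items()},
        stimulus_vectors={k: v[0] for k, v in raw["stimulus_vectors"].items()},
        bout_matrix=raw["bout_matrix"][0],
        bout_totals=raw["bout_totals"][0],
        masked_counts={k: int(v[0]) for k, v in raw["masked_counts"].items()},
    )
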