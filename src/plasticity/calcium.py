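"""Calcium-trace activity analysis.

Somatic fluorescence is extracted by averaging all pixels of a neuron's ROI,
zero-phase low-pass filtered at 10 Hz, and compensated for neuropil
contamination with

    ``F_comp = F_roi - alpha * F_neuropil + alpha * median(F_neuropil)``

with ``alpha = 0.7`` by default and the median taken over the whole session.
A calcium transient is a maximal run of at least ``min_duration_frames``
consecutive frames (default 20, ~0.7 s at 30 Hz) above a robust threshold
``median + k_sigma * 1.4826 * MAD``; a neuron is 'active' if it shows at
least one transient. Baseline activity is split at 1 transient/min into
'high' and 'low', and per-neuron activity histories across baseline, an
intermediate and a late session are classified into a fate taxonomy
(persistently active, silent, regained, newly active).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "CalciumRecording",
    "FluorescenceTrace",
    "TransientTrain",
    "ActivityFate",
    "extract_roi_traces",
    "lowpass",
    "neuropil_compensate",
    "detect_transients",
    "classify_baseline_level",
    "fate_classification",
    "fraction_active",
    "analyze_traces",
]

FATES_FROM_BASELINE = (
    "persistently_active",
    "silent_at_mid",
    "silent_at_late_only",
    "regained",
)
HISTORIES_AT_LATE = ("persistently_active", "regained", "newly_active")


@dataclass
class CalciumRecording:
    """One session's recording: either a movie with masks, or raw traces.

    ``roi_masks`` / ``neuropil_masks`` are label images in which the value
    ``i + 1`` marks neuron ``neuron_ids[i]``; ROI and neuropil labels are
    disjoint per neuron. Pre-extracted recordings store ``f_roi`` and
    ``f_neuropil`` as ``(n_neurons, n_frames)`` arrays instead.
    """

    frame_rate_hz: float
    neuron_ids: list[str]
    session: str = "baseline"
    population: dict[str, str] = field(default_factory=dict)
    movie: np.ndarray | None = None
    roi_masks: np.ndarray | None = None
    neuropil_masks: np.ndarray | None = None
    f_roi: np.ndarray | None = None
    f_neuropil: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.movie is None and self.f_roi is None:
            raise ValueError("recording needs either a movie or pre-extracted traces")


@dataclass
class FluorescenceTrace:
    f_roi: np.ndarray
    f_neuropil: np.ndarray
    frame_rate_hz: float
    f_comp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.f_roi) != len(self.f_neuropil):
            raise ValueError("f_roi and f_neuropil must have equal length")


@dataclass
class TransientTrain:
    """Detected events for one neuron; intervals are half-open frame ranges."""

    events: list[tuple[int, int, float]]
    n_frames: int
    frame_rate_hz: float

    @property
    def frequency_per_min(self) -> float:
        return 60.0 * len(self.events) * self.frame_rate_hz / self.n_frames

    @property
    def active(self) -> bool:
        return len(self.events) >= 1


@dataclass(frozen=True)
class ActivityFate:
    neuron_id: str
    active_baseline: bool
    active_mid: bool
    active_late: bool
    fate_from_baseline: str | None
    history_at_late: str | None


# ---------------------------------------------------------------------------


def extract_roi_traces(recording: CalciumRecording) -> dict[str, FluorescenceTrace]:
    """Average movie pixels within each neuron's ROI and neuropil mask."""
    if recording.movie is None:
        if recording.f_roi is None or recording.f_neuropil is None:
            raise ValueError("recording has neither movie nor traces")
        return {
            nid: FluorescenceTrace(
                np.asarray(recording.f_roi[i], dtype=float),
                np.asarray(recording.f_neuropil[i], dtype=float),
                recording.frame_rate_hz,
            )
            for i, nid in enumerate(recording.neuron_ids)
        }
    if recording.roi_masks is None or recording.neuropil_masks is None:
        raise ValueError("movie recording requires roi and neuropil label masks")
    movie = recording.movie
    traces: dict[str, FluorescenceTrace] = {}
    for i, nid in enumerate(recording.neuron_ids):
        roi = recording.roi_masks == i + 1
        npil = recording.neuropil_masks == i + 1
        if not roi.any():
            raise ValueError(f"empty ROI mask for neuron {nid!r}")
        if not npil.any():
            raise ValueError(f"empty neuropil mask for neuron {nid!r}")
        f_roi = movie[:, roi].mean(axis=1).astype(float)
        f_np = movie[:, npil].mean(axis=1).astype(float)
        traces[nid] = FluorescenceTrace(f_roi, f_np, recording.frame_rate_hz)
    return traces


def lowpass(trace: np.ndarray, frame_rate_hz: float, cutoff_hz: float = 10.0) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass.

    Forward-backward filtering (``filtfilt``) keeps event peaks in place.
    """
    trace = np.asarray(trace, dtype=float)
    nyquist = frame_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(2, cutoff_hz / nyquist)
    return filtfilt(b, a, trace)


def neuropil_compensate(
    f_roi: np.ndarray, f_neuropil: np.ndarray, alpha: float = 0.7
) -> np.ndarray:
    """Subtract scaled neuropil signal, re-centred on its session median."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_roi.shape != f_neuropil.shape:
        raise ValueError(
            f"trace length mismatch: {f_roi.shape} vs {f_neuropil.shape}"
        )
    # algebraically f_roi - alpha*f_np + alpha*median(f_np); grouping the
    # neuropil terms keeps the constant-neuropil identity exact in floats
    return f_roi - alpha * (f_neuropil - np.median(f_neuropil))


def detect_transients(
    f_comp: np.ndarray,
    frame_rate_hz: float,
    min_duration_frames: int = 20,
    k_sigma: float = 3.0,
) -> TransientTrain:
    """Threshold-crossing transient detection with a robust noise estimate.

    Baseline is the trace median; the noise scale is the normalized MAD
    (``1.4826 * median|x - median|``). An event is a maximal run of at least
    ``min_duration_frames`` frames strictly above ``baseline + k_sigma *
    sigma``. A constant trace (sigma = 0) yields zero events.
    """
    x = np.asarray(f_comp, dtype=float)
    if len(x) < min_duration_frames:
        raise ValueError("trace shorter than the minimum transient duration")
    baseline = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - baseline))
    events: list[tuple[int, int, float]] = []
    if sigma > 0:
        above = x > baseline + k_sigma * sigma
        padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_duration_frames:
                events.append((int(s), int(e), float(x[s:e].max() - baseline)))
    return TransientTrain(events, n_frames=len(x), frame_rate_hz=frame_rate_hz)


def classify_baseline_level(train: TransientTrain) -> str:
    """'high' at >= 1 transient/min, 'low' below, 'inactive' at zero events."""
    if not train.active:
        return "inactive"
    return "high" if train.frequency_per_min >= 1.0 else "low"


def fate_classification(
    active_baseline: bool | None,
    active_mid: bool | None,
    active_late: bool | None,
    neuron_id: str = "",
) -> ActivityFate:
    """Map one neuron's (baseline, mid, late) activity flags to fate labels.

    ``fate_from_baseline`` partitions baseline-active neurons; ``history_at_
    late`` partitions late-active neurons. Each taxonomy assigns exactly one
    label within its denominator and ``None`` outside it.
    """
    for name, flag in (
        ("baseline", active_baseline),
        ("mid", active_mid),
        ("late", active_late),
    ):
        if flag is None:
            raise ValueError(f"missing activity flag for session {name!r}")
    b, m, late = bool(active_baseline), bool(active_mid), bool(active_late)
    fate = None
    if b:
        if m and late:
            fate = "persistently_active"
        elif m and not late:
            fate = "silent_at_late_only"
        elif not m and late:
            fate = "regained"
        else:
            fate = "silent_at_mid"
    history = None
    if late:
        if b and m:
            history = "persistently_active"
        elif b and not m:
            history = "regained"
        else:
            history = "newly_active"
    return ActivityFate(neuron_id, b, m, late, fate, history)


def fraction_active(active_flags) -> float:
    """Fraction of active neurons in one population/session."""
    flags = np.asarray(list(active_flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("empty population")
    return float(flags.mean())


def analyze_traces(
    recording: CalciumRecording,
    *,
    alpha: float = 0.7,
    cutoff_hz: float = 10.0,
    min_duration_frames: int = 20,
    k_sigma: float = 3.0,
) -> pd.DataFrame:
    """Full per-neuron pipeline: filter, compensate, detect, classify.

    Returns one row per neuron with event count, frequency per minute,
    active flag and high/low/inactive level.
    """
    traces = extract_roi_traces(recording)
    rows = []
    for nid, tr in traces.items():
        f_roi = lowpass(tr.f_roi, tr.frame_rate_hz, cutoff_hz)
        f_np = lowpass(tr.f_neuropil, tr.frame_rate_hz, cutoff_hz)
        f_comp = neuropil_compensate(f_roi, f_np, alpha)
        train = detect_transients(f_comp, tr.frame_rate_hz, min_duration_frames, k_sigma)
        rows.append(
            {
                "neuron_id": nid,
                "session": recording.session,
                "population": recording.population.get(nid, ""),
                "n_events": len(train.events),
                "frequency_per_min": train.frequency_per_min,
                "active": train.active,
                "level": classify_baseline_level(train),
            }
        )
    return pd.DataFrame(rows)


def fate_table(
    active: pd.DataFrame,
    baseline: str,
    mid: str,
    late: str,
) -> pd.DataFrame:
    """Per-neuron fate labels from a long (neuron_id, session, active) table."""
    wide = active.pivot_table(
        index="neuron_id", columns="session", values="active", aggfunc="first"
    )
    for s in (baseline, mid, late):
        if s not in wide.columns:
            raise ValueError(f"missing session {s!r} in activity table")
    rows = []
    for nid, row in wide.iterrows():
        fate = fate_classification(
            bool(row[baseline]), bool(row[mid]), bool(row[late]), neuron_id=str(nid)
        )
        rows.append(
            {
                "neuron_id": nid,
                "active_baseline": fate.active_baseline,
                "active_mid": fate.active_mid,
                "active_late": fate.active_late,
                "fate_from_baseline": fate.fate_from_baseline,
                "history_at_late": fate.history_at_late,
            }
        )
    return pd.DataFrame(rows)
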