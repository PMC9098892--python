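"""Synthetic data generators with known ground truth.

Three generators emulate the raw inputs of the analysis layers:

* a discrete-time spine birth--death process over ordered imaging sessions,
  with session-specific elimination and formation hazards, producing the
  long-format presence tables consumed by :mod:`plasticity.spines`;
* 30 Hz GCaMP-like fluorescence traces (optionally rendered into a small
  movie) built from Poisson event trains convolved with a rise/decay kernel,
  plus Gaussian noise and additive neuropil contamination constructed so the
  standard neuropil compensation is its exact algebraic inverse;
* per-region presynaptic/starter count tables with Poisson connectivity for
  the monosynaptic-tracing analysis.

Every generator is deterministic given its seed and returns its ground truth
alongside the data, so parameter-recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .calcium import CalciumRecording
from .tracing import TracingCounts

__all__ = [
    "SpineSimParams",
    "CalciumSimParams",
    "TracingSimParams",
    "simulate_spine_tracks",
    "simulate_calcium_recording",
    "simulate_tracing_experiment",
    "simulate_tracing_cohort",
]

MORPH_TYPES = ("mushroom", "thin", "stubby")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SpineSimParams:
    """Parameters of the spine birth--death process.

    ``elimination_prob_per_session[s]`` is the probability that a spine
    present at the previous session is absent at session ``s``;
    ``formation_rate_per_session[s]`` is the expected number of new spines
    per spine present at the previous session (formation is Poisson with
    mean ``f_s * N_prev``, matching the per-previous-total percentage
    estimator used in the analysis layer).
    """

    n_dendrites: int = 10
    spines_per_dendrite_mean: float = 30.0
    dendrite_length_um: float = 60.0
    session_times: tuple[str, ...] = ("B1", "B2", "3d", "6d", "9d", "12d", "15d", "18d")
    elimination_prob_per_session: dict[str, float] = field(default_factory=dict)
    formation_rate_per_session: dict[str, float] = field(default_factory=dict)
    morph_type_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    reappearance_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.session_times) < 2:
            raise ValueError("at least two imaging sessions are required")
        if len(set(self.session_times)) != len(self.session_times):
            raise ValueError("session labels must be unique")
        if self.n_dendrites < 1 or self.spines_per_dendrite_mean < 0:
            raise ValueError("dendrite/spine counts must be positive")
        if self.dendrite_length_um <= 0:
            raise ValueError("dendrite_length_um must be > 0")
        for s, e in self.elimination_prob_per_session.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"elimination probability for session {s!r} not in [0, 1]: {e}")
        for s, f in self.formation_rate_per_session.items():
            if f < 0:
                raise ValueError(f"formation rate for session {s!r} negative: {f}")
        if not 0.0 <= self.reappearance_prob <= 1.0:
            raise ValueError("reappearance_prob must be in [0, 1]")
        p = np.asarray(self.morph_type_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("morph_type_probs must be a 3-simplex summing to 1")

    def hazards(self, session: str) -> tuple[float, float]:
        return (
            float(self.elimination_prob_per_session.get(session, 0.0)),
            float(self.formation_rate_per_session.get(session, 0.0)),
        )


@dataclass(frozen=True)
class CalciumSimParams:
    """Parameters of the spike-to-fluorescence simulator.

    Defaults mirror a typical 10 min somatic recording: 18,000 frames at
    30 Hz, GCaMP6m-like kernel (rise 0.08 s, decay 0.6 s) and a neuropil
    contamination coefficient of 0.7.
    """

    n_neurons: int = 10
    frame_rate_hz: float = 30.0
    n_frames: int = 18000
    event_rate_per_min: float = 1.2
    kernel_rise_s: float = 0.08
    kernel_decay_s: float = 0.6
    event_amplitude: float = 50.0
    baseline: float = 100.0
    noise_sd: float = 2.0
    neuropil_coefficient: float = 0.7
    neuropil_baseline: float = 60.0
    neuropil_signal_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.neuropil_coefficient < 0:
            raise ValueError("neuropil_coefficient must be >= 0")
        if self.event_rate_per_min < 0 or self.noise_sd < 0 or self.neuropil_signal_sd < 0:
            raise ValueError("rates and noise levels must be >= 0")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= self.kernel_rise_s:
            raise ValueError("kernel requires 0 < rise < decay")


@dataclass(frozen=True)
class TracingSimParams:
    """Parameters of the tracing-count generator.

    Region counts are Poisson with the given per-region means; the observed
    starter count is a binomial thinning of ``n_starters_true`` with
    probability ``sections_imaged / sections_total``, so proportional
    interpolation back to the whole brain is unbiased.
    """

    regions: tuple[str, ...] = ("somatosensory", "motor", "auditory", "thalamus")
    mean_presyn_per_region: dict[str, float] = field(default_factory=dict)
    hemisphere_per_region: dict[str, str] = field(default_factory=dict)
    n_starters_true: int = 60
    sections_imaged: int = 6
    sections_total: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sections_imaged < 1 or self.sections_imaged > self.sections_total:
            raise ValueError("require 1 <= sections_imaged <= sections_total")
        if self.n_starters_true < 0:
            raise ValueError("n_starters_true must be >= 0")
        for r, m in self.mean_presyn_per_region.items():
            if m < 0:
                raise ValueError(f"mean presynaptic count for region {r!r} negative")


# ---------------------------------------------------------------------------
# spine tracks


def simulate_spine_tracks(
    params: SpineSimParams,
) -> tuple[pd.DataFrame, dict]:
    """Simulate longitudinal spine presence tables.

    Returns a long-format table (animal_id, dendrite_id, dendrite_length_um,
    spine_id, session, present, morph_type) and a ground-truth dict with the
    per-session hazards actually used. Each spine's rows start at its birth
    session; by default an eliminated spine never reappears, so presence
    codes contain no 1->0->1 pattern unless ``reappearance_prob > 0``.
    """
    rng = np.random.default_rng(params.seed)
    sessions = list(params.session_times)
    n_sessions = len(sessions)
    morph_p = np.asarray(params.morph_type_probs, dtype=float)

    rows: list[tuple] = []
    for d in range(params.n_dendrites):
        dendrite_id = f"d{d:04d}"
        n0 = int(rng.poisson(params.spines_per_dendrite_mean))
        # spine state: birth session index, presence history list
        histories: list[list[int]] = [[1] for _ in range(n0)]
        births: list[int] = [0] * n0
        for t in range(1, n_sessions):
            e_t, f_t = params.hazards(sessions[t])
            n_prev = sum(h[-1] for h in histories)
            for h in histories:
                if h[-1] == 1:
                    h.append(0 if rng.random() < e_t else 1)
                else:
                    h.append(1 if rng.random() < params.reappearance_prob else 0)
            n_new = int(rng.poisson(f_t * n_prev)) if n_prev > 0 else 0
            for _ in range(n_new):
                histories.append([1])
                births.append(t)
        for sp, (birth, hist) in enumerate(zip(births, histories)):
            spine_id = f"{dendrite_id}s{sp:04d}"
            for k, pres in enumerate(hist):
                t = birth + k
                morph = (
                    MORPH_TYPES[rng.choice(3, p=morph_p)] if pres else np.nan
                )
                rows.append(
                    (
                        "a01",
                        dendrite_id,
                        params.dendrite_length_um,
                        spine_id,
                        sessions[t],
                        pres,
                        morph,
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "dendrite_id",
            "dendrite_length_um",
            "spine_id",
            "session",
            "present",
            "morph_type",
        ],
    )
    truth = {
        "session_order": sessions,
        "elimination_prob_per_session": {
            s: params.hazards(s)[0] for s in sessions[1:]
        },
        "formation_rate_per_session": {
            s: params.hazards(s)[1] for s in sessions[1:]
        },
        "seed": params.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# calcium traces and movies


def _event_kernel(params: CalciumSimParams) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    dt = 1.0 / params.frame_rate_hz
    length = int(np.ceil(6 * params.kernel_decay_s / dt)) + 1
    t = np.arange(length) * dt
    k = np.exp(-t / params.kernel_decay_s) - np.exp(-t / params.kernel_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def simulate_calcium_recording(
    params: CalciumSimParams,
    *,
    as_movie: bool = False,
    frame_shape: tuple[int, int] | None = None,
    session: str = "baseline",
) -> tuple[CalciumRecording, dict]:
    """Simulate GCaMP-like recordings with known events and contamination.

    Per neuron: the true somatic trace is ``baseline + amplitude * (event
    train (*) kernel)`` with a Poisson number of events placed uniformly over
    the recording. The neuropil trace fluctuates independently. The observed
    ROI trace is

        ``f_roi = true + alpha * (f_neuropil - median(f_neuropil)) + noise``

    which makes the compensation ``f_roi - alpha*f_neuropil +
    alpha*median(f_neuropil)`` recover the true trace exactly at zero noise.

    With ``as_movie=True``, ROI disk pixels carry the observed trace and
    annulus neuropil pixels carry the neuropil trace in a small label-masked
    movie.
    """
    rng = np.random.default_rng(params.seed)
    n, T = params.n_neurons, params.n_frames
    duration_min = T / params.frame_rate_hz / 60.0
    kernel = _event_kernel(params)
    alpha = params.neuropil_coefficient

    true = np.empty((n, T))
    f_np = np.empty((n, T))
    f_roi = np.empty((n, T))
    event_frames: list[np.ndarray] = []
    for i in range(n):
        n_ev = rng.poisson(params.event_rate_per_min * duration_min)
        frames = np.sort(rng.integers(0, T, size=n_ev))
        spikes = np.zeros(T)
        np.add.at(spikes, frames, 1.0)
        sig = np.convolve(spikes, kernel)[:T]
        true[i] = params.baseline + params.event_amplitude * sig
        # slow neuropil fluctuation: AR(1)-smoothed gaussian noise
        w = rng.standard_normal(T)
        a = 0.98
        npil = lfilter([1 - a], [1.0, -a], w)
        sd = npil.std()
        if sd > 0 and params.neuropil_signal_sd > 0:
            npil *= params.neuropil_signal_sd / sd
        else:
            npil[:] = 0.0
        f_np[i] = params.neuropil_baseline + npil
        contamination = alpha * (f_np[i] - np.median(f_np[i]))
        noise = params.noise_sd * rng.standard_normal(T) if params.noise_sd > 0 else 0.0
        f_roi[i] = true[i] + contamination + noise
        event_frames.append(frames)

    neuron_ids = [f"n{i:03d}" for i in range(n)]
    truth = {
        "event_frames": event_frames,
        "true_traces": true,
        "neuropil_coefficient": alpha,
        "seed": params.seed,
    }

    if not as_movie:
        rec = CalciumRecording(
            frame_rate_hz=params.frame_rate_hz,
            session=session,
            neuron_ids=neuron_ids,
            f_roi=f_roi,
            f_neuropil=f_np,
        )
        return rec, truth

    movie, roi_masks, np_masks = _render_movie(f_roi, f_np, frame_shape)
    rec = CalciumRecording(
        frame_rate_hz=params.frame_rate_hz,
        session=session,
        neuron_ids=neuron_ids,
        movie=movie,
        roi_masks=roi_masks,
        neuropil_masks=np_masks,
    )
    return rec, truth


def _render_movie(
    f_roi: np.ndarray,
    f_np: np.ndarray,
    frame_shape: tuple[int, int] | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paint per-neuron traces into disk ROIs and annulus neuropil masks."""
    n, T = f_roi.shape
    cell = 16  # px per neuron tile: disk r=3, annulus r in (4.5, 7)
    per_row = int(np.ceil(np.sqrt(n)))
    if frame_shape is None:
        side = max(64, per_row * cell)
        frame_shape = (side, side)
    H, W = frame_shape
    per_row = W // cell
    if per_row * (H // cell) < n:
        raise ValueError(f"frame shape {frame_shape} too small for {n} neurons")
    yy, xx = np.mgrid[0:H, 0:W]
    roi_masks = np.zeros((H, W), dtype=np.int32)
    np_masks = np.zeros((H, W), dtype=np.int32)
    for i in range(n):
        cy = (i // per_row) * cell + cell // 2
        cx = (i % per_row) * cell + cell // 2
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        roi_masks[r2 <= 3**2] = i + 1
        np_masks[(r2 > 4.5**2) & (r2 <= 7**2)] = i + 1
    movie = np.zeros((T, H, W), dtype=np.float32)
    for i in range(n):
        movie[:, roi_masks == i + 1] = f_roi[i][:, None].astype(np.float32)
        movie[:, np_masks == i + 1] = f_np[i][:, None].astype(np.float32)
    return movie, roi_masks, np_masks


# ---------------------------------------------------------------------------
# tracing counts


def simulate_tracing_experiment(
    params: TracingSimParams,
    *,
    brain_id: str = "b01",
    group: str = "control_7d",
) -> TracingCounts:
    """Simulate one brain's presynaptic/starter counts."""
    rng = np.random.default_rng(params.seed)
    region_counts = {
        r: int(rng.poisson(params.mean_presyn_per_region.get(r, 0.0)))
        for r in params.regions
    }
    p_obs = params.sections_imaged / params.sections_total
    starter_counted = int(rng.binomial(params.n_starters_true, p_obs))
    hemis = {
        r: params.hemisphere_per_region.get(r, "contralesional") for r in params.regions
    }
    return TracingCounts(
        brain_id=brain_id,
        group=group,
        starter_counted=starter_counted,
        starter_sections_imaged=params.sections_imaged,
        starter_sections_total=params.sections_total,
        region_counts=region_counts,
        hemispheres=hemis,
    )


def simulate_tracing_cohort(
    params: TracingSimParams,
    n_brains: int,
    *,
    group: str = "control_7d",
) -> list[TracingCounts]:
    """Simulate ``n_brains`` independent brains with per-brain child seeds."""
    ss = np.random.SeedSequence(params.seed)
    brains = []
    for i, child in enumerate(ss.spawn(n_brains)):
        seed_i = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        p_i = TracingSimParams(
            regions=params.regions,
            mean_presyn_per_region=params.mean_presyn_per_region,
            hemisphere_per_region=params.hemisphere_per_region,
            n_starters_true=params.n_starters_true,
            sections_imaged=params.sections_imaged,
            sections_total=params.sections_total,
            seed=seed_i,
        )
        brains.append(
            simulate_tracing_experiment(p_i, brain_id=f"{group}_b{i:03d}", group=group)
        )
    return brains
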