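"""CSV/TIFF/JSON readers and writers plus the run report.

All tabular formats are plain comma-separated UTF-8 with a header row and
'.' decimals. Spine tracks round-trip losslessly through
``write_spine_tracks`` / ``read_spine_tracks``; schema violations are
reported with the offending rows. Movies are multi-page TIFF with label-
image TIFF masks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calcium import CalciumRecording
from .spines import REQUIRED_COLUMNS, validate_table
from .tracing import TracingCounts

__all__ = [
    "read_spine_tracks",
    "write_spine_tracks",
    "read_traces",
    "write_traces",
    "read_movie",
    "write_movie",
    "read_tracing_tables",
    "write_tracing_tables",
    "config_hash",
    "run_report",
]


def write_spine_tracks(table: pd.DataFrame, path: str | Path) -> None:
    cols = [*REQUIRED_COLUMNS, "morph_type"]
    out = table.copy()
    if "morph_type" not in out.columns:
        out["morph_type"] = np.nan
    out[cols].to_csv(path, index=False)


def read_spine_tracks(path: str | Path, session_order: list[str]) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"animal_id": str, "dendrite_id": str, "spine_id": str})
    if table.empty and not set(REQUIRED_COLUMNS) <= set(table.columns):
        raise ValueError(f"spine track file {path} missing required header")
    validate_table(table, session_order)
    table["present"] = table["present"].astype(int)
    return table


def write_traces(recording: CalciumRecording, path: str | Path) -> None:
    """Long-format trace CSV: (neuron_id, frame, f_roi, f_neuropil)."""
    if recording.f_roi is None or recording.f_neuropil is None:
        raise ValueError("recording has no pre-extracted traces")
    n, T = recording.f_roi.shape
    df = pd.DataFrame(
        {
            "neuron_id": np.repeat(recording.neuron_ids, T),
            "frame": np.tile(np.arange(T), n),
            "f_roi": recording.f_roi.ravel(),
            "f_neuropil": recording.f_neuropil.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_traces(
    path: str | Path, frame_rate_hz: float, session: str = "baseline"
) -> CalciumRecording:
    df = pd.read_csv(path, dtype={"neuron_id": str})
    required = {"neuron_id", "frame", "f_roi", "f_neuropil"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    ids = list(dict.fromkeys(df["neuron_id"]))
    wide_roi = df.pivot(index="neuron_id", columns="frame", values="f_roi").loc[ids]
    wide_np = df.pivot(index="neuron_id", columns="frame", values="f_neuropil").loc[ids]
    if wide_roi.isna().any().any() or wide_np.isna().any().any():
        raise ValueError(f"trace file {path} has missing frames for some neuron")
    return CalciumRecording(
        frame_rate_hz=frame_rate_hz,
        neuron_ids=ids,
        session=session,
        f_roi=wide_roi.to_numpy(dtype=float),
        f_neuropil=wide_np.to_numpy(dtype=float),
    )


def write_movie(recording: CalciumRecording, directory: str | Path, stem: str = "movie") -> None:
    """Write a multi-page TIFF movie and label-image TIFF masks."""
    if recording.movie is None:
        raise ValueError("recording has no movie")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}.tif", recording.movie)
    tifffile.imwrite(directory / f"{stem}_roi_masks.tif", recording.roi_masks)
    tifffile.imwrite(directory / f"{stem}_neuropil_masks.tif", recording.neuropil_masks)


def read_movie(
    directory: str | Path,
    stem: str = "movie",
    frame_rate_hz: float = 30.0,
    session: str = "baseline",
) -> CalciumRecording:
    directory = Path(directory)
    movie = tifffile.imread(directory / f"{stem}.tif")
    if movie.ndim == 2:  # single-frame movie: detection is not meaningful
        movie = movie[None]
    roi = tifffile.imread(directory / f"{stem}_roi_masks.tif")
    npil = tifffile.imread(directory / f"{stem}_neuropil_masks.tif")
    if roi.shape != movie.shape[1:] or npil.shape != movie.shape[1:]:
        raise ValueError(
            f"mask shape {roi.shape}/{npil.shape} does not match movie frames {movie.shape[1:]}"
        )
    labels = sorted(int(v) for v in np.unique(roi) if v > 0)
    missing = [v for v in labels if not (npil == v).any()]
    if missing:
        raise ValueError(f"missing neuropil label(s) for ROI(s): {missing}")
    neuron_ids = [f"n{v - 1:03d}" for v in labels]
    return CalciumRecording(
        frame_rate_hz=frame_rate_hz,
        neuron_ids=neuron_ids,
        session=session,
        movie=movie,
        roi_masks=roi,
        neuropil_masks=npil,
    )


def write_tracing_tables(
    brains: list[TracingCounts], starters_path: str | Path, counts_path: str | Path
) -> None:
    starters = pd.DataFrame(
        [
            {
                "brain_id": b.brain_id,
                "group": b.group,
                "starter_counted": b.starter_counted,
                "sections_imaged": b.starter_sections_imaged,
                "sections_total": b.starter_sections_total,
            }
            for b in brains
        ]
    )
    counts = pd.DataFrame(
        [
            {
                "brain_id": b.brain_id,
                "region": region,
                "hemisphere": b.hemispheres.get(region, "contralesional"),
                "presyn_count": n,
            }
            for b in brains
            for region, n in b.region_counts.items()
        ]
    )
    starters.to_csv(starters_path, index=False)
    counts.to_csv(counts_path, index=False)


def read_tracing_tables(
    starters_path: str | Path, counts_path: str | Path
) -> list[TracingCounts]:
    starters = pd.read_csv(starters_path, dtype={"brain_id": str, "group": str})
    counts = pd.read_csv(counts_path, dtype={"brain_id": str, "region": str})
    for col in ("brain_id", "group", "starter_counted", "sections_imaged", "sections_total"):
        if col not in starters.columns:
            raise ValueError(f"starter file missing column {col!r}")
    for col in ("brain_id", "region", "presyn_count"):
        if col not in counts.columns:
            raise ValueError(f"counts file missing column {col!r}")
    brains = []
    for _, row in starters.iterrows():
        sub = counts[counts["brain_id"] == row["brain_id"]]
        hemis = (
            dict(zip(sub["region"], sub["hemisphere"]))
            if "hemisphere" in sub.columns
            else {}
        )
        brains.append(
            TracingCounts(
                brain_id=row["brain_id"],
                group=row["group"],
                starter_counted=int(row["starter_counted"]),
                starter_sections_imaged=int(row["sections_imaged"]),
                starter_sections_total=int(row["sections_total"]),
                region_counts=dict(zip(sub["region"], sub["presyn_count"].astype(int))),
                hemispheres=hemis,
            )
        )
    return brains


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (order-independent)."""
    payload = json.dumps(config, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


def run_report(
    outputs: dict[str, object],
    config: dict,
    path: str | Path | None = None,
) -> dict:
    """Assemble a deterministic JSON run report.

    Contains the package version, a config hash, all seeds found in the
    config, and the provided summary tables (DataFrames are serialized as
    records). Regenerating with identical inputs yields identical content.
    """
    from . import __version__

    def _ser(v):
        if isinstance(v, pd.DataFrame):
            return json.loads(v.to_json(orient="records"))
        return v

    report = {
        "version": __version__,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": {k: _ser(v) for k, v in outputs.items()},
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
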