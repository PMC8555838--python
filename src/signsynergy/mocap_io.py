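"""Marker-trajectory I/O and posture-matrix assembly.

A motion-capture trial is a ``T x M x 3`` array of marker positions sampled
at a fixed frame rate.  For analysis every frame is flattened into a posture
vector ``p(t) = [x1, y1, z1, ..., xM, yM, zM]`` and trials are stacked into a
posture matrix, one row per frame, with bookkeeping that remembers which rows
came from which signer and trial.

Coordinate convention (used consistently by :mod:`signsynergy.reporting`):
``x`` mediolateral (subject's right positive), ``y`` vertical (up positive),
``z`` anteroposterior (forward positive); right-handed.  Units are
millimetres unless a loader is told otherwise.

Supported on-disk formats: a wide CSV dialect (one row per frame, header
``<marker>_<axis>``, frame rate in a ``*.meta.yaml`` side-car or passed
explicitly) and TRC (tab-separated with the usual two header blocks).  C3D is
declared in the format enum for forward compatibility but no parser is
bundled.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

AXES = ("x", "y", "z")

#: The 21-marker upper-body set: trunk (pelvis, stomach, T10, sternum, C7),
#: four head markers, and per side shoulder, elbow, two wrist and two hand
#: markers.  L/R = left/right, F/B = front/back.
DEFAULT_UPPER_BODY_MARKERS = (
    "pelvis",
    "stomach",
    "T10",
    "sternum",
    "C7",
    "head_LB",
    "head_LF",
    "head_RB",
    "head_RF",
    "shoulder_L",
    "elbow_L",
    "wrist_LB",
    "wrist_LF",
    "hand_LB",
    "hand_LF",
    "shoulder_R",
    "elbow_R",
    "wrist_RB",
    "wrist_RF",
    "hand_RB",
    "hand_RF",
)


class MocapIOError(ValueError):
    """Base class for loader/validation failures."""


class MissingMarkerError(MocapIOError):
    """A required marker label is absent from a file."""


class UnsupportedFormatError(MocapIOError):
    """The requested file format has no bundled parser."""


@dataclasses.dataclass(frozen=True)
class MarkerSet:
    """An ordered set of marker labels with a declared origin marker."""

    names: tuple[str, ...]
    origin_marker: str = "pelvis"

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(set(self.names)) != len(self.names):
            raise MocapIOError("marker names must be unique")
        if self.origin_marker not in self.names:
            raise MocapIOError(
                f"origin marker {self.origin_marker!r} not in marker set"
            )

    @property
    def count(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise MissingMarkerError(f"marker {name!r} not in marker set") from None

    @classmethod
    def default_upper_body(cls) -> "MarkerSet":
        return cls(DEFAULT_UPPER_BODY_MARKERS, origin_marker="pelvis")

    def column_labels(self) -> tuple[str, ...]:
        """Flattened per-coordinate labels, ``<marker>_<axis>`` order of Eq-style rows."""
        return tuple(f"{m}_{a}" for m in self.names for a in AXES)


@dataclasses.dataclass
class Trial:
    """One recording unit: ``frames`` is a ``T x M x 3`` coordinate array."""

    signer_id: str
    trial_id: str
    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise MocapIOError(
                f"frames must be T x M x 3, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise MocapIOError("trial must contain at least one frame")
        if not self.frame_rate > 0:
            raise MocapIOError("frame rate must be positive")
        if np.isnan(self.frames).any():
            bad = sorted(set(np.argwhere(np.isnan(self.frames))[:, 0].tolist()))
            raise MocapIOError(f"NaN coordinates in frames {bad[:20]}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_markers(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclasses.dataclass(frozen=True)
class Segment:
    """Half-open row interval ``[start, stop)`` of one trial inside a posture matrix."""

    signer_id: str
    trial_id: str
    start: int
    stop: int


@dataclasses.dataclass
class PostureMatrix:
    """Stacked posture vectors with per-trial segment bookkeeping.

    ``rows`` is ``T_total x 3M`` (or fewer columns after static-column
    removal); ``segments`` partition the rows exactly, in order.
    """

    rows: np.ndarray
    frame_rate: float
    segments: list[Segment]
    column_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise MocapIOError("rows must be 2-D")
        if len(self.column_labels) != self.rows.shape[1]:
            raise MocapIOError("column_labels length must match column count")
        pos = 0
        for seg in self.segments:
            if seg.start != pos or seg.stop <= seg.start:
                raise MocapIOError("segments must partition rows without gap/overlap")
            pos = seg.stop
        if pos != self.rows.shape[0]:
            raise MocapIOError("segments do not cover all rows")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def signer_ids(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if seg.signer_id not in out:
                out.append(seg.signer_id)
        return out

    def signer_row_indices(self, signer_id: str) -> np.ndarray:
        idx = [
            np.arange(s.start, s.stop)
            for s in self.segments
            if s.signer_id == signer_id
        ]
        if not idx:
            raise MocapIOError(f"no segments for signer {signer_id!r}")
        return np.concatenate(idx)

    def signer_block(self, signer_id: str) -> np.ndarray:
        return self.rows[self.signer_row_indices(signer_id)]

    def trial_block(self, signer_id: str, trial_id: str) -> np.ndarray:
        for s in self.segments:
            if s.signer_id == signer_id and s.trial_id == trial_id:
                return self.rows[s.start : s.stop]
        raise MocapIOError(f"no segment for {signer_id!r}/{trial_id!r}")


@dataclasses.dataclass(frozen=True)
class StaticColumns:
    """Columns removed as (numerically) constant within every signer's block.

    The constants may differ across signers (e.g. each signer's trunk
    geometry), so they are stored per signer for reconstruction.
    """

    kept: np.ndarray  # indices into the original column layout
    dropped: np.ndarray
    dropped_values: dict[str, np.ndarray]  # signer -> constants
    dropped_labels: tuple[str, ...]


# ---------------------------------------------------------------------------
# loading / saving trials


def _csv_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def load_trial(
    path: str | Path,
    markerset: MarkerSet,
    format: str | None = None,
    frame_rate: float | None = None,
    signer_id: str | None = None,
    trial_id: str | None = None,
) -> Trial:
    """Load one trial, conforming marker order to ``markerset``.

    ``format`` is inferred from the suffix when omitted.  For CSV the frame
    rate comes from the ``*.meta.yaml`` side-car unless given explicitly.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    signer_id = signer_id or path.stem.split("__")[0]
    trial_id = trial_id or path.stem
    if fmt == "csv":
        return _load_csv(path, markerset, frame_rate, signer_id, trial_id)
    if fmt == "trc":
        return _load_trc(path, markerset, frame_rate, signer_id, trial_id)
    if fmt == "c3d":
        raise UnsupportedFormatError(
            "C3D reading is not bundled; convert to TRC or CSV first"
        )
    raise UnsupportedFormatError(f"unknown trial format {fmt!r}")


def _load_csv(
    path: Path,
    markerset: MarkerSet,
    frame_rate: float | None,
    signer_id: str,
    trial_id: str,
) -> Trial:
    df = pd.read_csv(path)
    if frame_rate is None:
        sidecar = _csv_sidecar(path)
        if not sidecar.exists():
            raise MocapIOError(
                f"no frame rate: pass frame_rate= or provide side-car {sidecar.name}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        frame_rate = float(meta["frame_rate"])
    cols = []
    for marker in markerset.names:
        for axis in AXES:
            label = f"{marker}_{axis}"
            if label not in df.columns:
                raise MissingMarkerError(
                    f"marker {marker!r} missing from {path.name} (no column {label!r})"
                )
            cols.append(label)
    data = df[cols].to_numpy(dtype=float)
    frames = data.reshape(len(df), markerset.count, 3)
    return Trial(signer_id, trial_id, frames, frame_rate)


def save_trial(
    path: str | Path, trial: Trial, markerset: MarkerSet, format: str | None = None
) -> Path:
    """Write a trial as CSV (plus frame-rate side-car) or TRC."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if trial.n_markers != markerset.count:
        raise MocapIOError("trial marker count does not match marker set")
    if fmt == "csv":
        flat = trial.frames.reshape(trial.n_frames, -1)
        df = pd.DataFrame(flat, columns=list(markerset.column_labels()))
        df.to_csv(path, index=False, float_format="%.9f")
        _csv_sidecar(path).write_text(
            yaml.safe_dump({"frame_rate": float(trial.frame_rate)})
        )
        return path
    if fmt == "trc":
        _save_trc(path, trial, markerset)
        return path
    raise UnsupportedFormatError(f"cannot write format {fmt!r}")


def _save_trc(path: Path, trial: Trial, markerset: MarkerSet) -> None:
    fr = trial.frame_rate
    n, m = trial.n_frames, markerset.count
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{fr:g}\t{fr:g}\t{n}\t{m}\tmm\t{fr:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(markerset.names) + "\t\t\t",
        "\t\t"
        + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(m)),
        "",
    ]
    rows = []
    for t in range(n):
        vals = "\t".join(f"{v:.9f}" for v in trial.frames[t].ravel())
        rows.append(f"{t + 1}\t{t / fr:.9f}\t{vals}")
    path.write_text("\n".join(lines + rows) + "\n")


def _load_trc(
    path: Path,
    markerset: MarkerSet,
    frame_rate: float | None,
    signer_id: str,
    trial_id: str,
) -> Trial:
    text = Path(path).read_text().splitlines()
    header_vals = text[2].split("\t")
    fr = frame_rate if frame_rate is not None else float(header_vals[0])
    names = [s for s in text[3].split("\t")[2:] if s.strip()]
    data_lines = [ln for ln in text[5:] if ln.strip()]
    raw = np.array(
        [[float(v) for v in ln.split("\t")[2:]] for ln in data_lines], dtype=float
    )
    frames = raw.reshape(len(data_lines), len(names), 3)
    # conform order to the requested marker set
    order = []
    for marker in markerset.names:
        if marker not in names:
            raise MissingMarkerError(f"marker {marker!r} missing from {path.name}")
        order.append(names.index(marker))
    return Trial(signer_id, trial_id, frames[:, order, :], fr)


# ---------------------------------------------------------------------------
# geometric preprocessing


def reference_to_pelvis(trial: Trial, markerset: MarkerSet) -> Trial:
    """Express every marker relative to the origin marker, per frame.

    The origin marker becomes (0, 0, 0) at every frame; whole-body
    translation common to all markers is removed exactly.  Idempotent.
    """
    origin = markerset.index(markerset.origin_marker)
    frames = trial.frames - trial.frames[:, origin : origin + 1, :]
    return Trial(trial.signer_id, trial.trial_id, frames, trial.frame_rate)


def extract_segment(trial: Trial, start_s: float, duration_s: float) -> Trial:
    """Take ``round(duration_s * fps)`` frames from a half-open window."""
    start = int(round(start_s * trial.frame_rate))
    n = int(round(duration_s * trial.frame_rate))
    if start + n > trial.n_frames:
        raise MocapIOError(
            f"window [{start_s}, {start_s + duration_s}) s exceeds trial duration "
            f"{trial.duration_s:.3f} s"
        )
    return Trial(
        trial.signer_id,
        trial.trial_id,
        trial.frames[start : start + n],
        trial.frame_rate,
    )


def build_posture_matrix(
    trials: Sequence[Trial], markerset: MarkerSet
) -> PostureMatrix:
    """Stack trials (in order) into one posture matrix with segments."""
    if not trials:
        raise MocapIOError("no trials given")
    fr = trials[0].frame_rate
    segments: list[Segment] = []
    blocks = []
    pos = 0
    for tr in trials:
        if tr.frame_rate != fr:
            raise MocapIOError(
                f"mixed frame rates: {tr.frame_rate} vs {fr} ({tr.trial_id})"
            )
        if tr.n_markers != markerset.count:
            raise MocapIOError(f"trial {tr.trial_id} marker count != marker set")
        blocks.append(tr.frames.reshape(tr.n_frames, -1))
        segments.append(Segment(tr.signer_id, tr.trial_id, pos, pos + tr.n_frames))
        pos += tr.n_frames
    return PostureMatrix(
        np.concatenate(blocks, axis=0), fr, segments, markerset.column_labels()
    )


def drop_static_columns(
    pm: PostureMatrix, atol: float = 1e-6
) -> tuple[PostureMatrix, StaticColumns]:
    """Remove columns whose value range is below ``atol`` (mm) in every signer block.

    The default tolerance treats sub-micron ranges as static, so file
    round-trips at finite precision do not resurrect constant columns.

    After pelvis referencing the origin marker's coordinates are identically
    zero and carry no movement information; any marker rigid with the pelvis
    is likewise constant within a signer (its constant differing across
    signers only through anthropometry).  Removed per-signer constants are
    retained so full-marker trajectories can be reconstructed for display.
    """
    signers = pm.signer_ids()
    spans = []
    for signer in signers:
        block = pm.signer_block(signer)
        spans.append(block.max(axis=0) - block.min(axis=0))
    span = np.max(spans, axis=0)
    kept = np.flatnonzero(span > atol)
    dropped = np.flatnonzero(span <= atol)
    values = {
        signer: pm.signer_block(signer)[0, dropped].copy() for signer in signers
    }
    static = StaticColumns(
        kept=kept,
        dropped=dropped,
        dropped_values=values,
        dropped_labels=tuple(pm.column_labels[i] for i in dropped),
    )
    reduced = PostureMatrix(
        pm.rows[:, kept],
        pm.frame_rate,
        list(pm.segments),
        tuple(pm.column_labels[i] for i in kept),
    )
    return reduced, static


def restore_static_columns(
    rows: np.ndarray, static: StaticColumns, signer_id: str | None = None
) -> np.ndarray:
    """Re-embed reduced rows into the original full column layout.

    ``signer_id`` selects whose static constants to use; it may be omitted
    when only one signer's constants are stored.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if signer_id is None:
        if len(static.dropped_values) != 1:
            raise MocapIOError("signer_id required: multiple signers' constants stored")
        signer_id = next(iter(static.dropped_values))
    n_full = static.kept.size + static.dropped.size
    full = np.empty((rows.shape[0], n_full), dtype=float)
    full[:, static.kept] = rows
    full[:, static.dropped] = static.dropped_values[signer_id]
    return full


# ---------------------------------------------------------------------------
# HDF5 bundle


def save_posture_matrix(group: h5py.Group, pm: PostureMatrix) -> None:
    str_dt = h5py.string_dtype()
    group.create_dataset("rows", data=pm.rows, track_times=False)
    group.attrs["frame_rate"] = pm.frame_rate
    group.create_dataset(
        "column_labels",
        data=np.array(pm.column_labels, dtype=str_dt),
        track_times=False,
    )
    seg = np.array(
        [(s.signer_id, s.trial_id, s.start, s.stop) for s in pm.segments],
        dtype=[("signer_id", str_dt), ("trial_id", str_dt), ("start", "i8"), ("stop", "i8")],
    )
    group.create_dataset("segments", data=seg, track_times=False)


def load_posture_matrix(group: h5py.Group) -> PostureMatrix:
    rows = group["rows"][...]
    labels = tuple(s.decode() for s in group["column_labels"][...])
    segs = [
        Segment(r["signer_id"].decode(), r["trial_id"].decode(), int(r["start"]), int(r["stop"]))
        for r in group["segments"][...]
    ]
    return PostureMatrix(rows, float(group.attrs["frame_rate"]), segs, labels)
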