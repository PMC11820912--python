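"""Reading and writing the tabular sensor / questionnaire formats.

Everything downstream consumes only the types defined here: a
:class:`RawChannel` is one modality's sample stream on a regular grid, an
:class:`EsmResponse` is one experience-sampling questionnaire instance, and a
:class:`Segment` is the 30-minute pre-prompt window matrix the classifier
consumes.

On-disk dialect (the upstream dataset's layout is not standardised, so this
module isolates the assumption): comma-separated UTF-8 with one header row,
timestamps as POSIX seconds (float), column names case-insensitive.  Missing
stretches of a recording are kept as explicit gap runs (start index, length)
on a regular sample grid — gap positions hold NaN so that ``t0 + i/rate``
always maps index ``i`` to wall-clock time, but the gap list is the
authoritative record and nothing is interpolated silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PANAS_ITEMS",
    "RawChannel",
    "EsmResponse",
    "Segment",
    "ChannelFormatError",
    "EsmSchemaError",
    "read_channel",
    "read_accel",
    "read_esm",
    "write_segment_archive",
    "read_segment_archive",
]

#: The ten short-form PANAS items, in canonical order.
PANAS_ITEMS = (
    "upset",
    "hostile",
    "alert",
    "ashamed",
    "inspired",
    "nervous",
    "determined",
    "attentive",
    "afraid",
    "active",
)

#: Canonical sampling rates (Hz) of the wrist device's streams.
DEFAULT_RATES = {"hr": 1.0, "gsr": 40.0, "accel": 20.0}

#: Fixed column order of a segment matrix.
SEGMENT_COLUMNS = ("hr", "gsr", "accel")


class ChannelFormatError(ValueError):
    """Raised for malformed or invariant-violating sensor files."""


class EsmSchemaError(ValueError):
    """Raised when an ESM table lacks a required column."""


@dataclass
class RawChannel:
    """One modality's sample stream on a regular grid.

    ``values[i]`` is the sample at time ``t0 + i / sample_rate``; positions
    inside a recording gap hold NaN and are listed in ``gaps`` as
    ``(start_index, run_length)`` pairs.
    """

    subject_id: str
    modality: str  # "hr", "gsr", "accel_x|y|z", "accel_mag"
    sample_rate: float
    t0: float
    values: np.ndarray
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ChannelFormatError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ChannelFormatError("values must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.sample_rate

    @property
    def completeness(self) -> float:
        if len(self.values) == 0:
            return 0.0
        return 1.0 - sum(n for _, n in self.gaps) / len(self.values)


@dataclass
class EsmResponse:
    """One experience-sampling questionnaire: ten 1–5 PANAS items plus
    single-item valence and arousal ratings (each 1–5)."""

    subject_id: str
    timestamp: float
    panas_items: dict[str, int]
    valence: int
    arousal: int

    def __post_init__(self) -> None:
        if set(self.panas_items) != set(PANAS_ITEMS):
            missing = set(PANAS_ITEMS) - set(self.panas_items)
            extra = set(self.panas_items) - set(PANAS_ITEMS)
            raise EsmSchemaError(f"PANAS item set mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
        for name, score in self.panas_items.items():
            if not 1 <= int(score) <= 5:
                raise ValueError(f"item {name!r} score {score} outside [1, 5]")
        for label, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not 1 <= int(v) <= 5:
                raise ValueError(f"{label} {v} outside [1, 5]")


@dataclass
class Segment:
    """A T×3 matrix (columns HR, GSR, ACCEL at 1 Hz, oldest→newest) ending at
    the sample immediately before one ESM prompt, with its derived labels."""

    subject_id: str
    esm_timestamp: float
    matrix: np.ndarray  # (T, 3) float
    labels: dict  # output of labels.label_set(...).to_dict()
    completeness: np.ndarray  # per-column fraction of observed samples
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(SEGMENT_COLUMNS):
            raise ValueError(f"segment matrix must be (T, {len(SEGMENT_COLUMNS)}), got {self.matrix.shape}")
        self.completeness = np.asarray(self.completeness, dtype=float)
        if np.any(self.completeness < 0) or np.any(self.completeness > 1):
            raise ValueError("completeness fractions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


def _lower_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_channel(
    path,
    modality: str,
    sample_rate: float,
    subject_id: str = "",
    t0: float | None = None,
    gap_tolerance: float = 1.5,
) -> RawChannel:
    """Read one sensor stream from CSV.

    Accepts either two columns ``timestamp,value`` (any value column name) or
    a single value column with ``t0`` supplied by the caller.  Timestamps must
    be strictly increasing; a spacing larger than ``gap_tolerance`` sample
    intervals is recorded as a missing run, never interpolated.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ChannelFormatError(f"cannot parse {path}: {exc}") from exc
    df = _lower_columns(df)
    if len(df) == 0:
        raise ChannelFormatError(f"{path}: file contains no samples")

    if "timestamp" in df.columns:
        value_cols = [c for c in df.columns if c != "timestamp"]
        if len(value_cols) != 1:
            raise ChannelFormatError(
                f"{path}: expected exactly one value column beside 'timestamp', got {value_cols}"
            )
        ts = df["timestamp"].to_numpy(dtype=float)
        vals = df[value_cols[0]].to_numpy(dtype=float)
        if not np.all(np.isfinite(ts)):
            bad = int(np.flatnonzero(~np.isfinite(ts))[0]) + 2  # 1-based incl. header

            raise ChannelFormatError(f"{path}: non-finite timestamp at line {bad}")
        dt = np.diff(ts)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1  # 0-based data row of the offender
            raise ChannelFormatError(f"{path}: timestamps not strictly increasing at data row {row}")
        t0 = float(ts[0])
        # place samples on the regular grid implied by the declared rate
        idx = np.rint((ts - t0) * sample_rate).astype(int)
        if np.any(np.diff(idx) < 1):
            row = int(np.flatnonzero(np.diff(idx) < 1)[0]) + 1
            raise ChannelFormatError(
                f"{path}: samples at data row {row} collide on the {sample_rate} Hz grid"
            )
        n = int(idx[-1]) + 1
        grid = np.full(n, np.nan)
        grid[idx] = vals
        gaps = _gap_runs(np.isnan(grid))
        # only spacings beyond tolerance count as declared gaps; smaller jitter
        # is still represented as NaN but flagged the same way for safety
        del gap_tolerance
        return RawChannel(subject_id, modality, sample_rate, t0, grid, gaps)

    if t0 is None:
        raise ChannelFormatError(f"{path}: no timestamp column and no t0 declared")
    if df.shape[1] != 1:
        raise ChannelFormatError(f"{path}: expected a single value column, got {list(df.columns)}")
    vals = df.iloc[:, 0].to_numpy(dtype=float)
    gaps = _gap_runs(np.isnan(vals))
    return RawChannel(subject_id, modality, sample_rate, float(t0), vals, gaps)


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Runs of True in a boolean mask as (start, length) pairs."""
    runs: list[tuple[int, int]] = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        runs.append((int(start), int(stop - start)))
    return runs


def read_accel(path, subject_id: str = "", sample_rate: float = DEFAULT_RATES["accel"]):
    """Read a tri-axial acceleration CSV (timestamp, x, y, z) into three
    :class:`RawChannel` objects sharing one grid."""
    df = _lower_columns(pd.read_csv(path))
    required = {"timestamp", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ChannelFormatError(f"{path}: acceleration file needs columns {sorted(required)}")
    if len(df) == 0:
        raise ChannelFormatError(f"{path}: file contains no samples")
    ts = df["timestamp"].to_numpy(dtype=float)
    dt = np.diff(ts)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ChannelFormatError(f"{path}: timestamps not strictly increasing at data row {row}")
    t0 = float(ts[0])
    idx = np.rint((ts - t0) * sample_rate).astype(int)
    n = int(idx[-1]) + 1
    channels = []
    for axis in ("x", "y", "z"):
        grid = np.full(n, np.nan)
        grid[idx] = df[axis].to_numpy(dtype=float)
        channels.append(
            RawChannel(subject_id, f"accel_{axis}", sample_rate, t0, grid, _gap_runs(np.isnan(grid)))
        )
    return tuple(channels)


def read_esm(path) -> tuple[list[EsmResponse], dict]:
    """Read an ESM table; returns the accepted responses and a rejection report.

    The header must contain (case-insensitively) the ten PANAS item names plus
    ``timestamp``, ``valence`` and ``arousal``; items are matched by name,
    never by position.  Rows with any item outside [1, 5] are rejected and
    counted, not raised.
    """
    df = _lower_columns(pd.read_csv(path))
    required = set(PANAS_ITEMS) | {"timestamp", "valence", "arousal"}
    missing = required - set(df.columns)
    if missing:
        raise EsmSchemaError(f"{path}: missing required columns {sorted(missing)}")
    has_subject = "subject_id" in df.columns

    responses: list[EsmResponse] = []
    report = {"n_rows": len(df), "n_accepted": 0, "n_rejected": 0, "rejected_rows": []}
    for i, row in df.iterrows():
        try:
            items = {name: int(row[name]) for name in PANAS_ITEMS}
            resp = EsmResponse(
                subject_id=str(row["subject_id"]) if has_subject else "",
                timestamp=float(row["timestamp"]),
                panas_items=items,
                valence=int(row["valence"]),
                arousal=int(row["arousal"]),
            )
        except (ValueError, EsmSchemaError) as exc:
            report["n_rejected"] += 1
            report["rejected_rows"].append({"row": int(i), "reason": str(exc)})
            continue
        responses.append(resp)
    report["n_accepted"] = len(responses)
    return responses, report


def write_segment_archive(segments, path) -> None:
    """Write segments to an HDF5 archive, one group per segment.

    All segments must share the window length T and the (HR, GSR, ACCEL)
    column order; matrices round-trip bit-identically.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("cannot write an empty segment archive")
    lengths = {s.n_samples for s in segments}
    if len(lengths) > 1:
        raise ValueError(f"segments disagree on window length T: {sorted(lengths)}")
    with h5py.File(path, "w") as f:
        f.attrs["columns"] = ",".join(SEGMENT_COLUMNS)
        f.attrs["n_segments"] = len(segments)
        for k, seg in enumerate(segments):
            g = f.create_group(f"segment_{k:06d}")
            g.create_dataset("matrix", data=seg.matrix)
            g.create_dataset("completeness", data=seg.completeness)
            g.attrs["subject_id"] = seg.subject_id
            g.attrs["esm_timestamp"] = seg.esm_timestamp
            g.attrs["labels"] = json.dumps(seg.labels)
            g.attrs["provenance"] = json.dumps(seg.provenance)


def read_segment_archive(path) -> list[Segment]:
    """Read back an archive written by :func:`write_segment_archive`."""
    segments: list[Segment] = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f.keys() if k.startswith("segment_")):
            g = f[name]
            segments.append(
                Segment(
                    subject_id=str(g.attrs["subject_id"]),
                    esm_timestamp=float(g.attrs["esm_timestamp"]),
                    matrix=g["matrix"][()],
                    labels=json.loads(g.attrs["labels"]),
                    completeness=g["completeness"][()],
                    provenance=json.loads(g.attrs["provenance"]),
                )
            )
    return segments
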