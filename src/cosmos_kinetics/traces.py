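"""Intensity traces, binding intervals, and interval-table I/O.

The bridge between raw per-location fluorescence time series and the
kinetic statistics: sliding-window averaging, hysteresis binarization,
run-length extraction of censor-flagged binding intervals, and lossless
CSV round-trip of interval tables.  A best-effort reader for MATLAB
interval containers of the kind produced by single-molecule colocalization
analysis GUIs is included.

Conventions: intervals are closed on the left, open on the right, in
seconds; a frame [f*dt, (f+1)*dt) belongs to the interval iff it is part of
the presence run.  Red-interleave frames are missing data, not absence, and
runs separated only by missing frames are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSchedule
from .simulate import PanelData, PresenceTrace

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "Interval",
    "IntervalsTable",
    "IntervalParseError",
    "UnsupportedFormatError",
    "sliding_average",
    "threshold_trace",
    "extract_intervals",
    "intervals_from_panel",
    "write_intervals",
    "read_intervals",
    "write_imscroll_intervals",
    "read_imscroll_intervals",
]


class IntervalParseError(ValueError):
    """Malformed interval file; message names the offending line."""


class UnsupportedFormatError(ValueError):
    """Container cannot be interpreted as an intervals file."""


@dataclass
class IntensityTrace:
    """One location's fluorescence time series with a missing-frame mask."""

    location_id: str
    times: np.ndarray  # frame start times, s, strictly increasing
    values: np.ndarray  # arbitrary fluorescence units
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.values.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (np.diff(self.times) > 0).all():
            raise ValueError("frame times must be strictly increasing")
        if not (self.times.shape == self.values.shape == self.missing.shape):
            raise ValueError("times, values and mask must have equal length")


@dataclass(frozen=True)
class Interval:
    """One bound period on one surface location.

    ``right_censored`` marks intervals that touch the final observed frame
    (the true dwell exceeds the observed span); ``left_censored`` the first.
    """

    location_id: str
    start: float
    end: float
    left_censored: bool = False
    right_censored: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"interval end must exceed start ({self.start}, {self.end})")

    @property
    def dwell(self) -> float:
        return self.end - self.start


@dataclass
class IntervalsTable:
    """Censor-flagged binding intervals plus per-location metadata.

    Every observed location appears in ``metadata`` (columns location_id,
    construct, n_frames_observed) even when it produced zero intervals —
    zero-event locations carry exactly the information the background
    correction and the per-location averages need.
    """

    intervals: list[Interval]
    metadata: pd.DataFrame
    schedule: AcquisitionSchedule = field(default_factory=AcquisitionSchedule)

    def __post_init__(self) -> None:
        required = {"location_id", "construct", "n_frames_observed"}
        if not required.issubset(self.metadata.columns):
            raise ValueError(f"metadata must have columns {sorted(required)}")
        if self.metadata["location_id"].duplicated().any():
            raise ValueError("duplicate location_id in metadata")
        known = set(self.metadata["location_id"])
        by_loc: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            if iv.location_id not in known:
                raise ValueError(f"interval references unknown location {iv.location_id!r}")
            by_loc.setdefault(iv.location_id, []).append(iv)
        for lid, ivs in by_loc.items():
            ivs_sorted = sorted(ivs, key=lambda i: i.start)
            for a, b in zip(ivs_sorted, ivs_sorted[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping intervals at location {lid!r}")
        self.intervals = sorted(self.intervals, key=lambda i: (i.location_id, i.start))

    # -- accessors ---------------------------------------------------------

    def constructs(self) -> list[str]:
        return sorted(self.metadata["construct"].unique())

    def location_ids(self, construct: str | None = None) -> list[str]:
        md = self.metadata
        if construct is not None:
            md = md[md["construct"] == construct]
        return sorted(md["location_id"])

    def intervals_for(self, construct: str) -> list[Interval]:
        lids = set(self.location_ids(construct))
        return [iv for iv in self.intervals if iv.location_id in lids]

    def dwells_by_location(self, construct: str) -> dict[str, np.ndarray]:
        """Observed dwell times keyed by location, empty arrays included."""
        out: dict[str, list[float]] = {lid: [] for lid in self.location_ids(construct)}
        for iv in self.intervals_for(construct):
            out[iv.location_id].append(iv.dwell)
        return {lid: np.asarray(d, dtype=float) for lid, d in out.items()}

    def observed_duration(self, location_id: str) -> float:
        md = self.metadata.set_index("location_id")
        return float(md.loc[location_id, "n_frames_observed"]) * self.schedule.frame_duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "location_id": iv.location_id,
                    "start_s": iv.start,
                    "end_s": iv.end,
                    "dwell_s": iv.dwell,
                    "left_censored": iv.left_censored,
                    "right_censored": iv.right_censored,
                    "label": iv.label,
                }
                for iv in self.intervals
            ],
            columns=[
                "location_id",
                "start_s",
                "end_s",
                "dwell_s",
                "left_censored",
                "right_censored",
                "label",
            ],
        )

    def merged_with(self, other: "IntervalsTable") -> "IntervalsTable":
        md = pd.concat([self.metadata, other.metadata], ignore_index=True)
        return IntervalsTable(self.intervals + other.intervals, md, self.schedule)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalsTable):
            return NotImplemented
        a = self.metadata.sort_values("location_id").reset_index(drop=True)
        b = other.metadata.sort_values("location_id").reset_index(drop=True)
        return (
            self.intervals == other.intervals
            and a[["location_id", "construct", "n_frames_observed"]].equals(
                b[["location_id", "construct", "n_frames_observed"]]
            )
            and self.schedule == other.schedule
        )


# ---------------------------------------------------------------------------
# trace processing


def sliding_average(trace: IntensityTrace, window: int = 5) -> IntensityTrace:
    """Centered moving mean over `window` frames, skipping missing frames.

    The missing mask is carried through unchanged.  ``window`` must be odd so
    the mean is centered; a window of 1 returns the input unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > trace.values.size:
        raise ValueError("window larger than trace")
    if window == 1:
        return trace
    half = window // 2
    vals = np.where(trace.missing, np.nan, trace.values)
    n = vals.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = vals[lo:hi]
        with np.errstate(invalid="ignore"):
            m = np.nanmean(seg) if not np.isnan(seg).all() else np.nan
        out[i] = m
    return replace(trace, values=out)


def threshold_trace(
    trace: IntensityTrace,
    on_level: float,
    off_level: float,
    schedule: AcquisitionSchedule | None = None,
) -> PresenceTrace:
    """Hysteresis binarization of an intensity trace.

    The detector turns on when the value reaches ``on_level`` and off when
    it drops below ``off_level`` (``on_level >= off_level``); the dead band
    between the two absorbs flicker around a single threshold.  Missing
    frames inherit the shared state of their non-missing neighbors, else
    absent.
    """
    if on_level < off_level:
        raise ValueError("on_level must be >= off_level")
    vals = trace.values
    missing = trace.missing
    n = vals.size
    present = np.zeros(n, dtype=bool)
    state = False
    for i in range(n):
        if missing[i]:
            present[i] = False  # filled in a second pass
            continue
        if not state and vals[i] >= on_level:
            state = True
        elif state and vals[i] < off_level:
            state = False
        present[i] = state
    # missing frames: inherit when both non-missing neighbors agree
    obs_idx = np.flatnonzero(~missing)
    for i in np.flatnonzero(missing):
        left = obs_idx[obs_idx < i]
        right = obs_idx[obs_idx > i]
        if left.size and right.size and present[left[-1]] == present[right[0]]:
            present[i] = present[left[-1]]
    sched = schedule or AcquisitionSchedule(
        frame_duration=float(trace.times[1] - trace.times[0]) if n > 1 else 1.0,
        total_duration=float(trace.times[-1] + (trace.times[1] - trace.times[0]))
        if n > 1
        else 1.0,
    )
    return PresenceTrace(trace.location_id, present, missing.copy(), sched)


def extract_intervals(
    trace: PresenceTrace,
    schedule: AcquisitionSchedule | None = None,
    label: str = "",
) -> list[Interval]:
    """Turn maximal presence runs into censor-flagged intervals.

    Runs separated only by missing frames are merged (a red interleave must
    not split one binding event into two).  An interval touching the first
    or last observed frame is flagged left- or right-censored respectively.
    """
    sched = schedule or trace.schedule
    dt = sched.frame_duration
    present = trace.present
    missing = trace.missing
    n = present.size
    obs = np.flatnonzero(~missing)
    if obs.size == 0:
        return []
    first_obs, last_obs = obs[0], obs[-1]

    # bridge: treat missing frames flanked by presence as present
    bridged = present.copy()
    runs: list[tuple[int, int]] = []  # [first_frame, last_frame] inclusive
    i = 0
    while i < n:
        if bridged[i] and not missing[i]:
            j = i
            while j + 1 < n and (bridged[j + 1] or missing[j + 1]):
                # extend through missing frames only if presence resumes
                if missing[j + 1]:
                    k = j + 1
                    while k < n and missing[k]:
                        k += 1
                    if k < n and bridged[k]:
                        j = k
                        continue
                    break
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    out = []
    for a, b in runs:
        out.append(
            Interval(
                trace.location_id,
                start=a * dt,
                end=(b + 1) * dt,
                left_censored=a <= first_obs,
                right_censored=b >= last_obs,
                label=label,
            )
        )
    return out


def intervals_from_panel(panel: PanelData, label: str = "") -> IntervalsTable:
    """Extract an IntervalsTable directly from simulated presence traces."""
    intervals: list[Interval] = []
    meta_rows = []
    construct_of = {lid: name for lid, name, _, _ in panel.layout.locations}
    for lid in sorted(panel.traces):
        tr = panel.traces[lid]
        intervals.extend(extract_intervals(tr, panel.schedule, label=label))
        meta_rows.append(
            {
                "location_id": lid,
                "construct": construct_of[lid],
                "n_frames_observed": int((~tr.missing).sum()),
            }
        )
    return IntervalsTable(intervals, pd.DataFrame(meta_rows), panel.schedule)


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = [
    "location_id",
    "construct",
    "start_s",
    "end_s",
    "left_censored",
    "right_censored",
    "label",
    "n_frames_observed",
]


def write_intervals(table: IntervalsTable, path) -> None:
    """Write an interval table as CSV.

    One row per interval; a location with zero intervals contributes a
    single row with empty start/end so the location census survives the
    round trip.  The schedule is stored in ``#schedule`` header comments.
    """
    md = table.metadata.set_index("location_id")
    rows = []
    seen = set()
    for iv in table.intervals:
        seen.add(iv.location_id)
        rows.append(
            {
                "location_id": iv.location_id,
                "construct": md.loc[iv.location_id, "construct"],
                "start_s": iv.start,
                "end_s": iv.end,
                "left_censored": int(iv.left_censored),
                "right_censored": int(iv.right_censored),
                "label": iv.label,
                "n_frames_observed": int(md.loc[iv.location_id, "n_frames_observed"]),
            }
        )
    for lid in table.metadata["location_id"]:
        if lid not in seen:
            rows.append(
                {
                    "location_id": lid,
                    "construct": md.loc[lid, "construct"],
                    "start_s": "",
                    "end_s": "",
                    "left_censored": "",
                    "right_censored": "",
                    "label": "",
                    "n_frames_observed": int(md.loc[lid, "n_frames_observed"]),
                }
            )
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    s = table.schedule
    with open(path, "w") as fh:
        fh.write(
            f"#schedule frame_duration={s.frame_duration} "
            f"green_block_length={s.green_block_length} "
            f"red_interleave_length={s.red_interleave_length} "
            f"total_duration={s.total_duration}\n"
        )
        frame.to_csv(fh, index=False)


def read_intervals(path) -> IntervalsTable:
    """Read an interval table written by :func:`write_intervals`.

    Malformed rows (e.g. end <= start) raise :class:`IntervalParseError`
    naming the file line.
    """
    schedule = AcquisitionSchedule()
    n_comment = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#schedule"):
            n_comment = 1
            kv = dict(tok.split("=") for tok in first.split()[1:])
            schedule = AcquisitionSchedule(
                frame_duration=float(kv["frame_duration"]),
                green_block_length=int(kv["green_block_length"]),
                red_interleave_length=int(kv["red_interleave_length"]),
                total_duration=float(kv["total_duration"]),
            )
    frame = pd.read_csv(path, comment="#", dtype={"location_id": str, "label": str})
    missing_cols = set(_CSV_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise IntervalParseError(f"missing columns: {sorted(missing_cols)}")
    intervals: list[Interval] = []
    meta: dict[str, tuple[str, int]] = {}
    for idx, row in frame.iterrows():
        line_no = idx + 2 + n_comment  # header + comment offset
        lid = str(row["location_id"])
        meta[lid] = (str(row["construct"]), int(row["n_frames_observed"]))
        if pd.isna(row["start_s"]):
            continue
        start, end = float(row["start_s"]), float(row["end_s"])
        if not end > start:
            raise IntervalParseError(
                f"{path}, line {line_no}: interval end {end} <= start {start}"
            )
        intervals.append(
            Interval(
                lid,
                start,
                end,
                left_censored=bool(int(row["left_censored"])),
                right_censored=bool(int(row["right_censored"])),
                label="" if pd.isna(row["label"]) else str(row["label"]),
            )
        )
    metadata = pd.DataFrame(
        [
            {"location_id": lid, "construct": c, "n_frames_observed": nf}
            for lid, (c, nf) in meta.items()
        ]
    )
    return IntervalsTable(intervals, metadata, schedule)


# ---------------------------------------------------------------------------
# MATLAB interval containers (best effort)


def write_imscroll_intervals(table: IntervalsTable, path) -> None:
    """Write a MATLAB container in the documented per-location layout.

    Layout: a struct ``intervals`` with cell field ``l`` (one n×2 double of
    [start_frame, stop_frame] rows per location), plus ``location_ids``,
    ``classes`` (construct names), ``nframes`` and ``framedur``.
    """
    from scipy.io import savemat

    dt = table.schedule.frame_duration
    lids = list(table.metadata["location_id"])
    md = table.metadata.set_index("location_id")
    cells = np.empty(len(lids), dtype=object)
    for i, lid in enumerate(lids):
        ivs = [iv for iv in table.intervals if iv.location_id == lid]
        arr = np.array(
            [[iv.start / dt, iv.end / dt - 1] for iv in ivs], dtype=float
        ).reshape(len(ivs), 2)
        cells[i] = arr
    savemat(
        path,
        {
            "intervals": {
                "l": cells,
                "location_ids": np.array(lids, dtype=object),
                "classes": np.array(
                    [md.loc[lid, "construct"] for lid in lids], dtype=object
                ),
                "nframes": np.array(
                    [int(md.loc[lid, "n_frames_observed"]) for lid in lids]
                ),
                "framedur": dt,
            }
        },
    )


def read_imscroll_intervals(path) -> IntervalsTable:
    """Best-effort reader for MATLAB interval containers.

    Looks for a struct variable holding per-location cell arrays of
    [start_frame, stop_frame, ...] rows under a field named ``l``, ``t`` or
    ``list``, and location classes under ``classes`` or ``class``.  Unknown
    fields are ignored with a logged warning; a container that cannot be
    interpreted raises :class:`UnsupportedFormatError` rather than returning
    silent partial data.
    """
    from scipy.io import loadmat

    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # noqa: BLE001 - any loadmat failure is terminal
        raise UnsupportedFormatError(f"cannot read {path} as a MATLAB file: {exc}")

    known_fields = {"l", "t", "list", "location_ids", "classes", "class", "nframes", "framedur"}
    for name, var in mat.items():
        if name.startswith("__"):
            continue
        fields = getattr(var, "_fieldnames", None)
        if fields is None:
            continue
        cell_field = next((f for f in ("l", "t", "list") if f in fields), None)
        if cell_field is None:
            continue
        for f in fields:
            if f not in known_fields:
                logger.warning("ignoring unknown field %r in %s", f, path)
        cells = np.atleast_1d(getattr(var, cell_field))
        if cells.dtype != object:
            # a single location's cell collapses to a plain numeric array
            single = np.asarray(getattr(var, cell_field), dtype=float)
            cells = np.empty(1, dtype=object)
            cells[0] = single
        n_loc = cells.size
        classes = None
        for cf in ("classes", "class"):
            if cf in fields:
                classes = np.atleast_1d(getattr(var, cf))
        lids = (
            np.atleast_1d(getattr(var, "location_ids"))
            if "location_ids" in fields
            else np.array([f"loc_{i:05d}" for i in range(n_loc)], dtype=object)
        )
        dt = float(getattr(var, "framedur", 1.0)) if "framedur" in fields else 1.0
        nframes = (
            np.atleast_1d(getattr(var, "nframes"))
            if "nframes" in fields
            else None
        )
        intervals: list[Interval] = []
        meta_rows = []
        max_frame = 0
        for i in range(n_loc):
            arr = np.atleast_2d(np.asarray(cells[i], dtype=float))
            lid = str(lids[i]) if i < len(lids) else f"loc_{i:05d}"
            cls = str(classes[i]) if classes is not None and i < len(classes) else "unknown"
            nf = int(nframes[i]) if nframes is not None and i < len(nframes) else 0
            if arr.size:
                if arr.shape[1] < 2:
                    raise UnsupportedFormatError(
                        f"{path}: per-location arrays need >= 2 columns"
                    )
                for row in arr:
                    start_f, stop_f = float(row[0]), float(row[1])
                    intervals.append(
                        Interval(lid, start_f * dt, (stop_f + 1) * dt)
                    )
                    max_frame = max(max_frame, int(stop_f) + 1)
            meta_rows.append(
                {"location_id": lid, "construct": cls, "n_frames_observed": nf}
            )
        meta = pd.DataFrame(
            meta_rows, columns=["location_id", "construct", "n_frames_observed"]
        )
        if len(meta) and (meta["n_frames_observed"] == 0).all() and max_frame:
            meta["n_frames_observed"] = max_frame
        max_meta_frames = int(meta["n_frames_observed"].max()) if len(meta) else 1
        total = max(max_frame, max_meta_frames, 1) * dt
        sched = AcquisitionSchedule(
            frame_duration=dt,
            green_block_length=max(int(round(total / dt)), 1),
            red_interleave_length=0,
            total_duration=max(total, dt),
        )
        return IntervalsTable(intervals, meta, sched)
    raise UnsupportedFormatError(
        f"{path}: no interval struct found (expected a struct with an "
        f"'l'/'t'/'list' cell field)"
    )
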