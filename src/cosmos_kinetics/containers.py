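"""Serialization of simulated panels.

Two equivalent on-disk forms: tidy CSV (one file for ground-truth events,
one for the layout, one for discretized traces) and a single-file HDF5
container holding the same arrays hierarchically.  Column meanings are
documented in ``docs/schemas.md``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .acquisition import AcquisitionSchedule
from .params import KineticModelParams
from .simulate import BindingEvent, PanelData, PresenceTrace, SlideLayout, TrueTimeline

__all__ = ["save_panel_csv", "save_panel_hdf5", "load_panel_hdf5"]


def save_panel_csv(panel: PanelData, directory) -> None:
    """Write layout, ground-truth events and traces as three CSV files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    panel.layout.to_frame().to_csv(d / "layout.csv", index=False)
    panel.ground_truth_events().to_csv(d / "ground_truth_events.csv", index=False)
    lids = sorted(panel.traces)
    mat = np.array([panel.traces[lid].present for lid in lids], dtype=int)
    missing = panel.schedule.red_frame_mask()
    frame = pd.DataFrame(mat.T, columns=lids)
    frame.insert(0, "frame_start_s", panel.schedule.frame_start_times())
    frame.insert(1, "missing", missing.astype(int))
    frame.to_csv(d / "presence_traces.csv", index=False)


def _schedule_attrs(sched: AcquisitionSchedule) -> dict:
    return {
        "frame_duration": sched.frame_duration,
        "green_block_length": sched.green_block_length,
        "red_interleave_length": sched.red_interleave_length,
        "total_duration": sched.total_duration,
    }


def save_panel_hdf5(panel: PanelData, path) -> None:
    """Write a panel into a single hierarchical container.

    Layout: ``/layout`` (table), ``/traces/<location_id>`` (uint8 presence),
    ``/events/<location_id>`` (n×5 float: arrival, departure, labeled,
    specific, bleached_at with NaN for never), schedule and kinetic
    parameters as root attributes.
    """
    with h5py.File(path, "w") as fh:
        for k, v in _schedule_attrs(panel.schedule).items():
            fh.attrs[f"schedule_{k}"] = v
        p = panel.params
        fh.attrs["labeling_fraction"] = p.labeling_fraction
        fh.attrs["bleach_rate"] = p.bleach_rate
        fh.attrs["synergy_factor"] = p.synergy_factor
        lay = fh.create_group("layout")
        lids = [lid for lid, _, _, _ in panel.layout.locations]
        lay.create_dataset("location_id", data=np.array(lids, dtype="S"))
        lay.create_dataset(
            "construct",
            data=np.array(
                [c for _, c, _, _ in panel.layout.locations], dtype="S"
            ),
        )
        lay.create_dataset("x_um", data=[x for _, _, x, _ in panel.layout.locations])
        lay.create_dataset("y_um", data=[y for _, _, _, y in panel.layout.locations])
        lay.attrs["field_x_um"] = panel.layout.field_size[0]
        lay.attrs["field_y_um"] = panel.layout.field_size[1]
        lay.attrs["density"] = panel.layout.density
        tr = fh.create_group("traces")
        for lid, trace in panel.traces.items():
            tr.create_dataset(lid, data=trace.present.astype(np.uint8))
        ev = fh.create_group("events")
        for lid, tl in panel.timelines.items():
            arr = np.array(
                [
                    [
                        e.arrival,
                        e.departure,
                        float(e.labeled),
                        float(e.specific),
                        np.nan if e.bleached_at is None else e.bleached_at,
                    ]
                    for e in tl.events
                ],
                dtype=float,
            ).reshape(len(tl.events), 5)
            ev.create_dataset(lid, data=arr)


def load_panel_hdf5(path, params: KineticModelParams | None = None) -> PanelData:
    """Read a panel container written by :func:`save_panel_hdf5`."""
    with h5py.File(path, "r") as fh:
        sched = AcquisitionSchedule(
            frame_duration=float(fh.attrs["schedule_frame_duration"]),
            green_block_length=int(fh.attrs["schedule_green_block_length"]),
            red_interleave_length=int(fh.attrs["schedule_red_interleave_length"]),
            total_duration=float(fh.attrs["schedule_total_duration"]),
        )
        lay = fh["layout"]
        lids = [s.decode() for s in lay["location_id"][()]]
        constructs = [s.decode() for s in lay["construct"][()]]
        xs, ys = lay["x_um"][()], lay["y_um"][()]
        layout = SlideLayout(
            list(zip(lids, constructs, map(float, xs), map(float, ys))),
            (float(lay.attrs["field_x_um"]), float(lay.attrs["field_y_um"])),
            float(lay.attrs["density"]),
        )
        missing = sched.red_frame_mask()
        traces = {
            lid: PresenceTrace(
                lid, fh["traces"][lid][()].astype(bool), missing.copy(), sched
            )
            for lid in fh["traces"]
        }
        timelines = {}
        for lid in fh["events"]:
            arr = fh["events"][lid][()]
            events = [
                BindingEvent(
                    float(a),
                    float(d),
                    bool(lab),
                    bool(spec),
                    None if np.isnan(bl) else float(bl),
                )
                for a, d, lab, spec, bl in arr
            ]
            timelines[lid] = TrueTimeline(lid, events)
        return PanelData(
            layout, sched, params or KineticModelParams(), traces, timelines
        )
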