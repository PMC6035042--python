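# File formats

## Interval table CSV (`write_intervals` / `read_intervals`)

First line: `#schedule frame_duration=... green_block_length=...
red_interleave_length=... total_duration=...` (all in seconds / frames).
Then a standard CSV with one row per interval:

| column | type | meaning |
|---|---|---|
| `location_id` | str | unique surface location |
| `construct` | str | RNA species name; `no_RNA` marks control locations |
| `start_s` | float | interval start, s (closed) |
| `end_s` | float | interval end, s (open); `end_s > start_s` |
| `left_censored` | 0/1 | interval touches the first observed frame |
| `right_censored` | 0/1 | interval touches the last observed frame |
| `label` | str | channel / subcomplex tag (free text) |
| `n_frames_observed` | int | non-missing frames observed at this location |

A location with zero intervals appears as one row with empty
`start_s`/`end_s` so the location census (the N in all per-location means)
survives a round trip.

## MATLAB interval container (`write_imscroll_intervals` / `read_imscroll_intervals`)

A `.mat` file with a struct variable `intervals`:

- `l` — cell array, one n×2 double per location with rows
  `[start_frame, stop_frame]` (0-based, inclusive);
- `location_ids` — cell array of strings;
- `classes` — cell array of construct names;
- `nframes` — observed frame count per location;
- `framedur` — frame duration in seconds.

The reader also accepts per-location cells under `t` or `list` and ignores
unknown fields with a logged warning; files without a recognizable
interval struct raise `UnsupportedFormatError`.

## Simulated panel CSV bundle (`save_panel_csv`)

- `layout.csv` — `location_id, construct, x_um, y_um`;
- `ground_truth_events.csv` — `location_id, construct, arrival_s,
  departure_s, labeled, specific, bleached_at_s` (empty = never bleached);
- `presence_traces.csv` — `frame_start_s, missing, <one 0/1 column per
  location>`.

## HDF5 panel container (`save_panel_hdf5`)

Root attributes `schedule_*` (the four schedule fields) plus
`labeling_fraction`, `bleach_rate`, `synergy_factor`; groups:

- `/layout` — datasets `location_id`, `construct`, `x_um`, `y_um`; attrs
  `field_x_um`, `field_y_um`, `density`;
- `/traces/<location_id>` — uint8 presence per frame;
- `/events/<location_id>` — n×5 float64 `[arrival_s, departure_s, labeled,
  specific, bleached_at_s]` with NaN for never-bleached.

## Experiment config YAML (`ExperimentConfig`)

Top-level keys `panel` (list of `{name, count, upstream_5ss_functional,
downstream_5ss_functional, bs_3ss_functional, spliceable}`), `n_controls`,
`params` (KineticModelParams fields), `schedule` (AcquisitionSchedule
fields), `duration_threshold_s`, `secondary_threshold_s`, `n_bootstrap`,
`frequency_per_second`, `seed`, `field_size_um`, `density_bounds`,
`synergy_constructs`. Unknown keys are rejected; every run writes the fully
resolved config (no hidden defaults) next to its outputs.
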