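"""Config-driven end-to-end analysis runs.

``run_simulated_experiment`` reproduces a complete experiment from a single
YAML-serializable config: simulate a panel, extract intervals, compute
every construct's dwell distribution, specific frequency (total and by
duration class), specific occupancy, first-binding fit, rastergram summary,
and — when the panel contains the both-sites/single-site construct trio —
the synergy ratio.  ``analyze_intervals`` runs the same statistics on
interval tables supplied from disk.

Runs are deterministic under their seed: the resolved config (no hidden
defaults) is written next to the outputs and rerunning produces a
byte-identical summary JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acquisition import AcquisitionSchedule
from .constructs import NO_RNA, ConstructSpec, validate_panel
from .params import KineticModelParams
from .simulate import PanelData, build_slide_layout, simulate_panel
from .stats import (
    build_rastergram,
    cumulative_dwell_distribution,
    first_binding_times,
    fit_first_binding,
    frequency_by_duration_class,
    frequency_occupancy_ratio,
    occupancy_from_table,
    specific_binding_frequency,
    synergy_ratio,
)
from .traces import IntervalsTable, intervals_from_panel, read_intervals, write_intervals

__all__ = ["ExperimentConfig", "run_simulated_experiment", "analyze_intervals"]


@dataclass
class ExperimentConfig:
    """Fully resolved description of one simulated experiment."""

    panel: list[dict] = field(
        default_factory=lambda: [
            {
                "name": "5i3e5",
                "count": 100,
                "upstream_5ss_functional": True,
                "downstream_5ss_functional": True,
                "bs_3ss_functional": True,
                "spliceable": True,
            },
            {
                "name": "Xi3e5",
                "count": 100,
                "upstream_5ss_functional": False,
                "downstream_5ss_functional": True,
                "bs_3ss_functional": True,
                "spliceable": False,
            },
            {
                "name": "5i3eX",
                "count": 100,
                "upstream_5ss_functional": True,
                "downstream_5ss_functional": False,
                "bs_3ss_functional": True,
                "spliceable": True,
            },
            {
                "name": "Xi3eX",
                "count": 100,
                "upstream_5ss_functional": False,
                "downstream_5ss_functional": False,
                "bs_3ss_functional": True,
                "spliceable": False,
            },
        ]
    )
    n_controls: int = 100
    params: dict = field(default_factory=lambda: asdict(KineticModelParams()))
    schedule: dict = field(default_factory=lambda: asdict(AcquisitionSchedule()))
    duration_threshold_s: float = 50.0
    secondary_threshold_s: float = 60.0
    n_bootstrap: int = 2000
    frequency_per_second: bool = False
    seed: int = 0
    field_size_um: tuple[float, float] = (120.0, 120.0)
    density_bounds: tuple[float, float] = (0.0, 0.5)
    synergy_constructs: tuple[str, str, str] | None = ("5i3e5", "5i3eX", "Xi3e5")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        cfg = cls()
        known = set(asdict(cfg))
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown config field: {key}")
            if key in ("field_size_um", "density_bounds", "synergy_constructs"):
                value = tuple(value) if value is not None else None
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        errors = []
        for i, entry in enumerate(self.panel):
            if "name" not in entry:
                errors.append(f"panel[{i}].name: missing")
            if entry.get("count", 0) <= 0:
                errors.append(f"panel[{i}].count: must be > 0")
        try:
            self.kinetic_params()
        except (TypeError, ValueError) as exc:
            errors.append(f"params: {exc}")
        try:
            self.acquisition_schedule()
        except (TypeError, ValueError) as exc:
            errors.append(f"schedule: {exc}")
        if self.n_bootstrap < 2:
            errors.append("n_bootstrap: must be >= 2")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    def constructs(self) -> list[ConstructSpec]:
        out = []
        for entry in self.panel:
            out.append(
                ConstructSpec(
                    entry["name"],
                    bool(entry.get("upstream_5ss_functional", False)),
                    bool(entry.get("downstream_5ss_functional", False)),
                    bool(entry.get("bs_3ss_functional", False)),
                    bool(entry.get("spliceable", False)),
                )
            )
        validate_panel(out)
        return out

    def kinetic_params(self) -> KineticModelParams:
        p = dict(self.params)
        if "dwell_mixture" in p:
            p["dwell_mixture"] = tuple(tuple(c) for c in p["dwell_mixture"])
        if "k_assoc_overrides" in p:
            p["k_assoc_overrides"] = tuple(
                tuple(c) for c in p["k_assoc_overrides"]
            )
        return KineticModelParams(**p)

    def acquisition_schedule(self) -> AcquisitionSchedule:
        return AcquisitionSchedule(**self.schedule)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# analysis core shared by the simulated and supplied-data entry points


def _analyze_table(
    table: IntervalsTable, cfg: ExperimentConfig, constructs: list[str]
) -> dict:
    summary: dict = {"constructs": {}}
    T = table.schedule.total_duration
    ctrl_present = NO_RNA in table.constructs()
    d_ctrl = (
        cumulative_dwell_distribution(table, NO_RNA) if ctrl_present else None
    )
    for name in constructs:
        if name == NO_RNA:
            continue
        entry: dict = {}
        d_rna = cumulative_dwell_distribution(table, name)
        entry["n_locations"] = d_rna.n_locations
        entry["events_per_location"] = d_rna.value(0.0)
        if d_ctrl is not None:
            freq = specific_binding_frequency(
                d_rna,
                d_ctrl,
                normalize_per_s=cfg.frequency_per_second,
                observed_duration=T,
                n_bootstrap=cfg.n_bootstrap,
                seed=cfg.seed,
            )
            entry["specific_frequency"] = {
                "value": freq.f_specific,
                "se": freq.se,
                "per_second": freq.per_second,
            }
            short, long_ = frequency_by_duration_class(
                table,
                name,
                threshold=cfg.duration_threshold_s,
                normalize_per_s=cfg.frequency_per_second,
                n_bootstrap=cfg.n_bootstrap,
                seed=cfg.seed,
            )
            entry["frequency_by_class"] = {
                short.duration_class: {"value": short.f_specific, "se": short.se},
                long_.duration_class: {"value": long_.f_specific, "se": long_.se},
            }
            occ = occupancy_from_table(
                table, name, n_bootstrap=cfg.n_bootstrap, seed=cfg.seed
            )
            entry["specific_occupancy"] = {
                "value": occ.specific_occupancy,
                "se": occ.se,
                "f_m": occ.f_m,
                "f_c": occ.f_c,
            }
            if occ.specific_occupancy != 0:
                entry["frequency_occupancy_ratio"] = frequency_occupancy_ratio(
                    freq, occ
                )
        raster = build_rastergram(table, name)
        entry["percent_bound"] = {
            "value": raster.percent_bound,
            "se": raster.percent_bound_se,
        }
        tf = first_binding_times(table, name)
        if len(tf) >= 10:
            ctrl_tf = (
                first_binding_times(table, NO_RNA) if ctrl_present else None
            )
            fit = fit_first_binding(tf, ctrl_tf)
            entry["first_binding"] = {
                "amplitude": fit.amplitude,
                "rate_per_s": fit.rate,
                "background_rate_per_s": fit.background_rate,
                "converged": fit.converged,
            }
        summary["constructs"][name] = entry

    trio = cfg.synergy_constructs
    if trio and d_ctrl is not None and all(
        c in table.constructs() for c in trio
    ):
        both, up, down = trio
        freqs = {
            c: specific_binding_frequency(
                cumulative_dwell_distribution(table, c),
                d_ctrl,
                observed_duration=T,
                n_bootstrap=cfg.n_bootstrap,
                seed=cfg.seed,
            )
            for c in trio
        }
        try:
            syn = synergy_ratio(
                freqs[both],
                freqs[up],
                freqs[down],
                n_bootstrap=cfg.n_bootstrap,
                seed=cfg.seed,
            )
            summary["synergy"] = {
                "ratio": syn.ratio,
                "ci_95": list(syn.ci),
                "f_both": syn.f_both,
                "f_single_sum": syn.f_up + syn.f_down,
            }
        except ValueError as exc:
            summary["synergy"] = {"undefined": str(exc)}
    return summary


def _write_summary(summary: dict, out_dir: Path) -> None:
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_plain(summary), fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_simulated_experiment(
    cfg: ExperimentConfig, out_dir, write_plots: bool = False
) -> dict:
    """Simulate a panel per the config and compute every statistic.

    Writes the resolved config, the interval table, and a summary JSON into
    ``out_dir``; returns the summary dict.  Deterministic under the config
    seed.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "resolved_config.yaml")

    panel = cfg.constructs()
    counts = {e["name"]: int(e["count"]) for e in cfg.panel}
    layout = build_slide_layout(
        counts,
        field_size=cfg.field_size_um,
        density_bounds=cfg.density_bounds,
        n_controls=cfg.n_controls,
        seed=cfg.seed,
    )
    data = simulate_panel(
        layout, cfg.kinetic_params(), cfg.acquisition_schedule(), cfg.seed, panel
    )
    table = intervals_from_panel(data)
    write_intervals(table, out / "intervals.csv")

    summary = _analyze_table(table, cfg, [c.name for c in panel])
    summary["seed"] = cfg.seed
    summary["version"] = __version__
    _write_summary(summary, out)
    if write_plots:
        _render_plots(table, [c.name for c in panel], out)
    return summary


def analyze_intervals(
    paths,
    cfg: ExperimentConfig | None = None,
    out_dir=None,
    construct_map: dict[str, str] | None = None,
    write_plots: bool = False,
) -> dict:
    """Compute the full statistics on interval tables from disk.

    Accepts one or more CSV paths written by
    :func:`~cosmos_kinetics.traces.write_intervals` (or the MATLAB
    container reader upstream); multiple tables are merged, so N adds up.
    ``construct_map`` renames location classes before analysis.
    """
    cfg = cfg or ExperimentConfig()
    if isinstance(paths, (str, Path)):
        paths = [paths]
    table: IntervalsTable | None = None
    for p in paths:
        t = read_intervals(p)
        table = t if table is None else table.merged_with(t)
    assert table is not None
    if construct_map:
        known = set(table.constructs())
        unknown = set(construct_map) - known
        if unknown:
            raise ValueError(f"unknown construct labels: {sorted(unknown)}")
        table.metadata["construct"] = table.metadata["construct"].map(
            lambda c: construct_map.get(c, c)
        )
    constructs = [c for c in table.constructs() if c != NO_RNA]
    summary = _analyze_table(table, cfg, constructs)
    summary["version"] = __version__
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_summary(summary, out)
        if write_plots:
            _render_plots(table, constructs, out)
    return summary


def _render_plots(table: IntervalsTable, constructs: list[str], out: Path) -> None:
    """Optional figures: rastergrams and cumulative dwell distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name in constructs:
        raster = build_rastergram(table, name)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(
            raster.matrix(),
            aspect="auto",
            interpolation="nearest",
            cmap="Greys",
        )
        ax.set_xlabel("frame")
        ax.set_ylabel("molecule (sorted by first binding)")
        ax.set_title(
            f"{name}: {raster.percent_bound:.0f}±{raster.percent_bound_se:.0f}% bound"
        )
        fig.savefig(out / f"rastergram_{name}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in constructs + ([NO_RNA] if NO_RNA in table.constructs() else []):
        d = cumulative_dwell_distribution(table, name)
        ax.plot(d.thresholds[1:], np.maximum(d.values[1:], 1e-4), label=name)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("dwell time t (s)")
    ax.set_ylabel("events per location with dwell >= t")
    ax.legend(fontsize=8)
    fig.savefig(out / "dwell_distributions.png", dpi=120)
    plt.close(fig)
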