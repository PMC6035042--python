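"""Forward simulator for single-molecule colocalization binding experiments.

Generates ground-truth binding timelines for panels of RNA constructs
co-deposited on one surface together with no-RNA control locations, then
discretizes them onto an alternating-excitation frame schedule.  Specific
binding is modeled as an alternating renewal process (exponential waiting
time at the construct's association rate, dwell from an exponential
mixture); short-lived nonspecific surface binding is superposed at every
location; each binder is dye-labeled with a fixed probability and labeled
dyes photobleach under cumulative green-excitation exposure.

The ground truth (true arrival/departure/labeling/bleaching of every event)
is retained so estimators downstream can be tested by parameter recovery.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSchedule
from .constructs import NO_RNA, NO_RNA_CONSTRUCT, ConstructSpec, validate_panel
from .params import KineticModelParams

__all__ = [
    "BindingEvent",
    "TrueTimeline",
    "PresenceTrace",
    "SlideLayout",
    "SplicingTimeline",
    "PanelData",
    "location_seed",
    "build_slide_layout",
    "simulate_location_timeline",
    "discretize_timeline",
    "simulate_panel",
    "simulate_intron_loss_panel",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class BindingEvent:
    """One ground-truth binding event on one location."""

    arrival: float
    departure: float  # censored at schedule end; see TrueTimeline
    labeled: bool
    specific: bool
    bleached_at: float | None = None  # wall time; None = never bleached

    @property
    def visible_until(self) -> float:
        """End of dye visibility: departure or bleaching, whichever first."""
        if self.bleached_at is None:
            return self.departure
        return min(self.departure, self.bleached_at)

    @property
    def visible(self) -> bool:
        return self.labeled and self.visible_until > self.arrival


@dataclass
class TrueTimeline:
    """Ground-truth event list for a single surface location."""

    location_id: str
    events: list[BindingEvent] = field(default_factory=list)

    def visible_intervals(self) -> list[tuple[float, float]]:
        """Merged union of dye-visible spans (labeled, pre-bleach)."""
        spans = sorted(
            (e.arrival, e.visible_until) for e in self.events if e.visible
        )
        merged: list[tuple[float, float]] = []
        for a, b in spans:
            if merged and a <= merged[-1][1]:
                prev_a, prev_b = merged[-1]
                merged[-1] = (prev_a, max(prev_b, b))
            else:
                merged.append((a, b))
        return merged


@dataclass
class PresenceTrace:
    """Per-frame binary presence with missing-frame (red interleave) mask."""

    location_id: str
    present: np.ndarray  # bool, length n_frames; False on missing frames
    missing: np.ndarray  # bool, True where no green data exists
    schedule: AcquisitionSchedule

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.present.shape != self.missing.shape:
            raise ValueError("present and missing masks must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.present.size)

    def observed_duration(self) -> float:
        """Total non-missing observation time in seconds."""
        return float((~self.missing).sum() * self.schedule.frame_duration)


@dataclass
class SlideLayout:
    """Surface locations: (location_id, construct name, x µm, y µm)."""

    locations: list[tuple[str, str, float, float]]
    field_size: tuple[float, float]  # µm × µm
    density: float  # locations per µm²

    def construct_of(self, location_id: str) -> str:
        return self._index()[location_id]

    def _index(self) -> dict[str, str]:
        return {lid: name for lid, name, _, _ in self.locations}

    def location_ids(self, construct: str | None = None) -> list[str]:
        if construct is None:
            return [lid for lid, _, _, _ in self.locations]
        return [lid for lid, name, _, _ in self.locations if name == construct]

    def positions(self) -> np.ndarray:
        return np.array([[x, y] for _, _, x, y in self.locations])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.locations, columns=["location_id", "construct", "x_um", "y_um"]
        )


@dataclass(frozen=True)
class SplicingTimeline:
    """Two-color splicing readout for one pre-mRNA molecule.

    ``exon_dye_present_until`` is the wall time at which the exon (green)
    dye signal was lost to bleaching or degradation, or the experiment
    duration if retained throughout.  ``intron_loss_time`` is the time at
    which intron (red) fluorescence disappeared — by splicing-driven intron
    release or by dye bleaching — or None if retained.
    """

    location_id: str
    exon_dye_present_until: float
    intron_loss_time: float | None
    atp_present: bool

    def __post_init__(self) -> None:
        if self.intron_loss_time is not None and self.intron_loss_time < 0:
            raise ValueError("intron_loss_time must be >= 0")


# ---------------------------------------------------------------------------
# seeding


def location_seed(master_seed: int, location_id: str) -> np.random.SeedSequence:
    """Per-location RNG stream derived by hashing (master seed, location id).

    Hash-derived streams make each location's draw independent of panel
    iteration order, so sub-panels reproduce exactly.
    """
    digest = hashlib.sha256(f"{master_seed}:{location_id}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.SeedSequence(list(words))


# ---------------------------------------------------------------------------
# slide layout


def build_slide_layout(
    panel_counts: dict[str, int],
    field_size: tuple[float, float] = (100.0, 100.0),
    density_bounds: tuple[float, float] = (0.0, 0.5),
    n_controls: int | None = None,
    min_separation: float = 0.8,
    density: float | None = None,
    edge_margin: float = 0.0,
    seed: int = 0,
) -> SlideLayout:
    """Place RNA molecules of several species and no-RNA controls on a field.

    Parameters
    ----------
    panel_counts
        Requested number of locations per construct name (controls excluded).
    n_controls
        Number of no-RNA control locations; defaults to the mean construct
        count.  Controls are placed with the same minimum-separation rule so
        they never overlap RNA locations.
    density
        If given, overrides the counts: the total location budget is
        ``density × area`` split evenly across the constructs and controls.
    min_separation
        Minimum centre-to-centre distance in µm between any two locations.
    edge_margin
        Keep locations at least this far (µm) from the field border, as one
        would when excluding molecules clipped at the field-of-view edge.

    Raises
    ------
    ValueError
        If the implied density falls outside ``density_bounds``.
    """
    if any(c <= 0 for c in panel_counts.values()):
        raise ValueError("per-construct counts must be > 0")
    area = field_size[0] * field_size[1]
    names = list(panel_counts)
    if density is not None:
        total = int(round(density * area))
        n_species = len(names) + 1  # + controls
        per = total // n_species
        counts = {n: per for n in names}
        n_ctrl = total - per * len(names)
    else:
        counts = dict(panel_counts)
        n_ctrl = (
            n_controls
            if n_controls is not None
            else int(round(np.mean(list(counts.values()))))
        )
    total = sum(counts.values()) + n_ctrl
    realized_density = total / area
    lo, hi = density_bounds
    if not lo <= realized_density <= hi:
        raise ValueError(
            f"requested density {realized_density:.3g} locations/um^2 outside "
            f"bounds [{lo}, {hi}]"
        )

    rng = np.random.default_rng(seed)
    positions = _dart_throw(rng, total, field_size, min_separation, edge_margin)
    locations: list[tuple[str, str, float, float]] = []
    i = 0
    for name in names:
        for j in range(counts[name]):
            x, y = positions[i]
            locations.append((f"{name}_{j:05d}", name, float(x), float(y)))
            i += 1
    for j in range(n_ctrl):
        x, y = positions[i]
        locations.append((f"{NO_RNA}_{j:05d}", NO_RNA, float(x), float(y)))
        i += 1
    return SlideLayout(locations, field_size, realized_density)


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    field_size: tuple[float, float],
    min_sep: float,
    margin: float = 0.0,
) -> np.ndarray:
    """Sequential random placement with a grid-accelerated exclusion check."""
    fx, fy = field_size
    cell = max(min_sep, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        if attempts > max_attempts:
            raise ValueError(
                "could not place all locations at the requested separation; "
                "lower the density or min_separation"
            )
        attempts += 1
        p = margin + rng.random(2) * (fx - 2 * margin, fy - 2 * margin)
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(pts[k] - p)) < min_sep:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((ci, cj), []).append(placed)
            placed += 1
    return pts


# ---------------------------------------------------------------------------
# single-location kinetics


def _renewal_events(
    rng: np.random.Generator,
    k_assoc: float,
    dwell_sampler,
    total_duration: float,
) -> list[tuple[float, float]]:
    """Alternating renewal draw: Exp(k) waits alternating with sampled dwells.

    Departures are truncated at the schedule end (right-censored events).
    """
    events: list[tuple[float, float]] = []
    if k_assoc <= 0:
        return events
    t = 0.0
    while True:
        t += rng.exponential(1.0 / k_assoc)
        if t >= total_duration:
            break
        dwell = float(dwell_sampler(rng))
        departure = t + dwell
        events.append((t, min(departure, total_duration)))
        t = departure
        if t >= total_duration:
            break
    return events


def simulate_location_timeline(
    construct: ConstructSpec,
    params: KineticModelParams,
    schedule: AcquisitionSchedule,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    location_id: str | None = None,
) -> TrueTimeline:
    """Simulate the ground-truth binding timeline at one surface location.

    Specific events occur only at active RNA locations whose construct has a
    nonzero resolved association rate; nonspecific events occur everywhere.
    Each event is independently dye-labeled; labeled dyes bleach at an
    exponential time in cumulative green-exposure units.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lid = location_id or construct.name
    T = schedule.total_duration

    k_spec = params.effective_association_rate(construct)
    active = rng.random() < params.frac_active
    raw: list[tuple[float, float, bool]] = []  # (arrival, departure, specific)
    if active and k_spec > 0:
        spec_dwell = lambda r: params.sample_specific_dwell(r, 1)[0]
        for a, d in _renewal_events(rng, k_spec, spec_dwell, T):
            raw.append((a, d, True))
    if params.k_assoc_nonspecific > 0:
        ns_dwell = lambda r: r.exponential(params.nonspecific_mean_dwell)
        for a, d in _renewal_events(rng, params.k_assoc_nonspecific, ns_dwell, T):
            raw.append((a, d, False))
    raw.sort()

    events: list[BindingEvent] = []
    for arrival, departure, specific in raw:
        labeled = bool(rng.random() < params.labeling_fraction)
        bleached_at: float | None = None
        if labeled and params.bleach_rate > 0:
            dose = rng.exponential(1.0 / params.bleach_rate)
            wall = schedule.wall_time_for_green_exposure(dose, start=arrival)
            if wall < departure:
                bleached_at = wall
        events.append(
            BindingEvent(arrival, departure, labeled, specific, bleached_at)
        )
    return TrueTimeline(lid, events)


def discretize_timeline(
    timeline: TrueTimeline, schedule: AcquisitionSchedule
) -> PresenceTrace:
    """Map a continuous timeline onto the frame schedule.

    A frame is marked present iff the union of dye-visible spans overlaps at
    least half of that frame's green exposure.  Red-interleave frames carry
    no green data and are flagged missing.
    """
    n = schedule.n_frames
    dt = schedule.frame_duration
    missing = schedule.red_frame_mask()
    coverage = np.zeros(n)
    for a, b in timeline.visible_intervals():
        first = int(np.floor(a / dt))
        last = min(int(np.ceil(b / dt)), n)
        for f in range(max(first, 0), last):
            t0, t1 = f * dt, (f + 1) * dt
            coverage[f] += max(0.0, min(b, t1) - max(a, t0))
    present = (coverage >= 0.5 * dt) & ~missing
    return PresenceTrace(timeline.location_id, present, missing, schedule)


# ---------------------------------------------------------------------------
# panel simulation


@dataclass
class PanelData:
    """One simulated experiment: layout, discretized traces, ground truth."""

    layout: SlideLayout
    schedule: AcquisitionSchedule
    params: KineticModelParams
    traces: dict[str, PresenceTrace]
    timelines: dict[str, TrueTimeline]

    def ground_truth_events(self) -> pd.DataFrame:
        """All ground-truth events as a tidy table."""
        rows = []
        construct_of = dict(
            (lid, name) for lid, name, _, _ in self.layout.locations
        )
        for lid, tl in self.timelines.items():
            for e in tl.events:
                rows.append(
                    {
                        "location_id": lid,
                        "construct": construct_of[lid],
                        "arrival_s": e.arrival,
                        "departure_s": e.departure,
                        "labeled": e.labeled,
                        "specific": e.specific,
                        "bleached_at_s": e.bleached_at,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "location_id",
                "construct",
                "arrival_s",
                "departure_s",
                "labeled",
                "specific",
                "bleached_at_s",
            ],
        )

    def visible_event_counts(self, specific_only: bool = False) -> pd.Series:
        """Per-location count of dye-visible ground-truth events.

        The natural comparator for recovered binding frequencies: only
        labeled, not-instantly-bleached events can be detected.
        """
        counts = {}
        for lid, tl in self.timelines.items():
            counts[lid] = sum(
                1
                for e in tl.events
                if e.visible and (e.specific or not specific_only)
            )
        return pd.Series(counts, name="visible_events")

    def detectable_event_counts(self, specific_only: bool = False) -> pd.Series:
        """Per-location ground-truth events that survive discretization.

        An event is detectable iff its dye-visible span overlaps at least
        half of some green frame — the same rule the discretizer applies —
        so this is the fair comparator for frequencies recovered from
        extracted intervals.
        """
        dt = self.schedule.frame_duration
        red = self.schedule.red_frame_mask()
        n = self.schedule.n_frames
        counts = {}
        for lid, tl in self.timelines.items():
            c = 0
            for e in tl.events:
                if not e.visible or (specific_only and not e.specific):
                    continue
                a, b = e.arrival, e.visible_until
                first = max(int(np.floor(a / dt)), 0)
                last = min(int(np.ceil(b / dt)), n)
                for f in range(first, last):
                    if red[f]:
                        continue
                    if min(b, (f + 1) * dt) - max(a, f * dt) >= 0.5 * dt:
                        c += 1
                        break
            counts[lid] = c
        return pd.Series(counts, name="detectable_events")

    def visible_bound_fraction(self) -> pd.Series:
        """Per-location fraction of the experiment with a visible dye bound."""
        T = self.schedule.total_duration
        fracs = {
            lid: sum(b - a for a, b in tl.visible_intervals()) / T
            for lid, tl in self.timelines.items()
        }
        return pd.Series(fracs, name="bound_fraction")


def simulate_panel(
    layout: SlideLayout,
    params: KineticModelParams,
    schedule: AcquisitionSchedule,
    seed: int = 0,
    panel: list[ConstructSpec] | None = None,
) -> PanelData:
    """Simulate every location of a slide layout.

    Per-location RNG streams are derived by hashing the master seed with the
    location id, so results are reproducible and independent of iteration
    order.  ``panel`` supplies the construct definitions; the no-RNA control
    construct is always known implicitly.
    """
    specs: dict[str, ConstructSpec] = {NO_RNA: NO_RNA_CONSTRUCT}
    if panel is not None:
        validate_panel(panel)
        specs.update({c.name: c for c in panel})
    traces: dict[str, PresenceTrace] = {}
    timelines: dict[str, TrueTimeline] = {}
    for lid, name, _, _ in layout.locations:
        if name not in specs:
            raise KeyError(f"layout references unknown construct {name!r}")
        rng = np.random.default_rng(location_seed(seed, lid))
        tl = simulate_location_timeline(
            specs[name], params, schedule, seed=rng, location_id=lid
        )
        timelines[lid] = tl
        traces[lid] = discretize_timeline(tl, schedule)
    return PanelData(layout, schedule, params, traces, timelines)


# ---------------------------------------------------------------------------
# two-color splicing (intron loss) simulation


def simulate_intron_loss_panel(
    n_molecules: int,
    loss_lag: float = 600.0,
    loss_rate: float = 1.0 / 600.0,
    frac_spliceable: float = 0.20,
    exon_loss_rate: float = 4.6e-6,
    intron_bleach_rate: float = 4.6e-6,
    atp: bool = True,
    schedule: AcquisitionSchedule | None = None,
    seed: int = 0,
) -> list[SplicingTimeline]:
    """Simulate two-color intron-release experiments.

    Each surface-tethered pre-mRNA carries an exon (green) dye and an intron
    (red) dye.  When ATP is present, a ``frac_spliceable`` subset completes
    splicing and releases its intron at ``lag + Exp(rate)``; independently,
    either dye can disappear by photobleaching/degradation at its own
    exponential wall-time hazard.  Without ATP no splicing occurs, so any
    intron-signal loss is bleaching only.

    Defaults emulate a 40-minute experiment in which roughly a fifth of
    molecules are splicing-competent and bleaching alone removes ~1% of
    intron signals.
    """
    if min(loss_rate, exon_loss_rate, intron_bleach_rate) < 0:
        raise ValueError("rates must be >= 0")
    if not 0.0 <= frac_spliceable <= 1.0:
        raise ValueError("frac_spliceable must lie in [0, 1]")
    sched = schedule or AcquisitionSchedule()
    T = sched.total_duration
    rng = np.random.default_rng(seed)
    out: list[SplicingTimeline] = []
    for i in range(n_molecules):
        exon_until = T
        if exon_loss_rate > 0:
            t_ex = rng.exponential(1.0 / exon_loss_rate)
            if t_ex < T:
                exon_until = float(t_ex)
        candidates: list[float] = []
        if intron_bleach_rate > 0:
            t_bl = rng.exponential(1.0 / intron_bleach_rate)
            if t_bl < T:
                candidates.append(float(t_bl))
        if atp and rng.random() < frac_spliceable and loss_rate > 0:
            t_sp = loss_lag + rng.exponential(1.0 / loss_rate)
            if t_sp < T:
                candidates.append(float(t_sp))
        loss = min(candidates) if candidates else None
        out.append(SplicingTimeline(f"mol_{i:05d}", exon_until, loss, atp))
    return out
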