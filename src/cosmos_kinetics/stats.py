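"""Kinetic statistics for single-molecule colocalization experiments.

Everything downstream of an :class:`~cosmos_kinetics.traces.IntervalsTable`:
cumulative dwell-time distributions, background-corrected specific binding
frequencies (total and split by duration class), time-averaged specific
occupancy, bootstrap standard errors over surface locations, censored
maximum-likelihood fits of time-to-first-binding, the cross-intron/cross-exon
synergy ratio, intron-retention curves, and rastergrams.

Background correction throughout uses no-RNA control locations measured on
the same surface: specific frequency is the RNA-minus-control difference of
per-location event frequencies, and specific occupancy is
``(f_m - f_c) / (1 - f_c)`` where ``f_m`` and ``f_c`` are the fractions of
observed time a fluorescent spot is present at RNA and control locations.
The bootstrap resampling unit is always the surface location — locations,
not events, are the independent experimental unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .acquisition import AcquisitionSchedule
from .constructs import NO_RNA
from .simulate import SplicingTimeline
from .traces import IntervalsTable

__all__ = [
    "DwellDistribution",
    "FrequencyResult",
    "OccupancyResult",
    "FirstBindingFit",
    "SynergyResult",
    "RetentionCurve",
    "Rastergram",
    "cumulative_dwell_distribution",
    "specific_binding_frequency",
    "frequency_by_duration_class",
    "specific_occupancy",
    "occupancy_from_table",
    "bootstrap_se",
    "first_binding_times",
    "fit_first_binding",
    "synergy_ratio",
    "intron_retention_curve",
    "build_rastergram",
    "frequency_occupancy_ratio",
]

DEFAULT_BOOTSTRAP_SAMPLES = 2000


# ---------------------------------------------------------------------------
# dwell distributions


@dataclass
class DwellDistribution:
    """Mean per-location frequency of events with dwell >= t.

    ``value(t) = |{intervals with dwell >= t}| / N`` where N counts all
    observed locations of the construct (not just those with events), so
    ``value(0)`` is the mean number of binding events per location over the
    experiment.  Monotone non-increasing in t by construction.
    """

    thresholds: np.ndarray  # dwell grid, s
    values: np.ndarray  # events per location with dwell >= t
    n_locations: int
    construct: str
    per_location_dwells: dict[str, np.ndarray] = field(default_factory=dict)

    def value(self, t: float) -> float:
        if not self.per_location_dwells:
            # fall back to the tabulated grid (step interpolation)
            idx = np.searchsorted(self.thresholds, t, side="right") - 1
            return float(self.values[max(idx, 0)])
        total = sum((d >= t).sum() for d in self.per_location_dwells.values())
        return float(total) / self.n_locations


def default_dwell_grid(total_duration: float = 2400.0) -> np.ndarray:
    """Log-spaced dwell grid from one frame to the experiment duration."""
    return np.concatenate([[0.0], np.geomspace(1.0, total_duration, 60)])


def cumulative_dwell_distribution(
    table: IntervalsTable,
    construct: str,
    grid: np.ndarray | None = None,
    include_censored: bool = True,
) -> DwellDistribution:
    """Cumulative dwell-time distribution for one construct.

    Censored intervals enter with their observed span (their true dwell is
    at least that long, so they legitimately count toward every threshold up
    to the span; beyond it nothing is assumed).  Set
    ``include_censored=False`` to drop them entirely.
    """
    lids = table.location_ids(construct)
    if not lids:
        raise ValueError(f"construct {construct!r} absent from table")
    per_loc = table.dwells_by_location(construct)
    if not include_censored:
        flagged = {
            (iv.location_id, iv.start)
            for iv in table.intervals_for(construct)
            if iv.left_censored or iv.right_censored
        }
        per_loc = {}
        for lid in lids:
            ds = [
                iv.dwell
                for iv in table.intervals_for(construct)
                if iv.location_id == lid and (lid, iv.start) not in flagged
            ]
            per_loc[lid] = np.asarray(ds, dtype=float)
    g = grid if grid is not None else default_dwell_grid(table.schedule.total_duration)
    g = np.asarray(g, dtype=float)
    all_dwells = (
        np.concatenate(list(per_loc.values()))
        if per_loc
        else np.empty(0)
    )
    values = np.array([(all_dwells >= t).sum() / len(lids) for t in g])
    return DwellDistribution(g, values, len(lids), construct, per_loc)


# ---------------------------------------------------------------------------
# frequencies


@dataclass
class FrequencyResult:
    """Background-corrected specific binding frequency.

    ``f_specific`` is the RNA-minus-control difference of mean events per
    location; with ``per_second`` the same divided by the observed duration.
    ``rna_intercept`` / ``ctrl_intercept`` are the uncorrected means (the
    vertical-axis intercepts of the cumulative dwell distributions).
    """

    f_specific: float
    se: float
    rna_intercept: float
    ctrl_intercept: float
    duration_class: str = "all"  # "all" | "<=50 s" | ">50 s" style labels
    per_second: bool = False
    n_rna: int = 0
    n_ctrl: int = 0
    observed_duration: float = 2400.0
    # per-location event counts retained for joint bootstraps downstream
    rna_counts: np.ndarray = field(default_factory=lambda: np.empty(0))
    ctrl_counts: np.ndarray = field(default_factory=lambda: np.empty(0))


def _per_location_counts(
    dist: DwellDistribution, lo: float = 0.0, hi: float = np.inf
) -> np.ndarray:
    return np.array(
        [
            ((d >= lo) & (d < hi)).sum()
            for d in dist.per_location_dwells.values()
        ],
        dtype=float,
    )


def specific_binding_frequency(
    d_rna: DwellDistribution,
    d_ctrl: DwellDistribution,
    normalize_per_s: bool = False,
    observed_duration: float = 2400.0,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
    duration_class: str = "all",
    dwell_range: tuple[float, float] = (0.0, np.inf),
) -> FrequencyResult:
    """RNA-specific binding frequency with bootstrap SE.

    The specific frequency is the control-subtracted mean event count per
    location, i.e. the difference of the two distributions' intercepts at
    dwell 0 (restricted to ``dwell_range`` for duration classes).  The SE
    comes from resampling locations, independently within the RNA and
    control groups.
    """
    if d_rna.thresholds.shape != d_ctrl.thresholds.shape or not np.allclose(
        d_rna.thresholds, d_ctrl.thresholds
    ):
        raise ValueError("dwell distributions must share the same grid")
    lo, hi = dwell_range
    rna_counts = _per_location_counts(d_rna, lo, hi)
    ctrl_counts = _per_location_counts(d_ctrl, lo, hi)
    f_rna = float(rna_counts.mean()) if rna_counts.size else 0.0
    f_ctrl = float(ctrl_counts.mean()) if ctrl_counts.size else 0.0
    scale = 1.0 / observed_duration if normalize_per_s else 1.0
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        rb = rng.choice(rna_counts, rna_counts.size, replace=True).mean()
        cb = (
            rng.choice(ctrl_counts, ctrl_counts.size, replace=True).mean()
            if ctrl_counts.size
            else 0.0
        )
        boots[b] = (rb - cb) * scale
    return FrequencyResult(
        f_specific=(f_rna - f_ctrl) * scale,
        se=float(boots.std(ddof=1)),
        rna_intercept=f_rna * scale,
        ctrl_intercept=f_ctrl * scale,
        duration_class=duration_class,
        per_second=normalize_per_s,
        n_rna=d_rna.n_locations,
        n_ctrl=d_ctrl.n_locations,
        observed_duration=observed_duration,
        rna_counts=rna_counts,
        ctrl_counts=ctrl_counts,
    )


def frequency_by_duration_class(
    table: IntervalsTable,
    construct: str,
    control: str = NO_RNA,
    threshold: float = 50.0,
    normalize_per_s: bool = False,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
) -> tuple[FrequencyResult, FrequencyResult]:
    """Specific frequencies of events shorter vs. at-least the threshold.

    The two classes partition the events, so their frequencies sum to the
    all-events specific frequency.  The conventional threshold separating
    transient sampling from stable engagement is 50 s; 60 s is a common
    secondary choice for the U1-like channel.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    d_rna = cumulative_dwell_distribution(table, construct)
    d_ctrl = cumulative_dwell_distribution(table, control)
    T = table.schedule.total_duration
    short = specific_binding_frequency(
        d_rna,
        d_ctrl,
        normalize_per_s,
        T,
        n_bootstrap,
        seed,
        duration_class=f"<{threshold:g} s",
        dwell_range=(0.0, threshold),
    )
    long = specific_binding_frequency(
        d_rna,
        d_ctrl,
        normalize_per_s,
        T,
        n_bootstrap,
        seed + 1,
        duration_class=f">={threshold:g} s",
        dwell_range=(threshold, np.inf),
    )
    return short, long


# ---------------------------------------------------------------------------
# occupancy


@dataclass
class OccupancyResult:
    """Background-corrected time-averaged occupancy.

    ``specific_occupancy = (f_m - f_c) / (1 - f_c)`` where ``f_m`` / ``f_c``
    are the mean fractions of observed time a spot is present at RNA /
    control locations.  Sampling noise can push the estimate below zero;
    it is reported unclamped.
    """

    f_m: float
    f_c: float
    specific_occupancy: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    n_rna: int = 0
    n_ctrl: int = 0


def specific_occupancy(f_m: float, f_c: float) -> OccupancyResult:
    """Background-corrected occupancy from the two raw bound-time fractions."""
    if not (0.0 <= f_m <= 1.0 and 0.0 <= f_c <= 1.0):
        raise ValueError("bound-time fractions must lie in [0, 1]")
    if f_c >= 1.0:
        raise ValueError("control fraction f_c = 1 leaves the correction undefined")
    return OccupancyResult(f_m, f_c, (f_m - f_c) / (1.0 - f_c))


def _bound_fractions(table: IntervalsTable, construct: str) -> np.ndarray:
    dt = table.schedule.frame_duration
    md = table.metadata.set_index("location_id")
    fracs = []
    for lid in table.location_ids(construct):
        observed = float(md.loc[lid, "n_frames_observed"]) * dt
        if observed <= 0:
            raise ValueError(f"location {lid!r} has zero observed time")
        bound = sum(
            iv.dwell for iv in table.intervals if iv.location_id == lid
        )
        fracs.append(min(bound / observed, 1.0))
    return np.asarray(fracs)


def occupancy_from_table(
    table: IntervalsTable,
    construct: str,
    control: str = NO_RNA,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
) -> OccupancyResult:
    """Specific occupancy of a construct with bootstrap SE.

    Per location, the bound-time fraction is total interval time divided by
    total non-missing observation time; the construct and control means
    feed the background-correction formula.  The bootstrap resamples
    locations independently within the two groups.
    """
    fm = _bound_fractions(table, construct)
    fc = _bound_fractions(table, control)
    if fm.size == 0 or fc.size == 0:
        raise ValueError("need at least one RNA and one control location")
    point = specific_occupancy(float(fm.mean()), float(fc.mean()))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bm = rng.choice(fm, fm.size, replace=True).mean()
        bc = rng.choice(fc, fc.size, replace=True).mean()
        boots[b] = (bm - bc) / (1.0 - bc) if bc < 1.0 else np.nan
    boots = boots[np.isfinite(boots)]
    return OccupancyResult(
        point.f_m,
        point.f_c,
        point.specific_occupancy,
        se=float(boots.std(ddof=1)),
        ci=(float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))),
        n_rna=fm.size,
        n_ctrl=fc.size,
    )


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_se(
    values: np.ndarray,
    statistic=np.mean,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap SE and 95% percentile CI of a per-location statistic.

    ``values`` holds one number per surface location; locations are
    resampled with replacement ``n_bootstrap`` times and the SE is the
    standard deviation of the resampled statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 locations")
    rng = np.random.default_rng(seed)
    stats = np.array(
        [
            statistic(rng.choice(values, values.size, replace=True))
            for _ in range(n_bootstrap)
        ]
    )
    return float(stats.std(ddof=1)), (
        float(np.percentile(stats, 2.5)),
        float(np.percentile(stats, 97.5)),
    )


# ---------------------------------------------------------------------------
# time to first binding


def first_binding_times(
    table: IntervalsTable, construct: str
) -> list[tuple[float, bool]]:
    """Per-location time of first binding, censored at the observation end.

    Returns ``(time_s, observed)`` pairs; never-bound locations contribute
    ``(total_duration, False)``.
    """
    firsts: dict[str, float] = {}
    for iv in table.intervals_for(construct):
        t = firsts.get(iv.location_id)
        firsts[iv.location_id] = iv.start if t is None else min(t, iv.start)
    T = table.schedule.total_duration
    out = []
    for lid in table.location_ids(construct):
        if lid in firsts:
            out.append((firsts[lid], True))
        else:
            out.append((T, False))
    return out


@dataclass
class FirstBindingFit:
    """Background-corrected single-exponential first-binding fit.

    Model for the cumulative fraction bound by time t:

        P(t) = A_f (1 - exp(-(k_f + k_bg) t)) + (1 - A_f)(1 - exp(-k_bg t))

    An active fraction ``A_f`` binds specifically at rate ``k_f`` on top of
    the background rate ``k_bg``; the inactive remainder only acquires
    background events.  ``k_bg`` is estimated separately from control
    locations by censored single-exponential maximum likelihood.
    """

    amplitude: float  # A_f, active fraction in [0, 1]
    rate: float  # k_f, s^-1
    background_rate: float  # k_bg, s^-1
    rate_se: float | None = None
    amplitude_se: float | None = None
    log_likelihood: float = np.nan
    n: int = 0
    n_censored: int = 0
    converged: bool = False


def _exp_mle_censored(times_flags: list[tuple[float, bool]]) -> float:
    """Censored exponential rate MLE: events / total time at risk."""
    n_events = sum(1 for _, obs in times_flags if obs)
    total_time = sum(t for t, _ in times_flags)
    return n_events / total_time if total_time > 0 else 0.0


def _first_binding_nll(params, times, observed, k_bg):
    a, kf = params
    lam = kf + k_bg
    t = times
    s = a * np.exp(-lam * t) + (1 - a) * np.exp(-k_bg * t)
    f = a * lam * np.exp(-lam * t) + (1 - a) * k_bg * np.exp(-k_bg * t)
    eps = 1e-300
    ll = np.where(observed, np.log(np.maximum(f, eps)), np.log(np.maximum(s, eps)))
    return -ll.sum()


def fit_first_binding(
    times_flags: list[tuple[float, bool]],
    control_times_flags: list[tuple[float, bool]] | None = None,
) -> FirstBindingFit:
    """Censored MLE of the background-corrected first-binding model.

    Censored locations (no event by the end of the observation) contribute
    survival terms to the likelihood, so slow binders do not bias the rate
    upward.  With no control data the background rate is fixed at zero.
    """
    if len(times_flags) < 10:
        raise ValueError("need >= 10 locations for a first-binding fit")
    k_bg = (
        _exp_mle_censored(control_times_flags) if control_times_flags else 0.0
    )
    times = np.array([t for t, _ in times_flags], dtype=float)
    observed = np.array([o for _, o in times_flags], dtype=bool)
    n, n_cens = times.size, int((~observed).sum())
    if not observed.any():
        warnings.warn("all first-binding times censored; amplitude set to 0")
        return FirstBindingFit(0.0, 0.0, k_bg, n=n, n_censored=n_cens, converged=True)

    frac_bound = observed.mean()
    mean_t = times[observed].mean()
    x0 = np.array([min(max(frac_bound, 0.05), 0.95), 1.0 / max(mean_t, 1.0)])
    res = optimize.minimize(
        _first_binding_nll,
        x0,
        args=(times, observed, k_bg),
        method="L-BFGS-B",
        bounds=[(1e-6, 1.0), (1e-8, 10.0)],
    )
    a_hat, kf_hat = res.x
    a_se, k_se = _fit_ses(res.x, times, observed, k_bg)
    return FirstBindingFit(
        amplitude=float(a_hat),
        rate=float(kf_hat),
        background_rate=float(k_bg),
        rate_se=k_se,
        amplitude_se=a_se,
        log_likelihood=float(-res.fun),
        n=n,
        n_censored=n_cens,
        converged=bool(res.success),
    )


def _fit_ses(x, times, observed, k_bg):
    """Asymptotic SEs from the numerically inverted observed information."""
    h = np.maximum(np.abs(x) * 1e-4, 1e-8)
    hess = np.empty((2, 2))
    f0 = _first_binding_nll(x, times, observed, k_bg)
    for i in range(2):
        for j in range(2):
            xi, xj = np.zeros(2), np.zeros(2)
            xi[i], xj[j] = h[i], h[j]
            fpp = _first_binding_nll(x + xi + xj, times, observed, k_bg)
            fpm = _first_binding_nll(x + xi - xj, times, observed, k_bg)
            fmp = _first_binding_nll(x - xi + xj, times, observed, k_bg)
            fmm = _first_binding_nll(x - xi - xj, times, observed, k_bg)
            hess[i, j] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
        if (np.diag(cov) <= 0).any():
            return None, None
        return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        return None, None


# ---------------------------------------------------------------------------
# synergy


@dataclass
class SynergyResult:
    """Ratio of the both-sites frequency to the sum of single-site ones.

    ``ratio = f_both / (f_up + f_down)``; 1 is the additivity null, values
    above 1 indicate synergy between the two flanking 5' splice sites.
    """

    ratio: float
    ci: tuple[float, float]
    f_both: float
    f_up: float
    f_down: float
    n_bootstrap: int = 0
    n_degenerate: int = 0  # bootstrap draws discarded for non-positive denominator


def synergy_ratio(
    f_both: FrequencyResult,
    f_up: FrequencyResult,
    f_down: FrequencyResult,
    n_bootstrap: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
) -> SynergyResult:
    """Synergy ratio with a joint bootstrap CI.

    All three frequencies must carry their per-location event counts (as
    produced by :func:`specific_binding_frequency`); each bootstrap draw
    resamples every constituent group of locations independently, so the CI
    propagates the uncertainty of numerator and denominator jointly.
    """
    denom = f_up.f_specific + f_down.f_specific
    if denom <= 0:
        raise ValueError("synergy ratio undefined: single-site frequency sum <= 0")
    ratio = f_both.f_specific / denom
    rng = np.random.default_rng(seed)
    samples = []
    n_degenerate = 0
    scale_b = 1.0 / f_both.observed_duration if f_both.per_second else 1.0

    def draw(fr: FrequencyResult) -> float:
        rb = rng.choice(fr.rna_counts, fr.rna_counts.size, replace=True).mean()
        cb = (
            rng.choice(fr.ctrl_counts, fr.ctrl_counts.size, replace=True).mean()
            if fr.ctrl_counts.size
            else 0.0
        )
        return (rb - cb) * scale_b

    for _ in range(n_bootstrap):
        b, u, d = draw(f_both), draw(f_up), draw(f_down)
        if u + d <= 0:
            n_degenerate += 1
            continue
        samples.append(b / (u + d))
    if not samples:
        raise ValueError("all bootstrap draws had non-positive denominators")
    arr = np.asarray(samples)
    return SynergyResult(
        ratio=float(ratio),
        ci=(float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))),
        f_both=f_both.f_specific,
        f_up=f_up.f_specific,
        f_down=f_down.f_specific,
        n_bootstrap=n_bootstrap,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# intron retention


@dataclass
class RetentionCurve:
    """Fraction of intron dyes remaining among exon-dye-retaining molecules."""

    times: np.ndarray  # s
    fraction_remaining: np.ndarray
    se: np.ndarray
    n: int  # conditioned molecules


def intron_retention_curve(
    panel: list[SplicingTimeline],
    schedule: AcquisitionSchedule | None = None,
    times: np.ndarray | None = None,
) -> RetentionCurve:
    """Intron-loss (splicing) curve conditioned on exon-dye retention.

    Molecules that lose exon-dye fluorescence before the experiment ends
    (degradation or green-dye bleaching) are excluded from N entirely; of
    the remainder, the curve reports the fraction whose intron dye is still
    present at each evaluation time, with binomial SE.
    """
    sched = schedule or AcquisitionSchedule()
    T = sched.total_duration
    conditioned = [m for m in panel if m.exon_dye_present_until >= T]
    if not conditioned:
        raise ValueError("no molecules retain the exon dye through the experiment")
    if times is None:
        red = np.flatnonzero(sched.red_frame_mask())
        times = (
            np.concatenate([[0.0], red * sched.frame_duration, [T]])
            if red.size
            else np.linspace(0.0, T, 9)
        )
    times = np.asarray(times, dtype=float)
    n = len(conditioned)
    frac = np.empty(times.size)
    for i, t in enumerate(times):
        kept = sum(
            1
            for m in conditioned
            if m.intron_loss_time is None or m.intron_loss_time > t
        )
        frac[i] = kept / n
    se = np.sqrt(frac * (1 - frac) / n)
    return RetentionCurve(times, frac, se, n)


# ---------------------------------------------------------------------------
# rastergrams


@dataclass
class Rastergram:
    """Sorted per-molecule binding timelines plus the percent-bound summary.

    Rows are ordered by time of first binding from latest to earliest, with
    never-bound molecules first, ties broken by location id — a stable,
    reproducible layout that puts the most active molecules at the bottom.
    """

    rows: list[tuple[str, np.ndarray]]  # (location_id, presence bool array)
    percent_bound: float
    percent_bound_se: float
    n: int
    construct: str

    def matrix(self) -> np.ndarray:
        return np.array([r for _, r in self.rows])


def build_rastergram(table: IntervalsTable, construct: str) -> Rastergram:
    """Rastergram of one construct's binding timelines.

    Presence is reconstructed on the frame grid from the interval table, so
    a rastergram can be drawn for any table regardless of its origin.
    """
    lids = table.location_ids(construct)
    if not lids:
        raise ValueError(f"construct {construct!r} absent from table")
    sched = table.schedule
    nf = sched.n_frames
    dt = sched.frame_duration
    frame_starts = np.arange(nf) * dt
    traces: dict[str, np.ndarray] = {lid: np.zeros(nf, dtype=bool) for lid in lids}
    firsts: dict[str, float] = {}
    for iv in table.intervals_for(construct):
        inside = (frame_starts >= iv.start) & (frame_starts < iv.end)
        traces[iv.location_id] |= inside
        t = firsts.get(iv.location_id)
        firsts[iv.location_id] = iv.start if t is None else min(t, iv.start)

    def key(lid: str):
        # never-bound first, then latest-to-earliest first binding
        return (0 if lid not in firsts else 1, -firsts.get(lid, np.inf), lid)

    order = sorted(lids, key=key)
    n = len(lids)
    n_bound = len(firsts)
    p = n_bound / n
    return Rastergram(
        rows=[(lid, traces[lid]) for lid in order],
        percent_bound=100.0 * p,
        percent_bound_se=100.0 * float(np.sqrt(p * (1 - p) / n)),
        n=n,
        construct=construct,
    )


# ---------------------------------------------------------------------------
# frequency / occupancy ratio


def frequency_occupancy_ratio(
    freq: FrequencyResult, occ: OccupancyResult
) -> dict[str, float]:
    """Ratio of specific binding frequency to specific occupancy.

    For a renewal process both quantities scale linearly with the labeling
    fraction, so their ratio cancels it and reports a dwell property of the
    bound state alone (in the per-second convention it approximates the
    reciprocal mean dwell at low occupancy).  Returned in both unit
    conventions: per experiment and per second.
    """
    if occ.specific_occupancy == 0:
        raise ValueError("occupancy is zero; ratio undefined")
    per_experiment = freq.f_specific / occ.specific_occupancy
    if freq.per_second:
        return {
            "per_second": per_experiment,
            "per_experiment": per_experiment * freq.observed_duration,
        }
    return {
        "per_experiment": per_experiment,
        "per_second": per_experiment / freq.observed_duration,
    }
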