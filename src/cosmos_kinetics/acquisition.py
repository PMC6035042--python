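"""Frame schedule of an alternating-excitation TIRF acquisition.

The default schedule mirrors a common single-molecule design: blocks of 100
one-second frames under green excitation (reporting subcomplex binding)
alternating with a single one-second frame under red excitation (reporting
the tethered RNA), for a total of 2,400 s.  Red-interleave frames carry no
green-channel data and are treated as missing, not as absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class AcquisitionSchedule:
    frame_duration: float = 1.0  # s
    green_block_length: int = 100  # frames of green excitation per block
    red_interleave_length: int = 1  # red frames between green blocks
    total_duration: float = 2400.0  # s

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be > 0")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if self.green_block_length < 1 or self.red_interleave_length < 0:
            raise ValueError("invalid block structure")

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration / self.frame_duration))

    @property
    def cycle_length(self) -> int:
        return self.green_block_length + self.red_interleave_length

    def frame_start_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_duration

    def red_frame_mask(self) -> np.ndarray:
        """Boolean mask, True where the frame is a red-interleave frame."""
        idx = np.arange(self.n_frames)
        return (idx % self.cycle_length) >= self.green_block_length

    def green_frame_mask(self) -> np.ndarray:
        return ~self.red_frame_mask()

    def n_green_frames(self) -> int:
        return int(self.green_frame_mask().sum())

    def green_exposure_before(self, t: float) -> float:
        """Cumulative green-excitation exposure (s) accrued by wall time t.

        Bleaching of green-excited dyes accrues only during green frames,
        so dose-time and wall-time differ whenever red frames interleave.
        """
        t = min(max(t, 0.0), self.total_duration)
        n_full = int(t // self.frame_duration)
        idx = np.arange(n_full)
        green = (idx % self.cycle_length) < self.green_block_length
        dose = green.sum() * self.frame_duration
        frac = t - n_full * self.frame_duration
        if frac > 0 and n_full < self.n_frames:
            if (n_full % self.cycle_length) < self.green_block_length:
                dose += frac
        return float(dose)

    def wall_time_for_green_exposure(self, dose: float, start: float = 0.0) -> float:
        """Wall time at which cumulative green exposure since `start` reaches `dose`.

        Returns ``inf`` if the dose is never reached within the schedule.
        Piecewise-linear inverse of :meth:`green_exposure_before`.
        """
        if dose <= 0:
            return start
        base = self.green_exposure_before(start)
        target = base + dose
        lo, hi = start, self.total_duration
        if self.green_exposure_before(hi) < target - 1e-12:
            return float("inf")
        # bisection on a monotone piecewise-linear function
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.green_exposure_before(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)
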