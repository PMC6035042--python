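"""Ground-truth kinetic parameters for the binding simulator.

These are the mechanistic quantities the downstream estimators try to
recover: association rates, the exponential dwell-time mixture, nonspecific
(surface) binding, the dye-labeling fraction, photobleaching, and the
multiplicative synergy of the two flanking 5' splice sites on association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constructs import ConstructSpec


@dataclass(frozen=True)
class KineticModelParams:
    """Kinetic ground truth for one labeled subcomplex.

    Parameters
    ----------
    k_assoc_specific
        Specific association rate, events·location⁻¹·s⁻¹, for a construct
        with exactly one functional 5' splice site.  Per-construct overrides
        may be supplied in ``k_assoc_overrides``.
    dwell_mixture
        Exponential mixture of specific dwell times as ``(weight, mean_s)``
        pairs; weights must sum to 1.  The canonical two-component choice has
        a short (seconds) and a long (>50 s) class.
    k_assoc_nonspecific
        Rate of short-lived surface binding, present at every location
        including no-RNA controls.
    nonspecific_mean_dwell
        Mean dwell (s) of nonspecific events (single exponential).
    labeling_fraction
        Probability that a given subcomplex copy carries a dye.  Only
        labeled copies are visible; event statistics scale with it.
    bleach_rate
        Photobleaching hazard (s⁻¹) per unit of green-excitation exposure.
    synergy_factor
        Multiplier on the *additive* two-site association rate when both
        flanking 5' splice sites are functional: the both-sites rate is
        ``synergy_factor * 2 * k_assoc_specific``.  1.0 therefore means the
        two sites act additively, and the frequency ratio
        f_both / (f_up + f_down) recovers this factor directly.
    frac_active
        Fraction of RNA locations competent to bind specifically (surface
        damage / misfolding leave the rest dark except for nonspecific
        events).
    requires_branch_site
        If True, the specific rate is zero on constructs whose branch
        site / 3'SS block is mutated (appropriate for a U2-like subcomplex
        recruited to the branch site).
    """

    k_assoc_specific: float = 5e-4
    dwell_mixture: tuple[tuple[float, float], ...] = ((0.7, 8.0), (0.3, 120.0))
    k_assoc_nonspecific: float = 1e-4
    nonspecific_mean_dwell: float = 3.0
    labeling_fraction: float = 0.6
    bleach_rate: float = 1e-4
    synergy_factor: float = 1.0
    frac_active: float = 0.8
    requires_branch_site: bool = True
    k_assoc_overrides: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        rates = (
            self.k_assoc_specific,
            self.k_assoc_nonspecific,
            self.bleach_rate,
            self.synergy_factor,
        )
        if any((not np.isfinite(r)) or r < 0 for r in rates):
            raise ValueError("rates and factors must be finite and >= 0")
        weights = [w for w, _ in self.dwell_mixture]
        if self.dwell_mixture and not np.isclose(sum(weights), 1.0):
            raise ValueError("dwell mixture weights must sum to 1")
        if any(w < 0 or m <= 0 for w, m in self.dwell_mixture):
            raise ValueError("mixture weights >= 0 and means > 0 required")
        if not 0.0 <= self.labeling_fraction <= 1.0:
            raise ValueError("labeling_fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_active <= 1.0:
            raise ValueError("frac_active must lie in [0, 1]")
        if self.nonspecific_mean_dwell <= 0:
            raise ValueError("nonspecific_mean_dwell must be > 0")

    def effective_association_rate(self, construct: ConstructSpec) -> float:
        """Specific association rate for a construct, resolved from its flags.

        Zero with no functional 5'SS (or, when ``requires_branch_site``,
        with a mutated branch site block); the base rate with one site; the
        base rate times ``synergy_factor`` with both.  A per-construct
        override, if present, wins.
        """
        overrides = dict(self.k_assoc_overrides)
        if construct.name in overrides:
            return overrides[construct.name]
        if construct.is_control:
            return 0.0
        if self.requires_branch_site and not construct.bs_3ss_functional:
            return 0.0
        n = construct.n_functional_5ss
        if n == 0:
            return 0.0
        if n == 1:
            return self.k_assoc_specific
        return 2.0 * self.k_assoc_specific * self.synergy_factor

    def mean_specific_dwell(self) -> float:
        return float(sum(w * m for w, m in self.dwell_mixture))

    def sample_specific_dwell(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw dwell times from the exponential mixture."""
        weights = np.array([w for w, _ in self.dwell_mixture])
        means = np.array([m for _, m in self.dwell_mixture])
        comp = rng.choice(len(weights), size=size, p=weights)
        return rng.exponential(means[comp])
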