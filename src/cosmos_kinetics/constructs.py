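"""RNA construct definitions.

A construct is an abstract description of a surface-tethered RNA in terms of
which splicing signals are functional: an upstream 5' splice site, a
downstream 5' splice site, and the branch site / polypyrimidine tract / 3'
splice site block.  Sequence-level detail is deliberately out of scope; the
flags are what the binding kinetics of the simulated subcomplex respond to.

The reserved name ``no_RNA`` denotes surface locations with no tethered RNA,
used as background controls.
"""

from __future__ import annotations

from dataclasses import dataclass

NO_RNA = "no_RNA"


@dataclass(frozen=True)
class ConstructSpec:
    """An RNA species defined by which splice-site elements are functional.

    Parameters
    ----------
    name
        Short label, e.g. ``"5i3"``, ``"3e5"``, ``"5i3e5"``, ``"Xi3eX"``.
        ``"no_RNA"`` is reserved for control locations and must carry all
        flags false.
    upstream_5ss_functional, downstream_5ss_functional
        Whether the 5' splice site upstream / downstream of the branch
        site block is intact (an ``X`` in the conventional label marks a
        mutated site).
    bs_3ss_functional
        Whether the branch site / polypyrimidine tract / 3' splice site
        block is intact.
    spliceable
        Whether the construct can complete splicing and release its intron.
    """

    name: str
    upstream_5ss_functional: bool = False
    downstream_5ss_functional: bool = False
    bs_3ss_functional: bool = False
    spliceable: bool = False

    def __post_init__(self) -> None:
        if self.name == NO_RNA and (
            self.upstream_5ss_functional
            or self.downstream_5ss_functional
            or self.bs_3ss_functional
            or self.spliceable
        ):
            raise ValueError("'no_RNA' is reserved for the all-false control construct")

    @property
    def n_functional_5ss(self) -> int:
        return int(self.upstream_5ss_functional) + int(self.downstream_5ss_functional)

    @property
    def is_control(self) -> bool:
        return self.name == NO_RNA


NO_RNA_CONSTRUCT = ConstructSpec(NO_RNA)

#: Cross-intron substrate: 5'SS -- intron -- 3'SS.
FIVE_I_THREE = ConstructSpec(
    "5i3", upstream_5ss_functional=True, bs_3ss_functional=True, spliceable=True
)
#: Cross-exon substrate: 3'SS -- exon -- 5'SS (not spliceable as a unit).
THREE_E_FIVE = ConstructSpec("3e5", downstream_5ss_functional=True, bs_3ss_functional=True)


def double_5ss_panel() -> list[ConstructSpec]:
    """The four-construct panel probing 5'SS synergy around a shared 3'SS.

    ``5i3e5`` carries both flanking 5' splice sites, ``Xi3e5`` and ``5i3eX``
    one each, and ``Xi3eX`` neither.  Together with no-RNA controls this
    panel lets the additivity of the two sites be tested.
    """
    return [
        ConstructSpec("5i3e5", True, True, True, spliceable=True),
        ConstructSpec("Xi3e5", False, True, True),
        ConstructSpec("5i3eX", True, False, True, spliceable=True),
        ConstructSpec("Xi3eX", False, False, True),
    ]


def validate_panel(panel: list[ConstructSpec]) -> None:
    """Check name uniqueness within a panel."""
    names = [c.name for c in panel]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate construct names in panel: {names}")
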