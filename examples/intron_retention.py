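"""Two-color splicing readout: the intron-loss (retention) curve.

Each pre-mRNA carries an exon dye and an intron dye; splicing releases the
intron and its dye signal disappears.  The curve conditions on molecules
that keep the exon dye through the whole 40-minute experiment (excluding
degraded/bleached molecules) and reports the fraction still carrying the
intron dye over time, with and without ATP.
"""

import cosmos_kinetics as ck

for atp in (True, False):
    panel = ck.simulate_intron_loss_panel(1000, atp=atp, seed=42)
    curve = ck.intron_retention_curve(panel)
    final = curve.fraction_remaining[-1]
    se = curve.se[-1]
    label = "with ATP" if atp else "without ATP (bleaching only)"
    print(
        f"{label}: {100 * (1 - final):.1f} ± {100 * se:.1f}% of {curve.n} "
        f"conditioned molecules lost the intron dye by 2,400 s"
    )
print(
    "(ATP-dependent loss reflects splicing-driven intron release; the "
    "no-ATP control sets the photobleaching floor)"
)
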