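# cosmos-kinetics

Simulation and kinetic analysis of colocalization single-molecule
spectroscopy (CoSMoS) experiments, in which dye-labeled factors — e.g.
spliceosomal subcomplexes U1, U2, U5 — bind individual surface-tethered
RNA molecules watched by alternating-excitation TIRF microscopy. The
package is for experimentalists and modelers who need the full statistics
layer for such data (with honest error bars and censoring) and a
ground-truth simulator to validate it by parameter recovery.

## What it computes

From per-location binding intervals:

- **Cumulative dwell-time distributions** — mean events per location with
  dwell ≥ t, per RNA species and for no-RNA control locations;
- **Specific binding frequency** — the control-subtracted intercept
  f = value_RNA(0) − value_ctrl(0), total and split at a 50 s (or 60 s)
  dwell threshold, per experiment or per second;
- **Specific occupancy** — the background-corrected time-averaged bound
  fraction (f_m − f_c)/(1 − f_c), where f_m and f_c are the fractions of
  observed time a spot is present at RNA and control locations;
- **Bootstrap errors** — resampling surface locations (the independent
  unit), 2,000 samples by default;
- **Time-to-first-binding fits** — censored MLE of
  P(t) = A_f(1 − e^−(k_f+k_bg)t) + (1−A_f)(1 − e^−k_bg·t), with the
  background rate k_bg estimated from control locations;
- **Synergy ratio** R = f_both/(f_up + f_down) for panels probing two
  5' splice sites around a shared branch site/3'SS, with joint bootstrap CI;
- **Intron retention curves** for two-color splicing assays, conditioned on
  exon-dye retention;
- **Rastergrams** sorted by first binding, with percent bound ± s.e.

The simulator generates the matching data: alternating renewal binding
with exponential-mixture dwells, nonspecific surface events at all
locations, partial dye labeling, photobleaching under green-exposure dose,
multiple RNA species plus no-RNA controls on one slide, and the 100-green/
1-red alternating frame schedule (2,400 s default). An optional imaging
layer renders synthetic TIRF movies (Gaussian PSF, shot/read noise,
fiducial beads, drift) and recovers events by matched-filter spot
detection and colocalization. See `docs/methods.md` for the model and
`docs/schemas.md` for file formats.

## Worked example

```sh
python examples/synergy_panel.py
```

simulates a four-construct panel (100 molecules each plus 100 controls,
2,400 s) with a 3× synergy between the two flanking 5' splice sites and
prints:

```
5i3e5: 3.05 ± 0.20 specific events/RNA
5i3eX: 0.56 ± 0.09 specific events/RNA
Xi3e5: 0.59 ± 0.09 specific events/RNA
Xi3eX: -0.05 ± 0.05 specific events/RNA
synergy ratio f_both/(f_up + f_down) = 2.65 (95% CI 2.08-3.49); a CI excluding 1 rejects additivity
```

The double-5'SS RNA binds far more than the sum of the single-site RNAs;
the no-site RNA is indistinguishable from background (its specific
frequency is zero within error, here slightly negative by sampling noise).
The CI contains the simulated factor 3 and excludes additivity. Other
examples cover dwell distributions and the 50 s split, occupancy,
first-binding fits, intron retention and the imaging round trip
(`examples/*.py`, each a few seconds).

A config-driven end-to-end run is also available from the shell:

```sh
cosmos-kinetics simulate --out run1 --seed 7
cosmos-kinetics report run1/summary.json
```

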