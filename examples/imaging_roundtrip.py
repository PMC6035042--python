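"""Render a synthetic TIRF movie and recover binding by spot detection.

The forward model draws each bound dye as a Gaussian PSF with shot and
read noise plus bright fiducial beads; the inverse pipeline averages
frames, detects spots with a matched filter and colocalizes them with the
known RNA positions.  Per-frame agreement with the rendered ground truth
is reported.
"""

import numpy as np

import cosmos_kinetics as ck
from cosmos_kinetics.imaging import recover_presence_traces, render_image_stack

sched = ck.AcquisitionSchedule(total_duration=240.0)
params = ck.KineticModelParams(
    k_assoc_specific=2e-3,
    dwell_mixture=((1.0, 60.0),),
    labeling_fraction=1.0,
    bleach_rate=0.0,
    frac_active=1.0,
)
layout = ck.build_slide_layout(
    {"5i3": 20}, field_size=(20.0, 20.0), n_controls=20,
    min_separation=1.2, edge_margin=1.0, seed=5,
)
panel = ck.simulate_panel(layout, params, sched, seed=5, panel=[ck.FIVE_I_THREE])

sigma, background, snr = 1.2, 25.0, 5.0
amplitude = snr * np.sqrt(background) * 2 * np.pi * sigma**2
stack = render_image_stack(
    panel, psf_sigma=sigma, pixel_size=0.16, amplitude=amplitude,
    background=background, read_noise=2.0, seed=5,
)
recovered = recover_presence_traces(
    stack, layout, sched,
    threshold=0.5 * amplitude / (4 * np.pi * sigma**2), psf_sigma=sigma,
)

tp = fn = 0
for lid, tr in panel.traces.items():
    tp += int((recovered[lid].present & tr.present).sum())
    fn += int((~recovered[lid].present & tr.present).sum())
print(
    f"recovered {100 * tp / (tp + fn):.1f}% of ground-truth bound frames "
    f"at peak SNR {snr:g} across {len(panel.traces)} locations"
)
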