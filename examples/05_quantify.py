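"""Concentration from event counts: C = E / (k * t).

Fits the calibration coefficient k (events per mM per ms) as the
through-origin slope of event rate versus concentration, then converts an
event count from an independent recording back into a concentration.
"""

from porescreen.quantify import fit_calibration, quantify

# concentration-dependence series: (C mM, events counted, recording time ms)
points = [
    (0.5, 310, 1_200_000.0),
    (1.0, 595, 1_200_000.0),
    (2.0, 1210, 1_200_000.0),
    (4.0, 2380, 1_200_000.0),
]
curve = fit_calibration(points, analyte="XYL")
print(f"fitted k = {curve.k:.6f} events/(mM*ms), "
      f"residual sd {curve.residual_sd:.2e} events/ms")

E, t_ms = 880, 600_000.0  # an unknown sample: 880 events in 10 min
c = quantify(E, curve, t_ms)
print(f"estimated concentration: {c:.2f} mM from {E} events in {t_ms/6e4:.0f} min")
# The slope is forced through the origin because a zero-concentration sample
# produces no capture events; see the quantification round-trip benchmark
# for the full simulate -> detect -> count -> calibrate -> re-estimate loop.
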