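# magstim

A hardware-free Python toolkit for low-frequency magnetic neuromodulation
rigs: the kind of open-source solenoid platform used for magnetomechanical
and magnetogenetic stimulation of cultured neurons and freely moving mice
(square-wave alternating fields of tens of millitesla below 200 Hz, driven
by H-bridge circuits, with closed-loop behavioral gating).

It is written for neuroengineers who want to design, verify, and dry-run
such a rig entirely on a desk:

* **`magstim.fieldsim`** — an analytic magnetostatic engine.  A thick
  solenoid cross-section is discretized into filamentary loops with uniform
  current share, and each loop's field is evaluated exactly through the
  complete elliptic integrals K and E, so coil and coaxial-array field maps
  need no finite-element mesh.  Rectangular cuboid coils are handled by the
  finite-segment Biot–Savart formula.  Field quality over a region is
  summarized by the homogeneity metric

  `homogeneity = (B_max − B_min) / B_mean × 100 %`

  computed over |B| samples inside the region.
* **`magstim.protocol`** — compiles stimulation phase tables
  (stim/rest durations, frequency, repeats) into per-channel H-bridge
  pin-pair timelines.  Bidirectional mode reverses the field every
  half-period with a both-pins-low **dead time** before every reversal, so
  a compiled waveform can never command shoot-through; event times are
  exact rationals.
* **`magstim.controller`** — a three-gate closed loop sampled at 20 Hz:
  stimulate only while (1) the protocol is ON, (2) all enabled sensor
  readings are within thresholds, and (3) the subject is in the target
  area.  Breach-to-off latency is bounded by one poll interval.
* **`magstim.sensors`** — sensor models (Hall, temperature, sound,
  vibration) with their detection ranges and raw-voltage conversions, plus
  Pearson correlation, Bland–Altman limits of agreement, and System
  Usability Scale scoring.
* **`magstim.tracking`** — the ROI-threshold video algorithms for
  light–dark box and three-chamber place-preference tests (median blur →
  binary threshold at 127 → black-pixel count), centroid extraction, and
  locomotion metrics.
* **`magstim.synthetic`** — seeded virtual arenas, mouse walks, rendered
  frames, and sensor traces with injectable anomalies, wired into a
  `virtual_rig` for end-to-end closed-loop simulation.

## Worked example

The four-coil array for a 10 cm behavioral arena (each coil: 11 cm bore,
5 cm radial build, 4 cm tall, 500 turns, 6 A; stacked with 1/2/1 cm gaps):

```sh
$ cat coil.yaml
preset: arena_10cm
$ magstim field homogeneity --config coil.yaml
cylinder_h5cm: homogeneity 12.41% (B 51.8-58.7 mT, mean 55.2 mT)
cylinder_h10cm: homogeneity 12.95% (B 51.8-59.0 mT, mean 55.2 mT)
cylinder_h15cm: homogeneity 23.23% (B 46.4-59.0 mT, mean 53.8 mT)
```

Reading: over the central cylinder of 10 cm diameter and 5 cm height the
field spans 51.8–58.7 mT — a 12.4 % spread relative to the 55.2 mT mean —
and degrades to a 23 % spread when the cylinder is extended to 15 cm
height, because the region then reaches beyond the outer coils.  The same
numbers are available programmatically:

```python
from magstim.fieldsim import evaluate_apparatus
report = evaluate_apparatus("arena_10cm")["cylinder_h5cm"]
print(report.B_min, report.B_max, report.homogeneity)
# 51.80957289670324 58.66658468142163 12.411321230043686
```

Protocols and the closed loop run the same way from Python; see
`tests/test_synthetic.py::TestVirtualRig` for a complete virtual
experiment (walk → rendered video → tracking → gated stimulation log).

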