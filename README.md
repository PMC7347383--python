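# dendron

Quantitative tools for two measurement problems in GnRH-neuron
neuroendocrinology:

1. **Synaptic density by expansion microscopy (ExM).** GnRH neurons project
   a long blended dendrite/axon ("dendron") to the median eminence. With no
   global post-synaptic marker available, a synapse must be defined from a
   presynaptic label and a cytoplasmic fill alone: an apposing bouton counts
   as a synapse when the overlap of the two channels' relative-fluorescence
   line-scan profiles exceeds a threshold calibrated on marker-confirmed
   GABAergic synapses (minimum overlap across VGAT/gephyrin-defined
   contacts: 0.23 µm pre-expansion side-on, 0.42 µm face-on, at expansion
   factor E ≈ 4.2). This package implements the full pipeline — punctum
   detection with the >0.4 µm bouton filter, apposition geometry, side-on /
   face-on orientation choice, half-maximum-support overlap, threshold
   calibration and density per 10 µm of dendrite — plus a synthetic-volume
   generator with ground-truth placements for validating the pipeline by
   parameter recovery.

2. **LH pulse and surge analysis.** Pulsatile LH secretion in tail-tip bleed
   series (3-min sampling, 2 h) is scored with the standard nadir-to-peak
   rule: a pulse is an increment of strictly more than 25 %
   (100 × (peak − nadir) / nadir) from the running nadir to the next local
   maximum. The package implements the sequential caller, per-animal
   summaries (frequency, peak-minus-nadir amplitude, mean LH), a fold-rise
   surge classifier for the four-sample (16:00 / 19:00 / 20:00 / 21:00)
   surge design, and a matching episodic-secretion simulator with known
   event times for round-trip validation. Group comparisons use the
   Mann-Whitney U test (exact for n ≤ 8 without ties) with Holm-Sidak
   multiplicity adjustment.

All lengths are explicit about their frame: pre-expansion micrometres refer
to the original tissue, post-expansion values are pre-expansion × E.

## Worked example

```python
from dendron import compute_density, build_report

prox = compute_density(zone="proximal", n_segments=38, n_contacted=36,
                       n_contacts_total=183, expansion_factor=4.2)
dist = compute_density(zone="distal", n_segments=211, n_contacted=112,
                       n_contacts_total=330, expansion_factor=4.2)
print(prox.density_display, dist.density_display)   # 0.8 2.0
report = build_report(density_reports=[prox, dist])
print(report["synaptic_density"]["distal_to_proximal_ratio"])  # 2.5
```

0.8 and 2.0 are synapses per 10 µm of proximal dendrite and distal dendron
(contacted segments in the denominator), and 2.5 is the distal:proximal
density ratio — the distal dendron receives 2.5-fold denser synaptic input.

Running `python examples/call_lh_pulses.py` prints, for one simulated
animal:

```
animal 1: 9 pulses called (9 true secretion events)
  frequency  4.5 pulses/h
  amplitude  3.18 ng/ml (mean peak-nadir)
  mean LH    4.45 ng/ml
```

i.e. the >25 % caller recovers the simulated ~15 min pulse timing and
~3 ng/ml bolus amplitude. The other `examples/` scripts demonstrate the ExM
quantification, surge classification and group comparison; a thin
`dendron` command-line interface (`simulate-exm`, `quantify`, `simulate-lh`,
`call-pulses`, `call-surge`, `report`) wraps the same functions for shell
use.

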