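"""Classify LH surges in the four-sample (16:00/19:00/20:00/21:00) design.

Simulates a normal surge and a suppressed (blocked) animal and applies the
fold-rise classifier to both.
"""

from dendron import SurgeParams, classify_surge, generate_surge

for label, suppressed in (("control", False), ("suppressed", True)):
    series = generate_surge(SurgeParams(seed=8, suppressed=suppressed))
    call = classify_surge(series)
    samples = ", ".join(f"{t:.0f}h={v:.2f}" for t, v in
                        zip(series.times, series.lh))
    print(f"{label}: {samples}")
    print(f"  fold rise over baseline {call.fold_rise:.1f} -> "
          f"{'SURGE' if call.is_surge else 'no surge'}")

print("\nA surge is called when the largest post-baseline sample exceeds "
      "both 2x the 16:00 baseline and 1 ng/ml; the raw fold rise is always "
      "reported so the criterion can be re-thresholded.")
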