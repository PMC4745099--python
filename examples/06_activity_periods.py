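"""Three-period structure of daily foraging activity.

Synthetic 30-day timelines are segmented per replicate into exploration,
unloaded-arm feeding and loaded-arm feeding (with clay building); aggregate
onset means and the kernel-smoothed loaded-arm activity curve are printed.
"""

import numpy as np

from claysub import (
    SynthSpec,
    contact_histogram,
    generate_timelines,
    kernel_activity_estimate,
    segment_periods,
    summarize_onsets,
)

spec = SynthSpec.lab_defaults(seed=5)
timelines = generate_timelines(spec, n_replicates=200)
segs = [segment_periods(t) for t in timelines]
summary = summarize_onsets(segs)

print(f"replicates: {summary['n']} (incomplete: {summary['n_incomplete']})")
for period, label in [
    ("exploration", "period 1: exploration (both arms contacted)"),
    ("noload_feeding", "period 2: feeding on unloaded wood"),
    ("load_feeding", "period 3: feeding on loaded wood + wall building"),
]:
    s = summary[period]
    print(f"  {label}\n    onset mean {s['mean']:5.2f} days (range {s['min']:.0f}-{s['max']:.0f})")

days, freq = contact_histogram(timelines, "loaded")
grid, dens = kernel_activity_estimate(days, freq)
peak = grid[np.argmax(dens)]
print(f"\nloaded-arm kernel activity peak at day {peak:.1f} "
      f"(density integrates to {np.trapezoid(dens, grid):.3f})")
print(
    "\nTermites explore both arms within days, quickly settle on the safe"
    "\nunloaded wood, and only turn to the load-bearing wood — building clay"
    "\nwalls as they eat — late in the trial."
)
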