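"""Generate a synthetic paired load-choice dataset at the lab study conditions.

32 replicate pairs are drawn (21 flagged as having termite contact to both
arms), with clay mass and leftover wood negatively rank-correlated in the
loaded arm only — the substitution signature the analysis is built to detect.
"""

import numpy as np
from scipy.stats import spearmanr

from claysub import SynthSpec, filter_included, generate_dataset

spec = SynthSpec.lab_defaults(seed=7)
ds = generate_dataset(spec)
included = filter_included(ds)

print(f"generated {len(ds)} replicate pairs, {included.n_included} contacted both arms")

for arm in ("unloaded", "loaded"):
    clay = [getattr(r, arm).clay_mass for r in included.replicates]
    left = [getattr(r, arm).leftover_wood for r in included.replicates]
    rho = spearmanr(clay, left).statistic
    print(
        f"{arm:>9}: clay {np.mean(clay):6.1f} +/- {np.std(clay, ddof=1):5.1f} g, "
        f"leftover wood {np.mean(left):4.2f} g, clay/leftover rank corr {rho:+.2f}"
    )

print(
    "\nThe loaded arm's negative rank correlation means replicates that"
    "\ndeposited more clay also ate more of the load-bearing wood; the"
    "\nunloaded (control) arm shows no such coupling."
)
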