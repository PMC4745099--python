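"""Classical test battery on a synthetic lab experiment.

Runs the balanced one-way ANOVAs comparing loaded vs unloaded arms, fits
percentage-scaled beta marginals, and bootstraps the predictive bivariate
joint distribution for each arm, comparing their kurtosis.
"""

from claysub import AnalysisConfig, SynthSpec, generate_dataset
from claysub.pipeline import analyze_dataset

cfg = AnalysisConfig(seed=1, n_bootstrap=10_000)
ds = generate_dataset(SynthSpec.lab_defaults(seed=1))
result = analyze_dataset(ds, cfg, seed=1)

print(f"included replicates: {result['n_included']}\n")
print("one-way ANOVAs (loaded vs unloaded):")
for name, block in result["anova"].items():
    print(
        f"  {name:<24} F = {block['F']:6.2f}  "
        f"df = ({block['df_between']}, {block['df_within']})  p = {block['p']:.4f}"
    )

print("\nbootstrap joint models (10,000 draws each):")
for arm, jm in result["joint_models"].items():
    print(
        f"  {arm:>9}: rank corr {jm['rank_correlation']:+.2f}, "
        f"margin excess kurtosis ({jm['excess_kurtosis'][0]:+.2f}, {jm['excess_kurtosis'][1]:+.2f})"
    )

kc = result["kurtosis_comparison"]
print(
    f"\nloaded joint distribution more platykurtic than unloaded: {kc['loaded_more_platykurtic']}"
    f" (joint excess-kurtosis difference {kc['joint_difference']:+.2f})"
)
print(
    "\nA flatter (platykurtic) loaded-arm joint distribution and its negative"
    "\nclay/leftover-wood correlation indicate progressive substitution of the"
    "\nload-bearing wood by clay; the unloaded arm shows neither."
)
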