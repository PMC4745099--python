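"""Foraging energetics: does moving clay pay for itself?

Cost: gravitational work to lift the extra loaded-arm clay (plus an equal
mass of building water) from the soil depths of the wall minerals.  Gain:
digestible (lignin-discounted) energy of the consumed wood.
"""

from claysub import MineralProfile, make_budget, weighted_depth

profile = MineralProfile.mound_default()
print(
    f"mineral profile: "
    + ", ".join(f"{c.name} {c.mass_fraction:.0%} @ {100 * c.depth_m:.1f} cm" for c in profile.components)
)
print(f"mass-weighted source depth: {weighted_depth(profile):.4f} m")

# Field experiment component masses: extra loaded-arm clay 4.66 - 2.74 =
# 1.92 kg; wood consumed 432.27 - 39.22 = 393.05 g.
budget = make_budget(clay_mass_kg=1.92, wood_consumed_g=393.05)

print(f"\nclay lifted (incl. water): {budget.clay_mass_kg * 2:.2f} kg")
print(f"lifting work:              {budget.lift_energy_j:8.2f} J")
print(f"wood consumed:             {budget.wood_consumed_g:8.2f} g")
print(
    f"digestible wood energy:    {budget.wood_energy:8.2f} {budget.wood_energy_unit}"
    f"  (gross {budget.gross_energy_kj_per_g} kJ/g, {budget.lignin_fraction:.0%} lignin)"
)
print(f"\nreturn on investment:      {budget.roi:8.1f}-fold")
print(
    "\nA several-hundred-fold energy return makes clay transport a cheap"
    "\nprice for unlocking wood that would otherwise collapse if eaten."
)
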