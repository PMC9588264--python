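"""Stopping power and effective Z of the iodinated hydrogel spacer.

The spacer is 88% water, 0.7% trilysine, 10.1% PEG and 1.2% iodine by
weight at 1.03 g/cm3. Its proton stopping-power ratio (SPR) tells the dose
engine how fast protons slow down inside it relative to water; its
effective atomic number explains why it is bright on CT (~120 HU) even
though it barely differs from water for protons. That mismatch — high CT
number, near-water stopping power — is the whole story of this package.
"""

from spacerdose import compute_spr, effective_z, hu_to_spr, spacer_material

spacer = spacer_material()
print("elemental weight fractions:")
for sym, w in sorted(spacer.weight_fractions.items()):
    print(f"  {sym:>2}: {w:.4f}")

spr = compute_spr(spacer, energy_MeV=198.3)
zeff = effective_z(spacer, exponent=3.5)
curve_value = hu_to_spr(120.0)

print(f"\ntheoretical SPR at 198.3 MeV : {spr:.4f}   (water = 1)")
print(f"effective Z (m = 3.5)        : {zeff:.2f}")
print(f"HU->SPR curve value at 120 HU: {curve_value:.3f}")
print(
    "\nA CT-number-based dose calculation assigns the spacer an SPR of "
    f"{curve_value:.2f}, ~{100 * (curve_value / spr - 1):.0f}% too high — "
    "protons are predicted to stop short of where they really do."
)
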