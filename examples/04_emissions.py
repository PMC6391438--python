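"""Convert fire carbon efflux into species emissions with the FINN algorithm.

Dry biomass burned = carbon efflux / 0.5; each species is a fixed emission
factor (g per kg dry biomass) times the biomass burned, so every species
total is an exact scalar multiple of the CO2 total.
"""

from firefeedback.emissions import EMISSION_FACTORS, compute_emissions, dry_biomass_from_c

c_efflux_kg = 5.0e8  # half a Tg of carbon released by fires
biomass_kg = dry_biomass_from_c(c_efflux_kg)
print(f"carbon efflux {c_efflux_kg:.3g} kg C -> dry biomass burned {biomass_kg:.3g} kg")

emitted = compute_emissions(biomass_kg)
print(f"{'species':<8}{'factor (g/kg)':>14}{'emitted (Tg)':>14}")
for sp, factor in EMISSION_FACTORS.items():
    print(f"{sp:<8}{factor:>14.1f}{emitted[sp] / 1e9:>14.4f}")

print("\nratio CH4:CO2 =", emitted["CH4"] / emitted["CO2"],
      "(exactly 4.9/1454 — linearity means published CO2 ranges determine "
      "every other species)")
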