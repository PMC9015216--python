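"""Generate a study-scale synthetic owl population and look at its structure.

Builds 40 annual cohorts breeding in 360 nest boxes over an elongated
500 km^2 study area, with a Mendelian brown/gray color morph and ~6% local
recruitment, then prints the recruit table's headline numbers.
"""

from morphdispersal import SimulationParams, simulate_population

params = SimulationParams(seed=7)
bundle = simulate_population(params)
rec = bundle.recruits

print(f"ringed offspring: {bundle.n_offspring}")
print(f"recruits:         {len(rec)} "
      f"({100 * len(rec) / bundle.n_offspring:.1f}% recruitment)")
print(f"brown recruits:   {(rec['morph'] == 'brown').sum()} "
      f"({100 * (rec['morph'] == 'brown').mean():.1f}%)")
print("dispersal (km):   mean {:.1f}, sd {:.1f}, range {:.1f}-{:.1f}".format(
    rec["dispersal_km"].mean(), rec["dispersal_km"].std(),
    rec["dispersal_km"].min(), rec["dispersal_km"].max()))
print(f"network diameter: {bundle.registry.diameter_km():.1f} km")

# The mean near 10.5 km and sd near 7 km are the scale of real tawny-owl
# natal dispersal; ~29% brown follows from a brown allele frequency of 0.16
# under Hardy-Weinberg with brown dominance.
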