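"""The flagship experiment: a climate specialist vs a generalist under warming.

Two species share a temperature optimum but differ in niche breadth; the
reference years at a case-study cell are re-scored under +0 / +1.5 / +3 degC
offsets.  The narrow-envelope species shows exceedance first and scores as
the more vulnerable — the pattern that, in real forests, singles out
drought-and-heat-sensitive conifers.
"""

from climenv.experiments import two_species_offset_study

res = two_species_offset_study(seed=0)

print("envelopes on annual mean temperature (BIO1):")
for sp in ("narrow", "wide"):
    env = res.envelopes[(sp, "bio01")]
    print(f"  {sp:7s}: [{env.lower:6.2f}, {env.upper:6.2f}] degC")

print("\npositive exceedance frequency of BIO1 (% of 30 pooled years):")
for sp in ("narrow", "wide"):
    freqs = [res.positive_frequency(sp, "bio01", o) for o in (0.0, 1.5, 3.0)]
    print(f"  {sp:7s}: +0 degC -> {freqs[0]:5.1f}   +1.5 -> {freqs[1]:5.1f}   "
          f"+3 -> {freqs[2]:5.1f}")

print("\nordination-weighted total scores at +3 degC:")
for sp in ("narrow", "wide"):
    print(f"  {sp:7s}: {res.score(sp, 3.0):6.2f}")
print("Zero exceedance at reference, rising with warming, and the "
      "specialist at least as exposed as the generalist at every level.")
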