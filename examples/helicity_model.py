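"""Exercise the built-in Lifson-Roig helix-coil model.

Shows the transfer-matrix estimator against its brute-force enumeration
oracle on a short peptide, the helix-former vs helix-breaker contrast, and
the cold-shift of helicity (helix formation is exothermic, so cooling
favours it).
"""

from amphiscreen import HelicityConfig, enumerate_helix_content, helix_content

seq = "KALAALEK"  # 8-mer: enumeration over 2^8 states is exact and instant
tm = helix_content(seq).value
enum = enumerate_helix_content(seq).value
print(f"{seq}: transfer matrix {tm:.6f}% vs enumeration {enum:.6f}% "
      f"(difference {abs(tm - enum):.2e})")

print(f"poly-Ala 18-mer: {helix_content('A' * 18).value:5.1f}% helical")
print(f"poly-Gly 18-mer: {helix_content('G' * 18).value:5.3f}% helical")

for temp in (278.0, 300.0, 320.0):
    val = helix_content("A" * 18, HelicityConfig(temperature=temp)).value
    print(f"poly-Ala 18-mer at {temp:.0f} K: {val:5.1f}%")

protected = helix_content(
    "A" * 18, HelicityConfig(n_term_protected=True, c_term_protected=True)
).value
print(f"poly-Ala 18-mer, acetylated + amidated: {protected:5.1f}% "
      "(terminal protection removes the end penalties)")
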