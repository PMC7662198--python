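"""Identity vs dominance turnover between two years.

ser_r (Jaccard dissimilarity on presence sets) sees only which taxa are
present; ser_a (Wishart dissimilarity on relative abundances) also sees
who dominates.  A pure dominance swap therefore has ser_r = 0 but large
ser_a — compositional reorganization with zero richness change.
"""

from ecoturn import AnnualAssemblage, delta_richness, ser_a, ser_r

y2000 = AnnualAssemblage("site", 2000, {"spA": 0.8, "spB": 0.2})
y2001 = AnnualAssemblage("site", 2001, {"spA": 0.2, "spB": 0.8})

print("dominance swap (same two taxa, 80:20 -> 20:80):")
print(f"  delta_S = {delta_richness(y2000, y2001)}")
print(f"  ser_r   = {ser_r(y2000, y2001):.3f}   (no identity exchanged)")
print(f"  ser_a   = {ser_a(y2000, y2001):.3f}   (dominance largely reorganized)")

y2002 = AnnualAssemblage("site", 2002, {"spB": 0.5, "spC": 0.5})
print("\nidentity replacement (spA lost, spC gained):")
print(f"  delta_S = {delta_richness(y2001, y2002)}")
print(f"  ser_r   = {ser_r(y2001, y2002):.3f}   (2 of the 3 union taxa exchanged)")
print(f"  ser_a   = {ser_a(y2001, y2002):.3f}")
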