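"""How many distinct decamers can two peroxiredoxin variants form?

The (alpha2)5 decamer is a ring of five head-to-tail dimers.  Two rings
count as the same particle if a rotation about the fivefold axis or a flip
about one of the five in-plane twofold axes maps one onto the other.  This
script counts the symmetry-distinct configurations with Burnside's lemma,
enumerates them explicitly, and breaks them down by subunit stoichiometry.
"""

from prxkit import burnside_count, composition_census, enumerate_orbits

total = burnside_count(m=2, d=5)
print(f"Two monomer types, five dimers: {total} distinct decamers")

census = composition_census(5)
print("\nstoichiometry (A:B)   distinct decamers")
for (k, comp), count in census.combined_ratios().items():
    label = "homodecamers" if k == 0 else f"{k}:{comp} or {comp}:{k}" if k != comp else f"{k}:{comp}"
    print(f"  {label:<18} {count}")

reps = enumerate_orbits(2, 5).representatives
print(f"\nfirst three canonical representatives (dimers are label pairs):")
for rep in reps[:3]:
    print("  ", rep.labels)

print("\nWith m states per monomer the count grows like m**10 / 10:")
for m in (2, 3, 4):
    print(f"  m={m}: {burnside_count(m, 5)} configurations")
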