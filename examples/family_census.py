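"""Supramolecular-construct census of a five-structure family.

Generates five toy crystals engineered like a real substituent-variation
series: all five share an inversion-related N-H...O dimer (A01), three share a
4.07 A stack (A11), two pairs share 13.4 A and 18.6 A tapes (A12/A13), and two
are isostructural (A31).  Prints the construct table and the relationship
diagram in DOT form.
"""

from packmotif import CrystalStructure, build_graph, compare_family, to_dot
from packmotif.synthetic import make_family

family, expected = make_family(seed=7)
structures = [CrystalStructure(c) for c in family]
result = compare_family(structures)

print(result.summary_table().to_string(index=False))
print("\nEach row is one shared packing motif: D its dimensionality, "
      "base vectors its lattice repeats,\nand dependencies its covering "
      "sub-construct (A11->A01: the stack is built from the dimer).")

graph = build_graph(result.constructs, result.structure_ids)
print("\nRelationship diagram (DOT):")
print(to_dot(graph))
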