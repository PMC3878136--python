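"""Validation against deposited experimental structures (requires downloads).

The five oxindole deposits (eCrystals DOIs 10.5258/ecrystals/1505, /1326,
/1327, /1324, /1325 for 3a-3e) and the three CSD entries (3f, 4a, 4b) are not
redistributed here.  Download the CIFs into a directory and run

    python examples/validate_deposits.py <cif_dir>

to reproduce, from the real coordinates: the water -> carbonyl O...O distances
of the two hydrates, the core/aryl interplanar angles, the dimer N-H...O
geometry, E/Z assignments and the family SC census.
"""

import sys
from pathlib import Path

from packmotif import (CrystalStructure, classify_cc_geometry, compare_family,
                       find_hydrogen_bonds, interplanar_angle, mean_plane,
                       parse_cif)

if len(sys.argv) != 2 or not Path(sys.argv[1]).is_dir():
    print(__doc__)
    sys.exit(0)

structures = []
for path in sorted(Path(sys.argv[1]).glob("*.cif")):
    contents = parse_cif(path.read_text(), structure_id=path.stem)
    st = CrystalStructure(contents)
    structures.append(st)
    hbonds, da_only = find_hydrogen_bonds(st)
    print(f"\n{st.structure_id}: {len(st.molecules_asym)} molecule(s), "
          f"{len(hbonds)} H-bond(s)")
    for b in hbonds:
        print(f"  {b}")
    host = st.host()
    # oxindole core = bicyclic N1/C2/C3/C3A/C4-C7/C7A; aryl = C10-C15.
    # adjust the label sets here if a deposit uses a different numbering.
    try:
        core = host.subset_coords(["N1", "C2", "C3", "C3A", "C4", "C5", "C6",
                                   "C7", "C7A"])
        aryl = host.subset_coords(["C10", "C11", "C12", "C13", "C14", "C15"])
        print(f"  interplanar angle: "
              f"{interplanar_angle(mean_plane(core), mean_plane(aryl)):.2f} deg")
        print(f"  exocyclic C=C geometry: "
              f"{classify_cc_geometry(host, ('C3', 'C9'), ('C2', 'C10'))}")
    except KeyError as exc:
        print(f"  (atom numbering differs from the assumed scheme: {exc})")

if len(structures) >= 2:
    result = compare_family(structures)
    print("\nFamily construct census:")
    print(result.summary_table().to_string(index=False))
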