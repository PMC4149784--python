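"""Bite angle and chelate-plane dihedral of a bis-chelate complex.

Builds ideal bis-chelate coordinates (one Cu, two N,N ligands) with a
prescribed bite angle and inter-plane dihedral, writes/reads them as XYZ,
and re-measures the geometry.  An 81 deg bite with an 82.8 deg dihedral is
the distorted-tetrahedral coordination of a cuprous bis-diimine; 90/90
would be the ideal tetrahedral bis-chelate.
"""

import tempfile
from pathlib import Path

import regulonprint as rp
from regulonprint.geometry import write_xyz

for bite, dihedral in ((81.0, 82.8), (90.0, 90.0), (90.0, 0.0)):
    model = rp.gen_bischelate(bite, dihedral, bond_len=2.05)
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "complex.xyz"
        write_xyz(model, path, comment="synthetic bis-chelate")
        loaded = rp.load_structure(path)
    geoms, summary = rp.analyze_structure(loaded)
    g = geoms[0]
    print(f"built bite {bite:5.1f} / dihedral {dihedral:5.1f} -> measured "
          f"bites {g.bite_angles_deg[0]:.1f}, {g.bite_angles_deg[1]:.1f}; "
          f"dihedral {g.dihedral_deg:.1f}; "
          f"Cu-N {g.distances[0]:.2f} A")
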