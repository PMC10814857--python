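"""Extract peptide-contacting residues from a domain–peptide complex.

A synthetic two-chain complex is generated with a known contact set, written
as PDB text, re-read, and analysed at the 4.0 Å cutoff: a domain residue is a
contact residue when any of its heavy atoms lies within 4.0 Å of any peptide
atom.
"""

import tempfile
from pathlib import Path

from sh3prm import ContactConfig, GeneratorConfig, find_contact_residues, read_structure
from sh3prm.synthetic import simulate_complex

cplx = simulate_complex(GeneratorConfig(seed=3), n_domain_residues=20, n_contacts=5)
pdb = Path(tempfile.mkdtemp()) / "complex.pdb"
pdb.write_text(cplx.pdb_text)

struct = read_structure(pdb, domain_chain="A", peptide_chain="B")
contacts = find_contact_residues(struct, ContactConfig(cutoff=4.0))

print("designed contact residues:", list(cplx.contact_positions))
print("extracted contact residues and their minimum atom distances:")
for r in contacts.residues:
    print(f"  residue {r['number']:>3d} {r['name']}  min distance {r['min_distance']:.2f} Å")
print("\nThe extracted set equals the designed one: every residue listed has")
print("at least one atom within 4.0 Å of the peptide chain; all others are")
print("kept at least 0.2 Å beyond the cutoff by construction.")
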