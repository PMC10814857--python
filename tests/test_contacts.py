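"""Contact extraction: threshold behaviour, oracle equivalence, invariances."""

import numpy as np
import pytest

from sh3prm.contacts import (
    Atom,
    ComplexStructure,
    ContactConfig,
    Residue,
    find_contact_residues,
    read_structure,
)
from sh3prm.synthetic import GeneratorConfig, simulate_complex

from conftest import oracle_contacts


def _residue(number: int, name: str, coords, element="C") -> Residue:
    return Residue(
        number=number,
        icode="",
        name=name,
        atoms=tuple(Atom(name=f"C{i}", element=element, coord=tuple(c)) for i, c in enumerate(coords)),
    )


def _two_chain(domain_residues, peptide_residues):
    return ComplexStructure(
        structure_id="toy",
        chains={"A": domain_residues, "B": peptide_residues},
        domain_chain="A",
        peptide_chain="B",
    )


@pytest.fixture()
def peptide_at_origin():
    return [_residue(1, "PRO", [(0.0, 0.0, 0.0)])]


class TestContactRule:
    def test_threshold_straddle_at_cutoff(self, peptide_at_origin):
        struct = _two_chain(
            [
                _residue(1, "ALA", [(3.9, 0, 0)]),
                _residue(2, "ALA", [(4.1, 0, 0)]),
                _residue(3, "ALA", [(4.0, 0, 0)]),  # tie: inclusive
            ],
            peptide_at_origin,
        )
        cs = find_contact_residues(struct, ContactConfig(cutoff=4.0))
        assert cs.positions == [1, 3]

    def test_min_distance_rule_over_atoms(self, peptide_at_origin):
        struct = _two_chain(
            [_residue(1, "ALA", [(6.0, 0, 0), (3.5, 0, 0)])], peptide_at_origin
        )
        cs = find_contact_residues(struct, ContactConfig(cutoff=4.0))
        assert cs.positions == [1]
        assert cs.residues[0]["min_distance"] == pytest.approx(3.5)

    def test_hydrogens_excluded_by_default_included_on_request(self, peptide_at_origin):
        hydrogen_only_near = _residue(1, "ALA", [(3.0, 0, 0)], element="H")
        far_carbon = Residue(
            number=1, icode="", name="ALA",
            atoms=hydrogen_only_near.atoms + (Atom("CA", "C", (9.0, 0, 0)),),
        )
        struct = _two_chain([far_carbon], peptide_at_origin)
        assert find_contact_residues(struct, ContactConfig(cutoff=4.0)).positions == []
        cfg = ContactConfig(cutoff=4.0, heavy_atoms_only=False)
        assert find_contact_residues(struct, cfg).positions == [1]

    def test_empty_chain_rejected(self, peptide_at_origin):
        struct = _two_chain([_residue(1, "ALA", [(1, 0, 0)])], peptide_at_origin)
        struct.chains["B"] = []
        with pytest.raises(ValueError):
            find_contact_residues(struct)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ContactConfig(cutoff=0.0)


class TestAgainstOracleAndInvariances:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_structures_match_brute_force(self, seed, tmp_path):
        cplx = simulate_complex(
            GeneratorConfig(seed=seed), n_domain_residues=30, n_contacts=seed % 8
        )
        path = tmp_path / "c.pdb"
        path.write_text(cplx.pdb_text)
        struct = read_structure(path, "A", "B")
        cs = find_contact_residues(struct, ContactConfig(cutoff=4.0))
        oracle = oracle_contacts(struct, 4.0)
        assert cs.positions == [num for num, _ in oracle]
        for rec, (_, dist) in zip(cs.residues, oracle):
            assert rec["min_distance"] == pytest.approx(dist, abs=1e-9)
        assert cs.positions == list(cplx.contact_positions)

    def test_cutoff_monotonicity(self, tmp_path):
        cplx = simulate_complex(GeneratorConfig(seed=7), n_domain_residues=25, n_contacts=6)
        path = tmp_path / "c.pdb"
        path.write_text(cplx.pdb_text)
        struct = read_structure(path, "A", "B")
        tight = find_contact_residues(struct, ContactConfig(cutoff=3.5)).positions
        loose = find_contact_residues(struct, ContactConfig(cutoff=5.0)).positions
        assert set(tight) <= set(loose)

    def test_rigid_transform_leaves_contacts_unchanged(self, peptide_at_origin):
        rng = np.random.default_rng(11)
        dom = [
            _residue(i + 1, "ALA", [rng.normal(0, 4, size=3)]) for i in range(15)
        ]
        struct = _two_chain(dom, peptide_at_origin)
        base = find_contact_residues(struct, ContactConfig(cutoff=4.0))

        # random rotation (QR orthogonalization) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(0, 50, size=3)

        def move(res):
            return Residue(
                res.number, res.icode, res.name,
                tuple(
                    Atom(a.name, a.element, tuple(q @ np.array(a.coord) + t))
                    for a in res.atoms
                ),
            )

        moved = _two_chain([move(r) for r in dom], [move(r) for r in peptide_at_origin])
        after = find_contact_residues(moved, ContactConfig(cutoff=4.0))
        assert after.positions == base.positions
        for a, b in zip(after.residues, base.residues):
            assert a["min_distance"] == pytest.approx(b["min_distance"], abs=1e-6)


class TestReadStructure:
    def test_round_trip_of_synthetic_complex(self, tmp_path):
        cplx = simulate_complex(GeneratorConfig(seed=5), n_domain_residues=5, n_contacts=2,
                                n_peptide_residues=3)
        path = tmp_path / "c.pdb"
        path.write_text(cplx.pdb_text)
        struct = read_structure(path, "A", "B")
        assert len(struct.chains["A"]) == 5
        assert len(struct.chains["B"]) == 3
        # PDB text carries 3 decimal places; re-read must be exact to that
        first = struct.chains["B"][0].atoms[0].coord
        assert first[0] == pytest.approx(0.0, abs=1e-3)

    def test_missing_chain_error_names_available_chains(self, tmp_path):
        cplx = simulate_complex(GeneratorConfig(seed=5))
        path = tmp_path / "c.pdb"
        path.write_text(cplx.pdb_text)
        with pytest.raises(ValueError, match=r"available chains.*A.*B"):
            read_structure(path, "A", "Z")

    def test_same_chain_for_domain_and_peptide_rejected(self, tmp_path):
        cplx = simulate_complex(GeneratorConfig(seed=5))
        path = tmp_path / "c.pdb"
        path.write_text(cplx.pdb_text)
        with pytest.raises(ValueError):
            read_structure(path, "A", "A")

    def test_waters_and_heteroatoms_excluded(self, tmp_path):
        cplx = simulate_complex(GeneratorConfig(seed=5), n_domain_residues=4, n_contacts=1)
        lines = [l for l in cplx.pdb_text.splitlines() if l.startswith(("ATOM", "TER"))]
        hoh = "HETATM 9999  O   HOH A 999       0.000   0.000   0.000  1.00  1.00           O"
        path = tmp_path / "c.pdb"
        path.write_text("\n".join(lines[:1] + [hoh] + lines[1:]) + "\nEND\n")
        struct = read_structure(path, "A", "B")
        assert all(r.name != "HOH" for r in struct.chains["A"])
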