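"""Contact-residue extraction from SH3 domain–peptide complex structures.

A domain residue is a *contact residue* when the minimum Euclidean distance
between any of its atoms and any atom of the bound peptide chain is within a
cutoff (4.0 Å by default, inclusive).  Hydrogens are excluded by default
because most crystal structures do not resolve them; waters and other
heteroatoms are always excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial.distance import cdist

DEFAULT_CUTOFF = 4.0


@dataclass(frozen=True)
class ContactConfig:
    """Distance cutoff in Å (inclusive) and atom policy."""

    cutoff: float = DEFAULT_CUTOFF
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    """One residue keyed by author numbering (insertion code included)."""

    number: int
    icode: str
    name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass
class ComplexStructure:
    structure_id: str
    chains: dict[str, list[Residue]]
    domain_chain: str
    peptide_chain: str

    def __post_init__(self) -> None:
        if self.domain_chain == self.peptide_chain:
            raise ValueError("domain and peptide chain ids must differ")
        for want in (self.domain_chain, self.peptide_chain):
            if want not in self.chains:
                raise ValueError(
                    f"chain {want!r} not in structure {self.structure_id!r}; "
                    f"available chains: {sorted(self.chains)}"
                )


@dataclass
class ContactSet:
    """Domain residues within the cutoff of the peptide, sorted by author number."""

    structure_id: str
    domain_chain: str
    cutoff: float
    residues: list[dict] = field(default_factory=list)  # number, icode, name, min_distance

    @property
    def positions(self) -> list[int]:
        return [r["number"] for r in self.residues]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure_id": self.structure_id,
                    "chain": self.domain_chain,
                    "resnum": r["number"],
                    "icode": r["icode"],
                    "resname": r["name"],
                    "min_distance": r["min_distance"],
                }
                for r in self.residues
            ],
            columns=["structure_id", "chain", "resnum", "icode", "resname", "min_distance"],
        )


def _convert_chain(chain) -> list[Residue]:
    residues = []
    for res in chain:
        hetflag = res.id[0]
        if hetflag != " ":  # waters and heteroatoms excluded
            continue
        atoms = []
        for atom in res:
            if atom.is_disordered():
                atom = atom.disordered_get()  # highest-occupancy conformer
            coord = atom.get_coord()
            if not np.all(np.isfinite(coord)):
                raise ValueError(
                    f"non-finite coordinates for atom {atom.get_full_id()}"
                )
            atoms.append(
                Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").upper(),
                    coord=tuple(float(c) for c in coord),
                )
            )
        if atoms:
            residues.append(
                Residue(
                    number=res.id[1],
                    icode=res.id[2].strip(),
                    name=res.get_resname(),
                    atoms=tuple(atoms),
                )
            )
    return residues


def read_structure(
    path, domain_chain: str, peptide_chain: str, structure_id: str | None = None
) -> ComplexStructure:
    """Read a two-chain complex from a PDB file.

    Residues keep author numbering and file order; for alternate locations
    only the highest-occupancy conformer is kept.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(structure_id or "complex", str(path))
        except Exception as exc:  # malformed records surface with file context
            raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    model = next(iter(structure))
    chains = {ch.id: _convert_chain(ch) for ch in model}
    chains = {cid: res for cid, res in chains.items() if res}
    return ComplexStructure(
        structure_id=structure_id or getattr(structure, "id", "complex"),
        chains=chains,
        domain_chain=domain_chain,
        peptide_chain=peptide_chain,
    )


def _atom_coords(residues: list[Residue], heavy_only: bool) -> tuple[np.ndarray, np.ndarray]:
    """Stacked coordinates plus the residue index of each atom row."""
    coords, owner = [], []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            if heavy_only and atom.element in ("H", "D"):
                continue
            coords.append(atom.coord)
            owner.append(i)
    if not coords:
        return np.empty((0, 3)), np.empty((0,), dtype=int)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def find_contact_residues(
    struct: ComplexStructure, cfg: ContactConfig = ContactConfig()
) -> ContactSet:
    """All domain residues whose minimum atom distance to the peptide ≤ cutoff.

    Ties at exactly the cutoff are included.  Result is sorted by author
    residue number (insertion code as secondary key) without duplicates.
    """
    dom = struct.chains[struct.domain_chain]
    pep = struct.chains[struct.peptide_chain]
    if not dom or not pep:
        raise ValueError("domain and peptide chains must both be nonempty")
    dom_xyz, dom_owner = _atom_coords(dom, cfg.heavy_atoms_only)
    pep_xyz, _ = _atom_coords(pep, cfg.heavy_atoms_only)
    if dom_xyz.size == 0 or pep_xyz.size == 0:
        raise ValueError("no atoms left after atom-policy filtering")
    d = cdist(dom_xyz, pep_xyz)
    per_atom_min = d.min(axis=1)
    out = ContactSet(
        structure_id=struct.structure_id,
        domain_chain=struct.domain_chain,
        cutoff=cfg.cutoff,
    )
    per_res_min: dict[int, float] = {}
    for atom_i, dist in zip(dom_owner, per_atom_min):
        prev = per_res_min.get(atom_i)
        if prev is None or dist < prev:
            per_res_min[int(atom_i)] = float(dist)
    for i in sorted(per_res_min, key=lambda i: (dom[i].number, dom[i].icode)):
        if per_res_min[i] <= cfg.cutoff:
            out.residues.append(
                {
                    "number": dom[i].number,
                    "icode": dom[i].icode,
                    "name": dom[i].name,
                    "min_distance": per_res_min[i],
                }
            )
    return out
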