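"""Projection of structure-derived contact positions onto an MSA.

The central object is the *interface alignment*: the column subset of a full
multiple sequence alignment restricted to peptide-contacting positions.  A
phylogeny built from that sub-alignment groups domains by binding specificity
rather than by overall sequence history (see :mod:`sh3prm.phylo`).

Alignments are plain ordered ``(id, gapped sequence)`` records; FASTA and
Clustal I/O goes through Bio.AlignIO.  All sequence and column coordinates in
this module are 1-based; gaps are ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class Alignment:
    """Rectangular gapped alignment with unique record ids."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment; lengths {sorted(lengths)}")
        self._index = {rid: seq.upper() for rid, seq in self.records}
        self.records = [(rid, seq.upper()) for rid, seq in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, record_id: str) -> str:
        return self._index[record_id]

    def ungapped(self, record_id: str) -> str:
        return self._index[record_id].replace(GAP, "")

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq)) for rec in aln])

    def write(self, path, fmt: str = "fasta") -> None:
        msa = MultipleSeqAlignment(
            [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.records]
        )
        AlignIO.write(msa, str(path), fmt)


def map_residue_to_column(aln: Alignment, record_id: str, seq_pos: int) -> int:
    """Alignment column (1-based) holding the ``seq_pos``-th non-gap residue."""
    seq = aln.sequence(record_id)
    if seq_pos < 1:
        raise IndexError(f"sequence position must be >= 1, got {seq_pos}")
    seen = 0
    for col, c in enumerate(seq, start=1):
        if c != GAP:
            seen += 1
            if seen == seq_pos:
                return col
    raise IndexError(
        f"position {seq_pos} beyond ungapped length {seen} of record {record_id!r}"
    )


def column_to_residue(aln: Alignment, record_id: str, col: int) -> int | None:
    """Inverse map: ungapped position at a column, or None if the record gaps there."""
    seq = aln.sequence(record_id)
    if not 1 <= col <= len(seq):
        raise IndexError(f"column {col} outside [1, {len(seq)}]")
    if seq[col - 1] == GAP:
        return None
    return len(seq[:col].replace(GAP, ""))


@dataclass(frozen=True)
class InterfaceColumns:
    """Sorted 1-based alignment columns flagged as peptide-binding."""

    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(sorted(set(self.columns))))

    def __len__(self) -> int:
        return len(self.columns)

    @classmethod
    def read(cls, path) -> "InterfaceColumns":
        with open(path) as fh:
            cols = [int(line) for line in fh if line.strip() and not line.startswith("#")]
        return cls(tuple(cols))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.columns:
                fh.write(f"{c}\n")


def derive_interface_columns(
    aln: Alignment, contact_maps: Iterable[tuple[str, Sequence[int]]]
) -> InterfaceColumns:
    """Union of contact positions mapped to alignment columns.

    ``contact_maps`` pairs each structure's alignment record id with the
    1-based ungapped sequence positions of its contact residues.
    """
    cols: set[int] = set()
    for record_id, positions in contact_maps:
        if record_id not in aln.ids:
            raise KeyError(f"record {record_id!r} not in alignment")
        for pos in positions:
            cols.add(map_residue_to_column(aln, record_id, pos))
    if not cols:
        raise ValueError("contact maps yielded no interface columns")
    return InterfaceColumns(tuple(cols))


def extract_interface_alignment(aln: Alignment, cols: InterfaceColumns) -> Alignment:
    """Restrict every record to the interface columns (order preserved).

    Records that gap an interface column keep the gap, so the result stays
    rectangular with one position per interface column.
    """
    if len(cols) == 0:
        raise ValueError("empty interface column set")
    bad = [c for c in cols.columns if not 1 <= c <= aln.n_columns]
    if bad:
        raise IndexError(f"interface columns outside alignment: {bad}")
    return Alignment(
        [
            (rid, "".join(seq[c - 1] for c in cols.columns))
            for rid, seq in aln.records
        ]
    )


@dataclass(frozen=True)
class Substitution:
    wt: str
    position: int  # 1-based, in the numbering of the sequence it applies to
    mutant: str

    @classmethod
    def parse(cls, label: str) -> "Substitution":
        """Parse the conventional mutation label, e.g. ``N205D``."""
        wt, pos, mut = label[0], label[1:-1], label[-1]
        return cls(wt=wt.upper(), position=int(pos), mutant=mut.upper())

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.mutant}"


@dataclass(frozen=True)
class MutationSet:
    """A named group of interface-residue substitutions (e.g. Set-1).

    ``offset`` shifts full-protein numbering into isolated-domain coordinates:
    a substitution at full-length position p applies at p − offset.
    """

    label: str
    substitutions: tuple[Substitution, ...]
    offset: int = 0

    def __post_init__(self) -> None:
        pos = [s.position for s in self.substitutions]
        if len(set(pos)) != len(pos):
            raise ValueError(f"duplicate positions in mutation set {self.label!r}")

    @classmethod
    def from_labels(cls, label: str, labels: Iterable[str], offset: int = 0) -> "MutationSet":
        return cls(label, tuple(Substitution.parse(s) for s in labels), offset)

    def inverse(self) -> "MutationSet":
        return MutationSet(
            f"{self.label}-inverse",
            tuple(Substitution(s.mutant, s.position, s.wt) for s in self.substitutions),
            self.offset,
        )


def apply_mutation_set(seq: str, ms: MutationSet) -> str:
    """Apply substitutions, validating the wild-type letter at every position."""
    seq = seq.upper()
    chars = list(seq)
    for s in ms.substitutions:
        idx = s.position - ms.offset - 1
        if not 0 <= idx < len(chars):
            raise IndexError(
                f"{ms.label}: position {s.position} (offset {ms.offset}) outside sequence"
            )
        if chars[idx] != s.wt:
            raise ValueError(
                f"{ms.label}: wild-type mismatch at position {s.position}: "
                f"expected {s.wt}, found {chars[idx]}"
            )
        chars[idx] = s.mutant
    return "".join(chars)
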