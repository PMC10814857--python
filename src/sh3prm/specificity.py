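"""Family→motif specificity map and qualitative SH3–peptide compatibility.

Each of the 10 SH3 specificity families recognizes a small set of consensus
motif classes.  A domain assigned to a family is predicted *compatible* with a
peptide when the peptide contains at least one match to at least one of the
family's classes; the supporting matches are the evidence.  This is a
deliberately qualitative map — affinities come from :mod:`sh3prm.binding`.

The packaged family table references motifs beyond the 14-class consensus
registry (several families have their own literal patterns), so specificity
loading uses an extended *family registry*: the consensus classes plus every
family-specific pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .motifs import (
    MotifMatch,
    MotifPattern,
    MotifRegistry,
    compile_pattern,
    default_registry,
    scan_sequence,
)


@dataclass(frozen=True)
class FamilySpecificity:
    family_id: int
    class_ids: tuple[str, ...]
    inferred: bool = False  # consensus proposed without structural/biochemical data
    note: str = ""


def family_registry() -> MotifRegistry:
    """Consensus registry extended with every family-specific pattern."""
    patterns = {p.class_id: p for p in default_registry()}
    table = _packaged_family_table()
    for _, row in table.iterrows():
        for cid in row["class_ids"].split(","):
            cid = cid.strip()
            if cid and cid not in patterns:
                patterns[cid] = compile_pattern(cid)
    return MotifRegistry(patterns.values(), version="prm-family-extended")


def _packaged_family_table() -> pd.DataFrame:
    with resources.as_file(
        resources.files("sh3prm.data") / "family_specificity.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")


def load_family_specificities(
    table: pd.DataFrame | None = None, registry: MotifRegistry | None = None
) -> list[FamilySpecificity]:
    """Load family→motif specificities, validating classes against a registry.

    With no arguments, loads the packaged 10-family table against the extended
    family registry.
    """
    if table is None:
        table = _packaged_family_table()
    if registry is None:
        registry = family_registry()
    if len(table) == 0:
        raise ValueError("empty family specificity table")
    out = []
    seen: set[int] = set()
    for _, row in table.iterrows():
        fid = int(row["family_id"])
        if fid in seen:
            raise ValueError(f"duplicate family id {fid}")
        seen.add(fid)
        cids = tuple(c.strip() for c in row["class_ids"].split(",") if c.strip())
        for cid in cids:
            if cid not in registry:
                raise KeyError(f"family {fid} references unknown class {cid!r}")
        out.append(
            FamilySpecificity(
                family_id=fid,
                class_ids=cids,
                inferred=str(row.get("inferred", "no")).lower() in ("yes", "true", "1"),
                note=str(row.get("note", "")),
            )
        )
    return out


def specificity_overlap(specs: list[FamilySpecificity]) -> pd.DataFrame:
    """Shared motif classes between family pairs (literal class identity)."""
    rows = []
    for a, b in itertools.combinations(specs, 2):
        shared = sorted(set(a.class_ids) & set(b.class_ids))
        if shared:
            rows.append(
                {"family_a": a.family_id, "family_b": b.family_id, "shared_classes": ",".join(shared)}
            )
    return pd.DataFrame(rows, columns=["family_a", "family_b", "shared_classes"])


def pattern_subsumes(broad: MotifPattern, narrow: MotifPattern) -> bool:
    """True when every sequence matching ``narrow`` contains a ``broad`` match.

    Checked by brute-force enumeration of all sequences realizable by the
    narrow pattern (feasible: patterns are short and most positions are
    fixed or small alternations; ``X`` positions only need one witness per
    choice that could break containment, so enumeration uses each position's
    allowed set, capped by substituting a single non-constrained residue for
    full ``X`` sets where the broad pattern has no fixed requirement).
    """
    if narrow.length < broad.length:
        return False
    # Enumerate over reduced candidate sets: for an X position, the residues
    # that could matter are those the broad pattern constrains anywhere,
    # plus one neutral residue.
    relevant: set[str] = set()
    for el in broad.elements:
        if len(el) < 20:
            relevant |= el
    neutral = next(iter(set("ACDEFGHIKLMNQSTVWY") - relevant), "A")
    candidate_sets = []
    for el in narrow.elements:
        if len(el) == 20:
            candidate_sets.append(sorted(relevant) + [neutral])
        else:
            candidate_sets.append(sorted(el))
    for combo in itertools.product(*candidate_sets):
        s = "".join(combo)
        if not any(
            broad.matches_window(s[i : i + broad.length])
            for i in range(narrow.length - broad.length + 1)
        ):
            return False
    return True


def overlap_with_subsumption(
    specs: list[FamilySpecificity], registry: MotifRegistry
) -> pd.DataFrame:
    """Family-pair overlap where one family's class is subsumed by the other's.

    Reports (family_a, family_b, narrow_class, broad_class) whenever every
    instance of family_a's ``narrow_class`` necessarily contains a match to
    family_b's ``broad_class`` (or vice versa, reported both ways).
    """
    rows = []
    for a, b in itertools.permutations(specs, 2):
        for narrow_id in a.class_ids:
            for broad_id in b.class_ids:
                if narrow_id == broad_id:
                    continue
                if pattern_subsumes(registry[broad_id], registry[narrow_id]):
                    rows.append(
                        {
                            "family_narrow": a.family_id,
                            "family_broad": b.family_id,
                            "narrow_class": narrow_id,
                            "broad_class": broad_id,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["family_narrow", "family_broad", "narrow_class", "broad_class"]
    )


@dataclass
class PredictionMatrix:
    cells: pd.DataFrame  # sh3_id, peptide_id, family_id, compatible, supporting
    support: dict[tuple[str, str], list[MotifMatch]]


def predict_interactions(
    assignments: dict[str, int],
    peptides: dict[str, str],
    registry: MotifRegistry | None = None,
    specs: list[FamilySpecificity] | None = None,
) -> PredictionMatrix:
    """Qualitative compatibility of family-assigned SH3 domains with peptides.

    A cell is compatible iff the peptide holds >= 1 match to >= 1 motif class
    of the domain's family; supporting matches are recorded per cell.
    """
    if registry is None:
        registry = family_registry()
    if specs is None:
        specs = load_family_specificities(registry=registry)
    by_family = {s.family_id: s for s in specs}
    for sh3, fam in assignments.items():
        if fam not in by_family:
            raise KeyError(f"SH3 {sh3!r} assigned to unknown family {fam}")

    # scan each peptide once against the full registry, then filter per family
    peptide_matches: dict[str, list[MotifMatch]] = {
        pid: scan_sequence(seq, registry, sequence_id=pid) for pid, seq in peptides.items()
    }
    rows, support = [], {}
    for sh3, fam in assignments.items():
        allowed = set(by_family[fam].class_ids)
        for pid in peptides:
            hits = [m for m in peptide_matches[pid] if m.class_id in allowed]
            rows.append(
                {
                    "sh3_id": sh3,
                    "peptide_id": pid,
                    "family_id": fam,
                    "compatible": bool(hits),
                    "supporting": ";".join(
                        f"{m.class_id}@{m.start}" for m in hits
                    ),
                }
            )
            support[(sh3, pid)] = hits
    return PredictionMatrix(cells=pd.DataFrame(rows), support=support)
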