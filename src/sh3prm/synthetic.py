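"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *statistical structure* of the study conditions,
not protein evolution:

* ``simulate_sh3_families`` — aligned SH3-like domains in which binding
  specificity is encoded only at interface columns (family-specific conserved
  signatures) while the remaining columns follow an orthogonal "evolutionary"
  clade structure.  This reproduces the phenomenon that a full-domain tree
  groups by overall homology while an interface-restricted tree groups by
  specificity family.
* ``simulate_complex`` — toy domain–peptide coordinates with a chosen set of
  residues below the 4.0 Å contact cutoff and the rest safely above it.
* ``simulate_prd`` — proline-rich sequences with planted motif occurrences
  separated by motif-free linkers.
* ``simulate_titration`` / ``simulate_screen`` — fluorescence-polarization
  curves from the quadratic binding model (probe 0.2 µM, protein 0–200 µM)
  and the 25 × 12 screen with 45 planted binders.

All randomness flows through one seeded :class:`numpy.random.Generator`; the
same seed reproduces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .binding import DEFAULT_PROBE_UM, TITRATION_MAX_UM, TitrationCurve, quadratic_binding_signal
from .motifs import MotifRegistry, default_registry, scan_sequence

AA = "ACDEFGHIKLMNPQRSTVWY"
#: Linker alphabet free of residues any registry class fixes or alternates
#: over (P, R, K, and A of the [PA]/[LA] alternations), so linkers and X-fill
#: cannot complete an accidental motif occurrence.
LINKER_AA = "GSTQ"


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    25 screened domains over 10 families and 45 binders of 300 combinations
    mirror the reference screen; 60-column domains with a 14-position binding
    interface are typical SH3 proportions.
    """

    seed: int = 0
    n_families: int = 10
    domains_per_family: int = 5
    alignment_length: int = 60
    interface_column_count: int = 14
    interface_conservation: float = 0.95
    background_divergence: float = 0.2
    titration_noise_frac: float = 0.02
    n_titration_points: int = 30
    n_screen_sh3: int = 25
    n_screen_peptides: int = 12
    planted_binder_count: int = 45

    def __post_init__(self) -> None:
        for prob in (self.interface_conservation, self.background_divergence,
                     self.titration_noise_frac):
            if not 0 <= prob <= 1:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.interface_column_count >= self.alignment_length:
            raise ValueError("interface_column_count must be < alignment_length")
        for count in (self.n_families, self.domains_per_family,
                      self.interface_column_count, self.n_titration_points):
            if count <= 0:
                raise ValueError("counts must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FamilyCohort:
    alignment_records: list[tuple[str, str]]
    true_families: dict[str, int]
    interface_columns: tuple[int, ...]  # 1-based
    background_clades: dict[str, int]


def simulate_sh3_families(cfg: GeneratorConfig) -> FamilyCohort:
    """Aligned cohort where family identity lives only at interface columns.

    Interface columns carry a family signature, copied with per-position
    fidelity ``interface_conservation``.  Background columns carry a *clade*
    signature — clades assigned round-robin, orthogonally to families —
    mutated per domain at rate ``background_divergence``.  A full-sequence
    tree therefore clusters by clade, an interface tree by family.
    """
    rng = cfg.rng()
    ncol = cfg.alignment_length
    interface = np.sort(
        rng.choice(ncol, size=cfg.interface_column_count, replace=False)
    )
    background = np.setdiff1d(np.arange(ncol), interface)
    aa = np.array(list(AA))

    n_clades = cfg.n_families
    fam_sig = {
        f: rng.choice(aa, size=cfg.interface_column_count)
        for f in range(1, cfg.n_families + 1)
    }
    clade_sig = {c: rng.choice(aa, size=background.size) for c in range(n_clades)}

    records, families, clades = [], {}, {}
    idx = 0
    for fam in range(1, cfg.n_families + 1):
        for _ in range(cfg.domains_per_family):
            clade = idx % n_clades  # round-robin: orthogonal to family blocks
            row = np.empty(ncol, dtype="<U1")
            keep = rng.random(cfg.interface_column_count) < cfg.interface_conservation
            row[interface] = np.where(
                keep, fam_sig[fam], rng.choice(aa, size=cfg.interface_column_count)
            )
            mutate = rng.random(background.size) < cfg.background_divergence
            row[background] = np.where(
                mutate, rng.choice(aa, size=background.size), clade_sig[clade]
            )
            rid = f"SH3_{idx + 1:03d}"
            records.append((rid, "".join(row)))
            families[rid] = fam
            clades[rid] = clade
            idx += 1
    return FamilyCohort(
        alignment_records=records,
        true_families=families,
        interface_columns=tuple(int(c) + 1 for c in interface),
        background_clades=clades,
    )


@dataclass
class SyntheticComplex:
    pdb_text: str
    domain_chain: str
    peptide_chain: str
    contact_positions: tuple[int, ...]  # author residue numbers designed < cutoff
    noncontact_positions: tuple[int, ...]


def simulate_complex(
    cfg: GeneratorConfig,
    n_domain_residues: int = 20,
    n_contacts: int = 5,
    n_peptide_residues: int = 4,
    cutoff: float = 4.0,
    margin: float = 0.2,
    contact_positions: list[int] | None = None,
) -> SyntheticComplex:
    """Two-chain coordinates with a designed contact set.

    Peptide CA atoms lie along the x axis; each domain residue is placed on a
    ray from its nearest peptide atom so its closest atom sits either below
    ``cutoff − margin`` (contacts) or above ``cutoff + margin`` (the rest).
    Contact residues are drawn at random unless ``contact_positions`` (author
    residue numbers, 1-based) pins them explicitly.
    """
    if margin <= 0 or cutoff <= margin:
        raise ValueError("infeasible geometry: need 0 < margin < cutoff")
    rng = cfg.rng()
    pep_xyz = np.column_stack(
        [np.arange(n_peptide_residues) * 3.8, np.zeros(n_peptide_residues), np.zeros(n_peptide_residues)]
    )
    if contact_positions is not None:
        contact_ids = sorted(set(int(p) for p in contact_positions))
        if contact_ids and not (
            1 <= contact_ids[0] and contact_ids[-1] <= n_domain_residues
        ):
            raise ValueError("contact_positions outside [1, n_domain_residues]")
    else:
        if n_contacts > n_domain_residues:
            raise ValueError("cannot request more contacts than domain residues")
        contact_ids = sorted(
            int(i) + 1 for i in rng.choice(n_domain_residues, size=n_contacts, replace=False)
        )
    builder = StructureBuilder()
    builder.init_structure("synthetic_complex")
    builder.init_model(0)
    builder.init_seg("    ")
    builder.init_chain("B")
    for i, xyz in enumerate(pep_xyz, start=1):
        builder.init_residue("PRO", " ", i, " ")
        builder.init_atom("CA", xyz.astype(np.float32), 1.0, 1.0, " ", " CA ", None, "C")
    builder.init_chain("A")
    for i in range(1, n_domain_residues + 1):
        anchor = pep_xyz[rng.integers(0, n_peptide_residues)]
        if i in contact_ids:
            dist = float(rng.uniform(cutoff - margin - 1.0, cutoff - margin))
        else:
            dist = float(rng.uniform(cutoff + margin, cutoff + margin + 6.0))
        # random direction away from the peptide axis (positive y half-space
        # keeps the residue's nearest peptide atom the intended anchor)
        theta = rng.uniform(0.2, np.pi - 0.2)
        direction = np.array([0.0, np.sin(theta), np.cos(theta)])
        pos = anchor + dist * direction
        builder.init_residue("ALA", " ", i, " ")
        builder.init_atom("CA", pos.astype(np.float32), 1.0, 1.0, " ", " CA ", None, "C")
        # a second atom strictly farther from every peptide atom
        far = pos + dist * direction
        builder.init_atom("CB", far.astype(np.float32), 1.0, 1.0, " ", " CB ", None, "C")
    structure = builder.get_structure()

    import io as _io

    out = _io.StringIO()
    pdbio = PDBIO()
    pdbio.set_structure(structure)
    pdbio.save(out)
    noncontacts = tuple(i for i in range(1, n_domain_residues + 1) if i not in contact_ids)
    return SyntheticComplex(
        pdb_text=out.getvalue(),
        domain_chain="A",
        peptide_chain="B",
        contact_positions=tuple(contact_ids),
        noncontact_positions=noncontacts,
    )


@dataclass
class SyntheticPRD:
    sequence: str
    planted: dict[str, tuple[int, int]]  # class_id -> (start, end), 1-based
    incidental_classes: tuple[str, ...] = ()


def _instance_of(pattern, rng: np.random.Generator) -> str:
    """A concrete realization of a pattern; X positions use linker letters."""
    letters = []
    for el in pattern.elements:
        if len(el) == 20:
            letters.append(rng.choice(list(LINKER_AA)))
        else:
            letters.append(rng.choice(sorted(el)))
    return "".join(str(c) for c in letters)


def simulate_prd(
    cfg: GeneratorConfig,
    classes_to_plant: list[str],
    registry: MotifRegistry | None = None,
    linker_length: int = 6,
    max_attempts: int = 50,
) -> SyntheticPRD:
    """Plant one occurrence of each requested class, separated by linkers.

    Linkers use an alphabet free of P/K/R so they cannot complete any registry
    class.  The assembly is re-drawn until no *unplanted* class occurs; if the
    requested combination cannot avoid incidental classes (some classes
    necessarily contain others), the incidental classes are reported.
    """
    if registry is None:
        registry = default_registry()
    for cid in classes_to_plant:
        if cid not in registry:
            raise KeyError(f"unknown motif class {cid!r}")
    rng = cfg.rng()
    best: SyntheticPRD | None = None
    for _ in range(max_attempts):
        parts, planted, pos = [], {}, 0

        def add_linker() -> None:
            nonlocal pos
            link = "".join(rng.choice(list(LINKER_AA), size=linker_length))
            parts.append(link)
            pos += linker_length

        add_linker()
        for cid in classes_to_plant:
            inst = _instance_of(registry[cid], rng)
            planted[cid] = (pos + 1, pos + len(inst))
            parts.append(inst)
            pos += len(inst)
            add_linker()
        seq = "".join(parts)
        found = {m.class_id for m in scan_sequence(seq, registry)}
        incidental = tuple(sorted(found - set(classes_to_plant)))
        candidate = SyntheticPRD(sequence=seq, planted=planted, incidental_classes=incidental)
        if not incidental:
            return candidate
        if best is None or len(incidental) < len(best.incidental_classes):
            best = candidate
    return best  # documented fallback: incidental classes reported


def simulate_titration(
    kd: float,
    probe: float = DEFAULT_PROBE_UM,
    noise_frac: float = 0.02,
    n_points: int = 30,
    seed: int = 0,
    s0: float = 50.0,
    smax: float = 250.0,
    max_conc: float = TITRATION_MAX_UM,
    sh3_id: str = "sh3",
    peptide_id: str = "peptide",
) -> TitrationCurve:
    """An FP titration from the quadratic model: P = 0 plus a log-spaced grid.

    ``n_points`` is the total point count; noise is Gaussian with standard
    deviation ``noise_frac × (smax − s0)``, signal-independent.
    """
    if not kd > 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    if n_points < 5:
        raise ValueError("need >= 5 points")
    rng = np.random.default_rng(seed)
    conc = np.concatenate(
        [[0.0], np.geomspace(0.01, max_conc, n_points - 1)]
    )
    signal = quadratic_binding_signal(conc, probe, kd, s0, smax)
    if noise_frac > 0:
        signal = signal + rng.normal(0.0, noise_frac * (smax - s0), size=conc.size)
    return TitrationCurve(
        protein_conc=conc, signal=np.asarray(signal), probe_conc=probe,
        sh3_id=sh3_id, peptide_id=peptide_id,
    )


@dataclass
class SyntheticScreen:
    intensities: pd.DataFrame  # sh3_id, peptide_id, intensity
    curves: list[TitrationCurve] = field(repr=False)
    true_kd: dict[tuple[str, str], float] = field(default_factory=dict)


def known_affinities() -> pd.DataFrame:
    """Packaged ground-truth dissociation constants for reference pairs (µM)."""
    with resources.as_file(
        resources.files("sh3prm.data") / "known_affinities.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t")


def simulate_screen(cfg: GeneratorConfig) -> SyntheticScreen:
    """The 25 × 12 dot-blot/titration screen with planted binders.

    Binder Kd values are log-uniform over [0.2, 125] µM (the observed affinity
    range); the packaged reference pairs keep their known affinities when
    their ids fit in the grid.  Dot intensity decreases with log Kd from near
    100 (tightest) toward ~10 (weakest); non-binders read 0.
    """
    rng = cfg.rng()
    sh3_ids = [f"SH3_{i + 1:02d}" for i in range(cfg.n_screen_sh3)]
    pep_ids = [f"P{i + 1}" for i in range(cfg.n_screen_peptides - 2)] + ["RP1", "RP2"]
    n_cells = len(sh3_ids) * len(pep_ids)
    if cfg.planted_binder_count > n_cells:
        raise ValueError("more binders requested than screen cells")
    all_pairs = [(s, p) for s in sh3_ids for p in pep_ids]
    binder_idx = rng.choice(n_cells, size=cfg.planted_binder_count, replace=False)
    kd_lo, kd_hi = 0.2, 125.0
    true_kd, rows, curves = {}, [], []
    binder_pairs = {all_pairs[i] for i in binder_idx}
    for pair in all_pairs:
        if pair in binder_pairs:
            kd = float(np.exp(rng.uniform(np.log(kd_lo), np.log(kd_hi))))
            true_kd[pair] = kd
            # intensity anchored to affinity: ~95 at 0.2 µM down to ~15 at 125 µM
            intensity = float(
                np.clip(95 - 80 * (np.log(kd) - np.log(kd_lo)) / (np.log(kd_hi) - np.log(kd_lo))
                        + rng.normal(0, 3), 1, 100)
            )
            curves.append(
                simulate_titration(
                    kd,
                    noise_frac=cfg.titration_noise_frac,
                    n_points=cfg.n_titration_points,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    sh3_id=pair[0],
                    peptide_id=pair[1],
                )
            )
        else:
            intensity = 0.0
        rows.append({"sh3_id": pair[0], "peptide_id": pair[1], "intensity": intensity})
    return SyntheticScreen(
        intensities=pd.DataFrame(rows), curves=curves, true_kd=true_kd
    )
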