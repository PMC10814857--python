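"""End-to-end pipeline driver: contacts → interface tree → families → motifs
→ prediction → affinity fits → summary report.

The default run executes the whole workflow on a synthetic cohort with known
ground truth (see :mod:`sh3prm.synthetic`); pointing the config at user files
replaces individual synthetic stages.  Every run writes each stage's output in
its standard format into the run directory, together with the serialized
configuration and a JSON summary.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import binding, contacts, interface_msa, motifs, phylo, specificity, synthetic


@dataclass
class PipelineConfig:
    out_dir: str = "sh3prm_run"
    seed: int = 1
    contact_cutoff: float = 4.0
    family_count: int = 10
    registry_path: str | None = None  # default packaged consensus registry
    alignment_path: str | None = None  # default: synthetic cohort
    alignment_format: str = "fasta"
    prd_classes: int = 13  # consensus classes planted in the synthetic PRD
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = synthetic.GeneratorConfig(**self.generator)
        if self.contact_cutoff <= 0:
            raise ValueError("contact cutoff must be positive")
        if self.family_count < 1:
            raise ValueError("family count must be >= 1")
        self.generator.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    registry = (
        motifs.MotifRegistry.from_tsv(cfg.registry_path)
        if cfg.registry_path
        else motifs.default_registry()
    )
    if len(registry) == 0:
        raise ValueError("motif registry is empty")
    summary: dict = {"seed": cfg.seed, "config_digest": cfg.digest(), "stages": []}

    def stage(name: str):
        summary["stages"].append(name)
        return name

    # --- stage: cohort alignment -------------------------------------------
    stage("cohort")
    cohort = synthetic.simulate_sh3_families(cfg.generator)
    aln = interface_msa.Alignment(cohort.alignment_records)
    if cfg.alignment_path:
        aln = interface_msa.Alignment.read(cfg.alignment_path, cfg.alignment_format)
    aln.write(out / "alignment.fasta")

    # --- stage: contacts ----------------------------------------------------
    stage("contacts")
    reps = {}
    for rid, fam in cohort.true_families.items():
        reps.setdefault(fam, rid)  # first domain of each family holds a complex
    contact_maps, contact_frames = [], []
    for fam, rid in sorted(reps.items()):
        cplx = synthetic.simulate_complex(
            synthetic.GeneratorConfig(seed=cfg.seed + fam),
            n_domain_residues=cfg.generator.alignment_length,
            contact_positions=list(cohort.interface_columns),
            cutoff=cfg.contact_cutoff,
        )
        (out / f"complex_family{fam}.pdb").write_text(cplx.pdb_text)
        struct = contacts.read_structure(
            out / f"complex_family{fam}.pdb",
            domain_chain=cplx.domain_chain,
            peptide_chain=cplx.peptide_chain,
            structure_id=f"family{fam}",
        )
        cset = contacts.find_contact_residues(
            struct, contacts.ContactConfig(cutoff=cfg.contact_cutoff)
        )
        contact_frames.append(cset.to_frame())
        contact_maps.append((rid, cset.positions))
    pd.concat(contact_frames).to_csv(out / "contacts.tsv", sep="\t", index=False)

    # --- stage: interface projection ---------------------------------------
    stage("projection")
    cols = interface_msa.derive_interface_columns(aln, contact_maps)
    cols.write(out / "interface_columns.txt")
    iface_aln = interface_msa.extract_interface_alignment(aln, cols)
    iface_aln.write(out / "interface_alignment.fasta")

    # --- stage: trees and families -----------------------------------------
    stage("trees")
    dm_full = phylo.alignment_distance_matrix(aln)
    dm_iface = phylo.alignment_distance_matrix(iface_aln)
    phylo.write_phylip(dm_iface, out / "interface_distances.phy")
    tree_full = phylo.neighbor_joining(dm_full)
    tree_iface = phylo.neighbor_joining(dm_iface)
    phylo.write_newick(tree_full, out / "tree_full.nwk")
    phylo.write_newick(tree_iface, out / "tree_interface.nwk")
    fam_full = phylo.cut_into_families(tree_full, cfg.family_count)
    fam_iface = phylo.cut_into_families(tree_iface, cfg.family_count)
    pd.DataFrame(
        {
            "domain": list(fam_iface),
            "family_interface_tree": [fam_iface[d] for d in fam_iface],
            "family_full_tree": [fam_full[d] for d in fam_iface],
            "family_true": [cohort.true_families[d] for d in fam_iface],
        }
    ).to_csv(out / "families.tsv", sep="\t", index=False)
    ids = sorted(cohort.true_families)
    truth = [cohort.true_families[d] for d in ids]
    ari_iface = float(adjusted_rand_score(truth, [fam_iface[d] for d in ids]))
    ari_full = float(adjusted_rand_score(truth, [fam_full[d] for d in ids]))

    # --- stage: motif scan --------------------------------------------------
    stage("motifs")
    to_plant = registry.class_ids[: cfg.prd_classes]
    prd = synthetic.simulate_prd(cfg.generator, to_plant, registry=registry)
    annotation = motifs.annotate_prd(prd.sequence, registry, sequence_id="synthetic_PRD")
    annotation.to_csv(out / "prd_annotation.tsv", sep="\t", index=False)
    scan = motifs.scan_sequence(prd.sequence, registry, sequence_id="synthetic_PRD")
    motifs.matches_to_frame(scan).to_csv(out / "prd_matches.tsv", sep="\t", index=False)

    # --- stage: prediction --------------------------------------------------
    stage("prediction")
    screen = synthetic.simulate_screen(cfg.generator)
    fam_registry = specificity.family_registry()
    specs = specificity.load_family_specificities(registry=fam_registry)
    pep_rng = synthetic.GeneratorConfig(seed=cfg.seed + 10_001)
    peptide_ids = list(dict.fromkeys(screen.intensities["peptide_id"]))
    consensus_ids = registry.class_ids
    peptides = {
        pid: synthetic.simulate_prd(
            synthetic.GeneratorConfig(seed=pep_rng.seed + i),
            [consensus_ids[i % len(consensus_ids)]],
            registry=registry,
            linker_length=3,
        ).sequence
        for i, pid in enumerate(peptide_ids)
    }
    sh3_ids = list(dict.fromkeys(screen.intensities["sh3_id"]))
    assignments = {sid: (i % cfg.family_count) + 1 for i, sid in enumerate(sh3_ids)}
    prediction = specificity.predict_interactions(
        assignments, peptides, registry=fam_registry, specs=specs
    )
    prediction.cells.to_csv(out / "predictions.tsv", sep="\t", index=False)

    # --- stage: affinity fits ----------------------------------------------
    stage("affinity")
    fits = [binding.fit_kd(curve) for curve in screen.curves]
    fits_frame = pd.DataFrame(
        [
            {
                "sh3_id": f.sh3_id,
                "peptide_id": f.peptide_id,
                "kd_uM": f.kd,
                "s0": f.s0,
                "smax": f.smax,
                "rss": f.rss,
                "affinity_class": f.affinity_class,
            }
            for f in fits
        ]
    )
    fits_frame.to_csv(out / "fits.tsv", sep="\t", index=False)
    matrix = binding.build_interaction_matrix(screen.intensities, fits)
    matrix.cells.to_csv(out / "interaction_matrix.tsv", sep="\t", index=False)

    # --- report -------------------------------------------------------------
    stage("report")
    summary.update(
        {
            "n_domains": len(aln.ids),
            "n_interface_columns": len(cols),
            "family_count": cfg.family_count,
            "ari_interface_tree": ari_iface,
            "ari_full_tree": ari_full,
            "prd_classes_planted": len(to_plant),
            "prd_classes_detected": int(annotation["present"].sum()),
            "n_combinations": matrix.n_combinations,
            "n_binders": matrix.n_binders,
            "affinity_tally": {k: int(v) for k, v in matrix.affinity_tally().items()},
            "n_compatible_predictions": int(prediction.cells["compatible"].sum()),
        }
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
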