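# sh3prm

Analysis toolkit for **SH3 domain–proline-rich-motif (PRM) specificity**: how
the ~60-residue SH3 interaction modules of human signalling proteins choose
among the short proline-rich peptides (PRPs) they bind.

SH3 domains share a conserved β-barrel fold yet diverge widely in ligand
preference, so a phylogeny of full domain sequences groups them by overall
homology, not by what they bind.  The central idea implemented here is to
restrict the phylogeny to the **binding interface**: residues within 4.0 Å of
the bound peptide in domain–peptide complex structures are projected onto the
multiple sequence alignment, the alignment is sliced to those columns, and a
neighbor-joining tree over the sliced alignment partitions domains into
specificity families that align with their PRM preferences.  Around that core
the package provides:

- **motifs** — the 14 PRM consensus classes in the standard grammar
  (`P` fixed proline, `X` any residue, `[KR]`/`(K/R)` alternations, e.g.
  `PXXP`, `PXXPX[KR]`), compiled into scanners that report all overlapping
  occurrences, plus per-class annotation of proline-rich domains (PRDs).
- **contacts** — contact-residue extraction from PDB complexes: residue *r*
  of the domain chain is a contact iff
  `min over atoms (a ∈ r, b ∈ peptide) ‖a − b‖ ≤ 4.0 Å` (heavy atoms).
- **interface_msa** — residue↔column projection, interface sub-alignments,
  and interface-residue mutation sets (e.g. the Set-1 swap
  N205D/D206T/D226Q/P227D).
- **phylo** — p-distances, neighbor joining (exact on additive matrices),
  and the deterministic cut of a tree into *k* families.
- **binding** — dissociation constants from fluorescence-polarization (FP)
  titrations via the exact two-state ("quadratic") binding equation

  ```
  B(P) = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·L)
  S(P) = S0 + (Smax − S0)·B(P)
  ```

  with probe concentration L = 0.2 µM and protein P titrated 0–200 µM;
  affinity classes high (≤1 µM), intermediate (≤5), low (≤25), very low
  (≤125); five dot-blot intensity groups; and the domains × peptides
  interaction matrix.
- **specificity** — the 10-family → motif-class map and qualitative
  compatibility prediction (a domain is compatible with a peptide iff the
  peptide matches ≥1 class of the domain's family).
- **synthetic** — seeded generators for every input with known ground truth:
  family cohorts, complex coordinates, PRDs with planted motifs, titrations,
  and the 25 × 12 screen with 45 binders.

## Worked example

```bash
python examples/04_fit_affinities.py
```

prints (abridged):

```
ARHGAP12        / P7   true Kd    0.2 µM  fitted   0.2000 µM  class high
NCK1-3          / P9   true Kd    0.9 µM  fitted   0.9000 µM  class high
NCK1-2          / RP2  true Kd    1.0 µM  fitted   1.0000 µM  class high
ARHGAP12_Set1   / P7   true Kd   23.0 µM  fitted  23.0000 µM  class low
NCK1_Set1       / P9   true Kd   14.0 µM  fitted  14.0000 µM  class low

ARHGAP12 Set-1 affinity loss for P7: 115.0-fold
NCK1 Set-1 affinity loss for P9:     15.6-fold
```

Noise-free titrations generated from the quadratic model at the packaged
reference affinities refit to the generating Kd; the Set-1 interface-residue
swaps weaken ARHGAP12/P7 binding 115-fold and NCK1-3/P9 binding 15.6-fold —
the interface residues, not the conserved scaffold, set affinity.

The other examples cover motif scanning (`01`), contact extraction (`02`),
the interface-vs-full phylogeny contrast (`03`, ARI 1.0 vs −0.089 on the
default cohort), and the end-to-end pipeline (`05`: 300 combinations, 45
binders, 10 families).  The same workflow is available as a thin CLI:

```bash
sh3prm run --seed 1 --out-dir run1
sh3prm scan --fasta peptides.fasta
sh3prm contacts --pdb complex.pdb --domain-chain A --peptide-chain B
```

## Layout

```
src/sh3prm/        library modules (motifs, contacts, interface_msa, phylo,
                   binding, specificity, synthetic, pipeline, cli)
src/sh3prm/data/   packaged tables: 14-class consensus registry, 10-family
                   specificity map, reference affinities
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, parameters, design choices, limitations
```
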