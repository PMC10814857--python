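# Methods

## The problem

SH3 domains bind short proline-rich motifs (PRMs) with moderate, low-micromolar
affinity.  Because the β-barrel scaffold is strongly conserved, overall
sequence similarity between two SH3 domains says little about whether they
prefer the same ligands; the discriminating information sits in the small set
of residues that actually touch the peptide.  The package operationalizes
this as a pipeline: extract peptide-contacting residues from complex
structures, project them onto the domain alignment, build a phylogeny from
the interface columns only, cut it into specificity families, and connect the
families to the motif classes their ligands carry.  Affinities of individual
domain–peptide pairs come from fluorescence-polarization (FP) titrations.

## Motif grammar and registry

A consensus class is an ordered list of position constraints: a fixed residue,
`X` (any of the 20 standard residues), or an alternation written `[KR]` or
`(K/R)` interchangeably.  Patterns must be at least 3 positions long,
constrain only standard residues, and contain at least one fixed proline.
Non-standard letters in subject sequences (B, Z, ...) match nothing, `X`
included.  Scanning tests every window of every class and reports all
overlapping and nested occurrences, because the quantity of interest is
motif co-occurrence within a proline-rich domain (PRD), not a non-overlapping
tiling.

The packaged consensus registry holds 14 classes: the 13 co-occurring in the
model PRD (PPPP, XPPX, PXP, PXPXP, PPXPP, PXXP, PXXPX[KR], [KR]XXPXXP,
PXXPXXP, PXXXP, PXXXPXXXP, PXXXPR, PXXXXP) plus PX[PA]XXR from the family-10
specificity list.  The choice of the 14th class is a packaging decision: no
single published list enumerates all fourteen in one place.

The family specificity map references additional literal patterns (PXXDY,
PPPXLP, ...) that are not consensus classes.  Two registries therefore ship:
the 14-class consensus registry (default for scanning/annotation) and an
extended *family registry* — consensus classes plus every family-specific
pattern — used for specificity loading and compatibility prediction.

## Contact extraction

A domain residue is a contact residue when the minimum Euclidean distance
between its atoms and any peptide-chain atom is ≤ the cutoff (default 4.0 Å,
inclusive at the boundary).  Heavy atoms only by default, since hydrogens are
rarely resolved in crystal structures; a flag includes all atoms.  Waters and
heteroatoms are excluded from both chains; alternate locations keep the
highest-occupancy conformer; author residue numbering and insertion codes are
preserved.  The peptide chain is designated by the caller — there is no
automatic peptide detection, mirroring manually curated complex sets.
Distances are double precision; the implementation vectorizes the all-pairs
computation and is checked against a pure-Python brute-force oracle in the
tests.

## Interface projection and mutation sets

Contact residues (1-based ungapped positions) map to alignment columns via
gap-aware counting; the interface column set is the union over all
contributing structures.  Slicing an alignment to interface columns keeps
per-record gaps, so the sub-alignment stays rectangular.  Mutation sets use
the conventional `N205D` labels in full-protein numbering with an explicit
per-domain offset; applying a set validates the wild-type letter at every
position, and applying the inverse set restores the original sequence.

The package consumes existing alignments (FASTA or Clustal).  It does not
bundle an aligner: the synthetic cohorts are generated pre-aligned, and for
real data any standard multiple aligner (e.g. MAFFT) produces the input.

## Phylogeny and family cut

Distances are p-distances — mismatch fraction over columns where neither
record gaps; a pair with zero comparable sites is an error rather than a
silent zero.  Trees are neighbor joining (via scikit-bio), which is exact on
additive matrices; negative branch lengths are clamped to zero with a
warning.  p-distance + NJ is deliberately simple: interface alignments are
very short (~10–20 columns), where substitution-model fitting is fragile.

`cut_into_families(tree, k)` removes k−1 branches to yield k leaf groups.
Branches are ranked internal-first, by length descending, with ties broken by
the lexicographically smallest leaf below the branch, so the cut is
deterministic; a cut that would strand a leaf-free fragment is skipped.
Terminal branches are only cut when k approaches the leaf count (singleton
families).  k defaults to 10 — the family count supported by structural and
biochemical evidence — and is a parameter, not automatically selected,
because family delimitation on real data also used biochemical evidence.

## Quadratic binding model and Kd fitting

With probe (labelled peptide) at concentration L comparable to Kd, free and
total protein concentrations differ materially, so the bound fraction is the
exact two-state solution

    B(P) = ((P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L)) / (2·L),
    S(P) = S0 + (Smax − S0)·B(P).

Defaults follow the reference protocol: L = 0.2 µM, P titrated 0–200 µM.
Fitting is bounded nonlinear least squares over (Kd, S0, Smax) — both
asymptotes float — initialized at the concentration of half-maximal signal
change and the curve endpoints, with tolerances of 1e-15 so noise-free curves
refit to better than 1e-4 relative error.  Noise is estimated model-free as
`std(diff(signal))/√2`; a curve whose endpoint-averaged signal change (mean
of the 3 highest-concentration points minus mean of the 3 lowest) is below
3× that noise is reported as "no binding" with no Kd.  The endpoint-averaged
change, rather than the raw signal range, keeps pure noise from being read
as amplitude.

Affinity classes partition (0, 125] µM using half-open intervals at the
printed lower edges, closing the gaps between the published bins
(0.1–1.0 / 1.1–5 / 5.1–25 / 26–125): high (0, 1], intermediate (1, 5],
low (5, 25], very_low (25, 125]; Kd > 125 µM is flagged out-of-range.
Dot-blot intensities (0–100) fall into five ordinal groups; only "exactly 0"
(group 1) and "> 80" (group 5) are externally anchored, so the interior
edges 20/50 are this package's convention.

## Specificity map and prediction

Each family lists its recognized motif classes; family 6 carries an
`inferred` flag because its consensus (RXXPXXP) rests on ligand homology
rather than direct structural or biochemical data.  Prediction is
deliberately qualitative: a domain is compatible with a peptide iff the
peptide contains ≥ 1 match to ≥ 1 class of the domain's family, with the
supporting matches as evidence.  The ≥1-match rule is this package's
operationalization of "potential interaction"; affinity is never predicted
from motifs.  Family overlap is reported two ways: literal shared classes,
and subsumption (every instance of one class necessarily contains a match of
another, decided by exhaustive enumeration over the narrow pattern's
realizations — feasible because patterns are ≤ 9 positions and, for `X`
positions, only residues the broad pattern constrains can matter).

## Synthetic data: what it emulates, and what it does not

All generators run from one seeded `numpy.random.Generator`; identical seeds
give identical outputs.

**Family cohorts.** 10 families × 5 domains, 60 alignment columns, 14
interface columns.  Interface columns carry a family signature copied with
per-position fidelity 0.95; background columns carry a *clade* signature —
clades assigned round-robin, orthogonal to families — with 20% per-domain
divergence.  The orthogonal clade structure models the real confound: overall
sequence history crosscuts binding specificity.  Consequently family recovery
from the interface alignment is perfect (ARI 1.0) while the full-sequence
tree recovers clades, not families (ARI ≈ 0).  The generator makes no claim
to evolutionary realism (no substitution model, no indels by default); it
reproduces the statistical structure the contrast depends on, so passing
tests demonstrate the pipeline's behaviour on that structure, not performance
on real proteomes.

**Complexes.** Peptide CA atoms along the x-axis at 3.8 Å spacing; each
domain residue is placed on a ray from its nearest peptide atom at a
controlled distance — contacts within [cutoff − 1.2, cutoff − 0.2] Å, the
rest at least 0.2 Å beyond the cutoff — so the designed contact set is
unambiguous at the default margin.

**PRDs.** One instance per requested class, separated by linkers over the
alphabet {G, S, T, Q}, which avoids every residue the registry fixes or
alternates over (P, K, R, A), so linkers cannot complete accidental motifs;
`X` positions in planted instances are filled from the same alphabet.
Assemblies are re-drawn until no unplanted class occurs; if a combination
cannot avoid incidental classes, they are reported rather than hidden.

**Titrations and screen.** Curves are P = 0 plus a log-spaced grid up to
200 µM (a dilution-series design); noise is Gaussian with σ =
noise_frac × (Smax − S0), signal-independent — an assumption, adequate for FP
over this dynamic range.  Defaults: 30 points, 2% noise, S0 = 50, Smax = 250
(typical polarization units).  The screen is 25 domains × 12 peptides
(P1–P10 plus two reference peptides) with 45 planted binders, Kd log-uniform
over the observed 0.2–125 µM range, and dot intensities decreasing with
log Kd (non-binders read 0).

## Numerical choices and degenerate inputs

- Contact ties at exactly the cutoff are included (≤, not <).
- NJ requires ≥ 3 taxa; all-equal distance matrices are resolved by
  scikit-bio's deterministic join order, stable across runs.
- `fold_change` is a plain ratio; display convention is one decimal.
- Empty sequences, empty registries, empty column sets, flat titrations,
  ragged alignments and wild-type mismatches all raise typed errors rather
  than returning sentinel values.

## Known limitations

- No mmCIF input; no structure superposition or homology modelling.
- No bootstrap support, maximum-likelihood or Bayesian trees.
- Prediction ignores non-canonical, proline-independent SH3 binding and
  multivalent/contextual effects; such pairs simply report "no motif
  support".
- No anisotropy↔polarization conversion or instrument I/O; one curve is fit
  at a time (no global multi-curve fits).
- The packaged family map stores the published per-family motif lists
  verbatim; whether those lists are exhaustive is not decidable from the
  source material.
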