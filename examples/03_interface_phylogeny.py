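"""The interface-restricted tree recovers specificity families; the full tree does not.

A synthetic cohort of 50 domains in 10 families encodes family identity only
at 14 binding-interface columns, while the other 46 columns follow an
orthogonal clade structure (overall sequence history).  Neighbor-joining
trees are built from both alignments and cut into 10 families; agreement with
the planted families is scored by the adjusted Rand index (ARI).
"""

from sklearn.metrics import adjusted_rand_score

from sh3prm import Alignment, GeneratorConfig, InterfaceColumns, extract_interface_alignment
from sh3prm.phylo import alignment_distance_matrix, cut_into_families, neighbor_joining
from sh3prm.synthetic import simulate_sh3_families

cohort = simulate_sh3_families(GeneratorConfig(seed=1))
aln = Alignment(cohort.alignment_records)
iface = extract_interface_alignment(aln, InterfaceColumns(cohort.interface_columns))
ids = sorted(cohort.true_families)
truth = [cohort.true_families[i] for i in ids]

for label, a in [("full-domain alignment", aln), ("interface alignment", iface)]:
    tree = neighbor_joining(alignment_distance_matrix(a))
    part = cut_into_families(tree, 10)
    ari = adjusted_rand_score(truth, [part[i] for i in ids])
    print(f"{label:<24s} ({a.n_columns:>2d} columns)  family-recovery ARI = {ari:.3f}")

print("\nARI 1.0 means the 10 cut families equal the planted specificity")
print("families exactly; the full-domain tree instead follows overall")
print("sequence similarity, which is uninformative about peptide specificity.")
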