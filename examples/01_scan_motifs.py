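"""Scan a proline-rich peptide for the 14 PRM consensus classes.

The subject here is a basic-anchored proline-rich heptapeptide of the kind
SH3 domains recognize.  Every window of every class is tested, so overlapping
and nested occurrences are all reported.
"""

from sh3prm import annotate_prd, default_registry, scan_sequence

PEPTIDE = "PPVPPRQ"

registry = default_registry()
print(f"registry: {len(registry)} consensus classes\n")

print(f"matches in {PEPTIDE}:")
for m in scan_sequence(PEPTIDE, registry, sequence_id="peptide"):
    print(f"  {m.class_id:<12s} at {m.start}-{m.end}  ({m.matched_text})")

table = annotate_prd(PEPTIDE, registry)
present = table[table["present"]]["class_id"].tolist()
print(f"\nclasses present: {len(present)} of {len(registry)}")
print("Each line is one motif-class occurrence; the start/end positions are")
print("1-based and inclusive. The PXXPX[KR] hit is the canonical core motif")
print("with a C-terminal basic anchor — the signature family-7 ligands carry.")
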