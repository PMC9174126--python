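"""Tryptic digestion and N-glycosylation sequon scanning.

Digests a small in-memory protein with the search settings (up to two
missed cleavages, minimum length seven) and lists every N-X(!=P)-[S/T]
sequon — the only positions where an N-glycan, and hence a core fucose,
can sit.
"""

from fucoquant.proteome import ProteinRecord, find_sequons, tryptic_digest

protein = ProteinRecord(
    "DEMO1",
    "DEMO1 synthetic protein with one sequon",
    "MAAKVCSNDNKTFDSSCHFFATKRGGELVISNPRTTAGK",
)

print(f"protein {protein.id}: {len(protein.sequence)} residues")
print("\nsequons (N-X!=P-[S/T]):")
for hit in find_sequons(protein):
    print(f"  N{hit.position}  motif {hit.motif}")

print("\ntryptic peptides (max 2 missed cleavages, length >= 7):")
for pep in tryptic_digest(protein):
    print(
        f"  {pep.start:>3}-{pep.end:<3} mc={pep.missed_cleavages}  {pep.sequence}"
    )

print("\nVCSNDNKTFDSSCHFFATK spans the sequon N10 with one missed cleavage;")
print("it is the peptide the glycopeptide search will place the remnant on.")
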