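"""Annotated theoretical spectrum of an Endo F3-simplified glycopeptide.

Generates the full ion table of the TMT-labelled core-fucosylated
VCSNDNK remnant glycopeptide at 2+: b/y ladders (starred ions mark loss
of the fucosylated GlcNAc, -349.14 Da), the precursor signature losses
[M-146]/[M-349], the oxonium diagnostics and the TMT6 reporters.
"""

from fucoquant.chem import (
    NTERM,
    GlycanComposition,
    Glycopeptide,
    standard_modifications,
)
from fucoquant.fragments import theoretical_spectrum

mods = standard_modifications(tmt=True)
gp = Glycopeptide(
    "VCSNDNK",
    mods=((NTERM, mods["TMT6-Nterm"]), (2, mods["Carbamidomethyl"]),
          (7, mods["TMT6-K"])),
    glyco_site=6,
    glycan=GlycanComposition({"HexNAc": 1, "dHex": 1}, core_fucosylated=True),
)

spec = theoretical_spectrum(gp, precursor_charge=2)
print(f"precursor [M+2H]2+ = {spec.precursor_mz:.4f}\n")
print(f"{'label':<14}{'series':<16}{'z':<3}{'glycan':<8}{'m/z':>10}")
for ion in spec.ions:
    glycan = "kept" if ion.glycan_retained else ("lost" if ion.neutral_loss else "-")
    print(f"{ion.label:<14}{ion.series:<16}{ion.charge:<3}{glycan:<8}{ion.mz:>10.4f}")

print("\nStarred b/y ions sit exactly 349.1373/z below their glycan-retaining")
print("partners; the retaining ions are what localizes the core-fucosylation")
print("site, while oxonium ions only prove that a glycan is present.")
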