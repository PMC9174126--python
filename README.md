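# fucoquant

Site-specific identification and quantification of **core-fucosylated
glycopeptides** from Endo F3-simplified tandem-MS data, with a synthetic
ground-truth generator that makes every stage of the pipeline testable
without instrument files.

## The problem

Core fucosylation — fucose attached α1,6 to the innermost GlcNAc of an
N-glycan — is installed by a single enzyme, Fut8, and its loss on specific
substrate proteins is implicated in lung pathology. Finding *which* proteins
and *which* asparagines carry Fut8-dependent core fucose requires a
site-specific, quantitative glycoproteomic readout:

1. proteins are digested with trypsin and labelled with TMT6 isobaric tags
   (channels 128/129 = control siRNA replicates, 130/131 = Fut8-knockdown
   replicates);
2. glycopeptides are lectin-enriched and treated with **Endo F3**, which
   trims each N-glycan down to the innermost GlcNAc — plus the core fucose
   when present — so every glycopeptide carries a remnant of composition
   HexNAc(1) or dHex(1)HexNAc(1) (+203.0794 or +349.1373 Da);
3. stepped-collision-energy HCD spectra contain b/y ladders with the remnant
   retained or lost (the "starred" −349.14 ions), precursor signature losses
   [M−146]/[M−349], GlcNAc oxonium diagnostics (204.09 / 168.07 / 138.05)
   and TMT reporter ions;
4. a candidate Fut8 target shows a low siFut8/siCon reporter ratio at a
   *localized* core-fucosylation site **without** a matching drop in its
   transcript — post-translational loss of the modification, not of the
   protein.

`fucoquant` implements this computational pipeline end to end: monoisotopic
mass model and remnant arithmetic, in-silico digestion and sequon scanning,
theoretical fragment generation, a simplified target-decoy search engine
(6 ppm precursor / 20 ppm fragment, q ≤ 0.01), glycan-retaining-ion site
localization, median-normalized TMT reporter quantification, 10 ppm XICs,
and the three-criterion candidate ranking. A first-class synthetic-data
module emulates the study design (two conditions × two replicates, a 0.05
knockdown of core-fucosylated forms) and provides the ground truth that the
test suite checks recovery against.

## Worked example

```python
from fucoquant.chem import (Glycopeptide, GlycanComposition, NTERM,
                            standard_modifications, peptide_monoisotopic_mass, mz)

mods = standard_modifications(tmt=True)
gp = Glycopeptide(
    "VCSNDNK",
    mods=((NTERM, mods["TMT6-Nterm"]), (2, mods["Carbamidomethyl"]),
          (7, mods["TMT6-K"])),
    glyco_site=6,
    glycan=GlycanComposition({"HexNAc": 1, "dHex": 1}, core_fucosylated=True),
)
M = peptide_monoisotopic_mass(gp)   # 1642.8126 Da
print(round(mz(M, 2), 4))           # 822.4136  -> prints as 822.41 at 2 dp
```

The neutral mass is the residue sum plus water, two TMT6 labels
(2 × 229.162932), carbamidomethyl (+57.021464) and the core-fucosylated
remnant (+349.1373); at 2+ this gives the observed precursor m/z 822.41.

Running the full synthetic pipeline (`python examples/04_simulate_search_quantify.py`)
prints:

```
simulated 138 spectra (51 core-fucosylated glycopeptides)
candidate index: 35966 entries (17983 targets)
identified 138 spectra, 138 accepted at q <= 1%

quantified 63 glycosylation sites
  core-fucosylated : median ratio rep1 = 0.048  (simulated 0.05)
  non-fucosylated  : median ratio rep1 = 1.018  (expected ~1)
```

i.e. the search recovers every simulated analyte at 1% FDR and the reporter
quantification returns the simulated knockdown ratio. The other scripts in
`examples/` each demonstrate one capability (mass reconstruction, digestion
and sequon scanning, spectrum annotation, candidate ranking) with a line on
what the printed numbers mean.

A thin CLI wraps the same library calls:

```bash
fucoquant pipeline --out-dir run1 --seed 5        # simulate -> search -> rank
fucoquant digest --fasta proteome.fasta --out digest.tsv
```

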