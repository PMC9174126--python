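# Methods

## Mass model

All arithmetic is monoisotopic. Constants live in a versioned JSON table
(`src/fucoquant/data/masses.json`): the 20 canonical residue masses, water
18.0105646 Da, proton 1.0072765 Da, monosaccharide residue masses
(HexNAc 203.079373, dHex 146.057909, Hex 162.052824, NeuAc 291.095417) and
the modification deltas (TMT6 229.162932, carbamidomethyl 57.021464,
oxidation 15.994915, acetyl 42.010565, deamidation 0.984016). Ambiguity
codes (B, Z, X, U) are rejected with the offending position rather than
guessed. A peptide's neutral mass is the residue sum + water + modification
deltas + glycan composition mass; m/z = (M + z·H⁺)/z.

The Endo F3 model is purely compositional: `endo_f3_simplify` maps any
HexNAc-containing composition to the remnant {HexNAc:1} or
{HexNAc:1, dHex:1} according to its core-fucosylation flag, is idempotent,
and rejects compositions without HexNAc. Glycan topology and linkage are
deliberately out of scope — after Endo F3 the composition fully determines
the mass, which is all the downstream search needs.

TMT is applied per **peptide** N-terminus (plus every lysine). This matches
the labelling chemistry and is the only assignment that reproduces the
822.41 precursor of the doubly charged VCSNDNK remnant glycopeptide
(two labels: N-terminus + K7).

## Digestion and sequon scanning

Trypsin cleaves C-terminal to K/R except before proline; peptides with
0–2 missed cleavages and ≥ 7 residues are emitted with 1-based protein
coordinates. The initiator methionine is *not* clipped by default (a
documented flag enables it). Glycosylation sites are the canonical
N-X(≠P)-[S/T] sequons; no occupancy prediction is attempted — the sequon
scan only proposes candidate positions for the search to test.

## Theoretical spectra

For each glycopeptide the generator emits b₁..b_{n−1} / y₁..y_{n−1} at
charges 1..min(z_precursor, 2); fragments spanning the glycosylation site
appear both glycan-retained and glycan-lost (starred, −349.1373 Da for the
fucosylated remnant). Core-fucosylated precursors additionally yield
[M−146.0579] (fucose loss; GlcNAc retained on the peptide) and [M−349.1373]
at the precursor charge and 1+. Glycopeptides of either remnant yield the
GlcNAc oxonium triplet (204.0866 / 168.0655 / 138.0550), and every TMT
spectrum carries the active reporter set (TMT6 reporters 126.1277–131.1382;
the emulated design uses 128–131). a-ions, internal ions and stacked
neutral losses are not generated; intensities are not modelled (uniform
sticks), since only m/z positions drive the matching.

## Synthetic data generator

The generator emulates the emulated study's conditions rather than generic
data:

* four TMT channels mapped (configurably) as 128→(siCon,1), 129→(siCon,2),
  130→(siFut8,1), 131→(siFut8,2);
* `knockdown_ratio` = 0.05 by default — the midpoint of the strongest
  reported target's replicate ratios (0.04 / 0.07); core-fucosylated sites
  get siFut8 abundances of exactly 0.05 × control, so the expected recovered
  ratio is known;
* a configurable fraction of sequon sites carries a remnant
  (default 0.8 of sites; 0.8 of those core-fucosylated), each riding the
  shortest covering tryptic peptide;
* non-glycosylated "background" peptides (3 per protein by default) are
  included: they emulate incompletely enriched material and anchor the
  reporter normalization;
* optionally, a fraction of proteins is *transcriptionally* suppressed:
  all their peptides drop in the siFut8 channels and their simulated mRNA
  ratio drops to match. These proteins carry only non-fucosylated remnants
  and are the designed false-positive challenge for the ranking stage.

Noise is applied at the spectrum stage: fragment m/z jitter
N(0, 5 ppm) and precursor jitter N(0, 1.5 ppm) by default — the precursor
is measured in MS1 with substantially better accuracy than HCD fragments,
and the 6/20 ppm search windows presuppose that asymmetry — log-normal
intensity noise (reporter CV 0.10, fragment CV 0.30), 20 uniform noise
peaks per spectrum at 5 % relative intensity, and 2 % peak dropout.
No acquisition-noise statistics were available to fit, so these are stated
defaults, chosen once as plausible for an Orbitrap-class instrument.
All randomness flows from integer seeds through `numpy.random.default_rng`;
the MGF writer uses fixed decimal formatting so identical seeds give
byte-identical files.

What the generator does **not** model — isotope envelopes, chromatographic
peak shapes, co-isolation/ratio compression, missed channels, variable
enrichment efficiency — bounds what passing tests show: they validate the
computational pipeline against its own declared spectral model, not
robustness to every artifact of real acquisitions.

## Search, FDR, localization

Candidates are every tryptic peptide × admissible modification combination
(fixed: carbamidomethyl C, TMT6 on N-terminus and K; variable: oxidation M,
deamidation N/Q, acetyl on the protein N-terminal peptide replacing TMT)
× remnant placement on each sequon N (at most one glycan per candidate;
both remnant compositions). Per-peptide variable-mod combinations are
capped at 64. Decoys are generated 1:1 by reversal preserving the
C-terminal residue, with modification positions and glycan sites mirrored
through the reversal so target and decoy mass distributions coincide.

Matching: candidates within 6 ppm of the observed neutral precursor mass
are scored as Σ log(1 + I/I_max) over matched theoretical ions, nearest
peak within 20 ppm, ties to the smallest ppm, each observed peak serving at
most one theoretical ion (greedy by intensity). Reporter ions are excluded
from the score — they are present in every TMT spectrum and carry no
identity information. The score is a deliberate simplification of a
production search engine; the pipeline's validity is established by
synthetic-truth recovery, not score parity.

q-values follow the standard target-decoy estimator: at each score
threshold FDR ≈ (#decoys + 1)/#targets, and a PSM's q-value is the minimum
over thresholds at or below its score (monotone along the ranked list).
A single PSM-level filter at q ≤ 0.01 is applied. Note the estimator's
granularity: with n accepted targets the smallest attainable q is 1/n, so
runs need ≥ 100 spectra for a 1 % cutoff to be meaningful.

A site is called localized only when matched **glycan-retaining** backbone
ions (b_i retaining ⇒ site ≤ i; y_j retaining ⇒ site in the last j
residues) narrow the candidate sequon set to exactly one position, with at
least one starred or non-covering ion in support. Precursor mass alone
never localizes — deamidation (+0.984) on another asparagine could mimic a
mass shift — and oxonium ions prove glycosylation, not position.

## Quantification

Reporter intensities are read within ±0.003 m/z of each channel.
Channels are median-normalized using the **non-glycosylated background
PSMs as the anchor**: in an enrichment experiment where the knockdown
suppresses the entire enriched class, per-channel medians over all spectra
are biased by the suppression itself (observed as a ~1.6× ratio distortion
in development runs on synthetic data); the naked background is the
population whose expectation is actually unchanged. With no naked PSMs the
medians fall back to all quantified spectra. After normalization a global
per-channel scale factor cancels exactly. Site intensities are summed over
PSMs per (protein, site); ratios are formed within replicate pairs
(130/128 and 131/129 under the default map). A missing channel flags the
affected ratio as absent rather than zero.

XICs integrate the summed intensity of MS1 sticks within ±10 ppm of the
target m/z over retention time with the trapezoidal rule.

## Ranking

A protein passes when (i) both replicate ratios ≤ 0.40, (ii) its transcript
ratio lies in [0.77, 1.30], and (iii) it has ≥ 1 site-localized PSM.
The numeric operating points are this package's own: the criteria were
stated qualitatively, so the thresholds were set to cover the published
passing values (largest passing TMT ratio 0.351; transcript ratios
0.88–1.05) with margin, and both are configurable and recorded in the run
metadata. Per-protein ratios take the minimum across sites within each
replicate (most-affected-site aggregation). Passing proteins are ranked
ascending by the *smaller* replicate ratio — the strongest observed
knockdown — which reproduces the published table order (SPARC first); the
pass criterion still requires the *larger* replicate ratio to clear the
threshold, so a single noisy low replicate cannot qualify a protein.
A missing transcript ratio fails criterion (ii) by default (configurable):
absent evidence of transcriptional stability is not treated as evidence.

## Numerical and scale choices

* Printed-value comparisons use ±0.005 m/z, covering 2–3-decimal rounding.
* Test problem sizes (20–55 proteins of 240 residues, ~140–460 spectra per
  run, 20-seed batteries) were chosen as the smallest sizes at which the
  statistical checks are meaningful — ≥ 500 pooled spectra for the FDR
  estimate, ≥ 100 core-fucosylated sites for ratio recovery — while keeping
  the whole suite fast on one CPU.
* Deterministic tie-breaks throughout: candidate ordering by (score,
  |ppm error|, decoy flag, protein id, modification string); ranking ties
  by protein id.

## Known limitations

* The remnant model assumes complete Endo F3 digestion; intact-glycan
  spectra would be unidentified, not misassigned.
* Single PSM-level FDR (no separate peptide/protein/site-level control).
* No retention-time alignment, match-between-runs, protein inference
  beyond peptide→protein, or TMT isotope-impurity correction.
* The scoring function ignores intensity models and co-fragmentation;
  it is adequate for remnant-simplified spectra but is not a general
  glycoproteomics engine.
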