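"""Ground-truth glycoproteome and MS/MS spectrum simulation.

The generator emulates the study design the downstream pipeline was
built for: mouse lung stem cells treated with control (siCon) or Fut8
(siFut8) siRNA, two biological replicates each, labelled with the TMT6
channels 128-131.  A configurable fraction of N-sequon sites carries an
Endo F3-simplified remnant (GlcNAc with or without core fucose); the
Fut8 knockdown suppresses the abundance of core-fucosylated forms to
``knockdown_ratio`` of control (default 0.05, the midpoint of the
strongest reported target's replicate ratios 0.04/0.07) while leaving
transcript levels — and hence non-glycosylated peptide abundance —
unchanged.  A configurable fraction of proteins is instead
*transcriptionally* down-regulated: their peptides drop in the siFut8
channels for reasons the ranking stage must reject, and their simulated
mRNA ratio drops accordingly.

Spectra are monoisotopic stick spectra: theoretical fragment m/z values
with ppm jitter, multiplicative intensity noise, uniform chemical noise
peaks and random peak dropout.  Reporter-region peaks carry the true
per-channel abundances.  No isotope envelopes, chromatographic peak
shapes or co-isolation effects are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    NTERM,
    GlycanComposition,
    Glycopeptide,
    default_mass_table,
    peptide_monoisotopic_mass,
    standard_modifications,
)
from .fragments import theoretical_spectrum
from .proteome import ProteinRecord, find_sequons, tryptic_digest
from .spectra import Ms1Scan, Spectrum, write_mgf

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "GroundTruthEntry",
    "GroundTruth",
    "make_synthetic_proteome",
    "simulate_ground_truth",
    "simulate_spectra",
    "simulate_ms1",
    "DEFAULT_CHANNEL_MAP",
]

#: default TMT6 channel assignment: 128/129 control, 130/131 knockdown
DEFAULT_CHANNEL_MAP: Mapping[int, tuple[str, int]] = {
    128: ("siCon", 1),
    129: ("siCon", 2),
    130: ("siFut8", 1),
    131: ("siFut8", 2),
}


@dataclass(frozen=True)
class StudyDesign:
    """The simulated experimental design.

    ``channel_map`` maps each active TMT channel to a (condition,
    replicate) pair and must contain exactly four channels covering the
    two-condition x two-replicate layout.  ``knockdown_ratio`` is the
    expected siFut8/siCon abundance ratio of core-fucosylated forms.
    """

    channel_map: Mapping[int, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP)
    )
    knockdown_ratio: float = 0.05
    n_proteins: int = 20
    protein_length: int = 240
    sites_per_protein: float = 2.0
    glyco_site_fraction: float = 0.8
    core_fuc_fraction: float = 0.8
    background_peptides_per_protein: int = 3
    transcript_shift_fraction: float = 0.0
    transcript_shift_ratio: float = 0.05
    transcript_jitter_sd: float = 0.05
    base_intensity: float = 1e5
    intensity_log_sd: float = 0.5
    charges: tuple[int, ...] = (2,)
    tmt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_map) != 4:
            raise ValueError("exactly 4 active TMT channels are required")
        conds = {c for c, _ in self.channel_map.values()}
        if conds != {"siCon", "siFut8"}:
            raise ValueError(f"channel conditions must be siCon/siFut8, got {conds}")
        if not 0 < self.knockdown_ratio <= 1:
            raise ValueError("knockdown_ratio must lie in (0, 1]")

    def channel(self, condition: str, replicate: int) -> int:
        for ch, (cond, rep) in self.channel_map.items():
            if cond == condition and rep == replicate:
                return ch
        raise KeyError(f"no channel for ({condition}, {replicate})")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted(self.channel_map))


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise parameters.

    ``mz_jitter_ppm_sd`` perturbs fragment m/z; ``precursor_ppm_sd``
    perturbs the precursor, reflecting the higher MS1 mass accuracy of
    the Orbitrap class of instrument.  ``reporter_cv`` is the
    coefficient of variation of reporter intensities (log-normal).
    """

    mz_jitter_ppm_sd: float = 5.0
    reporter_cv: float = 0.10
    n_noise_peaks: int = 20
    noise_intensity_scale: float = 0.05
    peak_dropout_prob: float = 0.02
    precursor_ppm_sd: float = 1.5
    fragment_cv: float = 0.30

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"noise parameter {name} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        """A silent instrument: exact m/z, exact intensities, no noise."""
        return cls(0.0, 0.0, 0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruthEntry:
    """One simulated analyte with its true per-channel abundances."""

    glycopeptide: Glycopeptide
    channel_abundance: Mapping[int, float]
    site_protein_coord: int | None  # protein coordinate of the glyco N
    transcript_shifted: bool

    @property
    def is_glyco(self) -> bool:
        return self.glycopeptide.glycan is not None

    @property
    def is_core_fuc(self) -> bool:
        g = self.glycopeptide.glycan
        return g is not None and g.core_fucosylated


@dataclass(frozen=True)
class GroundTruth:
    """Simulated glycoproteome state: analytes, abundances, transcripts."""

    entries: tuple[GroundTruthEntry, ...]
    transcript_ratios: Mapping[str, float]
    design: StudyDesign
    seed: int
    decoy_free: bool = True

    @property
    def core_fuc_entries(self) -> tuple[GroundTruthEntry, ...]:
        return tuple(e for e in self.entries if e.is_core_fuc)

    def true_target_proteins(self) -> set[str]:
        """Proteins carrying >=1 core-fucosylated site and stable transcripts."""
        return {
            e.glycopeptide.protein_id
            for e in self.entries
            if e.is_core_fuc and not e.transcript_shifted
        }


_AA = np.array(list("ACDEFGHILMNQSTVWYKRP"))
# K/R enriched enough for tryptic peptides of useful length; P kept rare
_AA_W = np.array(
    [6, 2, 5, 6, 4, 6, 2, 5, 8, 2, 4, 4, 7, 6, 7, 1, 3, 11, 9, 2], dtype=float
)
_AA_W /= _AA_W.sum()


def make_synthetic_proteome(
    n_proteins: int = 20,
    length: int = 240,
    sites_per_protein: float = 2.0,
    seed: int = 0,
    prefix: str = "SYNP",
) -> list[ProteinRecord]:
    """Random proteins with embedded N-X(!=P)-[S/T] sequons.

    Sequences are drawn from a tryptic-friendly residue distribution and
    then a Poisson(``sites_per_protein``) number of sequons is written at
    random interior positions.
    """
    rng = np.random.default_rng(seed)
    records = []
    for p in range(n_proteins):
        seq = rng.choice(_AA, size=length, p=_AA_W)
        n_sites = max(1, int(rng.poisson(sites_per_protein)))
        positions = rng.choice(np.arange(5, length - 5), size=n_sites, replace=False)
        for pos in positions:
            x = rng.choice(np.array(list("ACDEFGHILMQVWYK")))
            st = rng.choice(np.array(list("ST")))
            seq[pos], seq[pos + 1], seq[pos + 2] = "N", x, st
        records.append(
            ProteinRecord(
                id=f"{prefix}{p:03d}",
                description=f"{prefix}{p:03d} synthetic protein",
                sequence="".join(seq),
            )
        )
    return records


def _carrier_peptide(
    peptides: Sequence[Glycopeptide], site: int
) -> Glycopeptide | None:
    """The shortest digest peptide (fewest missed cleavages first) whose
    span covers a protein coordinate."""
    covering = [
        p for p in peptides if p.start is not None and p.start <= site <= p.end
    ]
    if not covering:
        return None
    covering.sort(key=lambda p: (p.missed_cleavages, len(p.sequence), p.start))
    return covering[0]


def _apply_fixed_mods(gp: Glycopeptide, tmt: bool) -> Glycopeptide:
    """Attach the fixed modification set: carbamidomethyl C, and when the
    TMT design is active the TMT6 label on the peptide N-terminus and K."""
    mods = standard_modifications(tmt=tmt)
    out = []
    if tmt:
        out.append((NTERM, mods["TMT6-Nterm"]))
    for i, aa in enumerate(gp.sequence, start=1):
        if aa == "C":
            out.append((i, mods["Carbamidomethyl"]))
        elif aa == "K" and tmt:
            out.append((i, mods["TMT6-K"]))
    return replace(gp, mods=tuple(out))


def simulate_ground_truth(
    design: StudyDesign,
    proteome: Sequence[ProteinRecord],
    seed: int | None = None,
) -> GroundTruth:
    """Assign remnant glycans, abundances and transcript ratios.

    A fraction ``glyco_site_fraction`` of sequon sites receives an Endo
    F3 remnant; of those, ``core_fuc_fraction`` are core-fucosylated.
    Core-fucosylated sites get siFut8 channel abundances suppressed to
    ``knockdown_ratio`` x siCon exactly (noise enters only at the
    spectrum-simulation stage).  Transcript-shifted proteins carry
    non-fucosylated remnants and have *all* their peptides suppressed in
    siFut8 channels, with a matching low transcript ratio — the decoy
    case for the ranking criteria.
    """
    if not proteome:
        raise ValueError("empty proteome")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    n_shifted = int(round(design.transcript_shift_fraction * len(proteome)))
    shifted_ids = set(
        rng.choice(
            np.array([p.id for p in proteome]), size=n_shifted, replace=False
        ).tolist()
        if n_shifted
        else []
    )

    entries: list[GroundTruthEntry] = []
    transcript_ratios: dict[str, float] = {}
    any_sequon = False

    for protein in proteome:
        shifted = protein.id in shifted_ids
        transcript_base = design.transcript_shift_ratio if shifted else 1.0
        transcript_ratios[protein.id] = float(
            transcript_base * math.exp(rng.normal(0.0, design.transcript_jitter_sd))
        )

        peptides = tryptic_digest(protein, max_missed=2, min_len=7)
        sequons = find_sequons(protein)
        any_sequon = any_sequon or bool(sequons)
        glyco_seqs: list[tuple[Glycopeptide, int, GlycanComposition]] = []
        used_carriers: set[tuple[int, int]] = set()
        for hit in sequons:
            if rng.random() >= design.glyco_site_fraction:
                continue
            carrier = _carrier_peptide(peptides, hit.position)
            if carrier is None:
                continue
            key = (carrier.start, hit.position)
            if key in used_carriers:
                continue
            used_carriers.add(key)
            core_fuc = (not shifted) and (rng.random() < design.core_fuc_fraction)
            glycan = (
                GlycanComposition({"HexNAc": 1, "dHex": 1}, core_fucosylated=True)
                if core_fuc
                else GlycanComposition({"HexNAc": 1})
            )
            site_in_pep = hit.position - carrier.start + 1
            gp = carrier.with_glycan(glycan, site_in_pep)
            glyco_seqs.append((gp, hit.position, glycan))

        def _abundances(suppress_core_fuc: bool) -> dict[int, float]:
            base = design.base_intensity * math.exp(
                rng.normal(0.0, design.intensity_log_sd)
            )
            out = {}
            for ch, (cond, _rep) in design.channel_map.items():
                a = base
                if cond == "siFut8":
                    if suppress_core_fuc:
                        a *= design.knockdown_ratio
                    if shifted:
                        a *= design.transcript_shift_ratio
                out[ch] = a
            return out

        for gp, site_coord, glycan in glyco_seqs:
            gp = _apply_fixed_mods(gp, design.tmt)
            entries.append(
                GroundTruthEntry(
                    glycopeptide=gp,
                    channel_abundance=_abundances(glycan.core_fucosylated),
                    site_protein_coord=site_coord,
                    transcript_shifted=shifted,
                )
            )

        # naked background: fully cleaved peptides that touch no sequon
        background = [
            p
            for p in peptides
            if p.missed_cleavages == 0
            and not any(p.start <= h.position <= p.end for h in sequons)
        ]
        k = min(design.background_peptides_per_protein, len(background))
        if k:
            idx = rng.choice(len(background), size=k, replace=False)
            for i in sorted(idx.tolist()):
                gp = _apply_fixed_mods(background[i], design.tmt)
                entries.append(
                    GroundTruthEntry(
                        glycopeptide=gp,
                        channel_abundance=_abundances(False),
                        site_protein_coord=None,
                        transcript_shifted=shifted,
                    )
                )

    if design.glyco_site_fraction > 0 and not any_sequon:
        raise ValueError("proteome contains no N-sequon but glyco fraction > 0")

    return GroundTruth(
        entries=tuple(entries),
        transcript_ratios=transcript_ratios,
        design=design,
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return math.exp(rng.normal(-0.5 * sigma * sigma, sigma))


def simulate_spectra(
    truth: GroundTruth,
    noise: NoiseModel,
    seed: int | None = None,
    mgf_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """One MS/MS spectrum per analyte per charge state.

    Peaks are the theoretical fragment m/z values jittered by
    N(0, ppm_sd), with multiplicative intensity noise, uniform noise
    peaks and random dropout; the reporter region carries the true
    channel abundances.  Returns the spectra and a ground-truth sidecar
    table; optionally writes them as MGF + TSV.  Fully reproducible from
    the seed.
    """
    if not truth.entries:
        raise ValueError("empty ground truth")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    table = default_mass_table()
    design = truth.design

    spectra: list[Spectrum] = []
    rows: list[dict] = []
    counter = 0
    for entry in truth.entries:
        gp = entry.glycopeptide
        mass = peptide_monoisotopic_mass(gp, table)
        for charge in design.charges:
            counter += 1
            sid = f"SYN{counter:05d}"
            tspec = theoretical_spectrum(
                gp, charge, reporter_channels=design.channels, table=table
            )
            mzs: list[float] = []
            ints: list[float] = []
            for ion in tspec.ions:
                if ion.series == "reporter":
                    ch = int(ion.label.replace("TMT", ""))
                    inten = entry.channel_abundance[ch] * _lognormal_factor(
                        rng, noise.reporter_cv
                    )
                else:
                    if noise.peak_dropout_prob and rng.random() < noise.peak_dropout_prob:
                        continue
                    inten = 100.0 * _lognormal_factor(rng, noise.fragment_cv)
                jitter = (
                    rng.normal(0.0, noise.mz_jitter_ppm_sd) * 1e-6
                    if noise.mz_jitter_ppm_sd
                    else 0.0
                )
                mzs.append(ion.mz * (1.0 + jitter))
                ints.append(inten)
            if noise.n_noise_peaks:
                lo, hi = 100.0, max(tspec.precursor_mz * charge, 500.0)
                for _ in range(noise.n_noise_peaks):
                    mzs.append(float(rng.uniform(lo, hi)))
                    ints.append(
                        float(
                            100.0
                            * noise.noise_intensity_scale
                            * rng.exponential(1.0)
                        )
                    )
            prec_jitter = (
                rng.normal(0.0, noise.precursor_ppm_sd) * 1e-6
                if noise.precursor_ppm_sd
                else 0.0
            )
            rt = 600.0 + 0.4 * (mass - 1000.0) + rng.normal(0.0, 5.0)
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=tspec.precursor_mz * (1.0 + prec_jitter),
                    charge=charge,
                    rt=float(rt),
                    mz=np.array(mzs),
                    intensity=np.array(ints),
                )
            )
            glycan = gp.glycan
            row = {
                "spectrum_id": sid,
                "protein_id": gp.protein_id,
                "peptide": gp.sequence,
                "start": gp.start,
                "charge": charge,
                "glyco_site_peptide": gp.glyco_site,
                "glyco_site_protein": entry.site_protein_coord,
                "glycan": "" if glycan is None else (
                    "dHex1HexNAc1" if glycan["dHex"] else "HexNAc1"
                ),
                "core_fucosylated": entry.is_core_fuc,
                "transcript_shifted": entry.transcript_shifted,
                "seed": seed,
            }
            for ch in design.channels:
                row[f"abundance_{ch}"] = entry.channel_abundance[ch]
            rows.append(row)

    sidecar = pd.DataFrame(rows)
    if mgf_path is not None:
        write_mgf(spectra, mgf_path)
    if sidecar_path is not None:
        sidecar.to_csv(sidecar_path, sep="\t", index=False)
    return spectra, sidecar


def simulate_ms1(
    species: Sequence[tuple[float, float, float, float]],
    rt_start: float = 0.0,
    rt_end: float = 120.0,
    dt: float = 1.0,
    mz_jitter_ppm_sd: float = 0.0,
    seed: int = 0,
) -> list[Ms1Scan]:
    """Gaussian elution profiles as MS1 stick scans, for XIC work.

    ``species`` are (mz, rt_apex, rt_sigma, height) tuples.  Returns
    scans sorted by retention time at a fixed cycle time ``dt``.
    """
    rng = np.random.default_rng(seed)
    scans = []
    for rt in np.arange(rt_start, rt_end + 1e-9, dt):
        mzs, ints = [], []
        for mz0, apex, sigma, height in species:
            inten = height * math.exp(-0.5 * ((rt - apex) / sigma) ** 2)
            if inten < height * 1e-4:
                continue
            jitter = rng.normal(0.0, mz_jitter_ppm_sd) * 1e-6 if mz_jitter_ppm_sd else 0.0
            mzs.append(mz0 * (1.0 + jitter))
            ints.append(inten)
        scans.append(Ms1Scan(rt=float(rt), mz=np.array(mzs), intensity=np.array(ints)))
    return scans
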