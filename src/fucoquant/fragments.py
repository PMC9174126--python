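"""Theoretical ion generation for Endo F3-simplified glycopeptides.

Stepped-collision-energy HCD of a TMT-labelled, Endo F3-simplified
core-fucosylated glycopeptide yields four informative ion families:

* b/y backbone ladders for sequencing.  Fragments that contain the
  glycosylation site appear both with the glycan remnant retained and
  with the fucosylated GlcNAc lost (the "starred" ions, -349.1373 Da),
  and it is the retained ions that localize the site.
* precursor signature losses [M-146] (fucose) and [M-349] (fucosylated
  GlcNAc), diagnostic of core fucosylation.
* low-mass oxonium ions from the innermost GlcNAc
  (204.09 / 168.07 / 138.05), diagnostic of glycosylation per se.
* TMT reporter ions carrying the per-channel quantification.

a-ions, internal fragments and multiple simultaneous losses are not
generated.  Intensities are not modelled: theoretical spectra are sticks
of uniform weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem import (
    FUC_GLCNAC_LOSS,
    FUCOSE_LOSS,
    NTERM,
    OXONIUM_MZ,
    TMT6_REPORTER_MZ,
    Glycopeptide,
    MassTable,
    default_mass_table,
    glycan_mass,
    peptide_monoisotopic_mass,
)

__all__ = [
    "FragmentIon",
    "TheoreticalSpectrum",
    "by_ladder",
    "signature_ions",
    "theoretical_spectrum",
    "DEFAULT_REPORTER_CHANNELS",
]

#: channels used in the emulated two-condition, two-replicate TMT6 design
DEFAULT_REPORTER_CHANNELS = (128, 129, 130, 131)


@dataclass(frozen=True)
class FragmentIon:
    """A typed theoretical ion with its m/z and annotation label.

    A ``*`` in the label marks a b/y ion that has lost the fucosylated
    GlcNAc remnant (-349.1373 Da); ``°`` marks loss of a bare GlcNAc
    remnant (-203.0794 Da) from a non-fucosylated glycopeptide.
    """

    series: str  # "b" | "y" | "precursor_loss" | "oxonium" | "reporter"
    index: int | None
    charge: int
    glycan_retained: bool
    neutral_loss: float
    mz: float
    label: str

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.series in ("oxonium", "reporter") and self.index is not None:
            raise ValueError(f"{self.series} ions carry no ladder index")

    @property
    def key(self) -> tuple:
        # label disambiguates the index-less series (oxonium, reporter)
        return (self.series, self.index, self.charge, self.glycan_retained,
                round(self.neutral_loss, 4), self.label)


@dataclass(frozen=True)
class TheoreticalSpectrum:
    """All theoretical ions of one glycopeptide at one precursor charge."""

    glycopeptide: Glycopeptide
    precursor_mz: float
    precursor_charge: int
    ions: tuple[FragmentIon, ...]

    def __post_init__(self) -> None:
        keys = [ion.key for ion in self.ions]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate fragment ions in theoretical spectrum")


def _prefix_masses(gp: Glycopeptide, table: MassTable) -> list[float]:
    """Neutral bare b-fragment masses (residues + mods, no water, no glycan)
    for i = 1..n-1; index i-1 holds b_i."""
    n = len(gp.sequence)
    masses = []
    for i in range(1, n):
        res = sum(table.residue(gp.sequence[k], position=k + 1) for k in range(i))
        mods = sum(m.delta_mass for pos, m in gp.mods if pos == NTERM or 1 <= pos <= i)
        masses.append(res + mods)
    return masses


def by_ladder(
    gp: Glycopeptide,
    max_frag_charge: int = 2,
    table: MassTable | None = None,
) -> list[FragmentIon]:
    """b1..b(n-1) and y1..y(n-1) ions at charges 1..max_frag_charge.

    For fragments spanning the glycosylation site both the
    glycan-retained and the glycan-lost variant are emitted; the lost
    variant of a core-fucosylated remnant is the starred -349.1373 ion.
    """
    table = table or default_mass_table()
    n = len(gp.sequence)
    if n < 2:
        raise ValueError("cannot fragment a peptide shorter than 2 residues")

    prefix = _prefix_masses(gp, table)
    gmass = glycan_mass(gp.glycan, table) if gp.glycan is not None else 0.0
    # bare peptide mass: residues + water + mods, glycan excluded
    bare_total = peptide_monoisotopic_mass(gp, table) - gmass
    fucosylated = gp.glycan is not None and gp.glycan["dHex"] >= 1
    loss_mark = "*" if fucosylated else "°"

    ions: list[FragmentIon] = []
    for i in range(1, n):
        b_bare = prefix[i - 1]
        y_bare = bare_total - b_bare  # complement; includes water
        b_has_site = gp.glyco_site is not None and gp.glyco_site <= i
        y_has_site = gp.glyco_site is not None and gp.glyco_site > i
        for series, bare, has_site, idx in (
            ("b", b_bare, b_has_site, i),
            ("y", y_bare, y_has_site, n - i),
        ):
            if has_site and gp.glycan is not None:
                # (retained?, fragment neutral mass, neutral loss, label mark)
                variants = [
                    (True, bare + gmass, 0.0, ""),
                    (False, bare, gmass, loss_mark),
                ]
            else:
                variants = [(False, bare, 0.0, "")]
            for retained, frag_mass, nloss, mark in variants:
                for z in range(1, max_frag_charge + 1):
                    frag_mz = (frag_mass + z * table.proton) / z
                    label = f"{series}{idx}{mark}" + (f"({z}+)" if z > 1 else "")
                    ions.append(
                        FragmentIon(
                            series=series,
                            index=idx,
                            charge=z,
                            glycan_retained=retained,
                            neutral_loss=nloss,
                            mz=frag_mz,
                            label=label,
                        )
                    )
    return ions


def signature_ions(
    gp: Glycopeptide,
    precursor_charge: int,
    table: MassTable | None = None,
    reporter_channels: tuple[int, ...] = DEFAULT_REPORTER_CHANNELS,
) -> list[FragmentIon]:
    """Precursor signature losses, oxonium diagnostics and TMT reporters.

    [M-146] (fucose) and [M-349] (fucosylated GlcNAc) are emitted at the
    precursor charge and singly charged, only for core-fucosylated
    remnants; [M-146] retains the GlcNAc on the peptide.  The oxonium
    triplet is emitted whenever a glycan is present.  Reporters are
    always emitted for the active channel set.
    """
    table = table or default_mass_table()
    ions: list[FragmentIon] = []

    if gp.glycan is not None:
        total = peptide_monoisotopic_mass(gp, table)
        if gp.glycan["dHex"] >= 1:
            charges = sorted({precursor_charge, 1})
            for nloss, tag in ((FUCOSE_LOSS, "[M-146]"), (FUC_GLCNAC_LOSS, "[M-349]")):
                for z in charges:
                    ions.append(
                        FragmentIon(
                            series="precursor_loss",
                            index=None,
                            charge=z,
                            glycan_retained=nloss < FUC_GLCNAC_LOSS,
                            neutral_loss=nloss,
                            mz=(total - nloss + z * table.proton) / z,
                            label=f"{tag}({z}+)" if z > 1 else f"{tag}+",
                        )
                    )
        for name, omz in OXONIUM_MZ.items():
            ions.append(
                FragmentIon(
                    series="oxonium",
                    index=None,
                    charge=1,
                    glycan_retained=False,
                    neutral_loss=0.0,
                    mz=omz,
                    label=f"[{name}]+",
                )
            )

    for ch in reporter_channels:
        ions.append(
            FragmentIon(
                series="reporter",
                index=None,
                charge=1,
                glycan_retained=False,
                neutral_loss=0.0,
                mz=TMT6_REPORTER_MZ[ch],
                label=f"TMT{ch}",
            )
        )
    return ions


def theoretical_spectrum(
    gp: Glycopeptide,
    precursor_charge: int,
    max_frag_charge: int | None = None,
    table: MassTable | None = None,
    reporter_channels: tuple[int, ...] = DEFAULT_REPORTER_CHANNELS,
) -> TheoreticalSpectrum:
    """Full theoretical spectrum: b/y ladder plus signature ions.

    Fragment charges default to min(precursor_charge, 2).  The ion list
    is de-duplicated and sorted by m/z; generation is a pure function of
    its inputs.
    """
    table = table or default_mass_table()
    if max_frag_charge is None:
        max_frag_charge = min(precursor_charge, 2)
    ions = by_ladder(gp, max_frag_charge, table) + signature_ions(
        gp, precursor_charge, table, reporter_channels
    )
    unique: dict[tuple, FragmentIon] = {}
    for ion in ions:
        unique.setdefault(ion.key, ion)
    ordered = tuple(sorted(unique.values(), key=lambda f: (f.mz, f.label)))
    total = peptide_monoisotopic_mass(gp, table)
    return TheoreticalSpectrum(
        glycopeptide=gp,
        precursor_mz=(total + precursor_charge * table.proton) / precursor_charge,
        precursor_charge=precursor_charge,
        ions=ordered,
    )


def spectrum_to_rows(spec: TheoreticalSpectrum) -> list[dict]:
    """Flatten a theoretical spectrum for TSV/JSON export."""
    return [
        {
            "label": ion.label,
            "series": ion.series,
            "index": ion.index,
            "charge": ion.charge,
            "glycan_retained": ion.glycan_retained,
            "neutral_loss": round(ion.neutral_loss, 4),
            "mz": round(ion.mz, 5),
        }
        for ion in spec.ions
    ]
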