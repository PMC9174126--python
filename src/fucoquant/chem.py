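"""Monoisotopic mass arithmetic for glycopeptides.

This module is the numerical foundation of the pipeline: residue and
modification mass tables, glycan composition masses, m/z conversion, and
the Endo F3 remnant model.  Endo F3 cleaves within the chitobiose core of
an N-glycan and leaves only the innermost GlcNAc — plus the alpha-1,6
core fucose when present — attached to the asparagine, so every
glycopeptide that reaches the mass spectrometer carries a remnant of
composition HexNAc(1) or dHex(1)HexNAc(1).

All masses are monoisotopic and expressed in Daltons.  The constants are
shipped as a versioned JSON table (``data/masses.json``) so that tests
and downstream code can pin exact values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "MassTable",
    "ModificationDef",
    "GlycanComposition",
    "Glycopeptide",
    "default_mass_table",
    "standard_modifications",
    "peptide_monoisotopic_mass",
    "mz",
    "glycan_mass",
    "endo_f3_simplify",
    "neutral_mass",
    "NTERM",
    "OXONIUM_MZ",
    "TMT6_REPORTER_MZ",
    "FUC_GLCNAC_LOSS",
    "FUCOSE_LOSS",
]

#: modification position index denoting the peptide N-terminus
NTERM = 0

_MONOSACCHARIDES = ("Hex", "HexNAc", "dHex", "NeuAc")


def _load_constants() -> dict:
    with resources.files("fucoquant.data").joinpath("masses.json").open() as fh:
        return json.load(fh)


_CONST = _load_constants()

#: diagnostic oxonium ion m/z values derived from the innermost GlcNAc
OXONIUM_MZ: Mapping[str, float] = dict(_CONST["oxonium"])

#: TMT6-plex reporter ion m/z by channel number
TMT6_REPORTER_MZ: Mapping[int, float] = {
    int(k): v for k, v in _CONST["tmt6_reporters"].items()
}

#: neutral loss of the fucosylated GlcNAc remnant (dHex + HexNAc), Da
FUC_GLCNAC_LOSS = _CONST["monosaccharides"]["dHex"] + _CONST["monosaccharides"]["HexNAc"]

#: neutral loss of the core fucose alone, Da
FUCOSE_LOSS = _CONST["monosaccharides"]["dHex"]


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic mass constants used throughout the pipeline."""

    residue_masses: Mapping[str, float]
    water: float
    proton: float
    element_masses: Mapping[str, float] = field(default_factory=dict)
    monosaccharide_masses: Mapping[str, float] = field(default_factory=dict)
    version: str = "unversioned"

    def residue(self, letter: str, position: int | None = None) -> float:
        try:
            return self.residue_masses[letter]
        except KeyError:
            where = "" if position is None else f" at position {position}"
            raise ValueError(
                f"unknown or non-canonical residue {letter!r}{where}"
            ) from None


def default_mass_table() -> MassTable:
    """The packaged constants table (version-pinned JSON)."""
    return MassTable(
        residue_masses=dict(_CONST["residues"]),
        water=_CONST["water"],
        proton=_CONST["proton"],
        monosaccharide_masses=dict(_CONST["monosaccharides"]),
        version=_CONST["version"],
    )


@dataclass(frozen=True)
class ModificationDef:
    """A fixed or variable modification.

    ``specificity`` is a residue letter ("C", "K", ...) or a terminus tag
    ("N-term", "Protein N-term").
    """

    name: str
    delta_mass: float
    specificity: str
    kind: str = "variable"  # "fixed" | "variable"

    def __post_init__(self) -> None:
        if not self.specificity:
            raise ValueError("modification specificity must be non-empty")
        if self.kind not in ("fixed", "variable"):
            raise ValueError(f"unknown modification kind {self.kind!r}")


def standard_modifications(tmt: bool = True) -> dict[str, ModificationDef]:
    """The study's modification set.

    Carbamidomethylation of cysteine is always fixed; the TMT6 label on the
    peptide N-terminus and lysine is fixed when the TMT design is active.
    Oxidised methionine, protein N-terminal acetylation, deamidation of
    N/Q, and the dHex-HexNAc remnant on asparagine are variable.
    """
    m = _CONST["modifications"]
    mods = {
        "Carbamidomethyl": ModificationDef("Carbamidomethyl", m["Carbamidomethyl"], "C", "fixed"),
        "Oxidation": ModificationDef("Oxidation", m["Oxidation"], "M", "variable"),
        "Acetyl": ModificationDef("Acetyl", m["Acetyl"], "Protein N-term", "variable"),
        "Deamidation-N": ModificationDef("Deamidation", m["Deamidation"], "N", "variable"),
        "Deamidation-Q": ModificationDef("Deamidation", m["Deamidation"], "Q", "variable"),
    }
    if tmt:
        mods["TMT6-Nterm"] = ModificationDef("TMT6", m["TMT6"], "N-term", "fixed")
        mods["TMT6-K"] = ModificationDef("TMT6", m["TMT6"], "K", "fixed")
    return mods


@dataclass(frozen=True)
class GlycanComposition:
    """A glycan as monosaccharide counts, with a core-fucosylation flag.

    Composition only — no topology or linkage.  After Endo F3 treatment
    the only compositions that remain peptide-linked are the remnants
    HexNAc(1) and dHex(1)HexNAc(1).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    core_fucosylated: bool = False

    def __post_init__(self) -> None:
        clean = {}
        for key, n in dict(self.counts).items():
            if key not in _MONOSACCHARIDES:
                raise ValueError(f"unknown monosaccharide class {key!r}")
            if n < 0 or n != int(n):
                raise ValueError(f"negative or non-integer count for {key}: {n}")
            if n:
                clean[key] = int(n)
        object.__setattr__(self, "counts", clean)
        if self.core_fucosylated and clean.get("dHex", 0) < 1:
            raise ValueError("core_fucosylated glycan must contain at least one dHex")

    def __getitem__(self, key: str) -> int:
        return self.counts.get(key, 0)

    @property
    def is_remnant(self) -> bool:
        """True for an Endo F3 remnant: HexNAc(1) with optional dHex(1)."""
        return (
            self["HexNAc"] == 1
            and self["dHex"] in (0, 1)
            and self["Hex"] == 0
            and self["NeuAc"] == 0
        )

    def mass(self, table: MassTable | None = None) -> float:
        return glycan_mass(self, table)


def glycan_mass(g: GlycanComposition, table: MassTable | None = None) -> float:
    """Sum of monosaccharide residue masses of a composition (Da)."""
    masses = (table.monosaccharide_masses if table and table.monosaccharide_masses
              else _CONST["monosaccharides"])
    return sum(n * masses[k] for k, n in g.counts.items())


def endo_f3_simplify(g: GlycanComposition) -> GlycanComposition:
    """Apply the Endo F3 trim: keep the innermost GlcNAc, and the core
    fucose iff the glycan was core-fucosylated.

    Idempotent; raises for compositions without any HexNAc (nothing for
    the endoglycosidase to act on).
    """
    if g["HexNAc"] < 1:
        raise ValueError("cannot Endo F3-simplify a composition without HexNAc")
    if g.core_fucosylated:
        return GlycanComposition({"HexNAc": 1, "dHex": 1}, core_fucosylated=True)
    return GlycanComposition({"HexNAc": 1}, core_fucosylated=False)


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide with modifications and an optional glycan remnant.

    ``mods`` holds (position, ModificationDef) pairs with 1-based residue
    positions; position 0 (:data:`NTERM`) denotes the peptide N-terminus.
    ``glyco_site`` is a 1-based index into ``sequence`` and must point at
    an asparagine.  ``start`` is the 1-based coordinate of the peptide's
    first residue in its parent protein (when known).
    """

    sequence: str
    mods: tuple[tuple[int, ModificationDef], ...] = ()
    glyco_site: int | None = None
    glycan: GlycanComposition | None = None
    protein_id: str = ""
    missed_cleavages: int = 0
    start: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        object.__setattr__(self, "mods", tuple(self.mods))
        n = len(self.sequence)
        for pos, mod in self.mods:
            if not (0 <= pos <= n):
                raise ValueError(
                    f"modification {mod.name} at out-of-range position {pos} "
                    f"(peptide length {n})"
                )
        if not 0 <= self.missed_cleavages <= 2:
            raise ValueError("missed_cleavages must be within [0, 2]")
        if self.glyco_site is not None:
            if not (1 <= self.glyco_site <= n):
                raise ValueError(f"glyco_site {self.glyco_site} outside peptide")
            if self.sequence[self.glyco_site - 1] != "N":
                raise ValueError(
                    f"glyco_site {self.glyco_site} does not point at an N "
                    f"(found {self.sequence[self.glyco_site - 1]!r})"
                )

    @property
    def end(self) -> int | None:
        return None if self.start is None else self.start + len(self.sequence) - 1

    def with_glycan(self, glycan: GlycanComposition, site: int) -> "Glycopeptide":
        return replace(self, glycan=glycan, glyco_site=site)

    def mod_string(self) -> str:
        """Compact human-readable modification summary, e.g. ``TMT6@0;CAM@2``."""
        parts = [f"{mod.name}@{pos}" for pos, mod in sorted(self.mods, key=lambda t: t[0])]
        if self.glycan is not None:
            tag = "dHex1HexNAc1" if self.glycan["dHex"] else "HexNAc1"
            parts.append(f"{tag}@{self.glyco_site}")
        return ";".join(parts)


def peptide_monoisotopic_mass(gp: Glycopeptide, table: MassTable | None = None) -> float:
    """Neutral monoisotopic mass of a (glyco)peptide.

    Residue masses + water + modification deltas + glycan remnant mass.
    Deterministic to <=1e-6 Da; rejects non-canonical residue letters
    (including B/Z/X/U ambiguity codes) with the offending position.
    """
    table = table or default_mass_table()
    mass = table.water
    for i, letter in enumerate(gp.sequence, start=1):
        mass += table.residue(letter, position=i)
    mass += sum(mod.delta_mass for _, mod in gp.mods)
    if gp.glycan is not None:
        mass += glycan_mass(gp.glycan, table)
    return mass


def mz(mass: float, charge: int, table: MassTable | None = None) -> float:
    """m/z of a neutral mass at a positive integer charge: (M + z*H+)/z."""
    if charge < 1 or charge != int(charge):
        raise ValueError(f"charge must be a positive integer, got {charge}")
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    proton = (table or default_mass_table()).proton
    return (mass + charge * proton) / charge


def neutral_mass(observed_mz: float, charge: int, table: MassTable | None = None) -> float:
    """Invert :func:`mz`: neutral mass from an observed m/z and charge."""
    proton = (table or default_mass_table()).proton
    return charge * (observed_mz - proton)
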