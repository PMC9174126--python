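"""FASTA ingestion, in-silico tryptic digestion, and N-sequon scanning.

Digestion follows the study's search settings: trypsin cleaving
C-terminal to K/R except before proline, up to two missed cleavages, and
a minimum peptide length of seven residues.  Sequon scanning applies the
canonical N-X(!=P)-[S/T] rule; no occupancy prediction is attempted.
All protein coordinates are 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .chem import Glycopeptide

__all__ = [
    "ProteinRecord",
    "SequonHit",
    "read_fasta",
    "write_fasta",
    "tryptic_digest",
    "find_sequons",
    "digest_to_tsv",
]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

# overlapping N-X(!=P)-[S/T] matches via lookahead
_SEQUON_RE = re.compile(r"N(?=([^P])[ST])")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: identifier, free-text description, sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _CANONICAL
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains non-canonical residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SequonHit:
    """An N-glycosylation sequon: the position of the N and its motif."""

    protein_id: str
    position: int  # 1-based index of the N
    motif: str  # the 3-residue N-X-[S/T] context

    def __post_init__(self) -> None:
        if not re.fullmatch(r"N[^P][ST]", self.motif):
            raise ValueError(f"invalid sequon motif {self.motif!r}")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into validated protein records.

    Sequences are upper-cased and whitespace-stripped; input order is
    preserved.  Empty files and records with non-canonical residues
    (ambiguity codes B/Z/X, selenocysteine U, ...) are rejected.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description,
                sequence=str(rec.seq).replace(" ", "").replace("\n", ""),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 7,
    clip_nterm_met: bool = False,
) -> list[Glycopeptide]:
    """Enumerate tryptic peptides with 0..max_missed missed cleavages.

    Each peptide is returned as an unmodified :class:`Glycopeptide`
    annotated with its missed-cleavage count and 1-based protein start
    coordinate.  ``min_len`` counts residues.  When ``clip_nterm_met`` is
    set, peptides are additionally generated from the protein with its
    initiator methionine removed (positions still refer to the unclipped
    protein numbering).
    """
    sequences = [(protein.sequence, 1)]
    if clip_nterm_met and protein.sequence.startswith("M"):
        sequences.append((protein.sequence[1:], 2))

    out: list[Glycopeptide] = []
    seen: set[tuple[int, int]] = set()
    for seq, offset in sequences:
        sites = cleavage_sites(seq)
        # segment boundaries: 0, site+1..., len
        bounds = [0] + [s + 1 for s in sites] + [len(seq)]
        nseg = len(bounds) - 1
        for i in range(nseg):
            for j in range(i, min(i + max_missed + 1, nseg)):
                start, end = bounds[i], bounds[j + 1]
                if end - start < min_len:
                    continue
                key = (start + offset, end + offset)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    Glycopeptide(
                        sequence=seq[start:end],
                        protein_id=protein.id,
                        missed_cleavages=j - i,
                        start=start + offset,
                    )
                )
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def find_sequons(protein: ProteinRecord) -> list[SequonHit]:
    """All N-X(!=P)-[S/T] motifs in a protein, 1-based, in order."""
    hits = []
    for m in _SEQUON_RE.finditer(protein.sequence):
        i = m.start()
        motif = protein.sequence[i : i + 3]
        hits.append(SequonHit(protein_id=protein.id, position=i + 1, motif=motif))
    return hits


def digest_to_tsv(peptides: Iterable[Glycopeptide], path: str | Path) -> None:
    """Write a digest as TSV: protein_id, start, end, sequence, missed_cleavages."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\tsequence\tmissed_cleavages\n")
        for p in peptides:
            fh.write(
                f"{p.protein_id}\t{p.start}\t{p.end}\t{p.sequence}\t{p.missed_cleavages}\n"
            )
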