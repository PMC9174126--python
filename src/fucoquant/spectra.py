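"""Centroided MS/MS spectrum container and MGF input/output.

MGF is the primary interchange format (mzML is accepted via pyteomics
when available); peak lists are held as parallel numpy arrays sorted by
m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "read_mgf", "write_mgf", "Ms1Scan"]


@dataclass
class Spectrum:
    """One centroided MS/MS spectrum."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def nearest_peak(self, target_mz: float) -> tuple[int, float] | None:
        """Index and |delta m/z| of the peak closest to ``target_mz``."""
        if self.mz.size == 0:
            return None
        i = int(np.searchsorted(self.mz, target_mz))
        best, bdist = None, np.inf
        for j in (i - 1, i):
            if 0 <= j < self.mz.size:
                d = abs(self.mz[j] - target_mz)
                if d < bdist:
                    best, bdist = j, d
        return best, bdist


@dataclass
class Ms1Scan:
    """One MS1 scan: retention time plus a centroided peak list."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray


def read_mgf(path: str | Path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 2
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"index={len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    rt=float(params.get("rtinseconds", 0.0)),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed numeric formatting (deterministic
    byte output for identical inputs)."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.charge}+\n")
            fh.write(f"RTINSECONDS={s.rt:.3f}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("END IONS\n")
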