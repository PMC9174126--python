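"""TMT reporter quantification and extracted ion chromatograms.

Reporter intensities are read from the low-mass region of each accepted
PSM's spectrum within a narrow absolute m/z tolerance, median-normalized
per channel across all quantified spectra (so a global per-channel scale
factor cancels), and summed per glycosylation site.  The two knockdown/
control ratios mirror the replicate structure of the emulated design:
ratio_rep1 = siFut8 replicate 1 / siCon replicate 1, likewise rep2.

XICs integrate MS1 stick intensities within +-10 ppm of a target m/z
over retention time with the trapezoidal rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import TMT6_REPORTER_MZ
from .search import PSM
from .simulate import DEFAULT_CHANNEL_MAP
from .spectra import Ms1Scan, Spectrum

__all__ = ["QuantRecord", "quantify_reporters", "quant_to_frame", "xic_area"]


@dataclass
class QuantRecord:
    """Per-site TMT quantification (the Table-1 ratio analogue)."""

    protein_id: str
    site: int  # protein coordinate of the glycosylated N
    reporter_intensities: Mapping[int, float]
    ratio_rep1: float | None
    ratio_rep2: float | None
    n_psms: int

    def __post_init__(self) -> None:
        if self.n_psms < 1:
            raise ValueError("a quant record needs at least one PSM")


def _extract_reporters(
    spectrum: Spectrum,
    channels: Sequence[int],
    tol_mz: float,
) -> dict[int, float]:
    out: dict[int, float] = {}
    for ch in channels:
        target = TMT6_REPORTER_MZ[ch]
        hit = spectrum.nearest_peak(target)
        if hit is not None and hit[1] <= tol_mz:
            out[ch] = float(spectrum.intensity[hit[0]])
        else:
            out[ch] = math.nan
    return out


def quantify_reporters(
    psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum] | Sequence[Spectrum],
    channel_map: Mapping[int, tuple[str, int]] | None = None,
    reporter_tol_mz: float = 0.003,
    normalize: bool = True,
) -> list[QuantRecord]:
    """Site-level TMT ratios from accepted PSMs.

    Per-channel normalization medians are computed over the PSMs of
    *non-glycosylated* peptides when any are present (that population is
    expected to be unchanged by the knockdown, so its medians estimate
    the per-channel labeling/loading scale without being dragged by the
    genuinely suppressed glycopeptide class); with a pure glycopeptide
    input the medians fall back to all quantified spectra.  Site records
    are emitted for glyco-localizable PSMs, aggregating reporter
    intensities by (protein, site) before forming the replicate ratios.
    A channel with no detectable reporter peak leaves the corresponding
    ratio ``None``.
    """
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    channels = sorted(channel_map)
    if not isinstance(spectra, Mapping):
        spectra = {s.spectrum_id: s for s in spectra}

    rows = []
    for psm in psms:
        if psm.is_decoy or psm.spectrum_id not in spectra:
            continue
        rep = _extract_reporters(spectra[psm.spectrum_id], channels, reporter_tol_mz)
        rows.append((psm, rep))
    if not rows:
        return []

    mat = np.array([[rep[ch] for ch in channels] for _, rep in rows])
    if normalize and len(rows) > 1:
        anchor = np.array(
            [psm.glycopeptide.glycan is None for psm, _ in rows], dtype=bool
        )
        ref = mat[anchor] if anchor.any() else mat
        with np.errstate(all="ignore"):
            medians = np.nanmedian(ref, axis=0)
        finite = np.isfinite(medians) & (medians > 0)
        if finite.any():
            grand = np.exp(np.mean(np.log(medians[finite])))
            factors = np.where(finite, grand / np.where(finite, medians, 1.0), 1.0)
            mat = mat * factors

    by_site: dict[tuple[str, int], list[np.ndarray]] = {}
    for (psm, _), inten in zip(rows, mat):
        gp = psm.glycopeptide
        if gp.glyco_site is None or gp.glycan is None or gp.start is None:
            continue
        site = gp.start + gp.glyco_site - 1
        by_site.setdefault((gp.protein_id, site), []).append(inten)

    def _ratio(total: np.ndarray, num_ch: int, den_ch: int) -> float | None:
        num = total[channels.index(num_ch)]
        den = total[channels.index(den_ch)]
        if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
            return None
        return float(num / den)

    inv = {v: k for k, v in channel_map.items()}
    records = []
    for (protein_id, site), stack in sorted(by_site.items()):
        total = np.nansum(np.vstack(stack), axis=0)
        # nansum turns all-NaN columns into 0; keep NaN to flag absence
        all_nan = np.all(np.isnan(np.vstack(stack)), axis=0)
        total = np.where(all_nan, np.nan, total)
        records.append(
            QuantRecord(
                protein_id=protein_id,
                site=site,
                reporter_intensities={
                    ch: float(total[i]) for i, ch in enumerate(channels)
                },
                ratio_rep1=_ratio(total, inv[("siFut8", 1)], inv[("siCon", 1)]),
                ratio_rep2=_ratio(total, inv[("siFut8", 2)], inv[("siCon", 2)]),
                n_psms=len(stack),
            )
        )
    return records


def quant_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "protein_id": r.protein_id,
            "site": r.site,
            "ratio_rep1": r.ratio_rep1,
            "ratio_rep2": r.ratio_rep2,
            "n_psms": r.n_psms,
        }
        for ch, v in r.reporter_intensities.items():
            row[f"intensity_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def xic_area(
    ms1_stream: Sequence[Ms1Scan],
    target_mz: float,
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal XIC area within +-tol_ppm of a target m/z.

    ``ms1_stream`` must be sorted by retention time.  An empty window
    yields area 0.
    """
    tol = target_mz * tol_ppm * 1e-6
    rts, sums = [], []
    for scan in ms1_stream:
        if rt_window is not None and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        mask = np.abs(scan.mz - target_mz) <= tol
        rts.append(scan.rt)
        sums.append(float(scan.intensity[mask].sum()) if scan.mz.size else 0.0)
    if len(rts) < 2:
        return 0.0
    if any(rts[i] > rts[i + 1] for i in range(len(rts) - 1)):
        raise ValueError("MS1 stream must be sorted by retention time")
    return float(np.trapezoid(sums, rts))
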