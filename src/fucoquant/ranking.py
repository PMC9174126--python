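"""Multi-criterion ranking of candidate Fut8 target proteins.

A protein is called a candidate Fut8 target when it satisfies all three
criteria used to build the published-style target table:

(i)   a low knockdown/control TMT ratio of its identified glycopeptides
      in both replicates (default: max replicate ratio <= 0.40);
(ii)  no transcriptional change after knockdown (default: mRNA ratio
      within [0.77, 1.30]) — separating post-translational loss of
      core fucose from mere down-regulation;
(iii) spectral evidence: at least one PSM whose core-fucosylation site
      is localized by glycan-retaining fragments.

The numeric thresholds are this package's own operating points (the
criteria were stated qualitatively); both are configurable and recorded
in the report metadata.  Passing proteins are ranked ascending by
min(ratio_rep1, ratio_rep2) — strongest observed knockdown response
first, which reproduces the published table order — while criterion (i)
conservatively requires *both* replicates (the max) to clear the
threshold.  Ties are broken by protein id.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .quant import QuantRecord
from .search import PSM

__all__ = ["RankingThresholds", "CandidateRecord", "rank_candidates", "write_report"]


@dataclass(frozen=True)
class RankingThresholds:
    """Operating points for the three candidate criteria."""

    max_tmt_ratio: float = 0.40
    transcript_ratio_band: tuple[float, float] = (0.77, 1.30)
    min_localized_psms: int = 1
    missing_transcript_passes: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.max_tmt_ratio < 1:
            raise ValueError("max_tmt_ratio must lie in (0, 1)")
        lo, hi = self.transcript_ratio_band
        if not lo <= 1.0 <= hi:
            raise ValueError("transcript_ratio_band must contain 1.0")


@dataclass
class CandidateRecord:
    """Per-protein aggregation with per-criterion verdicts and rank."""

    protein_id: str
    gene: str
    sites: tuple[int, ...]
    tmt_ratio_1: float | None
    tmt_ratio_2: float | None
    transcript_ratio: float | None
    spectral_evidence: int  # number of site-localized PSMs
    passes: dict = field(default_factory=dict)
    rank: int | None = None

    @property
    def passes_all(self) -> bool:
        return all(self.passes.values())

    @property
    def ranking_key(self) -> float:
        """Strongest observed knockdown: the smaller replicate ratio."""
        ratios = [r for r in (self.tmt_ratio_1, self.tmt_ratio_2) if r is not None]
        return min(ratios) if ratios else float("inf")


def rank_candidates(
    quant: Sequence[QuantRecord],
    transcripts: Mapping[str, float] | None,
    psms: Sequence[PSM] | None,
    thresholds: RankingThresholds | None = None,
) -> list[CandidateRecord]:
    """Aggregate site quantification per protein and apply the criteria.

    Per-protein TMT ratios take the minimum across sites within each
    replicate (most-affected-site aggregation).  ``transcripts`` maps
    gene/protein ids to knockdown/control mRNA ratios and may be partial;
    a missing entry makes criterion (ii) not evaluable and the verdict
    follows ``thresholds.missing_transcript_passes``.  ``psms`` supplies
    the localized-PSM counts for criterion (iii); pass ``None`` to accept
    external spectral-evidence counts of zero.
    """
    thresholds = thresholds or RankingThresholds()
    transcripts = dict(transcripts or {})

    localized: dict[str, int] = {}
    for psm in psms or []:
        if psm.site_localized and not psm.is_decoy:
            pid = psm.glycopeptide.protein_id
            localized[pid] = localized.get(pid, 0) + 1

    by_protein: dict[str, list[QuantRecord]] = {}
    for rec in quant:
        by_protein.setdefault(rec.protein_id, []).append(rec)

    records: list[CandidateRecord] = []
    for protein_id in sorted(by_protein):
        recs = by_protein[protein_id]
        r1 = [r.ratio_rep1 for r in recs if r.ratio_rep1 is not None]
        r2 = [r.ratio_rep2 for r in recs if r.ratio_rep2 is not None]
        tmt1 = min(r1) if r1 else None
        tmt2 = min(r2) if r2 else None
        tr = transcripts.get(protein_id)
        n_loc = localized.get(protein_id, 0) if psms is not None else max(
            (r.n_psms for r in recs), default=0
        )

        ratios = [r for r in (tmt1, tmt2) if r is not None]
        pass_tmt = bool(ratios) and max(ratios) <= thresholds.max_tmt_ratio
        lo, hi = thresholds.transcript_ratio_band
        pass_transcript = (
            thresholds.missing_transcript_passes
            if tr is None
            else lo <= tr <= hi
        )
        pass_spectra = n_loc >= thresholds.min_localized_psms

        records.append(
            CandidateRecord(
                protein_id=protein_id,
                gene=protein_id,
                sites=tuple(sorted(r.site for r in recs)),
                tmt_ratio_1=tmt1,
                tmt_ratio_2=tmt2,
                transcript_ratio=tr,
                spectral_evidence=n_loc,
                passes={
                    "low_tmt_ratio": pass_tmt,
                    "transcript_stable": pass_transcript,
                    "spectral_evidence": pass_spectra,
                },
            )
        )

    passing = sorted(
        (r for r in records if r.passes_all),
        key=lambda r: (r.ranking_key, r.protein_id),
    )
    for i, rec in enumerate(passing, start=1):
        rec.rank = i
    records.sort(
        key=lambda r: (r.rank if r.rank is not None else 10**9, r.protein_id)
    )
    return records


_REPORT_COLUMNS = [
    "rank",
    "protein_id",
    "gene",
    "sites",
    "tmt_ratio_1",
    "tmt_ratio_2",
    "transcript_ratio",
    "spectral_evidence",
    "pass_low_tmt_ratio",
    "pass_transcript_stable",
    "pass_spectral_evidence",
    "passes_all",
]


def write_report(
    candidates: Sequence[CandidateRecord],
    out_dir: str | Path,
    thresholds: RankingThresholds | None = None,
    metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write the candidate table (TSV) and a run-metadata JSON.

    The metadata records the thresholds, tool version, any caller-
    supplied entries (seeds, config paths), and a hash of the candidate
    table for re-run comparison.
    """
    thresholds = thresholds or RankingThresholds()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in candidates:
        rows.append(
            {
                "rank": rec.rank if rec.rank is not None else "",
                "protein_id": rec.protein_id,
                "gene": rec.gene,
                "sites": ";".join(str(s) for s in rec.sites),
                "tmt_ratio_1": "" if rec.tmt_ratio_1 is None else f"{rec.tmt_ratio_1:.4f}",
                "tmt_ratio_2": "" if rec.tmt_ratio_2 is None else f"{rec.tmt_ratio_2:.4f}",
                "transcript_ratio": ""
                if rec.transcript_ratio is None
                else f"{rec.transcript_ratio:.4f}",
                "spectral_evidence": rec.spectral_evidence,
                "pass_low_tmt_ratio": rec.passes.get("low_tmt_ratio", False),
                "pass_transcript_stable": rec.passes.get("transcript_stable", False),
                "pass_spectral_evidence": rec.passes.get("spectral_evidence", False),
                "passes_all": rec.passes_all,
            }
        )
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    table_path = out_dir / "candidates.tsv"
    frame.to_csv(table_path, sep="\t", index=False)

    digest = hashlib.sha256(table_path.read_bytes()).hexdigest()
    meta = {
        "tool": "fucoquant",
        "version": __version__,
        "thresholds": {
            "max_tmt_ratio": thresholds.max_tmt_ratio,
            "transcript_ratio_band": list(thresholds.transcript_ratio_band),
            "min_localized_psms": thresholds.min_localized_psms,
            "missing_transcript_passes": thresholds.missing_transcript_passes,
        },
        "candidate_table_sha256": digest,
        "n_candidates": len(candidates),
        "n_passing": sum(1 for c in candidates if c.passes_all),
    }
    if metadata:
        meta.update(dict(metadata))
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return {"candidates": table_path, "metadata": meta_path}
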