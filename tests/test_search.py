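"""Candidate indexing, spectrum matching, FDR control and localization."""

import numpy as np
import pytest

from fucoquant.chem import NTERM, Glycopeptide, default_mass_table, mz, peptide_monoisotopic_mass
from fucoquant.fragments import theoretical_spectrum
from fucoquant.proteome import ProteinRecord
from fucoquant.search import (
    PSM,
    SearchConfig,
    build_candidate_index,
    decoy_sequence,
    fdr_filter,
    localize_site,
    match_spectrum,
    search_spectra,
)
from fucoquant.simulate import NoiseModel, StudyDesign, simulate_ground_truth, simulate_spectra
from fucoquant.spectra import Spectrum

from conftest import REMNANT_FUC


@pytest.fixture(scope="module")
def sparc_like_protein():
    # carries the VCSNDNK / VCSNDNKTFDSSCHFFATK tryptic context with the
    # N-K-T sequon at protein position 10
    return ProteinRecord("SPARCLIKE", "", "AAAKVCSNDNKTFDSSCHFFATKRGGGGGGG")


@pytest.fixture(scope="module")
def toy_index(sparc_like_protein):
    return build_candidate_index([sparc_like_protein], SearchConfig())


def make_true_spectrum(gp, charge, spectrum_id="S1", channels=(128, 129, 130, 131)):
    tspec = theoretical_spectrum(gp, charge, reporter_channels=channels)
    mzs = np.array([i.mz for i in tspec.ions])
    ints = np.full(mzs.size, 100.0)
    return Spectrum(spectrum_id, tspec.precursor_mz, charge, 60.0, mzs, ints)


class TestCandidateIndex:
    def test_decoy_reversal_preserves_cterm(self):
        assert decoy_sequence("VCSNDNK") == "NDNSCVK"

    def test_index_size_matches_brute_force_enumeration(self):
        # ACDEFGHK (protein N-term: TMT or acetyl nterm states = 2),
        # VWYSTGK (1), ACDEFGHKVWYSTGK (2); no M/N/Q -> no other variable
        # mods, no sequons -> no glyco variants; decoys 1:1
        protein = ProteinRecord("T", "", "ACDEFGHKVWYSTGK")
        index = build_candidate_index([protein], SearchConfig())
        assert index.n_targets == 2 + 1 + 2
        assert len(index) == 2 * index.n_targets

    def test_peptide_without_sequon_gets_no_glyco_variants(self):
        protein = ProteinRecord("T", "", "ACDEFGHKVWYSTGK")
        index = build_candidate_index([protein], SearchConfig())
        assert all(c.glycopeptide.glycan is None for c in index.candidates)

    def test_sequon_peptides_get_both_remnants(self, toy_index):
        glycans = {
            (c.glycopeptide.sequence, str(sorted(c.glycopeptide.glycan.counts.items())))
            for c in toy_index.candidates
            if c.glycopeptide.glycan is not None and not c.is_decoy
        }
        assert ("VCSNDNK", "[('HexNAc', 1), ('dHex', 1)]") in glycans
        assert ("VCSNDNK", "[('HexNAc', 1)]") in glycans

    def test_mass_window_query(self, toy_index, table):
        cand = toy_index.candidates[len(toy_index.candidates) // 2]
        hits = toy_index.query(cand.mass, 6.0)
        assert cand in hits
        assert all(abs(h.mass - cand.mass) <= cand.mass * 6e-6 for h in hits)


class TestMatchSpectrum:
    def test_true_glycopeptide_is_top_ranked_with_correct_site(
        self, sparc_mouse_glycopeptide, toy_index
    ):
        gp = sparc_mouse_glycopeptide
        spectrum = make_true_spectrum(gp, 2)
        ranked = match_spectrum(spectrum, toy_index)
        top = ranked[0]
        assert top.glycopeptide.sequence == "VCSNDNK"
        assert not top.is_decoy
        assert top.glycopeptide.glyco_site == 6
        assert top.glycopeptide.glycan == REMNANT_FUC

    def test_precursor_outside_window_is_unidentified(
        self, sparc_mouse_glycopeptide, toy_index
    ):
        spectrum = make_true_spectrum(sparc_mouse_glycopeptide, 2)
        spectrum.precursor_mz *= 1 + 50e-6  # 50 ppm off
        assert match_spectrum(spectrum, toy_index) == []

    def test_random_spectra_show_no_target_decoy_bias(self, toy_index):
        """On pure-noise spectra the engine must not systematically favor
        targets over decoys."""
        rng = np.random.default_rng(0)
        wins = ties = losses = 0
        for k in range(40):
            cand = toy_index.candidates[
                int(rng.integers(len(toy_index.candidates)))
            ]
            precursor = mz(cand.mass, 2)
            spectrum = Spectrum(
                f"R{k}", precursor, 2, 0.0,
                rng.uniform(100, precursor * 2, size=200),
                rng.exponential(50, size=200),
            )
            ranked = match_spectrum(spectrum, toy_index)
            if not ranked:
                continue
            best_t = max((p.score for p in ranked if not p.is_decoy), default=None)
            best_d = max((p.score for p in ranked if p.is_decoy), default=None)
            if best_t is None or best_d is None:
                continue
            if best_t > best_d:
                wins += 1
            elif best_t < best_d:
                losses += 1
            else:
                ties += 1
        decided = wins + losses
        assert decided >= 10
        assert 0.2 <= wins / decided <= 0.8


class TestFdrFilter:
    def test_full_separation_accepts_all_targets(self):
        psms = [
            PSM(f"t{i}", Glycopeptide("GAVLSTK"), 100 - i * 0.1, 5, 0.0, False)
            for i in range(100)
        ] + [
            PSM(f"d{i}", Glycopeptide("KTSLVAG"), 10 - i * 0.1, 1, 0.0, True)
            for i in range(100)
        ]
        accepted = fdr_filter(psms, q=0.01)
        assert len(accepted) == 100
        assert all(p.q_value == pytest.approx(1 / 100) for p in accepted)

    def test_interleaved_scores_match_brute_force_q_values(self):
        rng = np.random.default_rng(1)
        psms = []
        for i in range(60):
            decoy = bool(rng.integers(2))
            score = float(rng.normal(10 if decoy else 12, 3))
            psms.append(
                PSM(f"s{i}", Glycopeptide("GAVLSTK"), max(score, 0), 3, 0.0, decoy)
            )
        fdr_filter(psms, q=0.01)
        ranked = sorted(psms, key=lambda p: (-p.score, p.is_decoy, p.spectrum_id))
        for i, p in enumerate(ranked):
            # brute force: best (d+1)/t over all thresholds at or below rank i
            expect = min(
                (sum(q.is_decoy for q in ranked[: j + 1]) + 1)
                / max(sum(not q.is_decoy for q in ranked[: j + 1]), 1)
                for j in range(i, len(ranked))
            )
            assert p.q_value == pytest.approx(min(expect, 1.0))

    def test_q_values_monotone_along_ranked_list(self):
        rng = np.random.default_rng(2)
        psms = [
            PSM(f"s{i}", Glycopeptide("GAVLSTK"), float(rng.exponential(5)), 3, 0.0,
                bool(rng.integers(2)))
            for i in range(80)
        ]
        fdr_filter(psms)
        ranked = sorted(psms, key=lambda p: -p.score)
        qs = [p.q_value for p in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_decoy_only_input_accepts_nothing(self):
        psms = [
            PSM(f"d{i}", Glycopeptide("GAVLSTK"), 5.0, 3, 0.0, True) for i in range(5)
        ]
        assert fdr_filter(psms) == []


class TestLocalization:
    def test_zero_noise_spectrum_localizes_true_site(
        self, sparc_mouse_glycopeptide, toy_index
    ):
        spectrum = make_true_spectrum(sparc_mouse_glycopeptide, 2)
        best = search_spectra([spectrum], toy_index)[0]
        assert best.site_localized
        assert best.glycopeptide.glyco_site == 6
        assert best.localization_evidence

    def test_two_sequons_without_discriminating_ions_stay_ambiguous(self, mods):
        gp = Glycopeptide(
            "ANCTANDTK",
            mods=((NTERM, mods["TMT6-Nterm"]), (9, mods["TMT6-K"]),
                  (3, mods["Carbamidomethyl"])),
            glyco_site=2,
            glycan=REMNANT_FUC,
        )
        psm = PSM("a", gp, 5.0, 2, 0.0, False, matched_fragment_ions=())
        assert not localize_site(psm).site_localized

    def test_oxonium_only_matches_do_not_localize(self, sparc_mouse_glycopeptide):
        tspec = theoretical_spectrum(sparc_mouse_glycopeptide, 2)
        oxonium = tuple(i for i in tspec.ions if i.series == "oxonium")
        psm = PSM("o", sparc_mouse_glycopeptide, 1.0, len(oxonium), 0.0, False,
                  matched_fragment_ions=oxonium)
        assert not localize_site(psm).site_localized

    def test_naked_peptide_is_never_localized(self):
        psm = PSM("n", Glycopeptide("GAVLSTK"), 5.0, 4, 0.0, False)
        assert not localize_site(psm).site_localized


class TestEndToEnd:
    def test_zero_noise_synthetic_run_identifies_everything(self):
        from fucoquant.simulate import make_synthetic_proteome

        proteome = make_synthetic_proteome(8, 200, 2, seed=21)
        design = StudyDesign(seed=21)
        truth = simulate_ground_truth(design, proteome)
        spectra, sidecar = simulate_spectra(truth, NoiseModel.none(), seed=22)
        index = build_candidate_index(proteome, SearchConfig())
        psms = search_spectra(spectra, index)
        assert len(psms) == len(spectra)
        truth_map = dict(zip(sidecar["spectrum_id"], sidecar["peptide"]))
        assert all(
            p.glycopeptide.sequence == truth_map[p.spectrum_id] and not p.is_decoy
            for p in psms
        )
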