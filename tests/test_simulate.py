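"""Ground-truth generator and spectrum simulator."""

import math

import numpy as np
import pytest

from fucoquant.chem import OXONIUM_MZ
from fucoquant.fragments import theoretical_spectrum
from fucoquant.proteome import ProteinRecord, find_sequons
from fucoquant.simulate import (
    NoiseModel,
    StudyDesign,
    make_synthetic_proteome,
    simulate_ground_truth,
    simulate_spectra,
)
from fucoquant.spectra import read_mgf, write_mgf


@pytest.fixture(scope="module")
def proteome():
    return make_synthetic_proteome(n_proteins=6, length=200, sites_per_protein=2, seed=7)


class TestSyntheticProteome:
    def test_sequences_canonical_and_sequon_bearing(self, proteome):
        assert len(proteome) == 6
        for rec in proteome:
            assert set(rec.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")
        assert any(find_sequons(rec) for rec in proteome)

    def test_deterministic_for_fixed_seed(self):
        a = make_synthetic_proteome(3, 150, 2, seed=11)
        b = make_synthetic_proteome(3, 150, 2, seed=11)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestGroundTruth:
    def test_null_design_has_unit_ratios(self, proteome):
        design = StudyDesign(knockdown_ratio=1.0, seed=3)
        truth = simulate_ground_truth(design, proteome)
        for e in truth.entries:
            a = e.channel_abundance
            assert a[130] / a[128] == pytest.approx(1.0)
            assert a[131] / a[129] == pytest.approx(1.0)

    def test_noise_free_core_fuc_ratio_is_exact_knockdown(self, proteome):
        design = StudyDesign(knockdown_ratio=0.05, seed=3)
        truth = simulate_ground_truth(design, proteome)
        assert truth.core_fuc_entries
        for e in truth.core_fuc_entries:
            a = e.channel_abundance
            assert a[130] / a[128] == pytest.approx(0.05)
            assert a[131] / a[129] == pytest.approx(0.05)

    def test_mean_recovered_ratio_near_knockdown_with_reporter_noise(self, proteome):
        """Monte-Carlo: with 10% reporter CV the per-spectrum reporter
        ratio estimator stays within 3 SE of the simulated knockdown."""
        design = StudyDesign(knockdown_ratio=0.05, seed=5, glyco_site_fraction=1.0)
        truth = simulate_ground_truth(design, proteome)
        spectra, sidecar = simulate_spectra(
            truth, NoiseModel(mz_jitter_ppm_sd=0, reporter_cv=0.10,
                              n_noise_peaks=0, noise_intensity_scale=0,
                              peak_dropout_prob=0, precursor_ppm_sd=0,
                              fragment_cv=0),
            seed=6,
        )
        by_id = {s.spectrum_id: s for s in spectra}
        ratios = []
        for row in sidecar.itertuples():
            if not row.core_fucosylated:
                continue
            s = by_id[row.spectrum_id]
            get = lambda mz0: s.intensity[np.argmin(np.abs(s.mz - mz0))]
            ratios.append(get(130.141145) / get(128.134436))
        assert len(ratios) >= 5
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.05) <= 3 * se + 1e-9

    def test_transcript_shifted_proteins_are_marked_and_low(self, proteome):
        design = StudyDesign(transcript_shift_fraction=0.5, seed=3)
        truth = simulate_ground_truth(design, proteome)
        shifted = {
            e.glycopeptide.protein_id for e in truth.entries if e.transcript_shifted
        }
        assert shifted
        for pid in shifted:
            assert truth.transcript_ratios[pid] < 0.5
        # shifted proteins never count as true Fut8 targets
        assert not shifted & truth.true_target_proteins()

    def test_rejects_sequon_free_proteome(self):
        naked = [ProteinRecord("flat", "", "AGAGAGKAGAGAGAGR" * 4)]
        with pytest.raises(ValueError, match="sequon"):
            simulate_ground_truth(StudyDesign(seed=1), naked)


class TestSimulateSpectra:
    def test_zero_noise_precursor_is_exact(self, proteome):
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        spectra, sidecar = simulate_spectra(truth, NoiseModel.none(), seed=4)
        by_id = {s.spectrum_id: s for s in spectra}
        for e, row in zip(truth.entries, sidecar.itertuples()):
            tspec = theoretical_spectrum(e.glycopeptide, row.charge)
            assert by_id[row.spectrum_id].precursor_mz == pytest.approx(
                tspec.precursor_mz, abs=1e-6
            )

    def test_same_seed_gives_byte_identical_mgf(self, proteome, tmp_path):
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        p1, p2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
        simulate_spectra(truth, NoiseModel(), seed=9, mgf_path=p1)
        simulate_spectra(truth, NoiseModel(), seed=9, mgf_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_oxonium_triplet_only_in_glyco_spectra(self, proteome):
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        spectra, sidecar = simulate_spectra(truth, NoiseModel.none(), seed=4)
        by_id = {s.spectrum_id: s for s in spectra}
        for row in sidecar.itertuples():
            s = by_id[row.spectrum_id]
            has_oxonium = any(
                np.any(np.abs(s.mz - v) < 0.01) for v in OXONIUM_MZ.values()
            )
            assert has_oxonium == bool(row.glycan)

    def test_fragment_jitter_keeps_peaks_inside_search_window(self, proteome):
        """5 ppm jitter leaves >=99% of true fragments within the 20 ppm
        fragment tolerance (a 4-sigma bound)."""
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        noise = NoiseModel(mz_jitter_ppm_sd=5.0, reporter_cv=0, n_noise_peaks=0,
                           noise_intensity_scale=0, peak_dropout_prob=0,
                           precursor_ppm_sd=0, fragment_cv=0)
        spectra, sidecar = simulate_spectra(truth, noise, seed=4)
        inside = total = 0
        for e, s, row in zip(truth.entries, spectra, sidecar.itertuples()):
            tspec = theoretical_spectrum(e.glycopeptide, row.charge)
            for ion in tspec.ions:
                d = np.min(np.abs(s.mz - ion.mz)) / ion.mz * 1e6
                total += 1
                inside += d <= 20.0
        assert total > 500
        assert inside / total >= 0.99

    def test_sidecar_records_seed(self, proteome):
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        _, sidecar = simulate_spectra(truth, NoiseModel.none(), seed=42)
        assert set(sidecar["seed"]) == {42}

    def test_mgf_round_trip(self, proteome, tmp_path):
        truth = simulate_ground_truth(StudyDesign(seed=3), proteome)
        spectra, _ = simulate_spectra(
            truth, NoiseModel.none(), seed=4, mgf_path=tmp_path / "rt.mgf"
        )
        back = read_mgf(tmp_path / "rt.mgf")
        assert len(back) == len(spectra)
        assert back[0].spectrum_id == spectra[0].spectrum_id
        assert back[0].charge == spectra[0].charge
        np.testing.assert_allclose(back[0].mz, spectra[0].mz, atol=1e-5)
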