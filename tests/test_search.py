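"""Theoretical spectra, matching/scoring and site localization."""

import numpy as np
import pytest
from pyteomics import mass as pyteomics_mass

from nuclink.chem import PROTON, neutral_mass
from nuclink.presets import EMPTY_ADDUCT, enumerate_precursor_adducts, get_preset
from nuclink.search import (
    CandidateIndex,
    CrosslinkCandidate,
    build_candidate_index,
    localize,
    match_and_score,
    search,
    theoretical_peaks,
)
from nuclink.seqdb import ProteinEntry, digest
from nuclink.simdata import SimulationConfig, simulate_spectrum
from nuclink.spectra import MsnSpectrum


def _peptide(seq):
    return digest(ProteinEntry("P", seq), "Trypsin/P", 2, 1, 50)[0]


def _adduct(preset, name):
    for a in enumerate_precursor_adducts(preset, preset.max_adduct_length):
        if a.matches_name(name):
            return a
    raise KeyError(name)


def _noiseless(candidate, preset, site=None, charge=2, seed=0):
    cfg = SimulationConfig(seed=seed, n_spectra=1)
    rng = np.random.default_rng(seed)
    spectrum, _ = simulate_spectrum(
        candidate.peptide, candidate.adduct, site, preset, cfg, rng, "s0", charge
    )
    return spectrum


class TestTheoreticalPeaks:
    def test_linear_peptide_matches_textbook_fragment_masses(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("PEPTIDE"), EMPTY_ADDUCT, "RNA-UV")
        peaks = theoretical_peaks(cand, rna_uv, precursor_charge=2)
        by = {(p.ion_type, p.index): p.mz for p in peaks if p.ion_type in "by" and p.charge == 1}
        for i in range(1, 7):
            assert by[("b", i)] == pytest.approx(
                pyteomics_mass.fast_mass("PEPTIDE"[:i], ion_type="b", charge=1), abs=2e-4)
            assert by[("y", i)] == pytest.approx(
                pyteomics_mass.fast_mass("PEPTIDE"[-i:], ion_type="y", charge=1), abs=2e-4)

    def test_fa_candidate_has_markers_but_no_shifted_fragments(self, rna_fa):
        cand = CrosslinkCandidate(_peptide("KVEADCR"), _adduct(rna_fa, "FA+A"), "RNA-FA")
        peaks = theoretical_peaks(cand, rna_fa, 2)
        assert not any(p.shifted and p.ion_type in "by" for p in peaks)
        assert any(p.ion_type == "marker" and p.label == "FA+A'" for p in peaks)

    def test_nm_histidine_site_restricts_ladders_and_adds_immonium(self, rna_nm):
        cand = CrosslinkCandidate(_peptide("LQHIDFVR"), _adduct(rna_nm, "NM+G"), "RNA-NM")
        peaks = theoretical_peaks(cand, rna_nm, 2, site=2)  # His-3, 0-based 2
        shifted_b = {p.index for p in peaks if p.ion_type == "b" and p.shifted}
        shifted_y = {p.index for p in peaks if p.ion_type == "y" and p.shifted}
        assert shifted_b == {3, 4, 5, 6, 7}
        assert shifted_y == {6, 7}
        assert any(p.label == "iH+NM+G'" for p in peaks)

    def test_site_out_of_range(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("PEPTIDE"), _adduct(rna_uv, "U"), "RNA-UV")
        with pytest.raises(IndexError):
            theoretical_peaks(cand, rna_uv, 2, site=7)


class TestCandidateIndex:
    def test_counts(self, rna_uv):
        peps = [_peptide("PEPTIDE")]
        adducts = enumerate_precursor_adducts(rna_uv, 1)
        index = build_candidate_index(peps, rna_uv, adducts)
        assert len(index) == len(adducts)

    def test_query_equals_linear_scan(self, uv_index):
        all_cands = list(uv_index)
        rng = np.random.default_rng(0)
        for cand in rng.choice(len(all_cands), 25, replace=False):
            target = all_cands[cand].total_mass
            got = {id(c) for c in uv_index.query(target, 6.0)}
            expected = {
                id(c) for c in all_cands
                if abs(c.total_mass - target) <= target * 6e-6
            }
            assert got == expected

    def test_empty_db(self):
        assert len(CandidateIndex([])) == 0


class TestMatchAndScore:
    def test_self_match_is_complete(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("NYITESGK"), _adduct(rna_uv, "U"), "RNA-UV")
        spectrum = _noiseless(cand, rna_uv, site=1)
        csm = match_and_score(spectrum, cand, rna_uv)
        assert csm is not None
        assert csm.subscores.frac_tic_explained == pytest.approx(1.0, abs=1e-4)
        # every observed peak is explained
        assert len(csm.matches) == spectrum.n_peaks

    def test_empty_spectrum_scores_zero(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("PEPTIDE"), EMPTY_ADDUCT, "RNA-UV")
        empty = MsnSpectrum("e", (cand.total_mass + 2 * PROTON) / 2, 2, 0.0,
                            np.array([]), np.array([]))
        csm = match_and_score(empty, cand, rna_uv)
        assert csm.main_score == 0.0
        assert csm.subscores.n_unshifted_b == csm.subscores.n_shifted_y == 0

    def test_precursor_gate_rejects_wrong_mass(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("PEPTIDE"), EMPTY_ADDUCT, "RNA-UV")
        off = MsnSpectrum("o", (cand.total_mass + 5.0 + 2 * PROTON) / 2, 2, 0.0,
                          np.array([200.0]), np.array([1.0]))
        assert match_and_score(off, cand, rna_uv) is None

    def test_isobaric_species_form_one_ambiguous_candidate(self, rna_uv):
        """C-NH3 and U-H2O are one merged candidate: no mass measurement can
        separate them, so the engine scores them once and reports 'C/U'."""
        pep = _peptide("VAVIKAVR")
        adduct = _adduct(rna_uv, "U-H2O")
        assert adduct == _adduct(rna_uv, "C-NH3")
        cand = CrosslinkCandidate(pep, adduct, "RNA-UV")
        spectrum = _noiseless(cand, rna_uv, site=4, seed=3)
        csm = match_and_score(spectrum, cand, rna_uv)
        assert csm.subscores.frac_tic_explained == pytest.approx(1.0, abs=1e-6)
        assert "C-NH3" in cand.adduct.name and "U-H2O" in cand.adduct.name

    def test_adding_matched_peak_never_lowers_score(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("NYITESGK"), _adduct(rna_uv, "U"), "RNA-UV")
        full = _noiseless(cand, rna_uv, site=1)
        score_prev = None
        for n in range(5, full.n_peaks + 1, 5):
            partial = MsnSpectrum("p", full.precursor_mz, 2, 0.0,
                                  full.mz[:n], full.intensity[:n])
            csm = match_and_score(partial, cand, rna_uv)
            total = csm.main_score - np.log1p(csm.subscores.frac_tic_explained)
            if score_prev is not None:
                assert total >= score_prev - 1e-12
            score_prev = total


class TestSearch:
    def test_planted_spectra_recovered(self, rna_uv, uv_index, toy_proteins):
        from nuclink.simdata import simulate_dataset

        cfg = SimulationConfig(seed=5, n_spectra=40, preset_id="RNA-UV", max_adduct_length=1)
        spectra, truth = simulate_dataset(cfg, toy_proteins)
        results = search(spectra, uv_index, rna_uv)
        for _, row in truth.iterrows():
            top = results[row.spectrum_id][0]
            assert top.candidate.peptide.sequence == row.peptide
            want = row.adduct_class if row.is_xl else ""
            assert top.candidate.adduct.composition.formula() == want

    def test_shifted_precursors_yield_nothing(self, rna_uv):
        from nuclink.seqdb import build_peptide_db
        from nuclink.simdata import random_proteins, simulate_dataset

        prots = random_proteins(1, 60, seed=2)
        index = build_candidate_index(
            build_peptide_db(prots), rna_uv, enumerate_precursor_adducts(rna_uv, 1))
        cfg = SimulationConfig(seed=5, n_spectra=10, preset_id="RNA-UV", max_adduct_length=1)
        spectra, _ = simulate_dataset(cfg, prots)
        for s in spectra:
            s.precursor_mz += 5000.0  # far beyond every candidate mass
        results = search(spectra, index, rna_uv)
        assert all(not v for v in results.values())


class TestLocalize:
    def test_tyrosine_site_recovered(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("NYITESGK"), _adduct(rna_uv, "U"), "RNA-UV")
        csm = match_and_score(_noiseless(cand, rna_uv, site=1), cand, rna_uv)
        csm = localize(csm, rna_uv)
        assert csm.best_site == 1  # Tyr-2
        assert csm.loc_score >= 1

    def test_histidine_site_with_immonium(self, rna_nm):
        cand = CrosslinkCandidate(_peptide("LQHIDFVR"), _adduct(rna_nm, "NM+G"), "RNA-NM")
        csm = match_and_score(_noiseless(cand, rna_nm, site=2), cand, rna_nm)
        csm = localize(csm, rna_nm)
        assert csm.best_site == 2  # His-3
        assert csm.loc_score >= 1

    def test_symmetric_evidence_leaves_site_unset(self, rna_uv):
        cand = CrosslinkCandidate(_peptide("NYITESGK"), _adduct(rna_uv, "U"), "RNA-UV")
        # spectrum with only the precursor peak: no site-determining evidence
        pmz = (cand.total_mass + 2 * PROTON) / 2
        s = MsnSpectrum("s", pmz, 2, 0.0, np.array([pmz]), np.array([10.0]))
        csm = localize(match_and_score(s, cand, rna_uv), rna_uv)
        assert csm.best_site is None
        assert csm.loc_score == 0.0

    def test_linear_and_fa_candidates_left_unlocalized(self, rna_uv, rna_fa):
        lin = CrosslinkCandidate(_peptide("PEPTIDE"), EMPTY_ADDUCT, "RNA-UV")
        s = _noiseless(lin, rna_uv)
        csm = localize(match_and_score(s, lin, rna_uv), rna_uv)
        assert csm.loc_score is None
        fa = CrosslinkCandidate(_peptide("KVEADCR"), _adduct(rna_fa, "FA+A"), "RNA-FA")
        s = _noiseless(fa, rna_fa)
        csm = localize(match_and_score(s, fa, rna_fa), rna_fa)
        assert csm.loc_score is None
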