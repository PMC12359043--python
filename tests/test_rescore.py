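"""q-value estimation, semi-supervised rescoring, protein inference."""

import numpy as np
import pytest

from nuclink.presets import EMPTY_ADDUCT, enumerate_precursor_adducts, get_preset
from nuclink.rescore import (
    ProteinGroup,
    peptide_level,
    protein_inference,
    qvalues,
    rank1,
    rescore,
)
from nuclink.search import CSM, CrosslinkCandidate, SubscoreVector
from nuclink.seqdb import PeptideCandidate


def _csm(sid, score, decoy=False, seq="PEPTIDEK", xl=False, accessions=("P1",), preset=None):
    pep = PeptideCandidate(seq, 0, len(seq), 0, (), frozenset(accessions), decoy)
    if xl:
        preset = preset or get_preset("RNA-UV")
        adduct = [a for a in enumerate_precursor_adducts(preset, 1) if a.matches_name("U")][0]
    else:
        adduct = EMPTY_ADDUCT
    cand = CrosslinkCandidate(pep, adduct, "RNA-UV")
    sub = SubscoreVector(main_score=score, peptide_length=len(seq), is_xl=int(xl))
    return CSM(spectrum_id=sid, candidate=cand, subscores=sub)


class TestQvalues:
    def test_hand_computed_plus_one_estimator(self):
        csms = [_csm("s1", 10), _csm("s2", 9), _csm("s3", 8), _csm("s4", 1, decoy=True)]
        out = qvalues(csms, class_separate=False)
        targets = [c for c in out if not c.is_decoy]
        assert [c.q_value for c in targets] == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_all_decoys_above_all_targets(self):
        csms = [_csm(f"d{i}", 10 + i, decoy=True) for i in range(3)]
        csms += [_csm(f"t{i}", i) for i in range(3)]
        out = qvalues(csms, class_separate=False)
        assert all(c.q_value == 1.0 for c in out if not c.is_decoy)

    def test_empty_input(self):
        assert qvalues([]) == []

    def test_q_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(0)
        csms = [_csm(f"s{i}", rng.normal(), decoy=bool(i % 3 == 0)) for i in range(60)]
        out = qvalues(csms, class_separate=False)
        ordered = sorted(out, key=lambda c: -c.main_score)
        qs = [c.q_value for c in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_q_strictly_positive(self):
        out = qvalues([_csm(f"s{i}", 10 - i) for i in range(5)], class_separate=False)
        assert all(c.q_value > 0 for c in out)

    def test_class_separation_isolates_crosslinked_matches(self):
        # decoys only in the linear class must not penalize the XL class
        csms = [_csm(f"x{i}", 5.0, xl=True) for i in range(4)]
        csms += [_csm(f"l{i}", 6.0, decoy=(i < 2)) for i in range(4)]
        out = qvalues(csms, class_separate=True)
        xl_q = sorted({c.q_value for c in out if c.is_crosslinked})
        assert xl_q == pytest.approx([1 / 4])


class TestRescore:
    def test_few_decoys_falls_back_to_main_score(self):
        csms = [_csm(f"s{i}", 10 - i, decoy=(i == 9)) for i in range(10)]
        with pytest.warns(UserWarning, match="decoys"):
            out = rescore(csms)
        assert all(c.combined_score == c.main_score for c in out)

    def test_perfect_separation_preserves_ranking(self):
        rng = np.random.default_rng(1)
        csms = []
        for i in range(120):
            decoy = i % 2 == 1
            score = (1.0 if decoy else 10.0) + rng.normal(0, 0.1)
            c = _csm(f"s{i}", score, decoy=decoy)
            c.subscores.frac_tic_explained = 0.1 if decoy else 0.9
            c.subscores.n_unshifted_b = 1 if decoy else 8
            csms.append(c)
        out = rescore(csms, seed=3)
        combined = sorted(out, key=lambda c: -c.combined_score)
        # every target outranks every decoy after rescoring as before
        first_decoy = next(i for i, c in enumerate(combined) if c.is_decoy)
        assert all(c.is_decoy for c in combined[first_decoy:][60:])
        n_targets_top = sum(not c.is_decoy for c in combined[:60])
        assert n_targets_top == 60

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        def make():
            out = []
            for i in range(150):
                decoy = i % 3 == 0
                c = _csm(f"s{i}", rng.normal(5 if not decoy else 2, 1), decoy=decoy)
                c.subscores.frac_tic_explained = float(rng.random())
                out.append(c)
            return out
        a = make()
        state = np.random.default_rng(2)
        b = [
            CSM(c.spectrum_id, c.candidate, SubscoreVector(**{
                f: getattr(c.subscores, f) for f in SubscoreVector.FEATURES}))
            for c in a
        ]
        ra = rescore(a, seed=11)
        rb = rescore(b, seed=11)
        assert [c.combined_score for c in ra] == [c.combined_score for c in rb]


class TestPeptideLevel:
    def test_best_csm_per_peptide_adduct_kept(self):
        csms = qvalues([_csm("s1", 10, seq="AAAAK"), _csm("s2", 8, seq="AAAAK")]
                       + [_csm(f"d{i}", 1, decoy=True, seq=f"CCCC{i}K"[:5]) for i in range(2)],
                       class_separate=False)
        out = peptide_level(csms, fdr=1.0, class_separate=False)
        rows = [c for c in out if c.candidate.peptide.sequence == "AAAAK"]
        assert len(rows) == 1 and rows[0].spectrum_id == "s1"

    def test_fdr_zero_admits_only_rows_above_all_decoys(self):
        csms = qvalues(
            [_csm("t1", 10), _csm("d1", 5, decoy=True), _csm("t2", 3)],
            class_separate=False)
        # with the +1 estimator no finite list reaches q = 0
        assert peptide_level(csms, fdr=0.0, class_separate=False) == []


class TestProteinInference:
    def test_disjoint_proteins_stay_separate(self):
        csms = [_csm("s1", 5, seq="AAAAK", accessions=("A",)),
                _csm("s2", 5, seq="CCCCK", accessions=("B",))]
        groups = protein_inference(csms)
        assert len(groups) == 2

    def test_identical_peptide_sets_merge(self):
        csms = [_csm("s1", 5, seq="AAAAK", accessions=("A", "B"))]
        (group,) = protein_inference(csms)
        assert group.accessions == ("A", "B")

    def test_subset_absorbed_by_greedy_cover(self):
        csms = [
            _csm("s1", 5, seq="AAAAK", accessions=("A",)),
            _csm("s2", 5, seq="CCCCK", accessions=("A", "B")),
        ]
        groups = protein_inference(csms)
        assert len(groups) == 1
        assert groups[0].n_unique_peptides == 2
        assert "A" in groups[0].accessions

    def test_csm_counts_accumulate(self):
        csms = [_csm(f"s{i}", 5, seq="AAAAK", accessions=("A",)) for i in range(3)]
        (group,) = protein_inference(csms)
        assert group.n_csms == 3 and group.n_unique_peptides == 1


def test_rank1_takes_top_hit_per_spectrum():
    results = {"s2": [_csm("s2", 9), _csm("s2", 5)], "s1": [_csm("s1", 7)], "s0": []}
    top = rank1(results)
    assert [c.spectrum_id for c in top] == ["s1", "s2"]
    assert top[1].main_score == 9
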