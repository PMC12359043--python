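"""Semi-supervised rescoring, target-decoy q-values and protein inference.

Subscores are combined by a Percolator-style iteration: positives are
initialized as targets passing 1% FDR on the main score against all decoys,
a regularized linear discriminant (logistic regression) is fitted per
cross-validation fold, held-out matches are scored by a model never trained
on their fold, positives are re-selected and the loop repeats.  The
combined score is the cross-validated discriminant value.

q-values use the (decoys + 1)/targets estimator with a running minimum from
the bottom of the ranked list, computed separately for crosslinked and
linear matches by default: the two classes have grossly different score
distributions and pooling is anti-conservative for the crosslinked class.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .search import CSM, SubscoreVector

MIN_DECOYS_FOR_RESCORING = 50
INIT_FDR = 0.01


def rank1(results: Dict[str, List[CSM]]) -> List[CSM]:
    """One rank-1 CSM per spectrum, in deterministic spectrum-id order."""
    return [csms[0] for _, csms in sorted(results.items()) if csms]


def _fold_of(spectrum_id: str, seed: int, n_folds: int) -> int:
    return zlib.crc32(f"{seed}:{spectrum_id}".encode()) % n_folds


def _qvalues_for_scores(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values over one class: FDR_i = (#decoys >= s_i + 1)/max(#targets >= s_i, 1),
    monotonized from the bottom."""
    order = np.argsort(-scores, kind="stable")
    n_decoys = np.cumsum(is_decoy[order])
    n_targets = np.cumsum(~is_decoy[order])
    fdr = (n_decoys + 1) / np.maximum(n_targets, 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _score_of(csm: CSM) -> float:
    return csm.combined_score if csm.combined_score is not None else csm.main_score


def qvalues(csms: Sequence[CSM], class_separate: bool = True) -> List[CSM]:
    """Attach q-values, within crosslinked/linear classes or pooled."""
    csms = list(csms)
    if not csms:
        return []
    scores = np.array([_score_of(c) for c in csms])
    decoys = np.array([c.is_decoy for c in csms])
    if class_separate:
        xl = np.array([c.is_crosslinked for c in csms])
        q = np.empty(len(csms))
        for mask in (xl, ~xl):
            if mask.any():
                q[mask] = _qvalues_for_scores(scores[mask], decoys[mask])
    else:
        q = _qvalues_for_scores(scores, decoys)
    for c, qv in zip(csms, q):
        c.q_value = float(qv)
    return csms


def rescore(
    csms: Sequence[CSM],
    n_folds: int = 3,
    n_iter: int = 3,
    seed: int = 0,
    class_separate: bool = True,
) -> List[CSM]:
    """Combine subscores into a cross-validated discriminant score.

    Falls back to the main score (with a warning) when there are fewer than
    50 decoys — the semi-supervised model is untrainable on such input.
    The main score itself competes as a candidate direction: if the learned
    discriminant admits fewer targets at 1% FDR than the main score alone,
    the main score is kept, so rescoring never loses identifications.
    Deterministic given the seed; fold assignment hashes the spectrum id.
    """
    csms = list(csms)
    n_decoys = sum(c.is_decoy for c in csms)
    if n_decoys < MIN_DECOYS_FOR_RESCORING:
        warnings.warn(
            f"only {n_decoys} decoys (< {MIN_DECOYS_FOR_RESCORING}); "
            "rescoring skipped, combined score = main score"
        )
        for c in csms:
            c.combined_score = c.main_score
        return csms

    X = np.vstack([c.subscores.as_array() for c in csms])
    y_decoy = np.array([c.is_decoy for c in csms])
    folds = np.array([_fold_of(c.spectrum_id, seed, n_folds) for c in csms])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xn = (X - mu) / sd
    main = np.array([c.main_score for c in csms])

    combined = np.array(main, dtype=np.float64)
    for fold in range(n_folds):
        train = folds != fold
        held = ~train
        if held.sum() == 0 or train.sum() == 0:
            continue
        scores = main[train]
        Xt, yt = Xn[train], y_decoy[train]
        model = None
        for _ in range(n_iter):
            q_sub = _qvalues_for_scores(scores, yt)
            positives = (~yt) & (q_sub <= INIT_FDR)
            if positives.sum() < 10:
                # too few confident targets: seed with the top-scoring decile
                order = np.argsort(-scores)
                top = order[~yt[order]][: max(10, int(0.1 * (~yt).sum()))]
                positives = np.zeros(len(scores), dtype=bool)
                positives[top] = True
            mask = positives | yt
            model = LogisticRegression(max_iter=1000, C=1.0)
            model.fit(Xt[mask], (~yt[mask]).astype(int))
            scores = model.decision_function(Xt)
        if model is not None:
            combined[held] = model.decision_function(Xn[held])
    def _n_accepted(scores: np.ndarray) -> int:
        n = 0
        xl = np.array([c.is_crosslinked for c in csms])
        for mask in (xl, ~xl) if class_separate else (np.ones(len(csms), bool),):
            if mask.any():
                q = _qvalues_for_scores(scores[mask], y_decoy[mask])
                n += int(((q <= INIT_FDR) & ~y_decoy[mask]).sum())
        return n

    if _n_accepted(combined) < _n_accepted(main):
        combined = main
    for c, s in zip(csms, combined):
        c.combined_score = float(s)
    return qvalues(csms, class_separate)


# ---------------------------------------------------------------------------
# Peptide-level results and protein inference
# ---------------------------------------------------------------------------

def peptide_level(csms: Sequence[CSM], fdr: float = 0.01, class_separate: bool = True) -> List[CSM]:
    """Best CSM per (peptide, adduct composition class), re-thresholded.

    The adduct class is the elemental composition, so exactly isobaric
    species (C-NH3 / U-H2O) collapse into one row.  q-values are recomputed
    on the reduced list and rows above ``fdr`` are dropped.
    """
    best: Dict[Tuple, CSM] = {}
    for c in csms:
        key = (
            c.candidate.peptide.sequence,
            c.candidate.peptide.mod_key,
            c.candidate.adduct.composition.formula(),
            c.is_decoy,
        )
        if key not in best or _score_of(c) > _score_of(best[key]):
            best[key] = c
    reduced = qvalues(list(best.values()), class_separate)
    return [c for c in reduced if c.q_value is not None and c.q_value <= fdr]


@dataclass
class ProteinGroup:
    accessions: Tuple[str, ...]
    peptides: Tuple[str, ...]
    n_unique_peptides: int
    n_csms: int
    is_decoy: bool


def protein_inference(csms: Sequence[CSM]) -> List[ProteinGroup]:
    """Greedy maximum-coverage protein grouping.

    Proteins with identical peptide sets merge into one group; remaining
    shared peptides are assigned to the group that explains the most
    still-unassigned peptides (ties to the lexicographically first
    accession tuple).  Counts are per assigned peptide.
    """
    pep_csms: Dict[Tuple[str, bool], int] = {}
    prot_peps: Dict[Tuple[str, bool], set] = {}
    for c in csms:
        pkey = (c.candidate.peptide.sequence, c.is_decoy)
        pep_csms[pkey] = pep_csms.get(pkey, 0) + 1
        for acc in c.candidate.peptide.accessions:
            prot_peps.setdefault((acc, c.is_decoy), set()).add(pkey)

    # merge proteins with identical peptide sets
    by_set: Dict[Tuple, List[Tuple[str, bool]]] = {}
    for key, peps in prot_peps.items():
        by_set.setdefault(tuple(sorted(peps)), []).append(key)

    groups = [
        (tuple(sorted(a for a, _ in accs)), set(peps), accs[0][1])
        for peps, accs in by_set.items()
    ]
    unassigned = set(pep_csms)
    out: List[ProteinGroup] = []
    while unassigned:
        groups.sort(key=lambda g: (-len(g[1] & unassigned), g[0]))
        accs, peps, is_decoy = groups[0]
        take = peps & unassigned
        if not take:
            break
        unassigned -= take
        seqs = tuple(sorted(s for s, _ in take))
        out.append(
            ProteinGroup(
                accessions=accs,
                peptides=seqs,
                n_unique_peptides=len(seqs),
                n_csms=sum(pep_csms[p] for p in take),
                is_decoy=is_decoy,
            )
        )
        groups.pop(0)
    return sorted(out, key=lambda g: (-g.n_csms, g.accessions))


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def csm_table(csms: Sequence[CSM]) -> pd.DataFrame:
    """CSM report with one row per match (1-based site in output)."""
    rows = []
    for c in csms:
        sub = c.subscores
        rows.append({
            "spectrum_id": c.spectrum_id,
            "peptide": c.candidate.peptide.sequence,
            "proteins": ";".join(sorted(c.candidate.peptide.accessions)),
            "adduct": c.candidate.adduct.name or "none",
            "adduct_mass": c.candidate.adduct.mass,
            "adduct_class": c.candidate.adduct.composition.formula(),
            "charge": sub.charge,
            "main_score": sub.main_score,
            "combined_score": _score_of(c),
            "n_unshifted_b": sub.n_unshifted_b, "n_unshifted_y": sub.n_unshifted_y,
            "n_shifted_b": sub.n_shifted_b, "n_shifted_y": sub.n_shifted_y,
            "frac_tic_explained": sub.frac_tic_explained,
            "marker_score": sub.marker_score,
            "precursor_evidence": sub.precursor_evidence,
            "mean_abs_ppm": sub.mean_abs_ppm,
            "longest_series": sub.longest_series,
            "best_site": (c.best_site + 1) if c.best_site is not None else 0,
            "loc_score": c.loc_score if c.loc_score is not None else "",
            "is_decoy": int(c.is_decoy),
            "is_xl": int(c.is_crosslinked),
            "q_value": c.q_value if c.q_value is not None else "",
        })
    return pd.DataFrame(rows)


def annotated_peaks_table(csm: CSM) -> pd.DataFrame:
    """Per-CSM sidecar of matched peaks for spectrum viewers."""
    return pd.DataFrame(
        [
            {
                "label": m.peak.label, "ion_type": m.peak.ion_type, "charge": m.peak.charge,
                "theoretical_mz": m.peak.mz, "observed_mz": m.observed_mz,
                "intensity": m.observed_intensity, "ppm_error": m.ppm_error,
                "shifted": int(m.peak.shifted),
            }
            for m in sorted(csm.matches, key=lambda m: m.observed_mz)
        ]
    )
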