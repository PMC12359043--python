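"""Candidate enumeration, theoretical spectra, spectrum matching and
crosslink-site localization.

The matcher scores a spectrum against a :class:`CrosslinkCandidate` (peptide
plus one precursor-adduct hypothesis) with a hyperscore-style main score —
``ln(Nb!) + ln(Ny!) + ln(1 + matched intensity fraction)`` with the
factorial arguments capped at 20 — where Nb/Ny count matched b/y ions over
both the unshifted and the adduct-shifted ladders.  A vector of subscores
(shifted/unshifted ion counts, explained intensity, marker-ion evidence,
precursor evidence, mass-error statistics, ladder length, and covariates)
feeds the downstream semi-supervised rescoring.

Localization assigns the crosslink to the residue whose adduct placement is
supported by the largest number of matched *site-determining* fragment
peaks: a matched peak counts for residue ``p`` when it is consistent with an
adduct at ``p`` (shifted fragments covering ``p``; unshifted fragments not
covering ``p``) and its presence is not implied by every alternative site.
A matched crosslinked immonium ion of the residue type at ``p`` adds one.
The localization score is the evidence margin between the best and
second-best site; a margin of at least 1 means one discriminating peak
separates them.
"""

from __future__ import annotations

import functools
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .chem import CO, PROTON, WATER, AA_RESIDUES, immonium_mz, mz as to_mz, neutral_mass
from .presets import (
    CrosslinkerPreset,
    PrecursorAdduct,
    fragment_adducts_for,
    marker_ions_for,
)
from .seqdb import PeptideCandidate

HYPERSCORE_FACTORIAL_CAP = 20
DEFAULT_PRECURSOR_TOL_PPM = 6.0
DEFAULT_FRAGMENT_TOL_PPM = 10.0

#: Residues whose (unmodified) immonium ions are generated.
IMMONIUM_RESIDUES = ("H", "M", "Y")


@dataclass(frozen=True)
class CrosslinkCandidate:
    peptide: PeptideCandidate
    adduct: PrecursorAdduct
    preset_id: str

    @functools.cached_property
    def total_mass(self) -> float:
        return self.peptide.mono_mass + self.adduct.mass

    @property
    def is_crosslinked(self) -> bool:
        return not self.adduct.is_empty

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    def key(self) -> Tuple:
        return (self.peptide.sequence, self.peptide.mod_key, self.adduct.name, self.peptide.is_decoy)


@dataclass(frozen=True)
class TheoreticalPeak:
    mz: float
    ion_type: str          # b | y | precursor | marker | immonium | immonium_xl
    index: int             # fragment ordinal (b_i / y_i), 0 otherwise
    charge: int
    shifted: bool          # carries a fragment adduct
    label: str
    covers: FrozenSet[int] = frozenset()    # residue indices covered by a fragment
    residue: str = ""                        # immonium residue type


@dataclass
class SubscoreVector:
    main_score: float = 0.0
    n_unshifted_b: int = 0
    n_unshifted_y: int = 0
    n_shifted_b: int = 0
    n_shifted_y: int = 0
    frac_tic_explained: float = 0.0
    marker_score: float = 0.0
    precursor_evidence: int = 0
    mean_abs_ppm: float = 0.0
    longest_series: int = 0
    peptide_length: int = 0
    charge: int = 0
    missed_cleavages: int = 0
    adduct_mass: float = 0.0
    is_xl: int = 0

    FEATURES = (
        "main_score", "n_unshifted_b", "n_unshifted_y", "n_shifted_b", "n_shifted_y",
        "frac_tic_explained", "marker_score", "precursor_evidence", "mean_abs_ppm",
        "longest_series", "peptide_length", "charge", "missed_cleavages",
        "adduct_mass", "is_xl",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FEATURES], dtype=np.float64)


@dataclass
class MatchedPeak:
    peak: TheoreticalPeak
    observed_mz: float
    observed_intensity: float
    ppm_error: float


@dataclass
class CSM:
    """A scored crosslink-spectrum match."""

    spectrum_id: str
    candidate: CrosslinkCandidate
    subscores: SubscoreVector
    matches: List[MatchedPeak] = field(default_factory=list)
    rank: int = 0
    site_scores: Optional[np.ndarray] = None
    best_site: Optional[int] = None          # 0-based residue index
    loc_score: Optional[float] = None
    combined_score: Optional[float] = None
    q_value: Optional[float] = None

    @property
    def is_decoy(self) -> bool:
        return self.candidate.is_decoy

    @property
    def is_crosslinked(self) -> bool:
        return self.candidate.is_crosslinked

    @property
    def main_score(self) -> float:
        return self.subscores.main_score


# ---------------------------------------------------------------------------
# Candidate index
# ---------------------------------------------------------------------------

class CandidateIndex:
    """Mass-sorted index of peptide x precursor-adduct candidates,
    binary-searchable by neutral mass within a ppm window."""

    def __init__(self, candidates: Sequence[CrosslinkCandidate]):
        ordered = sorted(candidates, key=lambda c: c.total_mass)
        self._candidates: List[CrosslinkCandidate] = ordered
        self._masses: List[float] = [c.total_mass for c in ordered]

    def __len__(self) -> int:
        return len(self._candidates)

    def __iter__(self):
        return iter(self._candidates)

    def query(self, neutral: float, tol_ppm: float) -> List[CrosslinkCandidate]:
        delta = neutral * tol_ppm * 1e-6
        lo = bisect_left(self._masses, neutral - delta)
        hi = bisect_right(self._masses, neutral + delta)
        return self._candidates[lo:hi]


def build_candidate_index(
    peptides: Sequence[PeptideCandidate],
    preset: CrosslinkerPreset,
    adducts: Sequence[PrecursorAdduct],
) -> CandidateIndex:
    """Cartesian product of peptides and precursor adducts, mass-indexed."""
    return CandidateIndex(
        [CrosslinkCandidate(p, a, preset.id) for p in peptides for a in adducts]
    )


# ---------------------------------------------------------------------------
# Theoretical spectrum generation
# ---------------------------------------------------------------------------

def _residue_masses(peptide: PeptideCandidate) -> List[float]:
    masses = [AA_RESIDUES[aa].mass for aa in peptide.sequence]
    for mod in peptide.modifications:
        masses[mod.position] += mod.mass_delta
    return masses


def theoretical_peaks(
    candidate: CrosslinkCandidate,
    preset: CrosslinkerPreset,
    precursor_charge: int = 2,
    site: Optional[int] = None,
) -> List[TheoreticalPeak]:
    """All expected peaks for a candidate at a given precursor charge.

    Unshifted b/y ions at fragment charges 1..min(z-1, 2); for crosslinked
    candidates additionally b/y ions shifted by each legal fragment adduct —
    restricted, when ``site`` is set, to fragments containing the site —
    plus marker ions, precursor(+loss) peaks at the observed charge, and
    (crosslinked) immonium ions.
    """
    pep = candidate.peptide
    n = len(pep.sequence)
    if site is not None and not (0 <= site < n):
        raise IndexError(f"site {site} out of range for peptide of length {n}")
    res = _residue_masses(pep)
    prefix = np.cumsum(res)            # prefix[i-1] = mass of residues 0..i-1
    total = prefix[-1]
    frag_charges = range(1, max(1, min(precursor_charge - 1, 2)) + 1)

    frag_adducts = fragment_adducts_for(preset, candidate.adduct) if candidate.is_crosslinked else []

    peaks: List[TheoreticalPeak] = []
    for i in range(1, n):
        b_neutral = prefix[i - 1]                  # b ion: residues minus OH, i.e. sum residues
        y_neutral = total - prefix[i - 1] + WATER.mass
        covers_b = frozenset(range(i))
        covers_y = frozenset(range(i, n))
        for z in frag_charges:
            peaks.append(TheoreticalPeak(
                to_mz(b_neutral, z), "b", i, z, False, f"b{i}^{z}", covers_b))
            peaks.append(TheoreticalPeak(
                to_mz(y_neutral, z), "y", n - i, z, False, f"y{n-i}^{z}", covers_y))
            for fa in frag_adducts:
                if site is None or site in covers_b:
                    peaks.append(TheoreticalPeak(
                        to_mz(b_neutral + fa.mass, z), "b", i, z, True,
                        f"b{i}+{fa.name}^{z}", covers_b))
                if site is None or site in covers_y:
                    peaks.append(TheoreticalPeak(
                        to_mz(y_neutral + fa.mass, z), "y", n - i, z, True,
                        f"y{n-i}+{fa.name}^{z}", covers_y))

    # marker ions (singly charged, peptide-independent)
    for name, mz_val in marker_ions_for(preset, candidate.adduct):
        peaks.append(TheoreticalPeak(mz_val, "marker", 0, 1, True, name))

    # precursor with each legal loss at the observed charge
    pmass = candidate.total_mass
    z = precursor_charge
    peaks.append(TheoreticalPeak(to_mz(pmass, z), "precursor", 0, z, False, f"[M+{z}H]"))
    losses = [("H2O", WATER.mass), ("NH3", 17.0265491015)]
    if "M" in pep.sequence:
        losses += [(name, comp.mass) for name, comp in preset.met_losses]
    for lname, lmass in losses:
        peaks.append(TheoreticalPeak(
            to_mz(pmass - lmass, z), "precursor", 0, z, False, f"[M-{lname}+{z}H]"))

    # immonium ions and crosslinked variants
    present = set(pep.sequence)
    for r in IMMONIUM_RESIDUES:
        if r in present:
            peaks.append(TheoreticalPeak(immonium_mz(r), "immonium", 0, 1, False, f"i{r}", residue=r))
    if candidate.is_crosslinked:
        for r in sorted(preset.reactive_residues & present):
            if site is not None and pep.sequence[site] != r:
                continue
            for fa in frag_adducts:
                peaks.append(TheoreticalPeak(
                    immonium_mz(r, fa.mass), "immonium_xl", 0, 1, True,
                    f"i{r}+{fa.name}", residue=r))
    return peaks


# ---------------------------------------------------------------------------
# Matching and scoring
# ---------------------------------------------------------------------------

def _greedy_match(
    peaks: Sequence[TheoreticalPeak],
    mz_arr: np.ndarray,
    intensity: np.ndarray,
    tol_ppm: float,
) -> List[MatchedPeak]:
    """Greedy nearest-ppm assignment; each observed and each theoretical
    peak is used at most once."""
    pairs = []
    for t_idx, peak in enumerate(peaks):
        tol = peak.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz_arr, peak.mz - tol, side="left")
        hi = np.searchsorted(mz_arr, peak.mz + tol, side="right")
        for o_idx in range(lo, hi):
            ppm = (mz_arr[o_idx] - peak.mz) / peak.mz * 1e6
            pairs.append((abs(ppm), t_idx, o_idx, ppm))
    pairs.sort()
    used_t: set = set()
    used_o: set = set()
    out: List[MatchedPeak] = []
    for _, t_idx, o_idx, ppm in pairs:
        if t_idx in used_t or o_idx in used_o:
            continue
        used_t.add(t_idx)
        used_o.add(o_idx)
        out.append(MatchedPeak(peaks[t_idx], float(mz_arr[o_idx]), float(intensity[o_idx]), ppm))
    return out


def _ln_factorial_capped(n: int) -> float:
    return math.lgamma(min(n, HYPERSCORE_FACTORIAL_CAP) + 1)


def _longest_run(indices: Sequence[int]) -> int:
    if not indices:
        return 0
    vals = sorted(set(indices))
    best = run = 1
    for a, b in zip(vals, vals[1:]):
        run = run + 1 if b == a + 1 else 1
        best = max(best, run)
    return best


def match_and_score(
    spectrum,
    candidate: CrosslinkCandidate,
    preset: CrosslinkerPreset,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    precursor_tol_ppm: Optional[float] = DEFAULT_PRECURSOR_TOL_PPM,
) -> Optional[CSM]:
    """Match a spectrum against one candidate and fill the subscore vector.

    Returns None when the observed neutral mass is outside the precursor
    tolerance (the candidate is not a legal explanation of the spectrum).
    """
    z = spectrum.precursor_charge or 2
    if precursor_tol_ppm is not None:
        observed = neutral_mass(spectrum.precursor_mz, z)
        if abs(observed - candidate.total_mass) > candidate.total_mass * precursor_tol_ppm * 1e-6:
            return None

    peaks = theoretical_peaks(candidate, preset, z)
    matches = _greedy_match(peaks, spectrum.mz, spectrum.intensity, frag_tol_ppm)

    sub = SubscoreVector(
        peptide_length=len(candidate.peptide.sequence),
        charge=z,
        missed_cleavages=candidate.peptide.missed_cleavages,
        adduct_mass=candidate.adduct.mass,
        is_xl=int(candidate.is_crosslinked),
    )
    tic = spectrum.tic
    matched_intensity = 0.0
    b_idx, y_idx = [], []
    abs_ppms = []
    for m in matches:
        p = m.peak
        abs_ppms.append(abs(m.ppm_error))
        if p.ion_type in ("b", "y"):
            matched_intensity += m.observed_intensity
            if p.ion_type == "b":
                b_idx.append(p.index)
                if p.shifted:
                    sub.n_shifted_b += 1
                else:
                    sub.n_unshifted_b += 1
            else:
                y_idx.append(p.index)
                if p.shifted:
                    sub.n_shifted_y += 1
                else:
                    sub.n_unshifted_y += 1
        elif p.ion_type == "marker":
            sub.marker_score += 1.0
            matched_intensity += m.observed_intensity
        elif p.ion_type == "precursor":
            sub.precursor_evidence += 1
            matched_intensity += m.observed_intensity
        elif p.ion_type in ("immonium", "immonium_xl"):
            matched_intensity += m.observed_intensity
    nb = sub.n_unshifted_b + sub.n_shifted_b
    ny = sub.n_unshifted_y + sub.n_shifted_y
    frac = matched_intensity / tic if tic > 0 else 0.0
    sub.frac_tic_explained = min(frac, 1.0)
    sub.main_score = _ln_factorial_capped(nb) + _ln_factorial_capped(ny) + math.log1p(frac)
    sub.mean_abs_ppm = float(np.mean(abs_ppms)) if abs_ppms else 0.0
    sub.longest_series = max(_longest_run(b_idx), _longest_run(y_idx))
    return CSM(spectrum_id=spectrum.native_id, candidate=candidate, subscores=sub, matches=matches)


def search(
    spectra,
    index: CandidateIndex,
    preset: CrosslinkerPreset,
    precursor_tol_ppm: float = DEFAULT_PRECURSOR_TOL_PPM,
    frag_tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
    charges: Sequence[int] = (2, 3, 4, 5, 6),
    max_rank: int = 5,
) -> Dict[str, List[CSM]]:
    """Score every candidate within precursor tolerance for every spectrum.

    Spectra with an annotated precursor charge are searched at that charge;
    unannotated spectra are tried at every charge in ``charges``.  Linear
    and crosslinked candidates compete in the same ranked list.  Ties on the
    main score are broken by more matched peaks, then lexicographic peptide.
    """
    results: Dict[str, List[CSM]] = {}
    for spectrum in spectra:
        if spectrum.is_empty():
            results[spectrum.native_id] = []
            continue
        zs = [spectrum.precursor_charge] if spectrum.precursor_charge else list(charges)
        csms: List[CSM] = []
        for z in zs:
            trial = replace(spectrum, precursor_charge=z) if z != spectrum.precursor_charge else spectrum
            observed = neutral_mass(spectrum.precursor_mz, z)
            for candidate in index.query(observed, precursor_tol_ppm):
                csm = match_and_score(trial, candidate, preset, frag_tol_ppm, precursor_tol_ppm)
                if csm is not None:
                    csms.append(csm)
        csms.sort(key=lambda c: (-c.main_score, -len(c.matches), c.candidate.peptide.sequence,
                                 c.candidate.adduct.name, c.is_decoy))
        for r, csm in enumerate(csms[:max_rank], start=1):
            csm.rank = r
        results[spectrum.native_id] = csms[:max_rank]
    return results


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------

def localize(csm: CSM, preset: CrosslinkerPreset) -> CSM:
    """Score every residue as the crosslink site and keep the best.

    All residues are enumerated (not only chemically plausible ones).  A
    matched fragment peak contributes to site ``p`` when it is consistent
    with an adduct at ``p`` and is site-determining, i.e. at least one
    alternative site is inconsistent with it.  Matched crosslinked immonium
    ions add 1 to every residue of their type.  The localization score is
    E(best) - E(second best); exact ties leave the site unset.
    """
    if not csm.is_crosslinked or not preset.fragmentation_stable or csm.candidate.adduct.is_sugar_phosphate:
        return csm
    n = len(csm.candidate.peptide.sequence)
    if n == 0:
        return csm
    evidence = np.zeros(n, dtype=np.float64)
    seq = csm.candidate.peptide.sequence
    all_sites = frozenset(range(n))
    for m in csm.matches:
        p = m.peak
        if p.ion_type in ("b", "y"):
            consistent = p.covers if p.shifted else (all_sites - p.covers)
            if consistent and consistent != all_sites:
                for s in consistent:
                    evidence[s] += 1.0
        elif p.ion_type == "immonium_xl":
            for s in range(n):
                if seq[s] == p.residue:
                    evidence[s] += 1.0
    csm.site_scores = evidence
    order = np.argsort(-evidence, kind="stable")
    best, second = int(order[0]), int(order[1]) if n > 1 else int(order[0])
    margin = float(evidence[best] - evidence[second]) if n > 1 else float(evidence[best])
    if n > 1 and evidence[best] == evidence[second]:
        csm.best_site = None
        csm.loc_score = 0.0
    else:
        csm.best_site = best
        csm.loc_score = margin
    return csm
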