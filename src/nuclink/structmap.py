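"""Map localized crosslink sites onto 3D structures.

Implements the distance-based model-validation protocol: for each crosslink
site, the Euclidean distance from the protein residue's C-alpha to nucleic
acid is measured either to the base nitrogen that carries the crosslink
chemistry (N3 for pyrimidines, N7 for purines; ``mode="n3n7"``) or to the
closest atom of the closest nucleotide (``mode="closest_atom"``).  Sites are
tallied against crosslinker-specific distance thresholds (UV 10 A, DEB and
NM 15 A) with incremental slacks of 0/2/3/5 A: SINGLE counts sites whose
*nearest* nucleotide is within threshold+slack, ALL counts every
(site, nucleotide) pair within it.  Alternative models of the same complex
are ranked by how many of their eight occurrence columns (d0,d2,d3,d5,
ALLd0,ALLd2,ALLd3,ALLd5) reach the column maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS: Dict[str, float] = {"UV": 10.0, "DEB": 15.0, "NM": 15.0}
DEFAULT_SLACKS: Tuple[float, ...] = (0.0, 2.0, 3.0, 5.0)
DEFAULT_MIN_CSM_COUNT = 3  # "CSM count > 2"

_PYRIMIDINES = {"U", "C", "DT", "DC", "DU", "T", "PSU"}
_RNA_NAMES = {"A", "C", "G", "U", "I", "PSU"}
_DNA_NAMES = {"DA", "DC", "DG", "DT", "DU", "DI"}


class MissingAtomError(ValueError):
    """A required atom (C-alpha or designated base nitrogen) is absent."""


@dataclass(frozen=True)
class XLSiteRecord:
    """One localized crosslink site on a protein chain (1-based numbering)."""

    chain: str
    resnum: int
    residue: str
    crosslinker: str          # UV | DEB | NM
    csm_count: int = 1
    loc_score: float = 0.0

    def __post_init__(self):
        if self.csm_count < 1:
            raise ValueError("csm_count must be >= 1")


@dataclass
class ModelScore:
    model_id: str
    single: Dict[float, int] = field(default_factory=dict)   # slack -> SINGLE count
    all_: Dict[float, int] = field(default_factory=dict)     # slack -> ALL count
    rank_score: int = 0

    def columns(self, slacks: Sequence[float] = DEFAULT_SLACKS) -> List[int]:
        return [self.single[s] for s in slacks] + [self.all_[s] for s in slacks]

    def total(self, slacks: Sequence[float] = DEFAULT_SLACKS) -> int:
        return sum(self.columns(slacks))


def residue_kind(res: gemmi.Residue) -> str:
    name = res.name.strip().upper()
    if name in _DNA_NAMES:
        return "nucleotide-DNA"
    if name in _RNA_NAMES:
        return "nucleotide-RNA"
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "amino-acid"
        if info.is_nucleic_acid():
            return "nucleotide-DNA" if name.startswith("D") else "nucleotide-RNA"
    return "other"


def _designated_nitrogen(res: gemmi.Residue) -> str:
    return "N3" if res.name.strip().upper() in _PYRIMIDINES else "N7"


def _best_altloc_atom(res: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """Atom by name, highest-occupancy conformer when altlocs exist."""
    best = None
    for atom in res:
        if atom.name == name and (best is None or atom.occ > best.occ):
            best = atom
    return best


class StructureModel:
    """Thin wrapper over a gemmi structure (first model only)."""

    def __init__(self, structure: gemmi.Structure, model_id: Optional[str] = None):
        self.structure = structure
        self.model_id = model_id or structure.name or "model"
        self._model = structure[0]
        self._nucleotides: List[Tuple[str, gemmi.Residue]] = []
        for chain in self._model:
            for res in chain:
                if residue_kind(res).startswith("nucleotide"):
                    self._nucleotides.append((chain.name, res))

    @classmethod
    def from_file(cls, path: str, model_id: Optional[str] = None) -> "StructureModel":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls(st, model_id or str(path))

    @property
    def nucleotides(self) -> List[Tuple[str, gemmi.Residue]]:
        return self._nucleotides

    def find_residue(self, chain_name: str, resnum: int) -> Optional[gemmi.Residue]:
        for chain in self._model:
            if chain.name != chain_name:
                continue
            for res in chain:
                if res.seqid.num == resnum:
                    return res
        return None

    def ca_position(self, chain_name: str, resnum: int) -> np.ndarray:
        res = self.find_residue(chain_name, resnum)
        if res is None:
            raise MissingAtomError(f"residue {chain_name}/{resnum} not in model {self.model_id}")
        ca = _best_altloc_atom(res, "CA")
        if ca is None:
            raise MissingAtomError(f"no C-alpha for {chain_name}/{resnum} in model {self.model_id}")
        return np.array([ca.pos.x, ca.pos.y, ca.pos.z])


def _nucleotide_distance(ca: np.ndarray, res: gemmi.Residue, mode: str) -> Optional[float]:
    """Distance from a C-alpha to one nucleotide residue, or None if the
    designated atom is missing (n3n7 mode)."""
    if mode == "n3n7":
        atom = _best_altloc_atom(res, _designated_nitrogen(res))
        if atom is None:
            return None
        d = ca - np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        return float(np.sqrt(d @ d))
    if mode == "closest_atom":
        best = None
        for atom in res:
            d = ca - np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            dist = float(np.sqrt(d @ d))
            if best is None or dist < best:
                best = dist
        return best
    raise ValueError(f"unknown distance mode {mode!r}; use 'n3n7' or 'closest_atom'")


def site_nucleotide_distances(
    model: StructureModel, site: XLSiteRecord, mode: str
) -> List[Tuple[float, str]]:
    """Distances from a site's C-alpha to every nucleotide residue, as
    (distance, nucleotide id) sorted ascending."""
    if not model.nucleotides:
        raise MissingAtomError(f"no nucleotide residues in model {model.model_id}")
    ca = model.ca_position(site.chain, site.resnum)
    out = []
    for chain_name, res in model.nucleotides:
        dist = _nucleotide_distance(ca, res, mode)
        if dist is not None:
            out.append((dist, f"{chain_name}/{res.name}{res.seqid.num}"))
    if not out:
        raise MissingAtomError(
            f"no nucleotide exposes the designated atom for site {site.chain}/{site.resnum}"
        )
    out.sort()
    return out


def site_distance(model: StructureModel, site: XLSiteRecord, mode: str) -> Tuple[float, str]:
    """Shortest site-to-nucleotide distance and the minimizing nucleotide."""
    return site_nucleotide_distances(model, site, mode)[0]


def filter_sites(
    sites: Sequence[XLSiteRecord],
    min_csm_count: int = DEFAULT_MIN_CSM_COUNT,
    min_loc_score: Optional[float] = None,
) -> List[XLSiteRecord]:
    """Site pre-filters: CSM count (validation protocol, default > 2) and/or
    localization score (survey filter, e.g. >= 1); both independent."""
    out = [s for s in sites if s.csm_count >= min_csm_count]
    if min_loc_score is not None:
        out = [s for s in out if s.loc_score >= min_loc_score]
    return out


def count_occurrences(
    model: StructureModel,
    sites: Sequence[XLSiteRecord],
    thresholds: Dict[str, float] = DEFAULT_THRESHOLDS,
    slacks: Sequence[float] = DEFAULT_SLACKS,
    mode: str = "n3n7",
) -> ModelScore:
    """SINGLE and ALL crosslink-occurrence counts for one model.

    SINGLE(dk): sites whose nearest nucleotide lies within
    threshold(crosslinker)+slack_k.  ALL(dk): all (site, nucleotide) pairs
    within it, one count per nucleotide residue.  Sites with missing atoms
    are skipped with a warning.
    """
    score = ModelScore(model_id=model.model_id,
                       single={s: 0 for s in slacks}, all_={s: 0 for s in slacks})
    for site in sites:
        thr = thresholds.get(site.crosslinker)
        if thr is None:
            warnings.warn(f"no distance threshold for crosslinker {site.crosslinker!r}; site skipped")
            continue
        try:
            dists = site_nucleotide_distances(model, site, mode)
        except MissingAtomError as exc:
            warnings.warn(str(exc))
            continue
        nearest = dists[0][0]
        for slack in slacks:
            if nearest <= thr + slack:
                score.single[slack] += 1
            score.all_[slack] += sum(1 for d, _ in dists if d <= thr + slack)
    return score


def rank_models(scores: Sequence[ModelScore], slacks: Sequence[float] = DEFAULT_SLACKS) -> List[ModelScore]:
    """Rank models by agreement with the per-column maxima.

    Column maxima are taken over all eight occurrence columns; each model's
    rank score is the number of its columns equal to the maximum.  Ties are
    broken by total occurrence sum, then model id.  The ranking is invariant
    to the input order.
    """
    if not scores:
        raise ValueError("rank_models requires at least one model")
    table = np.array([s.columns(slacks) for s in scores], dtype=np.int64)
    maxima = table.max(axis=0)
    ranked = []
    for s, row in zip(scores, table):
        s.rank_score = int((row == maxima).sum())
        ranked.append(s)
    return sorted(ranked, key=lambda s: (-s.rank_score, -s.total(slacks), s.model_id))


def median_site_distance(
    model: StructureModel,
    sites: Sequence[XLSiteRecord],
    mode: str = "closest_atom",
    thresholds: Dict[str, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-crosslinker median of nearest-nucleotide distances.

    Returns a per-site table with columns (chain, resnum, residue,
    crosslinker, distance, nucleotide, beyond_cap) — sites beyond the
    crosslinker's acceptance cap are flagged but included — plus the
    medians, accessible via ``df.groupby("crosslinker")["distance"].median()``.
    """
    rows = []
    for site in sites:
        try:
            dist, nuc = site_distance(model, site, mode)
        except MissingAtomError as exc:
            warnings.warn(str(exc))
            continue
        cap = thresholds.get(site.crosslinker, math.inf)
        rows.append({
            "chain": site.chain, "resnum": site.resnum, "residue": site.residue,
            "crosslinker": site.crosslinker, "distance": dist, "nucleotide": nuc,
            "beyond_cap": dist > cap,
        })
    return pd.DataFrame(rows, columns=["chain", "resnum", "residue", "crosslinker",
                                       "distance", "nucleotide", "beyond_cap"])


# ---------------------------------------------------------------------------
# Site-table I/O (TSV)
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chain", "resnum", "residue", "crosslinker", "csm_count", "loc_score"]


def read_sites(path: str) -> List[XLSiteRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SITE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns {sorted(missing)}")
    return [
        XLSiteRecord(
            chain=str(r["chain"]), resnum=int(r["resnum"]), residue=str(r["residue"]),
            crosslinker=str(r["crosslinker"]),
            csm_count=int(r.get("csm_count", 1)) if "csm_count" in df.columns else 1,
            loc_score=float(r.get("loc_score", 0.0)) if "loc_score" in df.columns else 0.0,
        )
        for _, r in df.iterrows()
    ]


def write_sites(path: str, sites: Sequence[XLSiteRecord]) -> None:
    pd.DataFrame([s.__dict__ for s in sites], columns=SITE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
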