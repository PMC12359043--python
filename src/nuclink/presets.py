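"""Crosslinker presets: the rule sets relating precursor adducts, fragment
adducts and marker ions for one crosslinker / nucleic-acid combination.

A preset answers three questions during search:

* which (oligo)nucleotide mass adducts may sit on an intact crosslinked
  peptide (``enumerate_precursor_adducts``),
* which smaller adduct species a backbone fragment ion may carry, given the
  precursor adduct (``fragment_adducts_for``) — always an elemental
  sub-multiset of the precursor adduct,
* which singly charged low-mass marker ions the spectrum should contain
  (``marker_ions_for``).

Eight default presets ship: {RNA,DNA} x {UV, DEB, NM, FA}.  UV crosslinks are
zero-length (empty remnant); the alkylating crosslinkers leave a remnant
bridging peptide and nucleotide: DEB C4H6O2 (diepoxybutane, ring-opened), NM
C5H9N (mechlorethamine minus 2 HCl), FA a single carbon (net methylene
bridge, CH2O minus H2O).  Formaldehyde crosslinks do not survive
fragmentation, so FA presets emit marker ions only and map every precursor
adduct to an empty fragment-adduct set.  4SU/6SG ids are declared stubs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import yaml

from .chem import (
    EMPTY,
    NMP,
    NUCLEOBASES,
    ElementalComposition,
    immonium_mz,
    mz,
)

_p = ElementalComposition.parse

KLASSES = ("nucleotide", "nucleoside", "nucleobase", "remnant", "loss", "sugar-phosphate")


@dataclass(frozen=True)
class AdductSpecies:
    """One named species usable as precursor/fragment adduct or marker."""

    name: str
    composition: ElementalComposition
    klass: str

    def __post_init__(self):
        if self.klass not in KLASSES:
            raise ValueError(f"unknown species klass {self.klass!r}")
        self.composition.finalize()

    @property
    def mass(self) -> float:
        return self.composition.mass


@dataclass(frozen=True)
class LossSpec:
    """A neutral loss and the nucleotide codes it may be taken from.

    ``applies_to`` containing ``"any"`` means the loss is legal for every
    adduct (phosphate chemistry); otherwise the adduct must contain one of
    the listed codes.
    """

    name: str
    composition: ElementalComposition
    applies_to: FrozenSet[str]

    def legal_for(self, codes: Sequence[str]) -> bool:
        return "any" in self.applies_to or any(c in self.applies_to for c in codes)


@dataclass(frozen=True)
class PrecursorAdduct:
    """One precursor-adduct hypothesis: nucleotide multiset, losses, mass.

    Exactly isobaric adducts (identical elemental composition, e.g.
    cytidine-NH3 and uridine-H2O) are merged into a single ambiguity-class
    entry whose name joins the member names with ``/`` and whose
    ``variants`` carry each member's (nucleotides, losses) for fragment and
    marker generation.  No mass measurement can separate the members, so
    one candidate with the union of their diagnostic species is both honest
    and cheaper to search.
    """

    name: str
    nucleotides: Tuple[str, ...]  # sorted codes; () for the linear peptide
    losses: Tuple[str, ...]
    composition: ElementalComposition
    is_sugar_phosphate: bool = False
    variants: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...] = ()

    def member_variants(self):
        return self.variants or ((self.nucleotides, self.losses),)

    @property
    def mass(self) -> float:
        return self.composition.mass

    @property
    def is_empty(self) -> bool:
        return self.composition.is_empty()

    def matches_name(self, name: str) -> bool:
        return name == self.name or name in self.name.split("/")


@dataclass(frozen=True)
class CrosslinkerPreset:
    id: str
    nucleic_type: str                     # "RNA" | "DNA"
    alphabet: Tuple[str, ...]             # nucleotide codes usable in adducts
    remnant: ElementalComposition         # EMPTY for UV
    remnant_name: str                     # "" for UV
    losses: Tuple[LossSpec, ...]
    max_adduct_length: int
    fragmentation_stable: bool
    reactive_residues: FrozenSet[str]     # residues with crosslinked immonium ions
    met_losses: Tuple[Tuple[str, ElementalComposition], ...] = ()
    sugar_phosphate_adducts: Tuple[AdductSpecies, ...] = ()
    include_remnant_only: bool = False    # hydrolyzed mono-link precursors
    max_losses_per_adduct: int = 2
    experimental: bool = False

    # -- species table ------------------------------------------------------
    def nucleotide_species(self, code: str) -> AdductSpecies:
        return AdductSpecies(code, NMP[code], "nucleotide")

    def base_species(self, code: str) -> AdductSpecies:
        return AdductSpecies(code + "'", NUCLEOBASES[code], "nucleobase")

    def _with_remnant(self, sp: AdductSpecies) -> AdductSpecies:
        if self.remnant.is_empty():
            return sp
        return AdductSpecies(f"{self.remnant_name}+{sp.name}", self.remnant + sp.composition, sp.klass)


class PresetError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Default preset table
# ---------------------------------------------------------------------------

_H2O, _NH3, _HPO3, _H3PO4 = _p("H2O"), _p("NH3"), _p("HPO3"), _p("H3PO4")
_CH4S, _C2H2S = _p("CH4S"), _p("C2H2S")

_RNA_ALPHABET = ("A", "C", "G", "U")
_DNA_ALPHABET = ("dA", "dC", "dG", "dT")


def _rna_losses() -> Tuple[LossSpec, ...]:
    return (
        LossSpec("H2O", _H2O, frozenset({"U"})),
        LossSpec("NH3", _NH3, frozenset({"C"})),
        LossSpec("HPO3", _HPO3, frozenset({"any"})),
        LossSpec("H3PO4", _H3PO4, frozenset({"any"})),
    )


def _dna_losses() -> Tuple[LossSpec, ...]:
    return (
        LossSpec("H2O", _H2O, frozenset({"dT"})),
        LossSpec("NH3", _NH3, frozenset({"dC"})),
        LossSpec("HPO3", _HPO3, frozenset({"any"})),
        LossSpec("H3PO4", _H3PO4, frozenset({"any"})),
    )


_SUGAR_PHOSPHATE = (
    AdductSpecies("d", _p("C5H9O6P"), "sugar-phosphate"),
    AdductSpecies("d-H2O", _p("C5H7O5P"), "sugar-phosphate"),
)

_REMNANTS = {
    "UV": ("", EMPTY),
    "DEB": ("DEB", _p("C4H6O2")),
    "NM": ("NM", _p("C5H9N")),
    "FA": ("FA", _p("C")),
}


def _build_default(preset_id: str) -> CrosslinkerPreset:
    nucleic, linker = preset_id.split("-")
    rname, remnant = _REMNANTS[linker]
    is_dna = nucleic == "DNA"
    reactive = {
        "UV": frozenset({"Y"}),
        "DEB": frozenset({"H", "M"}),
        "NM": frozenset({"H", "M"}),
        "FA": frozenset(),
    }[linker]
    return CrosslinkerPreset(
        id=preset_id,
        nucleic_type=nucleic,
        alphabet=_DNA_ALPHABET if is_dna else _RNA_ALPHABET,
        remnant=remnant,
        remnant_name=rname,
        losses=_dna_losses() if is_dna else _rna_losses(),
        max_adduct_length=3,
        fragmentation_stable=linker != "FA",
        reactive_residues=reactive,
        met_losses=(("CH4S", _CH4S), ("C2H2S", _C2H2S)) if linker in ("DEB", "NM") else (),
        sugar_phosphate_adducts=_SUGAR_PHOSPHATE if is_dna else (),
    )


DEFAULT_PRESET_IDS = tuple(
    f"{na}-{xl}" for na in ("RNA", "DNA") for xl in ("UV", "DEB", "NM", "FA")
)

#: Declared-but-empty experimental presets (thio-nucleoside photo-chemistry).
STUB_PRESET_IDS = ("RNA-4SU", "RNA-6SG")


def get_preset(preset_id: str) -> CrosslinkerPreset:
    """Return a default preset by id, e.g. ``"RNA-UV"``."""
    if preset_id in DEFAULT_PRESET_IDS:
        return _build_default(preset_id)
    if preset_id in STUB_PRESET_IDS:
        base = _build_default("RNA-UV")
        return replace(base, id=preset_id, experimental=True)
    raise PresetError(f"unknown preset id {preset_id!r}; known: {DEFAULT_PRESET_IDS + STUB_PRESET_IDS}")


def load_preset(preset_id: str, config_path: Optional[str] = None) -> CrosslinkerPreset:
    """Load a preset, merging a user YAML config over the defaults.

    Recognized keys (all optional): ``alphabet``, ``remnant`` (formula),
    ``remnant_name``, ``max_adduct_length``, ``include_remnant_only``,
    ``fragmentation_stable``, ``losses`` (list of ``{name, formula,
    applies_to}``), ``reactive_residues``.
    """
    preset = get_preset(preset_id)
    if config_path is None:
        return preset
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    section = cfg.get(preset_id, cfg)
    kw = {}
    if "alphabet" in section:
        kw["alphabet"] = tuple(section["alphabet"])
    if "remnant" in section:
        kw["remnant"] = _p(section["remnant"])
    if "remnant_name" in section:
        kw["remnant_name"] = section["remnant_name"]
    for key in ("max_adduct_length", "include_remnant_only", "fragmentation_stable"):
        if key in section:
            kw[key] = section[key]
    if "reactive_residues" in section:
        kw["reactive_residues"] = frozenset(section["reactive_residues"])
    if "losses" in section:
        kw["losses"] = tuple(
            LossSpec(l["name"], _p(l["formula"]), frozenset(l.get("applies_to", ["any"])))
            for l in section["losses"]
        )
    return replace(preset, **kw)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

EMPTY_ADDUCT = PrecursorAdduct(name="", nucleotides=(), losses=(), composition=EMPTY)


def enumerate_precursor_adducts(preset: CrosslinkerPreset, max_len: int) -> List[PrecursorAdduct]:
    """All legal precursor adducts with 1..max_len nucleotides (+ the empty one).

    Each nucleotide multiset is optionally combined with up to
    ``preset.max_losses_per_adduct`` distinct loss species legal for it; the
    crosslinker remnant (if any) is added to every adduct.  The empty adduct
    (linear peptide) is always additionally emitted, as are any standalone
    sugar-phosphate adducts the preset declares (deoxyribose-phosphate
    species from abasic sites in DNA).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if max_len > preset.max_adduct_length:
        raise ValueError(
            f"max_len {max_len} exceeds preset.max_adduct_length {preset.max_adduct_length}"
        )
    raw: List[PrecursorAdduct] = []
    seen = set()

    def emit(name, codes, losses, comp, sugar=False):
        key = (name, losses)
        if key in seen:
            return
        seen.add(key)
        raw.append(PrecursorAdduct(name, codes, losses, comp.finalize(), sugar))

    for length in range(1, max_len + 1):
        for combo in itertools.combinations_with_replacement(sorted(preset.alphabet), length):
            base = EMPTY
            for code in combo:
                base = base + NMP[code]
            base = base + preset.remnant
            stem = "".join(combo)
            if preset.remnant_name:
                stem = f"{preset.remnant_name}+{stem}"
            legal = [l for l in preset.losses if l.legal_for(combo)]
            emit(stem, combo, (), base)
            for k in range(1, preset.max_losses_per_adduct + 1):
                for losses in itertools.combinations(legal, k):
                    comp = base
                    for l in losses:
                        comp = comp - l.composition
                    if comp.has_negative():
                        continue
                    lname = "".join(f"-{l.name}" for l in losses)
                    emit(stem + lname, combo, tuple(l.name for l in losses), comp)
    for sp in preset.sugar_phosphate_adducts:
        emit(sp.name, (), (), sp.composition, sugar=True)
    if preset.include_remnant_only and not preset.remnant.is_empty():
        emit(preset.remnant_name, (), (), preset.remnant)

    # merge exactly isobaric adducts into one ambiguity-class entry
    by_comp: Dict[ElementalComposition, List[PrecursorAdduct]] = {}
    for a in raw:
        by_comp.setdefault(a.composition, []).append(a)
    out: List[PrecursorAdduct] = [EMPTY_ADDUCT]
    for comp, members in by_comp.items():
        members.sort(key=lambda a: a.name)
        if len(members) == 1:
            out.append(members[0])
        else:
            rep = members[0]
            out.append(PrecursorAdduct(
                name="/".join(a.name for a in members),
                nucleotides=rep.nucleotides,
                losses=rep.losses,
                composition=comp,
                is_sugar_phosphate=all(a.is_sugar_phosphate for a in members),
                variants=tuple((a.nucleotides, a.losses) for a in members),
            ))
    out.sort(key=lambda a: (a.mass, a.name))
    return out


def fragment_adducts_for(preset: CrosslinkerPreset, precursor: PrecursorAdduct) -> List[AdductSpecies]:
    """Fragment adduct species legal under a given precursor adduct.

    A fragment can carry at most what the precursor carries, so every
    candidate species is filtered by elemental containment in the precursor
    adduct composition.  Formaldehyde presets (unstable peptide-FA bond)
    return the empty set, as does the empty (linear) adduct.
    """
    if precursor.is_empty or not preset.fragmentation_stable:
        return []
    candidates: List[AdductSpecies] = []
    if precursor.is_sugar_phosphate:
        candidates.extend(preset.sugar_phosphate_adducts)
    else:
        if not preset.remnant.is_empty():
            candidates.append(AdductSpecies(preset.remnant_name, preset.remnant, "remnant"))
        codes = sorted({c for nucs, _ in precursor.member_variants() for c in nucs})
        for code in codes:
            for sp in (preset.nucleotide_species(code), preset.base_species(code)):
                candidates.append(preset._with_remnant(sp))
                # loss variants of the species itself
                for l in preset.losses:
                    if not l.legal_for([code]):
                        continue
                    lost = sp.composition - l.composition
                    if lost.has_negative():
                        continue
                    candidates.append(
                        preset._with_remnant(AdductSpecies(f"{sp.name}-{l.name}", lost, sp.klass))
                    )
    # containment filter, then merge species that are themselves isobaric
    by_comp: Dict[ElementalComposition, List[AdductSpecies]] = {}
    for sp in candidates:
        if precursor.composition.contains(sp.composition):
            group = by_comp.setdefault(sp.composition, [])
            if all(sp.name != g.name for g in group):
                group.append(sp)
    out = []
    for comp, group in by_comp.items():
        group.sort(key=lambda s: s.name)
        name = "/".join(s.name for s in group)
        out.append(AdductSpecies(name, comp, group[0].klass) if len(group) > 1 else group[0])
    out.sort(key=lambda s: (s.mass, s.name))
    return out


def marker_ions_for(preset: CrosslinkerPreset, precursor: PrecursorAdduct) -> List[Tuple[str, float]]:
    """Singly charged marker ions expected for a precursor adduct.

    Nucleobase / nucleotide species (optionally carrying the crosslinker
    remnant) for every nucleotide in the adduct, each protonated once.
    Crosslinked immonium ions are peptide-dependent and therefore generated
    in theoretical-spectrum construction, not here.
    """
    species: List[Tuple[str, ElementalComposition]] = []
    for code in sorted({c for nucs, _ in precursor.member_variants() for c in nucs}):
        base = preset.base_species(code)
        nt = preset.nucleotide_species(code)
        species.append((base.name, base.composition))
        species.append((nt.name, nt.composition))
        if not preset.remnant.is_empty():
            species.append((f"{preset.remnant_name}+{base.name}", preset.remnant + base.composition))
            species.append((f"{preset.remnant_name}+{nt.name}", preset.remnant + nt.composition))
        for l in preset.losses:
            if not l.legal_for([code]):
                continue
            lost = base.composition - l.composition
            if not lost.has_negative():
                species.append((f"{base.name}-{l.name}", lost))
    if precursor.is_sugar_phosphate:
        species.extend((sp.name, sp.composition) for sp in preset.sugar_phosphate_adducts)

    # only species containable in the precursor adduct; merge exact isobars
    by_comp: Dict[ElementalComposition, List[str]] = {}
    for name, comp in species:
        if precursor.composition.contains(comp):
            names = by_comp.setdefault(comp, [])
            if name not in names:
                names.append(name)
    out = [("/".join(sorted(names)), mz(comp.mass, 1)) for comp, names in by_comp.items()]
    out.sort(key=lambda t: (t[1], t[0]))
    return out
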