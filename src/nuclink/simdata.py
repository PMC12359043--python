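"""Ground-truthed synthetic inputs for every other module.

The spectrum simulator samples the theoretical peaks of a chosen
peptide-adduct-site triple (log-normal intensities, optional peak dropout
and ppm jitter) and adds uniformly placed noise peaks, mirroring the anatomy
of real crosslink MS2 spectra: unshifted and adduct-shifted b/y ladders,
marker ions, precursor(+loss) peaks and (crosslinked) immonium ions.  Truth
records carry the elemental-composition class of the planted adduct so that
evaluation never penalizes confusions between exactly isobaric species
(cytidine-NH3 versus uridine-H2O).

The structure simulator plants nucleotide pseudo-residues at exact distances
from designated protein residues on a straight C-alpha trace with sites
spaced far apart, so occurrence counts are known by construction.

Everything is deterministic under a fixed seed.  The noise model is
deliberately simple (uniform m/z, log-normal intensity) — sufficient to
stress matching and FDR control, not a physical model of an instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .chem import PROTON, mz as to_mz
from .presets import (
    EMPTY_ADDUCT,
    CrosslinkerPreset,
    PrecursorAdduct,
    enumerate_precursor_adducts,
    get_preset,
)
from .search import CrosslinkCandidate, theoretical_peaks
from .seqdb import PeptideCandidate, ProteinEntry, digest
from .spectra import MsnSpectrum
from .structmap import StructureModel, XLSiteRecord


@dataclass
class SimulationConfig:
    seed: int = 0
    n_spectra: int = 100
    fraction_crosslinked: float = 0.5
    preset_id: str = "RNA-UV"
    max_adduct_length: int = 1
    noise_peaks: float = 0.0          # Poisson mean per spectrum
    dropout: float = 0.0              # per-peak dropout probability
    intensity_mu: float = 4.0         # log-normal (natural log) parameters
    intensity_sigma: float = 0.7
    ppm_jitter_sd: float = 0.0
    charges: Tuple[int, ...] = (2, 3)
    min_peptide_len: int = 6
    max_peptide_len: int = 20
    include_sugar_adducts: bool = False

    def __post_init__(self):
        for p in (self.fraction_crosslinked, self.dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


TRUTH_COLUMNS = [
    "spectrum_id", "peptide", "adduct", "adduct_class", "site", "charge",
    "is_xl", "is_entrapment",
]


def simulate_spectrum(
    peptide: PeptideCandidate,
    adduct: PrecursorAdduct,
    site: Optional[int],
    preset: CrosslinkerPreset,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    charge: int = 2,
) -> Tuple[MsnSpectrum, Dict]:
    """One synthetic MS2 spectrum plus its truth record."""
    candidate = CrosslinkCandidate(peptide, adduct, preset.id)
    peaks = theoretical_peaks(candidate, preset, charge, site=site)
    mzs, intens = [], []
    for p in peaks:
        if cfg.dropout > 0 and rng.random() < cfg.dropout:
            continue
        m = p.mz
        if cfg.ppm_jitter_sd > 0:
            m *= 1.0 + rng.normal(0.0, cfg.ppm_jitter_sd) * 1e-6
        mzs.append(m)
        intens.append(rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma))
    n_noise = rng.poisson(cfg.noise_peaks) if cfg.noise_peaks > 0 else 0
    if n_noise:
        hi = to_mz(candidate.total_mass, 1)
        mzs.extend(rng.uniform(100.0, hi, n_noise))
        intens.extend(rng.lognormal(cfg.intensity_mu - 0.5, cfg.intensity_sigma, n_noise))
    pmz = to_mz(candidate.total_mass, charge)
    if cfg.ppm_jitter_sd > 0:
        pmz *= 1.0 + rng.normal(0.0, cfg.ppm_jitter_sd / 2.0) * 1e-6
    spectrum = MsnSpectrum(
        native_id=spectrum_id,
        precursor_mz=pmz,
        precursor_charge=charge,
        retention_time=0.0,
        mz=np.array(mzs, dtype=np.float64),
        intensity=np.array(intens, dtype=np.float64),
    )
    truth = {
        "spectrum_id": spectrum_id,
        "peptide": peptide.sequence,
        "adduct": adduct.name,
        "adduct_class": adduct.composition.formula(),
        "site": -1 if site is None else site,
        "charge": charge,
        "is_xl": int(not adduct.is_empty),
        "is_entrapment": 0,
    }
    return spectrum, truth


def _sim_peptides(proteins: Sequence[ProteinEntry], cfg: SimulationConfig) -> List[PeptideCandidate]:
    out = []
    for prot in proteins:
        out.extend(
            digest(prot, "Trypsin/P", max_missed_cleavages=0,
                   min_len=cfg.min_peptide_len, max_len=cfg.max_peptide_len)
        )
    if not out:
        raise ValueError("no peptides of simulatable length in the protein source")
    return sorted(out, key=lambda p: (p.sequence, sorted(p.accessions)))


def simulate_dataset(
    cfg: SimulationConfig,
    proteins: Sequence[ProteinEntry],
    entrapment_proteins: Optional[Sequence[ProteinEntry]] = None,
    entrapment_fraction: float = 0.0,
) -> Tuple[List[MsnSpectrum], pd.DataFrame]:
    """A mixture of crosslinked and linear spectra with a truth table.

    ``entrapment_fraction`` of spectra are drawn from
    ``entrapment_proteins`` — peptides absent from the searched database —
    providing a null population for FDR calibration.
    """
    preset = get_preset(cfg.preset_id)
    rng = np.random.default_rng(cfg.seed)
    peptides = _sim_peptides(proteins, cfg)
    foreign = _sim_peptides(entrapment_proteins, cfg) if entrapment_proteins else []
    adducts = [
        a for a in enumerate_precursor_adducts(preset, cfg.max_adduct_length)
        if not a.is_empty and (cfg.include_sugar_adducts or not a.is_sugar_phosphate)
    ]
    spectra: List[MsnSpectrum] = []
    truth_rows: List[Dict] = []
    for i in range(cfg.n_spectra):
        entrap = bool(foreign) and rng.random() < entrapment_fraction
        pool = foreign if entrap else peptides
        pep = pool[rng.integers(len(pool))]
        is_xl = rng.random() < cfg.fraction_crosslinked
        adduct = adducts[rng.integers(len(adducts))] if is_xl else EMPTY_ADDUCT
        site = int(rng.integers(len(pep.sequence))) if is_xl and preset.fragmentation_stable else None
        charge = int(rng.choice(cfg.charges))
        spectrum, truth = simulate_spectrum(
            pep, adduct, site, preset, cfg, rng, f"sim={cfg.seed}.{i}", charge
        )
        truth["is_entrapment"] = int(entrap)
        spectra.append(spectrum)
        truth_rows.append(truth)
    return spectra, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def write_dataset(
    out_prefix: str,
    spectra: Sequence[MsnSpectrum],
    truth: pd.DataFrame,
    proteins: Optional[Sequence[ProteinEntry]] = None,
) -> Dict[str, str]:
    """Write mzML + truth TSV (+ optional FASTA); returns the paths."""
    from ._mzml import write_mzml

    paths = {"mzml": f"{out_prefix}.mzML", "truth": f"{out_prefix}.truth.tsv"}
    write_mzml(paths["mzml"], list(spectra))
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if proteins is not None:
        paths["fasta"] = f"{out_prefix}.fasta"
        with open(paths["fasta"], "w") as fh:
            for p in proteins:
                fh.write(f">{p.accession}\n{p.sequence}\n")
    return paths


_AA_FREQ = "ACDEFGHIKLMNPQRSTVWY"


def random_proteins(n: int, length: int, seed: int, prefix: str = "SIM") -> List[ProteinEntry]:
    """Random protein sequences with tryptic sites guaranteed roughly every
    ten residues (K/R inserted), usable as a synthetic database."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        letters = [ _AA_FREQ[j] for j in rng.integers(0, len(_AA_FREQ), length) ]
        for pos in range(9, length, 10):
            letters[pos] = "K" if rng.random() < 0.5 else "R"
        out.append(ProteinEntry(f"{prefix}{i:03d}", "".join(letters)))
    return out


# ---------------------------------------------------------------------------
# Toy structures with planted distances
# ---------------------------------------------------------------------------

_SITE_SPACING = 16          # residues between designated sites (~61 A apart)
_CA_STEP = 3.8              # A between consecutive C-alphas on the trace

_NUC_FOR_XL = {"UV": "U", "DEB": "G", "NM": "G"}


def simulate_structure(
    planted: Sequence[Tuple[str, Sequence[float]]],
    seed: int = 0,
    n_residues: Optional[int] = None,
    csm_count: int = 3,
) -> Tuple[StructureModel, List[XLSiteRecord]]:
    """Protein C-alpha trace with nucleotides at exact planted distances.

    ``planted`` is one entry per crosslink site: (crosslinker, distances);
    each distance places one nucleotide residue whose designated base
    nitrogen (N3 pyrimidine / N7 purine) sits exactly that far from the
    site's C-alpha.  Sites are spaced widely enough that cross-site
    distances exceed all default thresholds+slacks.
    """
    if any(d < 0 for _, ds in planted for d in ds):
        raise ValueError("planted distances must be >= 0")
    rng = np.random.default_rng(seed)
    n_sites = len(planted)
    n_res = n_residues or (n_sites * _SITE_SPACING + 8)
    st = gemmi.Structure()
    st.name = f"synthetic-{seed}"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    ca_positions = []
    for i in range(n_res):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        pos = np.array([i * _CA_STEP, 0.0, 0.0])
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        chain.add_residue(res)
        ca_positions.append(pos)
    model.add_chain(chain)

    nchain = gemmi.Chain("B")
    sites: List[XLSiteRecord] = []
    nuc_num = 0
    for k, (crosslinker, distances) in enumerate(planted):
        res_idx = 4 + k * _SITE_SPACING
        ca = ca_positions[res_idx]
        sites.append(XLSiteRecord("A", res_idx + 1, "A", crosslinker, csm_count=csm_count))
        for d in distances:
            nuc_num += 1
            name = _NUC_FOR_XL.get(crosslinker, "U")
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(nuc_num, " ")
            # random direction in the y-z plane keeps cross-site distances large
            phi = rng.uniform(0, 2 * math.pi)
            u = np.array([0.0, math.cos(phi), math.sin(phi)])
            npos = ca + d * u
            natom = gemmi.Atom()
            natom.name = "N3" if name in ("U", "C") else "N7"
            natom.element = gemmi.Element("N")
            natom.pos = gemmi.Position(*npos)
            res.add_atom(natom)
            # a second atom strictly farther from the site's C-alpha
            extra = gemmi.Atom()
            extra.name = "C1'"
            extra.element = gemmi.Element("C")
            extra.pos = gemmi.Position(*(ca + (d + 1.5) * u))
            res.add_atom(extra)
            nchain.add_residue(res)
    model.add_chain(nchain)
    st.add_model(model)
    return StructureModel(st, model_id=st.name), sites


def apply_rigid_transform(model: StructureModel, seed: int = 0) -> StructureModel:
    """Random rotation + translation of all atoms (distance-preserving)."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))          # proper orthogonal
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-50, 50, 3)
    st = model.structure.clone()
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    atom.pos = gemmi.Position(*(q @ p + t))
    return StructureModel(st, model_id=model.model_id + "-transformed")
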