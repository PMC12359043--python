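# Methods

`nuclink` identifies crosslink-spectrum matches (CSMs) between tryptic (or
chymotryptic) peptides and (oligo)nucleotide adducts in centroided MS2
spectra, for UV crosslinking and for three alkylating crosslinkers
(1,2:3,4-diepoxybutane, DEB; mechlorethamine / nitrogen mustard, NM;
formaldehyde, FA) on RNA and DNA. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Mass model

All species are integer element-count vectors over a hard-coded table of
monoisotopic masses (H 1.0078250319, C 12 exactly, N 14.0030740052,
O 15.9949146221, P 30.97376151, S 31.97207069). Masses are linear in
counts, so species with identical elemental composition are *exactly*
isobaric rather than equal to a tolerance. Two consequences drive the
engine's behaviour:

* cytidine monophosphate − NH3 and uridine monophosphate − H2O are one
  composition (C9H11N2O8P); no mass spectrometer can separate them, so the
  engine merges them into a single ambiguity-class candidate named
  `C-NH3/U-H2O` and reports it as such;
* deoxy-GMP and AMP are one composition, an ambiguity inherited by any
  mixed RNA/DNA interpretation.

Nucleotide adducts are nucleoside-monophosphate residues (UMP C9H13N2O9P,
CMP C9H14N3O8P, AMP C10H14N5O7P, GMP C10H14N5O8P; dNMPs = NMP − O;
dTMP C10H15N2O8P). m/z is always (M + z·1.00727646688)/z.

## Crosslinker presets

A preset fixes, per crosslinker and nucleic-acid type: the nucleotide
alphabet, the crosslinker remnant composition, the legal neutral losses
with the nucleotides they apply to, and how fragment adducts and marker
ions derive from a precursor adduct. Default remnants follow standard
alkylation chemistry: DEB C4H6O2 (86.03678 Da, epoxide ring opening), NM
C5H9N (83.07350 Da, mechlorethamine − 2 HCl), FA a single carbon
(CH2O − H2O: the net methylene bridge). UV crosslinks are zero-length
(empty remnant). DNA presets additionally carry the standalone
deoxyribose-phosphate adducts C5H9O6P (196.01368 Da) and its dehydrated
form C5H7O5P (178.00311 Da), which arise from abasic sites.

Precursor adducts are enumerated as all nucleotide multisets up to a
configurable length (default search depth 2; simulations use 1), each
combined with at most two distinct loss species legal for that multiset,
plus the remnant. A fragment adduct is legal only if its composition is an
element-wise sub-multiset of the precursor adduct — a fragment cannot carry
what the precursor does not have — and the same containment rule prunes
marker ions (a precursor that lost NH3 from cytosine cannot emit intact
protonated cytosine). Formaldehyde crosslinks do not survive collisional
activation, so FA presets map every precursor adduct to the empty fragment
set and rely on marker ions and precursor evidence only.

The exact default/extended adduct lists shipped by production search tools
are instrument- and protocol-dependent; here they are chemistry-derived
defaults, overridable via a YAML preset config (alphabet, remnant, losses,
adduct length, reactive residues). Two Met-specific losses (CH4S and
C2H2S) are both registered for DEB/NM presets and emitted as optional
precursor-loss peaks when the peptide contains methionine; the literature
reports both and neither is clearly canonical. Thio-nucleoside presets
(4SU/6SG) are declared ids without default species.

## Search and scoring

Peptides come from an in-silico digest (Trypsin/P after K/R,
Chymotrypsin/P after F/W/Y/L, no proline restriction; defaults: ≤2 missed
cleavages, length 5–30, ≤2 variable Met oxidations, optional fixed
carbamidomethyl-Cys). Decoys are full-sequence reversals, one per target.
Candidates (peptide × precursor adduct, including the empty adduct for
linear peptides) are indexed by neutral mass and retrieved by binary
search within the precursor tolerance (default 6 ppm; fragment tolerance
10 ppm, both exposed on the CLI — Orbitrap-class acquisition).

The theoretical spectrum of a candidate contains unshifted b/y ions at
fragment charges 1..min(z−1, 2); for crosslinked candidates, b/y ions
shifted by each legal fragment adduct; marker ions; the precursor with its
legal losses at the observed charge; and immonium ions of His/Met/Tyr plus
crosslinked immonium variants for the preset's reactive residues.
Matching is greedy nearest-ppm with each observed and each theoretical
peak used at most once (prevents double-counted intensity). The main
score is hyperscore-style:

    ln(Nb!) + ln(Ny!) + ln(1 + matched_intensity / TIC)

with the factorial arguments capped at 20, where Nb/Ny count matched b/y
ions over both ladders. The functional form is a declared design choice
(a config hook allows swapping kernels); the subscore *classes* — shifted
and unshifted ion counts, explained intensity fraction, marker-ion count,
precursor evidence, mean |ppm| error, longest consecutive ladder, plus
covariates (length, charge, missed cleavages, adduct mass, crosslinked
flag) — are what the rescoring consumes.

## Localization

Localization runs post hoc on rank-1 crosslinked CSMs of
fragmentation-stable presets, enumerating *all* residues (restricting to
chemically plausible residues would hide unexpected reactivity, e.g. Glu
with DEB). Site evidence E(p) counts matched fragment peaks consistent
with an adduct at p — shifted fragments covering p, unshifted fragments
not covering p — that are site-determining (inconsistent with at least one
alternative site; the weaker "at least one" criterion keeps E monotone in
matched evidence), plus 1 for a matched crosslinked immonium ion of the
residue type at p. The localization score is E(best) − E(second best);
loc_score ≥ 1 therefore means at least one discriminating peak separates
the top two sites. Exact ties leave the site unset.

## Rescoring and FDR

Subscores are combined by a semi-supervised, cross-validated loop:
positives are initialized as targets at ≤1% FDR on the main score against
all decoys; a regularized logistic regression (a linear discriminant —
deterministic and dependency-light, same contract as an SVM-based
re-ranker) is fitted per fold (3 folds by spectrum-id hash, 3 iterations),
and every CSM is scored only by a model not trained on its fold. The main
score competes as a candidate direction: if the learned discriminant
admits fewer targets at 1% FDR, the main score is kept, so rescoring never
loses identifications. Fewer than 50 decoys ⇒ fall back to the main score
with a warning.

q-values use the (decoys + 1)/targets estimator with a running minimum
from the bottom; the +1 keeps every q strictly positive, which means very
small runs (under ~100 targets per class) cannot reach q ≤ 0.01 at all —
intended conservatism, not a defect. Crosslinked and linear CSMs form
separate FDR classes by default (their score distributions differ grossly;
pooling is anti-conservative for the crosslinked class) with a
`--pooled-fdr` flag for the pooled variant. Peptide-level reporting keeps
the best CSM per (peptide, modification pattern, adduct composition
class) and re-thresholds. Protein groups merge accessions with identical
peptide sets and assign shared peptides by greedy maximum coverage;
protein-level output is counts, not a protein FDR.

## Structure mapping

Localized sites (1-based residue numbers in author/PDB numbering) are
mapped onto PDB/mmCIF models (gemmi; highest-occupancy altloc only).
Distances run from the residue Cα either to the crosslink-bearing base
nitrogen — N3 for pyrimidines, N7 for purines (`n3n7`, the model-
validation convention) — or to the closest atom of the closest nucleotide
(`closest_atom`, the survey convention). The two conventions answer
different questions, so the mode is a mandatory CLI argument. Thresholds
are crosslinker-specific (UV 10 Å; DEB and NM 15 Å, matching spacer
lengths) with incremental slacks of 0/2/3/5 Å for conformational
flexibility. SINGLE(dk) counts sites whose nearest nucleotide is within
threshold+slack; ALL(dk) counts every (site, nucleotide residue) pair
within it (one count per nucleotide residue, regardless of how many of its
atoms qualify). Models are ranked by how many of the eight columns (d0,
d2, d3, d5, ALLd0..ALLd5) equal the column maximum, ties broken by total
occurrence sum then model id — the tie-breaks beyond the column-maxima
rule are declared choices. Site pre-filters (CSM count > 2 for model
validation; localization score ≥ 1 for surveys) are independent flags.

## Synthetic data

The generator is first-class, tested code; it defines the conditions every
other module is tested under. Spectra are sampled from the theoretical
peaks of a planted (peptide, adduct, site) triple with log-normal
intensities (ln-scale μ 4.0, σ 0.7 — arbitrary units), optional per-peak
dropout, Gaussian ppm jitter, and Poisson-distributed noise peaks placed
uniformly in m/z. Entrapment mode draws spectra from peptides absent from
the searched database, giving a ground-truth null for FDR calibration.
Everything is deterministic under a fixed seed, including file bytes.

Default study conditions used by the tests and the acceptance script:
noise-free closure runs use 200 spectra (50 per crosslinker preset,
adduct length 1, tryptic peptides of 6–20 residues from ten 120-residue
random proteins); calibration runs use 20 seeds × 500 spectra against a
20-protein database with 25 noise peaks, 40% peak dropout, 3 ppm jitter
and 25% entrapment spectra. These sizes make every property checkable in
seconds while leaving enough statistics (~7000 pooled acceptances) for a
binomial check of the 1% FDR level.

What the simulator does *not* model — isotope envelopes, correlated
fragment intensities, retention time, chimeric spectra, real instrument
noise — bounds what passing tests show: they validate the inference
machinery (scoring, localization, FDR control) under known truth, not
performance on any particular instrument or sample.

Toy structures place nucleotide pseudo-residues at exact planted distances
from designated residues on a straight Cα trace with sites spaced ~61 Å
apart, so occurrence counts are known by construction and invariant under
the random placement directions.

## Numerical and degenerate-input choices

* Factorial arguments in the main score cap at 20 (lgamma overflow guard
  and saturation of the count evidence).
* Greedy peak assignment breaks ties by smallest |ppm|, then input order
  (deterministic because theoretical peaks are generated in a fixed
  order).
* Search ties on the main score break by more matched peaks, then
  lexicographic peptide, then adduct name, decoys last.
* Empty spectra score 0 and produce no localization; palindromic decoys
  are retained so decoy counts stay exactly equal to target counts;
  peptides containing non-canonical residues (X, B, ...) are excluded from
  candidates.
* Spectrum preprocessing (top-20 peaks per 100 m/z, ≥10 peaks) is
  idempotent and never alters retained peak values. No deisotoping by
  default; matching tolerances absorb isotope error at 30k resolution.

## Known limitations

* mzML I/O is a minimal reader/writer pair (64/32-bit float, zlib or
  plain, base64) sufficient for centroided MS2 round trips, not a general
  mzML toolkit.
* a/c/z ion series, chimeric deconvolution, semi-tryptic digestion and
  open mass-offset search are out of scope.
* The remnant-only (hydrolyzed mono-link) precursor species is off by
  default and config-enabled.
* Protein-level FDR is not estimated (counts only).
* Solvent-accessible-surface distances are not computed; all structure
  distances are Euclidean.
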