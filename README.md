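# nuclink

A search engine for **peptide–(oligo)nucleotide crosslinks** in tandem mass
spectrometry data. It identifies crosslink-spectrum matches (CSMs) from
centroided MS2 spectra for UV crosslinking and for the alkylating
crosslinkers 1,2:3,4-diepoxybutane (DEB), mechlorethamine / nitrogen
mustard (NM) and formaldehyde (FA), on both RNA and DNA, with
target-decoy FDR control, crosslink-site localization at amino-acid
resolution, and downstream mapping of localized sites onto 3D structures.

It is written for people studying protein–nucleic-acid interactions by
crosslinking mass spectrometry (XL-MS): which proteins touch RNA or DNA,
through which residues, to which nucleotides — and whether a proposed 3D
model of the complex is compatible with the measured crosslinks.

## The model

A crosslinked precursor is a peptide carrying an (oligo)nucleotide mass
adduct: 1–3 nucleoside monophosphates, minus up to two neutral losses,
plus a crosslinker remnant (DEB C4H6O2, NM C5H9N, FA net CH2; UV is
zero-length). All chemistry is exact integer element-count algebra, so
exactly isobaric species collapse into one ambiguity class — cytidine−NH3
and uridine−H2O are a single candidate `C-NH3/U-H2O` (one composition,
C9H11N2O8P), and deoxy-GMP equals AMP.

Spectra are matched against candidates within a 6 ppm precursor window
using unshifted and adduct-shifted b/y ladders, crosslinker-specific
marker ions (nucleobase / nucleotide / remnant+base, e.g. `NM+G'`), and
(crosslinked) immonium ions, at 10 ppm fragment tolerance. The main score
is hyperscore-style,

    score = ln(Nb!) + ln(Ny!) + ln(1 + matched intensity fraction)

over both ladders (factorials capped at 20). A subscore vector feeds a
Percolator-style semi-supervised rescoring (cross-validated linear
discriminant); q-values use the (decoys+1)/targets estimator, computed
separately for crosslinked and linear matches. The crosslinked residue is
localized from site-determining shifted/unshifted fragments and
crosslinked immonium ions; `loc_score >= 1` means at least one
discriminating peak separates the best site from the runner-up (FA forms
no stable fragment adducts, so FA crosslinks identify the peptide but not
the residue).

Localized sites map onto PDB/mmCIF models: Cα-to-nucleotide distances
(N3/N7 convention or closest-atom convention), occurrence counts within
crosslinker-specific thresholds (UV 10 Å, DEB/NM 15 Å) plus 0/2/3/5 Å
slacks (d0/d2/d3/d5 and ALLd0..ALLd5), and a column-maxima ranking of
alternative models. See `docs/methods.md` for the full account.

## Worked example

Simulate a ground-truthed NM-crosslinked dataset and search it:

```sh
nuclink simulate --out-prefix demo --preset RNA-NM --n-spectra 300 \
    --adduct-length 1 --noise-peaks 20 --dropout 0.3 --ppm-jitter-sd 2 \
    --n-proteins 15 --protein-length 150 --seed 42
nuclink search demo.mzML demo.fasta --preset RNA-NM --adduct-length 1 --out-dir out
```

which logs one line per stage:

```
[nuclink] simulated: spectra=300 xl=148 mzml=demo.mzML truth=demo.truth.tsv fasta=demo.fasta
[nuclink] database: proteins=15 with_decoys=30
[nuclink] index: peptides=3421 adducts=15 candidates=51315
[nuclink] spectra: read=300
[nuclink] search: spectra_matched=300
[nuclink] rescore: csms=300 targets_at_fdr=300
[nuclink] inference: peptides_at_fdr=147 protein_groups=15
```

`out/csms.tsv` holds one row per rank-1 CSM; the first identification:

```
spectrum_id  peptide     adduct  charge  main_score  best_site  loc_score  q_value
sim=42.0     CGLEDVINMR  NM+C    3       85.31       5          7.0        0.0068
```

read as: spectrum `sim=42.0` matches peptide CGLEDVINMR carrying a
nitrogen-mustard–cytidine adduct (+406.1254 Da) at charge 3; the
crosslink localizes to residue 5 (Asp; `best_site` is 1-based in the
reports) with an evidence margin of 7 peaks, at a CSM q-value of 0.68%.
`out/peptides.tsv` and `out/proteins.tsv` give the peptide-level
(best CSM per peptide × adduct class, 1% FDR) and protein-group reports;
`manifest.json` records every parameter.

Map localized sites onto a structure and rank alternative models:

```sh
nuclink structmap model.pdb sites.tsv --mode n3n7
nuclink rank-models model_A.pdb model_B.pdb --sites sites.tsv --mode n3n7
```

`structmap` prints per-crosslinker median distances and writes the
d0/d2/d3/d5 and ALLd0..ALLd5 occurrence counts; `rank-models` scores each
model by how many of those eight columns reach the column maximum (8 =
best on every criterion).

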