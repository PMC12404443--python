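# ardscan

Burial-versus-variability missense analysis for channel ankyrin repeat
domains (ARDs), with the functional-assay quantification used to follow up
candidate residues.

## The problem

Population sequence databases such as gnomAD record, for every residue of a
protein, which alternate amino acids occur in the human population and how
many alleles carry each. Across the cytosolic ARD of the heat- and
capsaicin-gated cation channel TRPV1, the number of distinct missense amino
acids at a residue rises with that residue's solvent exposure: buried side
chains tolerate fewer substitutions. A *buried* residue that nonetheless
carries many variant types — while staying strictly conserved across
orthologs — is a structural anomaly worth an experiment. The canonical
example is the partially buried methionine M308 (rat numbering; M309 in
human TRPV1), which carries four variant types (Val:121, Thr:8, Ile:2,
Arg:2 alleles) despite ranking 35th most buried of the 251 ARD residues.

`ardscan` turns that reading into a tested pipeline:

1. **variants** — parse HGVS p. consequences from a gnomAD-style CSV,
   map numbering between orthologs (constant offset), and aggregate
   per-residue variant spectra.
2. **structure/SASA** — read PDB/mmCIF structures (gemmi) and compute
   per-atom solvent-accessible surface area with a deterministic
   Shrake–Rupley implementation (golden-spiral point set, probe 1.4 Å,
   960 points); per-residue fractional SASA uses the Tien et al. (2013)
   theoretical maxima.
3. **burial profile** — rank residues by fractional SASA, smooth
   variant-type counts with a centered 20-wide moving mean along the rank
   axis, and score burial/variability discordance with permutation
   p-values (plus a conditional permutation test for a pre-specified
   residue). Alignment-column identity quantifies conservation.
4. **functional assays** — Hill fits of capsaicin dose–response relations
   (I = Imax·[L]ⁿ/(EC50ⁿ+[L]ⁿ), all three parameters free), half-amplitude
   single-channel open probability on baseline-subtracted concatenated
   +80 mV segments, approximate macroscopic Po, and 2 °C-binned
   current–temperature relations normalized to the room-temperature mean.
5. **cell responses** — classify calcium-imaging traces into capsaicin
   responders / ionomycin-only / excluded by a ΔF/F₀ ≥ θ rule and compute
   control-normalized response fractions.
6. **synthetic data** — generate every input above (variant tables with
   SASA-coupled rates, ideal-helix PDBs, two-state Markov channel records,
   Hill dose–response tables, van 't Hoff temperature ramps, cell fields)
   with explicit seeds, so the whole pipeline runs offline.

## Worked example

```python
import ardscan as a

rows = [("p.Met309Val", 121), ("p.Met309Thr", 8),
        ("p.Met309Ile", 2), ("p.Met309Arg", 2)]
variants = [a.MissenseVariant(*a.parse_protein_consequence(h), ac)
            for h, ac in rows]
spectra = a.build_spectra(variants, a.HUMAN_TO_RAT_TRPV1)  # human -> rat
spectrum = spectra[308]
print(a.variant_type_count(spectrum))        # 4
print(max(spectrum.counts.values()))         # 121
print(a.normalized_spectrum(spectrum)["T"])  # 0.06611570247933884
```

Four variant types at one buried methionine, with valine dominating the
allele counts (the threonine bar is 121-fold smaller once normalized to
the most common substitution) — the signature that makes the position an
outlier once joined with its burial rank.

The same analysis end-to-end on synthetic data:

```sh
ardscan simulate structure --n-residues 40 --out helix.pdb
ardscan sasa --structure helix.pdb --out sasa.tsv
ardscan simulate variants --seed 2 --n-residues 40 --out gnomad.csv
ardscan variants --gnomad gnomad.csv --out spectra.tsv
ardscan burial --sasa sasa.tsv --spectra spectra.tsv --out burial.tsv
```

`burial.tsv` holds one row per residue: burial rank, fractional SASA, raw
and smoothed variant-type counts, discordance score and permutation
p-value.

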