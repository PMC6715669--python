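# mirms

A MALDI-TOF mass-spectrometry toolkit for detecting, site-localizing and
quantifying methyl marks on mature miRNAs.

Methylated miRNA species appear in negative-ion MALDI-TOF spectra as peaks
offset by +14 Da (one CH2 per methyl, 14.01565 Da monoisotopic) from the
predicted unmethylated mass. `mirms` implements the computational workflow
around that observation:

- **`rna_mass`** — elemental composition, monoisotopic/average mass, m/z and
  unit-mass isotope envelopes for modified RNA oligos (m6A, m1A, m5C, m3C).
- **`fragmentation`** — theoretical MS/MS fragment ladders (a/a-B/b/c/d from
  the 5' end, w/x/y/z from the 3' end).
- **`spectra_io`** — TSV peak lists, minimal mzML reading, centroiding with a
  robust (MAD) local-noise SNR rule, linear mass recalibration.
- **`detect_quant`** — intact-species prediction (0..k methyls, Na/K
  adducts), ppm-tolerance peak matching, methylation-fraction estimation,
  synthetic-standard calibration, isotope-overlap correction.
- **`site_localization`** — methyl-site assignment from MS/MS ladders, plus
  derivatization logic: hydrazine cleavage patterns (m5C protection) and
  dimethyl-sulfate shift classification (m6A vs m1A).
- **`synthesize`** — seeded simulators for intact spectra, MS/MS ladders,
  calibration dilution series and case/control cohorts.
- **`cohort_analysis`** — RIP-Seq consensus intersection (RPM + IP/input
  enrichment calls), paired t / Wilcoxon comparison, tie-corrected ROC/AUC.

## Conventions

- Sequences are RNA over `{A, C, G, U}` (`T` is read as `U`).
- Modification positions are **1-based from the 5' end**.
- Mature miRNAs default to **5'-phosphate / 3'-hydroxyl** termini.
- Only **negative-ion** m/z is computed (`[M - zH]^(z-)`); positive mode is
  an explicit error.
- The methylation fraction is the methylated share of total matched
  intensity, `sum_{k>=1} I_k / sum_k I_k`; when no methylated species is
  detected the fraction is reported as **0 with a below-detection flag**.
- Peak-list TSV dialect: UTF-8, tab-separated, dot decimal, header
  `mz<TAB>intensity` (optional third `snr` column).

## CLI

```sh
# neutral mass of a methylated oligo (m6A at position 13)
mirms mass --seq CAAAGUGCUUACAGUGCAGGUAG --mods 13:m6A

# theoretical MS/MS ladder
mirms fragments --seq UGAGGUAGUAGGUUGUAUAGUU --series c,y,w,a-B --out ladder.tsv

# match intact species and report the methylation fraction
mirms detect --peaks peaks.tsv --id hsa-miR-17-5p --kmax 3 --tol-ppm 50 --adducts Na,K

# localize the methyl site from an MS/MS peak list
mirms localize --msms msms.tsv --seq UGAGGUAGUAGGUUGUAUAGUU --mod m6A --tol-ppm 100

# type an adenine methyl from the post-DMS mass shift
mirms classify-adenine --seq AUAUAUAGGAC --shift 70.08

# simulators (seeded, deterministic)
mirms simulate cohort --n-case 20 --n-control 20 --case-mean 0.6 \
    --control-mean 0.2 --sd 0.1 --seed 17 --out cohort.tsv

# downstream stages
mirms compare cohort.tsv              # paired t-test
mirms roc cohort.tsv --plot roc.png   # AUC + curve
mirms consensus --counts s1.tsv --counts s2.tsv --min-rpm 1 --min-enrichment 2
```

`mirms simulate intact|msms|calibration` take a YAML config, e.g.

```yaml
sequence: UAAUACUGCCGGGUAAUGAUGGA
modifications: [[9, m5C]]
fractions: {0: 0.5, 1: 0.5}
mass_error_ppm: 20
intensity_cv: 0.05
adduct_rates: {Na: 0.1}
```

## Notes & limitations

- Which MS/MS ion series dominate is instrument-dependent; the localization
  default `{c, y, w, a-B}` is a configurable engineering choice.
- The DMS model assumes a complete reaction at free adenine N1 and ignores
  guanine N7 reactivity; the localization score is a discriminating-fragment
  count, not a probability.
- Hydrazine cleavage is modeled as excision of every unprotected cytosine
  (upstream product 3'-phosphate, downstream 5'-phosphate). Placements whose
  cleavage products are compositional isomers are inherently
  mass-indistinguishable.
- 2'-O-methylation, non-methyl modifications, DNA chemistry and positive-ion
  mode are out of scope.
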